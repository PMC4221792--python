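"""Run configuration loading and result serialisation.

Configs are YAML (or JSON — a YAML subset) with three top-level keys:

.. code-block:: yaml

    profile:              # either an explicit profile ...
      p: [15, 10, 15]
      g_mbp: [4, 12, 2]   # or g_bp, never both
    # generator:          # ... or a generated one, never both
    #   s: 4
    #   n: 40
    #   skew: uniform
    #   size_range_mbp: [1, 12]
    #   seed: 7
    params:
      M_u: 5
      M_l: 0.3
      tau: 0.2
      safety_factor: 2
      root_assembly: max        # max | sum | <bp>
      coverage_summary: min     # min | mean_weighted
    seed: 1

Missing parameters default to the ensemble-analysis settings
``M_u=5, M_l=0.3, tau=0.2, safety_factor=2``.  Unknown keys are rejected.
Results are written as JSON (with the resolved config echoed) plus a
companion TSV flattening the capture distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .community import CommunityProfile, Parameters, make_profile
from .ensemble import CaptureDistribution

__all__ = ["RunConfig", "load_config", "parse_config", "write_result", "read_result"]

_PARAM_KEYS = {
    "M_u": "m_upper",
    "M_l": "m_lower",
    "tau": "tau",
    "safety_factor": "safety_factor",
    "root_assembly": "root_assembly",
    "coverage_summary": "coverage_summary",
}
_PROFILE_KEYS = {"p", "g_bp", "g_mbp"}
_GENERATOR_KEYS = {"s", "n", "skew", "size_range_bp", "size_range_mbp", "seed"}
_TOP_KEYS = {"profile", "generator", "params", "seed"}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one run."""

    profile: CommunityProfile
    params: Parameters
    seed: int
    resolved: dict[str, Any]  # echoable plain-data form


def _err(field: str, msg: str) -> ValueError:
    return ValueError(f"config field {field!r}: {msg}")


def parse_config(data: Mapping[str, Any]) -> RunConfig:
    """Validate a parsed config mapping and resolve defaults."""
    if not isinstance(data, Mapping):
        raise ValueError("config must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise _err(sorted(unknown)[0], "unknown key")
    has_profile = "profile" in data
    has_generator = "generator" in data
    if has_profile == has_generator:
        raise ValueError(
            "config must contain exactly one of 'profile' and 'generator'"
        )

    raw_params = dict(data.get("params") or {})
    unknown = set(raw_params) - set(_PARAM_KEYS)
    if unknown:
        raise _err(f"params.{sorted(unknown)[0]}", "unknown key")
    kwargs = {attr: raw_params[key] for key, attr in _PARAM_KEYS.items()
              if key in raw_params}
    try:
        params = Parameters(**kwargs)
    except ValueError as exc:
        raise ValueError(f"config params: {exc}") from exc

    if has_profile:
        spec = dict(data["profile"])
        unknown = set(spec) - _PROFILE_KEYS
        if unknown:
            raise _err(f"profile.{sorted(unknown)[0]}", "unknown key")
        if "p" not in spec:
            raise _err("profile.p", "required")
        if ("g_bp" in spec) == ("g_mbp" in spec):
            raise _err("profile", "exactly one of g_bp / g_mbp is required")
        g = spec.get("g_bp") or [x * 1e6 for x in spec["g_mbp"]]
        try:
            profile = CommunityProfile(spec["p"], g)
        except ValueError as exc:
            raise ValueError(f"config profile: {exc}") from exc
    else:
        spec = dict(data["generator"])
        unknown = set(spec) - _GENERATOR_KEYS
        if unknown:
            raise _err(f"generator.{sorted(unknown)[0]}", "unknown key")
        for req in ("s", "n"):
            if req not in spec:
                raise _err(f"generator.{req}", "required")
        if ("size_range_bp" in spec) and ("size_range_mbp" in spec):
            raise _err("generator", "give size_range_bp or size_range_mbp, not both")
        if "size_range_mbp" in spec:
            rng = tuple(x * 1e6 for x in spec["size_range_mbp"])
        else:
            rng = tuple(spec.get("size_range_bp", (1e6, 12e6)))
        try:
            profile = make_profile(
                s=spec["s"], n=spec["n"], size_range=rng,
                skew=spec.get("skew", "uniform"), seed=spec.get("seed", 0),
            )
        except ValueError as exc:
            raise ValueError(f"config generator: {exc}") from exc

    seed = int(data.get("seed", 0))
    resolved = {
        "profile": {"p": list(profile.p), "g_bp": list(profile.g)},
        "params": {
            "M_u": params.m_upper,
            "M_l": params.m_lower,
            "tau": params.tau,
            "safety_factor": params.safety_factor,
            "root_assembly": params.root_assembly,
            "coverage_summary": params.coverage_summary,
        },
        "seed": seed,
    }
    return RunConfig(profile=profile, params=params, seed=seed, resolved=resolved)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config file."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        raise ValueError(f"config {path} is empty")
    return parse_config(data)


def write_result(
    result: Mapping[str, Any],
    path: str | Path,
    capture: CaptureDistribution | None = None,
) -> None:
    """Write a result payload as JSON, plus a TSV of the capture vector.

    The TSV (``<path stem>.capture.tsv``) has columns
    ``bitstring / index / probability``.  If ``capture`` is given it must
    be nonempty.
    """
    path = Path(path)
    if capture is not None and len(capture.P) == 0:
        raise ValueError("refusing to write an empty capture distribution")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(dict(result), indent=2, sort_keys=True) + "\n")
    if capture is not None:
        tsv = path.with_suffix(".capture.tsv")
        lines = ["bitstring\tindex\tprobability"]
        for idx, (bits, q) in enumerate(zip(capture.labels(), capture.P), start=1):
            lines.append(f"q{bits}\t{idx}\t{q:.10g}")
        tsv.write_text("\n".join(lines) + "\n")


def read_result(path: str | Path) -> dict[str, Any]:
    """Re-read a JSON result written by :func:`write_result`."""
    return json.loads(Path(path).read_text())
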