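"""Run configuration: TOML/JSON parsing, validation, bundled presets."""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .params import BASE_PARAMS, StoichParams, validate_params

_MODEL_KEYS = {"b", "K", "e", "d", "q", "theta", "c", "a", "P_total", "p"}
_NOISE_KEYS = {"eps1", "eps2"}
_SIM_KEYS = {"t_end", "h", "seed", "n_reps"}
_SSF_KEYS = {"P_fid"}
_TOP_KEYS = {"model", "noise", "sim", "ssf", "output_dir"}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    params: StoichParams
    eps1: float = 0.0
    eps2: float = 0.0
    t_end: float = 200.0
    h: float = 1e-3
    seed: int = 0
    n_reps: int = 1
    P_fid: tuple[float, ...] = (0.95,)
    output_dir: str = "stoichswitch_out"

    def as_dict(self) -> dict:
        return {
            "model": self.params.as_dict(),
            "noise": {"eps1": self.eps1, "eps2": self.eps2},
            "sim": {"t_end": self.t_end, "h": self.h, "seed": self.seed,
                    "n_reps": self.n_reps},
            "ssf": {"P_fid": list(self.P_fid)},
            "output_dir": self.output_dir,
        }


def _require_number(section: str, key: str, value) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"[{section}] {key}: expected a number, got {value!r}")
    return float(value)


def _build_params(model: dict) -> StoichParams:
    unknown = set(model) - _MODEL_KEYS
    if unknown:
        raise ConfigError(f"[model] unknown keys: {sorted(unknown)}")
    missing = {"b", "K", "e", "d", "q", "theta", "c", "a"} - set(model)
    if missing:
        raise ConfigError(f"[model] missing keys: {sorted(missing)}")
    has_P = "P_total" in model
    has_p = "p" in model
    if has_P == has_p:
        raise ConfigError("[model] exactly one of P_total or p must be given")
    vals = {k: _require_number("model", k, v) for k, v in model.items()}
    if has_p:
        p = vals.pop("p")
        params = StoichParams.from_p(**vals, p=p)
    else:
        params = StoichParams(**vals)
    violations = validate_params(params)
    if violations:
        raise ConfigError("model assumptions violated: " + "; ".join(violations))
    return params


def from_dict(data: dict) -> RunConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if "model" not in data:
        raise ConfigError("missing [model] section")
    params = _build_params(dict(data["model"]))

    kw: dict = {"params": params}
    noise = dict(data.get("noise", {}))
    if set(noise) - _NOISE_KEYS:
        raise ConfigError(f"[noise] unknown keys: {sorted(set(noise) - _NOISE_KEYS)}")
    for k in noise:
        kw[k] = _require_number("noise", k, noise[k])
    sim = dict(data.get("sim", {}))
    if set(sim) - _SIM_KEYS:
        raise ConfigError(f"[sim] unknown keys: {sorted(set(sim) - _SIM_KEYS)}")
    for k in sim:
        v = _require_number("sim", k, sim[k])
        kw[k] = int(v) if k in ("seed", "n_reps") else v
    ssf = dict(data.get("ssf", {}))
    if set(ssf) - _SSF_KEYS:
        raise ConfigError(f"[ssf] unknown keys: {sorted(set(ssf) - _SSF_KEYS)}")
    if "P_fid" in ssf:
        pf = ssf["P_fid"]
        if isinstance(pf, (int, float)):
            pf = [pf]
        pf = tuple(_require_number("ssf", "P_fid", v) for v in pf)
        if any(not 0 < v < 1 for v in pf):
            raise ConfigError("[ssf] P_fid values must lie in (0, 1)")
        kw["P_fid"] = pf
    if "output_dir" in data:
        kw["output_dir"] = str(data["output_dir"])
    return RunConfig(**kw)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_bytes()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = tomllib.loads(text.decode())
    return from_dict(data)


#: bundled presets for the two bistability case studies
PRESETS: dict[str, dict] = {
    # two stable coexistence equilibria, K in (K4, K2)
    "section3": {
        "model": {**BASE_PARAMS, "K": 0.567, "p": 0.615},
        "noise": {"eps1": 0.001, "eps2": 0.003},
        "sim": {"t_end": 200.0, "h": 1e-3, "seed": 1, "n_reps": 1},
        "ssf": {"P_fid": [0.95]},
    },
    # stable limit cycle vs stable equilibrium, K in (K2, K3)
    "section4": {
        "model": {**BASE_PARAMS, "K": 0.574, "p": 0.617},
        "noise": {"eps1": 0.0005, "eps2": 0.006},
        "sim": {"t_end": 200.0, "h": 1e-3, "seed": 1, "n_reps": 1},
        "ssf": {"P_fid": [0.95]},
    },
}


def get_preset(name: str) -> RunConfig:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return from_dict(PRESETS[name])
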