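"""Model configuration for the Bayesian-alphabet samplers.

``ModelConfig`` carries everything a chain needs besides the data: which
model, the prior-inclusion parameter pi, starting variances, chain control
and prior degrees of freedom.  Production-scale defaults (160 000
iterations, 10 000 burn-in) match common practice for 50K-chip analyses;
desk-scale work passes shorter chains explicitly.

Configs round-trip through a plain-text ``key: value`` format via
:func:`read_config` / :func:`write_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

MODELS = ("A", "B", "C", "Cpi")
_MODEL_CODES = {"A": 0, "B": 1, "C": 2, "Cpi": 3}


@dataclass(frozen=True)
class ModelConfig:
    model: str = "Cpi"
    pi: float = 0.5
    va_start: float = 1.0
    ve_start: float = 1.0
    chain_length: int = 160_000
    burn_in: int = 10_000
    mh_cycles: int = 2
    nu_a: float = 4.0
    nu_e: float = 4.0
    fix_variances: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.model == "A" and self.pi != 0.0:
            # BayesA fits every marker: pi is forced to 0
            object.__setattr__(self, "pi", 0.0)
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if not 0 <= self.burn_in < self.chain_length:
            raise ValueError("require 0 <= burn_in < chain_length")
        if self.va_start <= 0 or self.ve_start <= 0:
            raise ValueError("starting variances must be > 0")
        if self.mh_cycles < 1:
            raise ValueError("mh_cycles must be >= 1")

    @property
    def model_code(self) -> int:
        return _MODEL_CODES[self.model]

    def replace(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


def informed_start(target: ModelConfig, source_results) -> ModelConfig:
    """Return ``target`` with starting variances replaced by the posterior
    means of a previously fitted analysis (typically BayesCpi -> BayesA,
    whose variance components are sensitive to starting values)."""
    return target.replace(
        va_start=float(source_results.va), ve_start=float(source_results.ve)
    )


_FIELDS = {
    "model": str,
    "pi": float,
    "va_start": float,
    "ve_start": float,
    "chain_length": int,
    "burn_in": int,
    "mh_cycles": int,
    "nu_a": float,
    "nu_e": float,
    "fix_variances": lambda s: s.strip().lower() in ("1", "true", "yes"),
    "seed": int,
}


def write_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        for name in _FIELDS:
            fh.write(f"{name}: {getattr(config, name)}\n")


def read_config(path) -> ModelConfig:
    kw = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            key = key.strip()
            if key not in _FIELDS:
                raise ValueError(f"unknown config key {key!r}")
            kw[key] = _FIELDS[key](value.strip())
    return ModelConfig(**kw)
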