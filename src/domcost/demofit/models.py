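"""Two-population demographic model parameterizations.

Four nested models of a wild/domestic split, in diffusion units (sizes nu
relative to the ancestral size, times in 2*Nref generations, migration scaled
as 2*Nref*m):

  A: clean split, constant sizes, no gene flow      {nu1, nu2, T}
  B: A plus asymmetric gene flow                    {nu1, nu2, T, m12, m21}
  C: B with linear growth/reduction from (nu1, nu2)
     at the split to (nu1F, nu2F) at present        {nu1, nu2, nu1F, nu2F, T, m12, m21}
  D: C with an extra epoch boundary: sizes constant
     until T2 before present, then linear change    {..., T, T2, m12, m21}

C is D with T2 = T, B is C with nuF = nu, A is B with m = 0; AIC comparisons
between them are comparisons of nested composite likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "A": ("nu1", "nu2", "T"),
    "B": ("nu1", "nu2", "T", "m12", "m21"),
    "C": ("nu1", "nu2", "nu1F", "nu2F", "T", "m12", "m21"),
    "D": ("nu1", "nu2", "nu1F", "nu2F", "T", "T2", "m12", "m21"),
}

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "nu1": (1e-3, 50.0),
    "nu2": (1e-3, 50.0),
    "nu1F": (1e-3, 50.0),
    "nu2F": (1e-3, 50.0),
    "T": (1e-4, 5.0),
    "T2": (1e-4, 5.0),
    "m12": (1e-6, 20.0),
    "m21": (1e-6, 20.0),
}


@dataclass
class DemographicModelSpec:
    """One of the four model parameterizations plus per-parameter bounds."""

    model_id: str
    params: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_PARAMS:
            raise ValueError(f"unknown model {self.model_id!r}; expected one of A B C D")
        merged = dict(DEFAULT_BOUNDS)
        merged.update(self.bounds)
        self.bounds = {name: merged[name] for name in self.param_names}

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAMS[self.model_id]

    @property
    def k(self) -> int:
        """Number of free parameters (for AIC)."""
        return len(self.param_names)

    def with_params(self, values) -> "DemographicModelSpec":
        if isinstance(values, dict):
            params = {n: float(values[n]) for n in self.param_names}
        else:
            values = np.asarray(values, dtype=float)
            if values.shape != (self.k,):
                raise ValueError("parameter vector length mismatch")
            params = dict(zip(self.param_names, values))
        return DemographicModelSpec(self.model_id, params, dict(self.bounds))

    def param_vector(self) -> np.ndarray:
        self._check_complete()
        return np.array([self.params[n] for n in self.param_names], dtype=float)

    def _check_complete(self) -> None:
        missing = [n for n in self.param_names if n not in self.params]
        if missing:
            raise ValueError(f"model {self.model_id}: missing parameters {missing}")

    def validate(self) -> None:
        self._check_complete()
        for name in self.param_names:
            v = self.params[name]
            if not np.isfinite(v):
                raise ValueError(f"{name} is not finite")
            if name.startswith("nu") and v <= 0:
                raise ValueError(f"{name} must be > 0")
            if name.startswith("T") and v < 0:
                raise ValueError(f"{name} must be >= 0")
            if name.startswith("m") and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def epochs(self) -> list[tuple[float, float, float, float, float]]:
        """Forward-time epoch list (duration, nu1_0, nu1_1, nu2_0, nu2_1)."""
        self.validate()
        p = self.params
        if self.model_id == "A" or self.model_id == "B":
            return [(p["T"], p["nu1"], p["nu1"], p["nu2"], p["nu2"])]
        if self.model_id == "C":
            return [(p["T"], p["nu1"], p["nu1F"], p["nu2"], p["nu2F"])]
        # D: constant sizes until T2 before present, then linear change
        T2 = min(p["T2"], p["T"])
        out = []
        if p["T"] - T2 > 0:
            out.append((p["T"] - T2, p["nu1"], p["nu1"], p["nu2"], p["nu2"]))
        out.append((T2, p["nu1"], p["nu1F"], p["nu2"], p["nu2F"]))
        return out

    def migration(self) -> tuple[float, float]:
        if self.model_id == "A":
            return 0.0, 0.0
        return self.params["m12"], self.params["m21"]
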