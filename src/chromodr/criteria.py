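"""Critical method attributes: separation criteria, retention rule, gradient arithmetic.

The method's quality is judged by three critical method attributes (CMAs):

* ``S_12`` — baseline-separation criterion of the first critical peak pair
  (α-linolenic / myristic acid): start time of the later peak minus end time
  of the earlier one; positive ⇔ baseline-resolved.
* ``S_67`` — the same criterion for the oleic / petroselinic acid pair.
* ``k_last`` — retention factor of the last-eluted analyte (stearic acid),
  bounded above to cap the run time.

``S`` is modeled *indirectly*: separate response-surface models are fitted to
the four peak-boundary times, and ``S`` is formed from their predictions.
The module also implements the linear-gradient composition arithmetic used to
fix the organic-modifier range: the mobile-phase organic fraction seen by an
analyte eluting at ``t_r`` under a linear gradient delayed by the dwell time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .reference import K_LAST_BOUND, PROBABILITY_THRESHOLD

__all__ = [
    "GradientSpec",
    "PeakBoundaryPair",
    "CmaRule",
    "CmaRuleSet",
    "OutOfGradientWindowError",
    "separation_criterion",
    "gradient_composition",
    "rescale_dwell_time",
    "derive_cmas",
    "predict_cmas",
    "default_rules",
    "CMA_NAMES",
]

CMA_NAMES = ("S_12", "S_67", "k_last")


class OutOfGradientWindowError(ValueError):
    """Retention time outside [dwell, dwell + gradient] — Eq. holds only within."""


@dataclass(frozen=True)
class GradientSpec:
    """A linear gradient: organic fraction phi_i → phi_f (% v/v) over t_grad minutes.

    ``t_dwell`` is the pump-to-column delay (minutes): the gradient front
    reaches the column head only after it.
    """

    phi_i: float
    phi_f: float
    t_grad: float
    t_dwell: float = 0.0

    def __post_init__(self) -> None:
        if self.phi_f < self.phi_i:
            raise ValueError("phi_f must be >= phi_i (rising gradient)")
        if self.t_grad <= 0:
            raise ValueError("t_grad must be > 0")
        if self.t_dwell < 0:
            raise ValueError("t_dwell must be >= 0")


def gradient_composition(g: GradientSpec, t_r: float) -> float:
    """Organic fraction (% v/v) of the mobile phase at retention time ``t_r``.

    phi_e = phi_i + (phi_f − phi_i) / t_grad · (t_r − t_dwell).  Valid only for
    elution within the gradient window; out-of-window times raise rather than
    clamp.
    """
    if t_r < g.t_dwell or t_r > g.t_dwell + g.t_grad:
        raise OutOfGradientWindowError(
            f"t_r={t_r} outside the gradient window "
            f"[{g.t_dwell}, {g.t_dwell + g.t_grad}] min"
        )
    return g.phi_i + (g.phi_f - g.phi_i) / g.t_grad * (t_r - g.t_dwell)


def rescale_dwell_time(t_dwell_ref: float, flow_ref: float, flow: float) -> float:
    """Dwell time at another flow rate (dwell volume is fixed: t_D ∝ 1/flow)."""
    if flow <= 0 or flow_ref <= 0:
        raise ValueError("flow rates must be positive")
    return t_dwell_ref * flow_ref / flow


@dataclass(frozen=True)
class PeakBoundaryPair:
    """Boundary times (minutes) of two consecutive peaks."""

    t1_end: float
    t2_start: float

    def __post_init__(self) -> None:
        if self.t1_end <= 0 or self.t2_start <= 0:
            raise ValueError("boundary times must be positive")


def separation_criterion(pair_or_t1_end, t2_start: float | None = None):
    """Baseline-separation criterion S = t2_start − t1_end (minutes).

    Accepts a :class:`PeakBoundaryPair` or the two times directly; positive
    S means the peaks are baseline-resolved, S ≤ 0 means touching/overlap
    (a valid measurement, not an error).
    """
    if isinstance(pair_or_t1_end, PeakBoundaryPair):
        return pair_or_t1_end.t2_start - pair_or_t1_end.t1_end
    if t2_start is None:
        raise TypeError("separation_criterion needs a PeakBoundaryPair or (t1_end, t2_start)")
    return np.asarray(t2_start, dtype=float) - np.asarray(pair_or_t1_end, dtype=float)


# ---------------------------------------------------------------------------
# rule sets

_OPS = {">": np.greater, "<": np.less}


@dataclass(frozen=True)
class CmaRule:
    """One acceptance rule on a derived CMA, e.g. ``S_12 > 0``."""

    cma: str
    op: str
    bound: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"comparator must be one of {sorted(_OPS)}, got {self.op!r}")

    def holds(self, value):
        return _OPS[self.op](value, self.bound)


@dataclass(frozen=True)
class CmaRuleSet:
    """Joint acceptance rules plus the probability threshold for the design space."""

    rules: tuple[CmaRule, ...]
    probability_threshold: float = PROBABILITY_THRESHOLD

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("rule set must be non-empty")
        if not 0.0 < self.probability_threshold < 1.0:
            raise ValueError("probability_threshold must be in (0, 1)")

    def check(self, cmas: Mapping[str, np.ndarray]) -> np.ndarray:
        """Elementwise AND of all rules over arrays of CMA values."""
        out = None
        for r in self.rules:
            if r.cma not in cmas:
                raise KeyError(f"rule references unknown CMA {r.cma!r}")
            ok = r.holds(np.asarray(cmas[r.cma]))
            out = ok if out is None else (out & ok)
        return out


def default_rules() -> CmaRuleSet:
    """The study's acceptance rules: S_12 > 0, S_67 > 0, k_last < 18.8 at 90 %."""
    return CmaRuleSet(
        rules=(
            CmaRule("S_12", ">", 0.0),
            CmaRule("S_67", ">", 0.0),
            CmaRule("k_last", "<", K_LAST_BOUND),
        ),
        probability_threshold=PROBABILITY_THRESHOLD,
    )


# ---------------------------------------------------------------------------
# model-based CMA prediction

def derive_cmas(predictions: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Derived CMAs from per-response predictions (on the response scale)."""
    return {
        "S_12": np.asarray(predictions["t_start_peak2"]) - np.asarray(predictions["t_end_peak1"]),
        "S_67": np.asarray(predictions["t_start_peak7"]) - np.asarray(predictions["t_end_peak6"]),
        "k_last": np.asarray(predictions["k_last"]),
    }


def predict_cmas(models: Mapping, x) -> dict[str, np.ndarray]:
    """Evaluate the five response models at coded points ``x`` and derive the CMAs.

    ``models`` maps the five response names (four boundary times plus
    ``k_last``) to fitted :class:`~chromodr.rsm.QuadraticSurfaceRegressor`
    instances.  Emits an extrapolation warning (never an error) when any
    coded coordinate exceeds |1.5|.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if np.any(np.abs(x) > 1.5):
        warnings.warn(
            "coded settings beyond |1.5|: predictions extrapolate far outside the design",
            stacklevel=2,
        )
    needed = ("t_end_peak1", "t_start_peak2", "t_end_peak6", "t_start_peak7", "k_last")
    missing = [n for n in needed if n not in models]
    if missing:
        raise KeyError(f"missing response models: {missing}")
    preds = {name: models[name].predict(x) for name in needed}
    return derive_cmas(preds)
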