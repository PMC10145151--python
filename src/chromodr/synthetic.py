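"""Synthetic CCD response tables from known quadratic surfaces.

Generates response tables with exactly the statistical structure the fitting
pipeline assumes: each response is a reduced quadratic polynomial in the
coded factors on its transformed scale, plus homoscedastic Gaussian noise on
that same scale, back-transformed to the measurement scale.  Peak-boundary
pairs can alternatively be produced from apex-position surfaces split into
start/end boundaries by a half-width.

:func:`make_published_truth` turns the published coefficient table of the
LC-CAD fatty-acid study into such a ground truth, with noise matched to the
residual scatter of the corresponding refits, so end-to-end recovery of the
whole pipeline (fit → design space → working point) can be exercised under
realistic conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .factors import DesignTable
from .reference import PUBLISHED_MODELS, RESPONSE_NAMES, printed_value
from .rsm import canonical_terms, inverse_transform, term_matrix

__all__ = ["TruthSpec", "GenerationError", "generate_responses", "make_published_truth"]


class GenerationError(RuntimeError):
    """A generated chromatographic quantity came out non-positive."""


# apex-surface names and the boundary column each emits:
# a peak's *end* is apex + half-width, its *start* is apex − half-width
_APEX_EMIT = {
    "peak1": ("t_end_peak1", +1),
    "peak2": ("t_start_peak2", -1),
    "peak6": ("t_end_peak6", +1),
    "peak7": ("t_start_peak7", -1),
}

_CUBE = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], dtype=float
)


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for one response: a polynomial on a transformed scale.

    Parameters
    ----------
    response : str
        A measured response name (``t_end_peak1`` … ``k_last``) or an apex
        surface (``peak1``, ``peak2``, ``peak6``, ``peak7``) when
        ``half_width`` is given.
    transform : str
        Scale on which the polynomial and the noise live.
    coefficients : mapping term → float
        Coded-basis coefficients.
    noise_sd : float
        Gaussian noise standard deviation on the transformed scale.
    half_width : float, optional
        Minutes; splits an apex time into the emitted boundary.
    """

    response: str
    transform: str
    coefficients: Mapping[str, float]
    noise_sd: float = 0.0
    half_width: float | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.response in _APEX_EMIT and self.half_width is None:
            raise ValueError(f"apex truth {self.response!r} requires a half_width")
        if self.response not in _APEX_EMIT and self.response not in RESPONSE_NAMES:
            raise ValueError(f"unknown response {self.response!r}")
        canonical_terms(self.coefficients)  # validates term names
        # noiseless surface must be positive over the coded cube
        vals = self.evaluate(_CUBE)
        if np.any(vals <= 0):
            raise ValueError(
                f"truth for {self.response!r} is non-positive somewhere on the coded cube"
            )

    @property
    def emits(self) -> str:
        """Name of the response-table column this truth produces."""
        return _APEX_EMIT[self.response][0] if self.response in _APEX_EMIT else self.response

    def terms(self) -> tuple[str, ...]:
        return canonical_terms(self.coefficients)

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients.get(t, 0.0) for t in self.terms()], dtype=float)

    def evaluate(self, x_coded: np.ndarray) -> np.ndarray:
        """Noiseless response-scale values at coded points (apex shift applied)."""
        z = term_matrix(np.atleast_2d(x_coded), self.terms()) @ self.coef_vector()
        y = inverse_transform(z, self.transform)
        if self.response in _APEX_EMIT:
            y = y + _APEX_EMIT[self.response][1] * self.half_width
        return y


def generate_responses(
    truths: Iterable[TruthSpec],
    design: DesignTable,
    seed: int,
    round_decimals: int | None = None,
) -> pd.DataFrame:
    """Simulate a response table for ``design`` from ground-truth surfaces.

    Noise is drawn on each truth's transformed scale (where the linear model
    holds) and back-transformed; apex truths then shift by ±half_width.
    Truths are consumed in canonical response-column order with a single
    seeded generator, so output is reproducible.  ``round_decimals`` rounds
    the emitted table (e.g. 2 to mimic a printed data table).

    Returns a DataFrame indexed by ``run_id`` with the five canonical
    response columns.
    """
    by_column = {t.emits: t for t in truths}
    missing = [c for c in RESPONSE_NAMES if c not in by_column]
    if missing:
        raise ValueError(f"truth set does not cover responses: {missing}")
    rng = np.random.default_rng(seed)
    x = design.coded
    out = {}
    for col in RESPONSE_NAMES:
        t = by_column[col]
        z = term_matrix(x, t.terms()) @ t.coef_vector()
        z = z + rng.normal(0.0, t.noise_sd, size=len(z))
        y = inverse_transform(z, t.transform)
        if t.response in _APEX_EMIT:
            y = y + _APEX_EMIT[t.response][1] * t.half_width
        bad = np.where(y <= 0)[0]
        if bad.size:
            run = design.run_ids[bad[0]]
            raise GenerationError(
                f"generated {col} <= 0 at run {run}; truth surface or noise too extreme"
            )
        out[col] = y
    frame = pd.DataFrame(out, index=pd.Index(design.run_ids, name="run_id"))
    if round_decimals is not None:
        frame = frame.round(round_decimals)
    return frame


def make_published_truth(noise: str | float = "matched") -> tuple[TruthSpec, ...]:
    """Ground truth from the published coefficient table of the study.

    ``noise="matched"`` sets each response's noise_sd to the residual
    standard deviation (transformed scale) of the corresponding model refit
    on the bundled dataset; a float applies that sd to every response; 0
    gives noiseless surfaces.
    """
    if noise == "matched":
        from .workbench import fit_study_models, load_fatty_acid_ccd

        design, responses = load_fatty_acid_ccd()
        models = fit_study_models(design, responses)
        sds = {name: float(np.sqrt(m.sigma2_)) for name, m in models.items()}
    else:
        sds = {name: float(noise) for name in RESPONSE_NAMES}
    truths = []
    for name in RESPONSE_NAMES:
        spec = PUBLISHED_MODELS[name]
        truths.append(
            TruthSpec(
                response=name,
                transform=spec["transform"],
                coefficients={t: printed_value(v) for t, v in spec["coefficients"].items()},
                noise_sd=sds[name],
            )
        )
    return tuple(truths)
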