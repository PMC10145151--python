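"""Monte Carlo Method Operable Design Region (MODR) over a discretized factor space.

The factor space (flow rate × gradient time × temperature) is discretized on
an inclusive colon-range grid.  Model-coefficient uncertainty is propagated
by Monte Carlo: in each iteration one perturbed coefficient vector is drawn
per response model and evaluated at *every* grid point, a point "passes" the
iteration iff all CMA rules hold jointly in that perturbed world, and the
per-point probability is the pass fraction over iterations.  The MODR is the
set of grid points whose probability reaches the threshold; its deepest
interior cell provides an automatic working-point suggestion.

Coefficient perturbation defaults to a multivariate normal draw from the full
OLS coefficient covariance, which is the exact sampling distribution of the
estimates under the model.  For orthogonal coded designs the covariance is
diagonal for most term sets and the draw then coincides with independent
per-coefficient Normal(b, SE) draws, which remain available as
``perturbation="independent"``; for term sets with correlated estimates
(intercept vs. quadratics) the independent approximation overstates the
spread of predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .criteria import CmaRuleSet, derive_cmas
from .factors import Factor
from .rsm import inverse_transform, term_matrix

__all__ = [
    "AxisSpec",
    "GridSpec",
    "Grid",
    "McSettings",
    "ModrResult",
    "EmptyModrError",
    "build_grid",
    "monte_carlo_probability",
    "extract_modr",
    "select_working_point",
    "default_grid_spec",
    "ZONE_OUTSIDE",
    "ZONE_EDGE",
    "ZONE_INTERIOR",
]

ZONE_OUTSIDE, ZONE_EDGE, ZONE_INTERIOR = 0, 1, 2
_ZONE_LABELS = {ZONE_OUTSIDE: "outside", ZONE_EDGE: "edge", ZONE_INTERIOR: "interior"}


class EmptyModrError(RuntimeError):
    """No grid point reaches the probability threshold."""


@dataclass(frozen=True)
class AxisSpec:
    """Inclusive arithmetic sequence ``start : step : stop`` (colon-range semantics)."""

    start: float
    step: float
    stop: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9 or self.stop < self.start:
            raise ValueError(
                f"step {self.step} does not tile [{self.start}, {self.stop}] inclusively"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)


@dataclass(frozen=True)
class GridSpec:
    """Per-factor axes in fixed order (flow rate, gradient time, temperature)."""

    flow: AxisSpec
    t_grad: AxisSpec
    temperature: AxisSpec

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.flow.n_points, self.t_grad.n_points, self.temperature.n_points)

    @classmethod
    def from_factors(cls, factors) -> "GridSpec":
        axes = [AxisSpec(f.low, f.grid_step, f.high) for f in factors]
        return cls(*axes)


def default_grid_spec() -> GridSpec:
    """The study grid: flow [0.5:0.01:0.7], gradient time [8:0.35:15], temperature [30:1:40]."""
    from .reference import STUDY_FACTORS

    return GridSpec.from_factors(STUDY_FACTORS)


@dataclass(frozen=True)
class Grid:
    """Materialized grid: per-axis values and the Cartesian product of points."""

    spec: GridSpec
    axes: tuple[np.ndarray, np.ndarray, np.ndarray]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(len(a) for a in self.axes)

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def points(self) -> np.ndarray:
        """(N, 3) natural-unit points; first axis slowest (C order)."""
        mesh = np.meshgrid(*self.axes, indexing="ij")
        return np.column_stack([m.ravel() for m in mesh])


def build_grid(spec: GridSpec) -> Grid:
    """Materialize a :class:`GridSpec` into per-axis values and points."""
    return Grid(spec=spec, axes=tuple(a.values() for a in (spec.flow, spec.t_grad, spec.temperature)))


@dataclass(frozen=True)
class McSettings:
    """Monte Carlo settings: iteration count, seed, and perturbation mode."""

    n_iterations: int = 5000
    seed: int = 0
    perturbation: str = "covariance"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.perturbation not in ("covariance", "independent"):
            raise ValueError("perturbation must be 'covariance' or 'independent'")


def _draw_coefficients(model, n: int, rng: np.random.Generator, mode: str) -> np.ndarray:
    """(n, p) perturbed coefficient vectors for one fitted model."""
    if not hasattr(model, "se_") or not hasattr(model, "coef_"):
        raise ValueError(
            "model carries no coefficient standard errors; refit it before "
            "running the Monte Carlo propagation"
        )
    b = np.asarray(model.coef_, dtype=float)
    if mode == "independent":
        return rng.normal(b, np.asarray(model.se_, dtype=float), size=(n, len(b)))
    cov = np.asarray(model.cov_, dtype=float)
    if not np.any(cov):  # degenerate: zero uncertainty
        return np.tile(b, (n, 1))
    try:
        return rng.multivariate_normal(b, cov, size=n, method="cholesky")
    except np.linalg.LinAlgError:
        return rng.multivariate_normal(b, cov, size=n, method="svd")


def monte_carlo_probability(
    models: Mapping,
    rules: CmaRuleSet,
    grid: Grid,
    mc: McSettings,
    factors: tuple[Factor, Factor, Factor],
    chunk_size: int = 500,
) -> np.ndarray:
    """Per-grid-point probability of jointly meeting all CMA rules.

    One perturbed coefficient vector per model per iteration, shared across
    all grid points (the perturbation represents model error, not point
    noise).  Draws are made model by model in response order with a single
    seeded generator, so identical settings give bit-identical output
    regardless of ``chunk_size``.
    """
    if grid.n_points == 0:
        raise ValueError("grid is empty")
    rng = np.random.default_rng(mc.seed)
    names = ("t_end_peak1", "t_start_peak2", "t_end_peak6", "t_start_peak7", "k_last")
    missing = [n for n in names if n not in models]
    if missing:
        raise KeyError(f"missing response models: {missing}")

    natural = grid.points()
    coded = np.column_stack([f.code(natural[:, i]) for i, f in enumerate(factors)])
    # all draws up front, fixed order: model by model
    draws = {n: _draw_coefficients(models[n], mc.n_iterations, rng, mc.perturbation) for n in names}
    mats = {n: term_matrix(coded, models[n].terms_) for n in names}

    n_pass = np.zeros(grid.n_points, dtype=np.int64)
    for start in range(0, mc.n_iterations, chunk_size):
        sl = slice(start, min(start + chunk_size, mc.n_iterations))
        preds = {
            n: inverse_transform(mats[n] @ draws[n][sl].T, models[n].transform)
            for n in names
        }
        ok = rules.check(derive_cmas(preds))  # (N, chunk)
        n_pass += ok.sum(axis=1)
    return (n_pass / mc.n_iterations).reshape(grid.shape)


@dataclass
class ModrResult:
    """Probability cube with its threshold mask, zone labels, and working point."""

    grid: Grid
    probability: np.ndarray
    threshold: float
    mask: np.ndarray = field(init=False)
    zone: np.ndarray = field(init=False)
    working_point: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.probability.shape != self.grid.shape:
            raise ValueError("probability array shape does not match the grid")
        self.mask = self.probability >= self.threshold
        structure = ndimage.generate_binary_structure(3, 1)  # 6 face neighbors
        # border_value=0: array-boundary cells count as edge unless fully surrounded
        interior = ndimage.binary_erosion(self.mask, structure=structure, border_value=0)
        self.zone = np.full(self.mask.shape, ZONE_OUTSIDE, dtype=np.int8)
        self.zone[self.mask] = ZONE_EDGE
        self.zone[interior] = ZONE_INTERIOR

    @property
    def volume_fraction(self) -> float:
        return float(self.mask.mean())

    def to_frame(self) -> pd.DataFrame:
        """Long-format cube: flow, tgrad, temp, probability, zone."""
        pts = self.grid.points()
        return pd.DataFrame(
            {
                "flow_rate": pts[:, 0],
                "gradient_time": pts[:, 1],
                "temperature": pts[:, 2],
                "probability": self.probability.ravel(),
                "zone": [_ZONE_LABELS[z] for z in self.zone.ravel()],
            }
        )

    def summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_grid_points": self.grid.n_points,
            "n_in_modr": int(self.mask.sum()),
            "volume_fraction": self.volume_fraction,
            "working_point": list(self.working_point) if self.working_point else None,
        }

    def probability_at(self, natural_point) -> float:
        """Probability at the grid cell nearest to a natural-unit point."""
        idx = tuple(
            int(np.argmin(np.abs(ax - v))) for ax, v in zip(self.grid.axes, natural_point)
        )
        return float(self.probability[idx])


def extract_modr(probability: np.ndarray, threshold: float, grid: Grid) -> ModrResult:
    """Threshold the probability cube into mask + edge/interior zones."""
    return ModrResult(grid=grid, probability=np.asarray(probability, dtype=float), threshold=threshold)


def select_working_point(modr: ModrResult) -> tuple[float, float, float]:
    """Deepest-interior grid point of the MODR, in natural units.

    Maximizes the city-block grid distance to the nearest out-of-mask cell
    (cells beyond the array boundary count as out-of-mask); ties are broken
    by highest probability, then lowest flow rate (solvent economy), then
    lowest gradient time and temperature for determinism.  Stores the result
    on ``modr.working_point`` and returns it.
    """
    if not modr.mask.any():
        raise EmptyModrError("no feasible region: no grid point reaches the threshold")
    padded = np.pad(modr.mask, 1, constant_values=False)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")[1:-1, 1:-1, 1:-1]
    best = dist.max()
    cand = np.argwhere(dist == best)
    flow_ax, tg_ax, temp_ax = modr.grid.axes
    order = sorted(
        (tuple(c) for c in cand),
        key=lambda c: (-modr.probability[c], flow_ax[c[0]], tg_ax[c[1]], temp_ax[c[2]]),
    )
    i, j, k = order[0]
    wp = (float(flow_ax[i]), float(tg_ax[j]), float(temp_ax[k]))
    modr.working_point = wp
    return wp


def point_probability(models, rules, natural_point, mc: McSettings, factors) -> float:
    """Monte Carlo pass probability at one exact natural-unit point.

    Convenience wrapper over :func:`monte_carlo_probability` on a degenerate
    single-point grid; the point need not lie on any design-space grid.
    """
    axes = tuple(AxisSpec(v, 1.0, v) for v in natural_point)
    grid = build_grid(GridSpec(*axes))
    return float(monte_carlo_probability(models, rules, grid, mc, factors)[0, 0, 0])


def plot_probability_slices(modr: ModrResult, outdir, prefix: str = "modr") -> list:
    """Write one probability heatmap PNG per temperature level; returns the paths."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flow_ax, tg_ax, temp_ax = modr.grid.axes
    paths = []
    for k, temp in enumerate(temp_ax):
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.pcolormesh(
            tg_ax, flow_ax, modr.probability[:, :, k], vmin=0, vmax=1, shading="nearest"
        )
        ax.contour(tg_ax, flow_ax, modr.probability[:, :, k], levels=[modr.threshold], colors="w")
        ax.set_xlabel("gradient time [min]")
        ax.set_ylabel("flow rate [mL/min]")
        ax.set_title(f"P(all CMA rules) at {temp:g} degC")
        fig.colorbar(im, ax=ax, label="probability")
        path = outdir / f"{prefix}_T{temp:g}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
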