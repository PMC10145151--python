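"""Experimental factors, coded units, and the face-centered central composite design.

The three critical method parameters (CMPs) of a gradient LC method — flow
rate, gradient time, and column temperature — are varied on coded levels
−1/0/+1 of a face-centered CCD: 8 factorial corners, 6 axial points on the
cube faces, and replicated center points.  All model fitting downstream
happens on the coded basis; this module owns the natural↔coded conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignTable",
    "UnsupportedDesignError",
    "code",
    "decode",
    "build_face_centered_ccd",
]


class UnsupportedDesignError(ValueError):
    """Raised when a design other than the 3-factor face-centered CCD is requested."""


@dataclass(frozen=True)
class Factor:
    """A continuous method parameter with its natural range.

    Parameters
    ----------
    name : str
        Identifier used in column headers (e.g. ``"flow_rate"``).
    low, high : float
        Natural-unit range; coded −1 maps to `low`, +1 to `high`.
    units : str
        Display units (e.g. ``"mL/min"``).
    grid_step : float, optional
        Step used when this factor's axis is discretized for the design-space
        search.  Must divide ``high − low`` so the inclusive grid is well formed.
    """

    name: str
    low: float
    high: float
    units: str = ""
    grid_step: float | None = None

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"factor {self.name!r}: low must be < high")
        if self.grid_step is not None:
            if self.grid_step <= 0:
                raise ValueError(f"factor {self.name!r}: grid_step must be > 0")
            span = self.high - self.low
            n = span / self.grid_step
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"factor {self.name!r}: grid_step {self.grid_step} does not "
                    f"divide the range {span}"
                )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, value):
        """Map natural values to coded units; |coded| may exceed 1."""
        return (np.asarray(value, dtype=float) - self.center) / self.half_range

    def decode(self, coded):
        """Inverse of :meth:`code`."""
        return self.center + np.asarray(coded, dtype=float) * self.half_range


def code(value, factor: Factor):
    """Coded value of ``value`` for ``factor`` (midpoint → 0, high → +1)."""
    return factor.code(value)


def decode(coded, factor: Factor):
    """Natural value for a coded coordinate of ``factor``."""
    return factor.decode(coded)


# canonical run order: factorial block (x1 fastest), axial x1, x2, x3, centers
_FACTORIAL = [
    (-1, -1, -1), (+1, -1, -1), (-1, +1, -1), (+1, +1, -1),
    (-1, -1, +1), (+1, -1, +1), (-1, +1, +1), (+1, +1, +1),
]
_AXIAL = [
    (-1, 0, 0), (+1, 0, 0),
    (0, -1, 0), (0, +1, 0),
    (0, 0, -1), (0, 0, +1),
]


@dataclass
class DesignTable:
    """An ordered experimental plan with coded and natural factor settings.

    Coded levels are stored alongside the natural values (not recomputed) so
    tests and serialization round-trips are bit-stable.
    """

    factors: tuple[Factor, ...]
    frame: pd.DataFrame = field(repr=False)
    n_center: int = 0

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        missing = [c for c in self.expected_columns(self.factors) if c not in self.frame.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        # coded and natural blocks must agree through the factor coding
        recoded = np.column_stack([f.code(self.natural[:, i]) for i, f in enumerate(self.factors)])
        if not np.allclose(recoded, self.coded, atol=1e-12):
            raise ValueError("coded and natural columns are inconsistent with the factor ranges")

    @staticmethod
    def expected_columns(factors) -> list[str]:
        return (
            ["run_id"]
            + [f"{f.name}_coded" for f in factors]
            + [f"{f.name}_natural" for f in factors]
        )

    @property
    def n_runs(self) -> int:
        return len(self.frame)

    @property
    def run_ids(self) -> np.ndarray:
        return self.frame["run_id"].to_numpy()

    @property
    def coded(self) -> np.ndarray:
        cols = [f"{f.name}_coded" for f in self.factors]
        return self.frame[cols].to_numpy(dtype=float)

    @property
    def natural(self) -> np.ndarray:
        cols = [f"{f.name}_natural" for f in self.factors]
        return self.frame[cols].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, factors: tuple[Factor, ...] | None = None) -> "DesignTable":
        """Read a design written by :meth:`to_csv`.

        When ``factors`` is omitted they are reconstructed from the linear
        relation between the natural and coded columns (exact for any design
        that spans two coded levels).
        """
        frame = pd.read_csv(path)
        if factors is None:
            names = [c[: -len("_coded")] for c in frame.columns if c.endswith("_coded")]
            factors = []
            for name in names:
                x = frame[f"{name}_coded"].to_numpy(dtype=float)
                v = frame[f"{name}_natural"].to_numpy(dtype=float)
                A = np.column_stack([np.ones_like(x), x])
                (a, b), *_ = np.linalg.lstsq(A, v, rcond=None)
                factors.append(Factor(name=name, low=a - b, high=a + b))
            factors = tuple(factors)
        coded = frame[[f"{f.name}_coded" for f in factors]].to_numpy(dtype=float)
        n_center = int(np.sum(np.all(coded == 0, axis=1)))
        return cls(factors=factors, frame=frame, n_center=n_center)


def build_face_centered_ccd(
    factors,
    n_center: int = 4,
    shuffle_seed: int | None = None,
) -> DesignTable:
    """Construct the 3-factor face-centered CCD.

    Emits the canonical systematic run order (factorial block, axial x1, x2,
    x3, then the center replicates); pass ``shuffle_seed`` for a seeded random
    run order with run ids renumbered in execution order.

    Parameters
    ----------
    factors : sequence of 3 :class:`Factor`
    n_center : int
        Number of center-point replicates (≥ 1); 8 + 6 + ``n_center`` runs total.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"face-centered CCD is implemented for exactly 3 factors, got {len(factors)}"
        )
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    coded = np.array(_FACTORIAL + _AXIAL + [(0, 0, 0)] * n_center, dtype=float)
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        coded = coded[rng.permutation(len(coded))]
    natural = np.column_stack([f.decode(coded[:, i]) for i, f in enumerate(factors)])
    data = {"run_id": np.arange(1, len(coded) + 1)}
    for i, f in enumerate(factors):
        data[f"{f.name}_coded"] = coded[:, i]
    for i, f in enumerate(factors):
        data[f"{f.name}_natural"] = natural[:, i]
    return DesignTable(factors=factors, frame=pd.DataFrame(data), n_center=n_center)
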