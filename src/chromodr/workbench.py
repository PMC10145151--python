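"""Study configuration, the bundled dataset, and the end-to-end report.

Ties the pipeline together: load the 18-run face-centered CCD dataset of the
LC-CAD fatty-acid method (bundled as a CSV fixture), fit the five published
model structures, run the Monte Carlo design-space computation, and emit a
structured report comparing every refit coefficient and diagnostic to the
published table at its printed precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .criteria import CmaRule, CmaRuleSet, default_rules, predict_cmas
from .factors import DesignTable, Factor, build_face_centered_ccd
from .modr import (
    GridSpec,
    AxisSpec,
    McSettings,
    build_grid,
    extract_modr,
    monte_carlo_probability,
    point_probability,
    select_working_point,
)
from .reference import (
    MC_ITERATIONS,
    N_CENTER,
    PROBABILITY_THRESHOLD,
    PUBLISHED_DIAGNOSTICS,
    PUBLISHED_MODELS,
    RESPONSE_NAMES,
    STUDY_FACTORS,
    WORKING_POINT,
    printed_atol,
    printed_value,
)
from .rsm import QuadraticSurfaceRegressor, fit_rsm

__all__ = [
    "CorruptedFixtureError",
    "StudyConfig",
    "load_fatty_acid_ccd",
    "fit_study_models",
    "default_study_config",
    "run_report",
    "render_report",
    "save_models",
    "load_models",
]

_FIXTURE_NAME = "fatty_acid_ccd.csv"
_FIXTURE_SHA256 = "e4892253f9cab957b645ee4524ab8574caabd115ed5c8995fbb82aaf74835a3a"


class CorruptedFixtureError(RuntimeError):
    """The bundled dataset does not match its recorded checksum."""


def load_fatty_acid_ccd() -> tuple[DesignTable, pd.DataFrame]:
    """The bundled 18-run CCD dataset (design + measured responses).

    Returns the design table (coded + natural settings of the three factors)
    and the response table indexed by ``run_id`` with the four peak-boundary
    times (minutes) and the last-peak retention factor.
    """
    ref = resources.files("chromodr.data").joinpath(_FIXTURE_NAME)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise CorruptedFixtureError(
            f"bundled dataset checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    import io

    table = pd.read_csv(io.BytesIO(raw))
    natural = table[["flow_rate", "gradient_time", "temperature"]].to_numpy(float)
    data = {"run_id": table["run_id"].to_numpy()}
    for i, f in enumerate(STUDY_FACTORS):
        data[f"{f.name}_coded"] = f.code(natural[:, i])
    for i, f in enumerate(STUDY_FACTORS):
        data[f"{f.name}_natural"] = natural[:, i]
    design = DesignTable(
        factors=STUDY_FACTORS, frame=pd.DataFrame(data), n_center=N_CENTER
    )
    responses = table.set_index("run_id")[list(RESPONSE_NAMES)]
    return design, responses


def fit_study_models(design, responses) -> dict[str, QuadraticSurfaceRegressor]:
    """Fit the five published model structures (fixed term sets and transforms)."""
    models = {}
    for name in RESPONSE_NAMES:
        spec = PUBLISHED_MODELS[name]
        models[name] = fit_rsm(
            design,
            responses[name].to_numpy(float),
            terms=list(spec["coefficients"]),
            transform=spec["transform"],
        )
    return models


# ---------------------------------------------------------------------------
# model JSON round-trip

def save_models(models: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump({name: m.to_dict() for name, m in models.items()}, fh, indent=1)


def load_models(path) -> dict[str, QuadraticSurfaceRegressor]:
    with open(path) as fh:
        payload = json.load(fh)
    return {name: QuadraticSurfaceRegressor.from_dict(d) for name, d in payload.items()}


# ---------------------------------------------------------------------------
# configuration

@dataclass
class StudyConfig:
    """Everything needed for an end-to-end run.

    ``models`` maps each response name to ``{"transform": ..., "terms": [...]}``.
    """

    factors: tuple[Factor, Factor, Factor] = STUDY_FACTORS
    n_center: int = N_CENTER
    models: dict = field(default_factory=dict)
    rules: CmaRuleSet = field(default_factory=default_rules)
    grid: GridSpec | None = None
    mc: McSettings = field(default_factory=lambda: McSettings(n_iterations=MC_ITERATIONS, seed=0))
    fixture: str | None = None  # None -> bundled dataset

    def __post_init__(self) -> None:
        if len(self.factors) != 3:
            raise ValueError("exactly 3 factors required")
        if not self.models:
            self.models = {
                name: {
                    "transform": PUBLISHED_MODELS[name]["transform"],
                    "terms": list(PUBLISHED_MODELS[name]["coefficients"]),
                }
                for name in RESPONSE_NAMES
            }
        unknown = set(self.models) - set(RESPONSE_NAMES)
        if unknown:
            raise ValueError(f"model definitions for unknown responses: {sorted(unknown)}")
        missing = set(RESPONSE_NAMES) - set(self.models)
        if missing:
            raise ValueError(f"model definitions missing responses: {sorted(missing)}")
        if self.grid is None:
            self.grid = GridSpec.from_factors(self.factors)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "factors" in raw:
            kwargs["factors"] = tuple(Factor(**f) for f in raw["factors"])
        if "n_center" in raw:
            kwargs["n_center"] = int(raw["n_center"])
        if "models" in raw:
            kwargs["models"] = raw["models"]
        if "rules" in raw:
            r = raw["rules"]
            kwargs["rules"] = CmaRuleSet(
                rules=tuple(CmaRule(x["cma"], x["op"], float(x["bound"])) for x in r["rules"]),
                probability_threshold=float(r.get("probability_threshold", PROBABILITY_THRESHOLD)),
            )
        if "grid" in raw:
            kwargs["grid"] = GridSpec(
                **{k: AxisSpec(*v) for k, v in raw["grid"].items()}
            )
        if "mc" in raw:
            kwargs["mc"] = McSettings(**raw["mc"])
        if "fixture" in raw:
            kwargs["fixture"] = raw["fixture"]
        return cls(**kwargs)


def default_study_config(seed: int = 0) -> StudyConfig:
    """The study's own configuration: published model structures, rules, grid, 5000 draws."""
    return StudyConfig(mc=McSettings(n_iterations=MC_ITERATIONS, seed=seed))


# ---------------------------------------------------------------------------
# end-to-end report

def _load_data(config: StudyConfig):
    if config.fixture is None:
        return load_fatty_acid_ccd()
    table = pd.read_csv(config.fixture)
    natural = table[[f.name for f in config.factors]].to_numpy(float)
    data = {"run_id": table["run_id"].to_numpy()}
    for i, f in enumerate(config.factors):
        data[f"{f.name}_coded"] = f.code(natural[:, i])
    for i, f in enumerate(config.factors):
        data[f"{f.name}_natural"] = natural[:, i]
    coded = np.column_stack([f.code(natural[:, i]) for i, f in enumerate(config.factors)])
    n_center = int(np.sum(np.all(coded == 0, axis=1)))
    design = DesignTable(factors=config.factors, frame=pd.DataFrame(data), n_center=n_center)
    return design, table.set_index("run_id")[list(RESPONSE_NAMES)]


def _compare_to_published(name: str, model: QuadraticSurfaceRegressor) -> dict:
    """Per-term and per-diagnostic comparison at printed precision."""
    out = {"coefficients": {}, "diagnostics": {}}
    pub = PUBLISHED_MODELS[name]["coefficients"]
    for term, printed in pub.items():
        i = model.terms_.index(term)
        fitted = float(model.coef_[i])
        out["coefficients"][term] = {
            "fitted": fitted,
            "published": printed_value(printed),
            "matches_printed": bool(abs(fitted - printed_value(printed)) <= printed_atol(printed)),
        }
    diag = model.diagnostics_
    fitted_diag = {
        "r2": diag.r2,
        "adj_r2": diag.adj_r2,
        "pred_r2": diag.pred_r2,
        "lof_pvalue": diag.lof_pvalue,
    }
    for key, printed in PUBLISHED_DIAGNOSTICS[name].items():
        fitted = fitted_diag[key]
        out["diagnostics"][key] = {
            "fitted": fitted,
            "published": printed_value(printed),
            "matches_printed": bool(
                fitted is not None
                and abs(fitted - printed_value(printed)) <= printed_atol(printed)
            ),
        }
    return out


def run_report(config: StudyConfig | None = None) -> dict:
    """Execute design → fit → diagnostics → design space → working point.

    Returns a JSON-able report: per-model coefficients/SEs/diagnostics with
    printed-precision comparison to the published table, the grid size, the
    MODR volume, and the probabilities at the published and the auto-selected
    working points.  Deterministic for a fixed ``config.mc.seed``.
    """
    config = config or default_study_config()
    stage = "design"
    try:
        design, responses = _load_data(config)
        canonical = build_face_centered_ccd(config.factors, n_center=config.n_center)
        stage = "fit"
        models = {
            name: fit_rsm(
                design,
                responses[name].to_numpy(float),
                terms=config.models[name]["terms"],
                transform=config.models[name]["transform"],
            )
            for name in RESPONSE_NAMES
        }
        stage = "modr"
        grid = build_grid(config.grid)
        prob = monte_carlo_probability(models, config.rules, grid, config.mc, config.factors)
        modr = extract_modr(prob, config.rules.probability_threshold, grid)
        stage = "workpoint"
        selected = select_working_point(modr) if modr.mask.any() else None
        coded_wp = np.array(
            [[f.code(v) for f, v in zip(config.factors, WORKING_POINT)]]
        )
        cmas_wp = predict_cmas(models, coded_wp)
    except Exception as err:
        raise RuntimeError(f"report stage {stage!r} failed: {err}") from err

    report = {
        "seed": config.mc.seed,
        "n_iterations": config.mc.n_iterations,
        "perturbation": config.mc.perturbation,
        "design": {
            "n_runs": design.n_runs,
            "n_center": design.n_center,
            "matches_canonical_order": bool(
                np.allclose(design.natural, canonical.natural, atol=1e-12)
            ),
        },
        "models": {
            name: {
                "transform": models[name].transform,
                "terms": list(models[name].terms_),
                "coefficients": models[name].coef_.tolist(),
                "standard_errors": models[name].se_.tolist(),
                "diagnostics": models[name].diagnostics_.as_dict(),
                "published_comparison": _compare_to_published(name, models[name]),
            }
            for name in RESPONSE_NAMES
        },
        "grid": {"shape": list(grid.shape), "n_points": grid.n_points},
        "modr": modr.summary(),
        "published_working_point": {
            "natural": list(WORKING_POINT),
            "cmas": {k: float(v[0]) for k, v in cmas_wp.items()},
            "exact_probability": point_probability(
                models, config.rules, WORKING_POINT, config.mc, config.factors
            ),
            "nearest_cell_probability": modr.probability_at(WORKING_POINT),
            "in_modr": bool(modr.probability_at(WORKING_POINT) >= modr.threshold),
        },
        "selected_working_point": list(selected) if selected else None,
    }
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of :func:`run_report` output."""
    lines = []
    lines.append(
        f"Study report (seed={report['seed']}, {report['n_iterations']} MC iterations, "
        f"{report['perturbation']} perturbation)"
    )
    d = report["design"]
    lines.append(
        f"design: {d['n_runs']} runs ({d['n_center']} centers), "
        f"canonical order: {d['matches_canonical_order']}"
    )
    for name, m in report["models"].items():
        diag = m["diagnostics"]
        comp = m["published_comparison"]
        n_match = sum(c["matches_printed"] for c in comp["coefficients"].values())
        lines.append(
            f"model {name}: {m['transform']}, {len(m['terms'])} terms, "
            f"R2={diag['r2']:.4f} adjR2={diag['adj_r2']:.4f} predR2={diag['pred_r2']:.4f} "
            f"LOFp={diag['lof_pvalue']:.4f} | coefficients at printed precision: "
            f"{n_match}/{len(comp['coefficients'])}"
        )
    g = report["grid"]
    lines.append(f"grid: {g['shape'][0]}x{g['shape'][1]}x{g['shape'][2]} = {g['n_points']} points")
    mo = report["modr"]
    lines.append(
        f"MODR: {mo['n_in_modr']}/{mo['n_grid_points']} points "
        f"({100 * mo['volume_fraction']:.1f}%) at threshold {mo['threshold']}"
    )
    wp = report["published_working_point"]
    lines.append(
        f"published working point {tuple(wp['natural'])}: "
        f"S_12={wp['cmas']['S_12']:.3f} S_67={wp['cmas']['S_67']:.3f} "
        f"k_last={wp['cmas']['k_last']:.2f}; "
        f"P(all rules)={wp['nearest_cell_probability']:.3f} (in MODR: {wp['in_modr']})"
    )
    if report["selected_working_point"]:
        lines.append(f"auto-selected working point: {tuple(report['selected_working_point'])}")
    return "\n".join(lines)
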