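"""Constants of the published LC-CAD fatty-acid method-optimization study.

Centralizes the factor ranges, the reported response-surface coefficient
table, the acceptance rules on the critical method attributes (CMAs), the
design-space grid, and the selected working point, so that the fitting,
simulation, and reporting modules all draw from one place.

Published coefficient values are stored as *strings* to preserve the number
of printed decimals; printed-precision comparison tolerances are derived
from them (half a unit in the last printed place).
"""

from __future__ import annotations

from .factors import Factor

__all__ = [
    "FLOW", "GRADIENT_TIME", "TEMPERATURE", "STUDY_FACTORS",
    "RESPONSE_NAMES", "PUBLISHED_MODELS", "PUBLISHED_DIAGNOSTICS",
    "WORKING_POINT", "K_LAST_BOUND", "PROBABILITY_THRESHOLD",
    "MC_ITERATIONS", "N_CENTER", "SCOUTING_GRADIENT",
    "printed_value", "printed_atol",
]

# the three critical method parameters with design-space grid steps
FLOW = Factor("flow_rate", 0.5, 0.7, units="mL/min", grid_step=0.01)
GRADIENT_TIME = Factor("gradient_time", 8.0, 15.0, units="min", grid_step=0.35)
TEMPERATURE = Factor("temperature", 30.0, 40.0, units="degC", grid_step=1.0)
STUDY_FACTORS = (FLOW, GRADIENT_TIME, TEMPERATURE)

N_CENTER = 4  # center replicates -> 18 runs

# measured responses, in fixture column order: the boundary times (min) of the
# two critical peak pairs and the retention factor of the last-eluted analyte
RESPONSE_NAMES = (
    "t_end_peak1",    # end of the alpha-linolenic acid peak
    "t_start_peak2",  # start of the myristic acid peak
    "t_end_peak6",    # end of the oleic acid peak
    "t_start_peak7",  # start of the petroselinic acid peak
    "k_last",         # retention factor of stearic acid
)

# reported reduced models on the coded basis; values as printed (strings keep
# the printed precision); "/" -> term excluded -> absent from the dict
PUBLISHED_MODELS: dict[str, dict] = {
    "t_end_peak1": {
        "transform": "reciprocal",
        "coefficients": {
            "1": "+0.26", "x1": "+0.041", "x2": "-2.111e-3", "x3": "+0.016",
            "x1:x3": "+3.182e-3",
        },
    },
    "t_start_peak2": {
        "transform": "reciprocal",
        "coefficients": {
            "1": "+0.26", "x1": "+0.041", "x2": "-2.196e-3", "x3": "+0.019",
            "x1:x3": "+3.317e-3",
        },
    },
    "t_end_peak6": {
        "transform": "log10",
        "coefficients": {
            "1": "+0.88", "x1": "-0.062", "x2": "+0.018", "x3": "-0.035",
            "x1:x2": "-1.631e-3", "x1:x3": "-1.506e-3", "x2:x3": "-2.369e-3",
            "x1^2": "+4.776e-3", "x2^2": "-3.539e-3",
        },
    },
    "t_start_peak7": {
        "transform": "log10",
        "coefficients": {
            "1": "+0.88", "x1": "-0.062", "x2": "+0.019", "x3": "-0.035",
            "x1:x2": "-1.582e-3", "x1:x3": "-1.313e-3", "x2:x3": "-2.611e-3",
            "x1^2": "+4.493e-3", "x2^2": "-3.515e-3",
        },
    },
    "k_last": {
        "transform": "identity",
        "coefficients": {
            "1": "+16.89", "x1": "+0.48", "x2": "+1.24", "x3": "-1.36",
            "x2:x3": "-0.22", "x2^2": "-0.33",
        },
    },
}

PUBLISHED_DIAGNOSTICS: dict[str, dict[str, str]] = {
    "t_end_peak1": {"r2": "0.9993", "adj_r2": "0.9991", "pred_r2": "0.9985", "lof_pvalue": "0.7790"},
    "t_start_peak2": {"r2": "0.9993", "adj_r2": "0.9991", "pred_r2": "0.9987", "lof_pvalue": "0.6445"},
    "t_end_peak6": {"r2": "0.9997", "adj_r2": "0.9995", "pred_r2": "0.9991", "lof_pvalue": "0.9730"},
    "t_start_peak7": {"r2": "0.9998", "adj_r2": "0.9996", "pred_r2": "0.9992", "lof_pvalue": "0.9650"},
    "k_last": {"r2": "0.9902", "adj_r2": "0.9861", "pred_r2": "0.9805", "lof_pvalue": "0.9718"},
}

# CMA acceptance rules and design-space settings
K_LAST_BOUND = 18.8
PROBABILITY_THRESHOLD = 0.90
MC_ITERATIONS = 5000

# working point selected in the study (natural units: mL/min, min, degC)
WORKING_POINT = (0.575, 14.2, 33.0)

# scouting gradient used to fix the organic-modifier range:
# 65 -> 85 % (v/v) acetonitrile in 15 min, dwell time 1.37 min at 0.7 mL/min
SCOUTING_GRADIENT = {"phi_i": 65.0, "phi_f": 85.0, "t_grad": 15.0, "t_dwell": 1.37}


def printed_value(s: str) -> float:
    """Numeric value of a printed coefficient string."""
    return float(s)


def printed_atol(s: str) -> float:
    """Half a unit in the last printed decimal place of ``s``.

    ``"+0.041" -> 5e-4``; ``"-2.111e-3" -> 5e-7``; ``"0.9902" -> 5e-5``.
    """
    s = s.strip().lstrip("+-")
    mantissa, _, exp = s.partition("e")
    decimals = len(mantissa.partition(".")[2])
    scale = 10.0 ** int(exp) if exp else 1.0
    return 0.5 * 10.0 ** (-decimals) * scale
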