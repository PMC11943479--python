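"""Four-parameter Hill inhibition fitting and LOAEL determination.

Viability-style readouts (e.g. MTT absorbance) are normalized to percent of
untreated control, fitted with the variable-slope inhibition model

    response(c) = bottom + (top - bottom) / (1 + (c / IC50)^h),

which decreases in concentration for Hill slope h > 0, and summarized by
ICp values derived in closed form:

    ICp = (p / (100 - p))^(1/h) * IC50.

The LOAEL (lowest-observed-adverse-effect level) is the smallest tested
concentration whose group differs from the untreated control after a
one-way ANOVA with Dunnett's many-to-one adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import group_stats

__all__ = [
    "PlateResponse",
    "HillFit",
    "LoaelResult",
    "normalize_to_control",
    "fit_hill",
    "ic_p",
    "loael",
]


@dataclass(frozen=True)
class PlateResponse:
    """Dose series in percent-of-control units.

    concentrations     : tested concentrations (molar), strictly positive,
                         strictly increasing.
    responses          : (n_concentrations, n_replicates) matrix, % of control.
    control_responses  : replicate values of the untreated control wells
                         (also % of control; their mean is 100 by construction).
    """

    concentrations: np.ndarray
    responses: np.ndarray
    control_responses: np.ndarray | None = None
    control_label: str = "untreated"

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        if conc.ndim != 1 or resp.ndim != 2 or resp.shape[0] != conc.size:
            raise ValueError("responses must be (n_concentrations, n_replicates)")
        if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite")
        if self.control_responses is not None:
            ctrl = np.asarray(self.control_responses, dtype=float)
            object.__setattr__(self, "control_responses", ctrl)

    @property
    def mean_responses(self) -> np.ndarray:
        return self.responses.mean(axis=1)


@dataclass(frozen=True)
class HillFit:
    """Fitted four-parameter inhibition curve."""

    bottom: float
    top: float
    ic50: float
    hill_slope: float
    residual_sse: float
    converged: bool

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return _hill(conc, self.bottom, self.top, np.log10(self.ic50), self.hill_slope)


@dataclass(frozen=True)
class LoaelResult:
    """LOAEL call with the per-concentration Dunnett-adjusted p-values."""

    loael: float | None
    per_concentration_p: pd.DataFrame = field(repr=False)
    alpha: float = 0.05


def _hill(conc: np.ndarray, bottom: float, top: float, log_ic50: float, slope: float) -> np.ndarray:
    logc = np.log10(conc)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (logc - log_ic50)))


def normalize_to_control(
    raw: pd.DataFrame, control_wells: list[str] | None = None
) -> PlateResponse:
    """Convert a raw plate table to percent-of-untreated-control responses.

    ``raw`` is tidy with columns ``concentration``, ``well`` and
    ``absorbance``; control wells are named in ``control_wells`` (default:
    rows with concentration == 0). Each response becomes
    100 × absorbance / mean(control absorbance), so the control mean maps
    to exactly 100%.
    """
    required = {"concentration", "well", "absorbance"}
    if not required.issubset(raw.columns):
        raise ValueError(f"raw plate table needs columns {sorted(required)}")
    if control_wells is not None:
        is_control = raw["well"].isin(control_wells)
    else:
        is_control = raw["concentration"] == 0
    if not is_control.any():
        raise ValueError("no control wells found")
    control_mean = raw.loc[is_control, "absorbance"].mean()
    if not np.isfinite(control_mean) or control_mean <= 0:
        raise ValueError(f"control mean must be positive, got {control_mean!r}")

    treated = raw.loc[~is_control]
    pct = 100.0 * treated["absorbance"] / control_mean
    table = (
        pd.DataFrame({"concentration": treated["concentration"], "response": pct})
        .groupby("concentration")["response"]
        .apply(list)
        .sort_index()
    )
    n_rep = {len(v) for v in table}
    if len(n_rep) != 1:
        raise ValueError("unbalanced replicate counts across concentrations")
    responses = np.array(table.tolist(), dtype=float)
    control_pct = (100.0 * raw.loc[is_control, "absorbance"] / control_mean).to_numpy()
    return PlateResponse(
        concentrations=table.index.to_numpy(dtype=float),
        responses=responses,
        control_responses=control_pct,
    )


# Slope seeds for the multi-start; the first is the documented default init.
_SLOPE_SEEDS = (1.0, 0.5, 3.0)


def fit_hill(data: PlateResponse) -> HillFit:
    """Least-squares variable-slope inhibition fit.

    Initialization: top/bottom from the max/min mean response, IC50 at the
    concentration whose mean response is nearest halfway between them,
    slope 1; two further slope seeds (0.5, 3) are tried if the first
    attempt fails to converge. Deterministic given the data. Degenerate
    (flat) data are reported with ``converged=False`` rather than raised.
    """
    if data.concentrations.size < 4:
        raise ValueError("need >= 4 distinct concentrations for 4 free parameters")
    conc = np.repeat(data.concentrations, data.responses.shape[1])
    resp = data.responses.ravel()
    means = data.mean_responses
    top0, bottom0 = float(means.max()), float(means.min())
    if top0 - bottom0 < 1e-9:  # flat: no information about ic50 or slope
        return HillFit(bottom0, top0, float(np.median(data.concentrations)), 1.0,
                       float(((resp - resp.mean()) ** 2).sum()), False)
    half = 0.5 * (top0 + bottom0)
    log_ic50_0 = float(np.log10(data.concentrations[np.argmin(np.abs(means - half))]))

    best: tuple[float, np.ndarray] | None = None
    for slope0 in _SLOPE_SEEDS:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _hill, conc, resp,
                    p0=[bottom0, top0, log_ic50_0, slope0],
                    maxfev=20000,
                )
        except RuntimeError:
            continue
        sse = float(((resp - _hill(conc, *popt)) ** 2).sum())
        if np.isfinite(sse) and (best is None or sse < best[0]):
            best = (sse, popt)
        if best is not None and slope0 == _SLOPE_SEEDS[0]:
            break  # default init converged; keep it (deterministic path)
    if best is None:
        return HillFit(bottom0, top0, 10.0 ** log_ic50_0, 1.0, float("inf"), False)

    sse, (bottom, top, log_ic50, slope) = best
    if slope < 0:  # equivalent curve with top/bottom swapped; canonicalize
        bottom, top, slope = top, bottom, -slope
    converged = bool(np.isfinite(sse) and top > bottom)
    return HillFit(float(bottom), float(top), float(10.0 ** log_ic50),
                   float(slope), sse, converged)


def ic_p(fit: HillFit, p: float) -> float:
    """Concentration producing ``p`` percent inhibition.

    Closed form (p/(100-p))^(1/HillSlope) × IC50; returns IC50 exactly at
    p = 50 and is strictly increasing in p for positive Hill slope.
    """
    if not 0 < p < 100:
        raise ValueError(f"p must be in (0, 100), got {p!r}")
    if not fit.converged:
        raise ValueError("ic_p requires a converged fit")
    return (p / (100.0 - p)) ** (1.0 / fit.hill_slope) * fit.ic50


def loael(data: PlateResponse, alpha: float = 0.05) -> LoaelResult:
    """Lowest tested concentration significantly different from control.

    One-way ANOVA across control + concentration groups, then Dunnett
    many-to-one comparisons against the untreated control; the LOAEL is the
    smallest concentration with adjusted p < alpha, or ``None``.
    """
    if data.control_responses is None or len(data.control_responses) < 2:
        raise ValueError("loael requires >= 2 control replicates")
    if data.responses.shape[1] < 2:
        raise ValueError("loael requires >= 2 replicates per concentration")
    groups = [data.responses[i] for i in range(data.responses.shape[0])]
    result = group_stats.anova_dunnett_arrays(
        groups, control=np.asarray(data.control_responses, dtype=float)
    )
    table = pd.DataFrame({
        "concentration": data.concentrations,
        "p_adjusted": result.p_adjusted,
        "significant": result.p_adjusted < alpha,
    })
    hits = table.loc[table["significant"], "concentration"]
    return LoaelResult(
        loael=float(hits.min()) if not hits.empty else None,
        per_concentration_p=table,
        alpha=alpha,
    )
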