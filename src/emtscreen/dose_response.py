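"""Four-parameter logistic dose-response analysis.

Model (decreasing viability, hill > 0):

    v(c) = bottom + (top - bottom) / (1 + (c / ec50)^hill)

Fitting happens on the log10-concentration axis with multi-start
initialization (ec50 started at the 25/50/75% dose quantiles; best residual
sum of squares wins, ties broken by the smallest ec50).  Zero-dose points
are excluded from the fit: vehicle enters the analysis as the normalization
denominator, never as a fitted point.

The absolute IC50 is the concentration where the *fitted* curve crosses
viability 0.5 (closed form); it is censored as a bound ("<c_min" / ">c_max")
when the crossing lies outside the tested concentration range, never
extrapolated.  The relative EC50 is the curve midpoint and equals the
absolute IC50 exactly iff (top + bottom) / 2 == 0.5.

Also here: growth-rate-corrected GR metrics with GR50, rank correlation of
paired IC50/GR50 potencies, and the cumulative population-doubling-level
update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Censored",
    "FitError",
    "DoseResponseFit",
    "GRResult",
    "SelectivityResult",
    "PDLRecord",
    "four_pl",
    "fit_4pl",
    "absolute_ic50",
    "fold_selectivity",
    "gr_value",
    "compute_gr",
    "correlate_ic50_gr50",
    "pdl",
]


class FitError(ValueError):
    """Input unusable for dose-response fitting."""


@dataclass(frozen=True)
class Censored:
    """A bound on a quantity that fell outside the observable range.

    ``direction`` is ">" (true value above ``bound``) or "<" (below).
    """

    bound: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (">", "<"):
            raise ValueError("direction must be '>' or '<'")

    def __str__(self) -> str:
        return f"{self.direction}{self.bound:g}"

    @classmethod
    def parse(cls, text: str) -> "Censored":
        text = text.strip()
        if not text or text[0] not in "<>":
            raise ValueError(f"not a censored value: {text!r}")
        return cls(float(text[1:]), text[0])


def is_finite_value(x: float | Censored | None) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


def four_pl(
    c: np.ndarray | float, bottom: float, top: float, hill: float, ec50: float
) -> np.ndarray | float:
    """Evaluate the decreasing four-parameter logistic at concentration c."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ec50) ** hill)


@dataclass
class DoseResponseFit:
    compound_id: str | None
    cell_line: str | None
    bottom: float
    top: float
    hill: float
    ec50_rel: float
    ic50_abs: float | Censored | None
    rss: float
    converged: bool
    non_inhibitory: bool = False
    degenerate: bool = False
    n_points: int = 0
    c_min: float = math.nan
    c_max: float = math.nan


def _fit_once(
    logc: np.ndarray,
    v: np.ndarray,
    p0: Sequence[float],
    bounds: tuple,
    increasing: bool,
) -> tuple[np.ndarray, float] | None:
    sign = -1.0 if increasing else 1.0

    # v(c) = bottom + (top-bottom) / (1 + (c/ec50)^(sign*hill)) on log10 axis
    def model4(lc, bottom, top, hill, lec50):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (sign * hill * (lc - lec50)))

    try:
        popt, _ = optimize.curve_fit(
            model4, logc, v, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError):
        return None
    rss = float(np.sum((model4(logc, *popt) - v) ** 2))
    return popt, rss


def fit_4pl(
    concentrations: Sequence[float],
    viabilities: Sequence[float],
    compound_id: str | None = None,
    cell_line: str | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit on the log10-concentration axis.

    Requires >= 4 distinct positive concentrations.  Monotone-increasing
    input is fitted with the mirrored (increasing) parameterization and
    flagged ``non_inhibitory``; a constant response is flagged
    ``degenerate`` and left non-converged.
    """
    conc = np.asarray(concentrations, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    if conc.shape != viab.shape:
        raise FitError("concentrations and viabilities differ in length")
    if not np.all(np.isfinite(viab)):
        raise FitError("viabilities must be finite")
    keep = conc > 0  # zero dose is the normalization anchor, not a fit point
    conc, viab = conc[keep], viab[keep]
    if len(np.unique(conc)) < 4:
        raise FitError("need >= 4 distinct positive concentrations")

    c_min, c_max = float(conc.min()), float(conc.max())
    base = DoseResponseFit(
        compound_id=compound_id,
        cell_line=cell_line,
        bottom=math.nan,
        top=math.nan,
        hill=math.nan,
        ec50_rel=math.nan,
        ic50_abs=None,
        rss=math.nan,
        converged=False,
        n_points=int(len(conc)),
        c_min=c_min,
        c_max=c_max,
    )
    if np.allclose(viab, viab[0]):
        return replace(base, degenerate=True)

    logc = np.log10(conc)
    # direction of the dose trend decides the parameterization
    rho = stats.spearmanr(logc, viab).statistic
    increasing = bool(rho > 0)

    vmin, vmax = float(viab.min()), float(viab.max())
    span = vmax - vmin
    lo = (
        min(vmin - 0.5 * span, -0.5),
        min(vmin, 0.0),
        0.05,
        float(logc.min()) - 1.0,
    )
    hi = (
        max(vmax, 1.0),
        max(vmax + 0.5 * span, 1.5),
        10.0,
        float(logc.max()) + 1.0,
    )
    bounds = (lo, hi)

    starts = np.quantile(logc, [0.25, 0.5, 0.75])
    best: tuple[np.ndarray, float] | None = None
    for lec0 in starts:
        p0 = (
            max(lo[0], min(vmin, hi[0])),
            min(hi[1], max(vmax, lo[1] + 1e-6)),
            1.0,
            float(lec0),
        )
        result = _fit_once(logc, viab, p0, bounds, increasing)
        if result is None:
            continue
        popt, rss = result
        if (
            best is None
            or rss < best[1] - 1e-12
            or (abs(rss - best[1]) <= 1e-12 and popt[3] < best[0][3])
        ):
            best = (popt, rss)
    if best is None:
        return base

    (bottom, top, hill, lec50), rss = best
    fit = replace(
        base,
        bottom=float(bottom),
        top=float(top),
        hill=float(hill),
        ec50_rel=float(10.0 ** lec50),
        rss=rss,
        converged=True,
        non_inhibitory=increasing,
    )
    if not increasing:
        fit.ic50_abs = absolute_ic50(fit, c_min, c_max)
    return fit


def absolute_ic50(
    fit: DoseResponseFit, c_min: float, c_max: float, level: float = 0.5
) -> float | Censored:
    """Concentration where the fitted curve equals ``level`` (default 0.5).

    Closed form c = ec50 * ((top - level) / (level - bottom))^(1/hill).
    Censored as ">c_max" when the curve stays above ``level`` over the
    tested range (including bottom >= level), "<c_min" when already below
    at c_min (including top <= level).
    """
    if not fit.converged:
        raise FitError("absolute IC50 requires a converged fit")
    if fit.bottom >= level:
        return Censored(c_max, ">")
    if fit.top <= level:
        return Censored(c_min, "<")
    c = fit.ec50_rel * ((fit.top - level) / (level - fit.bottom)) ** (1.0 / fit.hill)
    if c > c_max:
        return Censored(c_max, ">")
    if c < c_min:
        return Censored(c_min, "<")
    return float(c)


@dataclass(frozen=True)
class SelectivityResult:
    compound_id: str | None
    ic50_resistant: float | Censored
    ic50_sensitive: float | Censored
    fold_selectivity: float | Censored
    reported_fold: int | str


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fold_selectivity(
    ic50_a: float | Censored,
    ic50_b: float | Censored,
    compound_id: str | None = None,
) -> SelectivityResult:
    """Fold-selectivity between two lines: IC50(less sensitive) / IC50(more).

    The larger IC50 goes in the numerator, so the fold is always >= 1 for
    finite inputs.  A censored ">x" numerator (resistant line never reached
    50% inhibition) yields a bound ">fold" rather than a number; censored
    inputs in any other position are unsupported.
    """
    a_fin, b_fin = is_finite_value(ic50_a), is_finite_value(ic50_b)
    if a_fin and b_fin:
        if ic50_a <= 0 or ic50_b <= 0:
            raise ValueError("IC50 values must be > 0")
        hi, lo = max(ic50_a, ic50_b), min(ic50_a, ic50_b)
        fold = hi / lo
        return SelectivityResult(compound_id, hi, lo, fold, _round_half_away(fold))
    # one censored ">" bound and one finite value -> bounded fold
    for cens, fin in ((ic50_a, ic50_b), (ic50_b, ic50_a)):
        if (
            isinstance(cens, Censored)
            and cens.direction == ">"
            and is_finite_value(fin)
            and cens.bound > fin
        ):
            bound = cens.bound / fin
            return SelectivityResult(
                compound_id, cens, fin, Censored(bound, ">"), f">{_round_half_away(bound)}"
            )
    raise ValueError(
        f"cannot compute fold-selectivity from {ic50_a} and {ic50_b}"
    )


# ---------------------------------------------------------------------------
# growth-rate-corrected metrics


@dataclass
class GRResult:
    cell_line: str | None
    compound_id: str | None
    concentrations: np.ndarray
    gr_values: np.ndarray
    gr50: float | Censored | None


def gr_value(x0: float, x_ctrl: float, x_c: float) -> float:
    """Normalized growth-rate inhibition for one treated endpoint count.

    GR = 2^( log2(x_c / x0) / log2(x_ctrl / x0) ) - 1: equals 1 when
    treated cells grew like controls, 0 when the population merely held its
    initial size (cytostatic), negative when cells died below the inoculum.
    """
    if x0 <= 0 or x_c <= 0:
        raise ValueError("cell counts must be > 0")
    if x_ctrl <= x0:
        raise ValueError("no control growth; GR undefined")
    return float(2.0 ** (math.log2(x_c / x0) / math.log2(x_ctrl / x0)) - 1.0)


def compute_gr(
    x0: float,
    x_ctrl: float,
    concentrations: Sequence[float],
    treated_counts: Sequence[float],
    cell_line: str | None = None,
    compound_id: str | None = None,
) -> GRResult:
    """Per-concentration GR values and the GR50 crossing.

    GR50 is the concentration where the GR curve crosses 0.5: from a 4PL
    fit of GR against concentration when >= 4 distinct doses are available,
    otherwise by log-linear interpolation between the bracketing doses.
    Censored as a bound when the tested range never crosses 0.5.
    """
    conc = np.asarray(concentrations, dtype=float)
    counts = np.asarray(treated_counts, dtype=float)
    if conc.shape != counts.shape:
        raise ValueError("concentrations and counts differ in length")
    gr = np.array([gr_value(x0, x_ctrl, x) for x in counts])
    order = np.argsort(conc)
    conc, gr = conc[order], gr[order]

    gr50: float | Censored | None
    c_min, c_max = float(conc.min()), float(conc.max())
    if len(np.unique(conc)) >= 4 and not np.allclose(gr, gr[0]):
        fit = fit_4pl(conc, gr, compound_id=compound_id, cell_line=cell_line)
        if fit.converged and not fit.non_inhibitory:
            gr50 = absolute_ic50(fit, c_min, c_max, level=0.5)
        else:
            gr50 = _interp_crossing(conc, gr, 0.5)
    else:
        gr50 = _interp_crossing(conc, gr, 0.5)
    return GRResult(cell_line, compound_id, conc, gr, gr50)


def _interp_crossing(
    conc: np.ndarray, values: np.ndarray, level: float
) -> float | Censored:
    """Log-linear interpolation of the first downward crossing of ``level``."""
    if values.min() > level:
        return Censored(float(conc.max()), ">")
    if values.max() < level:
        return Censored(float(conc.min()), "<")
    for i in range(len(conc) - 1):
        v0, v1 = values[i], values[i + 1]
        if (v0 - level) * (v1 - level) <= 0 and v0 != v1:
            f = (v0 - level) / (v0 - v1)
            logc = np.log10(conc[i]) + f * (np.log10(conc[i + 1]) - np.log10(conc[i]))
            return float(10.0 ** logc)
    return Censored(float(conc.max()), ">")


def correlate_ic50_gr50(
    ic50s: Sequence[float | Censored],
    gr50s: Sequence[float | Censored],
) -> tuple[float, float, int, int]:
    """Spearman correlation of log-transformed paired potencies.

    Censored pairs are excluded; returns (rho, two-sided p, n_used,
    n_censored).  Requires >= 3 uncensored pairs.
    """
    if len(ic50s) != len(gr50s):
        raise ValueError("paired vectors differ in length")
    pairs = [
        (a, b)
        for a, b in zip(ic50s, gr50s)
        if is_finite_value(a) and is_finite_value(b)
    ]
    n_censored = len(ic50s) - len(pairs)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 uncensored pairs, got {len(pairs)}")
    x = np.log10([a for a, _ in pairs])
    y = np.log10([b for _, b in pairs])
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), len(pairs), n_censored


# ---------------------------------------------------------------------------
# population doubling level

#: literal constant used by the published update; 1/log10(2) = 3.3219...
PDL_CONSTANT = 3.32


@dataclass(frozen=True)
class PDLRecord:
    x0: float
    xt: float
    pdl_prev: float
    pdl: float


def pdl(
    x0: float, xt: float, pdl_prev: float = 0.0, exact: bool = False
) -> PDLRecord:
    """Cumulative population doubling level after one passage.

    PDL_n = k * (log10 Xt - log10 X0) + PDL_{n-1}, with k = 3.32 verbatim
    by default; ``exact=True`` switches to k = 1/log10(2) so one doubling
    increments the PDL by exactly 1.
    """
    if x0 <= 0 or xt <= 0:
        raise ValueError("cell counts must be > 0")
    k = 1.0 / math.log10(2.0) if exact else PDL_CONSTANT
    return PDLRecord(x0, xt, pdl_prev, k * (math.log10(xt) - math.log10(x0)) + pdl_prev)
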