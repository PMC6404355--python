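"""Four-parameter-logistic viability fitting and CHIR calibration curves.

Viability data come from CCK-8 assays as percent of the untreated control at
two-fold dilution series of a drug.  The dose-response model is the standard
descending 4PL

    V(d) = bottom + (top - bottom) / (1 + (d / IC50)^hill),       hill > 0,

fitted by least squares with the IC50 parameterized as log10(IC50).  The
95% CI on the IC50 comes from the asymptotic (delta-method) covariance with a
t-quantile at the residual degrees of freedom.  CHIR-induced IC50 shifts are
tested with a two-sided z-test on the difference of log10 IC50s.

The module also calibrates CHIR -> CYP induction (piecewise log-linear fold
curves anchored at (0 uM, 1-fold)) and normalizes P450-Glo luminescence to
CCK-8 absorbance per cell number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InvalidParameterError

CONDITION_UNTREATED = "untreated"
CONDITION_CHIR9 = "CHIR_9uM"

VIABILITY_COLUMNS = ["drug", "condition", "dose", "unit", "replicate", "viability_pct"]

__all__ = [
    "CONDITION_UNTREATED",
    "CONDITION_CHIR9",
    "VIABILITY_COLUMNS",
    "FourPLFit",
    "SharedSectionFit",
    "IC50Comparison",
    "InductionCurve",
    "DEFAULT_INDUCTION_CURVES",
    "fourpl",
    "fit_4pl",
    "fit_4pl_shared",
    "compare_ic50",
    "induction_at",
    "normalize_cyp_activity",
    "read_viability_csv",
    "fit_report",
]


def fourpl(dose, top: float, bottom: float, ic50: float, hill: float):
    """Descending four-parameter logistic; exact ``top`` at dose 0."""
    d = np.asarray(dose, dtype=float)
    ic = np.broadcast_to(np.asarray(ic50, dtype=float), d.shape)
    u = np.zeros_like(d)
    nz = d > 0
    u[nz] = (d[nz] / ic[nz]) ** hill
    return bottom + (top - bottom) / (1.0 + u)


def _model(d, top, bottom, log_ic50, hill):
    return fourpl(d, top, bottom, 10.0**log_ic50, hill)


@dataclass(frozen=True)
class FourPLFit:
    """A fitted 4PL dose-response curve with IC50 inference."""

    top: float  # %
    bottom: float  # %
    hill: float
    ic50: float  # dose units
    ic50_ci95: "tuple[float, float]"
    log_ic50_se: float  # SE of log10(IC50)
    rss: float
    dof: int
    converged: bool
    message: str = ""
    drug: str = ""
    condition: str = ""

    def predict(self, dose):
        return fourpl(dose, self.top, self.bottom, self.ic50, self.hill)


def _validate_table(dose: np.ndarray, viab: np.ndarray) -> None:
    if np.any(dose < 0):
        raise InvalidParameterError("doses must be >= 0")
    if not np.all(np.isfinite(viab)):
        raise InvalidParameterError("viabilities must be finite")
    if np.unique(dose[dose > 0]).size < 4:
        raise InvalidParameterError("need >= 4 distinct nonzero doses to fit a 4PL")


def _initial_guess(dose: np.ndarray, viab: np.ndarray) -> "tuple[float, float, float, float]":
    levels = np.unique(dose)
    means = np.array([viab[dose == d].mean() for d in levels])
    top0 = means[: min(2, means.size)].mean()
    bottom0 = means[-min(2, means.size):].mean()
    mid = 0.5 * (top0 + bottom0)
    nz = levels > 0
    lvl, m = levels[nz], means[nz]
    # first dose interval whose mean viabilities bracket the half-way level
    lam0 = None
    for i in range(lvl.size - 1):
        a, b = m[i], m[i + 1]
        if (a - mid) * (b - mid) <= 0 and a != b:
            w = (a - mid) / (a - b)
            lam0 = (1 - w) * math.log10(lvl[i]) + w * math.log10(lvl[i + 1])
            break
    if lam0 is None:
        lam0 = 0.5 * (math.log10(lvl[0]) + math.log10(lvl[-1]))
    return top0, bottom0, lam0, 1.0


def _censored_refine(
    dose: np.ndarray,
    viab: np.ndarray,
    popt: np.ndarray,
    rss: float,
    dof: int,
    floor: float = 0.0,
) -> "tuple[np.ndarray, float] | None":
    """Left-censored Gaussian ML refinement of a least-squares 4PL fit.

    Viability readouts cannot fall below 0, so wells at the floor are
    censored observations, not exact values; ignoring that biases plain
    least squares low on the IC50 whenever the bottom plateau saturates.
    The likelihood uses the normal density for uncensored wells and the
    normal CDF mass below the floor for censored ones, with a common noise
    scale estimated jointly.  Returns (parameters, SE of log10 IC50) or
    None when the refinement fails.
    """
    cens = viab <= floor
    sigma0 = math.sqrt(rss / dof) if dof > 0 else 1.0

    def nll(theta: np.ndarray) -> float:
        top, bottom, lam, hill, logsig = theta
        if hill <= 0:
            return float("inf")
        sig = math.exp(logsig)
        mu = _model(dose, top, bottom, lam, hill)
        ll = np.where(
            cens,
            stats.norm.logcdf((floor - mu) / sig),
            stats.norm.logpdf(viab, mu, sig),
        )
        return float(-np.sum(ll))

    th0 = np.concatenate([popt, [math.log(max(sigma0, 1e-6))]])
    res = optimize.minimize(
        nll, th0, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    if not np.isfinite(res.fun):
        return None
    th = res.x
    h = 1e-4 * np.maximum(np.abs(th), 1e-2)
    n = th.size
    hess = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            tpp, tpm, tmp, tmm = (th.copy() for _ in range(4))
            tpp[i] += h[i]; tpp[j] += h[j]
            tpm[i] += h[i]; tpm[j] -= h[j]
            tmp[i] -= h[i]; tmp[j] += h[j]
            tmm[i] -= h[i]; tmm[j] -= h[j]
            hess[i, j] = hess[j, i] = (
                nll(tpp) - nll(tpm) - nll(tmp) + nll(tmm)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    var = cov[2, 2]
    if not (np.isfinite(var) and var > 0):
        return None
    return th[:4], math.sqrt(var)


def fit_4pl(
    table: pd.DataFrame,
    dose_col: str = "dose",
    value_col: str = "viability_pct",
    censor_floor: "float | None" = 0.0,
) -> FourPLFit:
    """Fit a 4PL to a viability table (one drug, one condition).

    The table needs ``dose`` and ``viability_pct`` columns; dose-0 control
    wells participate in the fit and anchor the ``top`` plateau.  Initial
    values follow the plateau means and the dose interval bracketing 50%
    response.  The primary fit is least squares with a delta-method CI on
    log10 IC50; when wells sit at the viability floor (0% by default) the
    fit is refined by left-censored Gaussian ML, which removes the
    censoring bias of plain least squares (pass ``censor_floor=None`` to
    disable).  Non-convergence is flagged on the returned fit, never silent.
    """
    dose = table[dose_col].to_numpy(dtype=float)
    viab = table[value_col].to_numpy(dtype=float)
    _validate_table(dose, viab)
    drug = str(table["drug"].iloc[0]) if "drug" in table else ""
    condition = str(table["condition"].iloc[0]) if "condition" in table else ""
    p0 = _initial_guess(dose, viab)
    bounds = ([-np.inf, -np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf, np.inf])
    dof = dose.size - 4
    try:
        popt, pcov = optimize.curve_fit(
            _model, dose, viab, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        nan = float("nan")
        return FourPLFit(
            nan, nan, nan, nan, (nan, nan), nan, nan, dof, False,
            f"curve_fit did not converge: {exc}", drug, condition,
        )
    resid = viab - _model(dose, *popt)
    rss = float(resid @ resid)
    se_lam = float(np.sqrt(pcov[2, 2]))
    if censor_floor is not None and np.any(viab <= censor_floor):
        refined = _censored_refine(dose, viab, popt, rss, dof, censor_floor)
        if refined is not None:
            popt, se_lam = np.asarray(refined[0]), refined[1]
            resid = viab - _model(dose, *popt)
            rss = float(resid @ resid)
    top, bottom, lam, hill = popt
    tq = stats.t.ppf(0.975, dof) if dof > 0 else float("nan")
    ci = (10.0 ** (lam - tq * se_lam), 10.0 ** (lam + tq * se_lam))
    converged = bool(np.isfinite(se_lam) and bottom < top)
    msg = "" if converged else "degenerate fit (bottom >= top or singular covariance)"
    return FourPLFit(
        float(top), float(bottom), float(hill), float(10.0**lam), ci,
        se_lam, rss, dof, converged, msg, drug, condition,
    )


@dataclass(frozen=True)
class SharedSectionFit:
    """Joint 4PL fit across channel sections with shared top/bottom/hill.

    One viability table per section; each section gets its own log10 IC50
    while the plateaus and slope are common, mirroring a single drug assayed
    along the CHIR gradient.  ``cov_log_ic50`` is the asymptotic covariance
    of the per-section log10 IC50 estimates.
    """

    top: float
    bottom: float
    hill: float
    log_ic50: np.ndarray  # per section, log10
    cov_log_ic50: np.ndarray  # (k, k)
    rss: float
    dof: int
    converged: bool
    drug: str = ""

    @property
    def ic50(self) -> np.ndarray:
        return 10.0**self.log_ic50

    @property
    def log_ic50_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_log_ic50))

    def section_fits(self) -> "list[FourPLFit]":
        out = []
        tq = stats.t.ppf(0.975, self.dof) if self.dof > 0 else float("nan")
        for lam, se in zip(self.log_ic50, self.log_ic50_se):
            ci = (10.0 ** (lam - tq * se), 10.0 ** (lam + tq * se))
            out.append(
                FourPLFit(
                    self.top, self.bottom, self.hill, 10.0**lam, ci, float(se),
                    self.rss, self.dof, self.converged, "", self.drug,
                )
            )
        return out


def fit_4pl_shared(tables: "list[pd.DataFrame]", drug: str = "") -> SharedSectionFit:
    """Fit k viability tables jointly: shared (top, bottom, hill), k IC50s."""
    if len(tables) < 2:
        raise InvalidParameterError("need at least two section tables")
    doses, viabs, idx = [], [], []
    for s, tab in enumerate(tables):
        d = tab["dose"].to_numpy(dtype=float)
        v = tab["viability_pct"].to_numpy(dtype=float)
        _validate_table(d, v)
        doses.append(d)
        viabs.append(v)
        idx.append(np.full(d.size, s))
    dose = np.concatenate(doses)
    viab = np.concatenate(viabs)
    sec = np.concatenate(idx)
    k = len(tables)
    n = dose.size
    p = 3 + k

    inits = [_initial_guess(d, v) for d, v in zip(doses, viabs)]
    top0 = float(np.mean([g[0] for g in inits]))
    bot0 = float(np.mean([g[1] for g in inits]))
    lam0 = np.array([g[2] for g in inits])
    x0 = np.concatenate([[top0, bot0, 1.0], lam0])

    def resid(theta):
        top, bottom, hill = theta[:3]
        lam = theta[3:]
        return _model(dose, top, bottom, lam[sec], hill) - viab

    lb = np.full(p, -np.inf)
    ub = np.full(p, np.inf)
    lb[2] = 1e-6
    res = optimize.least_squares(resid, x0, bounds=(lb, ub), method="trf")
    dof = n - p
    rss = float(2.0 * res.cost)
    s2 = rss / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        ok = bool(res.success and np.all(np.isfinite(cov)))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        ok = False
    top, bottom, hill = res.x[:3]
    return SharedSectionFit(
        float(top), float(bottom), float(hill), res.x[3:].copy(),
        cov[3:, 3:].copy(), rss, dof, ok and bottom < top, drug,
    )


@dataclass(frozen=True)
class IC50Comparison:
    """Two-sided z-test on the difference of log10 IC50s."""

    ratio: float  # a.ic50 / b.ic50
    z: float
    p: float
    significant: bool


def compare_ic50(a: FourPLFit, b: FourPLFit, alpha: float = 0.05) -> IC50Comparison:
    """Test whether two fitted IC50s differ (e.g. untreated vs 9 uM CHIR)."""
    if not (a.converged and b.converged):
        raise InvalidParameterError("compare_ic50 requires converged fits")
    delta = math.log10(a.ic50) - math.log10(b.ic50)
    se = math.hypot(a.log_ic50_se, b.log_ic50_se)
    if se == 0.0:
        z = 0.0 if delta == 0.0 else math.inf * math.copysign(1.0, delta)
    else:
        z = delta / se
    pval = 2.0 * stats.norm.sf(abs(z))
    return IC50Comparison(a.ic50 / b.ic50, z, float(pval), bool(pval < alpha))


@dataclass(frozen=True)
class InductionCurve:
    """CHIR -> fold-induction calibration for one CYP isoform.

    Points are (chir uM, fold over untreated); (0, 1) is mandatory and folds
    are interpolated log-linearly between points, clamped beyond the range.
    """

    cyp: str
    points: "tuple[tuple[float, float], ...]"

    def __post_init__(self) -> None:
        chir = [p[0] for p in self.points]
        folds = [p[1] for p in self.points]
        if len(self.points) < 2:
            raise InvalidParameterError("need >= 2 calibration points")
        if any(np.diff(chir) <= 0):
            raise InvalidParameterError("points must be sorted by CHIR concentration")
        if chir[0] != 0.0 or abs(folds[0] - 1.0) > 1e-12:
            raise InvalidParameterError("curve must be anchored at (0 uM, 1-fold)")
        if any(f <= 0 for f in folds):
            raise InvalidParameterError("folds must be > 0 for log interpolation")


#: Fig-1 calibrated fold inductions at the 9 uM anchor; intermediate points
#: are generator-configurable, not asserted.
DEFAULT_INDUCTION_CURVES = {
    "CYP1A2": InductionCurve("CYP1A2", ((0.0, 1.0), (9.0, 20.0))),
    "CYP2E1": InductionCurve("CYP2E1", ((0.0, 1.0), (9.0, 5.0))),
    "CYP3A4": InductionCurve("CYP3A4", ((0.0, 1.0), (9.0, 5.0))),
    "CYP2B6": InductionCurve("CYP2B6", ((0.0, 1.0), (9.0, 1.0))),
}


def induction_at(curve: InductionCurve, chir) -> "float | np.ndarray":
    """Fold induction at a CHIR concentration (uM), log-linear between points."""
    c = np.asarray(chir, dtype=float)
    if np.any(c < 0):
        raise InvalidParameterError("chir must be >= 0")
    xs = np.array([p[0] for p in curve.points])
    logf = np.log(np.array([p[1] for p in curve.points]))
    out = np.exp(np.interp(np.clip(c, xs[0], xs[-1]), xs, logf))
    return float(out) if out.ndim == 0 else out


def normalize_cyp_activity(luminescence, absorbance, control=None):
    """P450-Glo luminescence per CCK-8 absorbance (per-cell CYP activity).

    With ``control=(lum0, abs0)`` the ratio is rescaled relative to the
    control condition's ratio.
    """
    lum = np.asarray(luminescence, dtype=float)
    ab = np.asarray(absorbance, dtype=float)
    if np.any(ab <= 0):
        raise InvalidParameterError("absorbance must be > 0")
    ratio = lum / ab
    if control is not None:
        lum0, ab0 = control
        if ab0 <= 0 or lum0 <= 0:
            raise InvalidParameterError("control luminescence and absorbance must be > 0")
        ratio = ratio / (lum0 / ab0)
    return float(ratio) if ratio.ndim == 0 else ratio


def read_viability_csv(path) -> pd.DataFrame:
    """Read a viability CSV (drug,condition,dose,unit,replicate,viability_pct)."""
    df = pd.read_csv(path)
    missing = [c for c in ("dose", "viability_pct") if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"viability CSV missing columns: {missing}")
    return df


def fit_report(df: pd.DataFrame) -> "dict[str, dict]":
    """Fit every (drug, condition) group of a viability table.

    Returns a JSON-ready mapping ``"drug/condition" -> FourPLFit fields``.
    """
    out: "dict[str, dict]" = {}
    for (drug, cond), grp in df.groupby(["drug", "condition"], sort=True):
        fit = fit_4pl(grp)
        out[f"{drug}/{cond}"] = {
            "drug": drug,
            "condition": cond,
            "top": fit.top,
            "bottom": fit.bottom,
            "hill": fit.hill,
            "ic50": fit.ic50,
            "ic50_ci95": list(fit.ic50_ci95),
            "log_ic50_se": fit.log_ic50_se,
            "rss": fit.rss,
            "dof": fit.dof,
            "converged": fit.converged,
            "message": fit.message,
        }
    return out
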