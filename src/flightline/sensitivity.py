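"""Per-species phenological sensitivity with influence-based outlier screening.

For each species, onset day-of-year is regressed on a predictor (mean
spring temperature, or calendar year).  Opportunistic data occasionally
produce onset estimates displaced by months — artefacts of unusual
survey events rather than biology — so highly influential species-years
are identified on the initial fit by Cook's distance and removed with
the conventional 4/n cutoff, and the model is refit once on the
survivors.  The refit slope is the phenological sensitivity: days of
onset shift per unit of the predictor (days/degC for temperature).

Cook's distance for observation i under a p-parameter least-squares fit:

    D_i = e_i^2 / (p * s^2) * h_ii / (1 - h_ii)^2

with e_i the residual, h_ii the leverage and s^2 the residual mean
square.  This closed form equals the leave-one-out definition
D_i = sum_j (yhat_j - yhat_j(i))^2 / (p * s^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class OLSFit:
    """Simple linear regression summary (two parameters, intercept + slope)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_se: float
    n: int
    residuals: np.ndarray
    leverages: np.ndarray
    s2: float  # residual mean square, SSE / (n - 2)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        half = stats.t.ppf(0.5 + level / 2, self.n - 2) * self.slope_se
        return self.slope - half, self.slope + half


@dataclass(frozen=True)
class SensitivityFit:
    """Per-species regression summary for one predictor.

    ``ok`` is False (and the estimates NaN) when too few points survive
    screening to support a fit; such species are flagged, never silently
    reported.
    """

    species: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_se: float
    mean_onset: float
    sd_onset: float
    n_initial: int
    n_used: int
    n_removed: int
    removed_years: tuple[int, ...]
    ok: bool = True
    note: str = ""


def fit_ols(x: np.ndarray, y: np.ndarray) -> OLSFit:
    """Ordinary least squares of y on x with intercept.

    The slope p-value is the two-sided t-test with n-2 degrees of
    freedom.  Requires n >= 3 and a non-constant predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points to fit, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; slope is not identifiable")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    e = y - fitted
    sxx = float(np.sum((x - x.mean()) ** 2))
    h = 1.0 / n + (x - x.mean()) ** 2 / sxx
    s2 = float(np.sum(e**2) / (n - 2))
    return OLSFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope_se=float(res.stderr),
        n=n,
        residuals=e,
        leverages=h,
        s2=s2,
    )


def cooks_distance(fit: OLSFit) -> np.ndarray:
    """Cook's distance of each point under ``fit`` (p = 2 parameters)."""
    h = fit.leverages
    near_one = h >= 1.0 - 1e-12
    if near_one.any():
        i = int(np.flatnonzero(near_one)[0])
        raise ValueError(f"point {i} has leverage 1; Cook's distance undefined")
    if fit.s2 == 0.0:
        return np.zeros_like(h)
    return fit.residuals**2 / (2.0 * fit.s2) * h / (1.0 - h) ** 2


def screen_and_refit(
    years: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    species: str = "",
    predictor: str = "temperature",
    remove_outliers: bool = True,
    cutoff: float | None = None,
    iterate: bool = False,
    min_points: int = 5,
    moments_on: str = "survivors",
) -> SensitivityFit:
    """Fit, screen high-influence points at Cook's D > 4/n, and refit once.

    Parameters
    ----------
    years, x, y
        Year labels, predictor values and onset days, aligned.
    remove_outliers
        If False, report the plain fit (the outliers-included variant).
    cutoff
        Influence cutoff; defaults to 4/n with n the *initial* number of
        points.
    iterate
        Repeat screen+refit until no point exceeds the cutoff (off by
        default: the standard procedure is a single pass).
    min_points
        Minimum surviving points to report a fit; below it a flagged
        null result is returned.
    moments_on
        Compute mean/SD of onset on ``"survivors"`` (default) or
        ``"all"`` points.

    Screening is a set operation on the initial fit's distances, so it is
    invariant to the ordering of the input points.
    """
    years = np.asarray(years)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(years) == len(x) == len(y)):
        raise ValueError("years, x and y must be aligned")
    if moments_on not in ("survivors", "all"):
        raise ValueError(f"unknown moments_on: {moments_on!r}")

    n0 = len(x)
    keep = np.ones(n0, dtype=bool)

    def null_result(note: str) -> SensitivityFit:
        nan = float("nan")
        return SensitivityFit(
            species=species,
            predictor=predictor,
            slope=nan,
            intercept=nan,
            r_squared=nan,
            p_value=nan,
            slope_se=nan,
            mean_onset=nan,
            sd_onset=nan,
            n_initial=n0,
            n_used=int(keep.sum()),
            n_removed=int(n0 - keep.sum()),
            removed_years=tuple(int(t) for t in sorted(years[~keep])),
            ok=False,
            note=note,
        )

    if n0 < 3:
        return null_result("fewer than 3 points")

    fit = fit_ols(x, y)
    if remove_outliers:
        while True:
            d = np.full(n0, np.nan)
            d[keep] = cooks_distance(fit)
            thr = cutoff if cutoff is not None else 4.0 / int(keep.sum())
            flag = keep & (d > thr)
            if not flag.any():
                break
            keep &= ~flag
            n_kept = int(keep.sum())
            if n_kept < max(min_points, 3):
                return null_result(
                    f"only {n_kept} points survive influence screening"
                )
            fit = fit_ols(x[keep], y[keep])
            if not iterate:
                break

    moments = y[keep] if moments_on == "survivors" else y
    return SensitivityFit(
        species=species,
        predictor=predictor,
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        p_value=fit.p_value,
        slope_se=fit.slope_se,
        mean_onset=float(np.mean(moments)),
        sd_onset=float(np.std(moments, ddof=1)) if len(moments) > 1 else 0.0,
        n_initial=n0,
        n_used=int(keep.sum()),
        n_removed=int(n0 - keep.sum()),
        removed_years=tuple(int(t) for t in sorted(years[~keep])),
        ok=True,
        note="",
    )


def fit_sensitivities(
    onsets: pd.DataFrame,
    spring_temp: pd.DataFrame | None = None,
    predictor: str = "temperature",
    **screen_kwargs,
) -> pd.DataFrame:
    """Fit every species' sensitivity to one predictor.

    Parameters
    ----------
    onsets
        Long table ``species, year, onset_doy`` (plus optional columns).
    spring_temp
        Annual index ``year, temp_c``; required when
        ``predictor="temperature"``.
    predictor
        ``"temperature"`` or ``"year"``.
    **screen_kwargs
        Forwarded to :func:`screen_and_refit`.

    Returns a table with one row per species mirroring the standard
    per-species summary: slope, r^2, p, mean/SD onset, counts and the
    removed years.
    """
    if predictor == "temperature":
        if spring_temp is None:
            raise ValueError("temperature predictor requires spring_temp table")
        df = onsets.merge(spring_temp[["year", "temp_c"]], on="year", how="inner")
        xcol = "temp_c"
    elif predictor == "year":
        df = onsets.copy()
        df["year_value"] = df["year"].astype(float)
        xcol = "year_value"
    else:
        raise ValueError(f"unknown predictor: {predictor!r}")

    rows = []
    for species, grp in df.groupby("species", sort=True):
        fit = screen_and_refit(
            years=grp["year"].to_numpy(),
            x=grp[xcol].to_numpy(),
            y=grp["onset_doy"].to_numpy(dtype=float),
            species=str(species),
            predictor=predictor,
            **screen_kwargs,
        )
        rows.append(
            {
                "species": fit.species,
                "predictor": fit.predictor,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "slope_se": fit.slope_se,
                "intercept": fit.intercept,
                "mean_onset": fit.mean_onset,
                "sd_onset": fit.sd_onset,
                "n_initial": fit.n_initial,
                "n_used": fit.n_used,
                "n_removed": fit.n_removed,
                "removed_years": ";".join(str(t) for t in fit.removed_years),
                "ok": fit.ok,
                "note": fit.note,
            }
        )
    return pd.DataFrame(rows)
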