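"""Robust log-dose vs normalized-response IC50 fitting and group comparison.

The default model is the normalized two-parameter logistic

    y(d) = 100 / (1 + 10^((log10 d − log10 IC50) · hill)),   hill > 0,

so the response falls from 100% (vehicle) towards 0% with increasing dose
and equals 50% exactly at the IC50.  The four-parameter variant frees the
top and bottom plateaus.  Fitting is robust nonlinear least squares
(soft-L1 loss) in two stages: an ordinary fit provides residuals whose
scaled MAD (1.482·MAD) sets the robust loss scale for the refit, so a
single gross outlier point barely moves the estimate.

Zero-dose (vehicle) wells cannot enter a log-dose model; they are used only
to renormalize responses to percent of vehicle, then excluded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import NoInhibitionError, ParameterError

__all__ = ["FitResult", "dose_response_model", "fit_ic50", "compare_ic50_by_group"]


@dataclass
class FitResult:
    """Converged (or not) dose-response fit for one sample/drug."""

    log10_ic50: float
    hill_slope: float
    top: float
    bottom: float
    converged: bool
    model: str
    loss: str
    residual_scale: float
    n_points: int

    @property
    def ic50(self) -> float:
        return float(10.0 ** self.log10_ic50)


def dose_response_model(
    dose: np.ndarray,
    log10_ic50: float,
    hill: float,
    top: float = 100.0,
    bottom: float = 0.0,
) -> np.ndarray:
    """Forward model: viability (%) at each dose (same units as the IC50)."""
    x = np.log10(np.asarray(dose, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((x - log10_ic50) * hill))


def _initial_log10_ic50(logd: np.ndarray, y: np.ndarray) -> float:
    return float(logd[np.argmin(np.abs(y - 50.0))])


def fit_ic50(
    doses,
    viability,
    model: str = "normalized_2p",
    flat_range: float = 10.0,
) -> FitResult:
    """Fit the IC50 of one dose-response series.

    Parameters
    ----------
    doses : array of dose values (any consistent unit); zero doses are used
        to renormalize ``viability`` to percent of vehicle and then dropped.
    viability : array, % of vehicle.
    model : {"normalized_2p", "four_param"}
    flat_range : float
        Minimum response range (% points); flatter series raise
        :class:`~e2fsig.exceptions.NoInhibitionError`.

    Notes
    -----
    ``converged`` is False (never an exception) when the optimizer fails or
    the fitted IC50 lies more than 2 decades outside the dose range.
    """
    if model not in ("normalized_2p", "four_param"):
        raise ParameterError(f"unknown model {model!r}")
    d = np.asarray(doses, dtype=float)
    y = np.asarray(viability, dtype=float)
    if d.shape != y.shape:
        raise ParameterError("doses and viability must align")
    if not np.isfinite(y).all() or (d < 0).any():
        raise ParameterError("doses must be ≥0 and viability finite")
    vehicle = d == 0
    if vehicle.any():
        anchor = float(y[vehicle].mean())
        if anchor <= 0:
            raise ParameterError("vehicle viability must be positive")
        y = y * 100.0 / anchor
        d, y = d[~vehicle], y[~vehicle]
    if np.unique(d).size < 4:
        raise ParameterError("need ≥4 distinct positive doses")
    if float(y.max() - y.min()) < flat_range:
        raise NoInhibitionError(
            f"response range {y.max() - y.min():.1f}% < {flat_range}%; IC50 undefined"
        )
    logd = np.log10(d)

    if model == "normalized_2p":
        def resid(p, yy=y):
            return dose_response_model(d, p[0], p[1]) - yy
        p0 = np.array([_initial_log10_ic50(logd, y), 1.0])
        lb = np.array([logd.min() - 6, 0.05])
        ub = np.array([logd.max() + 6, 10.0])
    else:
        def resid(p, yy=y):
            return dose_response_model(d, p[0], p[1], p[2], p[3]) - yy
        p0 = np.array([_initial_log10_ic50(logd, y), 1.0, float(y.max()), float(y.min())])
        lb = np.array([logd.min() - 6, 0.05, 10.0, -50.0])
        ub = np.array([logd.max() + 6, 10.0, 200.0, 90.0])
    p0 = np.clip(p0, lb, ub)

    try:
        first = optimize.least_squares(resid, p0, bounds=(lb, ub))
        mad = float(np.median(np.abs(first.fun - np.median(first.fun))))
        scale = max(1.482 * mad, 1.0)  # floor keeps noiseless fits exact
        fit = optimize.least_squares(
            resid, first.x, bounds=(lb, ub), loss="soft_l1", f_scale=scale
        )
        ok = bool(fit.success)
        params = fit.x
    except Exception:
        ok, params, scale = False, p0, float("nan")

    log10_ic50 = float(params[0])
    in_range = logd.min() - 2 <= log10_ic50 <= logd.max() + 2
    if model == "normalized_2p":
        top, bottom = 100.0, 0.0
    else:
        top, bottom = float(params[2]), float(params[3])
        if top <= bottom:
            ok = False
    return FitResult(
        log10_ic50=log10_ic50,
        hill_slope=float(params[1]),
        top=top,
        bottom=bottom,
        converged=bool(ok and in_range),
        model=model,
        loss="soft_l1",
        residual_scale=scale,
        n_points=int(d.size),
    )


def fit_response_table(
    responses: pd.DataFrame, model: str = "normalized_2p"
) -> pd.DataFrame:
    """Fit every (sample_id, drug) series of a long-format response table.

    Expects columns ``sample_id, drug, dose_uM, viability_pct`` (replicate
    rows at the same dose are simply pooled).  Returns one row per series
    with the FitResult fields; series that raise (flat response, too few
    doses) get ``converged=False`` and a ``note``.
    """
    needed = {"sample_id", "drug", "dose_uM", "viability_pct"}
    if not needed <= set(responses.columns):
        raise ParameterError(f"response table needs columns {sorted(needed)}")
    rows = []
    for (sid, drug), grp in responses.groupby(["sample_id", "drug"], sort=False):
        note = ""
        try:
            fr = fit_ic50(grp["dose_uM"], grp["viability_pct"], model=model)
        except (NoInhibitionError, ParameterError) as err:
            fr = None
            note = str(err)
        rows.append(
            {
                "sample_id": sid,
                "drug": drug,
                "log10_ic50": fr.log10_ic50 if fr else np.nan,
                "ic50": fr.ic50 if fr else np.nan,
                "hill_slope": fr.hill_slope if fr else np.nan,
                "converged": bool(fr.converged) if fr else False,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def compare_ic50_by_group(fits: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Compare fitted IC50s between two groups, per drug.

    ``fits`` is the output of :func:`fit_response_table`; ``labels`` maps
    sample_id → group label (exactly two levels among the fitted samples).
    Group means ± SEM are reported on the linear µM scale; the two-sided
    Welch t-test runs on log10 IC50.  Non-converged fits are excluded and
    counted.
    """
    lab = fits["sample_id"].map(labels)
    if lab.isna().any():
        missing = fits.loc[lab.isna(), "sample_id"].unique().tolist()
        raise ParameterError(f"samples without a group label: {missing[:5]}")
    levels = sorted(lab.unique())
    if len(levels) != 2:
        raise ParameterError(f"need exactly 2 group labels, got {levels}")
    out = []
    for drug, grp in fits.groupby("drug", sort=False):
        glab = grp["sample_id"].map(labels)
        used = grp[grp["converged"]]
        ulab = used["sample_id"].map(labels)
        row: dict = {"drug": drug, "n_excluded": int((~grp["converged"]).sum())}
        sides = {}
        for lv in levels:
            vals = used.loc[ulab == lv, "log10_ic50"].to_numpy()
            if vals.size < 2:
                raise ParameterError(f"drug {drug!r}: group {lv!r} has <2 usable fits")
            lin = 10.0 ** vals
            sides[lv] = vals
            row[f"n_{lv}"] = int(vals.size)
            row[f"mean_ic50_{lv}"] = float(lin.mean())
            row[f"sem_ic50_{lv}"] = float(lin.std(ddof=1) / np.sqrt(lin.size))
        t, p = stats.ttest_ind(sides[levels[0]], sides[levels[1]], equal_var=False)
        row["t_log10"] = float(t)
        row["p_value"] = float(p)
        out.append(row)
    return pd.DataFrame(out)
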