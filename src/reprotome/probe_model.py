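"""Model-based expression indices from probe-level intensities.

Implements the multiplicative probe model y_ij ~ theta_i * phi_j on the
mismatch-corrected signal y = PM - MM, fitted per probeset by alternating
least squares under the identifiability constraint sum(phi_j^2) = J, with an
iterative outlier-exclusion rule, plus the lower-confidence-bound (LCB)
fold-change statistic: a 90% normal-theory confidence interval on the ratio
of group mean indices whose lower limit is the conservative measure of
differential expression.

Arrays are first normalized to the array with the median overall intensity
by linear rescaling of every other array's mean onto the reference mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, NormalizationError
from .simulate import ProbeMatrix

__all__ = [
    "ExpressionMatrix",
    "FoldChangeCI",
    "normalize_to_median_array",
    "fit_expression_index",
    "fold_change_with_ci",
    "fold_change_ci_from_summary",
    "group_mean_se",
    "EPS_FLOOR",
]

EPS_FLOOR = 1.0  # intensity units; floor for signals and denominators


@dataclass
class ExpressionMatrix:
    """Per-transcript expression indices theta with standard errors.

    ``theta``/``se`` are transcripts x samples data frames (columns are
    sample ids); ``phi`` maps transcript -> fitted probe-sensitivity vector;
    ``outlier_mask`` maps transcript -> boolean (J, A) array, True where a
    cell was excluded from the fit.  Unreliable transcripts (every cell
    excluded) carry NaN theta and are skipped downstream.
    """

    theta: pd.DataFrame
    se: pd.DataFrame
    samples: pd.DataFrame
    phi: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    outlier_mask: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.theta.index)

    def columns_for(self, condition: str, timepoint: str | None = None) -> list[str]:
        s = self.samples
        keep = s["condition"] == condition
        if timepoint is not None:
            keep &= s["timepoint"] == timepoint
        return list(s.loc[keep, "sample_id"])


@dataclass(frozen=True)
class FoldChangeCI:
    """Fold change of group means with its confidence interval."""

    fc: float
    lcb: float
    ucb: float
    level: float = 0.90

    def __post_init__(self):
        if not (self.lcb <= self.fc + 1e-12 and self.fc <= self.ucb + 1e-12):
            raise ValueError(f"CI invariant violated: {self.lcb}, {self.fc}, {self.ucb}")


# ---------------------------------------------------------------------------
# normalization


def normalize_to_median_array(pm: ProbeMatrix) -> tuple[ProbeMatrix, pd.Series]:
    """Rescale every array onto the array with the median mean intensity.

    The reference is the array whose overall mean intensity (over all PM and
    MM cells) is the median of per-array means; with an even array count the
    lower-mean array of the middle pair is taken.  Each other array is
    multiplied by ref_mean / its own mean.  Returns the rescaled matrix and
    the per-array scale factors.
    """
    if pm.pm.shape[1] < 1:
        raise ArgumentError("need at least one array")
    means = (pm.pm.mean(axis=0) + pm.mm.mean(axis=0)) / 2.0
    zero = np.where(means <= 0)[0]
    if zero.size:
        sid = pm.sample_ids[zero[0]]
        raise NormalizationError(f"array {sid!r} has non-positive mean intensity")
    order = np.argsort(means, kind="stable")
    a = len(means)
    ref = order[(a - 1) // 2]  # even count: lower-mean array of the middle pair
    factors = means[ref] / means
    out = pm.copy()
    out.pm *= factors[None, :]
    out.mm *= factors[None, :]
    return out, pd.Series(factors, index=pm.sample_ids, name="scale_factor")


# ---------------------------------------------------------------------------
# probe-model fit


def _als(y: np.ndarray, w: np.ndarray, tol: float = 1e-12, max_iter: int = 200):
    """Weighted rank-1 fit y ~ theta phi for a (G, J, A) block.

    Returns theta (G, A) and phi (G, J) with sum of retained phi^2 equal to
    the number of retained probes per probeset.
    """
    G, J, A = y.shape
    yw = y * w
    phi = np.ones((G, J))
    retained = w.sum(axis=2) > 0                    # (G, J)
    jr = np.maximum(retained.sum(axis=1), 1)        # (G,)
    theta = yw.sum(axis=1) / np.maximum(w.sum(axis=1), 1)
    for _ in range(max_iter):
        denom = np.einsum("gja,gj->ga", w, phi**2)
        theta_new = np.einsum("gja,gj->ga", yw, phi) / np.maximum(denom, 1e-300)
        denom = np.einsum("gja,ga->gj", w, theta_new**2)
        phi_new = np.einsum("gja,ga->gj", yw, theta_new) / np.maximum(denom, 1e-300)
        ss = np.sum(phi_new**2 * retained, axis=1)
        c = np.sqrt(np.maximum(ss, 1e-300) / jr)
        phi_new /= c[:, None]
        theta_new *= c[:, None]
        delta = np.max(np.abs(theta_new - theta)) / max(np.max(np.abs(theta_new)), 1e-300)
        theta, phi = theta_new, phi_new
        if delta < tol:
            break
    return theta, phi


def _polish_log_residuals(y: np.ndarray, w: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """Robust log-scale residuals of the multiplicative model via median polish.

    On the log scale the model is additive (log y = log theta + log phi), so
    alternately sweeping probe and array medians out of log y leaves residuals
    that a gross outlier cannot drag toward itself — unlike least-squares
    residuals, which a 100x contaminated cell in a small probeset dominates.
    Excluded cells are NaN.
    """
    r = np.where(w > 0, np.log(np.maximum(y, 1e-12)), np.nan)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_iter):
            med = np.nanmedian(r, axis=2, keepdims=True)
            r = r - np.nan_to_num(med)
            med = np.nanmedian(r, axis=1, keepdims=True)
            r = r - np.nan_to_num(med)
    return r


def _fit_block(y: np.ndarray, valid: np.ndarray, max_rounds: int, z_cut: float):
    """Fit one equal-probe-count block with iterative outlier exclusion.

    Each round computes robust (median-polish) standardized residuals on the
    retained cells; cells above ``z_cut`` robust standard deviations are
    excluded, then whole probes/arrays with more than half of their cells
    excluded; the mask is recomputed fresh each round (re-inclusion allowed)
    and iteration stops when it is stable or after ``max_rounds`` rounds.
    The reported fit is weighted alternating least squares on retained cells.
    """
    G, J, A = y.shape
    w = valid.astype(float)
    for _ in range(max_rounds):
        rel = _polish_log_residuals(y, w)
        absr = np.where(w > 0, np.abs(rel), np.nan)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mad = np.nanmedian(absr.reshape(G, -1), axis=1)
        sigma = np.maximum(1.4826 * mad, 1e-8)
        excl = valid & (np.abs(np.nan_to_num(rel)) > z_cut * sigma[:, None, None])
        # probes / arrays with more than half of their cells excluded
        keep = valid & ~excl
        bad_probe = excl.sum(axis=2) > (valid.sum(axis=2) / 2.0)
        keep &= ~bad_probe[:, :, None]
        bad_array = excl.sum(axis=1) > (valid.sum(axis=1) / 2.0)
        keep &= ~bad_array[:, None, :]
        w_new = keep.astype(float)
        if np.array_equal(w_new, w):
            break
        w = w_new
    theta, phi = _als(y, w)
    resid = (y - theta[:, None, :] * phi[:, :, None]) * w
    # standard errors from the final weighted fit
    ncell = w.sum(axis=(1, 2))
    jr = (w.sum(axis=2) > 0).sum(axis=1)
    ar = (w.sum(axis=1) > 0).sum(axis=1)
    dof = ncell - (jr + ar - 1)
    rss = np.sum(resid**2, axis=(1, 2))
    sigma2 = np.where(dof > 0, rss / np.maximum(dof, 1), 0.0)
    denom = np.einsum("gja,gj->ga", w, phi**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2[:, None] / denom)
    se[denom <= 0] = np.nan
    dead = w.sum(axis=1) <= 0                       # (G, A): array fully excluded
    theta = np.where(dead, np.nan, theta)
    se = np.where(dead, np.nan, se)
    return theta, se, phi, ~(w > 0)


def fit_expression_index(
    pm: ProbeMatrix,
    *,
    floor: float = EPS_FLOOR,
    max_outlier_rounds: int = 5,
    resid_z: float = 3.0,
) -> ExpressionMatrix:
    """Fit the multiplicative probe model to every probeset.

    The mismatch-corrected signal PM - MM (truncated below ``floor``) is fit
    as theta_i * phi_j per probeset; cells flagged by the outlier rule are
    excluded and refitted.  Fitted theta is floored at ``floor``.
    """
    y_all = pm.pm - pm.mm
    y_all = np.maximum(y_all, floor)
    psets, first, inverse, counts = np.unique(
        pm.probeset_ids, return_index=True, return_inverse=True, return_counts=True
    )
    order_pres = np.argsort(first, kind="stable")   # preserve input probeset order
    row_order = np.argsort(inverse, kind="stable")  # rows grouped by probeset
    starts = np.cumsum(counts) - counts

    theta_rows, se_rows, ids = [], [], []
    phi_map: dict[str, np.ndarray] = {}
    mask_map: dict[str, np.ndarray] = {}

    # group probesets by probe count so each group fits as one (G, J, A) block
    for J in np.unique(counts):
        sel = np.where(counts == J)[0]
        sel = sel[np.argsort(first[sel], kind="stable")]
        idx = np.stack([row_order[starts[p] : starts[p] + J] for p in sel])  # (G, J)
        y = y_all[idx]                              # (G, J, A)
        valid = np.ones(y.shape, bool)
        theta, se, phi, excl = _fit_block(y, valid, max_outlier_rounds, resid_z)
        theta = np.where(np.isnan(theta), np.nan, np.maximum(theta, floor))
        for g, p in enumerate(sel):
            name = str(psets[p])
            ids.append(name)
            theta_rows.append(theta[g])
            se_rows.append(se[g])
            phi_map[name] = phi[g]
            mask_map[name] = excl[g]

    frame_order = [str(psets[p]) for p in order_pres]
    theta_df = pd.DataFrame(theta_rows, index=ids, columns=pm.sample_ids).loc[frame_order]
    se_df = pd.DataFrame(se_rows, index=ids, columns=pm.sample_ids).loc[frame_order]
    return ExpressionMatrix(
        theta=theta_df, se=se_df, samples=pm.samples.copy(),
        phi=phi_map, outlier_mask=mask_map,
    )


# ---------------------------------------------------------------------------
# fold change with confidence interval


def group_mean_se(values: np.ndarray, ses: np.ndarray | None = None) -> tuple[float, float]:
    """Mean and standard error of a replicate group of expression indices.

    The group SE combines the between-replicate scatter of theta with the
    mean within-sample fitting variance, in quadrature:
    SE^2 = var(theta)/n + mean(se_theta^2)/n.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ArgumentError("empty group")
    if not np.isfinite(v).all():
        raise ArgumentError("group contains non-finite expression indices")
    n = v.size
    var_between = float(np.var(v, ddof=1)) if n > 1 else 0.0
    var_within = float(np.mean(np.square(ses))) if ses is not None else 0.0
    return float(np.mean(v)), math.sqrt(var_between / n + var_within / n)


def _z(level: float) -> float:
    if not 0 < level < 1:
        raise ArgumentError(f"level must lie in (0, 1), got {level}")
    return float(stats.norm.ppf(0.5 + level / 2.0))


def fold_ci_arrays(trt_mean, trt_se, ref_mean, ref_se, level=0.90, floor=EPS_FLOOR):
    """Vectorized fc / lcb / ucb on group summaries (see fold_change_with_ci)."""
    z = _z(level)
    trt_mean = np.asarray(trt_mean, float)
    ref_mean = np.maximum(np.asarray(ref_mean, float), floor)
    trt_se = np.asarray(trt_se, float)
    ref_se = np.asarray(ref_se, float)
    fc = trt_mean / ref_mean
    lcb = np.maximum(0.0, trt_mean - z * trt_se) / (ref_mean + z * ref_se)
    lo_ref = ref_mean - z * ref_se
    with np.errstate(divide="ignore"):
        ucb = np.where(
            lo_ref > floor, (trt_mean + z * trt_se) / np.maximum(lo_ref, floor), np.inf
        )
    return fc, lcb, ucb


def fold_change_ci_from_summary(
    trt_mean: float, trt_se: float, ref_mean: float, ref_se: float,
    level: float = 0.90, floor: float = EPS_FLOOR,
) -> FoldChangeCI:
    """Fold-change CI from group means and standard errors.

    fc = mean(trt)/mean(ref); the interval shifts each group mean by z
    standard errors (z the two-sided normal quantile, 1.645 at level 0.90):
    lcb = max(0, trt - z se_trt) / (ref + z se_ref) and
    ucb = (trt + z se_trt) / max(floor, ref - z se_ref), with ucb = +inf when
    the denominator floors.  The lower limit (LCB) is the study's measure of
    differential expression.
    """
    fc, lcb, ucb = fold_ci_arrays(trt_mean, trt_se, ref_mean, ref_se, level, floor)
    return FoldChangeCI(fc=float(fc), lcb=float(lcb), ucb=float(ucb), level=level)


def fold_change_with_ci(
    ref_values, trt_values, ref_se=None, trt_se=None,
    level: float = 0.90, floor: float = EPS_FLOOR,
) -> FoldChangeCI:
    """Fold-change CI from per-sample expression indices (and optional SEs)."""
    rm, rs = group_mean_se(ref_values, ref_se)
    tm, ts = group_mean_se(trt_values, trt_se)
    return fold_change_ci_from_summary(tm, ts, rm, rs, level=level, floor=floor)
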