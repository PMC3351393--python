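"""Regulated-transcript calls under the compound two-timepoint rule.

A transcript is called regulated when its lower-confidence-bound fold change
reaches 1.5 with an unpaired P < 0.05 in the treated-versus-control
comparison at day 3 and/or day 14; transcripts that instead change between
day 3 and day 14 in treated cells, but not in controls, are rescued by the
time-course clause.  Down-calls apply the same rule to the LCB of the
reciprocal (control/treated) comparison.  The target-enriched reference set
uses the stricter LCB >= 1.5, P < 0.01 contrast of target versus source
populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ArgumentError
from .probe_model import EPS_FLOOR, ExpressionMatrix, fold_ci_arrays, group_mean_se

__all__ = [
    "Contrast",
    "DifferentialRecord",
    "GeneSet",
    "unpaired_test",
    "call_regulated",
    "differential_table",
    "build_enriched_set",
    "collapse_to_genes",
]


def normalize_id(gene: str) -> str:
    return gene.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers, compared case-insensitively."""

    name: str
    members: frozenset[str]
    annotation: dict[str, str] = field(default_factory=dict, compare=False)

    @classmethod
    def from_ids(cls, name: str, ids, annotation: dict | None = None) -> "GeneSet":
        return cls(name, frozenset(normalize_id(g) for g in ids), dict(annotation or {}))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return normalize_id(gene) in self.members

    def intersection(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}&{other.name}", self.members & other.members)

    def union(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}|{other.name}", self.members | other.members)

    def sorted_ids(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class Contrast:
    """One two-group comparison: fold change, CI bounds both ways, p-value."""

    fc: float = 1.0
    lcb: float = 0.0
    ucb: float = np.inf
    lcb_recip: float = 0.0  # LCB of the swapped (reference/treated) ratio
    p: float = 1.0


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-transcript differential summary across the compound rule's clauses."""

    transcript_id: str
    d3: Contrast = Contrast()
    d14: Contrast = Contrast()
    timecourse_trt: Contrast = Contrast()
    timecourse_ctrl: Contrast = Contrast()
    call: str = "none"
    call_basis: tuple[str, ...] = ()

    # convenience accessors mirroring the flat table columns
    @property
    def fc_d3(self):
        return self.d3.fc

    @property
    def lcb_d3(self):
        return self.d3.lcb

    @property
    def p_d3(self):
        return self.d3.p

    @property
    def fc_d14(self):
        return self.d14.fc

    @property
    def lcb_d14(self):
        return self.d14.lcb

    @property
    def p_d14(self):
        return self.d14.p


# ---------------------------------------------------------------------------
# testing


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sided unpaired t-test with the zero-variance convention."""
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, axis=-1, equal_var=equal_var, nan_policy="omit")
        p = np.asarray(res.pvalue, float)
        va = np.nanvar(a, axis=-1)
        vb = np.nanvar(b, axis=-1)
        degenerate = (va == 0) & (vb == 0)
        equal_means = np.isclose(np.nanmean(a, axis=-1), np.nanmean(b, axis=-1))
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    return p


def unpaired_test(
    group_a, group_b, *, flavor: str = "welch", log_scale: bool = True,
    floor: float = EPS_FLOOR,
) -> float:
    """Two-sided unpaired t-test p-value between two replicate groups.

    Welch (unequal variance) on log-transformed indices by default; the
    Student equal-variance flavor and the raw scale are options.  Two
    zero-variance groups with equal means give p = 1 (and p = 0 when the
    means differ).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ArgumentError("each group needs at least 2 values")
    if flavor not in ("welch", "student"):
        raise ArgumentError(f"unknown test flavor {flavor!r}")
    if log_scale:
        a = np.log(np.maximum(a, floor))
        b = np.log(np.maximum(b, floor))
    return float(_ttest(a[None, :], b[None, :], equal_var=(flavor == "student"))[0])


# ---------------------------------------------------------------------------
# the compound call rule


def _call_arrays(
    lcb_d3, lcb_d3_dn, p_d3, lcb_d14, lcb_d14_dn, p_d14,
    tc_t_lcb, tc_t_dn, tc_t_p, tc_c_lcb, tc_c_dn, tc_c_p,
    fold_threshold: float, alpha: float,
):
    """Vectorized compound rule; returns (call, basis) object arrays."""
    thr, al = fold_threshold, alpha
    d3_up = (lcb_d3 >= thr) & (p_d3 < al)
    d14_up = (lcb_d14 >= thr) & (p_d14 < al)
    d3_dn = (lcb_d3_dn >= thr) & (p_d3 < al)
    d14_dn = (lcb_d14_dn >= thr) & (p_d14 < al)
    up = d3_up | d14_up
    down = d3_dn | d14_dn
    # conflicting directions (possible with opposite D3/D14 effects): the
    # direction with the larger LCB wins
    conflict = up & down
    up_wins = np.maximum(lcb_d3, lcb_d14) >= np.maximum(lcb_d3_dn, lcb_d14_dn)
    up &= ~conflict | up_wins
    down &= ~conflict | ~up_wins

    trt_up = (tc_t_lcb >= thr) & (tc_t_p < al)
    trt_dn = (tc_t_dn >= thr) & (tc_t_p < al)
    ctrl_moves = ((tc_c_lcb >= thr) | (tc_c_dn >= thr)) & (tc_c_p < al)
    rescue_up = ~up & ~down & trt_up & ~ctrl_moves
    rescue_dn = ~up & ~down & ~rescue_up & trt_dn & ~ctrl_moves

    n = np.shape(lcb_d3)[0]
    call = np.array(["none"] * n, object)
    call[down | rescue_dn] = "down"
    call[up | rescue_up] = "up"
    basis = np.empty(n, object)
    for i in range(n):
        parts = []
        if (up[i] and (d3_up[i])) or (down[i] and d3_dn[i]):
            parts.append("D3")
        if (up[i] and d14_up[i]) or (down[i] and d14_dn[i]):
            parts.append("D14")
        if rescue_up[i] or rescue_dn[i]:
            parts.append("timecourse")
        basis[i] = tuple(parts)
    return call, basis


def call_regulated(
    rec: DifferentialRecord, fold_threshold: float = 1.5, alpha: float = 0.05
) -> DifferentialRecord:
    """Classify one record as up/down/none under the compound rule."""
    call, basis = _call_arrays(
        *[
            np.array([v], float)
            for v in (
                rec.d3.lcb, rec.d3.lcb_recip, rec.d3.p,
                rec.d14.lcb, rec.d14.lcb_recip, rec.d14.p,
                rec.timecourse_trt.lcb, rec.timecourse_trt.lcb_recip, rec.timecourse_trt.p,
                rec.timecourse_ctrl.lcb, rec.timecourse_ctrl.lcb_recip, rec.timecourse_ctrl.p,
            )
        ],
        fold_threshold=fold_threshold,
        alpha=alpha,
    )
    return replace(rec, call=str(call[0]), call_basis=tuple(basis[0]))


# ---------------------------------------------------------------------------
# table-level drivers


def _group_stats(theta: pd.DataFrame, se: pd.DataFrame, cols: list[str]):
    v = theta[cols].to_numpy()
    s = se[cols].to_numpy()
    n = v.shape[1]
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = np.nanmean(v, axis=1)
        var_between = np.nanvar(v, axis=1, ddof=1) if n > 1 else np.zeros(len(v))
        var_within = np.nanmean(np.square(s), axis=1)
    var_within = np.where(np.isnan(var_within), 0.0, var_within)
    group_se = np.sqrt(var_between / n + var_within / n)
    return v, mean, group_se


def _contrast_frame(theta, se, trt_cols, ref_cols, level, flavor, log_scale, floor):
    trt_v, trt_m, trt_s = _group_stats(theta, se, trt_cols)
    ref_v, ref_m, ref_s = _group_stats(theta, se, ref_cols)
    fc, lcb, ucb = fold_ci_arrays(trt_m, trt_s, ref_m, ref_s, level, floor)
    _, lcb_recip, _ = fold_ci_arrays(ref_m, ref_s, trt_m, trt_s, level, floor)
    a, b = trt_v, ref_v
    if log_scale:
        a = np.log(np.maximum(a, floor))
        b = np.log(np.maximum(b, floor))
    p = _ttest(a, b, equal_var=(flavor == "student"))
    return fc, lcb, ucb, lcb_recip, p


def differential_table(
    expr: ExpressionMatrix,
    *,
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
    level: float = 0.90,
    flavor: str = "welch",
    log_scale: bool = True,
    bh_correct: bool = False,
    floor: float = EPS_FLOOR,
) -> pd.DataFrame:
    """Apply the compound rule to every transcript of an experiment.

    Requires control/treated samples at D3 and D14 in ``expr``.  Returns one
    row per transcript with the four contrasts (treated vs control at each
    day, and D14 vs D3 within treated and within control), the call, and the
    clauses that fired.  With ``bh_correct`` the day-wise p-values are
    Benjamini-Hochberg adjusted before thresholding (off by default).
    """
    groups = {}
    for cond in ("control", "treated"):
        for tp in ("D3", "D14"):
            cols = expr.columns_for(cond, tp)
            if len(cols) < 2:
                raise ArgumentError(f"need >= 2 replicates for {cond}/{tp}")
            groups[(cond, tp)] = cols
    th, se = expr.theta, expr.se

    out = pd.DataFrame(index=th.index)
    contrasts = {
        "d3": (groups[("treated", "D3")], groups[("control", "D3")]),
        "d14": (groups[("treated", "D14")], groups[("control", "D14")]),
        "tc_trt": (groups[("treated", "D14")], groups[("treated", "D3")]),
        "tc_ctrl": (groups[("control", "D14")], groups[("control", "D3")]),
    }
    for tag, (trt, ref) in contrasts.items():
        fc, lcb, ucb, lcb_r, p = _contrast_frame(
            th, se, trt, ref, level, flavor, log_scale, floor
        )
        out[f"fc_{tag}"] = fc
        out[f"lcb_{tag}"] = lcb
        out[f"ucb_{tag}"] = ucb
        out[f"lcb_{tag}_down"] = lcb_r
        out[f"p_{tag}"] = p

    p3, p14 = out["p_d3"].to_numpy().copy(), out["p_d14"].to_numpy().copy()
    pt, pc = out["p_tc_trt"].to_numpy().copy(), out["p_tc_ctrl"].to_numpy().copy()
    if bh_correct:
        for arr in (p3, p14, pt, pc):
            ok = np.isfinite(arr)
            if ok.any():
                arr[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    nansafe = lambda a: np.where(np.isfinite(a), a, np.inf)  # NaN p never passes
    call, basis = _call_arrays(
        nanneg(out["lcb_d3"]), nanneg(out["lcb_d3_down"]), nansafe(p3),
        nanneg(out["lcb_d14"]), nanneg(out["lcb_d14_down"]), nansafe(p14),
        nanneg(out["lcb_tc_trt"]), nanneg(out["lcb_tc_trt_down"]), nansafe(pt),
        nanneg(out["lcb_tc_ctrl"]), nanneg(out["lcb_tc_ctrl_down"]), nansafe(pc),
        fold_threshold=fold_threshold,
        alpha=alpha,
    )
    out["call"] = call
    out["call_basis"] = [",".join(b) for b in basis]
    out.index.name = "transcript_id"
    return out


def nanneg(series) -> np.ndarray:
    """NaN LCBs (unreliable transcripts) can never pass a threshold."""
    a = np.asarray(series, float)
    return np.where(np.isfinite(a), a, -np.inf)


def called_set(table: pd.DataFrame, direction: str = "up", name: str | None = None) -> GeneSet:
    ids = table.index[table["call"] == direction]
    return GeneSet.from_ids(name or f"called_{direction}", ids)


def build_enriched_set(
    expr: ExpressionMatrix,
    *,
    target_condition: str = "target",
    source_condition: str = "source",
    fold_threshold: float = 1.5,
    alpha: float = 0.01,
    level: float = 0.90,
    flavor: str = "welch",
    log_scale: bool = True,
    floor: float = EPS_FLOOR,
    name: str = "target_enriched",
) -> GeneSet:
    """Transcripts with LCB(target/source) >= threshold and unpaired p < alpha.

    This is the reference "path" set: what must be activated for complete
    source-to-target reprogramming.
    """
    tcols = expr.columns_for(target_condition)
    scols = expr.columns_for(source_condition)
    if len(tcols) < 2 or len(scols) < 2:
        raise ArgumentError("need >= 2 samples per group for the enriched set")
    fc, lcb, ucb, lcb_r, p = _contrast_frame(
        expr.theta, expr.se, tcols, scols, level, flavor, log_scale, floor
    )
    keep = (nanneg(lcb) >= fold_threshold) & (np.where(np.isfinite(p), p, np.inf) < alpha)
    return GeneSet.from_ids(name, expr.theta.index[keep])


def collapse_to_genes(table_or_expr, probeset_to_gene: dict[str, str]):
    """Collapse probeset rows to genes, keeping the highest-expressed probeset.

    ``table_or_expr`` may be the differential table (needs a mean expression
    ranking supplied through the map insertion order being irrelevant) or an
    ExpressionMatrix; with an ExpressionMatrix the probeset with the largest
    mean theta represents the gene.
    """
    if isinstance(table_or_expr, ExpressionMatrix):
        theta = table_or_expr.theta
        strength = theta.mean(axis=1)
        genes = pd.Series(
            [probeset_to_gene.get(i, i) for i in theta.index], index=theta.index
        )
        best = strength.groupby(genes).idxmax()
        return theta.loc[best.values].rename(index=dict(zip(best.values, best.index)))
    raise ArgumentError("collapse_to_genes expects an ExpressionMatrix")
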