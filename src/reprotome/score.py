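"""Reprogramming-completeness scores.

Given the set of transcripts activated by the treatment and the
target-enriched reference set (the transcripts that must be activated for a
full source-to-target conversion), the path-completion fraction is the share
of the reference set actually activated, and the overlap fraction the share
of activated transcripts that lie on the path.  The marker-panel score asks,
for a curated panel of conserved target-cell marker genes, how close the
treated cells' expression of each activated marker comes to its level in the
target population (the "signal fraction", which may exceed 1).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffcall import GeneSet, normalize_id
from .errors import ArgumentError
from .probe_model import ExpressionMatrix

__all__ = [
    "MarkerPanelStats",
    "ReprogrammingReport",
    "common_genes",
    "path_fraction",
    "marker_panel_score",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerPanelStats:
    n_markers: int
    n_markers_activated: int
    signal_fraction: dict[str, float]
    mean_signal_fraction: float | None
    min_signal_fraction: float | None
    max_signal_fraction: float | None
    fraction_markers_unregulated: float
    n_excluded: int = 0


@dataclass
class ReprogrammingReport:
    """Counts, fractions and (optionally) marker-panel statistics."""

    n_activated: int
    n_target_enriched: int
    n_overlap: int
    path_fraction: float
    overlap_fraction: float
    activated_ids: tuple[str, ...] = ()
    target_enriched_ids: tuple[str, ...] = ()
    overlap_ids: tuple[str, ...] = ()
    marker_panel: MarkerPanelStats | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)

    def summary_text(self) -> str:
        """Human-readable summary; percentages displayed at integer precision."""
        lines = [
            f"activated transcripts:       {self.n_activated}",
            f"target-enriched transcripts: {self.n_target_enriched}",
            f"overlap:                     {self.n_overlap}",
            f"path completed:              {self.path_fraction * 100:.0f}%"
            f" ({self.n_overlap} of {self.n_target_enriched})",
            f"activated on path:           {self.overlap_fraction * 100:.0f}%"
            f" ({self.n_overlap} of {self.n_activated})",
        ]
        mp = self.marker_panel
        if mp is not None:
            lines.append(
                f"marker panel: {mp.n_markers_activated} of {mp.n_markers} activated"
                f" ({mp.fraction_markers_unregulated * 100:.0f}% unregulated)"
            )
            if mp.mean_signal_fraction is not None:
                lines.append(
                    f"marker signal: mean {mp.mean_signal_fraction * 100:.0f}%"
                    f" (range {mp.min_signal_fraction * 100:.0f}"
                    f"-{mp.max_signal_fraction * 100:.0f}%)"
                )
        return "\n".join(lines)


def common_genes(a: GeneSet, b: GeneSet, name: str | None = None) -> GeneSet:
    """Exact identifier intersection (after case-normalization)."""
    return a.intersection(b, name=name)


def path_fraction(activated: GeneSet, target_enriched: GeneSet) -> ReprogrammingReport:
    """Path-completion and overlap fractions of an activated set.

    path_fraction = |activated & target| / |target|;
    overlap_fraction = |activated & target| / |activated| (0 when empty).
    """
    if len(target_enriched) == 0:
        raise ArgumentError("path undefined: target-enriched set is empty")
    overlap = activated.intersection(target_enriched)
    n_act, n_tgt, n_ov = len(activated), len(target_enriched), len(overlap)
    return ReprogrammingReport(
        n_activated=n_act,
        n_target_enriched=n_tgt,
        n_overlap=n_ov,
        path_fraction=n_ov / n_tgt,
        overlap_fraction=(n_ov / n_act) if n_act else 0.0,
        activated_ids=tuple(activated.sorted_ids()),
        target_enriched_ids=tuple(target_enriched.sorted_ids()),
        overlap_ids=tuple(overlap.sorted_ids()),
    )


def marker_panel_score(
    marker_ids: GeneSet,
    calls: pd.DataFrame,
    treated_expr: ExpressionMatrix,
    target_expr: ExpressionMatrix | None = None,
    *,
    timepoint: str = "D14",
    treated_condition: str = "treated",
    target_condition: str = "target",
) -> MarkerPanelStats:
    """Score a conserved marker panel against the treated cells' signal.

    A marker is "activated" when its call is up; its signal fraction is the
    mean treated expression index (at ``timepoint``) divided by its mean
    index in the target population.  Signal means use raw indices, not logs,
    and are never clipped (fractions above 1 are meaningful).  Markers absent
    from either matrix are excluded and counted.
    """
    if target_expr is None:
        target_expr = treated_expr
    tcols = treated_expr.columns_for(treated_condition, timepoint)
    gcols = target_expr.columns_for(target_condition)
    if not tcols or not gcols:
        raise ArgumentError("treated/target samples not found in expression matrices")

    idx_t = {normalize_id(i): i for i in treated_expr.theta.index}
    idx_g = {normalize_id(i): i for i in target_expr.theta.index}
    idx_c = {normalize_id(i): i for i in calls.index}

    present, excluded = [], 0
    for g in marker_ids.sorted_ids():
        if g in idx_t and g in idx_g and g in idx_c:
            present.append(g)
        else:
            excluded += 1
    if excluded:
        log.info("marker panel: %d marker(s) missing from a matrix, excluded", excluded)

    frac: dict[str, float] = {}
    n_up = 0
    for g in present:
        if calls.loc[idx_c[g], "call"] == "up":
            n_up += 1
            trt = float(treated_expr.theta.loc[idx_t[g], tcols].mean())
            tgt = float(target_expr.theta.loc[idx_g[g], gcols].mean())
            frac[g] = trt / tgt if tgt > 0 else np.inf
    n_markers = len(present)
    vals = list(frac.values())
    return MarkerPanelStats(
        n_markers=n_markers,
        n_markers_activated=n_up,
        signal_fraction=frac,
        mean_signal_fraction=float(np.mean(vals)) if vals else None,
        min_signal_fraction=float(np.min(vals)) if vals else None,
        max_signal_fraction=float(np.max(vals)) if vals else None,
        fraction_markers_unregulated=(1.0 - n_up / n_markers) if n_markers else 1.0,
        n_excluded=excluded,
    )
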