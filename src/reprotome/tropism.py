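"""Tissue-tropism classification against a multi-tissue expression atlas.

Regulated genes are classified by where in a tissue compendium they are
abundant: endocrine-selective (cluster A), central-nervous-system-selective
(cluster B), neuro-endocrine (cluster C, abundant in both), or miscellaneous
(MISC).  The endocrine-abundance score of a gene is its mean expression over
endocrine-category tissues divided by its mean over all other tissues; the
cns-abundance score is defined symmetrically.  Labels come from a fixed
threshold tau on the two scores, replacing the manual dendrogram curation
such atlases are usually read with; the dendrogram itself (1 - Pearson
correlation distance, centroid linkage on per-gene standardized profiles) is
kept for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffcall import GeneSet, normalize_id
from .errors import ArgumentError, LookupMissingError

__all__ = [
    "AtlasMatrix",
    "TropismResult",
    "hierarchical_cluster",
    "endocrine_abundance",
    "cns_abundance",
    "assign_tropism",
]

log = logging.getLogger(__name__)

_ABUNDANCE_FLOOR = 1e-6


@dataclass
class AtlasMatrix:
    """Genes x tissues mean-expression matrix with tissue categories."""

    values: pd.DataFrame
    tissue_category: dict[str, str]

    def __post_init__(self):
        missing = [t for t in self.values.columns if t not in self.tissue_category]
        if missing:
            raise ArgumentError(f"tissues without a category: {missing[:5]}")
        v = self.values.to_numpy()
        if not np.isfinite(v).all() or (v < 0).any():
            raise ArgumentError("atlas values must be finite and >= 0")

    def tissues_in(self, category: str) -> list[str]:
        return [t for t in self.values.columns if self.tissue_category[t] == category]

    def restrict(self, genes: GeneSet) -> "AtlasMatrix":
        keep = [g for g in self.values.index if normalize_id(g) in genes.members]
        return AtlasMatrix(self.values.loc[keep], dict(self.tissue_category))


@dataclass
class TropismResult:
    """Per-gene labels plus the dendrogram they were derived alongside."""

    assignments: pd.DataFrame      # gene, label, endocrine_abundance, cns_abundance, leaf_order
    composition: dict[str, float]  # label -> fraction of the input set
    linkage: np.ndarray | None = None
    leaf_order: list[str] = field(default_factory=list)
    newick: str = ""
    n_inversions: int = 0


# ---------------------------------------------------------------------------
# clustering


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; constant rows get correlation 0."""
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("%d constant gene profile(s): correlation set to 0", constant.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return 1.0 - corr


def _newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def rec(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, d, _ = Z[i - n]
        return f"({rec(int(a))},{rec(int(b))}):{d:.6g}"

    return (rec(2 * n - 2) if n > 1 else labels[0]) + ";"


def hierarchical_cluster(sub_atlas: AtlasMatrix):
    """Agglomerative clustering of genes by tissue profile.

    Per-gene profiles are standardized (z-score across tissues), the distance
    is 1 - Pearson correlation, and linkage is centroid via the
    Lance-Williams update on the precomputed distances.  Genes are sorted
    lexicographically first so the merge tree is invariant to input order;
    centroid inversions are tolerated and counted.
    """
    genes = sorted(sub_atlas.values.index, key=normalize_id)
    if len(genes) < 2:
        raise ArgumentError("clustering needs at least 2 genes")
    X = sub_atlas.values.loc[genes].to_numpy(float)
    sd = X.std(axis=1, keepdims=True)
    Xz = (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    D = _correlation_distance(Xz)
    Z = hierarchy.linkage(squareform(D, checks=False), method="centroid")
    heights = Z[:, 2]
    n_inv = int(np.sum(np.diff(heights) < -1e-12))
    if n_inv:
        log.info("centroid linkage produced %d inversion(s)", n_inv)
    order = [genes[i] for i in hierarchy.leaves_list(Z)]
    return Z, order, _newick(Z, genes), n_inv


# ---------------------------------------------------------------------------
# abundance scores and labels


def _abundance(atlas: AtlasMatrix, category: str) -> pd.Series:
    inside = atlas.tissues_in(category)
    outside = [t for t in atlas.values.columns if t not in inside]
    if not inside or not outside:
        raise ArgumentError(f"atlas needs tissues inside and outside category {category!r}")
    num = atlas.values[inside].mean(axis=1)
    den = atlas.values[outside].mean(axis=1).clip(lower=_ABUNDANCE_FLOOR)
    return num / den


def endocrine_abundance(gene: str, atlas: AtlasMatrix) -> float:
    """Mean expression over endocrine tissues relative to all other tissues."""
    series = _abundance(atlas, "endocrine")
    key = {normalize_id(g): g for g in series.index}
    norm = normalize_id(gene)
    if norm not in key:
        raise LookupMissingError(f"gene {gene!r} absent from atlas")
    return float(series[key[norm]])


def cns_abundance(gene: str, atlas: AtlasMatrix) -> float:
    """Mean expression over cns tissues relative to all other tissues."""
    series = _abundance(atlas, "cns")
    key = {normalize_id(g): g for g in series.index}
    norm = normalize_id(gene)
    if norm not in key:
        raise LookupMissingError(f"gene {gene!r} absent from atlas")
    return float(series[key[norm]])


def assign_tropism(genes: GeneSet, atlas: AtlasMatrix, tau: float = 3.0) -> TropismResult:
    """Label each gene A (endocrine), B (cns), C (both) or MISC.

    A gene is endocrine-selective when its endocrine abundance reaches
    ``tau`` while its cns abundance does not, and symmetrically for B;
    genes clearing both thresholds are neuro-endocrine (C); the rest are
    MISC.  Also reports the label composition of the input set and, when at
    least two genes are present, the dendrogram leaf order.
    """
    if len(genes) == 0:
        raise ArgumentError("empty gene set")
    sub = atlas.restrict(genes)
    missing = genes.members - {normalize_id(g) for g in sub.values.index}
    if missing:
        raise LookupMissingError(
            f"{len(missing)} gene(s) absent from atlas, e.g. {sorted(missing)[:3]}"
        )
    endo = _abundance(sub, "endocrine")
    cns = _abundance(sub, "cns")
    label = np.where(
        (endo >= tau) & (cns < tau), "A",
        np.where((cns >= tau) & (endo < tau), "B",
                 np.where((endo >= tau) & (cns >= tau), "C", "MISC")),
    )
    df = pd.DataFrame(
        {
            "gene": sub.values.index,
            "label": label,
            "endocrine_abundance": endo.to_numpy(),
            "cns_abundance": cns.to_numpy(),
        }
    ).set_index("gene")

    linkage = None
    leaf_order: list[str] = []
    newick = ""
    n_inv = 0
    if len(df) >= 2:
        linkage, leaf_order, newick, n_inv = hierarchical_cluster(sub)
        rank = {g: i for i, g in enumerate(leaf_order)}
        df["leaf_order"] = [rank[g] for g in df.index]
    else:
        df["leaf_order"] = 0

    n = len(df)
    composition = {lab: float((df["label"] == lab).sum()) / n for lab in ("A", "B", "C", "MISC")}
    return TropismResult(
        assignments=df.sort_index(),
        composition=composition,
        linkage=linkage,
        leaf_order=leaf_order,
        newick=newick,
        n_inversions=n_inv,
    )
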