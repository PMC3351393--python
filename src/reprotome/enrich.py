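"""Hypergeometric over-representation of annotation terms in a gene set.

For each term with K annotated genes in a universe of N, the probability of
seeing at least k of them among a query of n genes is the upper tail of the
hypergeometric distribution; terms with p below the threshold (0.001 by
default, uncorrected) are flagged as enriched.  Terms are flat sets — no
ontology-graph propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffcall import GeneSet, normalize_id
from .errors import ArgumentError

__all__ = ["AnnotationMap", "hypergeom_enrichment"]

log = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """term -> gene-id sets over a gene universe."""

    terms: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.universe = {normalize_id(g) for g in self.universe}
        self.terms = {t: {normalize_id(g) for g in gs} for t, gs in self.terms.items()}
        if not self.universe:
            self.universe = set().union(*self.terms.values()) if self.terms else set()
        stray = [t for t, gs in self.terms.items() if not gs <= self.universe]
        if stray:
            raise ArgumentError(
                f"terms annotate genes outside the universe, e.g. {stray[:3]}"
            )

    @classmethod
    def from_pairs(cls, pairs, labels=None, universe=None) -> "AnnotationMap":
        """Build from (gene, term) pairs, e.g. rows of a two-column TSV."""
        terms: dict[str, set[str]] = {}
        for gene, term in pairs:
            terms.setdefault(term, set()).add(normalize_id(gene))
        uni = set(universe) if universe is not None else set()
        return cls(terms=terms, labels=dict(labels or {}), universe=uni)


def hypergeom_enrichment(
    query: GeneSet, ann: AnnotationMap, threshold: float = 0.001,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every term in ``query``.

    Query genes outside the universe are logged and dropped.  Returns one
    row per term (k, n, K, N, p_value, enriched) sorted by ascending p, ties
    broken by term id.  ``bh_correct`` adds a Benjamini-Hochberg adjusted
    column and bases the flag on it (off by default, matching the raw
    threshold rule).
    """
    if not ann.universe:
        raise ArgumentError("empty annotation universe")
    q = {normalize_id(g) for g in query.members}
    stray = q - ann.universe
    if stray:
        log.info("dropping %d query gene(s) outside the universe", len(stray))
        q &= ann.universe
    if not q:
        raise ArgumentError("empty query after universe filtering")

    N, n = len(ann.universe), len(q)
    rows = []
    for term in sorted(ann.terms):
        members = ann.terms[term]
        K = len(members)
        k = len(q & members)
        # P[X >= k] for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 0.0), 1.0)
        rows.append((term, ann.labels.get(term, ""), k, n, K, N, p))
    out = pd.DataFrame(
        rows, columns=["term", "label", "k", "n", "K", "N", "p_value"]
    ).set_index("term")
    if bh_correct:
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["enriched"] = out["p_adjusted"] < threshold
    else:
        out["enriched"] = out["p_value"] < threshold
    # ascending p, ties broken by term id (rows were built in term order)
    return out.sort_values("p_value", kind="stable")
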