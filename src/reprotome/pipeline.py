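"""End-to-end analysis driver: simulate -> normalize/fit -> call -> score ->
tropism -> enrich -> report.

Each stage writes its table under the output directory; a manifest records
the configuration, the seed and per-table row counts.  Reruns with an
identical configuration are byte-identical.  Stage failures abort with the
stage name, leaving any partial output under a ``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as rio
from .diffcall import GeneSet, build_enriched_set, called_set, differential_table
from .enrich import hypergeom_enrichment
from .errors import ConfigurationError, StageError
from .probe_model import fit_expression_index, normalize_to_median_array
from .score import ReprogrammingReport, marker_panel_score, path_fraction
from .simulate import (
    SimulationConfig,
    gene_of_probeset,
    generate_annotation,
    generate_atlas,
    generate_experiment,
)
from .tropism import assign_tropism

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds and switches of the full analysis.

    Thresholds default to the study's printed values: 1.5-fold LCB with
    unpaired P < 0.05 for regulated calls, 1.5-fold LCB with P < 0.01 for
    the target-enriched set, P < 0.001 for term enrichment, a 90% fold-change
    interval, and an abundance threshold tau = 3 for tropism labels.
    """

    fold_threshold: float = 1.5
    alpha_regulated: float = 0.05
    alpha_enriched_set: float = 0.01
    go_threshold: float = 0.001
    ci_level: float = 0.90
    tau: float = 3.0
    test_flavor: str = "welch"          # welch | student
    log_scale_test: bool = True
    bh_correct: bool = False
    marker_timepoint: str = "D14"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    write_probes: bool = False          # probe-level TSV is large; opt in

    def validate(self) -> None:
        for name in ("alpha_regulated", "alpha_enriched_set", "go_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        if not 0 < self.ci_level < 1:
            raise ConfigurationError(f"ci_level must lie in (0, 1), got {self.ci_level!r}")
        if self.fold_threshold < 1:
            raise ConfigurationError("fold_threshold must be >= 1")
        if self.tau <= 0:
            raise ConfigurationError("tau must be > 0")
        if self.test_flavor not in ("welch", "student"):
            raise ConfigurationError(f"test_flavor must be welch|student, got {self.test_flavor!r}")
        if self.marker_timepoint not in ("D3", "D14"):
            raise ConfigurationError("marker_timepoint must be D3 or D14")
        self.sim.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["effect_fold_range"] = list(self.sim.effect_fold_range)
        d["sim"]["signal_fraction_range"] = list(self.sim.signal_fraction_range)
        d["sim"]["atlas_tissues"] = [list(t) for t in self.sim.atlas_tissues]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            if "effect_fold_range" in sim:
                sim["effect_fold_range"] = tuple(sim["effect_fold_range"])
            if "signal_fraction_range" in sim:
                sim["signal_fraction_range"] = tuple(sim["signal_fraction_range"])
            if "atlas_tissues" in sim:
                sim["atlas_tissues"] = tuple(tuple(t) for t in sim["atlas_tissues"])
            sim = SimulationConfig(**sim)
        return cls(sim=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _finalize(tmp: Path) -> Path:
    final = Path(str(tmp)[: -len(".partial")])
    tmp.rename(final)
    return final


class _StageWriter:
    """Writes stage outputs via .partial files, renamed on stage success."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.pending: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / (name + ".partial")
        self.pending.append(p)
        return p

    def commit(self):
        for p in self.pending:
            if p.exists():
                _finalize(p)
        self.pending = []


def run_pipeline(config: PipelineConfig, outdir) -> ReprogrammingReport:
    """Run the full synthetic analysis and write every stage table."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    w = _StageWriter(outdir)
    counts: dict[str, int] = {}
    stage = "simulate"
    try:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        probes, truth = generate_experiment(sim)
        atlas = generate_atlas(sim, truth)
        ann = generate_annotation(sim, truth)
        (outdir / "truth.json.partial").write_text(truth.to_json())
        w.pending.append(outdir / "truth.json.partial")
        rio.write_atlas(atlas, w.path("atlas.tsv"), w.path("atlas_categories.tsv"))
        rio.write_annotation_pairs(
            [(g, t) for t, gs in ann.terms.items() for g in sorted(gs)],
            w.path("annotation.tsv"), ann.labels, w.path("annotation_labels.tsv"),
        )
        if config.write_probes:
            rio.write_probe_matrix(probes, w.path("probes.tsv"), w.path("samples.tsv"))
        w.commit()

        stage = "express"
        normalized, factors = normalize_to_median_array(probes)
        expr = fit_expression_index(normalized)
        rio.write_expression(
            expr, w.path("expression.tsv"), w.path("expression_se.tsv"),
            w.path("samples.tsv"),
        )
        counts["expression"] = len(expr.theta)
        w.commit()

        stage = "diff"
        table = differential_table(
            expr,
            fold_threshold=config.fold_threshold,
            alpha=config.alpha_regulated,
            level=config.ci_level,
            flavor=config.test_flavor,
            log_scale=config.log_scale_test,
            bh_correct=config.bh_correct,
        )
        table.to_csv(w.path("differential.tsv"), sep="\t")
        counts["differential"] = len(table)
        up = GeneSet.from_ids(
            "activated",
            [gene_of_probeset(g) for g in table.index[table["call"] == "up"]],
        )
        down = GeneSet.from_ids(
            "suppressed",
            [gene_of_probeset(g) for g in table.index[table["call"] == "down"]],
        )
        enriched_ps = build_enriched_set(
            expr,
            fold_threshold=config.fold_threshold,
            alpha=config.alpha_enriched_set,
            level=config.ci_level,
            flavor=config.test_flavor,
            log_scale=config.log_scale_test,
        )
        enriched = GeneSet.from_ids(
            "target_enriched",
            [gene_of_probeset(g) for g in enriched_ps.members],
        )
        rio.write_gmt([up, down, enriched], w.path("gene_sets.gmt"))
        counts["activated"] = len(up)
        counts["suppressed"] = len(down)
        counts["target_enriched"] = len(enriched)
        w.commit()

        stage = "score"
        report = path_fraction(up, enriched)
        calls_by_gene = table.copy()
        calls_by_gene.index = [gene_of_probeset(g) for g in calls_by_gene.index]
        markers = GeneSet.from_ids("marker_panel", truth.marker_ids)
        expr_by_gene = dataclasses.replace(
            expr,
            theta=expr.theta.rename(index=gene_of_probeset),
            se=expr.se.rename(index=gene_of_probeset),
        )
        report.marker_panel = marker_panel_score(
            markers, calls_by_gene, expr_by_gene, timepoint=config.marker_timepoint
        )
        (outdir / "report.json.partial").write_text(report.to_json() + "\n")
        w.pending.append(outdir / "report.json.partial")
        (outdir / "report.txt.partial").write_text(report.summary_text() + "\n")
        w.pending.append(outdir / "report.txt.partial")
        w.commit()

        stage = "tropism"
        if len(up) >= 2:
            trop = assign_tropism(up, atlas, tau=config.tau)
            trop.assignments.to_csv(w.path("tropism.tsv"), sep="\t")
            (outdir / "dendrogram.nwk.partial").write_text(trop.newick + "\n")
            w.pending.append(outdir / "dendrogram.nwk.partial")
            counts["tropism"] = len(trop.assignments)
        w.commit()

        stage = "enrich"
        if len(up) > 0:
            enr = hypergeom_enrichment(
                up, ann, threshold=config.go_threshold, bh_correct=config.bh_correct
            )
            enr.to_csv(w.path("enrichment.tsv"), sep="\t")
            counts["enrichment"] = len(enr)
        w.commit()

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "row_counts": counts,
            "scale_factors": {k: float(v) for k, v in factors.items()},
        }
        rio.write_json(manifest, w.path("manifest.json"))
        w.commit()
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return report
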