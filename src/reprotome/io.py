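"""Plain-text file formats for every pipeline stage.

Matrices travel as TSV, gene sets as GMT, truth/report/manifest as JSON.
Floats are written with pandas' shortest round-trip representation, so a
write -> read -> write cycle is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .diffcall import GeneSet
from .errors import ArgumentError
from .probe_model import ExpressionMatrix
from .simulate import ProbeMatrix
from .tropism import AtlasMatrix

__all__ = [
    "write_probe_matrix", "read_probe_matrix",
    "write_expression", "read_expression",
    "write_atlas", "read_atlas",
    "write_gmt", "read_gmt",
    "write_annotation_pairs", "read_annotation_pairs",
    "write_json", "read_json",
]

_SAMPLE_COLS = ["sample_id", "condition", "timepoint", "replicate"]


def write_probe_matrix(pm: ProbeMatrix, probes_path, samples_path) -> None:
    """Probe TSV: probeset_id, probe_index, PM_<sample>..., MM_<sample>...;
    sample metadata TSV alongside."""
    df = pd.DataFrame({"probeset_id": pm.probeset_ids, "probe_index": pm.probe_index})
    for j, sid in enumerate(pm.sample_ids):
        df[f"PM_{sid}"] = pm.pm[:, j]
    for j, sid in enumerate(pm.sample_ids):
        df[f"MM_{sid}"] = pm.mm[:, j]
    df.to_csv(probes_path, sep="\t", index=False)
    pm.samples[_SAMPLE_COLS].to_csv(samples_path, sep="\t", index=False)


def read_probe_matrix(probes_path, samples_path) -> ProbeMatrix:
    df = pd.read_csv(probes_path, sep="\t", float_precision="round_trip")
    # keep_default_na: "NA" is a legitimate timepoint for untimed arrays
    samples = pd.read_csv(samples_path, sep="\t", keep_default_na=False)
    sids = list(samples["sample_id"])
    missing = [s for s in sids if f"PM_{s}" not in df.columns]
    if missing:
        raise ArgumentError(f"probe table lacks PM columns for samples {missing[:3]}")
    pm = df[[f"PM_{s}" for s in sids]].to_numpy(float)
    mm = df[[f"MM_{s}" for s in sids]].to_numpy(float)
    return ProbeMatrix(
        probeset_ids=df["probeset_id"].to_numpy(str),
        probe_index=df["probe_index"].to_numpy(int),
        pm=pm, mm=mm, samples=samples,
    )


def write_expression(expr: ExpressionMatrix, theta_path, se_path, samples_path) -> None:
    expr.theta.rename_axis("transcript_id").to_csv(theta_path, sep="\t")
    expr.se.rename_axis("transcript_id").to_csv(se_path, sep="\t")
    expr.samples[_SAMPLE_COLS].to_csv(samples_path, sep="\t", index=False)


def read_expression(theta_path, se_path, samples_path) -> ExpressionMatrix:
    theta = pd.read_csv(theta_path, sep="\t", index_col="transcript_id",
                        float_precision="round_trip")
    se = pd.read_csv(se_path, sep="\t", index_col="transcript_id",
                     float_precision="round_trip")
    theta.index.name = se.index.name = None
    samples = pd.read_csv(samples_path, sep="\t", keep_default_na=False)
    samples["timepoint"] = samples["timepoint"].astype(str)
    return ExpressionMatrix(theta=theta, se=se, samples=samples)


def write_atlas(atlas: AtlasMatrix, values_path, categories_path) -> None:
    atlas.values.rename_axis("gene").to_csv(values_path, sep="\t")
    pd.DataFrame(
        sorted(atlas.tissue_category.items()), columns=["tissue", "category"]
    ).to_csv(categories_path, sep="\t", index=False)


def read_atlas(values_path, categories_path) -> AtlasMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene",
                         float_precision="round_trip")
    values.index.name = None
    cats = pd.read_csv(categories_path, sep="\t")
    return AtlasMatrix(values=values, tissue_category=dict(zip(cats["tissue"], cats["category"])))


def write_gmt(sets: list[GeneSet], path) -> None:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    with open(path, "w") as fh:
        for gs in sets:
            desc = gs.annotation.get("description", "")
            fh.write("\t".join([gs.name, desc] + gs.sorted_ids()) + "\n")


def read_gmt(path) -> list[GeneSet]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ArgumentError(f"malformed GMT line: {line[:60]!r}")
            name, desc, ids = parts[0], parts[1], parts[2:]
            out.append(GeneSet.from_ids(name, ids, {"description": desc} if desc else {}))
    return out


def write_annotation_pairs(pairs, path, labels: dict | None = None, labels_path=None) -> None:
    """Two-column gene<TAB>term TSV (plus optional term-label TSV)."""
    pd.DataFrame(sorted(pairs), columns=["gene", "term"]).to_csv(path, sep="\t", index=False)
    if labels_path is not None:
        pd.DataFrame(
            sorted((labels or {}).items()), columns=["term", "label"]
        ).to_csv(labels_path, sep="\t", index=False)


def read_annotation_pairs(path, labels_path=None):
    df = pd.read_csv(path, sep="\t")
    pairs = list(zip(df["gene"], df["term"]))
    labels = {}
    if labels_path is not None and Path(labels_path).exists():
        ldf = pd.read_csv(labels_path, sep="\t")
        labels = dict(zip(ldf["term"], ldf["label"]))
    return pairs, labels


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1, default=_jsonable)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
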