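"""Synthetic probe-level expression data with known ground truth.

The generator emulates a two-timepoint transduction experiment on
adherent-to-suspension cultured duct cells: three replicate arrays per
condition for {control, treated} x {D3, D14}, plus replicate arrays of the
untransduced source population (duct) and the target population (endocrine /
beta-cell enriched fractions).  Intensities follow the multiplicative probe
model: each probeset interrogates one transcript with J probes whose
sensitivities phi_j scale a per-array abundance theta, observed with
log-normal cell noise on top of an additive background.  Mismatch probes
carry the background plus a fixed fraction of the specific signal, so the
mismatch-corrected difference PM - MM recovers the specific signal exactly
in the noiseless limit.

Ground truth records exactly which transcripts were activated or suppressed
by the treatment, their per-timepoint fold effects, which transcripts are
enriched in the target population (the "path" to be completed), and a
tissue-block membership used by the synthetic atlas.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "ProbeMatrix",
    "generate_experiment",
    "generate_atlas",
    "generate_annotation",
    "DEFAULT_TISSUES",
]

# ~50 tissues: 2 endocrine, 8 central-nervous-system, 40 other.
DEFAULT_TISSUES: tuple[tuple[str, str], ...] = tuple(
    [("pancreatic_islet", "endocrine"), ("beta_cell_fraction", "endocrine")]
    + [
        (t, "cns")
        for t in (
            "cerebral_cortex", "cerebellum", "hippocampus", "thalamus",
            "hypothalamus", "amygdala", "caudate_nucleus", "spinal_cord",
        )
    ]
    + [
        (t, "other")
        for t in (
            "whole_pancreas", "duct_cells", "liver", "kidney", "heart",
            "lung", "spleen", "thymus", "bone_marrow", "lymph_node",
            "tonsil", "peripheral_blood", "skeletal_muscle", "smooth_muscle",
            "adipose", "skin", "esophagus", "stomach", "small_intestine",
            "colon", "rectum", "bladder", "prostate", "testis", "ovary",
            "uterus", "placenta", "mammary_gland", "thyroid", "parathyroid",
            "adrenal_gland", "pituitary", "salivary_gland", "trachea",
            "bronchus", "aorta", "coronary_artery", "retina", "cornea",
            "fetal_liver",
        )
    ]
)

_TEMPORAL = ("d3_only", "d14_only", "both")
_BLOCKS = ("endocrine", "cns", "shared", "background")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce the study conditions: ~20,000 transcripts with 11
    probes each, n = 3 replicate arrays per condition, a 1128-transcript
    target-enriched set of which a fraction f is activated by the treatment
    (63/1128 by default), 77 activated transcripts off the path (140 total),
    48 suppressed transcripts, effect folds spanning 1.8-80x, and a temporal
    mix derived from the observed day-3 / day-14 / both up-regulation counts
    (68, 105, 140 distinct).
    """

    n_transcripts: int = 20_000
    probes_per_set: int = 11
    n_replicates: int = 3
    baseline_log_mean: float = 5.0   # natural-log scale; exp(5) ~ 148 units
    baseline_log_sd: float = 1.0
    probe_sensitivity_sd: float = 0.4
    noise_sd: float = 0.15           # log-scale cell noise
    target_enriched_size: int = 1128
    reprogramming_fraction_f: float = 63 / 1128
    n_activated_offpath: int = 77
    effect_fold_range: tuple[float, float] = (1.8, 80.0)
    d3_only_frac: float = 0.25
    d14_only_frac: float = 0.515
    both_frac: float = 0.235
    n_suppressed: int = 48
    signal_fraction_range: tuple[float, float] = (0.06, 1.04)
    endocrine_frac: float = 0.25
    cns_frac: float = 0.25
    shared_frac: float = 0.20
    marker_panel_size: int = 332
    atlas_tissues: tuple[tuple[str, str], ...] = DEFAULT_TISSUES
    atlas_high_fold: float = 20.0
    mm_fraction: float = 0.3
    background: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_transcripts": self.n_transcripts,
            "probes_per_set": self.probes_per_set,
            "n_replicates": self.n_replicates,
            "target_enriched_size": self.target_enriched_size,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a count >= 1, got {value!r}")
        for name in ("n_activated_offpath", "n_suppressed", "marker_panel_size"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("baseline_log_sd", "probe_sensitivity_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        f = self.reprogramming_fraction_f
        if not 0.0 <= f <= 1.0:
            raise ConfigurationError(
                f"reprogramming_fraction_f must lie in [0, 1], got {f!r}"
            )
        lo, hi = self.effect_fold_range
        if not (lo > 1.0 and hi >= lo):
            raise ConfigurationError(
                f"effect_fold_range must satisfy 1 < lo <= hi, got {self.effect_fold_range!r}"
            )
        mix = self.d3_only_frac + self.d14_only_frac + self.both_frac
        if abs(mix - 1.0) > 1e-9:
            raise ConfigurationError(
                f"d3_only_frac + d14_only_frac + both_frac must equal 1, got {mix!r}"
            )
        if min(self.d3_only_frac, self.d14_only_frac, self.both_frac) < 0:
            raise ConfigurationError("temporal fractions (d3_only_frac, ...) must be >= 0")
        s_lo, s_hi = self.signal_fraction_range
        if not (0 < s_lo <= s_hi):
            raise ConfigurationError(
                f"signal_fraction_range must satisfy 0 < lo <= hi, got {self.signal_fraction_range!r}"
            )
        blocks = self.endocrine_frac + self.cns_frac + self.shared_frac
        if min(self.endocrine_frac, self.cns_frac, self.shared_frac) < 0 or blocks > 1 + 1e-9:
            raise ConfigurationError(
                "block fractions (endocrine_frac, cns_frac, shared_frac) must be >= 0 and sum to <= 1"
            )
        needed = self.target_enriched_size + self.n_activated_offpath + self.n_suppressed
        if needed > self.n_transcripts:
            raise ConfigurationError(
                "n_transcripts too small for target_enriched_size + "
                "n_activated_offpath + n_suppressed"
            )
        if not self.atlas_tissues:
            raise ConfigurationError("atlas_tissues must not be empty")
        for t, cat in self.atlas_tissues:
            if cat not in ("endocrine", "cns", "other"):
                raise ConfigurationError(
                    f"atlas_tissues: category of {t!r} must be endocrine/cns/other"
                )
        if not 0 <= self.mm_fraction < 1:
            raise ConfigurationError("mm_fraction must lie in [0, 1)")
        if self.background < 0:
            raise ConfigurationError("background must be >= 0")
        if self.atlas_high_fold <= 1:
            raise ConfigurationError("atlas_high_fold must be > 1")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment."""

    activated_ids: tuple[str, ...]
    suppressed_ids: tuple[str, ...]
    target_enriched_ids: tuple[str, ...]
    per_gene_fold: dict[str, tuple[float, float]]  # gene -> (fold_d3, fold_d14)
    target_fold: dict[str, float]                  # target/source fold per path gene
    temporal_pattern: dict[str, str]               # gene -> d3_only | d14_only | both
    tissue_block: dict[str, str]                   # gene -> endocrine|cns|shared|background
    marker_ids: tuple[str, ...]
    f_realized: float
    log_baseline: dict[str, float] = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        for k in ("activated_ids", "suppressed_ids", "target_enriched_ids", "marker_ids"):
            d[k] = tuple(d[k])
        d["per_gene_fold"] = {g: tuple(v) for g, v in d["per_gene_fold"].items()}
        return cls(**d)


@dataclass
class ProbeMatrix:
    """Probe-level PM/MM intensities for a set of arrays.

    ``pm`` and ``mm`` are (n_probes_total, n_arrays) arrays whose rows are
    grouped by probeset (``probeset_ids``/``probe_index`` run in parallel);
    ``samples`` is a data frame with columns sample_id, condition, timepoint,
    replicate, one row per array column.
    """

    probeset_ids: np.ndarray        # (P,) str
    probe_index: np.ndarray         # (P,) int, 0..J-1 within probeset
    pm: np.ndarray                  # (P, A) float
    mm: np.ndarray                  # (P, A) float
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.pm.shape != self.mm.shape:
            raise ArgumentErrorShape(self.pm.shape, self.mm.shape)
        if len(self.samples) != self.pm.shape[1]:
            raise ValueError("samples rows must match intensity columns")
        if not self.samples["sample_id"].is_unique:
            raise ValueError("sample_id values must be unique")
        if not (np.isfinite(self.pm).all() and np.isfinite(self.mm).all()):
            raise ValueError("intensities must be finite")
        if (self.pm < 0).any() or (self.mm < 0).any():
            raise ValueError("intensities must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def copy(self) -> "ProbeMatrix":
        return ProbeMatrix(
            self.probeset_ids.copy(), self.probe_index.copy(),
            self.pm.copy(), self.mm.copy(), self.samples.copy(),
        )


def ArgumentErrorShape(a, b):  # small helper keeping __post_init__ terse
    return ValueError(f"PM and MM shapes differ: {a} vs {b}")


def gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def probeset_of(gene: str) -> str:
    return gene + "_at"


def gene_of_probeset(probeset: str) -> str:
    return probeset[:-3] if probeset.lower().endswith("_at") else probeset


def _apportion(n: int, fracs: list[float]) -> list[int]:
    """Integer counts summing to n, largest-remainder method (within +-1)."""
    raw = [n * f for f in fracs]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([-(r - b) for r, b in zip(raw, base)], kind="stable")
    for i in order[:short]:
        base[int(i)] += 1
    return base


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def generate_experiment(config: SimulationConfig) -> tuple[ProbeMatrix, SyntheticTruth]:
    """Simulate probe-level data and its ground truth.

    Returns arrays for {control, treated} x {D3, D14} plus source and target
    populations, ``n_replicates`` each.  Identical seeds give byte-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    genes = np.array(gene_ids(n))

    perm = rng.permutation(n)
    t_size = config.target_enriched_size
    n_in = int(round(config.reprogramming_fraction_f * t_size))
    target_idx = perm[:t_size]
    act_in_idx = target_idx[:n_in]
    off_idx = perm[t_size : t_size + config.n_activated_offpath]
    activated_idx = np.concatenate([act_in_idx, off_idx])
    sup_lo = t_size + config.n_activated_offpath
    suppressed_idx = perm[sup_lo : sup_lo + config.n_suppressed]

    # temporal patterns, exact to within the apportionment rule
    mix = [config.d3_only_frac, config.d14_only_frac, config.both_frac]

    def _patterns(idx: np.ndarray) -> dict[str, str]:
        counts = _apportion(len(idx), mix)
        labels = [p for p, c in zip(_TEMPORAL, counts) for _ in range(c)]
        shuffled = idx[rng.permutation(len(idx))]
        return {genes[i]: lab for i, lab in zip(shuffled, labels)}

    pattern = _patterns(activated_idx)
    pattern.update(_patterns(suppressed_idx))

    lo, hi = config.effect_fold_range
    per_gene_fold: dict[str, tuple[float, float]] = {}
    for idx, sign in ((activated_idx, +1), (suppressed_idx, -1)):
        folds = _log_uniform(rng, lo, hi, (len(idx), 2))
        for row, i in enumerate(idx):
            g = genes[i]
            pat = pattern[g]
            f3 = folds[row, 0] if pat in ("d3_only", "both") else 1.0
            f14 = folds[row, 1] if pat in ("d14_only", "both") else 1.0
            if sign < 0:
                f3, f14 = 1.0 / f3, 1.0 / f14
            per_gene_fold[g] = (float(f3), float(f14))

    target_fold = {
        genes[i]: float(v)
        for i, v in zip(target_idx, _log_uniform(rng, lo, hi, t_size))
    }
    # reprogramming is partial: treated cells reach only a fraction of the
    # target-cell level of each on-path gene, so tie the target fold to the
    # treated fold through a per-gene signal fraction; target folds stay
    # capped at the declared effect range so the target arrays' overall
    # intensity keeps the same scale as every other array
    s_lo, s_hi = config.signal_fraction_range
    sig = _log_uniform(rng, s_lo, s_hi, n_in)
    for i, s in zip(act_in_idx, sig):
        g = genes[i]
        f3, f14 = per_gene_fold[g]
        target_fold[g] = float(min(hi, max(f3, f14) / s))

    # tissue blocks over the activated set: endocrine and shared preferentially
    # on-path (those genes are high in the target population by construction),
    # cns and background off-path.
    n_act = len(activated_idx)
    bg_frac = 1.0 - config.endocrine_frac - config.cns_frac - config.shared_frac
    e, c, s, b = _apportion(
        n_act,
        [config.endocrine_frac, config.cns_frac, config.shared_frac, max(bg_frac, 0.0)],
    )
    block_labels = ["endocrine"] * e + ["shared"] * s + ["cns"] * c + ["background"] * b
    tissue_block = {genes[i]: "background" for i in range(n)}
    ordered_act = np.concatenate([act_in_idx, off_idx])
    for i, lab in zip(ordered_act, block_labels):
        tissue_block[genes[i]] = lab
    for i in target_idx[n_in:]:
        tissue_block[genes[i]] = "endocrine"

    # marker panel: endocrine-block members of the target-enriched set
    cand = np.array([i for i in target_idx if tissue_block[genes[i]] == "endocrine"])
    k = min(config.marker_panel_size, len(cand))
    marker_idx = rng.choice(cand, size=k, replace=False) if k else np.array([], int)
    marker_ids = tuple(sorted(genes[i] for i in marker_idx))

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n)

    # sample layout
    rows = []
    for cond in ("control", "treated"):
        for tp in ("D3", "D14"):
            for r in range(1, config.n_replicates + 1):
                rows.append((f"{cond}_{tp}_r{r}", cond, tp, r))
    for cond in ("source", "target"):
        for r in range(1, config.n_replicates + 1):
            rows.append((f"{cond}_r{r}", cond, "NA", r))
    samples = pd.DataFrame(rows, columns=["sample_id", "condition", "timepoint", "replicate"])
    n_arrays = len(samples)

    # per-array log effect
    log_effect = np.zeros((n, n_arrays))
    fold3 = np.zeros(n)
    fold14 = np.zeros(n)
    for g, (f3, f14) in per_gene_fold.items():
        i = int(g[1:]) - 1
        fold3[i], fold14[i] = np.log(f3), np.log(f14)
    tfold = np.zeros(n)
    for g, f in target_fold.items():
        tfold[int(g[1:]) - 1] = np.log(f)
    for a, (sid, cond, tp, _r) in enumerate(rows):
        if cond == "treated":
            log_effect[:, a] = fold3 if tp == "D3" else fold14
        elif cond == "target":
            log_effect[:, a] = tfold

    J = config.probes_per_set
    phi = np.exp(rng.normal(0.0, config.probe_sensitivity_sd, (n, J)))
    phi *= np.sqrt(J / np.sum(phi**2, axis=1))[:, None]

    log_theta = baseline[:, None] + log_effect                      # (n, A)
    eps = rng.normal(0.0, config.noise_sd, (n, J, n_arrays)) if config.noise_sd > 0 else 0.0
    signal = np.exp(log_theta[:, None, :] + np.log(phi)[:, :, None] + eps)
    m, bg = config.mm_fraction, config.background
    pm = bg + (1.0 + m) * signal
    mm = bg + m * signal

    P = n * J
    probeset_ids = np.repeat([probeset_of(g) for g in genes], J)
    probe_index = np.tile(np.arange(J), n)
    probes = ProbeMatrix(
        probeset_ids=np.asarray(probeset_ids),
        probe_index=probe_index,
        pm=pm.reshape(P, n_arrays),
        mm=mm.reshape(P, n_arrays),
        samples=samples,
    )

    truth = SyntheticTruth(
        activated_ids=tuple(sorted(genes[i] for i in activated_idx)),
        suppressed_ids=tuple(sorted(genes[i] for i in suppressed_idx)),
        target_enriched_ids=tuple(sorted(genes[i] for i in target_idx)),
        per_gene_fold=per_gene_fold,
        target_fold=target_fold,
        temporal_pattern=pattern,
        tissue_block=tissue_block,
        marker_ids=marker_ids,
        f_realized=n_in / t_size,
        log_baseline={g: float(v) for g, v in zip(genes, baseline)},
    )
    return probes, truth


def generate_atlas(config: SimulationConfig, truth: SyntheticTruth):
    """Simulate a genes x tissues expression atlas consistent with ``truth``.

    Genes in the endocrine block are high only in endocrine-category tissues,
    cns-block genes only in cns tissues, shared-block genes in both, and
    background genes are flat.  The atlas emulates an external compendium of
    tissue means, so per-gene base levels are drawn independently of the
    experiment's baselines.
    """
    from .tropism import AtlasMatrix  # local import avoids a cycle

    config.validate()
    if not config.atlas_tissues:
        raise ConfigurationError("atlas_tissues must not be empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    genes = sorted(truth.tissue_block)
    tissues = [t for t, _ in config.atlas_tissues]
    categories = {t: cat for t, cat in config.atlas_tissues}

    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(genes)))
    block = np.array([truth.tissue_block[g] for g in genes])
    cat = np.array([categories[t] for t in tissues])
    high = np.zeros((len(genes), len(tissues)), bool)
    high |= (block == "endocrine")[:, None] & (cat == "endocrine")[None, :]
    high |= (block == "cns")[:, None] & (cat == "cns")[None, :]
    high |= (block == "shared")[:, None] & np.isin(cat, ["endocrine", "cns"])[None, :]

    factor = np.where(high, config.atlas_high_fold, 1.0)
    noise = (
        np.exp(rng.normal(0.0, config.noise_sd, high.shape))
        if config.noise_sd > 0
        else 1.0
    )
    values = pd.DataFrame(base[:, None] * factor * noise, index=genes, columns=tissues)
    return AtlasMatrix(values=values, tissue_category=categories)


def generate_annotation(config: SimulationConfig, truth: SyntheticTruth,
                        n_decoy_terms: int = 20, decoy_size: int = 50):
    """Build a synthetic gene->term annotation over the simulated chip.

    Three signature terms follow the tissue blocks (endocrine, neural,
    neuro-endocrine); decoy terms are random draws from the universe, so
    over-representation of the signatures in the activated set is real and
    of the decoys accidental.
    """
    from .enrich import AnnotationMap

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 224737]))
    universe = sorted(truth.tissue_block)
    terms: dict[str, set[str]] = {
        "SIG:ENDOCRINE": {g for g, b in truth.tissue_block.items() if b == "endocrine"},
        "SIG:NEURAL": {g for g, b in truth.tissue_block.items() if b == "cns"},
        "SIG:NEUROENDOCRINE": {g for g, b in truth.tissue_block.items() if b == "shared"},
    }
    labels = {
        "SIG:ENDOCRINE": "endocrine secretion signature",
        "SIG:NEURAL": "neurogenesis / synaptic signature",
        "SIG:NEUROENDOCRINE": "neuro-endocrine shared signature",
    }
    for i in range(1, n_decoy_terms + 1):
        tid = f"DECOY:{i:04d}"
        size = min(decoy_size, len(universe))
        terms[tid] = set(rng.choice(universe, size=size, replace=False))
        labels[tid] = f"random background term {i}"
    return AnnotationMap(terms=terms, labels=labels, universe=set(universe))
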