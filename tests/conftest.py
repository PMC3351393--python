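import numpy as np
import pandas as pd
import pytest

from reprotome import SimulationConfig, generate_experiment
from reprotome.simulate import ProbeMatrix


def small_config(**kwargs) -> SimulationConfig:
    """A fast simulation preserving the study's set proportions."""
    defaults = dict(
        n_transcripts=400,
        probes_per_set=5,
        n_replicates=3,
        target_enriched_size=40,
        reprogramming_fraction_f=0.3,
        n_activated_offpath=8,
        n_suppressed=6,
        effect_fold_range=(2.5, 10.0),
        marker_panel_size=15,
        seed=7,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    return small_config(noise_sd=0.0, probe_sensitivity_sd=0.0, baseline_log_sd=0.5)


@pytest.fixture
def noiseless_experiment(noiseless_config):
    return generate_experiment(noiseless_config)


@pytest.fixture
def noisy_experiment():
    return generate_experiment(small_config())


def make_probe_matrix(pm: np.ndarray, mm: np.ndarray, probes_per_set: int = 1,
                      conditions=None) -> ProbeMatrix:
    """Wrap raw PM/MM arrays (probes x arrays) into a ProbeMatrix."""
    P, A = pm.shape
    n_sets = P // probes_per_set
    ids = np.repeat([f"PS{i:03d}" for i in range(n_sets)], probes_per_set)
    if conditions is None:
        conditions = [("control", "D3")] * A
    rows = [
        (f"s{a}", cond, tp, a) for a, (cond, tp) in enumerate(conditions)
    ]
    samples = pd.DataFrame(rows, columns=["sample_id", "condition", "timepoint", "replicate"])
    return ProbeMatrix(
        probeset_ids=ids,
        probe_index=np.tile(np.arange(probes_per_set), n_sets),
        pm=np.asarray(pm, float),
        mm=np.asarray(mm, float),
        samples=samples,
    )
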