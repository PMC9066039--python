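import numpy as np
import pytest

from lactnet.core_io import STAGES, ExpressionMatrix, SampleDesign
from lactnet.synthetic_data import SimulationConfig, simulate_dataset


def make_samples() -> list[SampleDesign]:
    return [
        SampleDesign(f"I{i}_S{s}", f"I{i}", s) for i in (1, 2, 3) for s in STAGES
    ]


def make_expression(
    counts: np.ndarray, feature_ids: list[str] | None = None
) -> ExpressionMatrix:
    """Wrap a counts matrix; FPKM layer = counts at a fixed unit depth
    (avoids compositional artifacts in tiny fixtures)."""
    samples = make_samples()
    counts = np.asarray(counts)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(counts.shape[0])]
    return ExpressionMatrix(feature_ids, samples, counts, counts.astype(float))


@pytest.fixture(scope="session")
def samples():
    return make_samples()


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """One small simulated study shared across read-only tests."""
    cfg = SimulationConfig(seed=11, n_transcripts=120, n_genes=40, n_de_lnc=6,
                           n_cis_pairs=3, n_snps=400, n_enriched_snps=40,
                           n_modules=2, module_size=10)
    out = tmp_path_factory.mktemp("sim")
    paths, truth = simulate_dataset(cfg, out)
    return cfg, paths, truth
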