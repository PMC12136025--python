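import pytest

from cpsort.data import default_plastid_matrix, default_ppc_matrix
from cpsort.fixtures import PlantPlan, REFERENCE_MIX, synth_proteome
from cpsort.io_formats import parse_predictor_output
from cpsort.matrixlib import WindowSet, build_scoring_matrix
from cpsort.predictor import PredictorConfig, predict_batch


def embed_window(window: str, site: int, tail: str = "G" * 12) -> str:
    """Place a 25-residue cleavage-site window into a sequence so that the
    window occupies positions site-4 .. site+20 (site >= 6)."""
    assert site >= 6 and len(window) == 25
    return "M" + "L" * (site - 6) + window + tail


@pytest.fixture(scope="session")
def plastid_matrix():
    return default_plastid_matrix()


@pytest.fixture(scope="session")
def ppc_matrix():
    return default_ppc_matrix()


@pytest.fixture(scope="session")
def conserved_matrix():
    """Uncorrected matrix from identical windows: every column fully conserved."""
    ws = WindowSet.from_sequences(["ACDEFGHIKLMNPQRSTVWYACDEF"] * 3)
    return build_scoring_matrix(ws, corrected=False, label="conserved")


@pytest.fixture(scope="session")
def default_config(plastid_matrix, ppc_matrix):
    return PredictorConfig(plastid_matrix=plastid_matrix, ppc_matrix=ppc_matrix)


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory):
    """Reference-mix synthetic proteome at high window conservation, with
    parsed upstream predictions: the packaged end-to-end test bed."""
    plan = PlantPlan(counts=REFERENCE_MIX, seed=11, conservation=0.9)
    proteome = synth_proteome(plan)
    outdir = tmp_path_factory.mktemp("benchmark")
    paths = proteome.write(outdir)
    preds = parse_predictor_output(paths["predictor"], "targetp2")
    return proteome, preds, paths


@pytest.fixture(scope="session")
def benchmark_results(benchmark, default_config):
    proteome, preds, _ = benchmark
    return predict_batch(list(proteome.proteins), preds, default_config)
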