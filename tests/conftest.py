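import numpy as np
import pytest

from kinbind.io import BindingMatrix, FeatureColumn, FeatureTable, MolecularGraph
from kinbind.synth import SynthSpec, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """An 8x4 bundle with a fully planted signal."""
    spec = SynthSpec(
        m=8, n=4, seq_len=60, n_active_columns=6, n_signal_columns=2,
        signal=1.0, positive_rate=0.3, seed=42,
    )
    return generate_bundle(spec)


@pytest.fixture
def toy_matrix():
    return BindingMatrix(
        kinase_ids=["k1", "k2", "k3"],
        inhibitor_ids=["i1", "i2", "i3"],
        labels=np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0]]),
    )


@pytest.fixture
def ethanol():
    return MolecularGraph(
        atoms=[("C", 0, 3), ("C", 0, 2), ("O", 0, 1)],
        bonds=[(0, 1, 1), (1, 2, 1)],
    )


def make_feature_table(ids, spec):
    """spec: list of (name, kind, group, values)."""
    cols = [FeatureColumn(n, k, g) for n, k, g, _ in spec]
    values = list(zip(*[v for _, _, _, v in spec]))
    return FeatureTable(ids, cols, [list(r) for r in values])
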