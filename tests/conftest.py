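import numpy as np
import pandas as pd
import pytest

from hepomix.kb_model import GROUP_CONTROL, GROUP_TREATMENT, LayerKind, OmicsLayer
from hepomix.synthetic_data import SimConfig


@pytest.fixture
def small_config():
    """A scaled-down study configuration for fast structural tests."""
    return SimConfig(
        seed=7,
        n_transcripts=300,
        n_proteins=120,
        n_metabolites=60,
        n_mirnas=80,
        n_pathways=8,
        pathway_size_range=(6, 12),
        n_regulators=3,
        targets_per_regulator=8,
        n_planted_mirnas=5,
        n_exclusive_proteins=6,
    )


@pytest.fixture
def groups_5v5():
    g = {f"C{i}": GROUP_CONTROL for i in range(1, 6)}
    g.update({f"T{i}": GROUP_TREATMENT for i in range(1, 6)})
    return g


def make_layer(kind, values, groups, feature_prefix="F"):
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        arr,
        index=[f"{feature_prefix}{i}" for i in range(1, arr.shape[0] + 1)],
        columns=list(groups),
    )
    return OmicsLayer(LayerKind(kind), df, groups)


@pytest.fixture
def count_layer_factory(groups_5v5):
    def _make(values, kind=LayerKind.TRANSCRIPT):
        return make_layer(kind, values, groups_5v5)
    return _make
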