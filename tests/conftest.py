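import numpy as np
import pandas as pd
import pytest

from clocknet.io import SWC_COLUMNS, Skeleton
from clocknet.synthetic_data import (
    build_ligand_receptor_catalog,
    build_synthetic_connectome,
    build_synthetic_expression,
    default_config,
)


@pytest.fixture(scope="session")
def config():
    """Default study conditions, fixed seed."""
    return default_config(seed=1)


@pytest.fixture(scope="session")
def connectome(config):
    return build_synthetic_connectome(config)


@pytest.fixture(scope="session")
def expression(config):
    expr, _ = build_synthetic_expression(config)
    return expr


@pytest.fixture(scope="session")
def catalog(config):
    return build_ligand_receptor_catalog(config)


def make_chain_skeleton(neuron_id: str, coords) -> Skeleton:
    """A path skeleton through the given coordinates (test helper)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(1, n + 1),
            "structure": [1] + [3] * (n - 1),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "radius": np.full(n, 0.1),
            "parent_id": [-1] + list(range(1, n)),
        },
        columns=SWC_COLUMNS,
    )
    return Skeleton(neuron_id=neuron_id, nodes=nodes)


def make_synapses(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["pre_id", "post_id", "n_synapses"])


def make_annotations(rows) -> pd.DataFrame:
    """rows: (neuron_id, cell_type, hemisphere, x, y, z[, super_class[, hemilineage]])."""
    out = []
    for r in rows:
        nid, ct, hemi, x, y, z = r[:6]
        sc = r[6] if len(r) > 6 else "central"
        hl = r[7] if len(r) > 7 else f"hl:{ct}"
        out.append(
            {
                "neuron_id": nid,
                "cell_type": ct,
                "super_class": sc,
                "hemilineage": hl,
                "hemisphere": hemi,
                "x": float(x),
                "y": float(y),
                "z": float(z),
            }
        )
    return pd.DataFrame(out)


def random_synapse_table(rng, n_neurons=50, p=0.10, max_count=8):
    ids = [f"n{i}" for i in range(n_neurons)]
    rows = []
    for a in ids:
        for b in ids:
            if a != b and rng.random() < p:
                rows.append((a, b, int(rng.integers(1, max_count + 1))))
    return make_synapses(rows), ids
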