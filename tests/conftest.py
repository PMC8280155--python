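import numpy as np
import pandas as pd
import pytest

from foxnet.signature_core import PerturbationType, Signature


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_signature(values, perturbation_id="p", cell_line="A549",
                   ptype=PerturbationType.COMPOUND, target=None, replicate=0):
    if isinstance(values, dict):
        series = pd.Series(values, dtype=float)
    else:
        series = pd.Series(
            np.asarray(values, dtype=float),
            index=[f"g{i}" for i in range(len(values))],
        )
    return Signature(
        perturbation_id=perturbation_id,
        cell_line=cell_line,
        values=series,
        perturbation_type=ptype,
        target_gene=target,
        replicate=replicate,
    )


@pytest.fixture()
def small_screen():
    """A small synthetic screen shared by screen-stage tests."""
    from foxnet.simulate import ScreenSimConfig, simulate_screen

    config = ScreenSimConfig(
        n_genes=300, n_decoy_compounds=20, mixing_weight=0.7, seed=17
    )
    return simulate_screen(config)
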