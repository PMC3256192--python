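import numpy as np
import pytest

from mdrkit import (GenotypeDataset, SimulationConfig, PenetranceModel,
                    simulate_case_control, snp_factor)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_dataset(values, status, factors=None, group=None):
    """Small GenotypeDataset from literal arrays (helper, not a fixture)."""
    values = np.asarray(values, dtype=np.int16)
    n, p = values.shape
    if factors is None:
        factors = [snp_factor(f"S{j + 1}") for j in range(p)]
    if group is None:
        group = ["case" if s else "control" for s in status]
    return GenotypeDataset(
        subjects=[f"id{i + 1:03d}" for i in range(n)],
        status=np.asarray(status, dtype=np.int8),
        group=np.asarray(group, dtype=object),
        factors=list(factors), values=values)


@pytest.fixture
def null_sim_dataset():
    """No-effect cohort: 4 SNPs, penetrance flat at baseline."""
    cfg = SimulationConfig(
        n_cases=30, n_controls=30,
        snps=[(f"S{j}", 0.3) for j in range(1, 5)],
        penetrance=PenetranceModel(factors=("S1",), table={}, baseline=0.1),
        seed=1)
    return simulate_case_control(cfg)
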