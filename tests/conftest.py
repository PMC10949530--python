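import numpy as np
import pandas as pd
import pytest

from mmgp import synthetic


@pytest.fixture(scope="session")
def small_met():
    """Complete 60-line x 3-environment trial, moderate heritability."""
    cfg = synthetic.SimConfig(J=60, I=3, M=400, seed=4)
    return synthetic.simulate_met(cfg)


@pytest.fixture(scope="session")
def medium_met():
    """200-line x 3-environment trial (600 observations)."""
    cfg = synthetic.SimConfig(J=200, I=3, M=1500, seed=21)
    return synthetic.simulate_met(cfg)


@pytest.fixture
def hapmap_file(tmp_path):
    """Write a small markers-as-rows TASSEL-coded genotype table."""

    def _write(rows, header="marker\tL1\tL2\tL3", name="geno.txt"):
        path = tmp_path / name
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return _write


@pytest.fixture
def tiny_pheno():
    rng = np.random.default_rng(0)
    envs, lines = ["E0", "E1"], [f"L{j}" for j in range(6)]
    rows = [
        (e, l, "trait", 10 + rng.standard_normal()) for e in envs for l in lines
    ]
    return pd.DataFrame(rows, columns=["environment", "line", "trait", "value"])
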