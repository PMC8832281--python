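import numpy as np
import pandas as pd
import pytest

from heteropat.genotypes import GenotypeMatrix
from heteropat.simdata import SimPanelSpec, simulate_panel


def make_matrix(dosage, chrom=None, pos=None, **kw) -> GenotypeMatrix:
    """Tiny GenotypeMatrix from a dosage array (rows=samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1)),
        ref=np.array(["A"] * m, dtype=object),
        alt=kw.pop("alt", [("T",)] * m),
        dosage=dosage,
        **kw,
    )


@pytest.fixture(scope="session")
def structured_panel():
    """Four well-separated subpopulations; shared across structure tests."""
    return simulate_panel(
        SimPanelSpec(
            n_subpops=4, samples_per_subpop=(50,) * 4, n_loci=2000,
            n_chromosomes=12, fst=0.3, seed=7,
        )
    )


@pytest.fixture()
def rcbd_3x2():
    """Hand-checkable 3-entry x 2-block trial: values (10,12),(20,22),(30,32)."""
    from heteropat.trials import TrialData

    obs = pd.DataFrame(
        [
            ("e1", "parent", "B1", "t", 10.0), ("e1", "parent", "B2", "t", 12.0),
            ("e2", "parent", "B1", "t", 20.0), ("e2", "parent", "B2", "t", 22.0),
            ("e3", "parent", "B1", "t", 30.0), ("e3", "parent", "B2", "t", 32.0),
        ],
        columns=["entry", "role", "block", "trait", "value"],
    )
    return TrialData(
        observations=obs, traits=pd.DataFrame({"trait": ["t"], "direction": ["high"]})
    )
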