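import numpy as np
import pandas as pd
import pytest

from pbtgsi.genotype_io import MISSING, AlleleFrequencies, BaselineRegistry, GenotypeTable
from pbtgsi.panel import LocusPanel


@pytest.fixture
def small_panel() -> LocusPanel:
    return LocusPanel.default(6)


@pytest.fixture
def toy_table(small_panel) -> GenotypeTable:
    rng = np.random.default_rng(0)
    geno = rng.integers(0, 3, size=(4, small_panel.n_loci)).astype(np.int8)
    geno[0, 0] = MISSING
    return GenotypeTable(
        [f"ind{i}" for i in range(4)],
        ["popA", "popA", "popB", "popB"],
        list(small_panel.locus_ids),
        geno,
    )


@pytest.fixture
def toy_registry() -> BaselineRegistry:
    return BaselineRegistry(
        pd.DataFrame(
            {
                "population": ["popA", "popB", "popC"],
                "cu": ["CU1", "CU1", "CU2"],
                "region": ["R1", "R1", "R2"],
                "country": ["CA", "CA", "US"],
            }
        )
    )


@pytest.fixture
def toy_freqs(small_panel) -> AlleleFrequencies:
    rng = np.random.default_rng(1)
    vals = rng.uniform(0.2, 0.8, size=(3, small_panel.n_loci))
    return AlleleFrequencies(["popA", "popB", "popC"], list(small_panel.locus_ids), vals)
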