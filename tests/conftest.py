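import numpy as np
import pandas as pd
import pytest

from tumourprint.cohort import simulate_cohort
from tumourprint.karyotype import Chromosome, Karyotype, default_female_karyotype
from tumourprint.pipeline import RunConfig, analyse_cohort

PAPER_SEED = 42


@pytest.fixture(scope="session")
def karyotype():
    return default_female_karyotype()


@pytest.fixture(scope="session")
def toy_karyotype():
    """Two-chromosome karyotype for fast unit tests."""
    return Karyotype(
        chromosomes=(
            Chromosome("chrA", 100_000_000, 50_000_000),
            Chromosome("chrB", 80_000_000, 30_000_000),
        )
    )


@pytest.fixture(scope="session")
def paper_bundle():
    return simulate_cohort("paper_cohort", PAPER_SEED)


@pytest.fixture(scope="session")
def paper_analysis(paper_bundle):
    """Full end-to-end analysis of the bundled 23-tumour preset."""
    return analyse_cohort(paper_bundle, RunConfig(seed=PAPER_SEED))


def states_frame(rows):
    """Helper: build a state table from (chrom, start, end, n_probes, cn, major)."""
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_probes", "cn", "major"]
    )
    df["minor"] = df["cn"] - df["major"]
    return df
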