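import numpy as np
import pandas as pd
import pytest

from bsfparentage.genotypes import GenotypeMatrix
from bsfparentage.simpop import (DesignConfig, build_design, drop_genotypes,
                                 sample_founder_frequencies)


@pytest.fixture(scope="session")
def design():
    return DesignConfig(n_loci=150, maf_low=0.30, maf_high=0.5)


@pytest.fixture(scope="session")
def pedigree(design):
    return build_design(design, seed=11)


@pytest.fixture(scope="session")
def founder_freqs(design):
    return sample_founder_frequencies(design.n_loci, design.maf_low,
                                      design.maf_high, seed=12)


@pytest.fixture(scope="session")
def truth_matrix(pedigree, founder_freqs):
    """Error-free genotypes for the whole session pedigree."""
    return drop_genotypes(pedigree, founder_freqs, seed=13)


def make_matrix(calls, colonies=None, depth=None, loci=None, parents=None):
    """Small hand-built GenotypeMatrix; calls is (samples x loci) list/array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    ids = [f"s{i}" for i in range(n)]
    samples = pd.DataFrame(
        {"id": ids,
         "colony": colonies if colonies is not None else ["A"] * n,
         "generation": 0, "family": "fam", "role": "larva",
         "sire": "", "dam": ""})
    if parents:
        for child, (sire, dam) in parents.items():
            samples.loc[samples["id"] == child, ["sire", "dam"]] = [sire, dam]
    if loci is None:
        loci = pd.DataFrame(
            {"id": [f"l{j}" for j in range(L)], "chrom": "chr1",
             "pos": np.arange(L) * 100 + 1,
             "rad_locus": [f"rad{j}" for j in range(L)], "pos_in_locus": 50})
    return GenotypeMatrix(calls=calls, samples=samples, loci=loci,
                          depth=None if depth is None else np.asarray(depth))
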