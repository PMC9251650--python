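import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import powan

settings.register_profile(
    "suite", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large])
settings.load_profile("suite")


def make_matrix(geno, pops, depth=None, chrom=None, pos=None, locus=None):
    """Build a GenotypeMatrix from a genotype array (samples x sites)."""
    geno = np.asarray(geno, dtype=np.int8)
    n, s = geno.shape
    sites = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * s,
        "pos": pos if pos is not None else np.arange(1, s + 1),
        "locus": locus if locus is not None else [f"L{j}" for j in range(s)],
        "ref": ["A"] * s, "alt": ["C"] * s})
    return powan.GenotypeMatrix([f"s{i}" for i in range(n)], list(pops), sites,
                                geno,
                                None if depth is None else np.asarray(depth, np.int32))


@pytest.fixture(scope="session")
def study_small():
    """A small study-like dataset (400 loci) shared across tests."""
    tpl = powan.StudyTemplate(n_loci=400)
    g, truth = powan.simulate.generate_vcf(tpl, 11)
    return g, truth, tpl


@pytest.fixture(scope="session")
def two_deme_model():
    """Plain two-deme split model used by several simulator tests."""
    return powan.DemographicModel(
        [powan.Deme("A", 4000), powan.Deme("B", 4000), powan.Deme("ANC", 8000)],
        [powan.Split(4000, "A", "ANC"), powan.Split(4000, "B", "ANC")]).validate()
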