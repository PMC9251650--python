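import numpy as np
import pytest
from scipy.stats import chisquare

import powan
from powan.coalescent import (Deme, DemographicModel, ModelError, Pulse,
                              SizeChange, Split, simulate_genealogy,
                              simulate_locus, simulate_msfs, simulate_tree_stats)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def test_two_deme_split_is_valid(two_deme_model):
    m = two_deme_model.validate()
    assert [e.time for e in m.events] == sorted(e.time for e in m.events)


def test_pulse_after_donor_merge_rejected():
    m = DemographicModel(
        [Deme("A", 1000), Deme("B", 1000), Deme("ANC", 1000)],
        [Split(100, "A", "ANC"), Split(100, "B", "ANC"),
         Pulse(200, "B", "A", 0.1)])
    with pytest.raises(ModelError, match="after it merged"):
        m.validate()


@pytest.mark.parametrize("events,msg", [
    ([Split(100, "X", "ANC")], "unknown deme"),
    ([Pulse(50, "A", "B", 1.5), Split(100, "A", "B")], "outside"),
    ([Split(-5, "A", "B")], "positive"),
    ([], "exactly one ancestral"),
])
def test_invalid_models_rejected(events, msg):
    m = DemographicModel([Deme("A", 1000), Deme("B", 1000),
                          Deme("ANC", 1000)],
                         events + [Split(500, "B", "ANC")])
    with pytest.raises(ModelError, match=msg):
        m.validate()


def test_study_point_estimate_model_is_valid():
    m = powan.whitefish_model()
    assert len(m.demes) == 11
    assert m.validate() is not None


def test_config_round_trip(tmp_path):
    m = powan.whitefish_model()
    m.to_json(tmp_path / "m.json")
    back = DemographicModel.from_json(tmp_path / "m.json")
    assert back.to_dict() == m.to_dict()


# ---------------------------------------------------------------------------
# genealogy simulation: closed forms and structure
# ---------------------------------------------------------------------------

def test_pair_tmrca_expectation():
    """Single deme, n=2 genes: E[TMRCA] = 2 N_e generations."""
    m = DemographicModel([Deme("A", 1500)])
    tm, _ = simulate_tree_stats(m, {"A": 1}, 10_000, seed=2)
    se = tm.std() / np.sqrt(len(tm))
    assert abs(tm.mean() - 3000) < 3 * se


def test_total_length_expectation_n8():
    """E[total length] = 4 N_e * sum_{i=1}^{7} 1/i for 8 genes."""
    m = DemographicModel([Deme("A", 1200)])
    _, tl = simulate_tree_stats(m, {"A": 4}, 10_000, seed=3)
    expect = 4 * 1200 * sum(1 / i for i in range(1, 8))
    se = tl.std() / np.sqrt(len(tl))
    assert abs(tl.mean() - expect) < 3 * se


def test_cross_deme_coalescence_postdates_split(two_deme_model):
    for seed in range(10):
        t = simulate_genealogy(two_deme_model, {"A": 2, "B": 2}, seed)
        below = t.leaves_below()
        demes = np.array(t.leaf_deme)
        for v in range(t.n_leaves, t.n_nodes):
            under = demes[below[v]]
            if len(set(under)) > 1:
                assert t.time[v] > 4000


def test_size_change_shifts_pair_tmrca():
    m = DemographicModel([Deme("A", 500)], [SizeChange(1.0, "A", 5000)])
    tm, _ = simulate_tree_stats(m, {"A": 1}, 8000, seed=4)
    # almost no mass below t=1: TMRCA ~ 1 + Exp(mean 10,000)
    assert abs(tm.mean() - 10_001) < 3 * tm.std() / np.sqrt(len(tm)) + 40


# ---------------------------------------------------------------------------
# mutation layer
# ---------------------------------------------------------------------------

def test_zero_length_tree_yields_no_sites():
    tree = simulate_genealogy(
        DemographicModel([Deme("A", 1000)]), {"A": 2}, 5)
    tree.time[:] = 0.0
    assert simulate_locus(tree, 1e-8, 142, 1).shape == (0, 4)


def test_site_frequency_equals_leaves_below_branch():
    tree = simulate_genealogy(
        DemographicModel([Deme("A", 1000)]), {"A": 4}, 7)
    carriers = simulate_locus(tree, 1e-4, 500, 9)
    below = tree.leaves_below()
    valid_counts = {int(below[v].sum()) for v in range(tree.n_nodes - 1)}
    for row in carriers:
        assert int(row.sum()) in valid_counts
        assert any(np.array_equal(row, below[v])
                   for v in range(tree.n_nodes - 1))


def test_segregating_sites_match_watterson():
    m = DemographicModel([Deme("A", 2000)], mutation_rate=1e-7, locus_length=200)
    sfs = simulate_msfs(m, {"A": 4}, 20_000, seed=8)
    expect = 1e-7 * 200 * 4 * 2000 * sum(1 / i for i in range(1, 8)) * 20_000
    s = sfs.n_polymorphic
    assert abs(s - expect) < 4 * np.sqrt(expect)


def test_folded_sfs_shape_matches_theory():
    """Folded 1-D SFS entries proportional to (1/i + 1/(2n-i))/(1+d_i)."""
    m = DemographicModel([Deme("A", 30_000)])
    sfs = simulate_msfs(m, {"A": 4}, 300_000, seed=12)
    obs = np.array([sfs.entries.get((i,), 0.0) for i in range(1, 5)])
    assert obs.sum() > 1e5
    exp = np.array([1 / i + 1 / (8 - i) for i in range(1, 4)] + [1 / 4])
    exp /= exp.sum()
    assert chisquare(obs, exp * obs.sum()).pvalue > 1e-3


def test_msfs_accounting_and_determinism(two_deme_model):
    sfs = simulate_msfs(two_deme_model, {"A": 3, "B": 3}, 500, seed=6)
    assert sfs.total == 500 * two_deme_model.locus_length
    again = simulate_msfs(two_deme_model, {"A": 3, "B": 3}, 500, seed=6)
    assert again.entries == sfs.entries and again.monomorphic == sfs.monomorphic
    other = simulate_msfs(two_deme_model, {"A": 3, "B": 3}, 500, seed=61)
    assert other.entries != sfs.entries


def test_extending_n_loci_preserves_earlier_loci(two_deme_model):
    """Counter-based substreams: the first loci are unchanged when more are
    simulated."""
    c1, l1, _ = powan.coalescent.simulate_sites(two_deme_model,
                                                {"A": 2, "B": 2}, 50, seed=5)
    c2, l2, _ = powan.coalescent.simulate_sites(two_deme_model,
                                                {"A": 2, "B": 2}, 80, seed=5)
    first = l2 < 50
    assert np.array_equal(c2[first], c1)


def test_near_zero_split_behaves_as_one_deme():
    """Two demes split at t~0 give the pooled one-deme folded SFS."""
    m2 = DemographicModel(
        [Deme("A", 3000), Deme("B", 3000), Deme("ANC", 3000)],
        [Split(1e-3, "A", "ANC"), Split(1e-3, "B", "ANC")])
    m1 = DemographicModel([Deme("ANC", 3000)])
    s2 = simulate_msfs(m2, {"A": 2, "B": 2}, 120_000, seed=9)
    s1 = simulate_msfs(m1, {"ANC": 4}, 120_000, seed=10)
    pooled = {}
    for (a, b), m in s2.entries.items():
        pooled[a + b] = pooled.get(a + b, 0.0) + m
    obs = np.array([pooled.get(i, 0.0) for i in range(1, 5)])
    ref = np.array([s1.entries.get((i,), 0.0) for i in range(1, 5)])
    assert chisquare(obs, ref / ref.sum() * obs.sum()).pvalue > 1e-3


# ---------------------------------------------------------------------------
# cross-simulator and admixture behaviour
# ---------------------------------------------------------------------------

def _fst_from_sim(simulator, n_batches=5):
    import pandas as pd
    from conftest import make_matrix
    vals = []
    for b in range(n_batches):
        geno, demes = simulator(b)
        g = make_matrix(geno, demes)
        vals.append(powan.wc_fst(g, "A", "B").theta)
    return np.array(vals)


def test_split_fst_matches_msprime(two_deme_model):
    """W&C F_ST from our engine vs msprime under identical parameters:
    overlapping 95% Monte-Carlo intervals over batches."""
    import msprime

    def ours(b):
        geno, locus_of, demes = powan.simulate_genotypes(
            two_deme_model, {"A": 5, "B": 5}, 800, seed=100 + b)
        return geno, demes

    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=4000)
    dem.add_population(name="B", initial_size=4000)
    dem.add_population(name="ANC", initial_size=8000)
    dem.add_population_split(time=4000, derived=["A", "B"], ancestral="ANC")

    def theirs(b):
        cols, demes = [], ["A"] * 5 + ["B"] * 5
        for r, ts in enumerate(msprime.sim_ancestry(
                samples={"A": 5, "B": 5}, demography=dem, num_replicates=800,
                sequence_length=142, random_seed=200 + b)):
            mts = msprime.sim_mutations(ts, rate=1e-8,
                                        random_seed=1 + 1000 * b + r,
                                        discrete_genome=False)
            gm = mts.genotype_matrix()          # sites x genes
            if gm.shape[0]:
                cols.append(gm[:, 0::2] + gm[:, 1::2])
        geno = np.vstack(cols).T
        return geno.astype(np.int8), demes

    a = _fst_from_sim(ours)
    b = _fst_from_sim(theirs)
    lo_a, hi_a = a.mean() - 2 * a.std(), a.mean() + 2 * a.std()
    lo_b, hi_b = b.mean() - 2 * b.std(), b.mean() + 2 * b.std()
    assert max(lo_a, lo_b) < min(hi_a, hi_b)


def test_pulse_strength_moves_fst_towards_panmixia():
    """F_ST between two demes decreases monotonically in the admixture
    fraction, reaching ~0 at alpha = 1 (full replacement)."""
    thetas = []
    for alpha in (0.0, 0.3, 0.6, 1.0):
        m = DemographicModel(
            [Deme("A", 2000), Deme("B", 2000), Deme("ANC", 2000)],
            [Pulse(10, "B", "A", alpha) if alpha else SizeChange(10, "B", 2000),
             Split(8000, "A", "ANC"), Split(8000, "B", "ANC")])
        geno, _, demes = powan.simulate_genotypes(m, {"A": 6, "B": 6}, 4000,
                                                  seed=31)
        from conftest import make_matrix
        g = make_matrix(geno, demes)
        thetas.append(powan.wc_fst(g, "A", "B").theta)
    assert thetas[0] > thetas[1] > thetas[2] > thetas[3]
    assert abs(thetas[3]) < 0.05
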