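import numpy as np
import pytest

import powan
from powan import (MSFS, Deme, DemographicModel, ModelTemplate, ParamSpec,
                   Split, simulate_msfs)
from powan.sfs import (cl_from_expected, compare_models,
                       composite_log_likelihood, downsample_genotypes, fit,
                       generations_to_years, hierarchical_build,
                       msfs_from_genotypes, parametric_bootstrap, profile_scan,
                       to_ky)
from conftest import make_matrix


# ---------------------------------------------------------------------------
# observed-MSFS construction
# ---------------------------------------------------------------------------

def test_single_het_increments_entry_one():
    g = make_matrix([[1], [0]], ["P1", "P1"])
    sfs = msfs_from_genotypes(g, ["P1"])
    assert sfs.entries == {(1,): 1.0}
    assert sfs.monomorphic == 0.0 and sfs.folded


def test_fixed_difference_folds_by_tie_rule():
    # 2 demes x 2 diploids, alt fixed in deme B: counts (0, 4) vs complement
    # (4, 0); the tie keeps the lexicographically smaller vector (0, 4)
    g = make_matrix([[0], [0], [2], [2]], ["A", "A", "B", "B"])
    sfs = msfs_from_genotypes(g, ["A", "B"])
    assert sfs.entries == {(0, 4): 1.0}


def test_msfs_total_equals_snp_count(study_small):
    g, _, _ = study_small
    ds = downsample_genotypes(g, 6)
    sfs = msfs_from_genotypes(ds, list(ds.pop_labels()))
    mono_in = sum(1 for j in range(ds.n_sites)
                  if ds.genotypes[:, j].sum() in (0, 2 * ds.n_samples))
    assert sfs.n_polymorphic == ds.n_sites - mono_in


def test_missing_genotype_error_names_site():
    g = make_matrix([[1, -1], [0, 1]], ["P1", "P1"])
    with pytest.raises(ValueError, match="chr1:2"):
        msfs_from_genotypes(g, ["P1"])


def test_downsample_identity_when_complete():
    g = make_matrix([[0, 1], [1, 2], [2, 0]], ["P1"] * 3)
    out = downsample_genotypes(g, 3)
    assert np.array_equal(out.genotypes, g.genotypes)


def test_downsample_excludes_missingness_carrier():
    geno = np.array([[0, 1, 2, 0], [1, 0, 1, 2], [-1, -1, -1, 0]])
    g = make_matrix(geno, ["P1"] * 3)
    out = downsample_genotypes(g, 2, seed=1)
    assert "s2" not in out.sample_ids
    assert out.n_sites == 4
    # contract: output always satisfies the msfs_from_genotypes precondition
    msfs_from_genotypes(out, ["P1"])


def test_downsample_too_small_population_rejected():
    g = make_matrix([[0], [1]], ["P1", "P1"])
    with pytest.raises(ValueError, match="P1"):
        downsample_genotypes(g, 3)


# ---------------------------------------------------------------------------
# composite likelihood
# ---------------------------------------------------------------------------

def test_cl_hand_arithmetic():
    """Three observed entries with fixed expected branch lengths."""
    obs = MSFS(("A",), np.array([4]), {(1,): 3.0, (2,): 2.0}, 10.0,
               folded=False)
    lengths = np.array([0.0, 2e5, 1e5, 0.0, 0.0])
    mu = 1e-8
    p1, p2 = mu * 2e5, mu * 1e5
    p_mono = 1 - (p1 + p2)
    expect = 3 * np.log(p1) + 2 * np.log(p2) + 10 * np.log(p_mono)
    assert cl_from_expected(obs, lengths, mu, 1e-12) == pytest.approx(expect)


def test_cl_floor_applies_to_unseen_entries():
    obs = MSFS(("A",), np.array([4]), {(3,): 1.0}, 0.0, folded=False)
    lengths = np.array([0.0, 1e5, 0.0, 0.0, 0.0])
    got = cl_from_expected(obs, lengths, 1e-8, 1e-9)
    assert got == pytest.approx(np.log(1e-9))


def test_cl_linear_in_counts_and_invariant_to_zero_entries(two_deme_model):
    obs = simulate_msfs(two_deme_model, {"A": 3, "B": 3}, 400, seed=3)
    cl1 = composite_log_likelihood(obs, two_deme_model, 3000, seed=7)
    doubled = MSFS(obs.deme_names, obs.sample_sizes,
                   {c: 2 * m for c, m in obs.entries.items()},
                   2 * obs.monomorphic, obs.folded)
    cl2 = composite_log_likelihood(doubled, two_deme_model, 3000, seed=7)
    assert cl2 == pytest.approx(2 * cl1, rel=1e-12)
    padded = MSFS(obs.deme_names, obs.sample_sizes,
                  {**obs.entries, (1, 2): obs.entries.get((1, 2), 0.0)},
                  obs.monomorphic, obs.folded)
    cl3 = composite_log_likelihood(padded, two_deme_model, 3000, seed=7)
    assert cl3 == pytest.approx(cl1, rel=1e-12)


def test_cl_rejects_sample_size_mismatch(two_deme_model):
    # deme order disagrees with the model's deme order and sizes differ
    bad = MSFS(("B", "A"), np.array([6, 4]), {(1, 1): 1.0}, 10.0, True)
    with pytest.raises(powan.ModelError, match="mismatch"):
        composite_log_likelihood(bad, two_deme_model, 500, seed=1)
    unknown = MSFS(("A", "X"), np.array([4, 4]), {(1, 1): 1.0}, 10.0, True)
    with pytest.raises(powan.ModelError, match="unknown deme"):
        composite_log_likelihood(unknown, two_deme_model, 500, seed=1)


def test_cl_peaks_at_generating_parameter(two_deme_model):
    """Self-consistency: no grid alternative beats the generating value."""
    obs = simulate_msfs(two_deme_model, {"A": 4, "B": 4}, 8000, seed=13)
    tpl = ModelTemplate(
        builder=lambda p: DemographicModel(
            [Deme("A", 4000), Deme("B", 4000), Deme("ANC", 8000)],
            [Split(p["t"], "A", "ANC"), Split(p["t"], "B", "ANC")]),
        fixed={"t": 4000.0}, name="two")
    grid = [1000, 2000, 3000, 4000, 5500, 8000, 12000]
    df = profile_scan(obs, tpl, "t", grid, n_sims=40_000, seed=17)
    assert df.loc[df["is_max"], "t"].iloc[0] == pytest.approx(4000)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

ONE_DEME = ModelTemplate(
    builder=lambda p: DemographicModel([Deme("A", p["n"])]),
    free={"n": ParamSpec(1e3, 1e5)}, name="one-deme")


def test_single_deme_size_recovery_and_reproducibility():
    truth = DemographicModel([Deme("A", 10_000)])
    obs = simulate_msfs(truth, {"A": 4}, 10_000, seed=1)
    f = fit(ONE_DEME, obs, n_starts=4, n_cycles=5, n_sims=20_000, seed=2)
    assert 5_000 <= f.params["n"] <= 20_000
    assert f.loglik >= max(l for _, l in f.per_start) - 1e-9
    again = fit(ONE_DEME, obs, n_starts=4, n_cycles=5, n_sims=20_000, seed=2)
    assert again.params == f.params and again.loglik == f.loglik


def test_total_sites_rescales_inferred_size_inversely():
    """Doubling the monomorphic total halves the inferred N (theta fixed)."""
    truth = DemographicModel([Deme("A", 10_000)])
    obs = simulate_msfs(truth, {"A": 4}, 10_000, seed=1)
    obs2 = obs.correct_monomorphic(2 * obs.total)
    f1 = fit(ONE_DEME, obs, n_starts=4, n_cycles=5, n_sims=20_000, seed=3)
    f2 = fit(ONE_DEME, obs2, n_starts=4, n_cycles=5, n_sims=20_000, seed=3)
    assert f2.params["n"] / f1.params["n"] == pytest.approx(0.5, rel=0.2)


def test_all_parameters_fixed_returns_evaluation_only(two_deme_model):
    obs = simulate_msfs(two_deme_model, {"A": 3, "B": 3}, 300, seed=5)
    tpl = ModelTemplate(builder=lambda p: two_deme_model, name="fixed")
    f = fit(tpl, obs, n_sims=2000, seed=6)
    assert f.n_starts == 0 and np.isfinite(f.loglik)


# ---------------------------------------------------------------------------
# model comparison and hierarchy
# ---------------------------------------------------------------------------

def _three_deme_builder(attach_to):
    def build(p):
        demes = [Deme("A", 3000), Deme("B", 3000), Deme("C", 3000),
                 Deme("AB", 3000), Deme("ROOT", 6000)]
        ev = [Split(p["t1"], "A", "AB"), Split(p["t1"], attach_to, "AB"),
              Split(p["t2"], "AB", "ROOT"),
              Split(p["t2"], "C" if attach_to == "B" else "B", "ROOT")]
        return DemographicModel(demes, ev)
    return build


def _three_deme_template(attach_to, name):
    return ModelTemplate(
        builder=_three_deme_builder(attach_to),
        free={"t1": ParamSpec(200, 20_000), "t2": ParamSpec(200, 40_000)},
        name=name)


def test_true_topology_outranks_misspecified():
    """((A,B),C) data: the generating topology wins in >= 2 of 3 replicates."""
    truth = _three_deme_builder("B")({"t1": 2000, "t2": 9000}).validate()
    wins = 0
    for rep in range(3):
        obs = simulate_msfs(truth, {"A": 3, "B": 3, "C": 3}, 2500,
                            seed=100 + rep)
        fits = [fit(_three_deme_template("B", "AB_C"), obs, n_starts=3,
                    n_cycles=4, n_sims=6000, seed=rep),
                fit(_three_deme_template("C", "AC_B"), obs, n_starts=3,
                    n_cycles=4, n_sims=6000, seed=rep)]
        table = compare_models(fits)
        if table.iloc[0]["model"] == "AB_C":
            wins += 1
    assert wins >= 2


def test_identical_models_tie_in_input_order(two_deme_model):
    obs = simulate_msfs(two_deme_model, {"A": 3, "B": 3}, 300, seed=5)
    tpl = ModelTemplate(builder=lambda p: two_deme_model, name="m1")
    tpl2 = ModelTemplate(builder=lambda p: two_deme_model, name="m2")
    f1 = fit(tpl, obs, n_sims=2000, seed=6)
    f2 = fit(tpl2, obs, n_sims=2000, seed=6)
    table = compare_models([f1, f2])
    assert table.iloc[0]["model"] == "m1" and bool(table.iloc[0]["best"])


def test_unnecessary_parameter_gains_little_and_loses_on_aic():
    truth = DemographicModel(
        [Deme("A", 4000), Deme("B", 4000), Deme("ANC", 8000)],
        [Split(4000, "A", "ANC"), Split(4000, "B", "ANC")]).validate()
    obs = simulate_msfs(truth, {"A": 3, "B": 3}, 3000, seed=21)

    def with_pulse(p):
        return DemographicModel(
            [Deme("A", 4000), Deme("B", 4000), Deme("ANC", 8000)],
            [powan.Pulse(100.0, "B", "A", p.get("alpha", 0.0)),
             Split(p["t"], "A", "ANC"), Split(p["t"], "B", "ANC")])

    small = ModelTemplate(builder=with_pulse,
                          free={"t": ParamSpec(500, 20_000)}, name="no-pulse")
    big = ModelTemplate(builder=with_pulse,
                        free={"t": ParamSpec(500, 20_000),
                              "alpha": ParamSpec(0.0, 0.5, scale="linear")},
                        name="pulse")
    f_small = fit(small, obs, n_starts=3, n_cycles=4, n_sims=8000, seed=22)
    f_big = fit(big, obs, n_starts=3, n_cycles=4, n_sims=8000, seed=22)
    table = compare_models([f_small, f_big]).set_index("model")
    assert abs(f_big.loglik - f_small.loglik) < 15
    assert table.loc["no-pulse", "AIC"] < table.loc["pulse", "AIC"] + 25


def test_compare_models_rejects_different_observations(two_deme_model):
    o1 = simulate_msfs(two_deme_model, {"A": 3, "B": 3}, 200, seed=5)
    o2 = simulate_msfs(two_deme_model, {"A": 3, "B": 3}, 200, seed=50)
    tpl = ModelTemplate(builder=lambda p: two_deme_model, name="m")
    with pytest.raises(ValueError, match="different observed"):
        compare_models([fit(tpl, o1, n_sims=1000, seed=1),
                        fit(tpl, o2, n_sims=1000, seed=1)])


def test_hierarchical_level_recovers_attachment():
    """Adding deme C: the generating ((A,B),C) attachment wins its level, and
    a single-candidate level degenerates to a plain sequential fit."""
    truth = _three_deme_builder("B")({"t1": 2000, "t2": 9000}).validate()
    obs = simulate_msfs(truth, {"A": 3, "B": 3, "C": 3}, 2500, seed=33)
    levels = [{"name": "add-C", "observed": obs,
               "candidates": [_three_deme_template("B", "AB_C"),
                              _three_deme_template("C", "AC_B")]}]
    out = hierarchical_build(levels, n_starts=3, n_cycles=4, n_sims=6000,
                             seed=34)
    name, best, table = out[0]
    assert best.template.name == "AB_C"
    assert best.template.build(
        {k: v for k, v in best.params.items()}).validate()
    single = hierarchical_build(
        [{"name": "only", "observed": obs,
          "candidates": [_three_deme_template("B", "AB_C")]}],
        n_starts=3, n_cycles=4, n_sims=6000, seed=101)
    direct = fit(_three_deme_template("B", "AB_C"), obs, n_starts=3,
                 n_cycles=4, n_sims=6000, seed=101)
    assert single[0][1].params == direct.params


def test_hierarchical_empty_candidates_rejected(two_deme_model):
    obs = simulate_msfs(two_deme_model, {"A": 3, "B": 3}, 100, seed=5)
    with pytest.raises(ValueError, match="empty candidate"):
        hierarchical_build([{"name": "x", "observed": obs, "candidates": []}])


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

TWO_DEME_T = ModelTemplate(
    builder=lambda p: DemographicModel(
        [Deme("A", 4000), Deme("B", 4000), Deme("ANC", 8000)],
        [Split(p["t"], "A", "ANC"), Split(p["t"], "B", "ANC")]),
    free={"t": ParamSpec(500, 20_000)}, name="two-deme")


def test_bootstrap_interval_tightens_with_more_loci():
    widths = []
    for n_loci in (400, 6400):
        truth = TWO_DEME_T.build({"t": 4000.0})
        obs = simulate_msfs(truth, {"A": 3, "B": 3}, n_loci, seed=41)
        f = fit(TWO_DEME_T, obs, n_starts=3, n_cycles=4, n_sims=4000, seed=42)
        ci = parametric_bootstrap(f, n_boot=6, n_opt=2, seed=43, n_cycles=3,
                                  n_sims=4000)
        lo, hi = ci.interval("t")
        widths.append(hi - lo)
    assert widths[1] < widths[0]


# ---------------------------------------------------------------------------
# time conversion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("gens,ky", [(26_247, 92), (18_674, 65),
                                     (23_205, 81), (0, 0)])
def test_generation_to_year_conversion(gens, ky):
    years = generations_to_years(gens)
    assert years == pytest.approx(gens * 3.5)
    assert to_ky(years) == ky


def test_negative_generations_rejected():
    with pytest.raises(ValueError):
        generations_to_years(-1)
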