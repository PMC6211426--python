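"""Mixture-model fitting, posterior computation and MAP ploidy selection."""

import numpy as np
import pytest

from polydose.inference import (
    LocusUnusableError,
    MISSING,
    call_genotypes,
    class_log_likelihoods,
    compute_class_likelihoods,
    fit_f1,
    fit_hwe,
    fit_locus,
    fit_ploidy_free,
    naive_posteriors,
    select_ploidy,
)
from polydose.simulate import SimulationSpec, simulate_locus


@pytest.mark.parametrize(
    "counts, argmax",
    [((30, 30), 2), ((0, 40), 4), ((10, 30), 3)],
)
def test_class_likelihood_argmax_at_nearest_ratio(make_obs, counts, argmax):
    obs = make_obs([counts])
    dens, observed = compute_class_likelihoods(obs, 4, 0.05)
    assert observed[0]
    assert int(np.argmax(dens[0])) == argmax


def test_zero_depth_individual_flagged_missing(make_obs):
    obs = make_obs([(0, 0), (10, 10)])
    dens, observed = compute_class_likelihoods(obs, 4, 0.05)
    assert not observed[0] and observed[1]
    assert np.isnan(dens[0]).all()


def test_naive_posterior_extreme_ratio(make_obs):
    """Ratio 1.0 sits 5 sd from the next class mean: posterior ~ 1."""
    obs = make_obs([(0, 60)])
    ll = class_log_likelihoods(obs, 4, 0.05)
    post = naive_posteriors(ll, obs.observed)
    assert post[0, 4] > 0.999


def test_naive_posterior_symmetry_about_half(make_obs):
    obs = make_obs([(30, 30)])
    for sigma in (0.02, 0.05, 0.2):
        ll = class_log_likelihoods(obs, 4, sigma)
        post = naive_posteriors(ll, obs.observed)
        assert post[0, 1] == pytest.approx(post[0, 3])
        assert post[0, 0] == pytest.approx(post[0, 4])


@pytest.mark.parametrize("mode", ["exact", "greedy"])
def test_fit_f1_noiseless_nulliplex_simplex(make_obs, sigma_grid, mode):
    """Parents at ratios 0 and 0.25, progeny split 1:1 -> pair (0, 1)."""
    progeny = [(40, 0)] * 10 + [(45, 15)] * 10
    obs = make_obs(progeny, par1=[(40, 0)] * 3, par2=[(30, 10)] * 3)
    fit = fit_f1(obs, 4, sigma_grid, mode)
    assert fit.map_config == (0, 1)
    prog_post = fit.model_posteriors[: len(progeny)]
    truth = np.array([0] * 10 + [1] * 10)
    assert (prog_post[np.arange(20), truth] > 0.99).all()


def test_fit_f1_simulated_recovers_cross(sigma_grid):
    spec = SimulationSpec(seed=42, model="f1", parent_dosages=(0, 1), n_individuals=100)
    obs, truth = simulate_locus(spec)
    fit = fit_f1(obs, 4, sigma_grid, "exact")
    assert fit.map_config == (0, 1)
    calls = call_genotypes(fit, select_ploidy([fit]), 0.0)
    called = calls.dosages[calls.progeny_mask]
    assert set(called[called != MISSING].tolist()) <= {0, 1}


def test_fit_f1_all_progeny_missing_is_unusable(make_obs, sigma_grid):
    obs = make_obs([(0, 0)] * 5, par1=[(40, 0)], par2=[(40, 0)])
    with pytest.raises(LocusUnusableError):
        fit_f1(obs, 4, sigma_grid, "exact")


def test_fit_f1_without_parent_replicates_marginalizes(make_obs, sigma_grid):
    """No replicates: the parental pair is still inferred from the progeny."""
    progeny = [(40, 0)] * 20 + [(45, 15)] * 20
    obs = make_obs(progeny)
    fit = fit_f1(obs, 4, sigma_grid, "exact")
    assert fit.map_config in ((0, 1), (1, 0))
    assert np.isfinite(fit.log_evidence)


def test_fit_hwe_fixed_reference(make_obs, sigma_grid):
    obs = make_obs([(40, 0)] * 30)
    fit = fit_hwe(obs, 4, sigma_grid, "exact")
    assert fit.map_config == 0.0
    calls = call_genotypes(fit, select_ploidy([fit]), 0.0)
    assert (calls.dosages == 0).all()


@pytest.mark.parametrize("mode", ["exact", "greedy"])
def test_fit_hwe_noiseless_balanced_panel(make_obs, sigma_grid, mode):
    """Ratios {0,.25,.5,.75,1} in binomial 1:4:6:4:1 proportions -> p = 0.5."""
    panel = (
        [(40, 0)] * 10
        + [(30, 10)] * 40
        + [(20, 20)] * 60
        + [(10, 30)] * 40
        + [(0, 40)] * 10
    )
    obs = make_obs(panel)
    fit = fit_hwe(obs, 4, sigma_grid, mode)
    assert abs(fit.map_config - 0.5) <= 0.01


def test_fit_hwe_ref_alt_swap_mirrors(sigma_grid):
    spec = SimulationSpec(seed=9, model="hwe", allele_freq=0.3, n_individuals=150)
    obs, _ = simulate_locus(spec)
    fit = fit_hwe(obs, 4, sigma_grid, "exact")
    swapped = type(obs)(
        locus_id=obs.locus_id,
        sample_ids=obs.sample_ids,
        ref_counts=obs.alt_counts,
        alt_counts=obs.ref_counts,
    )
    fit_sw = fit_hwe(swapped, 4, sigma_grid, "exact")
    assert fit_sw.map_config == pytest.approx(1.0 - fit.map_config)
    calls = call_genotypes(fit, select_ploidy([fit]), 0.0)
    calls_sw = call_genotypes(fit_sw, select_ploidy([fit_sw]), 0.0)
    obs_mask = calls.dosages != MISSING
    np.testing.assert_array_equal(
        calls_sw.dosages[obs_mask], 4 - calls.dosages[obs_mask]
    )


def test_ploidy_free_posterior_equals_naive(sigma_grid):
    spec = SimulationSpec(seed=2, model="free", n_individuals=50)
    obs, _ = simulate_locus(spec)
    fit = fit_ploidy_free(obs, 4, sigma_grid, "exact")
    np.testing.assert_allclose(
        fit.model_posteriors[obs.observed], fit.naive_posteriors[obs.observed]
    )
    assert np.isfinite(fit.log_evidence)


def test_single_individual_fits_are_finite(make_obs, sigma_grid):
    """One observed individual at ratio 0.5 fits at every ploidy and model."""
    obs = make_obs([(20, 20)])
    for m in (2, 4):
        for fit_fn in (fit_hwe, fit_ploidy_free):
            for mode in ("greedy", "exact"):
                fit = fit_fn(obs, m, sigma_grid, mode)
                assert np.isfinite(fit.log_evidence)
    for mode in ("greedy", "exact"):
        fit = fit_f1(obs, 4, sigma_grid, mode)
        assert np.isfinite(fit.log_evidence)


def test_exact_evidence_invariant_under_progeny_permutation(sigma_grid):
    spec = SimulationSpec(seed=13, model="f1", parent_dosages=(1, 2), n_individuals=40)
    obs, _ = simulate_locus(spec)
    fit = fit_f1(obs, 4, sigma_grid, "exact")
    rng = np.random.default_rng(0)
    perm = np.concatenate([rng.permutation(40), np.arange(40, obs.n_samples)])
    shuffled = type(obs)(
        locus_id=obs.locus_id,
        sample_ids=[obs.sample_ids[i] for i in perm],
        ref_counts=obs.ref_counts[perm],
        alt_counts=obs.alt_counts[perm],
        parent1_indices=obs.parent1_indices,
        parent2_indices=obs.parent2_indices,
    )
    fit_perm = fit_f1(shuffled, 4, sigma_grid, "exact")
    assert fit_perm.log_evidence == pytest.approx(fit.log_evidence, abs=1e-9)


def test_select_ploidy_single_and_ties(sigma_grid, make_obs):
    obs = make_obs([(20, 20)] * 5)
    fit4 = fit_ploidy_free(obs, 4, sigma_grid)
    sel = select_ploidy([fit4])
    assert sel.selected_ploidy == 4
    assert sel.ploidy_posterior[0] == pytest.approx(1.0)
    fit6 = fit_ploidy_free(obs, 6, sigma_grid)
    fit6.log_evidence = fit4.log_evidence  # forced tie
    sel = select_ploidy([fit6, fit4])
    assert sel.selected_ploidy == 4  # tie broken toward the lowest ploidy
    with pytest.raises(ValueError):
        select_ploidy([])


def test_select_ploidy_recovers_tetraploid_hwe(sigma_grid):
    """Five ratio clusters at p=0.5 defeat the 3-class diploid model."""
    spec = SimulationSpec(seed=17, model="hwe", allele_freq=0.5, n_individuals=200)
    obs, _ = simulate_locus(spec)
    sel = select_ploidy([fit_hwe(obs, m, sigma_grid, "exact") for m in (2, 4, 6)])
    assert sel.selected_ploidy == 4
    assert sel.ploidy_posterior.max() > 0.99


def test_call_genotypes_naive_threshold_masks(make_obs, sigma_grid):
    """An individual between classes has naive max ~0.5 and is masked at 0.9."""
    obs = make_obs([(20, 20), (35, 5)])  # ratio .5 and .125 (between 0 and .25)
    fit = fit_ploidy_free(obs, 4, sigma_grid)
    sel = select_ploidy([fit])
    strict = call_genotypes(fit, sel, 0.9)
    lax = call_genotypes(fit, sel, 0.0)
    assert strict.dosages[1] == MISSING
    assert (lax.dosages != MISSING).all()
    assert lax.dosages[0] == 2


def test_call_genotypes_zero_depth_missing(make_obs, sigma_grid):
    obs = make_obs([(20, 20), (0, 0)])
    fit = fit_ploidy_free(obs, 4, sigma_grid)
    calls = call_genotypes(fit, select_ploidy([fit]), 0.0)
    assert calls.dosages[1] == MISSING
    assert np.isnan(calls.naive_max[1])


def test_fit_locus_dispatch(make_obs, sigma_grid):
    obs = make_obs([(20, 20)] * 4)
    assert fit_locus(obs, 4, sigma_grid, "hw").inference_type == "hw"
    with pytest.raises(ValueError):
        fit_locus(obs, 4, sigma_grid, "bogus")
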