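"""Per-locus Bayesian allele-dosage inference from read depths.

The observation for individual ``i`` is its allele ratio
``r_i = alt_i / (ref_i + alt_i)``.  Conditional on dosage ``d`` at ploidy
``m`` the ratio is modelled as Gaussian with mean ``d/m`` and a shared
standard deviation ``sigma`` scanned over a user grid; the best ``sigma`` per
(locus, ploidy) is the one maximising the model evidence (empirical Bayes).
Individuals with zero total depth are missing and contribute nothing to any
likelihood product.

Three genetic models supply the mixture weights over dosage classes
(see :mod:`polydose.genetic_models`):

``f1``
    latent configuration = the ordered parental dosage pair ``(g1, g2)``;
    parent replicate samples contribute ``L(g)`` factors directly, progeny
    contribute the mixture ``sum_d pi(d | g1, g2) L_i(d)``.
``hw``
    latent configuration = the alternative-allele frequency ``p`` on the
    fixed grid ``{0, 0.01, ..., 1}``.
``ploidy``
    assumption-free: uniform weights, no latent configuration.

Two inference modes are provided.  *Exact* MAP inference scores every latent
configuration and averages them (uniform prior) for the evidence; posteriors
condition on the MAP configuration.  *Greedy* ML first assigns each
individual its maximum-likelihood class, picks the configuration maximising
the resulting single-configuration score, and evaluates evidence and
posteriors there.  Ties everywhere break toward the smaller index/value.

MAP ploidy selection compares best-``sigma`` evidences across the tested
ploidies under a uniform ploidy prior.  All products are accumulated in log
space with log-sum-exp for mixtures, so no fit returns ``-inf``/NaN evidence
for a locus with at least one observed individual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .genetic_models import (
    CrossSpec,
    f1_offspring_distribution,
    hwe_genotype_distribution,
    validate_ploidy,
)

__all__ = [
    "LocusObservations",
    "NoiseScale",
    "ModelFit",
    "PloidySelection",
    "DosageCallSet",
    "LocusUnusableError",
    "compute_class_likelihoods",
    "class_log_likelihoods",
    "naive_posteriors",
    "fit_f1",
    "fit_hwe",
    "fit_ploidy_free",
    "fit_locus",
    "select_ploidy",
    "call_genotypes",
    "MISSING",
    "HWE_P_GRID",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: Sentinel dosage for a missing call.
MISSING = -1

#: Fixed latent allele-frequency grid for the Hardy-Weinberg model.
HWE_P_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)

InferenceMode = Literal["greedy", "exact"]


class LocusUnusableError(Exception):
    """The locus has no usable individual (e.g. all progeny unobserved)."""


@dataclass
class LocusObservations:
    """Reference/alternative read counts for the samples at one variant.

    ``sample_ids`` are ordered progeny first, then parent-1 replicates, then
    parent-2 replicates; ``parent1_indices``/``parent2_indices`` index into
    that order and must be disjoint from each other and from the progeny.
    """

    locus_id: str
    sample_ids: Sequence[str]
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    parent1_indices: Sequence[int] = ()
    parent2_indices: Sequence[int] = ()

    def __post_init__(self) -> None:
        ref = np.asarray(self.ref_counts, dtype=np.int64)
        alt = np.asarray(self.alt_counts, dtype=np.int64)
        n = len(self.sample_ids)
        if ref.shape != (n,) or alt.shape != (n,):
            raise ValueError(
                f"{self.locus_id}: need one ref and one alt count per sample "
                f"({n}), got shapes {ref.shape} and {alt.shape}"
            )
        if (ref < 0).any() or (alt < 0).any():
            raise ValueError(f"{self.locus_id}: negative read counts")
        p1 = tuple(int(i) for i in self.parent1_indices)
        p2 = tuple(int(i) for i in self.parent2_indices)
        if set(p1) & set(p2):
            raise ValueError(f"{self.locus_id}: parent index sets overlap")
        for i in (*p1, *p2):
            if not 0 <= i < n:
                raise ValueError(f"{self.locus_id}: parent index {i} out of range")
        self.ref_counts = ref
        self.alt_counts = alt
        self.parent1_indices = p1
        self.parent2_indices = p2

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    @property
    def observed(self) -> np.ndarray:
        """True where an individual has at least one read."""
        return self.total_depth > 0

    @property
    def ratios(self) -> np.ndarray:
        """Alt-allele ratio per sample; NaN where unobserved."""
        tot = self.total_depth
        return np.where(tot > 0, self.alt_counts / np.maximum(tot, 1), np.nan)

    @property
    def progeny_indices(self) -> np.ndarray:
        parents = set(self.parent1_indices) | set(self.parent2_indices)
        return np.array(
            [i for i in range(self.n_samples) if i not in parents], dtype=np.int64
        )

    @property
    def progeny_mask(self) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        for i in (*self.parent1_indices, *self.parent2_indices):
            mask[i] = False
        return mask


@dataclass(frozen=True)
class NoiseScale:
    """Strictly increasing grid of positive allele-ratio standard deviations."""

    sigma_grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.sigma_grid, dtype=float)
        object.__setattr__(self, "sigma_grid", grid)
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError("sigma grid must be a non-empty 1-D vector")
        if (grid <= 0).any():
            raise ValueError("sigma values must be positive")
        if grid.size > 1 and (np.diff(grid) <= 0).any():
            raise ValueError("sigma grid must be strictly increasing")


@dataclass
class ModelFit:
    """Result of fitting one genetic model to one locus at one ploidy."""

    obs: LocusObservations
    ploidy: int
    inference_type: Literal["f1", "hw", "ploidy"]
    inference_mode: InferenceMode
    best_sigma: float
    log_evidence: float
    #: ``(g1, g2)`` for f1, allele frequency for hw, ``None`` for ploidy-free.
    map_config: Union[tuple[int, int], float, None]
    #: (n, m+1) per-individual posteriors under the genetic model; NaN rows
    #: mark missing individuals.
    model_posteriors: np.ndarray
    #: (n, m+1) posteriors under a uniform class prior (naive reporting).
    naive_posteriors: np.ndarray

    @property
    def observed(self) -> np.ndarray:
        return self.obs.observed


@dataclass
class PloidySelection:
    """MAP posterior over the tested ploidies for one locus."""

    tested_ploidies: list[int]
    ploidy_posterior: np.ndarray
    selected_ploidy: int
    selected_fit: ModelFit


@dataclass
class DosageCallSet:
    """Final per-sample dosage calls for one locus, plus VCF metadata."""

    locus_id: str
    ploidy: int
    sample_ids: Sequence[str]
    dosages: np.ndarray  # int; MISSING (-1) where no call
    naive_max: np.ndarray  # max naive posterior per sample; NaN where missing
    ploidy_posterior: float  # posterior probability of the selected ploidy
    best_sigma: float
    progeny_mask: np.ndarray
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    @property
    def called(self) -> np.ndarray:
        return self.dosages != MISSING

    @property
    def call_rate(self) -> float:
        """Fraction of progeny with a non-missing call."""
        prog = self.progeny_mask
        if not prog.any():
            return 0.0
        return float(self.called[prog].mean())


def class_log_likelihoods(obs: LocusObservations, ploidy: int, sigma: float) -> np.ndarray:
    """(n, m+1) Gaussian log-densities of each sample's allele ratio under
    class means ``d/m``.

    Rows of unobserved (zero-depth) individuals are identically zero, i.e. a
    likelihood factor of one: summing such a row into any log-product, or
    mixing it against a normalised prior, contributes nothing.
    """
    m = validate_ploidy(ploidy)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    means = np.arange(m + 1) / m
    r = obs.ratios
    with np.errstate(invalid="ignore"):
        z = (r[:, None] - means[None, :]) / sigma
        ll = -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI
    ll[~obs.observed] = 0.0
    return ll


def compute_class_likelihoods(
    obs: LocusObservations, ploidy: int, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual class likelihood densities and the observed mask.

    Returns ``(densities, observed)`` where ``densities`` is (n, m+1) with
    NaN rows for individuals flagged missing (zero total depth).
    """
    ll = class_log_likelihoods(obs, ploidy, sigma)
    dens = np.exp(ll)
    dens[~obs.observed] = np.nan
    return dens, obs.observed


def naive_posteriors(log_likelihoods: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Normalise per-individual likelihoods under a uniform class prior.

    Missing individuals get NaN rows.  An all-zero likelihood row for an
    observed individual is numerically impossible under a Gaussian density
    and raises defensively.
    """
    post = np.full_like(log_likelihoods, np.nan, dtype=float)
    if observed.any():
        lo = log_likelihoods[observed]
        norm = logsumexp(lo, axis=1, keepdims=True)
        if not np.isfinite(norm).all():
            raise FloatingPointError("all-zero likelihood row for an observed individual")
        post[observed] = np.exp(lo - norm)
    return post


def _normalized_posteriors(
    log_weights: np.ndarray, log_likelihoods: np.ndarray, observed: np.ndarray
) -> np.ndarray:
    """Posterior ∝ prior-weight × likelihood per observed individual."""
    w = log_weights[None, :] + log_likelihoods
    post = np.full_like(log_likelihoods, np.nan, dtype=float)
    if observed.any():
        lo = w[observed]
        post[observed] = np.exp(lo - logsumexp(lo, axis=1, keepdims=True))
    return post


def _log_f1_prior_table(ploidy: int) -> np.ndarray:
    """(m+1, m+1, m+1) table of ``log pi(d | g1, g2)``."""
    m = ploidy
    table = np.empty((m + 1, m + 1, m + 1))
    with np.errstate(divide="ignore"):
        for g1 in range(m + 1):
            for g2 in range(m + 1):
                table[g1, g2] = np.log(
                    f1_offspring_distribution(CrossSpec(g1, g2, m)).probs
                )
    return table


def fit_f1(
    obs: LocusObservations,
    ploidy: int,
    sigmas: NoiseScale,
    mode: InferenceMode = "exact",
) -> ModelFit:
    """Fit the F1 full-sib model at one ploidy.

    Exact mode scores every ordered parental pair ``(g1, g2)``:
    ``S = [prod parent-1 reps L(g1)] [prod parent-2 reps L(g2)]
    prod_progeny sum_d pi(d|g1,g2) L_i(d)``; the evidence is the mean of
    ``S`` over the ``(m+1)^2`` pairs at the best sigma, and posteriors
    condition on the argmax pair.  Greedy mode assigns each progeny its ML
    class, picks the pair maximising replicate likelihoods times
    ``prod_i pi(dhat_i | g1, g2)``, and evaluates evidence/posteriors at that
    single pair.  With no parent replicates the parental pair is simply
    marginalised/maximised over progeny information alone.
    """
    m = validate_ploidy(ploidy)
    if mode not in ("greedy", "exact"):
        raise ValueError(f"unknown inference mode {mode!r}")
    prog = obs.progeny_indices
    if prog.size == 0 or not obs.observed[prog].any():
        raise LocusUnusableError(f"{obs.locus_id}: no observed progeny")
    G = m + 1
    logpi = _log_f1_prior_table(m)
    p1 = np.asarray(obs.parent1_indices, dtype=np.int64)
    p2 = np.asarray(obs.parent2_indices, dtype=np.int64)

    best: Optional[tuple[float, float, tuple[int, int], np.ndarray]] = None
    for sigma in sigmas.sigma_grid:
        ll = class_log_likelihoods(obs, m, sigma)
        par1_term = ll[p1].sum(axis=0) if p1.size else np.zeros(G)
        par2_term = ll[p2].sum(axis=0) if p2.size else np.zeros(G)
        pll = ll[prog]  # unobserved rows are 0 => mixture term log(1)=0
        if mode == "exact":
            mix = logsumexp(
                logpi[:, :, None, :] + pll[None, None, :, :], axis=-1
            ).sum(axis=-1)
            score = par1_term[:, None] + par2_term[None, :] + mix
            evidence = float(logsumexp(score) - 2.0 * np.log(G))
            g1, g2 = np.unravel_index(int(np.argmax(score)), score.shape)
        else:
            obs_prog = obs.observed[prog]
            dhat = np.argmax(pll[obs_prog], axis=1)
            counts = np.bincount(dhat, minlength=G).astype(float)
            with np.errstate(invalid="ignore"):
                contrib = logpi * counts  # -inf * 0 -> nan, masked next
            contrib = np.where(counts > 0, contrib, 0.0)
            score = par1_term[:, None] + par2_term[None, :] + contrib.sum(axis=-1)
            g1, g2 = np.unravel_index(int(np.argmax(score)), score.shape)
            mix_at_pair = logsumexp(logpi[g1, g2][None, :] + pll, axis=-1).sum()
            evidence = float(par1_term[g1] + par2_term[g2] + mix_at_pair)
        if best is None or evidence > best[1]:
            best = (float(sigma), evidence, (int(g1), int(g2)), ll)

    assert best is not None
    sigma_hat, log_evidence, (g1, g2), ll = best
    model_post = _normalized_posteriors(logpi[g1, g2], ll, obs.observed)
    # Conditional on the MAP configuration, parental genotypes are fixed.
    for idx, g in ((p1, g1), (p2, g2)):
        for i in idx:
            if obs.observed[i]:
                row = np.zeros(G)
                row[g] = 1.0
                model_post[i] = row
    return ModelFit(
        obs=obs,
        ploidy=m,
        inference_type="f1",
        inference_mode=mode,
        best_sigma=sigma_hat,
        log_evidence=log_evidence,
        map_config=(g1, g2),
        model_posteriors=model_post,
        naive_posteriors=naive_posteriors(ll, obs.observed),
    )


def fit_hwe(
    obs: LocusObservations,
    ploidy: int,
    sigmas: NoiseScale,
    mode: InferenceMode = "exact",
) -> ModelFit:
    """Fit the Hardy-Weinberg model at one ploidy.

    The latent allele frequency is handled on the fixed 101-point grid
    ``{0, 0.01, ..., 1}``.  Exact mode: ``S(p) = prod_i sum_d Binom(d; m, p)
    L_i(d)``, evidence = mean over the grid, ``p_hat`` = argmax, posteriors
    at ``p_hat``.  Greedy mode: per-individual ML classes give ``p_hat =
    sum dhat_i / (m n)`` snapped to the nearest grid point, then evidence and
    posteriors are evaluated at that single ``p``.
    """
    m = validate_ploidy(ploidy)
    if mode not in ("greedy", "exact"):
        raise ValueError(f"unknown inference mode {mode!r}")
    if not obs.observed.any():
        raise LocusUnusableError(f"{obs.locus_id}: no observed individuals")
    with np.errstate(divide="ignore"):
        logB = np.stack(
            [np.log(hwe_genotype_distribution(p, m).probs) for p in HWE_P_GRID]
        )  # (101, m+1)

    best: Optional[tuple[float, float, int, np.ndarray]] = None
    for sigma in sigmas.sigma_grid:
        ll = class_log_likelihoods(obs, m, sigma)
        # (n, 101): per-individual mixture against each candidate p.
        per_p = logsumexp(ll[:, None, :] + logB[None, :, :], axis=-1)
        scores = per_p.sum(axis=0)  # (101,), missing rows contribute 0
        if mode == "exact":
            evidence = float(logsumexp(scores) - np.log(len(HWE_P_GRID)))
            p_idx = int(np.argmax(scores))
        else:
            observed = obs.observed
            dhat = np.argmax(ll[observed], axis=1)
            p_hat = dhat.sum() / (m * int(observed.sum()))
            p_idx = int(round(p_hat * 100))
            evidence = float(scores[p_idx])
        if best is None or evidence > best[1]:
            best = (float(sigma), evidence, p_idx, ll)

    assert best is not None
    sigma_hat, log_evidence, p_idx, ll = best
    return ModelFit(
        obs=obs,
        ploidy=m,
        inference_type="hw",
        inference_mode=mode,
        best_sigma=sigma_hat,
        log_evidence=log_evidence,
        map_config=float(HWE_P_GRID[p_idx]),
        model_posteriors=_normalized_posteriors(logB[p_idx], ll, obs.observed),
        naive_posteriors=naive_posteriors(ll, obs.observed),
    )


def fit_ploidy_free(
    obs: LocusObservations,
    ploidy: int,
    sigmas: NoiseScale,
    mode: InferenceMode = "exact",
) -> ModelFit:
    """Fit the assumption-free model: uniform mixture weights, no latent
    configuration; model posteriors equal the naive posteriors."""
    m = validate_ploidy(ploidy)
    if mode not in ("greedy", "exact"):
        raise ValueError(f"unknown inference mode {mode!r}")
    if not obs.observed.any():
        raise LocusUnusableError(f"{obs.locus_id}: no observed individuals")
    best: Optional[tuple[float, float, np.ndarray]] = None
    for sigma in sigmas.sigma_grid:
        ll = class_log_likelihoods(obs, m, sigma)
        contrib = logsumexp(ll[obs.observed], axis=1) - np.log(m + 1)
        evidence = float(contrib.sum())
        if best is None or evidence > best[1]:
            best = (float(sigma), evidence, ll)
    assert best is not None
    sigma_hat, log_evidence, ll = best
    naive = naive_posteriors(ll, obs.observed)
    return ModelFit(
        obs=obs,
        ploidy=m,
        inference_type="ploidy",
        inference_mode=mode,
        best_sigma=sigma_hat,
        log_evidence=log_evidence,
        map_config=None,
        model_posteriors=naive.copy(),
        naive_posteriors=naive,
    )


_FIT_FUNCTIONS = {"f1": fit_f1, "hw": fit_hwe, "ploidy": fit_ploidy_free}


def fit_locus(
    obs: LocusObservations,
    ploidy: int,
    sigmas: NoiseScale,
    inference: Literal["f1", "hw", "ploidy"],
    mode: InferenceMode = "greedy",
) -> ModelFit:
    """Dispatch to the fit function for the requested inference type."""
    try:
        fn = _FIT_FUNCTIONS[inference]
    except KeyError:
        raise ValueError(f"unknown inference type {inference!r}") from None
    return fn(obs, ploidy, sigmas, mode)


def select_ploidy(fits: Sequence[ModelFit]) -> PloidySelection:
    """MAP ploidy over the tested levels, uniform ploidy prior.

    The posterior is the softmax of the fits' log evidences; ties break
    toward the lowest ploidy.
    """
    if not fits:
        raise ValueError("select_ploidy needs at least one fit")
    fits = sorted(fits, key=lambda f: f.ploidy)
    log_ev = np.array([f.log_evidence for f in fits])
    posterior = np.exp(log_ev - logsumexp(log_ev))
    idx = int(np.argmax(posterior))  # first occurrence => lowest ploidy on ties
    return PloidySelection(
        tested_ploidies=[f.ploidy for f in fits],
        ploidy_posterior=posterior,
        selected_ploidy=fits[idx].ploidy,
        selected_fit=fits[idx],
    )


def call_genotypes(
    fit: ModelFit, selection: PloidySelection, naive_threshold: float = 0.0
) -> DosageCallSet:
    """Assign each individual the MAP dosage under the genetic model.

    Individuals whose *naive* posterior maximum falls below
    ``naive_threshold`` are set to missing, as are zero-depth individuals.
    With threshold 0 every observed individual keeps its call.
    """
    if not 0.0 <= naive_threshold <= 1.0:
        raise ValueError(f"naive threshold {naive_threshold!r} outside [0, 1]")
    if fit.ploidy != selection.selected_ploidy:
        raise ValueError(
            f"fit ploidy {fit.ploidy} != selected ploidy {selection.selected_ploidy}"
        )
    obs = fit.obs
    n = obs.n_samples
    observed = obs.observed
    dosages = np.full(n, MISSING, dtype=np.int64)
    naive_max = np.full(n, np.nan)
    if observed.any():
        dosages[observed] = np.argmax(fit.model_posteriors[observed], axis=1)
        naive_max[observed] = fit.naive_posteriors[observed].max(axis=1)
        low = observed & (naive_max < naive_threshold)
        dosages[low] = MISSING
    return DosageCallSet(
        locus_id=obs.locus_id,
        ploidy=fit.ploidy,
        sample_ids=list(obs.sample_ids),
        dosages=dosages,
        naive_max=naive_max,
        ploidy_posterior=float(selection.ploidy_posterior.max()),
        best_sigma=fit.best_sigma,
        progeny_mask=obs.progeny_mask,
        ref_counts=obs.ref_counts,
        alt_counts=obs.alt_counts,
    )
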