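# Methods

## The dosage-calling model

At a biallelic locus of even ploidy *m*, an individual carries *d* copies of
the alternative allele (*d* = 0..*m*). Given reference and alternative read
counts, the observation used for classification is the allele ratio
*r* = alt / (ref + alt), whose expected value is *d/m*. Conditional on
dosage, *r* is modelled as Gaussian with mean *d/m* and a standard deviation
σ shared by all classes of a locus:

    L_i(d) = N(r_i ; d/m, σ)

σ is not estimated continuously; it is scanned over a user grid (flag `-V`,
default `0.01:1:0.05`, i.e. 0.01, 0.06, ..., 0.96) and, per (locus, ploidy),
the grid value maximising the model evidence is kept (empirical Bayes). The
1-D ratio Gaussian is a deliberate design choice: the ratio is the quantity
that carries dosage information in count data, and a single scanned scalar
keeps the scan cheap and deterministic. Its main simplification is that the
ratio variance does not shrink with depth within a locus; the scanned σ
absorbs the locus-average depth instead. Individuals with zero total depth
are missing: they contribute a likelihood factor of one everywhere and can
never receive a call.

### Genetic priors

Three priors over dosage classes supply the mixture weights (flag `-I`):

* **f1** — full-sib family. The latent configuration is the ordered
  parental dosage pair (g1, g2). Each parent transmits *m*/2 chromosomes
  drawn without replacement (random bivalent pairing, no double reduction),
  so the gamete dosage is hypergeometric and the offspring prior
  π(d | g1, g2) is the convolution of the two gamete distributions. This
  reproduces the classical polysomic ratios (1:1, 3:1, 1:2:1, 1:1:1:1 ...).
  Parent replicate samples contribute factors L(g1) or L(g2) directly,
  pinning the pair; with no replicates the pair is inferred from the progeny
  mixture alone.
* **hw** — Hardy-Weinberg panel. The latent configuration is the
  alternative-allele frequency *p*, handled on the fixed grid
  {0, 0.01, ..., 1}; class weights are Binomial(*m*, *p*). The grid makes
  the estimate deterministic and testable; its 0.01 resolution is below the
  sampling noise of *p* at any realistic panel size.
* **ploidy** — assumption-free. Uniform weights 1/(m+1); the model
  posterior then equals the naive posterior by construction.

### Exact MAP versus greedy ML

*Exact* mode scores every latent configuration c:

    S(c) = [parent-replicate factors] × Π_i Σ_d π(d | c) L_i(d)

The evidence of a (locus, ploidy) is the mean of S over configurations
(uniform configuration prior) at the best σ; the MAP configuration is
argmax S, and per-individual posteriors condition on it:
P(d | i) ∝ π(d | ĉ) L_i(d). Conditioning on the MAP configuration rather
than mixing over all configurations is simpler, deterministic, and the two
coincide whenever the configuration posterior is concentrated — the regime
in which calls are worth keeping anyway. For the same reason parent
replicates receive a one-hot posterior at the MAP parental dosage.

*Greedy* mode first assigns each individual its maximum-likelihood class
(the class mean nearest to its ratio — independent of σ), then picks the
configuration maximising the single-configuration score (replicate factors ×
Π_i π(d̂_i | c)), and evaluates evidence and posteriors at that single
configuration. It is the default; on well-separated data it matches exact
mode essentially always (the acceptance suite measures the agreement), at a
fraction of the cost.

All products are accumulated in log space with log-sum-exp for mixtures, so
evidence is finite whenever one individual is observed, up to ploidy 16.
Every argmax tie (class, parental pair, *p* grid point, ploidy, σ) breaks
toward the smaller index/value, making runs bit-reproducible.

### Naive reporting probabilities

Alongside the model posterior, every individual gets a *naive* posterior:
likelihoods normalised under a uniform class prior, i.e. classification with
no genetic assumption. Calls whose naive maximum falls below `-n` are set to
missing; `-n 0` keeps every observed call. The naive probability is the
honest per-individual confidence — it cannot be rescued by a strong
population prior.

### MAP ploidy selection

Each ploidy in the tested range (`-M`, even values only) is fitted
separately; the ploidy posterior is the softmax of the best-σ log evidences
under a uniform ploidy prior, and the MAP ploidy wins (ties toward the
lowest level). Evidence uses the best σ rather than marginalising over the σ
grid: σ is a nuisance scale, and marginalising it would make the comparison
depend on the grid's extent. Comparing evidences across ploidies is
meaningful because all are densities of the same observed ratios.

## Filters

Per locus, in fixed order: biallelic check → mean depth (`-d`/`-D`; for F1
runs the parents are excluded from the mean, and zero-depth samples count in
the denominator) → model fits → ploidy posterior (`-p`) → ploidy level
(`-f`) → naive masking (`-n`) → progeny call rate (`-c`). Masking precedes
the call-rate computation, so a stringent `-n` directly lowers call rates.
Call rate is computed over progeny only; parent replicates are reported but
not counted, mirroring their exclusion from the depth filter. Every locus
receives exactly one outcome reason, written to a tab-separated log beside
the output VCF; reason counts always sum to the number of input loci.

## The simulator

The generator draws true dosages from one of the three priors, then per
individual: total depth ~ Poisson(λ), zeroed with probability *dropout*;
alternative reads ~ Binomial(total, clip(d/m·(1−ε) + (1−d/m)·ε)) with
symmetric per-read error ε. Defaults are the study conditions used
throughout the tests: tetraploid, 200 individuals, λ = 60 reads, dropout
0.02, ε = 0.001, and twelve replicates per parent for F1 designs. These
match a GBS experiment optimised for dosage calling in a tetraploid; the
binomial ratio noise at λ = 60 has standard deviation ≈ 0.065 at ratio 0.5,
comfortably inside the default σ grid.

What the simulator does *not* emulate: PCR duplicates and allele-specific
amplification bias (which skew ratios asymmetrically), restriction-site
dropout correlated across individuals, mapping error, and multi-locus
artefacts such as paralog collapse (which produce the over-dispersed,
off-grid ratio clouds real GBS data show). Passing tests therefore
demonstrate correctness of the inference machinery under its own noise
model, not robustness to every artefact of a real library; the quality
filters (`-p`, `-n`, `-d`/`-D`) are the tooling the caller offers against
those artefacts.

## Problem sizes in the test and acceptance suites

Parameter-recovery checks use all 15 unordered tetraploid parental pairs ×
10 seeded replicates at n = 200 and depth 60; ploidy recovery uses 50 seeded
loci searched over ploidies {2, 4, 6}; determinism uses a 1,000-locus,
40-individual fixture run at 1 and 8 threads; greedy-vs-exact agreement uses
20 seeded replicates at depth 100. These sizes give stable rates (binomial
standard errors of a few percent or less) while keeping a full run on one
CPU in the low minutes.

## Known limitations

* No double reduction or preferential pairing: segregation is strictly
  polysomic with random bivalents. Loci with appreciable double reduction
  will show extra classes the F1 prior assigns zero weight.
* Only even ploidies; odd levels are rejected rather than approximated.
* The shared-σ ratio model ignores per-individual depth differences within a
  locus; very uneven depths flatten the naive posteriors of shallow
  individuals rather than miscalling them.
* Multi-allelic records are skipped, not split; splitting belongs upstream.
* The HWE grid bounds the frequency estimate's resolution at 0.01.
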