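"""Prior distributions over allele-dosage classes in autopolyploids.

At a biallelic locus of even ploidy ``m`` an individual carries ``d`` copies
of the alternative allele, ``d = 0..m`` (nulliplex through ``m``-plex).  Three
closed-form priors over the dosage classes are used during genotype calling:

* **F1** -- offspring of a biparental cross.  Each parent of dosage ``d``
  transmits ``m/2`` chromosomes drawn without replacement from its ``d``
  alternative and ``m - d`` reference copies (random bivalent pairing, no
  double reduction), so the gamete dosage ``k`` is hypergeometric::

      P(k) = C(d, k) * C(m - d, m/2 - k) / C(m, m/2)

  The offspring distribution is the convolution of the two parental gamete
  distributions.  This reproduces the classical polysomic segregation ratios
  (1:1 for nulliplex x simplex, 1:2:1 for simplex x simplex, ...).
* **Hardy-Weinberg** -- panmictic population with alternative-allele
  frequency ``p``: dosage is ``Binomial(m, p)``.
* **Assumption-free** -- uniform over the ``m + 1`` classes; used when no
  population structure can be assumed and for naive per-individual reporting.

All probabilities are computed in exact rational arithmetic (hypergeometric
and convolution) or directly from binomial coefficients, so they remain exact
up to float conversion even at ploidy 16.  Only even ploidies are supported;
odd ploidy raises :class:`InvalidPloidyError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np

__all__ = [
    "InvalidPloidyError",
    "DosageDistribution",
    "CrossSpec",
    "gamete_distribution",
    "f1_offspring_distribution",
    "hwe_genotype_distribution",
    "uniform_genotype_distribution",
    "validate_ploidy",
]


class InvalidPloidyError(ValueError):
    """Raised for odd, fractional or non-positive ploidy levels."""


def validate_ploidy(ploidy: int) -> int:
    """Return ``ploidy`` as an int, rejecting anything but even integers >= 2."""
    if int(ploidy) != ploidy or ploidy < 2 or ploidy % 2:
        raise InvalidPloidyError(f"ploidy must be an even integer >= 2, got {ploidy!r}")
    return int(ploidy)


@dataclass(frozen=True)
class DosageDistribution:
    """Probability vector over dosage classes ``0..m`` for ploidy ``m``.

    Invariants (checked at construction): length ``m + 1``, entries in
    ``[0, 1]``, sum within ``1e-12`` of one.
    """

    ploidy: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        m = validate_ploidy(self.ploidy)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (m + 1,):
            raise ValueError(
                f"dosage distribution for ploidy {m} needs {m + 1} entries, "
                f"got shape {probs.shape}"
            )
        if np.any(probs < -1e-15) or np.any(probs > 1 + 1e-15):
            raise ValueError("dosage probabilities must lie in [0, 1]")
        if abs(float(probs.sum()) - 1.0) > 1e-12:
            raise ValueError(f"dosage probabilities sum to {probs.sum()!r}, not 1")

    @property
    def mean_dosage(self) -> float:
        return float(np.arange(self.ploidy + 1) @ self.probs)


@dataclass(frozen=True)
class CrossSpec:
    """A biparental cross: two parental dosages at a locus of ploidy ``m``."""

    parent1_dosage: int
    parent2_dosage: int
    ploidy: int

    def __post_init__(self) -> None:
        m = validate_ploidy(self.ploidy)
        for d in (self.parent1_dosage, self.parent2_dosage):
            if int(d) != d or not 0 <= d <= m:
                raise ValueError(f"parent dosage {d!r} outside 0..{m}")


def _comb0(n: int, k: int) -> int:
    return comb(n, k) if 0 <= k <= n else 0


def _gamete_fractions(parent_dosage: int, ploidy: int) -> list[Fraction]:
    m = validate_ploidy(ploidy)
    d = parent_dosage
    if int(d) != d or not 0 <= d <= m:
        raise ValueError(f"parent dosage {d!r} outside 0..{m}")
    half = m // 2
    denom = comb(m, half)
    return [Fraction(_comb0(d, k) * _comb0(m - d, half - k), denom) for k in range(half + 1)]


def gamete_distribution(parent_dosage: int, ploidy: int) -> np.ndarray:
    """Gamete dosage distribution of a parent under random bivalent pairing.

    A parent of dosage ``d`` at ploidy ``m`` transmits ``m/2`` chromosomes
    sampled without replacement; the returned vector over ``k = 0..m/2`` is
    the hypergeometric pmf ``C(d,k) C(m-d, m/2-k) / C(m, m/2)``.
    """
    return np.array([float(f) for f in _gamete_fractions(parent_dosage, ploidy)])


def f1_offspring_distribution(cross: CrossSpec) -> DosageDistribution:
    """Offspring dosage prior for a biparental cross: the convolution of the
    two parental gamete distributions."""
    g1 = _gamete_fractions(cross.parent1_dosage, cross.ploidy)
    g2 = _gamete_fractions(cross.parent2_dosage, cross.ploidy)
    m = cross.ploidy
    out = [Fraction(0)] * (m + 1)
    for i, a in enumerate(g1):
        for j, b in enumerate(g2):
            out[i + j] += a * b
    return DosageDistribution(m, np.array([float(f) for f in out]))


def hwe_genotype_distribution(alt_allele_freq: float, ploidy: int) -> DosageDistribution:
    """Hardy-Weinberg dosage prior: ``Binomial(m, p)`` class frequencies."""
    m = validate_ploidy(ploidy)
    p = float(alt_allele_freq)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p!r} outside [0, 1]")
    probs = np.array([comb(m, d) * p**d * (1.0 - p) ** (m - d) for d in range(m + 1)])
    return DosageDistribution(m, probs)


def uniform_genotype_distribution(ploidy: int) -> DosageDistribution:
    """Assumption-free prior: every dosage class equally likely."""
    m = validate_ploidy(ploidy)
    return DosageDistribution(m, np.full(m + 1, 1.0 / (m + 1)))
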