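"""Seeded simulator of GBS-style allele read counts for dosage calling.

Each locus draws true dosages from one of the genetic priors (F1 cross,
Hardy-Weinberg, or free class weights), then per-individual read counts:
total depth is Poisson with mean ``mean_depth``, zeroed with probability
``dropout`` (a missing individual), and the alternative-read count is
binomial around the expected allele ratio ``d/m`` contaminated by a
symmetric per-read sequencing error ``error_rate``::

    alt ~ Binomial(total, clip(d/m * (1 - eps) + (1 - d/m) * eps, 0, 1))

For F1 populations, parent replicate samples (named ``P1_rep01`` ...) carry
the true parental dosages.  The simulator writes VCFs in any of the three
depth dialects plus a tab-separated truth table of locus x individual
dosages; the seed is mandatory and fully determines the output.

Defaults emulate a tetraploid GBS experiment optimised for dosage calling:
200 individuals, mean depth 60 reads, 2% dropout, per-read error 1e-3, and
twelve replicates per parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genetic_models import (
    DosageDistribution,
    f1_offspring_distribution,
    CrossSpec,
    hwe_genotype_distribution,
    uniform_genotype_distribution,
    validate_ploidy,
)
from .inference import LocusObservations

__all__ = ["SimulationSpec", "simulate_locus", "simulate_dataset", "write_simulated_vcf"]

_MODELS = ("f1", "hwe", "free")


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated dataset."""

    seed: int
    model: str = "hwe"  # f1 | hwe | free
    ploidy: int = 4
    parent_dosages: tuple[int, int] = (1, 1)  # f1 only
    allele_freq: float = 0.3  # hwe only
    class_weights: Optional[tuple[float, ...]] = None  # free only; None = uniform
    n_individuals: int = 200
    n_loci: int = 100
    mean_depth: float = 60.0  # Poisson mean, reads
    dropout: float = 0.02  # probability an individual yields zero reads
    error_rate: float = 0.001  # per-read symmetric sequencing error
    n_parent_replicates: int = 12  # per parent, f1 only

    def __post_init__(self) -> None:
        validate_ploidy(self.ploidy)
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for name in ("dropout", "error_rate", "allele_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.n_individuals < 1 or self.n_loci < 1:
            raise ValueError("need at least one individual and one locus")
        if self.model == "f1" and self.n_parent_replicates < 0:
            raise ValueError("n_parent_replicates must be non-negative")

    @property
    def dosage_prior(self) -> DosageDistribution:
        if self.model == "f1":
            g1, g2 = self.parent_dosages
            return f1_offspring_distribution(CrossSpec(g1, g2, self.ploidy))
        if self.model == "hwe":
            return hwe_genotype_distribution(self.allele_freq, self.ploidy)
        if self.class_weights is None:
            return uniform_genotype_distribution(self.ploidy)
        w = np.asarray(self.class_weights, dtype=float)
        return DosageDistribution(self.ploidy, w / w.sum())

    @property
    def sample_names(self) -> list[str]:
        names = [f"Ind{i + 1:04d}" for i in range(self.n_individuals)]
        if self.model == "f1":
            names += [f"P1_rep{i + 1:02d}" for i in range(self.n_parent_replicates)]
            names += [f"P2_rep{i + 1:02d}" for i in range(self.n_parent_replicates)]
        return names


def simulate_locus(
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
    locus_id: str = "loc00001",
) -> tuple[LocusObservations, np.ndarray]:
    """Simulate one locus; returns observations plus the true dosage vector
    (progeny first, then parent replicates)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    m = spec.ploidy
    dosages = rng.choice(m + 1, size=spec.n_individuals, p=spec.dosage_prior.probs)
    p1_idx: tuple[int, ...] = ()
    p2_idx: tuple[int, ...] = ()
    if spec.model == "f1":
        g1, g2 = spec.parent_dosages
        reps = spec.n_parent_replicates
        dosages = np.concatenate(
            [dosages, np.full(reps, g1, dtype=np.int64), np.full(reps, g2, dtype=np.int64)]
        )
        p1_idx = tuple(range(spec.n_individuals, spec.n_individuals + reps))
        p2_idx = tuple(range(spec.n_individuals + reps, spec.n_individuals + 2 * reps))
    n = dosages.size
    total = rng.poisson(spec.mean_depth, size=n)
    total[rng.random(n) < spec.dropout] = 0
    eps = spec.error_rate
    q = np.clip(dosages / m * (1.0 - eps) + (1.0 - dosages / m) * eps, 0.0, 1.0)
    alt = rng.binomial(total, q)
    obs = LocusObservations(
        locus_id=locus_id,
        sample_ids=spec.sample_names,
        ref_counts=total - alt,
        alt_counts=alt,
        parent1_indices=p1_idx,
        parent2_indices=p2_idx,
    )
    return obs, dosages


def simulate_dataset(spec: SimulationSpec) -> list[tuple[LocusObservations, np.ndarray]]:
    """Simulate ``spec.n_loci`` loci from one seeded generator."""
    rng = np.random.default_rng(spec.seed)
    return [
        simulate_locus(spec, rng=rng, locus_id=f"loc{i + 1:05d}")
        for i in range(spec.n_loci)
    ]


_DIALECT_HEADERS = {
    "AD": (
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for '
        'the ref and alt alleles in the order listed">',
    ),
    "RA/AA": (
        '##FORMAT=<ID=RA,Number=1,Type=Integer,Description="Reference allele read depth">',
        '##FORMAT=<ID=AA,Number=1,Type=Integer,Description="Alternative allele read depth">',
    ),
    "RO/AO": (
        '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">',
        '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">',
    ),
}


def _depth_string(ref: int, alt: int, dialect: str) -> str:
    if dialect == "AD":
        return f"{ref},{alt}"
    return f"{ref}:{alt}"


def write_simulated_vcf(
    spec: SimulationSpec,
    out_path: str,
    dialect: str = "AD",
    truth_path: Optional[str] = None,
) -> tuple[str, str]:
    """Write a simulated VCF plus its truth table; returns both paths.

    The VCF carries depths in the chosen dialect (no GT field -- depths are
    the observation); the truth table is one row per locus with the true
    dosage of every sample.
    """
    if dialect not in _DIALECT_HEADERS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if truth_path is None:
        truth_path = str(out_path) + ".truth.tsv"
    names = spec.sample_names
    fmt = "AD" if dialect == "AD" else ":".join(dialect.split("/"))
    loci = simulate_dataset(spec)
    contig_len = 1000 * (spec.n_loci + 1)
    with open(out_path, "w") as vcf, open(truth_path, "w") as truth:
        vcf.write("##fileformat=VCFv4.2\n")
        vcf.write("##source=polydose-simulate\n")
        vcf.write(f"##contig=<ID=1,length={contig_len}>\n")
        for line in _DIALECT_HEADERS[dialect]:
            vcf.write(line + "\n")
        vcf.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        truth.write("locus_id\t" + "\t".join(names) + "\n")
        for i, (obs, dosages) in enumerate(loci):
            pos = 1000 * (i + 1)
            fields = [
                "1",
                str(pos),
                obs.locus_id,
                "A",
                "C",
                ".",
                ".",
                ".",
                fmt,
            ]
            fields.extend(
                _depth_string(int(r), int(a), dialect)
                for r, a in zip(obs.ref_counts, obs.alt_counts)
            )
            vcf.write("\t".join(fields) + "\n")
            truth.write(obs.locus_id + "\t" + "\t".join(str(int(d)) for d in dosages) + "\n")
    return str(out_path), str(truth_path)
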