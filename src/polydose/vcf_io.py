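"""VCF input/output for polyploid dosage calls.

Input VCFs (plain or gzip) are read with pysam.  Per-sample read depths are
extracted from one of three FORMAT dialects: ``AD`` (allelic depths for the
reference and alternative alleles in the order listed), ``RA``/``AA``
(reference/alternative allele depths) or ``RO``/``AO`` (reference/alternative
allele observation counts).  Only biallelic SNP/indel records are processed;
multi-allelic and ref-only records are skipped with a warning.

Output VCFs carry polyploid genotypes: dosage ``d`` at ploidy ``m`` becomes a
``GT`` of ``m - d`` zeros followed by ``d`` ones (``0/1/1/1`` for a triplex
tetraploid), and a missing call is written with ploidy-matching arity
(``./././.`` at ploidy 4) so the GT arity is uniform per record.  The input
depth fields are copied through and three INFO keys are added: ``PLD``
(selected ploidy), ``PLDP`` (its posterior) and ``SIG`` (best sigma).  The
writer emits each field explicitly so output is byte-deterministic.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import IO, Iterator, Optional, Sequence

import numpy as np
import pysam

from .inference import DosageCallSet, LocusObservations, MISSING

__all__ = [
    "ConfigError",
    "VcfDialectError",
    "DIALECTS",
    "SampleSelection",
    "expand_file_pattern",
    "extract_depths",
    "select_samples",
    "encode_genotype",
    "decode_genotype",
    "iter_locus_observations",
    "write_variants",
    "check_dialect",
    "contig_header_lines",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (patterns, ranges, sample selection)."""


class VcfDialectError(ValueError):
    """The requested depth fields are absent from the VCF."""


#: Depth dialect name -> required FORMAT field IDs (ref field first).
DIALECT_FIELDS = {"AD": ("AD",), "RA/AA": ("RA", "AA"), "RO/AO": ("RO", "AO")}
DIALECTS = tuple(DIALECT_FIELDS)


def expand_file_pattern(
    path_pattern: str, start: Optional[int] = None, end: Optional[int] = None
) -> list[str]:
    """Expand a ``+`` wildcard (usually the chromosome number) into paths.

    ``("chr+.vcf", 1, 3)`` yields ``chr1.vcf .. chr3.vcf``; a pattern without
    ``+`` is returned as a single literal path.
    """
    if "+" not in path_pattern:
        return [path_pattern]
    if start is None or end is None:
        raise ConfigError(
            f"pattern {path_pattern!r} contains '+' but --sF/--eF bounds are missing"
        )
    if start > end:
        raise ConfigError(f"--sF {start} exceeds --eF {end}")
    return [path_pattern.replace("+", str(i)) for i in range(start, end + 1)]


@dataclass(frozen=True)
class SampleSelection:
    """Progeny and parent-replicate selectors.

    Patterns are substring matchers against sample names; ranges are 1-based
    inclusive positions in VCF header order.  With no progeny selector, all
    samples not claimed by a parent selector are progeny.
    """

    progeny_pattern: Optional[str] = None
    progeny_range: Optional[tuple[int, int]] = None
    par1_pattern: Optional[str] = None
    par1_range: Optional[tuple[int, int]] = None
    par2_pattern: Optional[str] = None
    par2_range: Optional[tuple[int, int]] = None

    @property
    def has_parents(self) -> bool:
        return any(
            x is not None
            for x in (self.par1_pattern, self.par1_range, self.par2_pattern, self.par2_range)
        )


def _resolve_one(
    samples: Sequence[str],
    pattern: Optional[str],
    rng: Optional[tuple[int, int]],
    what: str,
) -> Optional[list[int]]:
    if pattern is not None and rng is not None:
        raise ConfigError(f"give either a pattern or a range for {what}, not both")
    if pattern is not None:
        return [i for i, s in enumerate(samples) if pattern in s]
    if rng is not None:
        lo, hi = rng
        if not (1 <= lo <= hi <= len(samples)):
            raise ConfigError(
                f"{what} range {lo}:{hi} outside 1..{len(samples)} (header order)"
            )
        return list(range(lo - 1, hi))
    return None


def select_samples(
    samples: Sequence[str], selection: SampleSelection
) -> tuple[list[int], list[int], list[int]]:
    """Resolve (progeny, parent-1, parent-2) index sets in header order.

    Overlapping explicit selections and an empty progeny set are
    configuration errors.
    """
    par1 = _resolve_one(samples, selection.par1_pattern, selection.par1_range, "parent 1") or []
    par2 = _resolve_one(samples, selection.par2_pattern, selection.par2_range, "parent 2") or []
    if set(par1) & set(par2):
        raise ConfigError("parent 1 and parent 2 selections overlap")
    progeny = _resolve_one(
        samples, selection.progeny_pattern, selection.progeny_range, "progeny"
    )
    parent_set = set(par1) | set(par2)
    if progeny is None:
        progeny = [i for i in range(len(samples)) if i not in parent_set]
    elif set(progeny) & parent_set:
        overlap = sorted(set(progeny) & parent_set)
        names = ", ".join(samples[i] for i in overlap[:5])
        raise ConfigError(f"progeny selection overlaps parent replicates ({names})")
    if not progeny:
        raise ConfigError("progeny selection matched no samples")
    return progeny, par1, par2


def _first(value) -> Optional[int]:
    if isinstance(value, tuple):
        value = value[0] if value else None
    return None if value is None else int(value)


def check_dialect(header: pysam.VariantHeader, dialect: str) -> None:
    """Raise :class:`VcfDialectError` if the dialect fields are undeclared."""
    if dialect not in DIALECT_FIELDS:
        raise ConfigError(f"unknown depth dialect {dialect!r}; choose from {DIALECTS}")
    for f in DIALECT_FIELDS[dialect]:
        if f not in header.formats:
            raise VcfDialectError(
                f"FORMAT field {f!r} (dialect {dialect}) absent from VCF header"
            )


def extract_depths(record: pysam.libcbcf.VariantRecord, dialect: str) -> np.ndarray:
    """(n_samples, 2) non-negative (ref, alt) read counts for one record.

    Absent or ``.`` values become ``(0, 0)``, i.e. missing.
    """
    if dialect not in DIALECT_FIELDS:
        raise ConfigError(f"unknown depth dialect {dialect!r}; choose from {DIALECTS}")
    for f in DIALECT_FIELDS[dialect]:
        if f not in record.header.formats:
            raise VcfDialectError(
                f"FORMAT field {f!r} (dialect {dialect}) absent from header "
                f"at {record.chrom}:{record.pos}"
            )
    n = len(record.samples)
    out = np.zeros((n, 2), dtype=np.int64)
    for i, sample in enumerate(record.samples.values()):
        if dialect == "AD":
            ad = sample.get("AD")
            if (
                not isinstance(ad, tuple)
                or len(ad) < 2
                or ad[0] is None
                or ad[1] is None
            ):
                continue
            out[i] = (int(ad[0]), int(ad[1]))
        elif dialect == "RA/AA":
            ref = _first(sample.get("RA"))
            alt = _first(sample.get("AA"))
            if ref is None or alt is None:
                continue
            out[i] = (ref, alt)
        else:  # RO/AO
            ref = _first(sample.get("RO"))
            alt = _first(sample.get("AO"))
            if ref is None or alt is None:
                continue
            out[i] = (ref, alt)
    if (out < 0).any():
        out = np.maximum(out, 0)
    return out


def encode_genotype(dosage: Optional[int], ploidy: int) -> str:
    """``/``-joined GT string: ``m - d`` zeros then ``d`` ones; missing
    (``None`` or the MISSING sentinel) becomes ``m`` dots."""
    if ploidy < 1:
        raise ValueError(f"ploidy must be positive, got {ploidy}")
    if dosage is None or dosage == MISSING:
        return "/".join(["."] * ploidy)
    if not 0 <= dosage <= ploidy:
        raise ValueError(f"dosage {dosage} outside 0..{ploidy}")
    return "/".join(["0"] * (ploidy - dosage) + ["1"] * dosage)


def decode_genotype(gt: str) -> Optional[int]:
    """Inverse of :func:`encode_genotype`: count alt-allele tokens."""
    tokens = gt.replace("|", "/").split("/")
    if all(t == "." for t in tokens):
        return None
    return sum(1 for t in tokens if t == "1")


def locus_id_of(record: pysam.libcbcf.VariantRecord) -> str:
    alt = record.alts[0] if record.alts else "."
    return f"{record.chrom}:{record.pos}:{record.ref}:{alt}"


def iter_locus_observations(
    vcf: pysam.VariantFile,
    dialect: str,
    progeny: Sequence[int],
    par1: Sequence[int] = (),
    par2: Sequence[int] = (),
) -> Iterator[tuple[pysam.libcbcf.VariantRecord, Optional[LocusObservations]]]:
    """Yield ``(record, observations)`` per record; ``None`` observations flag
    a skipped non-biallelic or ref-only record.

    Selected samples are reordered progeny-first, then parent-1 and parent-2
    replicates, matching :class:`LocusObservations` conventions.
    """
    samples = list(vcf.header.samples)
    order = [*progeny, *par1, *par2]
    names = [samples[i] for i in order]
    n_prog = len(progeny)
    p1_idx = tuple(range(n_prog, n_prog + len(par1)))
    p2_idx = tuple(range(n_prog + len(par1), n_prog + len(par1) + len(par2)))
    for record in vcf:
        if record.alts is None or len(record.alts) != 1 or record.alts[0] in (".", "*"):
            logger.warning(
                "skipping non-biallelic or ref-only record at %s:%s",
                record.chrom,
                record.pos,
            )
            yield record, None
            continue
        depths = extract_depths(record, dialect)[order]
        yield record, LocusObservations(
            locus_id=locus_id_of(record),
            sample_ids=names,
            ref_counts=depths[:, 0],
            alt_counts=depths[:, 1],
            parent1_indices=p1_idx,
            parent2_indices=p2_idx,
        )


_FORMAT_DEFS = {
    "GT": '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    "AD": (
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for '
        'the ref and alt alleles in the order listed">'
    ),
    "RA": '##FORMAT=<ID=RA,Number=1,Type=Integer,Description="Reference allele read depth">',
    "AA": '##FORMAT=<ID=AA,Number=1,Type=Integer,Description="Alternative allele read depth">',
    "RO": '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">',
    "AO": '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">',
}

_INFO_DEFS = (
    '##INFO=<ID=PLD,Number=1,Type=Integer,Description="Selected ploidy level (MAP over tested ploidies)">',
    '##INFO=<ID=PLDP,Number=1,Type=Float,Description="Posterior probability of the selected ploidy">',
    '##INFO=<ID=SIG,Number=1,Type=Float,Description="Best-fitting allele-ratio standard deviation">',
)


def contig_header_lines(header: pysam.VariantHeader) -> list[str]:
    """``##contig`` lines reproducing the input header's contigs."""
    lines = []
    for contig in header.contigs.values():
        if contig.length:
            lines.append(f"##contig=<ID={contig.name},length={contig.length}>")
        else:
            lines.append(f"##contig=<ID={contig.name}>")
    return lines


def _open_text(path: str, mode: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _sample_field(calls: DosageCallSet, j: int, dialect: str) -> str:
    gt = encode_genotype(int(calls.dosages[j]), calls.ploidy)
    r = int(calls.ref_counts[j])
    a = int(calls.alt_counts[j])
    if dialect == "AD":
        return f"{gt}:{r},{a}"
    return f"{gt}:{r}:{a}"


def write_variants(
    results: Sequence[tuple[pysam.libcbcf.VariantRecord, DosageCallSet]],
    out_path: str,
    sample_names: Sequence[str],
    dialect: str,
    contig_lines: Sequence[str] = (),
) -> None:
    """Write the output VCF for the surviving loci, preserving input order.

    ``results`` pairs each surviving input record with its call set; the
    original CHROM/POS/ID/REF/ALT are preserved, FORMAT is GT plus the
    dialect's depth fields, and INFO gains PLD/PLDP/SIG.
    """
    if dialect not in DIALECT_FIELDS:
        raise ConfigError(f"unknown depth dialect {dialect!r}; choose from {DIALECTS}")
    fmt = "GT:" + ":".join(DIALECT_FIELDS[dialect])
    seen = {line.split("ID=")[1].split(",")[0].rstrip(">") for line in contig_lines}
    extra_contigs = []
    for record, _ in results:
        if record.chrom not in seen:
            seen.add(record.chrom)
            extra_contigs.append(f"##contig=<ID={record.chrom}>")
    try:
        with _open_text(out_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=polydose\n")
            for line in (*contig_lines, *extra_contigs):
                fh.write(line + "\n")
            for line in _INFO_DEFS:
                fh.write(line + "\n")
            fh.write(_FORMAT_DEFS["GT"] + "\n")
            for f in DIALECT_FIELDS[dialect]:
                fh.write(_FORMAT_DEFS[f] + "\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(sample_names)
                + "\n"
            )
            for record, calls in results:
                if list(calls.sample_ids) != list(sample_names):
                    raise ValueError(
                        f"{calls.locus_id}: call set samples do not match output columns"
                    )
                info = (
                    f"PLD={calls.ploidy};PLDP={calls.ploidy_posterior:.4f};"
                    f"SIG={calls.best_sigma:g}"
                )
                fields = [
                    record.chrom,
                    str(record.pos),
                    record.id or ".",
                    record.ref,
                    record.alts[0],
                    ".",
                    ".",
                    info,
                    fmt,
                ]
                fields.extend(
                    _sample_field(calls, j, dialect) for j in range(len(sample_names))
                )
                fh.write("\t".join(fields) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing output VCF {out_path!r}: {exc}") from exc
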