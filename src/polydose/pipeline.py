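"""Per-file orchestration: parse, filter, fit, select ploidy, call, write.

The per-locus work (model fits across the tested ploidies and sigma grid,
MAP ploidy selection, genotype calling, quality filters) is distributed over
a thread pool, one locus per task, and results are gathered back in input
order -- output is a deterministic function of (input files, config) and the
thread count never changes an emitted byte.

Filter order per locus: biallelic check -> mean depth -> model fits ->
ploidy posterior -> ploidy level -> naive masking -> call rate.  A per-locus
model failure marks the locus unusable and never aborts the run.  A filter
summary (locus id, reason, selected ploidy, posterior) is written as a
tab-separated log next to each output file.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pysam

from .filters import (
    FilterConfig,
    FilterOutcome,
    FilterReason,
    call_rate_filter,
    mean_depth_filter,
    ploidy_level_filter,
    ploidy_posterior_filter,
)
from .inference import (
    DosageCallSet,
    LocusObservations,
    LocusUnusableError,
    NoiseScale,
    call_genotypes,
    fit_locus,
    select_ploidy,
)
from .vcf_io import (
    ConfigError,
    DIALECTS,
    SampleSelection,
    check_dialect,
    contig_header_lines,
    expand_file_pattern,
    iter_locus_observations,
    select_samples,
    write_variants,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "parse_sigma_range",
    "parse_ploidy_range",
    "parse_ploidy_filter",
    "parse_sample_range",
    "run_pipeline",
    "process_locus",
]

logger = logging.getLogger(__name__)

_LOG_EVERY = 10_000


def parse_sigma_range(spec: str) -> NoiseScale:
    """Parse ``lower:upper:step`` into the sigma grid ``lower, lower+step,
    ...`` not exceeding ``upper`` (e.g. ``0.01:1:0.05`` gives 20 values)."""
    parts = spec.split(":")
    if len(parts) != 3:
        raise ConfigError(f"sigma range {spec!r} must be lower:upper:step")
    try:
        lower, upper, step = (float(p) for p in parts)
    except ValueError as exc:
        raise ConfigError(f"malformed sigma range {spec!r}: {exc}") from None
    if lower <= 0 or step <= 0:
        raise ConfigError(f"sigma range {spec!r}: bounds and step must be positive")
    if lower > upper:
        raise ConfigError(f"sigma range {spec!r}: lower bound exceeds upper bound")
    count = int(math.floor((upper - lower) / step + 1e-9)) + 1
    return NoiseScale(lower + step * np.arange(count))


def parse_ploidy_range(spec: str) -> list[int]:
    """Parse ``lo:hi`` (or a single value) into all even ploidies in range."""
    parts = spec.split(":")
    try:
        values = [int(p) for p in parts]
    except ValueError as exc:
        raise ConfigError(f"malformed ploidy range {spec!r}: {exc}") from None
    if len(values) == 1:
        lo = hi = values[0]
    elif len(values) == 2:
        lo, hi = values
    else:
        raise ConfigError(f"ploidy range {spec!r} must be 'lo:hi' or a single value")
    for v in (lo, hi):
        if v < 2 or v % 2:
            raise ConfigError(f"ploidy range {spec!r}: {v} is not an even ploidy >= 2")
    if lo > hi:
        raise ConfigError(f"ploidy range {spec!r}: lower bound exceeds upper bound")
    return list(range(lo, hi + 1, 2))


def parse_ploidy_filter(spec: str) -> frozenset[int]:
    """-f accepts a single even value or a ``lo:hi`` colon range."""
    return frozenset(parse_ploidy_range(spec))


def parse_sample_range(spec: str) -> tuple[int, int]:
    """Parse a 1-based inclusive ``lo:hi`` sample range."""
    parts = spec.split(":")
    if len(parts) != 2:
        raise ConfigError(f"sample range {spec!r} must be 'lo:hi' (1-based, inclusive)")
    try:
        lo, hi = (int(p) for p in parts)
    except ValueError as exc:
        raise ConfigError(f"malformed sample range {spec!r}: {exc}") from None
    if lo < 1 or lo > hi:
        raise ConfigError(f"sample range {spec!r} must satisfy 1 <= lo <= hi")
    return lo, hi


@dataclass
class PipelineConfig:
    """Everything a run needs; mirrors the command-line surface."""

    input_pattern: str
    output_pattern: str
    inference: Literal["f1", "hw", "ploidy"]
    dialect: str
    ploidies: list[int]
    sigmas: NoiseScale
    start_file: Optional[int] = None
    end_file: Optional[int] = None
    exact: bool = False
    filters: FilterConfig = field(default_factory=FilterConfig)
    selection: SampleSelection = field(default_factory=SampleSelection)
    threads: int = 1

    def validate(self) -> None:
        if self.inference not in ("f1", "hw", "ploidy"):
            raise ConfigError(f"unknown inference type {self.inference!r}")
        if self.dialect not in DIALECTS:
            raise ConfigError(f"unknown depth dialect {self.dialect!r}")
        if not self.ploidies:
            raise ConfigError("no ploidy levels to test")
        if self.threads < 1:
            raise ConfigError("threads must be >= 1")
        if self.inference == "f1" and not self.selection.has_parents:
            raise ConfigError("f1 inference requires at least one parent selector")
        if self.inference != "f1" and self.selection.has_parents:
            raise ConfigError(
                f"{self.inference} inference does not accept parent selectors"
            )


@dataclass
class PipelineResult:
    """Run summary: per-reason locus counts and emitted outputs."""

    reason_counts: Counter
    n_written: int
    output_paths: list[str]
    filter_log_paths: list[str]

    @property
    def n_input_loci(self) -> int:
        return sum(self.reason_counts.values())


def process_locus(
    obs: Optional[LocusObservations], cfg: PipelineConfig
) -> tuple[FilterOutcome, Optional[DosageCallSet]]:
    """Run the full per-locus pipeline; never raises for model failures."""
    if obs is None:
        return FilterOutcome("", False, FilterReason.NON_BIALLELIC), None
    is_f1 = cfg.inference == "f1"
    mode = "exact" if cfg.exact else "greedy"
    try:
        if not mean_depth_filter(obs, cfg.filters, is_f1=is_f1):
            return FilterOutcome(obs.locus_id, False, FilterReason.DEPTH_OUT_OF_RANGE), None
        fits = [
            fit_locus(obs, m, cfg.sigmas, cfg.inference, mode) for m in cfg.ploidies
        ]
        selection = select_ploidy(fits)
        selected = selection.selected_ploidy
        posterior = float(selection.ploidy_posterior.max())
        if not ploidy_posterior_filter(selection, cfg.filters):
            return (
                FilterOutcome(
                    obs.locus_id, False, FilterReason.LOW_PLOIDY_POSTERIOR, selected, posterior
                ),
                None,
            )
        if not ploidy_level_filter(selection, cfg.filters):
            return (
                FilterOutcome(
                    obs.locus_id, False, FilterReason.DISALLOWED_PLOIDY, selected, posterior
                ),
                None,
            )
        calls = call_genotypes(
            selection.selected_fit, selection, cfg.filters.naive_threshold
        )
        if not call_rate_filter(calls, cfg.filters):
            return (
                FilterOutcome(
                    obs.locus_id, False, FilterReason.LOW_CALL_RATE, selected, posterior
                ),
                None,
            )
        return (
            FilterOutcome(obs.locus_id, True, FilterReason.PASS, selected, posterior),
            calls,
        )
    except LocusUnusableError:
        return FilterOutcome(obs.locus_id, False, FilterReason.UNUSABLE), None


def _write_filter_log(outcomes: list[FilterOutcome], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\treason\tselected_ploidy\tploidy_posterior\n")
        for o in outcomes:
            ploidy = "." if o.selected_ploidy is None else str(o.selected_ploidy)
            post = "." if o.ploidy_posterior is None else f"{o.ploidy_posterior:.4f}"
            fh.write(f"{o.locus_id}\t{o.reason.value}\t{ploidy}\t{post}\n")


def _process_file(in_path: str, out_path: str, cfg: PipelineConfig) -> tuple[Counter, int, str]:
    with pysam.VariantFile(in_path) as vcf:
        check_dialect(vcf.header, cfg.dialect)
        samples = list(vcf.header.samples)
        progeny, par1, par2 = select_samples(samples, cfg.selection)
        order = [*progeny, *par1, *par2]
        sample_names = [samples[i] for i in order]
        contig_lines = contig_header_lines(vcf.header)
        entries = list(iter_locus_observations(vcf, cfg.dialect, progeny, par1, par2))

    with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
        processed = list(pool.map(lambda e: process_locus(e[1], cfg), entries))

    outcomes: list[FilterOutcome] = []
    survivors = []
    counts: Counter = Counter()
    for i, ((record, obs), (outcome, calls)) in enumerate(zip(entries, processed)):
        if outcome.reason is FilterReason.NON_BIALLELIC and not outcome.locus_id:
            outcome = FilterOutcome(
                f"{record.chrom}:{record.pos}", False, FilterReason.NON_BIALLELIC
            )
        outcomes.append(outcome)
        counts[outcome.reason.value] += 1
        if calls is not None:
            survivors.append((record, calls))
        if (i + 1) % _LOG_EVERY == 0:
            logger.info("%s: processed %d loci", in_path, i + 1)

    write_variants(survivors, out_path, sample_names, cfg.dialect, contig_lines)
    log_path = str(out_path) + ".filters.tsv"
    _write_filter_log(outcomes, log_path)
    return counts, len(survivors), log_path


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the caller over every input file; returns the run summary."""
    cfg.validate()
    inputs = expand_file_pattern(cfg.input_pattern, cfg.start_file, cfg.end_file)
    outputs = expand_file_pattern(cfg.output_pattern, cfg.start_file, cfg.end_file)
    if len(outputs) != len(inputs):
        raise ConfigError(
            "output pattern must expand to one path per input file "
            f"(got {len(outputs)} outputs for {len(inputs)} inputs)"
        )
    totals: Counter = Counter()
    n_written = 0
    log_paths = []
    for in_path, out_path in zip(inputs, outputs):
        counts, written, log_path = _process_file(in_path, out_path, cfg)
        totals.update(counts)
        n_written += written
        log_paths.append(log_path)
        logger.info("%s -> %s: wrote %d loci", in_path, out_path, written)
    for reason in FilterReason:
        if totals[reason.value]:
            logger.info("  %-22s %d", reason.value, totals[reason.value])
    return PipelineResult(totals, n_written, outputs, log_paths)
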