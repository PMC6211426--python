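"""Locus-level quality filters, applied in a fixed order.

The pipeline evaluates, per locus: biallelic check -> mean depth ->
(model fitting) -> ploidy posterior -> ploidy level -> naive-probability
masking of individual calls -> call rate.  Each locus receives exactly one
:class:`FilterOutcome`; naive masking happens before the call rate is
computed, so a stringent naive threshold directly lowers call rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .inference import DosageCallSet, LocusObservations, LocusUnusableError, PloidySelection

__all__ = [
    "FilterConfig",
    "FilterOutcome",
    "FilterReason",
    "mean_depth_filter",
    "ploidy_posterior_filter",
    "ploidy_level_filter",
    "call_rate_filter",
]


class FilterReason(str, Enum):
    PASS = "pass"
    NON_BIALLELIC = "non_biallelic"
    DEPTH_OUT_OF_RANGE = "depth_out_of_range"
    LOW_PLOIDY_POSTERIOR = "low_ploidy_posterior"
    DISALLOWED_PLOIDY = "disallowed_ploidy"
    LOW_CALL_RATE = "low_call_rate"
    UNUSABLE = "unusable"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds mirroring the command-line flags -d/-D/-p/-f/-n/-c.

    ``allowed_ploidies=None`` keeps every tested ploidy.
    """

    min_mean_depth: float = 0.0  # -d, reads
    max_mean_depth: float = math.inf  # -D, reads
    ploidy_posterior_min: float = 0.0  # -p
    allowed_ploidies: Optional[frozenset[int]] = None  # -f
    naive_threshold: float = 0.0  # -n
    min_call_rate: float = 0.0  # -c

    def __post_init__(self) -> None:
        if self.min_mean_depth > self.max_mean_depth:
            raise ValueError("min_mean_depth exceeds max_mean_depth")
        for name in ("ploidy_posterior_min", "naive_threshold", "min_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.allowed_ploidies is not None:
            allowed = frozenset(int(p) for p in self.allowed_ploidies)
            if not allowed:
                raise ValueError("allowed_ploidies must be non-empty or None")
            object.__setattr__(self, "allowed_ploidies", allowed)


@dataclass(frozen=True)
class FilterOutcome:
    """Disposition of one locus; ``kept`` iff ``reason`` is PASS."""

    locus_id: str
    kept: bool
    reason: FilterReason
    selected_ploidy: Optional[int] = None
    ploidy_posterior: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kept != (self.reason is FilterReason.PASS):
            raise ValueError("kept must be True exactly when reason is 'pass'")


def mean_depth_filter(obs: LocusObservations, cfg: FilterConfig, is_f1: bool = False) -> bool:
    """True iff the mean total depth per relevant sample is within [-d, -D].

    For F1 families the parents are excluded from the mean; zero-depth
    samples are included in the denominator.
    """
    idx = obs.progeny_indices if is_f1 else np.arange(obs.n_samples)
    if idx.size == 0:
        raise LocusUnusableError(f"{obs.locus_id}: no samples relevant to depth filter")
    mean = float(obs.total_depth[idx].mean())
    return cfg.min_mean_depth <= mean <= cfg.max_mean_depth


def ploidy_posterior_filter(selection: PloidySelection, cfg: FilterConfig) -> bool:
    """True iff the MAP ploidy's posterior reaches the -p threshold."""
    return float(selection.ploidy_posterior.max()) >= cfg.ploidy_posterior_min


def ploidy_level_filter(selection: PloidySelection, cfg: FilterConfig) -> bool:
    """True iff the selected ploidy is in the -f allowed set."""
    if cfg.allowed_ploidies is None:
        return True
    return selection.selected_ploidy in cfg.allowed_ploidies


def call_rate_filter(calls: DosageCallSet, cfg: FilterConfig) -> bool:
    """True iff the progeny call rate (after naive masking) reaches -c."""
    return calls.call_rate >= cfg.min_call_rate
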