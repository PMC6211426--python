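import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polydose.inference import LocusObservations, NoiseScale
from polydose.pipeline import parse_sigma_range

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def sigma_grid() -> NoiseScale:
    """The standard scanned sigma grid (20 values, 0.01 .. 0.96)."""
    return parse_sigma_range("0.01:1:0.05")


@pytest.fixture
def make_obs():
    """Factory building LocusObservations from (ref, alt) count lists.

    Parent replicates, if any, are appended after the progeny counts.
    """

    def _make(progeny, par1=(), par2=(), locus_id="test_locus"):
        counts = [*progeny, *par1, *par2]
        n_prog = len(progeny)
        names = [f"Ind{i:03d}" for i in range(n_prog)]
        names += [f"P1_rep{i:02d}" for i in range(len(par1))]
        names += [f"P2_rep{i:02d}" for i in range(len(par2))]
        return LocusObservations(
            locus_id=locus_id,
            sample_ids=names,
            ref_counts=np.array([c[0] for c in counts]),
            alt_counts=np.array([c[1] for c in counts]),
            parent1_indices=tuple(range(n_prog, n_prog + len(par1))),
            parent2_indices=tuple(
                range(n_prog + len(par1), n_prog + len(par1) + len(par2))
            ),
        )

    return _make
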