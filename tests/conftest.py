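import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).resolve().parent))

settings.register_profile(
    "oligomap",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("oligomap")

from oligomap.fixtures import (  # noqa: E402
    FixtureSpec,
    generate_genome,
    plant_probes,
)


def small_spec(seed: int = 7, **overrides) -> FixtureSpec:
    """A fixture spec small enough for per-test generation."""
    defaults = dict(
        n_chromosomes=2,
        chrom_length=8_000,
        n_unplaced=2,
        unplaced_length=2_000,
        fate_counts={
            "unique_plus": 8,
            "unique_minus": 4,
            "dup_same_chrom": 2,
            "dup_cross_chrom": 2,
            "unplaced_only": 2,
            "absent": 2,
            "mismatched_1": 2,
            "mismatched_3": 2,
        },
        perturbation_counts={
            "chrom_one_side": 1,
            "chrom_conflict": 1,
            "locus_one_side": 1,
            "pos_gt2": 2,
            "off_by_one": 3,
        },
        seed=seed,
    )
    defaults.update(overrides)
    return FixtureSpec(**defaults)


@pytest.fixture(scope="session")
def tiny_fixture():
    """(spec, genome, records, truths) for a 24-probe fixture."""
    spec = small_spec()
    genome = generate_genome(spec)
    records, truths, genome = plant_probes(genome, spec)
    return spec, genome, records, truths
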