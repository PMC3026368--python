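import pytest

from dyadscan import (
    FilterParams,
    KnownSet,
    NucleotideSequence,
    PlantSpec,
    compute_metrics,
    make_genome,
    scan,
)


@pytest.fixture(scope="session")
def small_fixture():
    """A 12 kb genome with 8 lightly degraded planted hairpins."""
    spec = PlantSpec(
        stem_length=28,
        loop_length=8,
        wobble_fraction=0.05,
        substitution_rate=0.08,
        indel_rate=0.03,
        count=8,
        background_length=12_000,
        background_gc=0.5,
        seed=7,
    )
    return make_genome(spec)


@pytest.fixture(scope="session")
def small_scan(small_fixture):
    """Scan of the small fixture with metrics computed (unfiltered)."""
    records = scan(small_fixture.genome())
    for rec in records:
        compute_metrics(rec)
    return records


@pytest.fixture(scope="session")
def small_known(small_fixture):
    """The planted hairpins viewed as a known precursor set."""
    return KnownSet.from_pairs(
        (p.id, NucleotideSequence(p.sequence)) for p in small_fixture.plants
    )


@pytest.fixture
def base_params():
    return FilterParams.base()
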