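import pytest
from hypothesis import HealthCheck, settings

from irefkit.fixtures import FixtureConfig, generate_mitab

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table_manifest():
    """The reference mixed fixture: every record class present, seed 1."""
    return generate_mitab(seed=1)


@pytest.fixture(scope="session")
def table(table_manifest):
    return table_manifest[0]


@pytest.fixture(scope="session")
def manifest(table_manifest):
    return table_manifest[1]


def small_config(i: int) -> FixtureConfig:
    """Deterministic family of small, varied configurations (<= 50 binary rows)."""
    return FixtureConfig(
        n_proteins=30 + (i % 3) * 10,
        n_binary=8 + (i % 5) * 4,
        n_ht_screens=i % 2,
        ht_screen_size=8,
        n_reported_complexes=i % 3,
        complex_size=(3, 6),
        n_spoke_complexes=i % 4,
        spoke_size=(3, 6),
        n_polymers=i % 2,
        duplicate_fraction=0.1 * (i % 3),
        isoform_group_sizes=(2,) if i % 2 else (),
    )


def make_single_complex_table(m: int, seed: int = 0):
    """A table holding exactly one reported complex of m distinct members."""
    cfg = FixtureConfig(
        n_proteins=max(m + 4, 16),
        n_binary=0, n_ht_screens=0, n_spoke_complexes=0, n_polymers=0,
        n_reported_complexes=1, complex_size=(m, m),
        isoform_group_sizes=(),
    )
    return generate_mitab(cfg, seed=seed)
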