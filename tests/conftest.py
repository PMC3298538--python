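import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# vault work factor for tests: the round-trip/tamper/blocking properties are
# invariant to the KDF iteration count, so tests use a light setting
TEST_KDF_ITERATIONS = 1_000


@pytest.fixture
def toolkit(tmp_path):
    from benchwork.fixtures import make_toolkit

    return make_toolkit(tmp_path / "toolkit")


@pytest.fixture
def engine_factory(tmp_path, toolkit):
    """Build (and rebuild, for crash/restart scenarios) engines over a home."""
    from benchwork import build_engine

    def make(home="engine", **kwargs):
        kwargs.setdefault("kdf_iterations", TEST_KDF_ITERATIONS)
        return build_engine(tmp_path / home, toolkit.config_path, **kwargs)

    return make


@pytest.fixture
def engine(engine_factory):
    return engine_factory()


@pytest.fixture
def dataset(engine, tmp_path):
    """Three seeded pseudo-FASTA files on the local backend; returns (dataset, base_uri)."""
    from benchwork.fixtures import make_dataset

    base_uri = f"file://{tmp_path}/data"
    ds = make_dataset(engine.storage, base_uri, seed=7, n_files=3)
    return ds, base_uri
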