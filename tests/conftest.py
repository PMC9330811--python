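"""Shared phantom fixtures (session-scoped: generation dominates runtime)."""

import hashlib
import os

import pytest
from hypothesis import settings

from conelung import PhantomSpec, RunConfig, generate_cohort, generate_thorax_phantom, run_protocol

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")

#: small thorax that fits an 11×9.5×9.5 mm grid — cheap unit-test phantom
SMALL_SPEC = PhantomSpec(
    shape=(112, 96, 96),
    spacing=(0.1, 0.1, 0.1),
    carina_width_mm=4.5,
    diaphragm_depth_mm=5.5,
    height_mm=6.0,
    noise_sd_hu=0.0,
    seed=5,
)

#: compact pipeline configuration reused by determinism checks
PIPELINE_CONFIG = dict(
    seed=7,
    n_healthy=6,
    n_pathologic=3,
    n_controls=3,
    grid_shape=(100, 120, 140),
    grid_spacing=0.18,
)


@pytest.fixture(scope="session")
def healthy_phantom():
    """Default-geometry healthy thorax, zero noise (exact-recovery tests)."""
    return generate_thorax_phantom(PhantomSpec(noise_sd_hu=0.0, seed=11))


@pytest.fixture(scope="session")
def pathologic_phantom():
    """Consolidated thorax: 30% of a fully aerated lung turned radiodense."""
    return generate_thorax_phantom(
        PhantomSpec(
            pathology="consolidation",
            burden_fraction=0.3,
            aeration_fraction=1.0,
            noise_sd_hu=0.0,
            seed=12,
        )
    )


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise thorax on a coarser grid (realistic-conditions tests)."""
    return generate_thorax_phantom(
        PhantomSpec(shape=(136, 128, 128), spacing=(0.1, 0.1, 0.1), seed=13)
    )


@pytest.fixture(scope="session")
def regression_cohort():
    """Cohort drawn around lung = 0.20·thoracic + 300 mm³ with 20 mm³ scatter."""
    return generate_cohort(40, noise_sd=20.0, seed=1, render_volumes=False)


def _hash_outputs(out_dir: str) -> dict[str, str]:
    digests = {}
    for name in ("report.json", "cohort.csv"):
        with open(os.path.join(out_dir, name), "rb") as fh:
            digests[name] = hashlib.sha256(fh.read()).hexdigest()
    return digests


@pytest.fixture(scope="session")
def pipeline_double_run(tmp_path_factory):
    """Two end-to-end protocol runs with identical config; returns
    (first report, first hashes, second hashes)."""
    out = str(tmp_path_factory.mktemp("protocol") / "run")
    config = RunConfig(out_dir=out, **PIPELINE_CONFIG)
    report = run_protocol(config)
    first = _hash_outputs(out)
    run_protocol(config)
    second = _hash_outputs(out)
    return report, first, second
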