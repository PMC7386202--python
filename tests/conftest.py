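import pytest

from pogoscout.config import PipelineConfig
from pogoscout.families import build_templates, load_reference_panel
from pogoscout.pipeline import run_synthetic
from pogoscout.synth import SynthSpec, generate_genome

CLEAN_SPEC = SynthSpec(
    genome_length=200_000,
    copies_per_family=4,          # 7 families x 4 = 28 planted FULL elements
    substitution_rate=0.0,
    truncation_probability=0.0,
    rng_seed=11,
)


@pytest.fixture(scope="session")
def templates():
    return build_templates()


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_genome():
    """A decay-free genome with 28 planted FULL elements plus its truth."""
    contigs, truth = generate_genome(CLEAN_SPEC)
    return contigs, truth


@pytest.fixture(scope="session")
def clean_run():
    """Full pipeline output on the clean genome (shared across tests)."""
    manifest, elements, truth = run_synthetic(CLEAN_SPEC, n_boot_family=50)
    return manifest, elements, truth


def match_element(elements, truth_copy):
    """The annotated element overlapping a planted copy (or None)."""
    for el in elements:
        if el.locus.overlaps(truth_copy.locus):
            return el
    return None
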