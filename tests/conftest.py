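import random

import pytest

from gpxprx.alignment import Alignment, progressive_msa
from gpxprx.features import map_reference_columns
from gpxprx.records import AA20, GpxClass, ProteinRecord
from gpxprx.synthetic import ScaffoldSpec, make_scaffold, synthesize_cohort


@pytest.fixture(scope="session")
def spec() -> ScaffoldSpec:
    return ScaffoldSpec(seed=11)


@pytest.fixture(scope="session")
def scaffold(spec):
    return make_scaffold(spec)


@pytest.fixture(scope="session")
def small_cohort(spec):
    """10 sequences per class at divergence 0, with the scaffold reference."""
    return synthesize_cohort(spec, 10, 10, 10, divergence=0.0, seed=21)


@pytest.fixture(scope="session")
def small_cohort_alignment(small_cohort):
    aln = progressive_msa([small_cohort.reference] + small_cohort.records)
    colmap = map_reference_columns(aln, small_cohort.reference.id)
    return aln, colmap


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(1234)
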