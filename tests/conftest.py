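"""Shared fixtures: small synthetic coding sequences and reference bundles."""

from __future__ import annotations

import random

import pytest

from alignfix.benchmark import BenchmarkSpec, generate_cases
from alignfix.homology import Homolog
from alignfix.seqs import translate

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_cds(rng: random.Random, n_codons: int = 40) -> str:
    """ATG-initial, stop-terminated, stop-free coding sequence."""
    return "ATG" + "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons)) + "TAA"


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture
def cds(rng) -> str:
    return random_cds(rng)


@pytest.fixture
def homologs(cds) -> list[Homolog]:
    return [Homolog(f"h{i}", cds) for i in range(3)]


@pytest.fixture(scope="session")
def small_cases():
    """A reusable 30-case benchmark at low divergence, all indel kinds."""
    spec = BenchmarkSpec(
        n_transcripts=30,
        cds_length_range=(300, 900),
        homolog_divergence=0.03,
        indel_kind_probs={"del1": 0.3, "ins1": 0.3, "del2": 0.15,
                          "ins2": 0.15, "del4": 0.1},
        seed=42,
    )
    return spec, generate_cases(spec)


def protein_of(dna: str) -> str:
    return translate(dna)
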