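"""Shared fixtures: small alignments and scaled-down simulation configs."""

from __future__ import annotations

import numpy as np
import pytest

from endoclock.seqdiv import BASES, CodonAlignment, GENETIC_CODE, STOP_CODONS

NON_STOP_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)


def random_codon_seq(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(
        NON_STOP_CODONS[i]
        for i in rng.integers(0, len(NON_STOP_CODONS), size=n_codons)
    )


def mutate_sites(
    seq: str, positions: list[int], rng: np.random.Generator
) -> str:
    """Substitute each listed site with a different random base."""
    s = list(seq)
    for pos in positions:
        choices = [b for b in BASES if b != s[pos]]
        s[pos] = choices[rng.integers(0, 3)]
    return "".join(s)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture
def pair_alignment(rng) -> CodonAlignment:
    """Random 200-codon pair with ~60 scattered substitutions, no stops."""
    while True:
        a = random_codon_seq(rng, 200)
        positions = rng.choice(600, size=60, replace=False)
        b = mutate_sites(a, list(positions), rng)
        codons_b = [b[i : i + 3] for i in range(0, len(b), 3)]
        if not any(c in STOP_CODONS for c in codons_b):
            return CodonAlignment(taxa=("x", "y"), sequences={"x": a, "y": b})
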