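"""Shared fixtures: a tiny deterministic toy locus and the bundled reference.

The toy locus (3 V, 2 J; short genes, short tags, no ambiguity) keeps
unit tests readable and fast; the bundled synthetic TRB-like reference
exercises the realistic geometry including subfamily ambiguity.
"""

from __future__ import annotations

import numpy as np
import pytest

from tcrtag.germline import GermlineGene, TagSet, load_bundled

STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"

TOY_TAG_PARAMS = dict(tag_length=8, v_guard=6, v_window=24, j_guard=4,
                      ambiguous="error")


def _codon(rng) -> str:
    while True:
        c = "".join(BASES[i] for i in rng.integers(0, 4, 3))
        if c not in STOPS:
            return c


def make_toy_genes(seed: int = 7) -> list[GermlineGene]:
    """3 V genes (60 nt, Cys codon at 51) + 2 J genes (30 nt, Phe at 12)."""
    rng = np.random.default_rng(seed)
    genes = []
    for name in ("VA", "VB", "VC"):
        codons = [_codon(rng) for _ in range(20)]
        codons[17] = "TGT"
        genes.append(GermlineGene(name, "V", "".join(codons), 51,
                                  cdr1_span=(9, 18), cdr2_span=(24, 33)))
    for name in ("JA", "JB"):
        head = "".join(BASES[i] for i in rng.integers(0, 4, 12))
        codons = [_codon(rng) for _ in range(6)]
        codons[0] = "TTC"
        genes.append(GermlineGene(name, "J", head + "".join(codons), 12))
    return genes


@pytest.fixture(scope="session")
def toy_genes() -> list[GermlineGene]:
    return make_toy_genes()


@pytest.fixture(scope="session")
def toy_tagset(toy_genes) -> TagSet:
    return TagSet.from_genes(toy_genes, **TOY_TAG_PARAMS)


@pytest.fixture(scope="session")
def bundled_tagset() -> TagSet:
    return load_bundled()
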