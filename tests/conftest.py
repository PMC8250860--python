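"""Shared fixtures: synthetic communities at several scales.

Expensive builds (the default-scale community and its 50% pan-genome) are
session-scoped so multiple test modules can reuse them.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from stalkscan.genome_io import TraitTable
from stalkscan.pangenome import build_pangenome
from stalkscan.simulate import SynthConfig, generate_community

SMALL = SynthConfig(
    n_positive=4, n_negative=2, n_dread=1, n_core=12, n_accessory=6,
    accessory_presence=0.5, n_unique_per_genome=2, n_decoys=1,
    cluster_size=3, neighbor_size=2, median_len=220.0, seed=7,
)


@pytest.fixture(scope="session")
def small_community():
    return generate_community(SMALL)


@pytest.fixture(scope="session")
def small_pan50(small_community):
    genomes, _ = small_community
    return build_pangenome(genomes, 50.0)


@pytest.fixture(scope="session")
def default_community():
    return generate_community(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def default_pan50(default_community):
    genomes, _ = default_community
    return build_pangenome(genomes, 50.0)


@pytest.fixture(scope="session")
def default_traits(default_community):
    _, truth = default_community
    return TraitTable(dict(truth.trait))


def truth_gene_sets(truth):
    """truth family label -> frozenset of all member gene ids."""
    return {
        lab: frozenset(g for v in fam.members.values() for g in v)
        for lab, fam in truth.families.items()
    }


def label_of_gene(truth):
    out = {}
    for lab, fam in truth.families.items():
        for genes in fam.members.values():
            for g in genes:
                out[g] = lab
    return out
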