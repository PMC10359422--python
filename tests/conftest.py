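"""Shared fixtures: small simulated datasets and genome construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from paleoretain.core_model import AnnotatedGenome, Gene
from paleoretain.simulate import SimParams, asteraceae_trio, simulate_dataset
from paleoretain.synteny import AnchorPair

GENE_SPACING = 10_000
GENE_SPAN = 2_000


def build_genome(species: str, layout: dict[str, list[tuple[str, str, str]]]
                 ) -> AnnotatedGenome:
    """Build a genome from {chrom: [(gene_id, family_id, strand), ...]} with
    evenly spaced gene coordinates."""
    g = AnnotatedGenome(species=species)
    for chrom, genes in layout.items():
        glist = []
        for i, (gid, fam, strand) in enumerate(genes):
            start = GENE_SPACING + i * GENE_SPACING + 1
            glist.append(Gene(gid, species, chrom, start,
                              start + GENE_SPAN - 1, strand, fam, rank=i))
        g.chromosomes.append((chrom, GENE_SPACING * (len(genes) + 2)))
        g.genes[chrom] = glist
    return g


def anchors_from_ranks(pairs: list[tuple[int, int]],
                       weights: list[float] | None = None,
                       strands: list[tuple[str, str]] | None = None
                       ) -> list[AnchorPair]:
    """Anchor list from (rank_a, rank_b) coordinates on one chromosome pair."""
    out = []
    for i, (a, b) in enumerate(pairs):
        sa, sb = strands[i] if strands else ("+", "+")
        ga = Gene(f"a{i:03d}", "A", "chrA", 1 + a * 10, 5 + a * 10, sa, f"F{i}",
                  rank=a)
        gb = Gene(f"b{i:03d}", "B", "chrB", 1 + b * 10, 5 + b * 10, sb, f"F{i}",
                  rank=b)
        out.append(AnchorPair(ga, gb, weights[i] if weights else 1.0))
    return out


@pytest.fixture(scope="session")
def trio():
    """Canonical simulated trio at desk scale (shared across tests)."""
    tree, params = asteraceae_trio(seed=5, n_ancestral_genes=300)
    tips, log = simulate_dataset(tree, params)
    return {"tips": tips, "log": log, "tree": tree, "params": params}


@pytest.fixture(scope="session")
def triplication_pair():
    """Two-taxon scenario: a reference without polyploidy and a target that
    underwent one whole-genome triplication followed by fractionation."""
    tree = "(reference:1.0,polyploid:1.0);"
    events = [{"branch": "polyploid", "type": "wg_multiplication",
               "time": 0.9, "multiplicity": 3}]
    params = SimParams(seed=11, n_ancestral_genes=800, n_chromosomes=4,
                       stem_length=1.0, events=events, retention_prob=0.5,
                       tandem_rate=0.0)
    tips, log = simulate_dataset(tree, params)
    return {"tips": tips, "log": log, "tree": tree, "params": params}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
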