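"""Collinear block detection by anchor chaining in gene-rank space.

Anchors (homologous gene pairs) are chained by sparse dynamic programming
separately for the two orientations. Chains maximise
``sum(weights) - gap_penalty * sum(skipped genes)`` under strict rank
monotonicity (increasing in both genomes for ``same`` orientation,
increasing/decreasing for ``inverted``), with a cap on the gene gap between
consecutive anchors. Working in rank coordinates makes chaining robust to
intergenic length variation; base-pair spans are derived afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core_model import AnnotatedGenome, Gene

__all__ = [
    "AnchorPair",
    "SyntenyBlock",
    "BestKLayout",
    "find_anchors",
    "chain_anchors",
    "best_k_layout",
    "syntenic_depth",
    "write_blocks_tsv",
]


@dataclass
class AnchorPair:
    gene_a: Gene
    gene_b: Gene
    weight: float = 1.0


@dataclass
class SyntenyBlock:
    block_id: str
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    score: float
    anchors: list[AnchorPair] = field(default_factory=list)

    @property
    def span_a(self) -> tuple[int, int]:
        ranks = [p.gene_a.rank for p in self.anchors]
        return (min(ranks), max(ranks))

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [p.gene_b.rank for p in self.anchors]
        return (min(ranks), max(ranks))

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def find_anchors(genome_a: AnnotatedGenome, genome_b: AnnotatedGenome,
                 mode: str = "family", top_hits: int | None = None,
                 similarity: Mapping[tuple[str, str], float] | None = None
                 ) -> list[AnchorPair]:
    """Homologous gene pairs between (or within) genomes.

    In ``family`` mode, all cross-genome pairs sharing a family_id become
    anchors with weight 1.0 (or the similarity score when a table is given).
    Self-comparison excludes self-pairs and keeps each unordered pair once.
    ``top_hits`` caps the number of anchors any single gene participates in,
    keeping the highest-weight ones (ties broken by gene_id).
    """
    if mode == "score" and similarity is None:
        raise ValueError("score mode requires a similarity table")
    if mode not in {"family", "score"}:
        raise ValueError(f"unknown anchor mode {mode!r}")

    self_cmp = genome_a is genome_b or (
        genome_a.species == genome_b.species and genome_a.n_genes == genome_b.n_genes
    )
    fams_a: dict[str, list[Gene]] = {}
    for g in genome_a.all_genes():
        fams_a.setdefault(g.family_id, []).append(g)
    fams_b: dict[str, list[Gene]] = {}
    for g in genome_b.all_genes():
        fams_b.setdefault(g.family_id, []).append(g)

    anchors: list[AnchorPair] = []
    for fam in sorted(set(fams_a) & set(fams_b)):
        for ga in fams_a[fam]:
            for gb in fams_b[fam]:
                if self_cmp and ga.gene_id >= gb.gene_id:
                    continue  # exclude self-pairs, keep each unordered pair once
                w = 1.0
                if similarity is not None:
                    w = similarity.get((ga.gene_id, gb.gene_id),
                                       similarity.get((gb.gene_id, ga.gene_id), 0.0))
                    if mode == "score" and w <= 0:
                        continue
                anchors.append(AnchorPair(ga, gb, w))

    if top_hits is not None:
        if top_hits < 1:
            raise ValueError("top_hits must be >= 1")
        anchors.sort(key=lambda p: (-p.weight, p.gene_a.gene_id, p.gene_b.gene_id))
        used_a: dict[str, int] = {}
        used_b: dict[str, int] = {}
        kept = []
        for p in anchors:
            if used_a.get(p.gene_a.gene_id, 0) < top_hits and \
               used_b.get(p.gene_b.gene_id, 0) < top_hits:
                kept.append(p)
                used_a[p.gene_a.gene_id] = used_a.get(p.gene_a.gene_id, 0) + 1
                used_b[p.gene_b.gene_id] = used_b.get(p.gene_b.gene_id, 0) + 1
        anchors = kept

    anchors.sort(key=lambda p: (p.gene_a.chrom, p.gene_a.rank,
                                p.gene_b.chrom, p.gene_b.rank, p.gene_b.gene_id))
    return anchors


def _chain_group(points: list[AnchorPair], inverted: bool, gap_penalty: float,
                 max_gap_genes: int, min_block_anchors: int
                 ) -> list[tuple[float, list[AnchorPair]]]:
    """Iteratively extract maximal-score monotone chains from one
    chromosome-pair group; each anchor joins at most one chain."""
    sign = -1 if inverted else 1
    pts = sorted(points, key=lambda p: (p.gene_a.rank, sign * p.gene_b.rank))
    remaining = list(pts)
    chains: list[tuple[float, list[AnchorPair]]] = []
    while remaining:
        n = len(remaining)
        score = [p.weight for p in remaining]
        back = [-1] * n
        for i in range(n):
            ai, bi = remaining[i].gene_a.rank, sign * remaining[i].gene_b.rank
            best = 0.0
            best_j = -1
            for j in range(i):
                aj, bj = remaining[j].gene_a.rank, sign * remaining[j].gene_b.rank
                if aj >= ai or bj >= bi:
                    continue
                da, db = ai - aj - 1, bi - bj - 1
                if da > max_gap_genes or db > max_gap_genes:
                    continue
                cand = score[j] - gap_penalty * (da + db)
                if cand > best + 1e-12:
                    best = cand
                    best_j = j
            score[i] = remaining[i].weight + best
            back[i] = best_j
        # best chain end: max score, ties to smaller (a, b)
        end = max(range(n), key=lambda i: (score[i], -remaining[i].gene_a.rank,
                                           -sign * remaining[i].gene_b.rank))
        chain = []
        i = end
        while i != -1:
            chain.append(remaining[i])
            i = back[i]
        chain.reverse()
        if len(chain) < min_block_anchors:
            break
        chains.append((score[end], chain))
        used = {id(p) for p in chain}
        remaining = [p for p in remaining if id(p) not in used]
    return chains


def chain_anchors(anchors: Sequence[AnchorPair], gap_penalty: float = 0.2,
                  max_gap_genes: int = 25, min_block_anchors: int = 5
                  ) -> list[SyntenyBlock]:
    """Chain anchors into collinear blocks, one pass per orientation.

    Returns blocks sorted deterministically and labelled ``B0001`` onwards.
    """
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for p in anchors:
        groups.setdefault((p.gene_a.chrom, p.gene_b.chrom), []).append(p)

    raw: list[tuple[tuple, float, str, list[AnchorPair]]] = []
    for (ca, cb) in sorted(groups):
        pts = groups[(ca, cb)]
        for orientation, inverted in (("same", False), ("inverted", True)):
            for sc, chain in _chain_group(pts, inverted, gap_penalty,
                                          max_gap_genes, min_block_anchors):
                key = (ca, cb, chain[0].gene_a.rank, chain[0].gene_b.rank,
                       orientation)
                raw.append((key, sc, orientation, chain))
    raw.sort(key=lambda r: r[0])
    blocks = []
    for i, (key, sc, orientation, chain) in enumerate(raw, start=1):
        ga, gb = chain[0].gene_a, chain[0].gene_b
        blocks.append(SyntenyBlock(
            block_id=f"B{i:04d}",
            species_a=ga.species, species_b=gb.species,
            chrom_a=ga.chrom, chrom_b=gb.chrom,
            orientation=orientation, score=sc, anchors=chain,
        ))
    return blocks


@dataclass
class BestKLayout:
    """Per reference gene: up to k best target regions with presence flags."""

    k: int
    reference_species: str
    target_species: str
    # gene_id -> [(block_id, homolog present in that region)]
    entries: dict[str, list[tuple[str, bool]]] = field(default_factory=dict)


def best_k_layout(reference: AnnotatedGenome, target: AnnotatedGenome, k: int,
                  blocks: Sequence[SyntenyBlock]) -> BestKLayout:
    """For each reference gene, the k highest-scoring blocks covering its
    rank, each flagged by whether the gene itself has an anchor in it."""
    if k < 1:
        raise ValueError("k must be >= 1")
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    block_genes: dict[str, set[str]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom_a, []).append(b)
        block_genes[b.block_id] = {p.gene_a.gene_id for p in b.anchors}

    layout = BestKLayout(k=k, reference_species=reference.species,
                         target_species=target.species)
    for chrom in reference.chrom_names():
        chrom_blocks = by_chrom.get(chrom, [])
        for g in reference.genes[chrom]:
            covering = [b for b in chrom_blocks
                        if b.span_a[0] <= g.rank <= b.span_a[1]]
            covering.sort(key=lambda b: (-b.score, b.block_id))
            chosen = covering[:k]
            layout.entries[g.gene_id] = [
                (b.block_id, g.gene_id in block_genes[b.block_id]) for b in chosen
            ]
    return layout


def syntenic_depth(layout: BestKLayout) -> dict[str, int]:
    """Copy-count track: per reference gene, the number of layout regions
    containing a homolog."""
    return {gid: sum(1 for _, present in regions if present)
            for gid, regions in layout.entries.items()}


def write_blocks_tsv(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    lines = ["\t".join(["block_id", "species_a", "species_b", "chrom_a",
                        "chrom_b", "orientation", "score", "n_anchors",
                        "anchor_pairs"])]
    for b in blocks:
        pairs = ";".join(f"{p.gene_a.gene_id}|{p.gene_b.gene_id}" for p in b.anchors)
        lines.append("\t".join([
            b.block_id, b.species_a, b.species_b, b.chrom_a, b.chrom_b,
            b.orientation, f"{b.score:.4f}", str(b.n_anchors), pairs,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
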