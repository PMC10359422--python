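"""Synteny-based tracing of single-gene presence/absence and loss mechanism.

Given a reference genome that carries a gene family and a target genome to
interrogate, the family's expected target locus is interpolated from the
flanking anchors of the covering collinear block. A family absent from the
whole target genome is a loss candidate; when a detected inversion's
breakpoint lies within ``border_tolerance`` genes of the expected locus the
loss is classified as occurring at an inversion border — the signature of a
rearrangement-mediated gene loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core_model import AnnotatedGenome
from .synteny import AnchorPair, SyntenyBlock

__all__ = [
    "MappedLocus",
    "InvertedSegment",
    "LossReport",
    "map_family_locus",
    "detect_inversions",
    "classify_loss",
    "trace_family_loss",
]


@dataclass
class MappedLocus:
    family_id: str
    reference_species: str
    target_species: str
    status_hint: str  # retained | moved | lost_candidate | unresolved
    block_id: str | None = None
    target_chrom: str | None = None
    expected_rank_lo: int | None = None
    expected_rank_hi: int | None = None
    ref_gene_id: str | None = None
    target_gene_ids: list[str] = field(default_factory=list)


def map_family_locus(family_id: str, reference: AnnotatedGenome,
                     target: AnnotatedGenome, blocks: Sequence[SyntenyBlock]
                     ) -> MappedLocus:
    """Locate the expected target interval of ``family_id``.

    The reference copy's covering block is found; the expected target rank
    interval is spanned by the nearest flanking anchors. Presence of a target
    family member inside the block means retained, elsewhere in the genome
    moved, nowhere a loss candidate.
    """
    ref_fams = reference.families()
    if family_id not in ref_fams:
        raise KeyError(f"family {family_id} absent from reference")
    ref_gene = sorted(ref_fams[family_id], key=lambda g: g.gene_id)[0]

    covering = [b for b in blocks
                if b.chrom_a == ref_gene.chrom
                and b.span_a[0] <= ref_gene.rank <= b.span_a[1]]
    covering.sort(key=lambda b: (-b.score, b.block_id))
    target_fams = target.families()
    target_copies = sorted(g.gene_id for g in target_fams.get(family_id, []))

    if not covering:
        return MappedLocus(family_id, reference.species, target.species,
                           "unresolved", ref_gene_id=ref_gene.gene_id,
                           target_gene_ids=target_copies)
    return _map_via_block(family_id, ref_gene, covering[0], reference, target,
                          target_copies)


def _map_via_block(family_id: str, ref_gene, block: SyntenyBlock,
                   reference: AnnotatedGenome, target: AnnotatedGenome,
                   target_copies: list[str]) -> MappedLocus:
    target_fams = target.families()
    below = [p for p in block.anchors if p.gene_a.rank < ref_gene.rank]
    above = [p for p in block.anchors if p.gene_a.rank > ref_gene.rank]
    flank_b = []
    if below:
        flank_b.append(max(below, key=lambda p: p.gene_a.rank).gene_b.rank)
    if above:
        flank_b.append(min(above, key=lambda p: p.gene_a.rank).gene_b.rank)
    self_anchor = [p for p in block.anchors if p.gene_a.gene_id == ref_gene.gene_id]
    if self_anchor:
        flank_b.append(self_anchor[0].gene_b.rank)
    lo, hi = (min(flank_b), max(flank_b)) if flank_b else (None, None)

    in_block = set()
    if target_copies:
        span_lo, span_hi = block.span_b
        for g in target_fams[family_id]:
            if g.chrom == block.chrom_b and span_lo <= g.rank <= span_hi:
                in_block.add(g.gene_id)
    if in_block:
        status = "retained"
    elif target_copies:
        status = "moved"
    else:
        status = "lost_candidate"
    return MappedLocus(family_id, reference.species, target.species, status,
                       block_id=block.block_id, target_chrom=block.chrom_b,
                       expected_rank_lo=lo, expected_rank_hi=hi,
                       ref_gene_id=ref_gene.gene_id,
                       target_gene_ids=target_copies)


@dataclass
class InvertedSegment:
    target_chrom: str
    rank_lo: int
    rank_hi: int
    n_genes: int
    n_anchors: int
    strand_corroborated: bool


def detect_inversions(block: SyntenyBlock,
                      anchors: Sequence[AnchorPair] | None = None,
                      min_anchors: int = 3,
                      a_window: tuple[int, int] | None = None
                      ) -> list[InvertedSegment]:
    """Locally orientation-flipped anchor runs inside a block's span.

    Walking anchors in reference order, maximal runs whose target ranks move
    against the block's consensus orientation are reported. Because chaining
    enforces monotonicity, the block's own anchors exclude inverted
    segments; passing the full anchor set (restricted here to the block's
    reference span and chromosome pair) recovers them. Strand agreement
    (relative strand flipped against the block majority) corroborates but is
    not required.
    """
    if anchors is None:
        pts = list(block.anchors)
        if a_window is not None:
            pts = [p for p in pts if a_window[0] <= p.gene_a.rank <= a_window[1]]
    else:
        lo, hi = a_window if a_window is not None else block.span_a
        pts = [p for p in anchors
               if p.gene_a.chrom == block.chrom_a and p.gene_b.chrom == block.chrom_b
               and lo <= p.gene_a.rank <= hi]
    pts.sort(key=lambda p: (p.gene_a.rank, p.gene_b.rank))
    if len(pts) < 3:
        return []
    sign = 1 if block.orientation == "same" else -1
    rel = [1 if p.gene_a.strand == p.gene_b.strand else -1 for p in pts]
    majority = 1 if sum(rel) >= 0 else -1

    segments: list[InvertedSegment] = []
    run: list[AnchorPair] = []

    def flush() -> None:
        if len(run) >= min_anchors:
            b_ranks = [p.gene_b.rank for p in run]
            flipped = [1 if p.gene_a.strand == p.gene_b.strand else -1 for p in run]
            corroborated = sum(1 for f in flipped if f == -majority) * 2 > len(run)
            segments.append(InvertedSegment(
                target_chrom=run[0].gene_b.chrom,
                rank_lo=min(b_ranks), rank_hi=max(b_ranks),
                n_genes=max(b_ranks) - min(b_ranks) + 1,
                n_anchors=len(run),
                strand_corroborated=corroborated))
        run.clear()

    for i, p in enumerate(pts):
        if not run:
            run.append(p)
            continue
        step = p.gene_b.rank - run[-1].gene_b.rank
        against = (sign * step) < 0
        if against:
            run.append(p)
        else:
            flush()
            run.append(p)
    flush()
    # single leading anchor before a descending run belongs to the run start:
    # handled implicitly because the first anchor seeds the run.
    return segments


@dataclass
class LossReport:
    family_id: str
    reference_species: str
    target_species: str
    status: str  # retained | moved | lost | lost_at_inversion_border | unresolved
    block_id: str | None
    expected_rank_lo: int | None
    expected_rank_hi: int | None
    inversions: list[InvertedSegment]
    distance_to_breakpoint: int | None

    def to_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "reference_species": self.reference_species,
            "target_species": self.target_species,
            "status": self.status,
            "block_id": self.block_id,
            "expected_rank_lo": self.expected_rank_lo,
            "expected_rank_hi": self.expected_rank_hi,
            "inversions": [
                {"chrom": s.target_chrom, "rank_lo": s.rank_lo,
                 "rank_hi": s.rank_hi, "n_genes": s.n_genes,
                 "n_anchors": s.n_anchors,
                 "strand_corroborated": s.strand_corroborated}
                for s in self.inversions
            ],
            "distance_to_breakpoint": self.distance_to_breakpoint,
        }


def classify_loss(mapped: MappedLocus, inversions: Sequence[InvertedSegment],
                  border_tolerance: int = 2) -> LossReport:
    """Combine locus mapping and inversion detection into a loss call.

    A loss candidate whose expected locus lies within ``border_tolerance``
    genes of a detected inversion breakpoint is classified as
    ``lost_at_inversion_border``; otherwise plain ``lost``. Retained/moved/
    unresolved statuses pass through unchanged.
    """
    distance: int | None = None
    if mapped.status_hint == "lost_candidate" and \
            mapped.expected_rank_lo is not None:
        lo, hi = mapped.expected_rank_lo, mapped.expected_rank_hi
        best = None
        for seg in inversions:
            if mapped.target_chrom is not None and \
                    seg.target_chrom != mapped.target_chrom:
                continue
            for bp in (seg.rank_lo, seg.rank_hi):
                d = 0 if lo <= bp <= hi else min(abs(bp - lo), abs(bp - hi))
                best = d if best is None else min(best, d)
        distance = best
    if mapped.status_hint == "lost_candidate":
        if distance is not None and distance <= border_tolerance:
            status = "lost_at_inversion_border"
        else:
            status = "lost"
    else:
        status = mapped.status_hint if mapped.status_hint != "lost_candidate" \
            else "lost"
    return LossReport(
        family_id=mapped.family_id,
        reference_species=mapped.reference_species,
        target_species=mapped.target_species,
        status=status,
        block_id=mapped.block_id,
        expected_rank_lo=mapped.expected_rank_lo,
        expected_rank_hi=mapped.expected_rank_hi,
        inversions=list(inversions),
        distance_to_breakpoint=distance,
    )


def trace_family_loss(family_id: str, reference: AnnotatedGenome,
                      target: AnnotatedGenome, blocks: Sequence[SyntenyBlock],
                      anchors: Sequence[AnchorPair] | None = None,
                      border_tolerance: int = 2,
                      window: int = 40) -> LossReport:
    """End-to-end loss trace examining every homeologous region.

    After a polyploidy event the reference locus maps into several target
    regions; a rearrangement scar need only exist on the homeolog that
    actually carried the lost copy. Each block covering the reference rank is
    therefore mapped and scanned for inversions within ``window`` genes of
    the locus, and the homeolog with the closest breakpoint decides the
    classification.
    """
    mapped = map_family_locus(family_id, reference, target, blocks)
    if mapped.status_hint != "lost_candidate":
        return classify_loss(mapped, [], border_tolerance)

    ref_gene = reference.gene_index()[mapped.ref_gene_id]
    covering = sorted(
        (b for b in blocks
         if b.chrom_a == ref_gene.chrom
         and b.span_a[0] <= ref_gene.rank <= b.span_a[1]),
        key=lambda b: (-b.score, b.block_id))
    a_window = (ref_gene.rank - window, ref_gene.rank + window)

    best_report: LossReport | None = None
    for block in covering:
        m = _map_via_block(family_id, ref_gene, block, reference, target,
                           mapped.target_gene_ids)
        invs = detect_inversions(block, anchors=anchors, a_window=a_window)
        rep = classify_loss(m, invs, border_tolerance)
        if best_report is None:
            best_report = rep
        else:
            d_new = rep.distance_to_breakpoint
            d_old = best_report.distance_to_breakpoint
            if d_new is not None and (d_old is None or d_new < d_old):
                best_report = rep
    return best_report if best_report is not None else \
        classify_loss(mapped, [], border_tolerance)
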