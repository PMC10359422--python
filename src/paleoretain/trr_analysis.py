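"""Triplication-retained regions: calling, composition, enrichment.

A retained region is a maximal run of consecutive reference genes whose
syntenic depth reaches the required copy number, tolerating up to
``max_gap`` consecutive sub-threshold genes inside the run. Composition
(genic vs repetitive fraction per window) is compared between retained
regions and the genome background by a two-tailed Student's t test, and
category membership (repeat families, functional labels) by hypergeometric
enrichment/depletion with Benjamini-Hochberg control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_model import AnnotatedGenome, Window
from .synteny import SyntenyBlock

__all__ = [
    "TRRParams",
    "TRRInterval",
    "EnrichmentResult",
    "call_trrs",
    "window_composition",
    "compare_composition",
    "split_windows_by_intervals",
    "trr_target_intervals",
    "hypergeom_enrichment",
    "fisher_domain_enrichment",
    "write_trrs_bed",
]


@dataclass
class TRRParams:
    """Thresholds for retained-region calling.

    ``k`` is the layout size (3 for a triplication screen; 6 when an extra
    duplication doubled the expected copy number), ``min_copies`` the depth a
    gene must reach to qualify, ``min_run`` the minimum number of qualifying
    genes per region, and ``max_gap`` the number of consecutive
    sub-threshold genes tolerated inside a region.
    """

    k: int = 3
    min_copies: int = 3
    min_run: int = 3
    max_gap: int = 1

    def __post_init__(self) -> None:
        if self.min_copies > self.k:
            raise ValueError("min_copies cannot exceed k")
        if self.min_run < 1 or self.max_gap < 0:
            raise ValueError("min_run >= 1 and max_gap >= 0 required")


@dataclass
class TRRInterval:
    chrom: str
    start_rank: int
    end_rank: int
    start_bp: int
    end_bp: int
    n_genes: int              # genes spanned (first..last qualifying)
    n_qualifying: int
    gene_ids: list[str] = field(default_factory=list)
    copy_counts: list[int] = field(default_factory=list)


def call_trrs(depth_track: Mapping[str, int], params: TRRParams,
              genome: AnnotatedGenome) -> list[TRRInterval]:
    """Maximal runs of reference genes with depth >= min_copies.

    Runs start and end on qualifying genes; at most ``max_gap`` consecutive
    non-qualifying genes are tolerated inside a run; runs with fewer than
    ``min_run`` qualifying genes are discarded. Output order follows the
    genome's chromosome order and is independent of processing order.
    """
    out: list[TRRInterval] = []
    for chrom in genome.chrom_names():
        glist = genome.genes.get(chrom, [])
        qual = [depth_track.get(g.gene_id, 0) >= params.min_copies for g in glist]
        i = 0
        n = len(glist)
        while i < n:
            if not qual[i]:
                i += 1
                continue
            start = i
            last_q = i
            j = i + 1
            gap = 0
            while j < n:
                if qual[j]:
                    last_q = j
                    gap = 0
                else:
                    gap += 1
                    if gap > params.max_gap:
                        break
                j += 1
            n_qual = sum(1 for t in range(start, last_q + 1) if qual[t])
            if n_qual >= params.min_run:
                genes = glist[start : last_q + 1]
                out.append(TRRInterval(
                    chrom=chrom,
                    start_rank=start,
                    end_rank=last_q,
                    start_bp=genes[0].start,
                    end_bp=genes[-1].end,
                    n_genes=last_q - start + 1,
                    n_qualifying=n_qual,
                    gene_ids=[g.gene_id for g in genes],
                    copy_counts=[depth_track.get(g.gene_id, 0) for g in genes],
                ))
            i = last_q + 1
    return out


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def _merged_overlap(intervals: list[tuple[int, int]], lo: int, hi: int) -> int:
    """Total bp of the union of 1-based inclusive intervals inside [lo, hi]."""
    clipped = sorted(
        (max(s, lo), min(e, hi)) for s, e in intervals if e >= lo and s <= hi
    )
    total = 0
    cur_s, cur_e = None, None
    for s, e in clipped:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def window_composition(genome: AnnotatedGenome, windows: Sequence[Window]
                       ) -> pd.DataFrame:
    """Genic fraction, repeat fraction and per-family repeat bp per window.

    Overlapping intervals within a track are counted once (union).
    """
    genes_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genome.all_genes():
        genes_by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    reps_by_chrom: dict[str, list[tuple[int, int]]] = {}
    reps_by_fam: dict[str, dict[str, list[tuple[int, int]]]] = {}
    fams = sorted({r[3] for r in genome.repeats})
    for chrom, s, e, fam in genome.repeats:
        reps_by_chrom.setdefault(chrom, []).append((s, e))
        reps_by_fam.setdefault(fam, {}).setdefault(chrom, []).append((s, e))

    rows = []
    for w in windows:
        width = w.width
        genic = _merged_overlap(genes_by_chrom.get(w.chrom, []), w.start, w.end)
        rep = _merged_overlap(reps_by_chrom.get(w.chrom, []), w.start, w.end)
        row = {
            "chrom": w.chrom, "start": w.start, "end": w.end, "width": width,
            "partial": w.partial,
            "genic_frac": genic / width,
            "repeat_frac": rep / width,
        }
        for fam in fams:
            row[f"rep_{fam}_bp"] = _merged_overlap(
                reps_by_fam[fam].get(w.chrom, []), w.start, w.end)
        rows.append(row)
    return pd.DataFrame(rows)


def split_windows_by_intervals(comp: pd.DataFrame,
                               intervals: Sequence[tuple[str, int, int]]
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each window by majority overlap with ``intervals`` (bp)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    mask = []
    for _, row in comp.iterrows():
        ov = _merged_overlap(by_chrom.get(row.chrom, []), row.start, row.end)
        mask.append(ov * 2 > row.width)
    mask = np.array(mask, dtype=bool)
    return comp[mask].reset_index(drop=True), comp[~mask].reset_index(drop=True)


def trr_target_intervals(trrs: Sequence[TRRInterval],
                         blocks: Sequence[SyntenyBlock]
                         ) -> list[tuple[str, int, int]]:
    """Map reference-coordinate retained regions onto the target genome via
    the anchors of overlapping blocks: for each block, the bp span of its
    target-side anchor genes falling inside the region."""
    out: list[tuple[str, int, int]] = []
    for trr in trrs:
        for b in blocks:
            if b.chrom_a != trr.chrom:
                continue
            inside = [p.gene_b for p in b.anchors
                      if trr.start_rank <= p.gene_a.rank <= trr.end_rank]
            if len(inside) < 2:
                continue
            lo = min(g.start for g in inside)
            hi = max(g.end for g in inside)
            out.append((b.chrom_b, lo, hi))
    return sorted(out)


@dataclass
class CompositionTest:
    track: str
    mean_test: float
    mean_background: float
    t: float
    df: int
    p: float | None
    direction: str  # "higher" | "lower" | "equal"
    degenerate: bool = False


def compare_composition(trr_windows: pd.DataFrame, genome_windows: pd.DataFrame,
                        tracks: Sequence[str] = ("genic_frac", "repeat_frac"),
                        welch: bool = False) -> list[CompositionTest]:
    """Two-tailed Student's t test (pooled variance by default) per track."""
    out = []
    for track in tracks:
        a = trr_windows[track].to_numpy(dtype=float)
        b = genome_windows[track].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need >= 2 windows per group")
        direction = ("higher" if a.mean() > b.mean()
                     else "lower" if a.mean() < b.mean() else "equal")
        df = a.size + b.size - 2
        if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
            if np.allclose(a.mean(), b.mean()):
                out.append(CompositionTest(track, a.mean(), b.mean(), 0.0, df,
                                           1.0, "equal", degenerate=True))
            else:
                out.append(CompositionTest(track, a.mean(), b.mean(),
                                           float("nan"), df, None, direction,
                                           degenerate=True))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        out.append(CompositionTest(track, float(a.mean()), float(b.mean()),
                                   float(t), df, float(p), direction))
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    category: str
    k_in: int
    n_test: int
    K_total: int
    N_total: int
    p_value: float
    adjusted_p: float
    direction: str  # "enriched" | "depleted"
    significant: bool = False


def hypergeom_enrichment(test_set: Iterable[str], background: Iterable[str],
                         categories: Mapping[str, str | set[str]],
                         threshold: float = 0.01) -> list[EnrichmentResult]:
    """Hypergeometric enrichment/depletion of categories in a test set
    against a background, Benjamini-Hochberg adjusted.

    ``categories`` maps element id to a category (or set of categories).
    For each category the upper-tail (enrichment) and lower-tail (depletion)
    p-values are computed; the smaller is reported with its direction.
    """
    test = set(test_set)
    bg = set(background)
    if not test <= bg:
        raise ValueError("test set must be a subset of the background")

    def cats_of(x: str) -> set[str]:
        c = categories.get(x)
        if c is None:
            return set()
        return {c} if isinstance(c, str) else set(c)

    bg_counts: dict[str, int] = {}
    test_counts: dict[str, int] = {}
    for x in bg:
        for c in cats_of(x):
            bg_counts[c] = bg_counts.get(c, 0) + 1
    for x in test:
        for c in cats_of(x):
            test_counts[c] = test_counts.get(c, 0) + 1
    for c in set(test_counts) - set(bg_counts):
        warnings.warn(f"category {c!r} absent from background; skipped")

    N, n = len(bg), len(test)
    results = []
    for c in sorted(bg_counts):
        K = bg_counts[c]
        k = test_counts.get(c, 0)
        p_enr = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_dep = float(stats.hypergeom.cdf(k, N, K, n))
        if p_enr <= p_dep:
            p, direction = p_enr, "enriched"
        else:
            p, direction = p_dep, "depleted"
        results.append(EnrichmentResult(c, k, n, K, N, min(p, 1.0), 1.0, direction))
    if results:
        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
            r.significant = r.adjusted_p < threshold
    return results


def fisher_domain_enrichment(count_tables: Mapping[str, pd.DataFrame],
                             alpha: float = 0.05, min_species: int = 2
                             ) -> tuple[dict[str, list[EnrichmentResult]], list[str]]:
    """Two-sided Fisher exact test per functional domain per species.

    Each species table is indexed by domain with columns
    ``in_with, in_without, out_with, out_without`` (the 2x2 table of domain
    presence inside/outside the gene set of interest). P-values are BH
    adjusted within species; the summary lists domains significant
    (adjusted p < alpha) in at least ``min_species`` species.
    """
    per_species: dict[str, list[EnrichmentResult]] = {}
    hits: dict[str, int] = {}
    for sp in sorted(count_tables):
        tab = count_tables[sp]
        results = []
        for domain, row in tab.sort_index().iterrows():
            a, b = int(row["in_with"]), int(row["in_without"])
            c, d = int(row["out_with"]), int(row["out_without"])
            if a + b + c + d == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            in_rate = a / (a + b) if a + b else 0.0
            out_rate = c / (c + d) if c + d else 0.0
            direction = "enriched" if in_rate >= out_rate else "depleted"
            results.append(EnrichmentResult(
                category=str(domain), k_in=a, n_test=a + b, K_total=a + c,
                N_total=a + b + c + d, p_value=float(p), adjusted_p=1.0,
                direction=direction))
        if results:
            adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
            for r, padj in zip(results, adj):
                r.adjusted_p = float(padj)
                r.significant = r.adjusted_p < alpha
                if r.significant and r.direction == "enriched":
                    hits[r.category] = hits.get(r.category, 0) + 1
        per_species[sp] = results
    summary = sorted(c for c, n in hits.items() if n >= min_species)
    return per_species, summary


def write_trrs_bed(trrs: Iterable[TRRInterval], path: str | Path) -> None:
    """Export retained regions as BED (0-based half-open)."""
    lines = [
        f"{t.chrom}\t{t.start_bp - 1}\t{t.end_bp}\tTRR_{i:04d}\t{t.n_qualifying}"
        for i, t in enumerate(trrs, start=1)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
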