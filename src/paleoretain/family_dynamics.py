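"""Gene-family counting, expansion testing, duplication-mechanism
classification, selection summaries, and low-copy-number ortholog selection."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import AnnotatedGenome, FamilyTable, Gene
from .ks_evolution import KsPair
from .synteny import SyntenyBlock

__all__ = [
    "ExpansionTestResult",
    "DuplicationCall",
    "SelectionSummary",
    "expansion_test",
    "classify_duplication",
    "kaks_selection_summary",
    "select_lcn",
    "count_families",
]


@dataclass
class ExpansionTestResult:
    family_id: str
    clade_mean: float
    rest_mean: float
    t: float
    df: int
    p: float | None
    degenerate: bool
    sig_01: bool
    sig_001: bool
    sig_0001: bool


def expansion_test(table: FamilyTable, clade_species: Sequence[str],
                   rest_species: Sequence[str], welch: bool = False
                   ) -> pd.DataFrame:
    """Per-family two-tailed Student's t test of per-species gene counts,
    clade versus the remaining species.

    Significance flags follow the conventional star thresholds
    (p < 0.01, < 0.001, < 0.0001). Families where both groups have zero
    variance are flagged degenerate ("not testable") rather than given p=0.
    """
    if len(clade_species) < 2 or len(rest_species) < 2:
        raise ValueError("need >= 2 species per group")
    if set(clade_species) & set(rest_species):
        raise ValueError("species groups must be disjoint")
    counts = table.counts(list(clade_species) + list(rest_species))
    rows = []
    for fam in counts.columns:
        a = counts.loc[list(clade_species), fam].to_numpy(dtype=float)
        b = counts.loc[list(rest_species), fam].to_numpy(dtype=float)
        df = a.size + b.size - 2
        if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
            t = 0.0 if a.mean() == b.mean() else float("nan")
            p = 1.0 if a.mean() == b.mean() else None
            degen = True
        else:
            with warnings.catch_warnings():
                # one group may be constant; pooled variance is still valid
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(a, b, equal_var=not welch)
            t, p = float(t), float(p)
            degen = False
        rows.append(ExpansionTestResult(
            family_id=str(fam), clade_mean=float(a.mean()),
            rest_mean=float(b.mean()), t=t, df=df, p=p, degenerate=degen,
            sig_01=p is not None and p < 0.01,
            sig_001=p is not None and p < 0.001,
            sig_0001=p is not None and p < 0.0001,
        ))
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("family_id")


@dataclass
class DuplicationCall:
    gene_a: str
    gene_b: str
    mechanism: str  # tandem | wgd_segmental | dispersed
    intervening_genes: int | None = None
    block_id: str | None = None


def classify_duplication(pair: tuple[Gene, Gene], genome: AnnotatedGenome,
                         blocks: Sequence[SyntenyBlock], D: int = 10
                         ) -> DuplicationCall:
    """Classify a same-family duplicate pair by mechanism.

    Same chromosome with at most ``D`` intervening genes is tandem; a pair
    that is itself an anchor of an intra-genome collinear block is
    WGD/segmental; anything else is dispersed.
    """
    ga, gb = pair
    if ga.family_id != gb.family_id:
        raise ValueError("pair must belong to one family")
    if ga.chrom == gb.chrom:
        intervening = abs(ga.rank - gb.rank) - 1
        if intervening <= D:
            return DuplicationCall(ga.gene_id, gb.gene_id, "tandem",
                                   intervening_genes=intervening)
    key = frozenset((ga.gene_id, gb.gene_id))
    for b in blocks:
        for p in b.anchors:
            if frozenset((p.gene_a.gene_id, p.gene_b.gene_id)) == key:
                return DuplicationCall(ga.gene_id, gb.gene_id, "wgd_segmental",
                                       block_id=b.block_id)
    intervening = abs(ga.rank - gb.rank) - 1 if ga.chrom == gb.chrom else None
    return DuplicationCall(ga.gene_id, gb.gene_id, "dispersed",
                           intervening_genes=intervening)


@dataclass
class SelectionSummary:
    n_pairs: int
    n_unratioed: int
    ratios: list[float]
    mean_ratio: float
    median_ratio: float
    frac_purifying: float


def kaks_selection_summary(pairs: Sequence[KsPair]) -> SelectionSummary:
    """Distribution of Ka/Ks and the fraction under purifying selection
    (ratio < 1). Pairs with Ks = 0 or saturated Ks are reported separately
    as unratioed."""
    if not pairs:
        raise ValueError("no pairs supplied")
    ratios = []
    unratioed = 0
    for p in pairs:
        if p.saturated or p.ks == 0 or math.isnan(p.ks):
            unratioed += 1
            continue
        ratios.append(p.ka / p.ks)
    if ratios:
        arr = np.array(ratios)
        return SelectionSummary(
            n_pairs=len(ratios), n_unratioed=unratioed, ratios=ratios,
            mean_ratio=float(arr.mean()), median_ratio=float(np.median(arr)),
            frac_purifying=float((arr < 1.0).mean()))
    return SelectionSummary(0, unratioed, [], float("nan"), float("nan"),
                            float("nan"))


def select_lcn(table: FamilyTable, required_species: Sequence[str],
               min_other_single: int, other_species: Sequence[str]
               ) -> list[str]:
    """Low-copy-number ortholog groups: strictly single copy in every
    required species AND single copy in at least ``min_other_single`` of the
    other species (boundary inclusive)."""
    if set(required_species) & set(other_species):
        raise ValueError("required and other species sets must be disjoint")
    counts = table.counts(list(required_species) + list(other_species))
    selected = []
    for fam in counts.columns:
        req = counts.loc[list(required_species), fam]
        if not (req == 1).all():
            continue
        others = counts.loc[list(other_species), fam]
        if int((others == 1).sum()) >= min_other_single:
            selected.append(str(fam))
    return sorted(selected)


def count_families(table: FamilyTable,
                   species_subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Species x family count matrix."""
    return table.counts(species_subset)
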