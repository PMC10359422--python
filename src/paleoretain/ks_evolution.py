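"""Synonymous/nonsynonymous divergence and polyploidy-event inference.

Per-pair divergence uses Nei-Gojobori (1986) site/difference counting with
the Jukes-Cantor multiple-hit correction applied separately to the
synonymous and nonsynonymous proportions. Multi-substitution codons are
resolved by averaging over minimal substitution pathways; pathways passing
through a stop codon are excluded (all codon changes *to* a stop count as
nonsynonymous). A proportion >= 3/4 is flagged saturated.

Ks distributions are summarised by Gaussian mixtures on log-Ks; peaks shared
across species are assigned to tree branches and ordered against speciation
by comparing paralog peak Ks with the relevant ortholog peak Ks.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from sklearn.mixture import GaussianMixture

from .synteny import SyntenyBlock

__all__ = [
    "KsPair",
    "KsPeakModel",
    "DatingParams",
    "BlockKsSummary",
    "ng86_pair",
    "align_cds",
    "block_ks_summary",
    "fit_ks_peaks",
    "classify_wg_events",
    "ks_to_time",
]

_BASES = "TCAG"
CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_CODON_IDX = {c: i for i, c in enumerate(CODONS)}

_table = CodonTable.unambiguous_dna_by_id[1]
AA: dict[str, str] = {}
for c in CODONS:
    AA[c] = "*" if c in _table.stop_codons else _table.forward_table[c]


def _build_site_table() -> np.ndarray:
    """Synonymous site count per codon (NG86): at each position, the fraction
    of the three possible single-nucleotide changes that preserve the amino
    acid. Changes to stop codons are nonsynonymous. Stops carry NaN."""
    sites = np.full(64, np.nan)
    for c in CODONS:
        if AA[c] == "*":
            continue
        s = 0.0
        for pos in range(3):
            for alt in "ACGT":
                if alt == c[pos]:
                    continue
                mut = c[:pos] + alt + c[pos + 1 :]
                if AA[mut] == AA[c]:
                    s += 1.0 / 3.0
        sites[_CODON_IDX[c]] = s
    return sites


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over minimal
    substitution pathways between two non-stop codons."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = c1
        sd = nd = 0.0
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if AA[nxt] == "*" and step < len(order) - 1:
                return None  # pathway through a stop codon
            if AA[nxt] == AA[cur] and AA[nxt] != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [r for r in
               (walk(order) for order in itertools.permutations(diff_pos))
               if r is not None]
    if not results:  # every pathway blocked: fall back to counting via stops
        results = []
        for order in itertools.permutations(diff_pos):
            cur = c1
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if AA[nxt] == AA[cur] and AA[nxt] != "*":
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            results.append((sd, nd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _build_diff_tables() -> tuple[np.ndarray, np.ndarray]:
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i, c1 in enumerate(CODONS):
        if AA[c1] == "*":
            sd[i, :] = nd[i, :] = np.nan
            continue
        for j, c2 in enumerate(CODONS):
            if AA[c2] == "*":
                sd[i, j] = nd[i, j] = np.nan
            elif j > i:
                sd[i, j], nd[i, j] = _pathway_diffs(c1, c2)
    iu = np.triu_indices(64, 1)
    sd[(iu[1], iu[0])] = sd[iu]
    nd[(iu[1], iu[0])] = nd[iu]
    return sd, nd


SYN_SITES = _build_site_table()
SD_TABLE, ND_TABLE = _build_diff_tables()


@dataclass
class KsPair:
    """NG86 divergence estimates for one aligned coding pair."""

    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    ks: float  # NaN when saturated
    ka: float  # NaN when saturated
    saturated_s: bool = False
    saturated_n: bool = False

    @property
    def saturated(self) -> bool:
        return self.saturated_s or self.saturated_n

    @property
    def ka_ks(self) -> float | None:
        if self.saturated or self.ks == 0 or math.isnan(self.ks):
            return None
        return self.ka / self.ks


def _encode_codons(seq: str) -> np.ndarray:
    seq = seq.upper()
    n = len(seq) // 3
    out = np.full(n, -1, dtype=np.int16)
    for i in range(n):
        out[i] = _CODON_IDX.get(seq[3 * i : 3 * i + 3], -1)
    return out


def _jc(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return max(0.0, -0.75 * math.log(1.0 - 4.0 * p / 3.0)), False


def ng86_pair(cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b") -> KsPair:
    """Ks/Ka for a gap-free, in-frame aligned coding pair.

    A shared trailing stop codon is stripped; an internal stop or a length
    mismatch raises. Codons with ambiguous bases are skipped.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned sequences must have equal length")
    if len(cds_a) % 3:
        raise ValueError("aligned length must be a multiple of 3")
    ia, ib = _encode_codons(cds_a), _encode_codons(cds_b)
    if ia.size and AA.get(CODONS[ia[-1]] if ia[-1] >= 0 else "", "") == "*" \
            and AA.get(CODONS[ib[-1]] if ib[-1] >= 0 else "", "") == "*":
        ia, ib = ia[:-1], ib[:-1]
    for name, idx in (("first", ia), ("second", ib)):
        stops = [k for k in idx if k >= 0 and AA[CODONS[k]] == "*"]
        if stops:
            raise ValueError(f"internal stop codon in {name} sequence")

    valid = (ia >= 0) & (ib >= 0)
    ia, ib = ia[valid], ib[valid]
    if ia.size == 0:
        raise ValueError("no usable codons")
    S = float(SYN_SITES[ia].sum() + SYN_SITES[ib].sum()) / 2.0
    N = 3.0 * ia.size - S
    Sd = float(SD_TABLE[ia, ib].sum())
    Nd = float(ND_TABLE[ia, ib].sum())
    ks, sat_s = _jc(Sd / S) if S > 0 else (float("nan"), True)
    ka, sat_n = _jc(Nd / N) if N > 0 else (float("nan"), True)
    return KsPair(gene_a, gene_b, S, N, Sd, Nd, ks, ka, sat_s, sat_n)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def translate(cds: str) -> str:
    prot = "".join(AA.get(cds[i : i + 3].upper(), "X") for i in range(0, len(cds) - len(cds) % 3, 3))
    return prot[:-1] if prot.endswith("*") else prot


def align_cds(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon-aware pairwise alignment: globally align the translations, map
    back to codons, and drop gapped columns. Returns equal-length gap-free
    nucleotide strings ready for :func:`ng86_pair`."""
    if not cds_a or not cds_b:
        raise ValueError("empty coding sequence")
    pa, pb = translate(cds_a), translate(cds_b)
    aln = _ALIGNER.align(pa, pb)[0]
    sa, sb = str(aln[0]), str(aln[1])
    out_a: list[str] = []
    out_b: list[str] = []
    i = j = 0
    for ca, cb in zip(sa, sb):
        if ca != "-" and cb != "-":
            out_a.append(cds_a[3 * i : 3 * i + 3])
            out_b.append(cds_b[3 * j : 3 * j + 3])
        if ca != "-":
            i += 1
        if cb != "-":
            j += 1
    return "".join(out_a), "".join(out_b)


def alignment_score(cds_a: str, cds_b: str) -> float:
    """Score of the global protein alignment used by :func:`align_cds`."""
    return float(_ALIGNER.score(translate(cds_a), translate(cds_b)))


# ---------------------------------------------------------------------------
# Block summaries and peak models
# ---------------------------------------------------------------------------

@dataclass
class BlockKsSummary:
    block_id: str
    median_ks: float
    pairs: list[KsPair]
    n_usable: int
    low_confidence: bool


def block_ks_summary(block: SyntenyBlock, cds_a: Mapping[str, str],
                     cds_b: Mapping[str, str],
                     flagged: Iterable[str] = ()) -> BlockKsSummary:
    """Median non-saturated anchor Ks for one block; fewer than 3 usable
    anchors flags the block low-confidence."""
    flagged = set(flagged)
    pairs: list[KsPair] = []
    for p in block.anchors:
        a, b = p.gene_a.gene_id, p.gene_b.gene_id
        if a in flagged or b in flagged:
            continue
        sa, sb = cds_a.get(a), cds_b.get(b)
        if sa is None or sb is None:
            continue
        if len(sa) != len(sb):
            sa, sb = align_cds(sa, sb)
        pairs.append(ng86_pair(sa, sb, a, b))
    usable = [p.ks for p in pairs if not p.saturated_s and not math.isnan(p.ks)]
    med = float(np.median(usable)) if usable else float("nan")
    return BlockKsSummary(block.block_id, med, pairs, len(usable),
                          low_confidence=len(usable) < 3)


@dataclass
class KsPeakModel:
    """Gaussian mixture on log-Ks; components ordered by mean."""

    components: list[tuple[float, float, float]]  # (mean log-Ks, sd, weight)
    n_components: int
    bic: float
    n_values: int

    @property
    def peak_ks(self) -> list[float]:
        return [math.exp(m) for m, _, _ in self.components]

    @property
    def weights(self) -> list[float]:
        return [w for _, _, w in self.components]

    def dominant_peak(self) -> float:
        m, _, _ = max(self.components, key=lambda c: c[2])
        return math.exp(m)

    def primary_peak(self, min_weight: float = 0.10) -> float:
        """Smallest-Ks component with non-trivial weight. For an ortholog
        distribution this is the speciation peak: cross-species pairs can be
        older than the split (paleo-homeologs) but not younger."""
        eligible = [c for c in self.components if c[2] >= min_weight]
        if not eligible:
            eligible = self.components
        return math.exp(min(c[0] for c in eligible))

    def to_dict(self) -> dict:
        return {
            "components": [list(c) for c in self.components],
            "n_components": self.n_components,
            "bic": self.bic,
            "n_values": self.n_values,
            "peak_ks": self.peak_ks,
        }


def fit_ks_peaks(ks_values: Sequence[float], max_components: int = 4,
                 ks_range: tuple[float, float] = (0.01, 3.0),
                 seed: int = 0, min_values: int = 50) -> KsPeakModel:
    """Fit a Gaussian mixture to log-Ks and select the component count by
    minimum BIC over 1..max_components (ties to fewer components)."""
    x = np.asarray(ks_values, dtype=float)
    x = x[np.isfinite(x) & (x >= ks_range[0]) & (x <= ks_range[1])]
    if x.size < min_values:
        raise ValueError(
            f"need >= {min_values} non-saturated Ks values in range, got {x.size}"
        )
    X = np.log(x).reshape(-1, 1)
    best: GaussianMixture | None = None
    best_bic = math.inf
    best_n = 0
    for n in range(1, max_components + 1):
        gm = GaussianMixture(n_components=n, covariance_type="full",
                             random_state=seed, n_init=3, reg_covar=1e-4,
                             max_iter=500)
        gm.fit(X)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best, best_bic, best_n = gm, bic, n
    assert best is not None
    comps = sorted(
        (float(best.means_[i, 0]), float(np.sqrt(best.covariances_[i, 0, 0])),
         float(best.weights_[i]))
        for i in range(best_n)
    )
    return KsPeakModel(components=comps, n_components=best_n,
                       bic=float(best_bic), n_values=int(x.size))


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------

@dataclass
class DatingParams:
    """Strict-clock conversion between Ks and absolute time."""

    clock_rate: float  # synonymous substitutions per site per year

    def __post_init__(self) -> None:
        if self.clock_rate <= 0:
            raise ValueError("clock_rate must be positive")


def ks_to_time(ks: float, params: DatingParams) -> float:
    """Divergence time T = Ks / (2r) under a strict synonymous clock."""
    if math.isnan(ks):
        raise ValueError("cannot date a saturated Ks value")
    return ks / (2.0 * params.clock_rate)


def _clade_lookup(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    out = {}
    for node in tree.preorder_node_iter():
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        out[tips] = node
    return out


def classify_wg_events(
    paralog_models: Mapping[str, KsPeakModel],
    ortholog_models: Mapping[tuple[str, str] | frozenset, KsPeakModel],
    tree: str | dendropy.Tree,
    min_peak_sep: float = 0.02,
    match_log_tol: float = 0.25,
    min_weight: float = 0.10,
    depth_tracks: Mapping[str, tuple[Sequence[float], Sequence[int]]] | None = None,
) -> pd.DataFrame:
    """Assign paralog Ks peaks to tree branches and order them against
    speciation.

    Peaks from different species agreeing within ``match_log_tol`` in log-Ks
    are clustered; a cluster whose species set matches a clade is placed on
    that clade's stem branch (terminal branch for singletons). The event is
    ordered after the relevant speciation when its peak Ks is smaller than
    the ortholog peak between the clade and its sister (``indistinguishable``
    below ``min_peak_sep``). Multiplicity is the modal syntenic depth of
    pairs near the peak when depth tracks are supplied.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    clades = _clade_lookup(tree)
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ortho = {frozenset(k): v for k, v in ortholog_models.items()}

    peaks = []
    for sp in sorted(paralog_models):
        for mean, sd, w in paralog_models[sp].components:
            if w >= min_weight:
                peaks.append((mean, sp))
    peaks.sort()

    clusters: list[list[tuple[float, str]]] = []
    for mean, sp in peaks:
        if clusters and mean - np.mean([m for m, _ in clusters[-1]]) <= match_log_tol:
            clusters[-1].append((mean, sp))
        else:
            clusters.append([(mean, sp)])

    rows = []
    for cl in clusters:
        species = frozenset(sp for _, sp in cl)
        peak = float(math.exp(np.mean([m for m, _ in cl])))
        status = "ok"
        branch = "+".join(sorted(species))
        if species not in clades:
            status = "unresolved"
            order = "unresolved"
            mult = None
        else:
            node = clades[species]
            if species == all_tips:
                order = "n/a"  # no outgroup inside the tree to order against
            else:
                parent = node.parent_node
                sisters = frozenset(
                    l.taxon.label for l in parent.leaf_iter()
                ) - species
                ortho_peak = None
                for a in sorted(species):
                    for b in sorted(sisters):
                        m = ortho.get(frozenset((a, b)))
                        if m is not None:
                            ortho_peak = m.primary_peak(min_weight)
                            break
                    if ortho_peak is not None:
                        break
                if ortho_peak is None:
                    order = "unknown"
                elif abs(peak - ortho_peak) < min_peak_sep:
                    order = "indistinguishable"
                elif peak < ortho_peak:
                    order = "after_speciation"
                else:
                    order = "before_speciation"
            mult = None
            if depth_tracks is not None:
                depths: list[int] = []
                lo, hi = peak * math.exp(-match_log_tol), peak * math.exp(match_log_tol)
                for sp in sorted(species):
                    if sp not in depth_tracks:
                        continue
                    ks_arr, d_arr = depth_tracks[sp]
                    for kv, dv in zip(ks_arr, d_arr):
                        if lo <= kv <= hi:
                            depths.append(int(dv))
                if depths:
                    vals, counts = np.unique(depths, return_counts=True)
                    mult = int(vals[np.argmax(counts)])
        rows.append({
            "peak_ks": round(peak, 4),
            "species": "+".join(sorted(species)),
            "branch": branch,
            "n_species": len(species),
            "order_vs_speciation": order,
            "multiplicity": mult,
            "status": status,
        })
    return pd.DataFrame(rows)


def write_peak_models_json(models: Mapping, path: str | Path) -> None:
    def key(k):
        return "+".join(sorted(k)) if isinstance(k, (tuple, frozenset)) else str(k)

    payload = {key(k): m.to_dict() for k, m in models.items()}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
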