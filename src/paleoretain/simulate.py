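"""Genome-evolution simulator with a ground-truth event log.

The simulator evolves a single-copy ancestor along a small species tree,
applying whole-genome multiplications, biased fractionation, tandem
duplications, inversions/translocations, targeted gene losses, and coding-
sequence divergence. Every event is appended to an :class:`EventLog` so that
downstream inference (synteny depth, Ks peaks, retained regions, loss
tracing) can be scored against known truth.

Coding sequences use a restricted codon alphabet: the six fourfold-degenerate
codon families Val (GTN), Ser (TCN), Pro (CCN), Thr (ACN), Ala (GCN) and
Gly (GGN). Under this alphabet every codon carries exactly one synonymous
site (the third position, where substitution is a 4-state Jukes-Cantor
process) and two nonsynonymous sites, so the expected pairwise Ks of two
sequences separated by total branch time ``t`` is exactly ``syn_rate * t``
and Nei-Gojobori counting with the Jukes-Cantor correction is a consistent
estimator of it. Amino-acid-changing events move between codon families that
differ by a single first- or second-position nucleotide, so no stop codon can
ever arise.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable, Sequence

import dendropy
import numpy as np

from .core_model import (
    AnnotatedGenome,
    FamilyTable,
    Gene,
    write_cds_fasta,
    write_family_tsv,
    write_genome_gff3,
    write_repeats_bed,
)

__all__ = [
    "SimParams",
    "Event",
    "EventLog",
    "build_ancestor",
    "apply_wg_multiplication",
    "apply_fractionation",
    "apply_tandem_duplications",
    "apply_rearrangement",
    "apply_targeted_loss",
    "evolve_cds",
    "simulate_repeats",
    "simulate_dataset",
    "write_dataset",
    "replay_tip",
    "copy_genome",
    "encode_cds",
    "decode_cds",
    "asteraceae_trio",
]

# Fourfold-degenerate codon-family prefixes (first two codon positions).
PREFIXES = ["GT", "TC", "CC", "AC", "GC", "GG"]
# Single-nucleotide moves between prefixes (symmetric adjacency).
PREFIX_NEIGHBORS: dict[int, list[int]] = {
    0: [4, 5],          # GT <-> GC, GG
    1: [2, 3, 4],       # TC <-> CC, AC, GC
    2: [1, 3, 4],       # CC <-> TC, AC, GC
    3: [1, 2, 4],       # AC <-> TC, CC, GC
    4: [1, 2, 3, 0, 5], # GC <-> TC, CC, AC, GT, GG
    5: [4, 0],          # GG <-> GC, GT
}
NUCS = "ACGT"


def encode_cds(seq: str) -> np.ndarray:
    """Encode a CDS over the simulator's codon alphabet as an (L, 2) array
    of (prefix index, third-position nucleotide index)."""
    if len(seq) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    out = np.empty((len(seq) // 3, 2), dtype=np.int8)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        try:
            out[i // 3, 0] = PREFIXES.index(codon[:2])
        except ValueError as exc:
            raise ValueError(f"codon {codon} outside simulator alphabet") from exc
        out[i // 3, 1] = NUCS.index(codon[2])
    return out


def decode_cds(arr: np.ndarray) -> str:
    return "".join(PREFIXES[p] + NUCS[t] for p, t in arr)


def _as_array(cds_entry: str | np.ndarray) -> np.ndarray:
    return cds_entry if isinstance(cds_entry, np.ndarray) else encode_cds(cds_entry)


@dataclass
class SimParams:
    """Generative parameters for the simulated evolutionary scenario.

    Rates are per unit branch time (interpreted as million years in the
    canonical scenario). ``syn_rate`` is the synonymous substitution rate per
    synonymous site, so a pair of lineages separated for time T attains true
    Ks = 2 * syn_rate * T. ``retention_bias`` multiplies the per-copy
    post-polyploidy survival probability for genes carrying a label;
    ``retained_run_frac`` designates runs of consecutive ancestral genes where
    all polyploidy copies survive fractionation (dosage-sensitive clusters),
    and repeat density is depleted around them by ``repeat_depletion``.
    """

    seed: int = 0
    n_ancestral_genes: int = 400
    n_chromosomes: int = 4
    cds_codons: int = 300
    wg_multiplicity: int = 3
    retention_prob: float = 0.5
    retention_bias: dict[str, float] = field(
        default_factory=lambda: {"cellwall": 1.3, "fattyacid": 1.6}
    )
    retained_run_frac: float = 0.15
    retained_run_len: tuple[int, int] = (30, 60)
    tandem_rate: float = 0.02
    inversion_sizes: tuple[int, int] = (20, 30)
    syn_rate: float = 5e-3
    nonsyn_factor: float = 0.2
    label_weights: dict[str, float] = field(
        default_factory=lambda: {
            "fattyacid": 0.10,
            "cellwall": 0.10,
            "nitrogen": 0.05,
            "other": 0.75,
        }
    )
    gene_span: int = 2400
    gene_spacing: int = 12000
    repeat_base_frac: float = 0.55
    repeat_depletion: float = 0.5
    repeat_family_mix: dict[str, float] = field(
        default_factory=lambda: {"LTR_RT": 0.7, "DNA_TE": 0.2, "LINE": 0.1}
    )
    stem_length: float = 75.0
    events: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention_prob <= 1.0:
            raise ValueError("retention_prob must be in [0, 1]")
        if self.wg_multiplicity < 2:
            raise ValueError("wg_multiplicity must be >= 2")
        if self.inversion_sizes[0] < 2:
            raise ValueError("inversion sizes must be >= 2")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class Event:
    type: str
    branch: str
    time: float
    payload: dict[str, Any] = field(default_factory=dict)
    seq: int = 0

    def tips(self) -> set[str]:
        return set(self.branch.split("+"))


class EventLog:
    """Ordered ground-truth record of simulated events."""

    def __init__(self) -> None:
        self.events: list[Event] = []
        self._seq = 0

    def add(self, type: str, branch: str, time: float, **payload: Any) -> Event:
        ev = Event(type=type, branch=branch, time=time, payload=payload, seq=self._seq)
        self._seq += 1
        self.events.append(ev)
        return ev

    def of_type(self, *types: str) -> list[Event]:
        return [e for e in self.events if e.type in types]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps([asdict(e) for e in self.events], indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "EventLog":
        log = cls()
        for d in json.loads(text):
            log.events.append(Event(**d))
        log._seq = len(log.events)
        return log


def copy_genome(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Deep copy that avoids generic deepcopy overhead on CDS arrays."""
    g2 = AnnotatedGenome(species=genome.species)
    g2.chromosomes = list(genome.chromosomes)
    g2.genes = {
        c: [copy.copy(g) for g in glist] for c, glist in genome.genes.items()
    }
    for glist in g2.genes.values():
        for g in glist:
            g.labels = set(g.labels)
    g2.repeats = list(genome.repeats)
    g2.cds = {
        k: (v.copy() if isinstance(v, np.ndarray) else v)
        for k, v in genome.cds.items()
    }
    g2.flagged_cds = set(genome.flagged_cds)
    g2.retained_genes = set(genome.retained_genes)
    return g2


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------

def build_ancestor(params: SimParams, species: str = "ancestor",
                   rng: np.random.Generator | None = None) -> AnnotatedGenome:
    """Single-copy ancestral genome: one gene per family, random strands,
    labels drawn from the label vocabulary, random in-frame CDS."""
    if params.n_ancestral_genes < params.n_chromosomes:
        raise ValueError("need at least one gene per chromosome")
    rng = rng if rng is not None else params.rng()
    genome = AnnotatedGenome(species=species)

    labels = sorted(params.label_weights)
    weights = np.array([params.label_weights[l] for l in labels], dtype=float)
    weights = weights / weights.sum()

    n, k = params.n_ancestral_genes, params.n_chromosomes
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    margin = params.gene_spacing
    gidx = 0
    for ci, size in enumerate(sizes):
        chrom = f"chr{ci + 1}"
        length = margin + size * params.gene_spacing + margin
        genome.chromosomes.append((chrom, length))
        glist: list[Gene] = []
        for j in range(size):
            start = margin + j * params.gene_spacing + 1
            label = labels[int(rng.choice(len(labels), p=weights))]
            gene = Gene(
                gene_id=f"g{gidx:05d}",
                species=species,
                chrom=chrom,
                start=start,
                end=start + params.gene_span - 1,
                strand="+" if rng.random() < 0.5 else "-",
                family_id=f"F{gidx:05d}",
                rank=j,
                labels={label},
            )
            glist.append(gene)
            arr = np.empty((params.cds_codons, 2), dtype=np.int8)
            arr[:, 0] = rng.integers(0, len(PREFIXES), params.cds_codons)
            arr[:, 1] = rng.integers(0, 4, params.cds_codons)
            genome.cds[gene.gene_id] = arr
            gidx += 1
        genome.genes[chrom] = glist

    _designate_retained_runs(genome, params, rng)
    return genome


def _designate_retained_runs(genome: AnnotatedGenome, params: SimParams,
                             rng: np.random.Generator) -> None:
    if params.retained_run_frac <= 0:
        return
    lo, hi = params.retained_run_len
    for chrom in genome.chrom_names():
        glist = genome.genes[chrom]
        quota = int(round(params.retained_run_frac * len(glist)))
        taken = np.zeros(len(glist), dtype=bool)
        placed = 0
        attempts = 0
        while placed < quota and attempts < 200:
            attempts += 1
            run_len = int(rng.integers(lo, hi + 1))
            if run_len > len(glist):
                break
            start = int(rng.integers(0, len(glist) - run_len + 1))
            if taken[start : start + run_len].any():
                continue
            taken[start : start + run_len] = True
            for g in glist[start : start + run_len]:
                genome.retained_genes.add(g.gene_id)
            placed += run_len


# ---------------------------------------------------------------------------
# Structural events
# ---------------------------------------------------------------------------

def apply_wg_multiplication(genome: AnnotatedGenome, multiplicity: int,
                            log: EventLog, branch: str = "", time: float = 0.0,
                            suffixes: list[str] | None = None
                            ) -> AnnotatedGenome:
    """Whole-genome multiplication: every chromosome copied (multiplicity-1)
    extra times; copies carry a ``.k`` suffix chosen to avoid collision with
    names left by earlier multiplications."""
    if multiplicity < 2:
        raise ValueError("multiplicity must be >= 2")
    base_chroms = list(genome.chromosomes)
    if suffixes is None:
        existing = set(genome.chrom_names()) | set(genome.cds)
        offset = 1
        while True:
            suffixes = [f".{k}" for k in range(offset, offset + multiplicity - 1)]
            clash = any(f"{name}{suf}" in existing
                        for name, _ in base_chroms for suf in suffixes)
            if not clash:
                break
            offset += 1
    for name, length in base_chroms:
        for k, suffix in enumerate(suffixes, start=1):
            new_chrom = f"{name}{suffix}"
            new_list: list[Gene] = []
            for g in genome.genes[name]:
                g2 = copy.copy(g)
                g2.labels = set(g.labels)
                g2.gene_id = g.gene_id + suffix
                g2.chrom = new_chrom
                new_list.append(g2)
                genome.cds[g2.gene_id] = _as_array(genome.cds[g.gene_id]).copy()
                if g.gene_id in genome.retained_genes:
                    genome.retained_genes.add(g2.gene_id)
            genome.chromosomes.append((new_chrom, length))
            genome.genes[new_chrom] = new_list
    log.add("wg_multiplication", branch, time,
            multiplicity=multiplicity,
            chroms=[c for c, _ in base_chroms],
            suffixes=suffixes)
    return genome


def apply_fractionation(genome: AnnotatedGenome, params: SimParams, log: EventLog,
                        branch: str = "", time: float = 0.0,
                        rng: np.random.Generator | None = None,
                        respect_retained_runs: bool = True) -> AnnotatedGenome:
    """Post-polyploidy copy loss. One copy per family always survives; every
    additional copy survives independently with probability
    ``retention_prob * retention_bias[label]`` (capped at 1). Genes inside
    designated retained runs always survive when
    ``respect_retained_runs`` is set."""
    rng = rng if rng is not None else params.rng()
    deleted: list[str] = []
    fams = genome.families()
    for fam in sorted(fams):
        copies = sorted(fams[fam], key=lambda g: g.gene_id)
        if len(copies) < 2:
            continue
        keeper = int(rng.integers(0, len(copies)))
        for i, g in enumerate(copies):
            if i == keeper:
                continue
            if respect_retained_runs and g.gene_id in genome.retained_genes:
                continue
            bias = max((params.retention_bias.get(l, 1.0) for l in g.labels),
                       default=1.0)
            p_eff = min(1.0, params.retention_prob * bias)
            if rng.random() >= p_eff:
                deleted.append(g.gene_id)
    _delete_genes(genome, deleted)
    log.add("fractionation_loss", branch, time, deleted=sorted(deleted))
    return genome


def _delete_genes(genome: AnnotatedGenome, gene_ids: Iterable[str]) -> None:
    doomed = set(gene_ids)
    if not doomed:
        return
    for chrom in list(genome.genes):
        genome.genes[chrom] = [g for g in genome.genes[chrom] if g.gene_id not in doomed]
    for gid in doomed:
        genome.cds.pop(gid, None)
        genome.retained_genes.discard(gid)
    genome.recompute_ranks()


def apply_tandem_duplications(genome: AnnotatedGenome, params: SimParams,
                              log: EventLog, branch: str = "", time: float = 0.0,
                              rng: np.random.Generator | None = None,
                              rate: float | None = None) -> AnnotatedGenome:
    """Duplicate sampled genes immediately adjacent to their parent (same
    chromosome, strand and family). Expected duplications per gene = rate."""
    rng = rng if rng is not None else params.rng()
    rate = params.tandem_rate if rate is None else rate
    if rate < 0:
        raise ValueError("tandem rate must be >= 0")
    new_records = []
    for chrom in genome.chrom_names():
        for g in list(genome.genes[chrom]):
            n_dup = int(rng.poisson(rate))
            prev = g
            for d in range(n_dup):
                new_id = f"{g.gene_id}.t{d + 1}"
                start = prev.end + 10
                g2 = copy.copy(g)
                g2.labels = set(g.labels)
                g2.gene_id = new_id
                g2.start = start
                g2.end = start + g.length - 1
                genome.genes[chrom].append(g2)
                genome.cds[new_id] = _as_array(genome.cds[g.gene_id]).copy()
                if g.gene_id in genome.retained_genes:
                    genome.retained_genes.add(new_id)
                if g2.end > genome.chrom_length(chrom):
                    genome.set_chrom_length(chrom, g2.end + params.gene_spacing)
                new_records.append(
                    {"parent": g.gene_id, "copy": new_id, "chrom": chrom,
                     "start": g2.start, "end": g2.end, "strand": g2.strand}
                )
                prev = g2
    genome.recompute_ranks()
    log.add("tandem_duplication", branch, time, copies=new_records)
    return genome


def apply_rearrangement(genome: AnnotatedGenome, kind: str, interval,
                        log: EventLog, branch: str = "", time: float = 0.0
                        ) -> AnnotatedGenome:
    """Apply an inversion, micro-inversion, or reciprocal translocation.

    For (micro-)inversions ``interval`` is ``(chrom, rank_start, rank_end)``
    inclusive; gene order is reversed, base-pair positions are mirrored within
    the inverted segment, and all strands inside flip. For translocations
    ``interval`` is ``((chromA, rankA), (chromB, rankB))``: the tails starting
    at those ranks are exchanged.
    """
    if kind in {"inversion", "micro_inversion"}:
        chrom, rs, re_ = interval
        glist = genome.genes[chrom]
        if not (0 <= rs <= re_ < len(glist)):
            raise ValueError(f"inversion interval {interval} crosses chromosome end")
        lo = glist[rs].start
        hi = glist[re_].end
        segment = glist[rs : re_ + 1]
        for g in segment:
            s, e = g.start, g.end
            g.start = lo + hi - e
            g.end = lo + hi - s
            g.strand = "+" if g.strand == "-" else "-"
        genome.genes[chrom] = glist[:rs] + list(reversed(segment)) + glist[re_ + 1 :]
        genome.recompute_ranks()
        log.add(kind, branch, time, chrom=chrom, rank_start=rs, rank_end=re_,
                n_genes=re_ - rs + 1)
    elif kind == "translocation":
        (ca, ra), (cb, rb) = interval
        la, lb = genome.genes[ca], genome.genes[cb]
        if not (0 < ra < len(la)) or not (0 < rb < len(lb)):
            raise ValueError("translocation breakpoints must be interior ranks")
        bp_a, bp_b = la[ra].start, lb[rb].start
        tail_a, tail_b = la[ra:], lb[rb:]
        for g in tail_a:
            g.chrom = cb
            g.start, g.end = bp_b + (g.start - bp_a), bp_b + (g.end - bp_a)
        for g in tail_b:
            g.chrom = ca
            g.start, g.end = bp_a + (g.start - bp_b), bp_a + (g.end - bp_b)
        genome.genes[ca] = la[:ra] + tail_b
        genome.genes[cb] = lb[:rb] + tail_a
        spacing = 12000
        for c in (ca, cb):
            tail = max((g.end for g in genome.genes[c]), default=1)
            genome.set_chrom_length(c, max(genome.chrom_length(c), tail + spacing))
        genome.recompute_ranks()
        log.add(kind, branch, time, chrom_a=ca, rank_a=ra, chrom_b=cb, rank_b=rb)
    else:
        raise ValueError(f"unknown rearrangement kind {kind!r}")
    return genome


def apply_targeted_loss(genome: AnnotatedGenome, family_id: str, log: EventLog,
                        branch: str = "", time: float = 0.0,
                        rng: np.random.Generator | None = None,
                        at_inversion_border: bool = False,
                        inversion_size: int | None = None,
                        size_range: tuple[int, int] = (20, 30)) -> AnnotatedGenome:
    """Delete one copy of ``family_id``. With ``at_inversion_border`` a
    micro-inversion whose boundary gene is the target is applied first, then
    the target is deleted — leaving the loss scar at the inversion edge."""
    rng = rng if rng is not None else np.random.default_rng(0)
    fams = genome.families()
    if family_id not in fams:
        raise KeyError(f"family {family_id} absent from genome")
    copies = sorted(fams[family_id], key=lambda g: g.gene_id)
    target = copies[int(rng.integers(0, len(copies)))]
    chrom = target.chrom
    if at_inversion_border:
        glist = genome.genes[chrom]
        r = target.rank
        L = inversion_size if inversion_size is not None else int(
            rng.integers(size_range[0], size_range[1] + 1)
        )
        if r + L - 1 < len(glist):
            rs, re_ = r, r + L - 1
        elif r - L + 1 >= 0:
            rs, re_ = r - L + 1, r
        else:
            raise ValueError("chromosome too short for requested micro-inversion")
        apply_rearrangement(genome, "micro_inversion", (chrom, rs, re_), log,
                            branch, time)
    gene = genome.gene_index()[target.gene_id]
    log.add("targeted_gene_loss", branch, time, gene_id=gene.gene_id,
            family_id=family_id, chrom=gene.chrom, rank=gene.rank,
            at_inversion_border=at_inversion_border)
    _delete_genes(genome, [gene.gene_id])
    return genome


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _jc_evolve_third(third: np.ndarray, counts: np.ndarray,
                     rng: np.random.Generator) -> None:
    """Apply `counts[i]` sequential uniform-to-other-3 substitutions at each
    third-position site, sampling the final state exactly: after c steps the
    chain stays at its origin with probability 1/4 + (3/4)(-1/3)^c."""
    hit = counts > 0
    if not hit.any():
        return
    c = counts[hit].astype(float)
    p_same = 0.25 + 0.75 * np.power(-1.0 / 3.0, c)
    move = rng.random(c.size) >= p_same
    idx = np.where(hit)[0][move]
    third[idx] = (third[idx] + rng.integers(1, 4, idx.size)) % 4


def evolve_cds(genome: AnnotatedGenome, branch_time: float, syn_rate: float,
               log: EventLog, rng: np.random.Generator | None = None,
               nonsyn_rate: float | None = None, branch: str = "") -> AnnotatedGenome:
    """Poisson sequence evolution over ``branch_time``.

    Synonymous substitutions hit third positions at ``syn_rate`` per
    synonymous site (one per codon); amino-acid changes move the codon-family
    prefix at ``nonsyn_rate`` per nonsynonymous site (two per codon).
    """
    if branch_time < 0:
        raise ValueError("branch_time must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(0)
    if nonsyn_rate is None:
        nonsyn_rate = 0.0
    total_syn = 0
    total_nonsyn = 0
    if branch_time > 0:
        for gid in sorted(genome.cds):
            arr = _as_array(genome.cds[gid])
            genome.cds[gid] = arr
            L = arr.shape[0]
            n_syn = int(rng.poisson(syn_rate * branch_time * L))
            if n_syn:
                pos = rng.integers(0, L, n_syn)
                counts = np.bincount(pos, minlength=L)
                _jc_evolve_third(arr[:, 1], counts, rng)
                total_syn += n_syn
            n_non = int(rng.poisson(nonsyn_rate * branch_time * 2 * L))
            for _ in range(n_non):
                p = int(rng.integers(0, L))
                nb = PREFIX_NEIGHBORS[int(arr[p, 0])]
                arr[p, 0] = nb[int(rng.integers(0, len(nb)))]
            total_nonsyn += n_non
    log.add("cds_evolution", branch, 0.0, branch_time=branch_time,
            syn_rate=syn_rate, nonsyn_rate=nonsyn_rate,
            syn_events=total_syn, nonsyn_events=total_nonsyn)
    return genome


def finalize_cds(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Convert internal codon arrays to nucleotide strings."""
    genome.cds = {
        gid: (decode_cds(v) if isinstance(v, np.ndarray) else v)
        for gid, v in genome.cds.items()
    }
    return genome


# ---------------------------------------------------------------------------
# Repeats
# ---------------------------------------------------------------------------

def simulate_repeats(genome: AnnotatedGenome, params: SimParams,
                     rng: np.random.Generator) -> None:
    """Fill intergenic gaps with repeat intervals.

    Each gap receives repeat bp totalling roughly ``repeat_base_frac`` of its
    length, split across repeat families; the LTR retrotransposon share is
    multiplied by ``repeat_depletion`` when the flanking genes belong to a
    designated retained run (emulating preferential LTR-RT removal there).
    """
    genome.repeats = []
    fams = sorted(params.repeat_family_mix)
    mix = np.array([params.repeat_family_mix[f] for f in fams], dtype=float)
    mix = mix / mix.sum()
    for chrom, length in genome.chromosomes:
        glist = genome.genes.get(chrom, [])
        bounds: list[tuple[int, int, bool]] = []
        prev_end = 0
        prev_retained = False
        for g in glist:
            flank_retained = prev_retained and (g.gene_id in genome.retained_genes)
            if prev_end == 0:
                flank_retained = g.gene_id in genome.retained_genes
            bounds.append((prev_end + 1, g.start - 1, flank_retained))
            prev_end = g.end
            prev_retained = g.gene_id in genome.retained_genes
        bounds.append((prev_end + 1, length, prev_retained))
        for lo, hi, retained in bounds:
            gap = hi - lo + 1
            if gap < 300:
                continue
            cursor = lo
            for f, frac in zip(fams, mix):
                share = params.repeat_base_frac * frac
                if retained and f == "LTR_RT":
                    # preferential removal of whole retrotransposon elements
                    if rng.random() >= params.repeat_depletion:
                        continue
                rep_len = int(gap * share * rng.uniform(0.85, 1.15))
                if rep_len < 50 or cursor + rep_len - 1 > hi:
                    continue
                genome.repeats.append((chrom, cursor, cursor + rep_len - 1, f))
                cursor += rep_len + 1
    genome.repeats.sort()


# ---------------------------------------------------------------------------
# Tree-driven simulation
# ---------------------------------------------------------------------------

def _branch_key(node: dendropy.Node) -> str:
    tips = sorted(l.taxon.label for l in node.leaf_iter())
    return "+".join(tips)


def _pick_family_for_loss(genome: AnnotatedGenome, label: str,
                          rng: np.random.Generator,
                          min_chrom_genes: int = 35) -> str:
    """Pick (via the run's RNG) a single-copy family carrying ``label`` on a
    chromosome long enough to host a micro-inversion, away from the ends so
    flanking anchors exist."""
    fams = genome.families()
    candidates: list[str] = []
    fallback: list[str] = []
    for fam in sorted(fams):
        copies = fams[fam]
        if len(copies) != 1:
            continue
        g = copies[0]
        n = len(genome.genes[g.chrom])
        if n >= min_chrom_genes and 2 <= g.rank <= n - 3:
            (candidates if label in g.labels else fallback).append(fam)
    if not candidates:
        candidates = fallback  # no single-copy family carries the label
    if not candidates:
        raise ValueError("no suitable single-copy family for targeted loss")
    return candidates[int(rng.integers(0, len(candidates)))]


def _apply_branch_events(genome: AnnotatedGenome, events: list[dict[str, Any]],
                         t_top: float, t_bottom: float, branch: str,
                         params: SimParams, log: EventLog,
                         rng: np.random.Generator) -> None:
    """Evolve along one branch from age t_top (older) down to t_bottom,
    interleaving configured events at their stated ages."""
    evs = sorted([e for e in events], key=lambda e: -float(e.get("time", t_top)))
    cursor = t_top
    nonsyn = params.nonsyn_factor * params.syn_rate
    for ev in evs:
        t_ev = float(ev.get("time", cursor))
        t_ev = min(max(t_ev, t_bottom), t_top)
        if cursor - t_ev > 0:
            evolve_cds(genome, cursor - t_ev, params.syn_rate, log, rng,
                       nonsyn_rate=nonsyn, branch=branch)
        cursor = t_ev
        etype = ev["type"]
        if etype == "wg_multiplication":
            apply_wg_multiplication(genome, int(ev.get("multiplicity",
                                                       params.wg_multiplicity)),
                                    log, branch, t_ev)
            if ev.get("fractionation", True):
                apply_fractionation(genome, params, log, branch, t_ev, rng)
        elif etype == "fractionation":
            apply_fractionation(genome, params, log, branch, t_ev, rng)
        elif etype == "tandem_duplication":
            apply_tandem_duplications(genome, params, log, branch, t_ev, rng,
                                      rate=ev.get("rate"))
        elif etype in {"inversion", "micro_inversion", "translocation"}:
            apply_rearrangement(genome, etype, ev["interval"], log, branch, t_ev)
        elif etype == "targeted_gene_loss":
            fam = ev.get("family_id")
            if fam is None:
                fam = _pick_family_for_loss(genome, ev.get("label", "nitrogen"), rng)
            apply_targeted_loss(
                genome, fam, log, branch, t_ev, rng,
                at_inversion_border=bool(ev.get("at_inversion_border", False)),
                inversion_size=ev.get("inversion_size"),
                size_range=params.inversion_sizes)
        else:
            raise ValueError(f"unknown event type {etype!r}")
    if cursor - t_bottom > 0:
        evolve_cds(genome, cursor - t_bottom, params.syn_rate, log, rng,
                   nonsyn_rate=nonsyn, branch=branch)


def simulate_dataset(tree: str | dendropy.Tree, params: SimParams,
                     out_dir: str | Path | None = None
                     ) -> tuple[dict[str, AnnotatedGenome], EventLog]:
    """Evolve the ancestor along ``tree`` applying the events configured in
    ``params.events`` and return tip genomes plus the truth log.

    Branch lengths are in the same time unit as event ages and rates. Events
    reference branches by the sorted '+'-joined tip labels of their clade;
    the branch above the root is addressed as ``"stem"`` and has length
    ``params.stem_length``. Polytomies are rejected.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) != 2:
            raise ValueError("tree must be strictly bifurcating (no polytomies)")

    # node ages: tips at 0, root at max root-to-tip path length
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        el = node.edge.length or 0.0
        depths[node] = (depths.get(node.parent_node, 0.0) + el) if node.parent_node else 0.0
    root = tree.seed_node
    root_age = max(depths[l] for l in tree.leaf_node_iter())
    ages = {n: root_age - depths[n] for n in tree.preorder_node_iter()}

    rng = params.rng()
    log = EventLog()
    events_by_branch: dict[str, list[dict[str, Any]]] = {}
    for ev in params.events:
        events_by_branch.setdefault(ev["branch"], []).append(ev)

    ancestor = build_ancestor(params, rng=rng)
    log.add("ancestor", "stem", root_age + params.stem_length,
            n_genes=ancestor.n_genes,
            retained_runs=sorted(ancestor.retained_genes))

    state = copy_genome(ancestor)
    _apply_branch_events(state, events_by_branch.get("stem", []),
                         root_age + params.stem_length, root_age, "stem",
                         params, log, rng)

    tips: dict[str, AnnotatedGenome] = {}

    def descend(genome: AnnotatedGenome, node: dendropy.Node) -> None:
        if node.is_leaf():
            genome.species = node.taxon.label
            for g in genome.all_genes():
                g.species = genome.species
            simulate_repeats(genome, params, rng)
            finalize_cds(genome)
            tips[genome.species] = genome
            return
        log.add("speciation", _branch_key(node), ages[node],
                children=[_branch_key(c) for c in node.child_nodes()])
        for child in node.child_nodes():
            sub = copy_genome(genome)
            key = _branch_key(child)
            _apply_branch_events(sub, events_by_branch.get(key, []),
                                 ages[node], ages[child], key, params, log, rng)
            descend(sub, child)

    descend(state, root)

    if out_dir is not None:
        write_dataset(tips, log, out_dir)
    return tips, log


def write_dataset(genomes: dict[str, AnnotatedGenome], log: EventLog,
                  out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp in sorted(genomes):
        g = genomes[sp]
        write_genome_gff3(g, out / f"{sp}.gff3")
        write_cds_fasta(g, out / f"{sp}.cds.fa")
        write_repeats_bed(g.repeats, out / f"{sp}.repeats.bed")
    table = FamilyTable.from_genomes(genomes[sp] for sp in sorted(genomes))
    write_family_tsv(table, out / "families.tsv")
    log.to_json(out / "truth_log.json")


# ---------------------------------------------------------------------------
# Canonical scenario and replay
# ---------------------------------------------------------------------------

def asteraceae_trio(seed: int = 0, **overrides: Any) -> tuple[str, SimParams]:
    """Canonical three-taxon scenario: an outgroup carrying only an old
    whole-genome triplication, and two ingroups that share both the old
    triplication and a younger one dated shortly after their split from the
    outgroup, plus a targeted single-gene loss at a micro-inversion border on
    the ingroup stem and tandem bursts on the terminal branches.

    With the default clock (5e-3 synonymous substitutions per site per Myr)
    the old event at 150 Mya yields a paralog Ks peak near 1.5, the ingroup/
    outgroup split at 85 Mya an ortholog peak near 0.85, and the young event
    at 80 Mya a paralog peak near 0.80 confined to the ingroups.
    """
    tree = "((ingroupA:70.0,ingroupB:70.0):15.0,outgroup:85.0);"
    events = [
        {"branch": "stem", "type": "wg_multiplication", "time": 150.0,
         "multiplicity": 3},
        {"branch": "ingroupA+ingroupB", "type": "targeted_gene_loss",
         "time": 82.0, "label": "nitrogen", "at_inversion_border": True},
        {"branch": "ingroupA+ingroupB", "type": "wg_multiplication",
         "time": 80.0, "multiplicity": 3},
        {"branch": "ingroupA", "type": "tandem_duplication", "time": 35.0},
        {"branch": "ingroupB", "type": "tandem_duplication", "time": 35.0},
        {"branch": "outgroup", "type": "tandem_duplication", "time": 42.0},
    ]
    kwargs: dict[str, Any] = {"seed": seed, "stem_length": 75.0, "events": events}
    kwargs.update(overrides)
    return tree, SimParams(**kwargs)


def replay_tip(ancestor: AnnotatedGenome, log: EventLog, tip: str
               ) -> AnnotatedGenome:
    """Replay the structural events on the root-to-tip path against the
    ancestor, reproducing the tip's gene content, order, strands and
    coordinates (sequence substitutions are logged as counts, not replayed)."""
    genome = copy_genome(ancestor)
    path_events = [
        e for e in log.events
        if (e.branch == "stem" or tip in e.tips())
        and e.type in {"wg_multiplication", "fractionation_loss",
                       "tandem_duplication", "inversion", "micro_inversion",
                       "translocation", "targeted_gene_loss"}
    ]
    path_events.sort(key=lambda e: e.seq)
    silent = EventLog()
    for ev in path_events:
        p = ev.payload
        if ev.type == "wg_multiplication":
            apply_wg_multiplication(genome, p["multiplicity"], silent,
                                    suffixes=p["suffixes"])
        elif ev.type == "fractionation_loss":
            _delete_genes(genome, p["deleted"])
        elif ev.type == "tandem_duplication":
            for rec in p["copies"]:
                parent = genome.gene_index()[rec["parent"]]
                g2 = copy.copy(parent)
                g2.labels = set(parent.labels)
                g2.gene_id = rec["copy"]
                g2.start, g2.end = rec["start"], rec["end"]
                genome.genes[rec["chrom"]].append(g2)
                genome.cds[g2.gene_id] = _as_array(genome.cds[parent.gene_id]).copy()
                if g2.end > genome.chrom_length(rec["chrom"]):
                    genome.set_chrom_length(rec["chrom"], g2.end + 12000)
            genome.recompute_ranks()
        elif ev.type in {"inversion", "micro_inversion"}:
            apply_rearrangement(genome, ev.type,
                                (p["chrom"], p["rank_start"], p["rank_end"]),
                                silent)
        elif ev.type == "translocation":
            apply_rearrangement(genome, "translocation",
                                ((p["chrom_a"], p["rank_a"]),
                                 (p["chrom_b"], p["rank_b"])), silent)
        elif ev.type == "targeted_gene_loss":
            _delete_genes(genome, [p["gene_id"]])
    genome.species = tip
    for g in genome.all_genes():
        g.species = tip
    return genome
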