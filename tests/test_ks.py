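"""Ks/Ka estimation, codon-aware alignment, peak fitting, event rules.

The NG86 checks use an independently written brute-force implementation with
its own genetic-code table; the alignment check uses a quadratic-space Gotoh
dynamic program written here.
"""

import itertools
import math

import numpy as np
import pytest

import paleoretain.ks_evolution as ksmod
from paleoretain.ks_evolution import (
    DatingParams,
    KsPeakModel,
    align_cds,
    alignment_score,
    block_ks_summary,
    classify_wg_events,
    fit_ks_peaks,
    ks_to_time,
    ng86_pair,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_syn_sites(codon):
    s = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if GENETIC_CODE[mut] != "*" and GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                s += 1 / 3
    return s


def oracle_codon_diffs(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur, sd, nd = c1, 0.0, 0.0
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*" and step < len(order) - 1 and not allow_stops:
                return None
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur] and GENETIC_CODE[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [r for r in (walk(o, False) for o in itertools.permutations(diff))
             if r is not None]
    if not paths:
        paths = [walk(o, True) for o in itertools.permutations(diff)]
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def oracle_ng86(seq_a, seq_b):
    n = len(seq_a) // 3
    S = N = Sd = Nd = 0.0
    for i in range(n):
        ca, cb = seq_a[3 * i:3 * i + 3], seq_b[3 * i:3 * i + 3]
        S += (oracle_syn_sites(ca) + oracle_syn_sites(cb)) / 2
        N += 3 - (oracle_syn_sites(ca) + oracle_syn_sites(cb)) / 2
        sd, nd = oracle_codon_diffs(ca, cb)
        Sd += sd
        Nd += nd

    def jc(p):
        if p >= 0.75:
            return float("nan")
        return max(0.0, -0.75 * math.log(1 - 4 * p / 3))

    return S, N, Sd, Nd, jc(Sd / S), jc(Nd / N)


def oracle_gotoh_score(pa, pb, matrix, open_=-10.0, extend=-0.5):
    """Global affine-gap alignment score; a gap of length L costs
    |open| + (L-1)|extend| (end gaps penalized)."""
    n, m = len(pa), len(pb)
    NEG = -1e18
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in pb (pa aligned to -)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = matrix[pa[i - 1], pb[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend,
                          Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend,
                          X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


NONSTOP = [c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"]


def random_cds(rng, n_codons):
    return "".join(NONSTOP[i] for i in rng.integers(0, len(NONSTOP), n_codons))


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

class TestNG86:
    def test_identical_sequences(self):
        kp = ng86_pair("ATGGCTAAA", "ATGGCTAAA")
        assert kp.Sd == kp.Nd == 0 and kp.ks == 0 and kp.ka == 0

    def test_lysine_run_hand_computation(self):
        a = "AAA" * 100
        b = "AAA" * 98 + "AAG" + "AAG"
        kp = ng86_pair(a, b)
        assert kp.S == pytest.approx(100 / 3)
        assert kp.Sd == 2 and kp.Nd == 0
        assert kp.Sd / kp.S == pytest.approx(0.06)
        assert kp.ks == pytest.approx(0.0625, abs=1e-4)

    def test_matches_independent_oracle(self, rng):
        for _ in range(60):
            a = random_cds(rng, 30)
            b = random_cds(rng, 30)
            kp = ng86_pair(a, b)
            S, N, Sd, Nd, ks, ka = oracle_ng86(a, b)
            assert kp.S == pytest.approx(S, abs=1e-9)
            assert kp.Sd == pytest.approx(Sd, abs=1e-9)
            assert kp.Nd == pytest.approx(Nd, abs=1e-9)
            # flags can only disagree when p sits exactly on the 3/4 boundary
            if abs(Sd / S - 0.75) > 1e-9:
                assert kp.saturated_s == math.isnan(ks)
                if not kp.saturated_s:
                    assert kp.ks == pytest.approx(ks, abs=1e-9)
            if abs(Nd / N - 0.75) > 1e-9:
                assert kp.saturated_n == math.isnan(ka)
                if not kp.saturated_n:
                    assert kp.ka == pytest.approx(ka, abs=1e-9)

    def test_symmetric_in_arguments(self, rng):
        for _ in range(20):
            a, b = random_cds(rng, 20), random_cds(rng, 20)
            k1, k2 = ng86_pair(a, b), ng86_pair(b, a)
            for f in ("S", "N", "Sd", "Nd"):
                assert getattr(k1, f) == pytest.approx(getattr(k2, f))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ng86_pair("ATGATG", "ATG")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_pair("ATGTAAATG", "ATGATGATG")

    def test_shared_trailing_stop_stripped(self):
        kp = ng86_pair("ATGAAATAA", "ATGAAATGA")
        assert kp.S == pytest.approx(ng86_pair("ATGAAA", "ATGAAA").S)

    def test_saturation_flagged(self):
        # every third position differs: pS = 3 >> 3/4
        a = "GGT" * 50
        b = "GGA" * 50
        kp = ng86_pair(a, b)
        assert kp.saturated_s and math.isnan(kp.ks)


class TestAlignment:
    def test_identical_no_gaps(self):
        a = "ATGGCTGCTAAA"
        assert align_cds(a, a) == (a, a)

    def test_codon_deletion_removed(self):
        a = "ATGGCTCCTACTGAA"
        b = a[:6] + a[9:]  # drop third codon
        out_a, out_b = align_cds(a, b)
        assert len(out_a) == len(a) - 3 and out_a == out_b

    def test_score_matches_gotoh_oracle(self, rng):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        for _ in range(20):
            a = random_cds(rng, int(rng.integers(5, 15)))
            b = random_cds(rng, int(rng.integers(5, 15)))
            got = alignment_score(a, b)
            pa = "".join(GENETIC_CODE[a[i:i + 3]] for i in range(0, len(a), 3))
            pb = "".join(GENETIC_CODE[b[i:i + 3]] for i in range(0, len(b), 3))
            assert got == pytest.approx(oracle_gotoh_score(pa, pb, blosum))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_cds("", "ATG")


# ---------------------------------------------------------------------------
# Block summary
# ---------------------------------------------------------------------------

class TestBlockSummary:
    def _block(self, cds_pairs):
        from paleoretain.synteny import SyntenyBlock
        from conftest import anchors_from_ranks

        anchors = anchors_from_ranks([(i, i) for i in range(len(cds_pairs))])
        cds_a = {p.gene_a.gene_id: cds_pairs[i][0] for i, p in enumerate(anchors)}
        cds_b = {p.gene_b.gene_id: cds_pairs[i][1] for i, p in enumerate(anchors)}
        block = SyntenyBlock("B1", "A", "B", "chrA", "chrB", "same", 1.0, anchors)
        return block, cds_a, cds_b

    def test_median_of_uniform_values(self):
        base = "GGT" * 30
        var = "GGT" * 27 + "GGA" * 3  # same shift for every anchor
        block, ca, cb = self._block([(base, var)] * 3)
        s = block_ks_summary(block, ca, cb)
        expected = ng86_pair(base, var).ks
        assert s.median_ks == pytest.approx(expected)
        assert not s.low_confidence

    def test_median_and_saturated_exclusion(self):
        base = "GGT" * 40

        def shifted(k):  # k third-position changes
            return "GGA" * k + "GGT" * (40 - k)

        pairs = [(base, shifted(2)), (base, shifted(40)), (base, shifted(6))]
        block, ca, cb = self._block(pairs)
        s = block_ks_summary(block, ca, cb)
        k_lo = ng86_pair(base, shifted(2)).ks
        k_hi = ng86_pair(base, shifted(6)).ks
        assert s.n_usable == 2 and s.low_confidence
        assert s.median_ks == pytest.approx((k_lo + k_hi) / 2)


# ---------------------------------------------------------------------------
# Peak model and event classification
# ---------------------------------------------------------------------------

class TestPeakFitting:
    def test_single_tight_cluster(self):
        rng = np.random.default_rng(0)
        vals = 0.5 * np.exp(rng.normal(0, 0.02, 300))
        m = fit_ks_peaks(vals, seed=0)
        assert m.n_components == 1
        assert m.peak_ks[0] == pytest.approx(0.5, abs=0.02)

    def test_two_mode_recovery(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([
            0.8 * np.exp(rng.normal(0, 0.10, 1000)),
            1.6 * np.exp(rng.normal(0, 0.10, 1000)),
        ])
        m = fit_ks_peaks(vals, seed=1)
        assert m.n_components == 2
        assert m.peak_ks[0] == pytest.approx(0.8, abs=0.1)
        assert m.peak_ks[1] == pytest.approx(1.6, abs=0.1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        vals = np.exp(rng.normal(-0.3, 0.3, 500))
        m1 = fit_ks_peaks(vals, seed=7)
        m2 = fit_ks_peaks(vals, seed=7)
        assert m1.components == m2.components

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_ks_peaks([0.5] * 10)


def _model(*comps):
    return KsPeakModel(components=[(math.log(k), 0.1, w) for k, w in comps],
                       n_components=len(comps), bic=0.0, n_values=1000)


class TestEventClassification:
    TREE = "((A:70.0,B:70.0):15.0,C:85.0);"

    def test_shared_young_peak_after_speciation(self):
        paralogs = {
            "A": _model((0.80, 0.5), (1.50, 0.5)),
            "B": _model((0.80, 0.5), (1.50, 0.5)),
            "C": _model((1.50, 1.0)),
        }
        orthologs = {frozenset(("A", "C")): _model((0.85, 1.0))}
        table = classify_wg_events(paralogs, orthologs, self.TREE)
        young = table[table.n_species == 2].iloc[0]
        assert young.branch == "A+B"
        assert young.order_vs_speciation == "after_speciation"
        old = table[table.n_species == 3].iloc[0]
        assert old.order_vs_speciation == "n/a"

    def test_identical_peak_sets_no_lineage_specific_events(self):
        paralogs = {s: _model((1.5, 1.0)) for s in "ABC"}
        table = classify_wg_events(paralogs, {}, self.TREE)
        assert len(table) == 1 and table.iloc[0].n_species == 3

    def test_peak_separation_below_resolution_indistinguishable(self):
        paralogs = {
            "A": _model((0.845, 1.0)),
            "B": _model((0.845, 1.0)),
        }
        orthologs = {frozenset(("A", "C")): _model((0.85, 1.0))}
        table = classify_wg_events(paralogs, orthologs, self.TREE)
        assert table.iloc[0].order_vs_speciation == "indistinguishable"

    def test_private_peak_on_terminal_branch(self):
        paralogs = {
            "A": _model((0.30, 0.5), (1.5, 0.5)),
            "B": _model((1.5, 1.0)),
            "C": _model((1.5, 1.0)),
        }
        orthologs = {frozenset(("A", "B")): _model((0.70, 1.0))}
        table = classify_wg_events(paralogs, orthologs, self.TREE)
        private = table[table.n_species == 1].iloc[0]
        assert private.branch == "A"
        assert private.order_vs_speciation == "after_speciation"

    def test_multiplicity_from_depth_tracks(self):
        paralogs = {"A": _model((0.8, 1.0)), "B": _model((0.8, 1.0))}
        orthologs = {frozenset(("A", "C")): _model((0.85, 1.0))}
        tracks = {"A": ([0.78, 0.82, 0.80, 1.4], [3, 3, 2, 1])}
        table = classify_wg_events(paralogs, orthologs, self.TREE,
                                   depth_tracks=tracks)
        assert table.iloc[0].multiplicity == 3


class TestDating:
    def test_strict_clock_conversion(self):
        p = DatingParams(clock_rate=5e-9)
        assert ks_to_time(0.8, p) == pytest.approx(8e7)
        assert ks_to_time(0.0, p) == 0.0
        assert ks_to_time(0.8, DatingParams(clock_rate=1e-8)) == \
            pytest.approx(ks_to_time(0.8, p) / 2)

    def test_saturated_value_rejected(self):
        with pytest.raises(ValueError):
            ks_to_time(float("nan"), DatingParams(clock_rate=5e-9))

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            DatingParams(clock_rate=0.0)
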