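"""Simulator: event mechanics, ground-truth bookkeeping, and replay."""

import numpy as np
import pytest

from paleoretain.simulate import (
    EventLog,
    SimParams,
    apply_fractionation,
    apply_rearrangement,
    apply_tandem_duplications,
    apply_targeted_loss,
    apply_wg_multiplication,
    build_ancestor,
    copy_genome,
    decode_cds,
    evolve_cds,
    replay_tip,
    simulate_dataset,
)


def _family_sizes(genome):
    return {fam: len(copies) for fam, copies in genome.families().items()}


class TestAncestor:
    def test_single_copy_families(self):
        g = build_ancestor(SimParams(seed=0, n_ancestral_genes=100,
                                     n_chromosomes=2))
        sizes = _family_sizes(g)
        assert len(sizes) == 100 and set(sizes.values()) == {1}

    def test_same_seed_reproduces_genome(self):
        params = SimParams(seed=9, n_ancestral_genes=60, n_chromosomes=3)
        g1, g2 = build_ancestor(params), build_ancestor(params)
        t1 = [(x.gene_id, x.chrom, x.start, x.strand, tuple(sorted(x.labels)))
              for x in g1.all_genes()]
        t2 = [(x.gene_id, x.chrom, x.start, x.strand, tuple(sorted(x.labels)))
              for x in g2.all_genes()]
        assert t1 == t2
        assert all(np.array_equal(g1.cds[k], g2.cds[k]) for k in g1.cds)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            build_ancestor(SimParams(seed=0, n_ancestral_genes=2,
                                     n_chromosomes=4))

    def test_label_frequencies_match_weights(self):
        weights = {"cellwall": 0.2, "fattyacid": 0.3, "other": 0.5}
        params = SimParams(seed=3, n_ancestral_genes=4000, n_chromosomes=4,
                           label_weights=weights, cds_codons=10)
        g = build_ancestor(params)
        counts = {l: 0 for l in weights}
        for x in g.all_genes():
            counts[next(iter(x.labels))] += 1
        for label, w in weights.items():
            sd = np.sqrt(4000 * w * (1 - w))
            assert abs(counts[label] - 4000 * w) < 4 * sd


class TestWholeGenomeMultiplication:
    def test_triplication_triples_every_family(self):
        g = build_ancestor(SimParams(seed=1, n_ancestral_genes=10,
                                     n_chromosomes=1, cds_codons=5))
        apply_wg_multiplication(g, 3, EventLog())
        assert set(_family_sizes(g).values()) == {3}
        assert g.n_genes == 30

    def test_two_duplications_compose(self):
        g = build_ancestor(SimParams(seed=1, n_ancestral_genes=10,
                                     n_chromosomes=1, cds_codons=5))
        log = EventLog()
        apply_wg_multiplication(g, 2, log)
        apply_wg_multiplication(g, 2, log)
        assert set(_family_sizes(g).values()) == {4}

    def test_gene_order_preserved_in_copies(self):
        g = build_ancestor(SimParams(seed=2, n_ancestral_genes=12,
                                     n_chromosomes=1, cds_codons=5))
        original = [x.family_id for x in g.genes["chr1"]]
        apply_wg_multiplication(g, 3, EventLog())
        for chrom in g.chrom_names():
            assert [x.family_id for x in g.genes[chrom]] == original


class TestFractionation:
    def _triplicated(self, n=1000, **kw):
        params = SimParams(seed=4, n_ancestral_genes=n, n_chromosomes=2,
                           cds_codons=4, retained_run_frac=0.0,
                           retention_bias={}, **kw)
        g = build_ancestor(params)
        apply_wg_multiplication(g, 3, EventLog())
        return g, params

    def test_full_retention_keeps_everything(self):
        g, params = self._triplicated(n=100)
        params.retention_prob = 1.0
        before = g.n_genes
        apply_fractionation(g, params, EventLog(), rng=np.random.default_rng(0))
        assert g.n_genes == before

    def test_zero_retention_reduces_to_single_copy(self):
        g, params = self._triplicated(n=100)
        params.retention_prob = 0.0
        apply_fractionation(g, params, EventLog(), rng=np.random.default_rng(0))
        assert set(_family_sizes(g).values()) == {1}

    def test_fully_triplicated_fraction_matches_p_squared(self):
        g, params = self._triplicated(n=1000)
        params.retention_prob = 0.5
        apply_fractionation(g, params, EventLog(), rng=np.random.default_rng(7))
        sizes = _family_sizes(g)
        n_full = sum(1 for s in sizes.values() if s == 3)
        p2 = 0.25
        sd = np.sqrt(1000 * p2 * (1 - p2))
        assert abs(n_full - 1000 * p2) < 3 * sd

    def test_last_copy_never_deleted(self):
        g, params = self._triplicated(n=200)
        params.retention_prob = 0.0
        apply_fractionation(g, params, EventLog(), rng=np.random.default_rng(1))
        assert len(_family_sizes(g)) == 200


class TestTandem:
    def test_zero_rate_is_identity(self):
        params = SimParams(seed=5, n_ancestral_genes=50, n_chromosomes=1,
                           cds_codons=4)
        g = build_ancestor(params)
        before = [(x.gene_id, x.rank) for x in g.all_genes()]
        apply_tandem_duplications(g, params, EventLog(),
                                  rng=np.random.default_rng(0), rate=0.0)
        assert [(x.gene_id, x.rank) for x in g.all_genes()] == before

    def test_copy_lands_adjacent_with_same_family_and_strand(self):
        params = SimParams(seed=5, n_ancestral_genes=30, n_chromosomes=1,
                           cds_codons=4)
        g = build_ancestor(params)
        log = EventLog()
        apply_tandem_duplications(g, params, log,
                                  rng=np.random.default_rng(2), rate=0.2)
        idx = g.gene_index()
        recs = log.of_type("tandem_duplication")[0].payload["copies"]
        assert recs, "expected at least one duplication at rate 0.2"
        for rec in recs:
            parent, copy = idx[rec["parent"]], idx[rec["copy"]]
            assert copy.chrom == parent.chrom
            assert copy.family_id == parent.family_id
            assert copy.strand == parent.strand
            assert abs(copy.rank - parent.rank) <= len(recs)

    def test_duplication_count_is_poisson(self):
        params = SimParams(seed=6, n_ancestral_genes=1000, n_chromosomes=2,
                           cds_codons=4)
        g = build_ancestor(params)
        log = EventLog()
        apply_tandem_duplications(g, params, log,
                                  rng=np.random.default_rng(3), rate=0.01)
        n_dup = len(log.of_type("tandem_duplication")[0].payload["copies"])
        assert abs(n_dup - 10) < 4 * np.sqrt(10)


class TestRearrangement:
    def _linear(self, n=8):
        params = SimParams(seed=7, n_ancestral_genes=n, n_chromosomes=1,
                           cds_codons=4)
        return build_ancestor(params)

    def test_inversion_reverses_order_and_flips_strands(self):
        g = self._linear(8)
        fams = [x.family_id for x in g.genes["chr1"]]
        strands = [x.strand for x in g.genes["chr1"]]
        apply_rearrangement(g, "inversion", ("chr1", 3, 6), EventLog())
        out = [x.family_id for x in g.genes["chr1"]]
        assert out == fams[:3] + fams[3:7][::-1] + fams[7:]
        new_strands = [x.strand for x in g.genes["chr1"]]
        flip = {"+": "-", "-": "+"}
        assert new_strands == strands[:3] + [flip[s] for s in strands[3:7]][::-1] \
            + strands[7:]

    def test_single_gene_inversion_flips_strand_only(self):
        g = self._linear(5)
        fams = [x.family_id for x in g.genes["chr1"]]
        s2 = g.genes["chr1"][2].strand
        apply_rearrangement(g, "inversion", ("chr1", 2, 2), EventLog())
        assert [x.family_id for x in g.genes["chr1"]] == fams
        assert g.genes["chr1"][2].strand != s2

    def test_inversion_is_involution(self):
        g = self._linear(10)
        before = [(x.gene_id, x.start, x.end, x.strand)
                  for x in g.genes["chr1"]]
        apply_rearrangement(g, "inversion", ("chr1", 2, 7), EventLog())
        apply_rearrangement(g, "inversion", ("chr1", 2, 7), EventLog())
        assert [(x.gene_id, x.start, x.end, x.strand)
                for x in g.genes["chr1"]] == before

    def test_interval_past_chromosome_end_rejected(self):
        g = self._linear(5)
        with pytest.raises(ValueError):
            apply_rearrangement(g, "inversion", ("chr1", 3, 9), EventLog())


class TestTargetedLoss:
    def test_plain_loss_removes_family_keeps_neighbors(self):
        params = SimParams(seed=8, n_ancestral_genes=20, n_chromosomes=1,
                           cds_codons=4)
        g = build_ancestor(params)
        order = [x.family_id for x in g.genes["chr1"]]
        fam = order[10]
        apply_targeted_loss(g, fam, EventLog(), rng=np.random.default_rng(0))
        assert fam not in g.families()
        assert [x.family_id for x in g.genes["chr1"]] == \
            order[:10] + order[11:]

    def test_loss_at_border_logs_adjacent_inversion(self):
        params = SimParams(seed=8, n_ancestral_genes=60, n_chromosomes=1,
                           cds_codons=4)
        g = build_ancestor(params)
        fam = g.genes["chr1"][10].family_id
        log = EventLog()
        apply_targeted_loss(g, fam, log, rng=np.random.default_rng(0),
                            at_inversion_border=True, inversion_size=25)
        inv = log.of_type("micro_inversion")[0].payload
        loss = log.of_type("targeted_gene_loss")[0].payload
        assert inv["n_genes"] == 25
        assert loss["rank"] in (inv["rank_start"], inv["rank_end"])
        assert fam not in g.families()

    def test_absent_family_rejected(self):
        params = SimParams(seed=8, n_ancestral_genes=10, n_chromosomes=1,
                           cds_codons=4)
        g = build_ancestor(params)
        with pytest.raises(KeyError):
            apply_targeted_loss(g, "NOPE", EventLog(),
                                rng=np.random.default_rng(0))


class TestSequenceEvolution:
    def test_zero_time_is_identity(self):
        params = SimParams(seed=10, n_ancestral_genes=10, n_chromosomes=1)
        g = build_ancestor(params)
        before = {k: v.copy() for k, v in g.cds.items()}
        evolve_cds(g, 0.0, 0.01, EventLog(), np.random.default_rng(0))
        assert all(np.array_equal(g.cds[k], before[k]) for k in before)

    def test_zero_nonsyn_rate_gives_zero_ka(self):
        from paleoretain.ks_evolution import ng86_pair

        params = SimParams(seed=10, n_ancestral_genes=30, n_chromosomes=1,
                           cds_codons=100)
        g = build_ancestor(params)
        g2 = copy_genome(g)
        evolve_cds(g2, 20.0, 5e-3, EventLog(), np.random.default_rng(1),
                   nonsyn_rate=0.0)
        for gid in g.cds:
            kp = ng86_pair(decode_cds(g.cds[gid]), decode_cds(g2.cds[gid]))
            assert kp.Nd == 0 and kp.ka == 0


class TestDataset:
    def test_no_events_yields_identical_structures(self):
        params = SimParams(seed=12, n_ancestral_genes=40, n_chromosomes=2,
                           syn_rate=0.0, nonsyn_factor=0.0, tandem_rate=0.0,
                           events=[], cds_codons=5)
        tips, _ = simulate_dataset("((a:1.0,b:1.0):1.0,c:2.0);", params)
        shapes = {
            sp: [(x.chrom, x.gene_id, x.start, x.strand) for x in g.all_genes()]
            for sp, g in tips.items()
        }
        assert shapes["a"] == shapes["b"] == shapes["c"]

    def test_polytomy_rejected(self):
        params = SimParams(seed=12, n_ancestral_genes=10, n_chromosomes=1,
                           cds_codons=4)
        with pytest.raises(ValueError, match="bifurcating"):
            simulate_dataset("(a:1.0,b:1.0,c:1.0);", params)

    def test_stem_triplication_restricted_to_ingroup(self):
        params = SimParams(
            seed=13, n_ancestral_genes=60, n_chromosomes=2, cds_codons=4,
            retained_run_frac=0.0, tandem_rate=0.0,
            events=[{"branch": "a+b", "type": "wg_multiplication",
                     "time": 0.5, "multiplicity": 3, "fractionation": False}])
        tips, _ = simulate_dataset("((a:1.0,b:1.0):1.0,c:2.0);", params)
        assert set(_family_sizes(tips["c"]).values()) == {1}
        assert set(_family_sizes(tips["a"]).values()) == {3}

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        params_kw = dict(seed=14, n_ancestral_genes=160, n_chromosomes=2,
                         cds_codons=10)
        from paleoretain.simulate import asteraceae_trio

        for d in ("r1", "r2"):
            tree, params = asteraceae_trio(**params_kw)
            simulate_dataset(tree, params, out_dir=tmp_path / d)
        for f in sorted((tmp_path / "r1").iterdir()):
            assert f.read_bytes() == (tmp_path / "r2" / f.name).read_bytes()


class TestGroundTruth:
    def test_replay_reproduces_tip_structure(self, trio):
        params = trio["params"]
        ancestor = build_ancestor(params, rng=params.rng())
        for tip in ("ingroupA", "ingroupB", "outgroup"):
            rep = replay_tip(ancestor, trio["log"], tip)
            got = sorted((x.chrom, x.gene_id, x.start, x.end, x.strand,
                          x.rank, x.family_id)
                         for x in trio["tips"][tip].all_genes())
            want = sorted((x.chrom, x.gene_id, x.start, x.end, x.strand,
                           x.rank, x.family_id) for x in rep.all_genes())
            assert got == want

    def test_gene_count_balances_with_log(self, trio):
        log, params = trio["log"], trio["params"]
        for tip, genome in trio["tips"].items():
            n = params.n_ancestral_genes
            for e in log.events:
                if e.branch != "stem" and tip not in e.tips():
                    continue
                if e.type == "wg_multiplication":
                    n *= e.payload["multiplicity"]
                elif e.type == "fractionation_loss":
                    n -= len(e.payload["deleted"])
                elif e.type == "tandem_duplication":
                    n += len(e.payload["copies"])
                elif e.type == "targeted_gene_loss":
                    n -= 1
            assert genome.n_genes == n

    def test_strand_flips_only_inside_logged_inversions(self, trio):
        params = trio["params"]
        ancestor = build_ancestor(params, rng=params.rng())
        anc_strand = {g.gene_id: g.strand for g in ancestor.all_genes()}
        log = trio["log"]
        outgroup = trio["tips"]["outgroup"]
        inverted_branches = {e.branch for e in
                             log.of_type("inversion", "micro_inversion")}
        assert "outgroup" not in inverted_branches
        for g in outgroup.all_genes():
            root_id = g.gene_id.split(".")[0]
            assert g.strand == anc_strand[root_id]


class TestTranslocation:
    def test_reciprocal_tail_swap(self):
        params = SimParams(seed=15, n_ancestral_genes=20, n_chromosomes=2,
                           cds_codons=4)
        g = build_ancestor(params)
        c1 = [x.gene_id for x in g.genes["chr1"]]
        c2 = [x.gene_id for x in g.genes["chr2"]]
        apply_rearrangement(g, "translocation", (("chr1", 4), ("chr2", 6)),
                            EventLog())
        assert [x.gene_id for x in g.genes["chr1"]] == c1[:4] + c2[6:]
        assert [x.gene_id for x in g.genes["chr2"]] == c2[:6] + c1[4:]
        g.validate()

    def test_translocation_replayable(self):
        params = SimParams(seed=16, n_ancestral_genes=20, n_chromosomes=2,
                           cds_codons=4)
        g = build_ancestor(params)
        ref = copy_genome(g)
        log = EventLog()
        apply_rearrangement(g, "translocation", (("chr1", 3), ("chr2", 5)),
                            log, branch="x")
        rep = replay_tip(ref, log, "x")
        assert sorted((x.chrom, x.gene_id, x.start) for x in g.all_genes()) == \
            sorted((x.chrom, x.gene_id, x.start) for x in rep.all_genes())


class TestEventLogSerialization:
    def test_json_round_trip(self, trio):
        text = trio["log"].to_json()
        log2 = EventLog.from_json(text)
        assert log2.to_json() == text
        assert len(log2.events) == len(trio["log"].events)
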