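"""Reproducible desk-scale experiments exercising the full inference stack.

Each function simulates a scenario with known ground truth, runs the
corresponding inference, and reports how well the truth is recovered. These
are the package's benchmark conditions: the trio event-recovery experiment,
the Ks estimator consistency run, retained-region recovery, the composition
contrast, and loss-mechanism classification.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import core_model, gene_loss, ks_evolution, synteny, trr_analysis
from .simulate import (
    EventLog,
    SimParams,
    apply_targeted_loss,
    asteraceae_trio,
    build_ancestor,
    copy_genome,
    decode_cds,
    evolve_cds,
    finalize_cds,
    simulate_dataset,
)

__all__ = [
    "ks_estimator_consistency",
    "trio_event_recovery",
    "trr_recovery",
    "composition_contrast",
    "loss_classification",
    "pipeline_determinism",
]


def ks_estimator_consistency(seed: int = 7, n_pairs: int = 200,
                             n_codons: int = 300,
                             true_ks: Sequence[float] = (0.2, 0.5, 1.0)
                             ) -> dict[str, Any]:
    """Mean NG86 Ks over simulated pairs versus the true divergence."""
    params = SimParams(seed=seed, n_ancestral_genes=n_pairs, n_chromosomes=2,
                       cds_codons=n_codons)
    rng = params.rng()
    anc = build_ancestor(params, rng=rng)
    out: dict[str, Any] = {"n_pairs": n_pairs, "levels": {}}
    for level in true_ks:
        t = level / (2 * params.syn_rate)
        a, b = copy_genome(anc), copy_genome(anc)
        log = EventLog()
        nonsyn = params.nonsyn_factor * params.syn_rate
        evolve_cds(a, t, params.syn_rate, log, rng, nonsyn_rate=nonsyn)
        evolve_cds(b, t, params.syn_rate, log, rng, nonsyn_rate=nonsyn)
        finalize_cds(a)
        finalize_cds(b)
        ks_vals = []
        for gid in sorted(a.cds):
            kp = ks_evolution.ng86_pair(a.cds[gid], b.cds[gid])
            if not kp.saturated_s:
                ks_vals.append(kp.ks)
        mean = float(np.mean(ks_vals))
        out["levels"][level] = {
            "mean_ks": mean,
            "rel_err_pct": abs(mean - level) / level * 100.0,
            "n_usable": len(ks_vals),
        }
    out["max_rel_err_pct"] = max(v["rel_err_pct"] for v in out["levels"].values())
    return out


def _syntelog_ks(genome_a, genome_b, self_cmp: bool) -> list[float]:
    if self_cmp:
        anchors = synteny.find_anchors(genome_a, genome_a)
    else:
        anchors = synteny.find_anchors(genome_a, genome_b)
    blocks = synteny.chain_anchors(anchors)
    vals: list[float] = []
    for b in blocks:
        s = ks_evolution.block_ks_summary(b, genome_a.cds, genome_b.cds)
        vals.extend(p.ks for p in s.pairs if not p.saturated_s)
    return vals


def trio_event_recovery(seed: int = 1, n_genes: int = 2000) -> dict[str, Any]:
    """Simulate the canonical trio, fit Ks peak models, classify events.

    Truth: an old triplication shared by all three species (paralog Ks 1.5)
    and a young one confined to the two ingroups (paralog Ks 0.8), dated
    after the ingroup/outgroup split (ortholog Ks 0.85).
    """
    tree, params = asteraceae_trio(seed=seed, n_ancestral_genes=n_genes)
    tips, _ = simulate_dataset(tree, params)
    models = {}
    for sp in sorted(tips):
        vals = _syntelog_ks(tips[sp], tips[sp], self_cmp=True)
        models[sp] = ks_evolution.fit_ks_peaks(vals, seed=seed)
    ortho_vals = _syntelog_ks(tips["outgroup"], tips["ingroupA"],
                              self_cmp=False)
    ortho_model = ks_evolution.fit_ks_peaks(ortho_vals, seed=seed)
    table = ks_evolution.classify_wg_events(
        models, {frozenset(("outgroup", "ingroupA")): ortho_model}, tree)
    young = table[table.n_species == 2].iloc[0]
    old = table[table.n_species == 3].iloc[0]
    return {
        "n_genes": n_genes,
        "young_peak_ks": float(young.peak_ks),
        "old_peak_ks": float(old.peak_ks),
        "ortholog_peak_ks": float(ortho_model.primary_peak()),
        "young_branch": str(young.branch),
        "young_order": str(young.order_vs_speciation),
        "events_table": table,
        "true_young_ks": 0.80,
        "true_old_ks": 1.50,
    }


def _triplication_scenario(seed: int, n_genes: int, retention_prob: float,
                           **overrides) -> tuple[dict, EventLog, SimParams]:
    tree = "(reference:1.0,polyploid:1.0);"
    events = [{"branch": "polyploid", "type": "wg_multiplication",
               "time": 0.9, "multiplicity": 3}]
    params = SimParams(seed=seed, n_ancestral_genes=n_genes, n_chromosomes=4,
                       stem_length=1.0, events=events,
                       retention_prob=retention_prob, tandem_rate=0.0,
                       **overrides)
    tips, log = simulate_dataset(tree, params)
    return tips, log, params


def trr_recovery(seed: int = 11, n_genes: int = 800,
                 retention_prob: float = 0.5) -> dict[str, Any]:
    """Per-gene retained-region membership versus the truth log.

    Truth membership applies the same run definition (min_run 3, max_gap 1)
    to the true per-gene copy counts of the polyploid.
    """
    tips, _, _ = _triplication_scenario(seed, n_genes, retention_prob)
    ref, tgt = tips["reference"], tips["polyploid"]
    fam_sizes: dict[str, int] = {}
    for g in tgt.all_genes():
        fam_sizes[g.family_id] = fam_sizes.get(g.family_id, 0) + 1
    truth_depth = {g.gene_id: min(3, fam_sizes.get(g.family_id, 0))
                   for g in ref.all_genes()}

    anchors = synteny.find_anchors(ref, tgt)
    blocks = synteny.chain_anchors(anchors)
    layout = synteny.best_k_layout(ref, tgt, 3, blocks)
    depth = synteny.syntenic_depth(layout)

    tparams = trr_analysis.TRRParams(k=3, min_copies=3, min_run=3, max_gap=1)
    pred = {g for t in trr_analysis.call_trrs(depth, tparams, ref)
            for g in t.gene_ids}
    truth = {g for t in trr_analysis.call_trrs(truth_depth, tparams, ref)
             for g in t.gene_ids}
    tp = len(pred & truth)
    return {
        "n_genes": n_genes,
        "n_predicted": len(pred),
        "n_truth": len(truth),
        "precision": tp / len(pred) if pred else float("nan"),
        "recall": tp / len(truth) if truth else float("nan"),
    }


def composition_contrast(seed: int = 21, n_genes: int = 2000,
                         window_bp: int = 500_000) -> dict[str, Any]:
    """Genic/repeat composition of retained regions versus the background.

    Windows are scaled to the desk-scale genome (the simulated chromosomes
    are two orders of magnitude shorter than multi-Gb plant genomes).
    """
    tips, _, _ = _triplication_scenario(seed, n_genes, 0.5,
                                        repeat_depletion=0.5)
    ref, tgt = tips["reference"], tips["polyploid"]
    anchors = synteny.find_anchors(ref, tgt)
    blocks = synteny.chain_anchors(anchors)
    depth = synteny.syntenic_depth(synteny.best_k_layout(ref, tgt, 3, blocks))
    trrs = trr_analysis.call_trrs(depth, trr_analysis.TRRParams(), ref)
    intervals = trr_analysis.trr_target_intervals(trrs, blocks)
    windows = core_model.window_iter(tgt, window_bp, window_bp)
    comp = trr_analysis.window_composition(tgt, windows)
    trr_w, bg_w = trr_analysis.split_windows_by_intervals(comp, intervals)
    tests = {t.track: t for t in trr_analysis.compare_composition(trr_w, bg_w)}

    # repeat-family enrichment/depletion of elements inside retained regions
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    rep_ids = {}
    test_elems = set()
    for i, (chrom, s, e, fam) in enumerate(tgt.repeats):
        rid = f"rep{i:06d}"
        rep_ids[rid] = fam
        mid = (s + e) // 2
        if any(lo <= mid <= hi for lo, hi in by_chrom.get(chrom, [])):
            test_elems.add(rid)
    enr = {r.category: r for r in trr_analysis.hypergeom_enrichment(
        test_elems, set(rep_ids), rep_ids, threshold=0.01)}
    return {
        "n_windows": len(comp),
        "n_trr_windows": len(trr_w),
        "genic": tests["genic_frac"],
        "repeat": tests["repeat_frac"],
        "ltr_depletion": enr.get("LTR_RT"),
    }


def loss_classification(seed: int = 1000, n_replicates: int = 100,
                        n_genes: int = 200) -> dict[str, Any]:
    """Targeted-loss replicates: half at micro-inversion borders (20-30
    genes), half plain deletions; noiseless synteny."""
    rng = np.random.default_rng(seed)
    correct = 0
    bp_exact = 0
    n_border = 0
    for rep in range(n_replicates):
        at_border = rep % 2 == 0
        params = SimParams(seed=seed + rep, n_ancestral_genes=n_genes,
                           n_chromosomes=1, cds_codons=4,
                           retained_run_frac=0.0)
        ref = build_ancestor(params, rng=params.rng())
        tgt = copy_genome(ref)
        tgt.species = "target"
        for g in tgt.all_genes():
            g.species = "target"
        log = EventLog()
        fam = sorted(tgt.families())[int(rng.integers(40, n_genes - 40))]
        apply_targeted_loss(tgt, fam, log, rng=rng,
                            at_inversion_border=at_border)
        anchors = synteny.find_anchors(ref, tgt)
        blocks = synteny.chain_anchors(anchors)
        report = gene_loss.trace_family_loss(fam, ref, tgt, blocks,
                                             anchors=anchors,
                                             border_tolerance=2)
        want = "lost_at_inversion_border" if at_border else "lost"
        if report.status == want:
            correct += 1
        if at_border:
            n_border += 1
            inv = log.of_type("micro_inversion")[0].payload
            del_rank = log.of_type("targeted_gene_loss")[0].payload["rank"]
            rs, re_ = inv["rank_start"], inv["rank_end"]
            lo = rs - (1 if del_rank < rs else 0)
            hi = re_ - (1 if del_rank <= re_ else 0)
            segs = [s for r in report.inversions for s in [r]]
            if any((s.rank_lo, s.rank_hi) == (lo, hi) for s in segs):
                bp_exact += 1
    return {
        "n_replicates": n_replicates,
        "accuracy": correct / n_replicates,
        "breakpoint_exact_frac": bp_exact / n_border if n_border else 0.0,
    }


def pipeline_determinism(seed: int, out_dir: str | Path,
                         n_genes: int = 300) -> dict[str, Any]:
    """Run the demo pipeline twice with one seed; manifests must match."""
    from .pipeline import run_pipeline

    out_dir = Path(out_dir)
    cfg = {"seed": seed, "simulate": {"scenario": "trio",
                                      "n_ancestral_genes": n_genes}}
    run_pipeline(cfg, out_dir / "run1")
    run_pipeline(cfg, out_dir / "run2")
    h1 = hashlib.sha256((out_dir / "run1" / "manifest.json").read_bytes())
    h2 = hashlib.sha256((out_dir / "run2" / "manifest.json").read_bytes())
    return {
        "identical": h1.hexdigest() == h2.hexdigest(),
        "manifest_sha256": h1.hexdigest(),
    }
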