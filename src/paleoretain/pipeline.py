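"""End-to-end orchestration of the comparative-genomics workflow.

A run takes a YAML/dict configuration (either a simulation scenario or
per-species input files), executes
synteny -> Ks -> event classification -> retained-region calling ->
composition/enrichment -> loss tracing -> family dynamics, and emits a
manifest listing every output with its checksum. Re-running with an
identical configuration and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import core_model, family_dynamics, gene_loss, ks_evolution, simulate, synteny, trr_analysis
from .core_model import AnnotatedGenome, FamilyTable
from .simulate import SimParams, asteraceae_trio

__all__ = ["load_config", "run_pipeline"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "reference": "outgroup",
    "targets": ["ingroupA", "ingroupB"],
    "chaining": {"gap_penalty": 0.2, "max_gap_genes": 25, "min_block_anchors": 5},
    "ks": {"max_components": 4, "ks_range": [0.01, 3.0], "min_values": 50},
    "trr": {"k": 3, "min_copies": 3, "min_run": 3, "max_gap": 1},
    "windows": {"width": 1_000_000, "step": 1_000_000},
    "enrichment": {"fdr": 0.01},
    "loss": {"border_tolerance": 2, "max_candidates": 10},
    "tandem_distance": 10,
}


def load_config(path_or_dict: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(path_or_dict, (str, Path)):
        cfg = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        cfg = dict(path_or_dict)
    merged = json.loads(json.dumps(DEFAULTS))
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, config: dict[str, Any], out_dir: Path):
        self.config = config
        self.out = out_dir
        self.out.mkdir(parents=True, exist_ok=True)
        self.stages: list[dict[str, Any]] = []
        self.genomes: dict[str, AnnotatedGenome] = {}
        self.table: FamilyTable | None = None
        self.blocks_ref: dict[str, list[synteny.SyntenyBlock]] = {}
        self.anchors_ref: dict[str, list[synteny.AnchorPair]] = {}
        self.blocks_self: dict[str, list[synteny.SyntenyBlock]] = {}
        self.paralog_ks: dict[str, list[ks_evolution.KsPair]] = {}
        self.ortholog_ks: dict[str, list[ks_evolution.KsPair]] = {}
        self.paralog_models: dict[str, ks_evolution.KsPeakModel] = {}
        self.ortholog_models: dict[frozenset, ks_evolution.KsPeakModel] = {}
        self.layouts: dict[str, synteny.BestKLayout] = {}
        self.trrs: dict[str, list[trr_analysis.TRRInterval]] = {}
        self.tree: str | None = None

    def record(self, name: str, params: Mapping[str, Any], outputs: list[Path],
               status: str = "ok") -> None:
        self.stages.append({
            "name": name,
            "status": status,
            "params": dict(sorted(params.items())),
            "outputs": [
                {"path": str(p.relative_to(self.out)), "sha256": _sha256(p)}
                for p in outputs
            ],
        })

    def skip(self, name: str, reason: str) -> None:
        self.stages.append({"name": name, "status": f"skipped: {reason}",
                            "params": {}, "outputs": []})


def _stage_inputs(run: _Run) -> None:
    cfg = run.config
    data_dir = run.out / "data"
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        scenario = sim.pop("scenario", "trio")
        if scenario != "trio":
            raise ValueError(f"unknown scenario {scenario!r}")
        tree, params = asteraceae_trio(seed=int(cfg["seed"]), **sim)
        run.tree = tree
        genomes, log = simulate.simulate_dataset(tree, params, out_dir=data_dir)
        run.genomes = genomes
        run.table = FamilyTable.from_genomes(genomes[s] for s in sorted(genomes))
        outputs = sorted(data_dir.iterdir())
        run.record("inputs", {"scenario": scenario, "tree": tree,
                              **{k: str(v) for k, v in sim.items()}}, outputs)
    else:
        species_cfg = cfg["inputs"]["species"]
        for sp, paths in sorted(species_cfg.items()):
            run.genomes[sp] = core_model.load_genome(
                paths["gff3"], paths.get("cds"), species=sp)
            if "repeats" in paths:
                run.genomes[sp].repeats = core_model.load_repeats(paths["repeats"])
        if "families" in cfg["inputs"]:
            run.table = core_model.load_family_table(cfg["inputs"]["families"])
        else:
            run.table = FamilyTable.from_genomes(
                run.genomes[s] for s in sorted(run.genomes))
        run.tree = cfg["inputs"].get("tree")
        run.record("inputs", {"species": sorted(species_cfg)}, [])


def _stage_synteny(run: _Run) -> None:
    cfg = run.config
    ch = cfg["chaining"]
    ref = cfg["reference"]
    outputs = []
    for target in sorted(cfg["targets"]):
        anchors = synteny.find_anchors(run.genomes[ref], run.genomes[target])
        blocks = synteny.chain_anchors(anchors, **ch)
        run.anchors_ref[target] = anchors
        run.blocks_ref[target] = blocks
        p = run.out / f"blocks.{ref}-{target}.tsv"
        synteny.write_blocks_tsv(blocks, p)
        outputs.append(p)
    for sp in sorted(run.genomes):
        anchors = synteny.find_anchors(run.genomes[sp], run.genomes[sp])
        blocks = synteny.chain_anchors(anchors, **ch)
        run.blocks_self[sp] = blocks
        p = run.out / f"blocks.{sp}-self.tsv"
        synteny.write_blocks_tsv(blocks, p)
        outputs.append(p)
    run.record("synteny", ch, outputs)


def _collect_block_ks(blocks, cds_a, cds_b, flagged) -> list[ks_evolution.KsPair]:
    pairs: list[ks_evolution.KsPair] = []
    for b in blocks:
        summary = ks_evolution.block_ks_summary(b, cds_a, cds_b, flagged)
        pairs.extend(summary.pairs)
    return pairs


def _stage_ks(run: _Run) -> bool:
    cfg = run.config
    missing = [sp for sp in sorted(run.genomes) if not run.genomes[sp].cds]
    if missing:
        run.skip("ks", f"missing CDS for {','.join(missing)}")
        return False
    outputs = []
    for sp in sorted(run.genomes):
        g = run.genomes[sp]
        run.paralog_ks[sp] = _collect_block_ks(run.blocks_self[sp], g.cds,
                                               g.cds, g.flagged_cds)
        outputs.append(_write_ks_tsv(run.out / f"ks.paralogs.{sp}.tsv",
                                     run.paralog_ks[sp]))
    ref = cfg["reference"]
    for target in sorted(cfg["targets"]):
        flagged = run.genomes[ref].flagged_cds | run.genomes[target].flagged_cds
        pairs = _collect_block_ks(run.blocks_ref[target],
                                  run.genomes[ref].cds,
                                  run.genomes[target].cds, flagged)
        run.ortholog_ks[target] = pairs
        outputs.append(_write_ks_tsv(
            run.out / f"ks.orthologs.{ref}-{target}.tsv", pairs))
    run.record("ks", {}, outputs)
    return True


def _write_ks_tsv(path: Path, pairs) -> Path:
    df = pd.DataFrame([
        {"gene_a": p.gene_a, "gene_b": p.gene_b, "S": round(p.S, 3),
         "N": round(p.N, 3), "Sd": round(p.Sd, 3), "Nd": round(p.Nd, 3),
         "ks": round(p.ks, 6) if np.isfinite(p.ks) else "saturated",
         "ka": round(p.ka, 6) if np.isfinite(p.ka) else "saturated"}
        for p in pairs
    ])
    df.to_csv(path, sep="\t", index=False)
    return path


def _stage_peaks(run: _Run) -> None:
    cfg = run.config
    kcfg = cfg["ks"]
    seed = int(cfg["seed"])
    ref = cfg["reference"]
    for sp in sorted(run.paralog_ks):
        vals = [p.ks for p in run.paralog_ks[sp] if not p.saturated_s]
        run.paralog_models[sp] = ks_evolution.fit_ks_peaks(
            vals, max_components=kcfg["max_components"],
            ks_range=tuple(kcfg["ks_range"]), seed=seed,
            min_values=kcfg["min_values"])
    for target in sorted(run.ortholog_ks):
        vals = [p.ks for p in run.ortholog_ks[target] if not p.saturated_s]
        run.ortholog_models[frozenset((ref, target))] = ks_evolution.fit_ks_peaks(
            vals, max_components=kcfg["max_components"],
            ks_range=tuple(kcfg["ks_range"]), seed=seed,
            min_values=kcfg["min_values"])
    p_models = run.out / "ks_peak_models.json"
    ks_evolution.write_peak_models_json(
        {**run.paralog_models, **run.ortholog_models}, p_models)
    outputs = [p_models]
    if run.tree is not None:
        events = ks_evolution.classify_wg_events(
            run.paralog_models, run.ortholog_models, run.tree)
        p_events = run.out / "wg_events.tsv"
        events.to_csv(p_events, sep="\t", index=False)
        outputs.append(p_events)
    run.record("peaks", {"seed": seed, **{k: str(v) for k, v in kcfg.items()}},
               outputs)


def _stage_trr(run: _Run) -> None:
    cfg = run.config
    params = trr_analysis.TRRParams(**cfg["trr"])
    ref = cfg["reference"]
    outputs = []
    for target in sorted(cfg["targets"]):
        layout = synteny.best_k_layout(run.genomes[ref], run.genomes[target],
                                       params.k, run.blocks_ref[target])
        run.layouts[target] = layout
        depth = synteny.syntenic_depth(layout)
        trrs = trr_analysis.call_trrs(depth, params, run.genomes[ref])
        run.trrs[target] = trrs
        p = run.out / f"trrs.{target}.bed"
        trr_analysis.write_trrs_bed(trrs, p)
        outputs.append(p)
    run.record("trr", {k: getattr(params, k) for k in
                       ("k", "min_copies", "min_run", "max_gap")}, outputs)


def _stage_composition(run: _Run) -> None:
    cfg = run.config
    wcfg = cfg["windows"]
    fdr = cfg["enrichment"]["fdr"]
    ref = cfg["reference"]
    outputs = []
    summary_rows = []
    for target in sorted(cfg["targets"]):
        g = run.genomes[target]
        windows = core_model.window_iter(g, wcfg["width"], wcfg["step"])
        comp = trr_analysis.window_composition(g, windows)
        intervals = trr_analysis.trr_target_intervals(
            run.trrs[target], run.blocks_ref[target])
        trr_w, bg_w = trr_analysis.split_windows_by_intervals(comp, intervals)
        p_comp = run.out / f"composition.{target}.tsv"
        comp.to_csv(p_comp, sep="\t", index=False)
        outputs.append(p_comp)
        if len(trr_w) >= 2 and len(bg_w) >= 2:
            tests = trr_analysis.compare_composition(trr_w, bg_w)
            for t in tests:
                summary_rows.append({
                    "target": target, "track": t.track,
                    "mean_trr": round(t.mean_test, 6),
                    "mean_background": round(t.mean_background, 6),
                    "t": round(t.t, 4) if np.isfinite(t.t) else "nan",
                    "df": t.df,
                    "p": (round(t.p, 8) if t.p is not None else "degenerate"),
                    "direction_in_trr": t.direction,
                })
        # label enrichment among reference genes inside retained regions
        trr_genes = {gid for trr in run.trrs[target] for gid in trr.gene_ids}
        ref_genome = run.genomes[ref]
        categories = {g2.gene_id: g2.labels for g2 in ref_genome.all_genes()}
        if trr_genes:
            enr = trr_analysis.hypergeom_enrichment(
                trr_genes, set(categories), categories, threshold=fdr)
            p_enr = run.out / f"label_enrichment.{target}.tsv"
            _write_enrichment_tsv(p_enr, enr)
            outputs.append(p_enr)
        # repeat-family enrichment of elements inside mapped TRR intervals
        rep_ids = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        test_elems = set()
        for i, (chrom, s, e, fam) in enumerate(g.repeats):
            rid = f"rep{i:06d}"
            rep_ids[rid] = fam
            mid = (s + e) // 2
            if any(lo <= mid <= hi for lo, hi in by_chrom.get(chrom, [])):
                test_elems.add(rid)
        if test_elems:
            enr = trr_analysis.hypergeom_enrichment(
                test_elems, set(rep_ids), rep_ids, threshold=fdr)
            p_rep = run.out / f"repeat_enrichment.{target}.tsv"
            _write_enrichment_tsv(p_rep, enr)
            outputs.append(p_rep)
    p_sum = run.out / "composition_tests.tsv"
    pd.DataFrame(summary_rows).to_csv(p_sum, sep="\t", index=False)
    outputs.append(p_sum)
    run.record("composition", {**wcfg, "fdr": fdr}, outputs)


def _write_enrichment_tsv(path: Path, results) -> None:
    pd.DataFrame([
        {"category": r.category, "k_in": r.k_in, "n_test": r.n_test,
         "K_total": r.K_total, "N_total": r.N_total,
         "p_value": f"{r.p_value:.6g}", "adjusted_p": f"{r.adjusted_p:.6g}",
         "direction": r.direction, "significant": r.significant}
        for r in results
    ]).to_csv(path, sep="\t", index=False)


def _stage_loss(run: _Run) -> None:
    cfg = run.config
    ref = cfg["reference"]
    tol = cfg["loss"]["border_tolerance"]
    cap = cfg["loss"]["max_candidates"]
    ref_genome = run.genomes[ref]
    reports = []
    for target in sorted(cfg["targets"]):
        target_fams = set(run.genomes[target].families())
        candidates = sorted(set(ref_genome.families()) - target_fams)[:cap]
        for fam in candidates:
            reports.append(gene_loss.trace_family_loss(
                fam, ref_genome, run.genomes[target], run.blocks_ref[target],
                anchors=run.anchors_ref[target], border_tolerance=tol))
    p_json = run.out / "loss_reports.json"
    p_json.write_text(json.dumps([r.to_dict() for r in reports], indent=1,
                                 sort_keys=True))
    p_tsv = run.out / "loss_reports.tsv"
    pd.DataFrame([
        {"family_id": r.family_id, "target": r.target_species,
         "status": r.status, "block_id": r.block_id,
         "expected_rank_lo": r.expected_rank_lo,
         "expected_rank_hi": r.expected_rank_hi,
         "n_inversions": len(r.inversions),
         "distance_to_breakpoint": r.distance_to_breakpoint}
        for r in reports
    ]).to_csv(p_tsv, sep="\t", index=False)
    run.record("loss", {"border_tolerance": tol}, [p_json, p_tsv])


def _stage_families(run: _Run) -> None:
    cfg = run.config
    assert run.table is not None
    counts = family_dynamics.count_families(run.table)
    p_counts = run.out / "family_counts.tsv"
    counts.to_csv(p_counts, sep="\t")
    outputs = [p_counts]

    D = cfg["tandem_distance"]
    dup_rows = []
    for sp in sorted(run.genomes):
        g = run.genomes[sp]
        idx = g.gene_index()
        fams = g.families()
        blocks = run.blocks_self.get(sp, [])
        for fam in sorted(fams):
            copies = sorted(fams[fam], key=lambda x: x.gene_id)
            for i in range(len(copies)):
                for j in range(i + 1, len(copies)):
                    call = family_dynamics.classify_duplication(
                        (copies[i], copies[j]), g, blocks, D=D)
                    dup_rows.append({"species": sp, "family_id": fam,
                                     "gene_a": call.gene_a, "gene_b": call.gene_b,
                                     "mechanism": call.mechanism})
    p_dup = run.out / "duplication_calls.tsv"
    pd.DataFrame(dup_rows).to_csv(p_dup, sep="\t", index=False)
    outputs.append(p_dup)

    if run.paralog_ks:
        sel_rows = []
        for sp in sorted(run.paralog_ks):
            try:
                s = family_dynamics.kaks_selection_summary(run.paralog_ks[sp])
            except ValueError:
                continue
            sel_rows.append({"species": sp, "n_pairs": s.n_pairs,
                             "n_unratioed": s.n_unratioed,
                             "mean_ka_ks": round(s.mean_ratio, 4),
                             "median_ka_ks": round(s.median_ratio, 4),
                             "frac_purifying": round(s.frac_purifying, 4)})
        p_sel = run.out / "selection_summary.tsv"
        pd.DataFrame(sel_rows).to_csv(p_sel, sep="\t", index=False)
        outputs.append(p_sel)

    clade = cfg.get("clade_species") or []
    rest = cfg.get("rest_species") or []
    if len(clade) >= 2 and len(rest) >= 2:
        res = family_dynamics.expansion_test(run.table, clade, rest)
        p_exp = run.out / "expansion_tests.tsv"
        res.to_csv(p_exp, sep="\t")
        outputs.append(p_exp)
    if "lcn" in cfg:
        lcn = family_dynamics.select_lcn(
            run.table, cfg["lcn"]["required_species"],
            cfg["lcn"]["min_other_single"], cfg["lcn"]["other_species"])
        p_lcn = run.out / "lcn_families.txt"
        p_lcn.write_text("\n".join(lcn) + ("\n" if lcn else ""))
        outputs.append(p_lcn)
    run.record("families", {"tandem_distance": D}, outputs)


def run_pipeline(config: str | Path | Mapping[str, Any],
                 out_dir: str | Path) -> dict[str, Any]:
    """Execute the full workflow; returns the manifest (also written to
    ``out_dir/manifest.json``)."""
    cfg = load_config(config)
    run = _Run(cfg, Path(out_dir))
    stage_fns = [
        ("inputs", _stage_inputs),
        ("synteny", _stage_synteny),
        ("ks", _stage_ks),
        ("peaks", _stage_peaks),
        ("trr", _stage_trr),
        ("composition", _stage_composition),
        ("loss", _stage_loss),
        ("families", _stage_families),
    ]
    ks_ok = True
    for name, fn in stage_fns:
        if name == "peaks" and not ks_ok:
            run.skip("peaks", "upstream ks stage skipped")
            continue
        try:
            if name == "ks":
                ks_ok = fn(run)
            else:
                fn(run)
        except Exception as exc:
            (run.out / "FAILED").write_text(
                f"stage {name} failed: {exc}\n{traceback.format_exc()}")
            manifest = _build_manifest(run, failed_stage=name)
            _write_manifest(run, manifest)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest = _build_manifest(run)
    _write_manifest(run, manifest)
    return manifest


def _build_manifest(run: _Run, failed_stage: str | None = None) -> dict[str, Any]:
    return {
        "seed": run.config.get("seed"),
        "config": run.config,
        "failed_stage": failed_stage,
        "stages": run.stages,
    }


def _write_manifest(run: _Run, manifest: dict[str, Any]) -> None:
    (run.out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
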