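"""End-to-end demo: simulate every input type, run the full pipeline, and
check each recovered quantity against the generator's ground truth.

The report is a plain dict (JSON-serializable, no timestamps or absolute
paths) so that two runs with the same seed produce byte-identical output.
"""

from __future__ import annotations

import numpy as np

from . import coregulation, motifs, proteomics, simulate, splicing, windows
from .config import RunConfig


def _check(report: dict, name: str, passed: bool, detail) -> None:
    report["checks"].append({"name": name, "passed": bool(passed), "detail": detail})


def run_demo(config: RunConfig | None = None) -> dict:
    """Run the demo pipeline; the report's ``all_passed`` drives exit status."""
    cfg = config or RunConfig()
    seed = cfg.seed
    report: dict = {"seed": seed, "checks": []}

    # -- quadrant classification ------------------------------------------
    table_a, table_b, ct_truth = simulate.sim_contrast_tables(
        n_events=200, quadrant_counts=(30, 10, 5, 15), n_null=2000, seed=seed
    )
    result = coregulation.classify_coregulated(
        table_a, table_b, dpsi_min=cfg.dpsi_min, mv_min=cfg.mv_min
    )
    planted = ct_truth["quadrant_counts"]
    if cfg.dpsi_min > 35:  # threshold above every planted |dPSI|: empty set expected
        report["empty_coregulated_set"] = result.total == 0
        _check(
            report,
            "quadrant_set_empty_at_threshold",
            result.total == 0,
            {"dpsi_min": cfg.dpsi_min, "recovered_total": result.total},
        )
    else:
        _check(
            report,
            "quadrant_counts_recovered",
            result.counts == planted,
            {"planted": planted, "recovered": result.counts},
        )
    controls = coregulation.select_control_events(
        table_a,
        table_b,
        n=cfg.controls_n,
        dpsi_max=cfg.control_dpsi_max,
        mv_max=cfg.control_mv_max,
        base_mean_min=cfg.base_mean_min,
        seed=seed,
    )
    _check(report, "control_sample_size", len(controls) == cfg.controls_n, len(controls))

    # -- windows + motif scan + enrichment --------------------------------
    genome, introns, win_truth = simulate.sim_intron_genome(
        n_fg=60, n_bg=150, seed=seed,
        window=(cfg.yeast_window_from_up, cfg.yeast_window_to_up),
    )
    core = motifs.MotifPattern(cfg.core_motif, cfg.core_motif)
    halfsite = motifs.MotifPattern(cfg.halfsite_motif, cfg.halfsite_motif)
    wins = windows.extract_windows(
        genome, introns, cfg.yeast_window_from_up, cfg.yeast_window_to_up
    )
    reports = [
        motifs.classify_window(w, core=core, halfsite=halfsite, max_dist=cfg.halfsite_max_dist)
        for w in wins
    ]
    truth_by_id = {t["intron_id"]: t for t in win_truth["windows"]}
    mismatches = sum(
        1 for r in reports if r.category != truth_by_id[r.intron_id]["category"]
    )
    _check(report, "motif_categories_exact", mismatches == 0, {"mismatches": mismatches})
    groups = {i.intron_id: i.group for i in introns}
    fg = [r.is_dual for r in reports if groups[r.intron_id] == "foreground"]
    bg = [r.is_dual for r in reports if groups[r.intron_id] == "background"]
    stat, p, table = motifs.enrichment_2x2(fg, bg, method=cfg.enrichment_method)
    report["motif_enrichment"] = {
        "statistic": float(stat),
        "p_value": float(p),
        "table": np.asarray(table).tolist(),
        "dual_fraction_fg": float(np.mean(fg)),
        "dual_fraction_bg": float(np.mean(bg)),
    }

    # -- percent unspliced -------------------------------------------------
    cm, count_truth = simulate.sim_counts(
        n_genes=150, n_planted=20, n_intronless=60,
        class_l2fc={"intronless": -1.0}, seed=seed,
    )
    pu = splicing.pu_table(cm, alpha=cfg.pu_alpha, expression_min=cfg.expression_min)
    pu_idx = pu.set_index("gene_id")
    planted_genes = list(count_truth["planted_genes"])
    recall = float(
        np.mean([bool(pu_idx.loc[g, "significant"]) for g in planted_genes if g in pu_idx.index])
    )
    null_genes = [g for g in pu_idx.index if g not in count_truth["planted_genes"]]
    fp = float(pu_idx.loc[null_genes, "significant"].mean())
    _check(report, "pu_planted_recall", recall >= 0.8, {"recall": recall})
    _check(report, "pu_null_fp_rate", fp <= 0.25, {"fp_rate": fp})

    shift = splicing.class_abundance_shift(cm, pseudocount=cfg.pseudocount, tpm_min=cfg.tpm_min)
    ordered = (
        shift.medians["unspliced"] > shift.medians["spliced"] > shift.medians["intronless"]
    )
    _check(report, "class_l2fc_ordering", ordered, shift.medians)
    report["class_shift_p"] = {f"{a}_vs_{b}": p for (a, b), p in shift.pairwise_p.items()}

    # -- proteomics --------------------------------------------------------
    nsc, dia, dia_groups, prot_truth = simulate.sim_proteomics(seed=seed)
    enr = proteomics.bg_corrected_enrichment(nsc)
    counts = proteomics.eu2_sign_counts(enr).set_index("substrate")
    sign_ok = all(
        counts.loc[sub, "n_pos"] == prot_truth["sign_counts"][sub]["n_pos"]
        and counts.loc[sub, "n_neg"] == prot_truth["sign_counts"][sub]["n_neg"]
        for sub in proteomics.SUBSTRATES
    )
    _check(
        report,
        "eu2_sign_counts_exact",
        sign_ok,
        {
            s: {k: int(v) for k, v in counts.loc[s].items()}
            for s in proteomics.SUBSTRATES
        },
    )
    z = proteomics.row_zscores(enr.set_index("protein_id")[proteomics.SUBSTRATES])
    order, _ = proteomics.cluster_rows(z)
    report["n_clustered_proteins"] = len(order)

    dia_res = proteomics.dia_differential(
        dia, dia_groups, "WT", "dnDEL",
        loose_l2fc=cfg.dia_loose_l2fc, strict_l2fc=cfg.dia_strict_l2fc, p_max=cfg.dia_p_max,
    ).set_index("protein_id")
    planted_dia = prot_truth["dia_planted_l2fc"]
    dia_recall = float(
        np.mean([bool(dia_res.loc[p, "pass_strict"]) for p in planted_dia])
    )
    _check(report, "dia_strict_recall", dia_recall >= 0.9, {"recall": dia_recall})

    report["all_passed"] = all(c["passed"] for c in report["checks"])
    return report
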