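"""Full-analysis orchestration and report rendering.

Runs the stages in dependency order — contrasts, summaries, strong-DEG
selection, KOG classification, target-set analyses, motif counting —
from one configuration, writes a TSV bundle plus a human-readable
summary, and records a run manifest (input/output digests, version,
seed).  A failure in one target set is recorded and does not abort the
other sets; the motif stage is skipped when no genome is supplied.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .deg import (
    CANONICAL_CONTRASTS,
    STRESS_CONTRASTS,
    ContrastResult,
    run_contrast,
    select_strong_degs,
    summarize_contrast,
)
from .io import (
    AnalysisConfig,
    provenance_comment,
    read_annotation,
    read_count_table,
    read_gene_set,
    read_genes_bed,
    write_tsv,
)
from .kog import build_kog_table
from .motifs import MotifCountTable, count_motifs_by_region, load_genome
from .targets import run_target_analysis

logger = logging.getLogger(__name__)

__all__ = ["run_all", "render_table2_style"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_table2_style(motif_table: MotifCountTable) -> pd.DataFrame:
    """Per-gene motif counts with row totals and a final totals row.

    Column order: SKN-1 upstream / intragenic / downstream / total,
    then the pooled DAF-16 (DBE + DAE) group in the same order.
    """
    return motif_table.with_totals()


def run_all(
    config: AnalysisConfig,
    counts_path: str | Path,
    annotation_path: str | Path,
    out_dir: str | Path,
    genome_path: str | Path | None = None,
    genes_bed_path: str | Path | None = None,
    sets_dir: str | Path | None = None,
) -> dict:
    """Execute the whole analysis and return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {"counts": Path(counts_path), "annotation": Path(annotation_path)}
    if genome_path:
        inputs["genome"] = Path(genome_path)
    if genes_bed_path:
        inputs["genes_bed"] = Path(genes_bed_path)
    set_paths = []
    if sets_dir:
        set_paths = sorted(p for p in Path(sets_dir).iterdir() if p.is_file())
    missing = [str(p) for p in (*inputs.values(), *set_paths) if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")

    started = time.time()
    table = read_count_table(inputs["counts"])
    annotation = read_annotation(inputs["annotation"])
    comment = provenance_comment(config, seed=config.rng_seed)
    outputs: dict[str, Path] = {}
    report_lines: list[str] = [f"stressdeg {__version__} analysis report", ""]

    # --- contrasts -------------------------------------------------------
    results: dict[str, ContrastResult] = {}
    summary_rows = []
    for name, spec in CANONICAL_CONTRASTS.items():
        result = run_contrast(table, annotation, spec, config)
        results[name] = result
        path = out / f"contrast_{name}.tsv"
        write_tsv(result.frame.reset_index(), path, comment=comment)
        outputs[f"contrast_{name}"] = path
        s = summarize_contrast(result)
        summary_rows.append(dataclasses.asdict(s))
        report_lines.append(
            f"contrast {name}: {s.n_up} up / {s.n_down} down DEGs"
            + (f", R = {s.ratio_R:.3f}" if s.ratio_R is not None else "")
        )
    summary = pd.DataFrame(summary_rows)
    path = out / "contrast_summary.tsv"
    write_tsv(summary, path, comment=comment)
    outputs["contrast_summary"] = path

    # --- strong DEGs -----------------------------------------------------
    strong = select_strong_degs(
        results[STRESS_CONTRASTS[0]], results[STRESS_CONTRASTS[1]], config
    )
    path = out / "strong_degs.tsv"
    write_tsv(strong.rename_axis("gene_id").reset_index(), path, comment=comment)
    outputs["strong_degs"] = path
    report_lines.append(f"strong DEGs (stress contrasts): {len(strong)}")

    # --- KOG -------------------------------------------------------------
    for name, result in results.items():
        kog_table = build_kog_table(result, annotation, config)
        frame = kog_table.frame.reset_index()
        frame.insert(0, "contrast", name)
        path = out / f"kog_{name}.tsv"
        write_tsv(frame, path, comment=comment)
        outputs[f"kog_{name}"] = path
        deviating = (
            kog_table.frame["deviating"].sum() if len(kog_table.frame) else 0
        )
        report_lines.append(
            f"KOG {name}: U={kog_table.U} D={kog_table.D}, "
            f"{int(deviating)} deviating categories at alpha={config.kog_alpha}"
        )

    # --- target sets -----------------------------------------------------
    wt_stress = results[STRESS_CONTRASTS[0]]
    pmk1_stress = results[STRESS_CONTRASTS[1]]
    target_summaries = []
    failures: dict[str, str] = {}
    for set_path in set_paths:
        try:
            gene_set = read_gene_set(set_path)
            res = run_target_analysis(gene_set, wt_stress, pmk1_stress, config)
            path = out / f"targets_{gene_set.name}.tsv"
            write_tsv(res.frame.reset_index(), path, comment=comment)
            outputs[f"targets_{gene_set.name}"] = path
            row = {
                "set": res.set_name,
                "metric": res.metric,
                "n_overlap": len(res.frame),
                "n_A": len(res.group_A),
                "n_C": len(res.group_C),
                "n_ties": len(res.ties),
                "U_levels": res.test_levels[0] if res.test_levels else None,
                "p_levels": res.test_levels[1] if res.test_levels else None,
                "U_deltas": res.test_deltas[0] if res.test_deltas else None,
                "p_deltas": res.test_deltas[1] if res.test_deltas else None,
                "n_strong": len(res.strong_subset),
                "note": res.skipped_reason or "",
            }
            for group in ("A", "C"):
                sub = res.frame[res.frame["group"] == group]
                values = sub["change_WT"] if group == "A" else sub["change_pmk1"]
                row[f"median_{group}"] = values.median() if len(sub) else None
                row[f"q25_{group}"] = values.quantile(0.25) if len(sub) else None
                row[f"q75_{group}"] = values.quantile(0.75) if len(sub) else None
            target_summaries.append(row)
            report_lines.append(
                f"target set {res.set_name}: overlap {len(res.frame)} "
                f"(A={len(res.group_A)}, C={len(res.group_C)}, ties={len(res.ties)})"
                + (
                    f", levels p={res.test_levels[1]:.3g}" if res.test_levels else ""
                )
            )
        except Exception as exc:  # noqa: BLE001 - isolate per-set failures
            logger.exception("target set %s failed", set_path.name)
            failures[set_path.name] = str(exc)
            report_lines.append(f"target set {set_path.name}: FAILED ({exc})")
    if target_summaries:
        path = out / "target_summary.tsv"
        write_tsv(pd.DataFrame(target_summaries), path, comment=comment)
        outputs["target_summary"] = path

    # --- motifs ----------------------------------------------------------
    if genome_path and genes_bed_path:
        genome = load_genome(genome_path)
        bed = read_genes_bed(genes_bed_path)
        genes = annotation.loc[annotation.index.intersection(bed["name"])]
        motif_table = count_motifs_by_region(genes, genome, config=config)
        path = out / "motif_counts.tsv"
        write_tsv(
            render_table2_style(motif_table).reset_index(), path, comment=comment
        )
        outputs["motif_counts"] = path
        report_lines.append(
            f"motif counts: {len(motif_table.rows)} genes, "
            f"SKN-1 total {int(motif_table.totals['skn1_total'])}, "
            f"DAF-16 total {int(motif_table.totals['daf16_total'])}"
        )
    else:
        report_lines.append("motif counts: skipped (no genome/BED supplied)")

    # --- report + manifest ----------------------------------------------
    report_path = out / "report.txt"
    report_path.write_text("\n".join(report_lines) + "\n")
    outputs["report"] = report_path

    manifest = {
        "version": __version__,
        "seed": config.rng_seed,
        "config": dataclasses.asdict(config),
        "inputs": {k: {"path": str(p), "sha256": _digest(p)} for k, p in inputs.items()},
        "gene_sets": {p.name: _digest(p) for p in set_paths},
        "outputs": {k: {"path": str(p), "sha256": _digest(p)} for k, p in outputs.items()},
        "failures": failures,
        "started": started,
        "finished": time.time(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
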