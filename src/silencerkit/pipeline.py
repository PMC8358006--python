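"""File-level orchestration of the analysis stages.

Each ``stage_*`` function reads its inputs from a run directory produced by
the simulator (or assembled by hand with the same file names), writes TSV
outputs with provenance headers into an analysis directory, and returns its
in-memory results so stages can be chained without re-reading files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from silencerkit import io
from silencerkit.core import CoverageTrack, GenomicInterval
from silencerkit.domains import (
    CallingParams,
    Domain,
    classify_domains,
    merge_peaks,
    metagene_matrix,
    quantify_domain_signal,
)
from silencerkit.genes import (
    ConstraintRecord,
    breadth_expression_trend,
    constraint_association,
    map_domains_to_genes,
)
from silencerkit.differential import (
    activation_summary,
    classify_h3k27me3_change,
    integrate_expression_changes,
    internal_differential_expression,
    quantify_gene_signal,
    region_mark_profiles,
)
from silencerkit.simulate import write_manifest
from silencerkit.stats import rank_correlation
from silencerkit.tads import (
    assign_target_genes,
    interaction_connectivity,
    permutation_interaction_test,
    tad_overlap_summary,
    tad_position_profile,
)

logger = logging.getLogger(__name__)


class MissingInputError(FileNotFoundError):
    """A required stage input is absent; message names the file and remedy."""


def _require(path: Path, what: str, remedy: str = "") -> Path:
    if not path.exists():
        hint = f" ({remedy})" if remedy else ""
        raise MissingInputError(f"missing {what}: {path}{hint}")
    return path


def _read_track_pair(run_dir: Path, mark: str, cond: str
                     ) -> tuple[CoverageTrack, CoverageTrack]:
    meta = io.read_track_metadata(_require(
        run_dir / "tracks.tsv", "track metadata", "run `silencerkit simulate`"
    ))
    pair = []
    for role in ("treat", "input"):
        rec = meta.get((mark, cond, role))
        if rec is None:
            raise MissingInputError(f"no {mark}/{cond}/{role} track in tracks.tsv")
        pair.append(io.read_bedgraph(
            _require(run_dir / rec["file"], f"{mark} {cond} {role} bedGraph"),
            total_mapped=rec["total_mapped"],
        ))
    return pair[0], pair[1]


def _read_methylation(run_dir: Path, cond: str) -> Optional[CoverageTrack]:
    path = run_dir / f"methylation_{cond}.bedgraph"
    if not path.exists():
        logger.warning("methylation track missing: %s", path)
        return None
    return io.read_bedgraph(path, value_bounds=(0.0, 1.0))


# ---------------------------------------------------------------------------
# call-domains
# ---------------------------------------------------------------------------

def stage_call_domains(
    run_dir: str | Path,
    out_dir: str | Path,
    params: Optional[CallingParams] = None,
    peaks_path: Optional[Path] = None,
) -> list[Domain]:
    run_dir, out_dir = Path(run_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = params or CallingParams()
    peaks_path = peaks_path or run_dir / "peaks_h3k27me3_normal.bed"
    peaks = io.read_bed(_require(peaks_path, "H3K27me3 peak BED"))
    treat, inp = _read_track_pair(run_dir, "h3k27me3", "normal")

    domains = merge_peaks(peaks, params.merge_gap)
    for d in domains:
        d.signal_rpkm = quantify_domain_signal(d.interval, treat, inp)
    labeled, report = classify_domains(domains, params)

    header = io.provenance_header(stage="call-domains", seed=params.seed,
                                  merge_gap=params.merge_gap,
                                  grand_quantile=params.grand_quantile,
                                  min_breadth=params.min_breadth)
    io.write_bed(out_dir / "domains.bed", [
        GenomicInterval(d.chrom, d.start, d.end, name=d.class_label,
                        score=round(d.signal_rpkm * 10))
        for d in labeled
    ], header=header)
    with open(out_dir / "threshold_report.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("key\tvalue\n")
        for key, val in report.items():
            fh.write(f"{key}\t{val}\n")

    grand = [d for d in labeled if d.class_label == "grand"]
    if grand:
        _, profile, _ = metagene_matrix(grand, treat)
        with open(out_dir / "metagene_grand.tsv", "wt", encoding="utf-8") as fh:
            fh.write(header)
            fh.write("bin\tmean_depth\n")
            for i, v in enumerate(profile):
                fh.write(f"{i}\t{v:.6g}\n")
    return labeled


def load_domains(out_dir: str | Path) -> list[Domain]:
    """Rehydrate classified domains from domains.bed (score = signal x 10)."""
    path = _require(Path(out_dir) / "domains.bed", "classified domains BED",
                    "run `silencerkit call-domains` first")
    domains = []
    for i, iv in enumerate(io.read_bed(path, min_fields=5)):
        domains.append(Domain(
            interval=iv, breadth=iv.length,
            signal_rpkm=(iv.score or 0.0) / 10.0,
            class_label=iv.name or "typical",
            domain_id=f"D{i:05d}",
        ))
    return domains


def domains_by_class(domains: Sequence[Domain]) -> dict[str, list[Domain]]:
    out: dict[str, list[Domain]] = {"grand": [], "typical": [], "narrow": [],
                                    "control": []}
    for d in domains:
        out.setdefault(d.class_label, []).append(d)
    return out


# ---------------------------------------------------------------------------
# annotate-genes
# ---------------------------------------------------------------------------

def stage_annotate_genes(
    run_dir: str | Path,
    out_dir: str | Path,
    domains: Optional[Sequence[Domain]] = None,
    extension: int = 2000,
    n_trend_bins: int = 20,
) -> dict:
    run_dir, out_dir = Path(run_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if domains is None:
        domains = load_domains(out_dir)
    genes = io.read_gene_table(_require(run_dir / "genes.tsv", "gene table"))
    marks = map_domains_to_genes(domains, genes, extension=extension)

    header = io.provenance_header(stage="annotate-genes", extension=extension)
    result: dict = {"marks": marks, "genes": genes}

    constraint_path = run_dir / "constraint.tsv"
    if constraint_path.exists():
        raw = io.read_constraint_table(constraint_path)
        constraints = {g: ConstraintRecord(g, z, dn) for g, (z, dn) in raw.items()}
        assoc = constraint_association(marks, constraints)
        result["constraint_association"] = assoc
        with open(out_dir / "constraint_association.tsv", "wt",
                  encoding="utf-8") as fh:
            fh.write(header)
            fh.write("metric\tgrand_median\tother_median\tdirection\t"
                     "p_value\tn_grand\tn_other\n")
            for metric, t in assoc["tests"].items():
                fh.write(f"{metric}\t{t['grand_median']:.4g}\t"
                         f"{t['other_median']:.4g}\t{t['direction']}\t"
                         f"{t['p_value']:.4g}\t{t['n_grand']}\t{t['n_other']}\n")

    expr_path = run_dir / "expression.tsv"
    if expr_path.exists():
        expr = io.read_expression_table(expr_path)
        tpm = {g: rec["tpm_normal"] for g, rec in expr.items()}
        trend = breadth_expression_trend(marks, tpm, n_bins=n_trend_bins)
        result["expression_trend"] = trend
        with open(out_dir / "breadth_expression_trend.tsv", "wt",
                  encoding="utf-8") as fh:
            fh.write(header)
            fh.write(f"# spearman_r={trend['spearman_r']:.4f}\t"
                     f"p={trend['p_value']:.4g}\n")
            fh.write("bin\tn_genes\tmedian_breadth\tmedian_tpm\n")
            for row in trend["bins"]:
                fh.write(f"{row['bin']}\t{row['n_genes']}\t"
                         f"{row['median_breadth']:.0f}\t{row['median_tpm']:.4f}\n")

    with open(out_dir / "gene_marks.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("gene_id\tclass\tmark_breadth\tbreadth_bin\n")
        for m in marks:
            fh.write(f"{m.gene_id}\t{m.class_label}\t{m.mark_breadth}\t"
                     f"{m.breadth_quantile_bin}\n")
    return result


# ---------------------------------------------------------------------------
# tad
# ---------------------------------------------------------------------------

def stage_tad(
    run_dir: str | Path,
    out_dir: str | Path,
    domains: Optional[Sequence[Domain]] = None,
    marks=None,
    n_perm: int = 1000,
    seed: int = 0,
    entirety_threshold: float = 0.9,
    target_distance: int = 3000,
) -> dict:
    run_dir, out_dir = Path(run_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if domains is None:
        domains = load_domains(out_dir)
    tads = io.read_bed(_require(run_dir / "tads.bed", "TAD BED"))
    loops = io.read_bedpe(_require(run_dir / "loops.bedpe", "loop BEDPE"))
    chrom_sizes = io.read_chrom_sizes(
        _require(run_dir / "chrom.sizes", "chromosome sizes"))
    genes = io.read_gene_table(_require(run_dir / "genes.tsv", "gene table"))
    by_class = domains_by_class(domains)

    census = tad_overlap_summary(by_class, tads, loops,
                                 coverage_threshold=entirety_threshold)
    profile = tad_position_profile(by_class, tads)
    connectivity = interaction_connectivity(by_class, loops)
    perm = permutation_interaction_test(by_class["grand"], loops, chrom_sizes,
                                        n_perm=n_perm, seed=seed)
    marked_ids = None
    if marks is not None:
        marked_ids = {m.gene_id for m in marks
                      if m.marked and m.class_label == "grand"}
    targets = assign_target_genes(by_class["grand"], loops, genes,
                                  distance=target_distance,
                                  marked_gene_ids=marked_ids)

    header = io.provenance_header(stage="tad", n_perm=n_perm, seed=seed,
                                  entirety_threshold=entirety_threshold,
                                  target_distance=target_distance)
    with open(out_dir / "tad_census.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("class\tn_domains\tn_overlap_tad\tn_mark_anchor\t"
                 "n_span_entire_tad\n")
        for label, rels in census.items():
            fh.write(f"{label}\t{len(rels)}\t"
                     f"{sum(r.overlaps_tad for r in rels)}\t"
                     f"{sum(r.marks_anchor for r in rels)}\t"
                     f"{sum(r.spans_entire_tad for r in rels)}\n")
    with open(out_dir / "tad_position_profile.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("class\tbin_left\tbin_right\tdensity\n")
        edges = profile["bin_edges"]
        for label, rec in profile["classes"].items():
            for b, dens in enumerate(rec["density"]):
                fh.write(f"{label}\t{edges[b]:.2f}\t{edges[b + 1]:.2f}\t"
                         f"{dens:.6g}\n")
    with open(out_dir / "connectivity.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("class\tn_domains\tn_connected\tconnected_fraction\t"
                 "multiplex_1\tmultiplex_2\tmultiplex_ge3\n")
        for label, rec in connectivity.items():
            h = rec["multiplexity"]
            fh.write(f"{label}\t{rec['n_domains']}\t{rec['n_connected']}\t"
                     f"{rec['connected_fraction']:.4f}\t{h['1']}\t{h['2']}\t"
                     f"{h['>=3']}\n")
    with open(out_dir / "permutation_test.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("observed\tn_perm\tnull_mean\tnull_max\tp\tseed\tshuffle_mode\n")
        nc = perm.null_counts
        fh.write(f"{perm.observed}\t{perm.n_perm}\t{np.mean(nc):.3f}\t"
                 f"{max(nc)}\t{perm.p:.6g}\t{perm.seed}\t{perm.shuffle_mode}\n")
    with open(out_dir / "permutation_null.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("replicate\tnull_count\n")
        for i, c in enumerate(perm.null_counts):
            fh.write(f"{i}\t{c}\n")
    with open(out_dir / "target_genes.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("domain_id\ttarget_gene_ids\n")
        for did, gids in targets["targets"].items():
            fh.write(f"{did}\t{','.join(gids) if gids else '.'}\n")

    return {"census": census, "position_profile": profile,
            "connectivity": connectivity, "permutation": perm,
            "targets": targets}


# ---------------------------------------------------------------------------
# differential
# ---------------------------------------------------------------------------

def stage_differential(
    run_dir: str | Path,
    out_dir: str | Path,
    domains: Optional[Sequence[Domain]] = None,
    marks=None,
    pseudocount: float = 0.25,
    fold_threshold: float = 1.0,
    de_table_path: Optional[Path] = None,
) -> dict:
    run_dir, out_dir = Path(run_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if domains is None:
        domains = load_domains(out_dir)
    genes = io.read_gene_table(_require(run_dir / "genes.tsv", "gene table"))
    if marks is None:
        marks = map_domains_to_genes(domains, genes)
    gene_by_id = {g.gene_id: g for g in genes}
    class_of = {m.gene_id: m.class_label for m in marks if m.marked}

    treat_n, input_n = _read_track_pair(run_dir, "h3k27me3", "normal")
    treat_t, input_t = _read_track_pair(run_dir, "h3k27me3", "tumor")
    marked = [m for m in marks if m.marked]
    signal_normal = {m.gene_id: quantify_gene_signal(
        gene_by_id[m.gene_id], treat_n, input_n) for m in marked}
    signal_tumor = {m.gene_id: quantify_gene_signal(
        gene_by_id[m.gene_id], treat_t, input_t) for m in marked}
    k27 = classify_h3k27me3_change(signal_normal, signal_tumor,
                                   pseudocount=pseudocount,
                                   fold_threshold=fold_threshold)

    if de_table_path is not None:
        de = io.read_de_table(de_table_path)
    else:
        expr = io.read_expression_table(
            _require(run_dir / "expression.tsv", "expression table",
                     "or pass an external DE table"))
        de = internal_differential_expression(
            {g: r["counts_normal"] for g, r in expr.items()},
            {g: r["counts_tumor"] for g, r in expr.items()},
        )
    calls = integrate_expression_changes(k27, signal_normal, signal_tumor, de)
    background_fc = [fc for fc, _ in de.values()]

    gsd_calls = [c for c in calls if class_of.get(c.gene_id) == "grand"]
    summary = activation_summary(gsd_calls, domain_class_of_gene=class_of,
                                 background_expr_log2fc=background_fc)

    # per-class signal-vs-expression correlation across all marked genes
    corr_by_class: dict[str, dict] = {}
    for label in ("grand", "typical", "narrow", "control"):
        cs = [c for c in calls if class_of.get(c.gene_id) == label
              and c.expr_log2fc is not None]
        if len(cs) >= 3:
            xs = [c.log2_signal_fc for c in cs]
            ys = [c.expr_log2fc for c in cs]
            if np.ptp(xs) > 0 and np.ptp(ys) > 0:
                r, p = rank_correlation(xs, ys, method="spearman")
                corr_by_class[label] = {"spearman_r": r, "p_value": p,
                                        "n": len(cs)}

    header = io.provenance_header(stage="differential",
                                  pseudocount=pseudocount,
                                  fold_threshold=fold_threshold)
    with open(out_dir / "differential_calls.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("gene_id\tclass\tsignal_normal\tsignal_tumor\t"
                 "log2_signal_fc\tk27_class\texpr_log2fc\texpr_fdr\t"
                 "activation_class\n")
        for c in calls:
            efc = f"{c.expr_log2fc:.4f}" if c.expr_log2fc is not None else "NA"
            efdr = f"{c.expr_fdr:.4g}" if c.expr_fdr is not None else "NA"
            fh.write(f"{c.gene_id}\t{class_of.get(c.gene_id, 'unmarked')}\t"
                     f"{c.signal_normal:.4f}\t{c.signal_tumor:.4f}\t"
                     f"{c.log2_signal_fc:.4f}\t{c.k27_class}\t{efc}\t{efdr}\t"
                     f"{c.activation_class}\n")
    with open(out_dir / "activation_summary.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("key\tvalue\n")
        for key in ("n_genes", "n_loss", "n_gain", "n_stable", "n_activated",
                    "n_silenced", "pct_loss", "pct_gain",
                    "pct_activated_of_loss", "pct_silenced_of_gain"):
            fh.write(f"{key}\t{getattr(summary, key)}\n")
        for label, rec in corr_by_class.items():
            fh.write(f"spearman_{label}\t{rec['spearman_r']:.4f}\n")
    if summary.cumulative is not None:
        with open(out_dir / "cumulative_shift.tsv", "wt", encoding="utf-8") as fh:
            fh.write(header)
            fh.write("log2fc\tactivated_cdf\tbackground_cdf\n")
            cum = summary.cumulative
            for x, a, b in zip(cum["log2fc_grid"], cum["activated_cdf"],
                               cum["background_cdf"]):
                fh.write(f"{x:.4f}\t{a:.4f}\t{b:.4f}\n")

    # mark/methylation profiles over the activated gene set
    activated = [gene_by_id[c.gene_id] for c in calls
                 if c.activation_class == "activated"]
    profiles = None
    if activated:
        tracks = {}
        for mark in ("h3k4me3", "h3k27ac", "h3k4me1"):
            tracks[mark] = {}
            for cond in ("normal", "tumor"):
                try:
                    t, _ = _read_track_pair(run_dir, mark, cond)
                    tracks[mark][cond] = t
                except MissingInputError:
                    logger.warning("%s %s track missing; skipped", mark, cond)
        methylation = {cond: _read_methylation(run_dir, cond)
                       for cond in ("normal", "tumor")}
        profiles = region_mark_profiles(activated, tracks,
                                        methylation=methylation)
        with open(out_dir / "activated_profiles.tsv", "wt",
                  encoding="utf-8") as fh:
            fh.write(header)
            fh.write("mark\tcondition\tbin\tmean_depth\n")
            for mark, by_cond in profiles["profiles"].items():
                for cond, vals in by_cond.items():
                    for b, v in enumerate(vals):
                        fh.write(f"{mark}\t{cond}\t{b}\t{v:.6g}\n")
        if profiles["methylation"] is not None:
            with open(out_dir / "methylation_deltas.tsv", "wt",
                      encoding="utf-8") as fh:
                fh.write(header)
                fh.write("key\tvalue\n")
                for key, val in profiles["methylation"].items():
                    fh.write(f"{key}\t{val}\n")

    return {"calls": calls, "summary": summary, "profiles": profiles,
            "corr_by_class": corr_by_class, "de": de}


# ---------------------------------------------------------------------------
# report + demo
# ---------------------------------------------------------------------------

def stage_report(out_dir: str | Path) -> Path:
    """Assemble a markdown report from the analysis TSVs present."""
    out_dir = Path(out_dir)
    report = out_dir / "report.md"
    sections = ["# silencerkit run report\n"]
    for title, name in (
        ("Domain calling thresholds", "threshold_report.tsv"),
        ("TAD census", "tad_census.tsv"),
        ("Loop connectivity", "connectivity.tsv"),
        ("Permutation test", "permutation_test.tsv"),
        ("Activation summary", "activation_summary.tsv"),
        ("Methylation deltas", "methylation_deltas.tsv"),
        ("Constraint association", "constraint_association.tsv"),
    ):
        path = out_dir / name
        if not path.exists():
            continue
        sections.append(f"\n## {title}\n\n```\n")
        body = [ln for ln in path.read_text(encoding="utf-8").splitlines()
                if not ln.startswith("#")]
        sections.append("\n".join(body))
        sections.append("\n```\n")
    trend = out_dir / "breadth_expression_trend.tsv"
    if trend.exists():
        for ln in trend.read_text(encoding="utf-8").splitlines():
            if ln.startswith("# spearman_r"):
                sections.append(f"\n## Breadth-expression trend\n\n{ln[2:]}\n")
    report.write_text("".join(sections), encoding="utf-8")
    return report


def run_demo(out_dir: str | Path, seed: int = 0, n_perm: int = 1000,
             config=None) -> dict:
    """simulate -> call-domains -> annotate-genes -> tad -> differential ->
    report, all under one master seed.

    Derived seeds: simulation = master, control sample = master + 1000,
    permutation = master + 2000.
    """
    from silencerkit.simulate import SimulationConfig, simulate_all

    out_dir = Path(out_dir)
    run_dir = out_dir / "data"
    analysis = out_dir / "analysis"
    if config is None:
        config = SimulationConfig(seed=seed)
    truth = simulate_all(config, run_dir)

    params = CallingParams(seed=seed + 1000)
    domains = stage_call_domains(run_dir, analysis, params=params)
    annotated = stage_annotate_genes(run_dir, analysis, domains=domains)
    tad_res = stage_tad(run_dir, analysis, domains=domains,
                        marks=annotated["marks"], n_perm=n_perm,
                        seed=seed + 2000)
    diff_res = stage_differential(run_dir, analysis, domains=domains,
                                  marks=annotated["marks"])
    stage_report(analysis)
    write_manifest(analysis)
    return {"truth": truth, "domains": domains, "annotated": annotated,
            "tad": tad_res, "differential": diff_res,
            "run_dir": run_dir, "analysis_dir": analysis}
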