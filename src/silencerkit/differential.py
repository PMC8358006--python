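"""Two-condition loss/gain analysis integrated with expression and methylation.

Per-gene repressive-mark signal (body +/- 2 kb, input-subtracted RPKM) is
compared between conditions on a log2 scale with a pseudocount; losses and
gains beyond the fold threshold are crossed with an expression
differential-call table to produce the activation catalog, summary
percentages, cumulative-shift test and per-mark/methylation profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from silencerkit.core import CoverageTrack, GeneModel, ValidationError
from silencerkit.stats import bh_fdr, mann_whitney, rank_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedProfile",
    "DifferentialCall",
    "ActivationSummary",
    "gene_binned_profile",
    "quantify_gene_signal",
    "classify_h3k27me3_change",
    "integrate_expression_changes",
    "internal_differential_expression",
    "activation_summary",
    "region_mark_profiles",
]

LOSS, GAIN, STABLE = "loss", "gain", "stable"
ACTIVATED, SILENCED, LOSS_ONLY, GAIN_ONLY = (
    "activated", "silenced", "loss_only", "gain_only"
)


@dataclass
class BinnedProfile:
    """Strand-oriented binned coverage: flank + body + flank, 5' first."""

    gene_id: str
    values: np.ndarray
    flank_bins: int
    body_bins: int
    oriented: bool = True

    def __post_init__(self):
        expected = 2 * self.flank_bins + self.body_bins
        if len(self.values) != expected:
            raise ValidationError(
                f"profile length {len(self.values)} != {expected}"
            )


@dataclass
class DifferentialCall:
    gene_id: str
    signal_normal: float
    signal_tumor: float
    log2_signal_fc: float
    k27_class: str
    expr_log2fc: Optional[float] = None
    expr_fdr: Optional[float] = None
    activation_class: str = STABLE


@dataclass
class ActivationSummary:
    n_genes: int
    n_loss: int
    n_gain: int
    n_stable: int
    n_activated: int
    n_silenced: int
    pct_loss: float
    pct_gain: float
    pct_activated_of_loss: float
    pct_silenced_of_gain: float
    correlation_by_class: dict
    shift_test: Optional[dict]
    cumulative: Optional[dict]

    def __post_init__(self):
        # percentages must be recomputable from this object's own counts
        assert self.pct_loss == _pct(self.n_loss, self.n_genes)
        assert self.pct_gain == _pct(self.n_gain, self.n_genes)
        assert self.pct_activated_of_loss == _pct(self.n_activated, self.n_loss)
        assert self.pct_silenced_of_gain == _pct(self.n_silenced, self.n_gain)


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 1) if den else 0.0


def gene_binned_profile(
    gene: GeneModel,
    track: CoverageTrack,
    body_bins: int = 50,
    flank: int = 2000,
    flank_bins: int = 10,
) -> BinnedProfile:
    """Mean coverage over gene body bins plus fixed flanks, 5'->3'.

    Minus-strand genes are reversed so index 0 is always the 5' end.  Flanks
    running off the chromosome start are truncated (recorded via log).
    """
    body = gene.body
    if body.length < body_bins:
        logger.warning("gene %s body (%d bp) shorter than %d bins",
                       gene.gene_id, body.length, body_bins)
    up_start = body.start - flank
    if up_start < 0:
        logger.info("gene %s: upstream flank truncated at chromosome start",
                    gene.gene_id)
        up_start = 0
    if up_start < body.start:
        left = track.binned_means(gene.chrom, up_start, body.start, flank_bins)
    else:
        left = np.zeros(flank_bins)
    mid = track.binned_means(gene.chrom, body.start, body.end, body_bins)
    right = track.binned_means(gene.chrom, body.end, body.end + flank, flank_bins)
    values = np.concatenate([left, mid, right])
    if gene.strand == "-":
        values = values[::-1]
    return BinnedProfile(gene.gene_id, values, flank_bins, body_bins)


def quantify_gene_signal(
    gene: GeneModel,
    treatment: CoverageTrack,
    input_track: CoverageTrack,
    extension: int = 2000,
) -> float:
    """Input-subtracted RPKM over the gene body +/- extension, floored at 0."""
    body = gene.body
    start = max(0, body.start - extension)
    end = body.end + extension
    t = treatment.rpkm(gene.chrom, start, end)
    i = input_track.rpkm(gene.chrom, start, end)
    return max(0.0, t - i)


def classify_h3k27me3_change(
    signal_normal: Mapping[str, float],
    signal_tumor: Mapping[str, float],
    pseudocount: float = 0.25,
    fold_threshold: float = 1.0,
) -> dict[str, tuple[float, str]]:
    """Per-gene log2 signal change and loss/gain/stable class.

    log2FC = log2((tumor + pc) / (normal + pc)); loss below -fold_threshold,
    gain above +fold_threshold, stable otherwise.  Swapping the two
    conditions maps loss <-> gain exactly (antisymmetry).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    out: dict[str, tuple[float, str]] = {}
    for gene_id, s_n in signal_normal.items():
        if gene_id not in signal_tumor:
            continue
        s_t = signal_tumor[gene_id]
        if s_n < 0 or s_t < 0:
            raise ValidationError(f"negative signal for gene {gene_id}")
        fc = math.log2((s_t + pseudocount) / (s_n + pseudocount))
        if fc < -fold_threshold:
            cls = LOSS
        elif fc > fold_threshold:
            cls = GAIN
        else:
            cls = STABLE
        out[gene_id] = (fc, cls)
    return out


def internal_differential_expression(
    counts_normal: Mapping[str, Sequence[float]],
    counts_tumor: Mapping[str, Sequence[float]],
    pseudocount: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Replicate-count differential expression: gene -> (log2FC, FDR).

    log2FC from mean counts with a pseudocount; per-gene rank-sum p across
    replicates, BH-adjusted.  This internal mode exists so synthetic runs
    need no external differential-expression tool.
    """
    genes = sorted(set(counts_normal) & set(counts_tumor))
    pvals, fcs = [], []
    for g in genes:
        cn = np.asarray(counts_normal[g], dtype=float)
        ct = np.asarray(counts_tumor[g], dtype=float)
        fcs.append(math.log2((ct.mean() + pseudocount) / (cn.mean() + pseudocount)))
        pvals.append(mann_whitney(ct, cn, alternative="two-sided").p_value)
    fdrs = bh_fdr(pvals)
    return {g: (fc, fdr) for g, fc, fdr in zip(genes, fcs, fdrs)}


def integrate_expression_changes(
    k27_changes: Mapping[str, tuple[float, str]],
    signal_normal: Mapping[str, float],
    signal_tumor: Mapping[str, float],
    de_table: Mapping[str, tuple[float, float]],
    expr_fc_threshold: float = 1.0,
    expr_fdr_threshold: float = 0.05,
) -> list[DifferentialCall]:
    """Cross repressive-mark change with expression change per gene.

    activated = loss AND expr log2FC > threshold AND FDR < threshold;
    silenced = gain AND expr log2FC < -threshold AND FDR < threshold.
    Genes absent from the DE table keep k27-only labels (loss_only /
    gain_only / stable).
    """
    calls: list[DifferentialCall] = []
    for gene_id in sorted(k27_changes):
        fc, k27 = k27_changes[gene_id]
        call = DifferentialCall(
            gene_id=gene_id,
            signal_normal=signal_normal.get(gene_id, float("nan")),
            signal_tumor=signal_tumor.get(gene_id, float("nan")),
            log2_signal_fc=fc,
            k27_class=k27,
        )
        de = de_table.get(gene_id)
        if de is not None:
            call.expr_log2fc, call.expr_fdr = de
        if k27 == LOSS:
            if (de is not None and call.expr_log2fc > expr_fc_threshold
                    and call.expr_fdr < expr_fdr_threshold):
                call.activation_class = ACTIVATED
            else:
                call.activation_class = LOSS_ONLY
        elif k27 == GAIN:
            if (de is not None and call.expr_log2fc < -expr_fc_threshold
                    and call.expr_fdr < expr_fdr_threshold):
                call.activation_class = SILENCED
            else:
                call.activation_class = GAIN_ONLY
        else:
            call.activation_class = STABLE
        calls.append(call)
    return calls


def activation_summary(
    calls: Sequence[DifferentialCall],
    domain_class_of_gene: Optional[Mapping[str, str]] = None,
    background_expr_log2fc: Optional[Sequence[float]] = None,
) -> ActivationSummary:
    """Counts, percentages, per-class correlation and shift test.

    Percentages are computed from this summary's own counts: loss% and
    gain% of all genes, activated% of loss genes, silenced% of gain genes.
    When domain classes are supplied, a Spearman correlation of signal
    log2FC vs expression log2FC is reported per class; when a background
    expression-change vector is supplied, a rank-sum shift test of the
    activated set against it plus a cumulative-distribution table are
    emitted.
    """
    if not calls:
        raise ValueError("activation_summary requires at least one call")
    n = len(calls)
    n_loss = sum(1 for c in calls if c.k27_class == LOSS)
    n_gain = sum(1 for c in calls if c.k27_class == GAIN)
    n_act = sum(1 for c in calls if c.activation_class == ACTIVATED)
    n_sil = sum(1 for c in calls if c.activation_class == SILENCED)

    corr: dict = {}
    if domain_class_of_gene:
        by_class: dict[str, list[DifferentialCall]] = {}
        for c in calls:
            label = domain_class_of_gene.get(c.gene_id)
            if label is not None:
                by_class.setdefault(label, []).append(c)
        for label, cs in sorted(by_class.items()):
            xs = [c.log2_signal_fc for c in cs if c.expr_log2fc is not None]
            ys = [c.expr_log2fc for c in cs if c.expr_log2fc is not None]
            if len(xs) >= 3 and np.ptp(xs) > 0 and np.ptp(ys) > 0:
                r, p = rank_correlation(xs, ys, method="spearman")
                corr[label] = {"spearman_r": r, "p_value": p, "n": len(xs)}
            else:
                corr[label] = {"spearman_r": None, "p_value": None, "n": len(xs)}

    shift_test = None
    cumulative = None
    if background_expr_log2fc is not None:
        activated_fc = [c.expr_log2fc for c in calls
                        if c.activation_class == ACTIVATED
                        and c.expr_log2fc is not None]
        bg = list(background_expr_log2fc)
        if activated_fc and bg:
            tr = mann_whitney(activated_fc, bg, alternative="greater")
            shift_test = {"statistic": tr.statistic, "p_value": tr.p_value,
                          "n_activated": tr.n1, "n_background": tr.n2}
            grid = np.linspace(
                min(min(activated_fc), min(bg)),
                max(max(activated_fc), max(bg)), 101,
            )
            af = np.sort(activated_fc)
            bf = np.sort(bg)
            cumulative = {
                "log2fc_grid": grid.tolist(),
                "activated_cdf": (np.searchsorted(af, grid, side="right")
                                  / len(af)).tolist(),
                "background_cdf": (np.searchsorted(bf, grid, side="right")
                                   / len(bf)).tolist(),
            }

    return ActivationSummary(
        n_genes=n,
        n_loss=n_loss,
        n_gain=n_gain,
        n_stable=n - n_loss - n_gain,
        n_activated=n_act,
        n_silenced=n_sil,
        pct_loss=_pct(n_loss, n),
        pct_gain=_pct(n_gain, n),
        pct_activated_of_loss=_pct(n_act, n_loss),
        pct_silenced_of_gain=_pct(n_sil, n_gain),
        correlation_by_class=corr,
        shift_test=shift_test,
        cumulative=cumulative,
    )


def region_mark_profiles(
    genes: Sequence[GeneModel],
    tracks: Mapping[str, Mapping[str, CoverageTrack]],
    methylation: Optional[Mapping[str, CoverageTrack]] = None,
    upstream: int = 5000,
    downstream: int = 10000,
    n_bins: int = 60,
    promoter_halfwidth: int = 2000,
) -> dict:
    """Mean mark profiles over TSS-upstream ... TES+downstream plus
    promoter/body methylation deltas.

    ``tracks`` maps mark -> condition -> CoverageTrack (conditions "normal"
    and "tumor").  Methylation deltas are means over the promoter
    (TSS +/- promoter_halfwidth) and the gene body beyond the promoter
    (TSS+promoter_halfwidth ... TES), reported with a flag for the
    body-hypermethylation-without-promoter-hypomethylation signature.
    """
    if not genes:
        raise ValueError("no genes to profile")

    def _region_profile(track: CoverageTrack, gene: GeneModel) -> np.ndarray:
        if gene.strand == "+":
            start = max(0, gene.tss - upstream)
            end = gene.tes + downstream
            vals = track.binned_means(gene.chrom, start, end, n_bins)
        else:
            start = max(0, gene.tes - downstream)
            end = gene.tss + upstream
            vals = track.binned_means(gene.chrom, start, end, n_bins)[::-1]
        return vals

    profiles: dict = {}
    for mark, by_cond in tracks.items():
        profiles[mark] = {}
        for cond, track in by_cond.items():
            if track is None:
                logger.warning("mark %s condition %s missing; skipped", mark, cond)
                continue
            mat = np.vstack([_region_profile(track, g) for g in genes])
            profiles[mark][cond] = mat.mean(axis=0).tolist()

    meth: Optional[dict] = None
    if methylation is not None and all(
        methylation.get(c) is not None for c in ("normal", "tumor")
    ):
        prom_delta, body_delta = [], []
        for g in genes:
            prom = (max(0, g.tss - promoter_halfwidth), g.tss + promoter_halfwidth)
            if g.strand == "+":
                body = (g.tss + promoter_halfwidth, g.tes)
            else:
                body = (g.tes, g.tss - promoter_halfwidth)
            if body[1] <= body[0]:
                continue
            dn = methylation["tumor"].mean_over(g.chrom, *prom) - \
                methylation["normal"].mean_over(g.chrom, *prom)
            db = methylation["tumor"].mean_over(g.chrom, *body) - \
                methylation["normal"].mean_over(g.chrom, *body)
            prom_delta.append(dn)
            body_delta.append(db)
        mp, mb = float(np.mean(prom_delta)), float(np.mean(body_delta))
        meth = {
            "promoter_delta_mean": mp,
            "body_delta_mean": mb,
            "n_genes": len(body_delta),
            "body_hyper_without_promoter_hypo": bool(mb > 0 and mp >= -0.01),
        }
    return {"profiles": profiles, "methylation": meth,
            "upstream": upstream, "downstream": downstream, "n_bins": n_bins}
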