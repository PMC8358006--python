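"""Synthetic paired normal/tumor epigenome with planted ground truth.

Generates every input the pipeline consumes — repressive-mark peaks with a
heavy-tailed breadth distribution, breadth-linked coverage tracks for four
histone marks with matched inputs, methylation tracks, an expression table
with replicate counts, gene/constraint tables, TADs and loops — plus a
truth JSON that records the planted class and tumor state of every domain
and gene, keyed to the seed.

Layout is deterministic given the seed: independent PCG64 streams are
derived for layout, constraint, epigenome and interaction stages so that
each stage can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from silencerkit import io
from silencerkit.core import ChromatinLoop, GeneModel, GenomicInterval

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_reference",
    "simulate_epigenome_pair",
    "simulate_interactions",
    "simulate_all",
    "write_manifest",
]

MARKS = ("h3k27me3", "h3k4me3", "h3k27ac", "h3k4me1")
TOTAL_MAPPED = 20_000_000  # library size recorded for every read-derived track
INPUT_RPKM = 1.0           # flat input level inside domains
_DEPTH = lambda rpkm: rpkm * TOTAL_MAPPED / 1e9  # per-bp depth for target RPKM


@dataclass
class SimulationConfig:
    """Generator parameters; fractions default to the planted loss/gain/
    activation rates the pipeline is expected to recover."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 30_000_000
    n_genes: int = 1200
    n_peaks: int = 2000
    # breadth law: lognormal body plus Pareto tail
    breadth_log_mean: float = math.log(4500.0)
    breadth_log_sigma: float = 0.6
    breadth_body_max: int = 40_000
    tail_fraction: float = 0.035
    tail_scale: int = 60_000
    tail_alpha: float = 2.5
    tail_max: int = 320_000
    # signal link: log2 signal = a + b * log2(breadth/1kb) + N(0, sigma)
    signal_a: float = 1.0
    signal_b: float = 0.8
    signal_sigma: float = 0.3
    # expression
    repression_slope: float = 2.5  # log2-TPM drop per 100 kb of mark breadth
    expr_log2_mean: float = 5.0
    expr_log2_sigma: float = 1.0
    n_reps: int = 9
    nb_dispersion: float = 0.02
    depth_factor: float = 2.0
    # tumor dynamics
    loss_fraction: float = 0.66
    gain_fraction: float = 0.184
    activation_fraction_given_loss: float = 0.373
    silenced_fraction_given_gain: float = 0.194
    activation_log2fc_low: float = 2.0
    activation_log2fc_high: float = 4.0
    # constraint shifts for grand-marked genes
    constraint_z_shift: float = 1.2
    dnds_shift: float = 0.5
    # 3D genome
    tad_count: int = 60  # approximate TADs per chromosome
    tad_span_fraction: float = 0.4
    loop_density: int = 75  # background loops per chromosome
    p_in: float = 0.35
    p_out: float = 0.0
    target_loop_fraction: float = 0.4
    anchor_width: int = 5000
    # methylation
    methylation_body_shift: float = 0.25
    methylation_baseline: float = 0.5
    methylation_run: int = 200

    def __post_init__(self):
        for name in ("tail_fraction", "loss_fraction", "gain_fraction",
                     "activation_fraction_given_loss",
                     "silenced_fraction_given_gain", "tad_span_fraction",
                     "p_in", "p_out", "target_loop_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.loss_fraction + self.gain_fraction > 1.0:
            raise ValueError("loss_fraction + gain_fraction > 1")
        if self.tail_scale <= 0 or self.breadth_body_max <= 0:
            raise ValueError("breadth law must yield positive lengths")

    @property
    def null_interactions(self) -> bool:
        """Loops independent of domain placement when p_in == p_out."""
        return self.p_in == self.p_out

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}

    # -- key=value config file --------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for _, line in io._data_lines(path):
            if "=" not in line:
                raise ValueError(f"bad config line (need key=value): {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValueError(f"unknown config key: {key}")
            anno = str(fields[key])
            kwargs[key] = int(raw) if "int" in anno else float(raw)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("# silencerkit simulation config\n")
            for key, val in asdict(self).items():
                fh.write(f"{key}={val}\n")


@dataclass
class _PlantedDomain:
    domain_id: str
    chrom: str
    start: int
    end: int
    is_grand: bool
    split_points: list[int] = field(default_factory=list)
    signal_rpkm: float = 0.0
    tumor_state: str = "stable"   # loss / gain / stable
    tumor_scale: float = 1.0

    @property
    def breadth(self) -> int:
        return self.end - self.start


@dataclass
class _PlantedGene:
    gene: GeneModel
    domain_id: Optional[str]
    marked_class: str           # grand / typical / unmarked
    tpm_normal: float = 0.0
    tpm_tumor: float = 0.0
    state: str = "none"         # activated / silenced / loss / gain / none


@dataclass
class SyntheticTruth:
    seed: int
    domains: list[_PlantedDomain]
    genes: list[_PlantedGene]
    config: SimulationConfig

    def grand_domains(self) -> list[_PlantedDomain]:
        return [d for d in self.domains if d.is_grand]

    def fractions(self) -> dict:
        grand = self.grand_domains()
        n_loss = sum(1 for d in grand if d.tumor_state == "loss")
        n_gain = sum(1 for d in grand if d.tumor_state == "gain")
        loss_genes = [g for g in self.genes if g.state in ("loss", "activated")]
        gain_genes = [g for g in self.genes if g.state in ("gain", "silenced")]
        n_act = sum(1 for g in self.genes if g.state == "activated")
        n_sil = sum(1 for g in self.genes if g.state == "silenced")
        return {
            "n_grand": len(grand),
            "loss_fraction": n_loss / len(grand) if grand else 0.0,
            "gain_fraction": n_gain / len(grand) if grand else 0.0,
            "activation_fraction_given_loss":
                n_act / len(loss_genes) if loss_genes else 0.0,
            "silenced_fraction_given_gain":
                n_sil / len(gain_genes) if gain_genes else 0.0,
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config": asdict(self.config),
            "fractions": self.fractions(),
            "domains": [asdict(d) for d in self.domains],
            "genes": [{
                "gene_id": g.gene.gene_id,
                "chrom": g.gene.chrom,
                "strand": g.gene.strand,
                "tss": g.gene.tss,
                "tes": g.gene.tes,
                "domain_id": g.domain_id,
                "marked_class": g.marked_class,
                "tpm_normal": g.tpm_normal,
                "tpm_tumor": g.tpm_tumor,
                "state": g.state,
            } for g in self.genes],
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.PCG64(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    ))


# ---------------------------------------------------------------------------
# layout: domains and genes (stream 0)
# ---------------------------------------------------------------------------

def _build_layout(config: SimulationConfig) -> SyntheticTruth:
    rng = _rng(config, 0)
    chroms = config.chrom_names()
    per_chrom = [config.n_peaks // config.n_chroms] * config.n_chroms
    for i in range(config.n_peaks % config.n_chroms):
        per_chrom[i] += 1

    domains: list[_PlantedDomain] = []
    margin = 100_000
    for ci, chrom in enumerate(chroms):
        cursor = margin
        for _ in range(per_chrom[ci]):
            if rng.random() < config.tail_fraction:
                breadth = int(min(
                    config.tail_scale * (1.0 + rng.pareto(config.tail_alpha)),
                    config.tail_max,
                ))
                is_grand = True
            else:
                breadth = int(np.clip(
                    rng.lognormal(config.breadth_log_mean,
                                  config.breadth_log_sigma),
                    500, config.breadth_body_max,
                ))
                is_grand = False
            gap = int(rng.integers(6000, 30000))
            start = cursor + gap
            end = start + breadth
            if end > config.chrom_length - margin:
                raise ValueError(
                    f"genome too small: ran out of space on {chrom} "
                    f"({per_chrom[ci]} peaks on {config.chrom_length} bp)"
                )
            split_points: list[int] = []
            if is_grand and rng.random() < 0.3:
                # emit this domain as 2-3 peaks with sub-merge-gap spacing
                n_cuts = int(rng.integers(1, 3))
                cuts = sorted(rng.integers(start + 5000, end - 5000,
                                           size=n_cuts).tolist())
                split_points = [int(c) for c in cuts]
            domains.append(_PlantedDomain(
                domain_id=f"P{len(domains):05d}",
                chrom=chrom, start=start, end=end, is_grand=is_grand,
                split_points=split_points,
            ))
            cursor = end

    # gene slots: one per grand domain first, then typical-domain and
    # inter-domain-gap slots interleaved
    grand_slots: list[tuple] = []
    other_slots: list[tuple] = []
    by_chrom: dict[str, list[_PlantedDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom in chroms:
        ds = by_chrom.get(chrom, [])
        for i, d in enumerate(ds):
            if d.is_grand:
                glen = int(min(rng.integers(5000, 15000), d.breadth - 12_000))
                gstart = d.start + int(rng.integers(3000, 5000))
                grand_slots.append((chrom, gstart, gstart + glen, d))
            else:
                if rng.random() < 0.5 and d.breadth >= 1500:
                    glen = int(rng.integers(2000, 8000))
                    gstart = d.start + 100
                    gend = min(gstart + glen, d.end + 1500)
                    if gend > gstart + 500:
                        other_slots.append((chrom, gstart, gend, d))
            # gap slot after this domain
            nxt = ds[i + 1].start if i + 1 < len(ds) else config.chrom_length
            lo, hi = d.end + 3000, nxt - 3000
            if hi - lo > 4000 and rng.random() < 0.5:
                glen = int(rng.integers(2000, min(8000, hi - lo)))
                other_slots.append((chrom, lo, lo + glen, None))

    slots = grand_slots + other_slots
    if len(slots) < config.n_genes:
        raise ValueError(
            f"genome too small to place {config.n_genes} genes "
            f"(only {len(slots)} slots)"
        )
    slots = slots[: config.n_genes]

    genes: list[_PlantedGene] = []
    for gi, (chrom, gstart, gend, dom) in enumerate(
        sorted(slots, key=lambda s: (s[0], s[1]))
    ):
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (gstart, gend) if strand == "+" else (gend, gstart)
        gene = GeneModel(f"g{gi:04d}", chrom, strand, tss, tes)
        if dom is None:
            genes.append(_PlantedGene(gene, None, "unmarked"))
        else:
            genes.append(_PlantedGene(
                gene, dom.domain_id, "grand" if dom.is_grand else "typical"
            ))
    return SyntheticTruth(seed=config.seed, domains=domains, genes=genes,
                          config=config)


# ---------------------------------------------------------------------------
# reference files (stream 1 for constraint draws)
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig, outdir: str | Path,
                       truth: Optional[SyntheticTruth] = None) -> SyntheticTruth:
    """Write gene table, chromosome sizes and constraint table.

    Genes destined to be marked by a planted grand domain draw missense Z
    with a positive location shift and dN/dS with a negative (log-scale)
    shift; everything else draws from the background law.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if truth is None:
        truth = _build_layout(config)
    rng = _rng(config, 1)

    header = io.provenance_header(stage="simulate_reference", seed=config.seed)
    io.write_gene_table(outdir / "genes.tsv",
                        [g.gene for g in truth.genes], header=header)
    io.write_chrom_sizes(outdir / "chrom.sizes", config.chrom_sizes())

    with open(outdir / "constraint.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("gene_id\tmissense_z\tdn_ds\n")
        for g in truth.genes:
            z = rng.normal(0.0, 1.0)
            log_dnds = rng.normal(math.log(0.25), 0.4)
            if g.marked_class == "grand":
                z += config.constraint_z_shift
                log_dnds -= config.dnds_shift
            fh.write(f"{g.gene.gene_id}\t{z:.4f}\t{math.exp(log_dnds):.4f}\n")
    return truth


# ---------------------------------------------------------------------------
# epigenome pair (stream 2)
# ---------------------------------------------------------------------------

def _flatten_runs(runs: list[tuple[int, int, float]],
                  combine: str) -> list[tuple[int, int, float]]:
    """Resolve overlapping runs into a non-overlapping piecewise track.

    ``sum`` models additive read coverage (overlapping fragments pile up);
    ``mean`` averages, for bounded value tracks such as methylation betas.
    """
    events: list[tuple[int, float, int]] = []
    for start, end, value in runs:
        if end > start:
            events.append((start, value, 1))
            events.append((end, -value, -1))
    events.sort()
    out: list[tuple[int, int, float]] = []
    total, count, prev = 0.0, 0, None
    i = 0
    while i < len(events):
        pos = events[i][0]
        if prev is not None and count > 0 and pos > prev:
            value = total if combine == "sum" else total / count
            out.append((prev, pos, value))
        while i < len(events) and events[i][0] == pos:
            total += events[i][1]
            count += events[i][2]
            i += 1
        prev = pos
    return out


def _write_track(path: Path, runs_by_chrom: dict[str, list[tuple[int, int, float]]],
                 header: str, combine: str = "sum",
                 clamp: Optional[tuple[float, float]] = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(header)
        for chrom in sorted(runs_by_chrom):
            for start, end, value in _flatten_runs(runs_by_chrom[chrom], combine):
                if clamp is not None:
                    value = min(max(value, clamp[0]), clamp[1])
                if value > 1e-12:
                    fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def simulate_epigenome_pair(config: SimulationConfig, outdir: str | Path,
                            truth: Optional[SyntheticTruth] = None
                            ) -> SyntheticTruth:
    """Write peaks, coverage, methylation, expression and truth JSON for a
    normal/tumor pair.

    Tumor "loss" scales repressive-mark coverage of planted grand domains
    down at least 4-fold (multiplicative, not peak deletion); "gain" scales
    it up; activated genes get an expression log2FC above the activation
    threshold, a methylation shift over the gene body only, and elevated
    active-mark coverage via their expression link.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if truth is None:
        truth = _build_layout(config)
    rng = _rng(config, 2)
    header = io.provenance_header(stage="simulate_epigenome_pair",
                                  seed=config.seed)

    # -- domain signal and tumor state ------------------------------------
    for d in truth.domains:
        log2sig = (config.signal_a
                   + config.signal_b * math.log2(d.breadth / 1000.0)
                   + rng.normal(0.0, config.signal_sigma))
        d.signal_rpkm = max(0.05, 2.0 ** log2sig)
        if d.is_grand:
            u = rng.random()
            if u < config.loss_fraction:
                d.tumor_state, d.tumor_scale = "loss", float(rng.uniform(0.08, 0.22))
            elif u < config.loss_fraction + config.gain_fraction:
                d.tumor_state, d.tumor_scale = "gain", float(rng.uniform(3.0, 5.0))

    # -- peaks -------------------------------------------------------------
    peaks = []
    for d in truth.domains:
        bounds = [d.start] + d.split_points + [d.end]
        for a, b in zip(bounds, bounds[1:]):
            # split pieces separated by < merge gap so calling re-unifies them
            peaks.append(GenomicInterval(d.chrom, a, max(a + 1, b - 800)
                                         if b != d.end else b))
    for cond in ("normal", "tumor"):
        io.write_bed(outdir / f"peaks_h3k27me3_{cond}.bed", peaks, header=header)

    # -- H3K27me3 coverage -------------------------------------------------
    dom_by_chrom: dict[str, list[_PlantedDomain]] = {}
    for d in truth.domains:
        dom_by_chrom.setdefault(d.chrom, []).append(d)
    for cond in ("normal", "tumor"):
        treat: dict[str, list] = {}
        inp: dict[str, list] = {}
        for chrom, ds in dom_by_chrom.items():
            for d in ds:
                sig = d.signal_rpkm * (d.tumor_scale if cond == "tumor" else 1.0)
                treat.setdefault(chrom, []).append(
                    (d.start, d.end, _DEPTH(sig + INPUT_RPKM)))
                inp.setdefault(chrom, []).append(
                    (d.start, d.end, _DEPTH(INPUT_RPKM)))
        _write_track(outdir / f"h3k27me3_{cond}_treat.bedgraph", treat, header)
        _write_track(outdir / f"h3k27me3_{cond}_input.bedgraph", inp, header)

    # -- gene states and expression ---------------------------------------
    breadth_of = {d.domain_id: d.breadth for d in truth.domains}
    state_of = {d.domain_id: d.tumor_state for d in truth.domains}
    for g in truth.genes:
        base = rng.normal(config.expr_log2_mean, config.expr_log2_sigma)
        if g.domain_id is not None:
            base -= config.repression_slope * breadth_of[g.domain_id] / 1e5
        shift = float(np.clip(rng.normal(0.0, 0.2), -0.8, 0.8))
        dstate = state_of.get(g.domain_id, "stable") if g.domain_id else "stable"
        if g.marked_class == "grand" and dstate == "loss":
            if rng.random() < config.activation_fraction_given_loss:
                g.state = "activated"
                shift = float(rng.uniform(config.activation_log2fc_low,
                                          config.activation_log2fc_high))
            else:
                g.state = "loss"
        elif g.marked_class == "grand" and dstate == "gain":
            if rng.random() < config.silenced_fraction_given_gain:
                g.state = "silenced"
                shift = -float(rng.uniform(config.activation_log2fc_low,
                                           config.activation_log2fc_high))
            else:
                g.state = "gain"
        g.tpm_normal = 2.0 ** base
        g.tpm_tumor = 2.0 ** (base + shift)

    size = 1.0 / config.nb_dispersion
    with open(outdir / "expression.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        cols = (["gene_id", "tpm_normal", "tpm_tumor"]
                + [f"count_normal_{i + 1}" for i in range(config.n_reps)]
                + [f"count_tumor_{i + 1}" for i in range(config.n_reps)])
        fh.write("\t".join(cols) + "\n")
        for g in truth.genes:
            counts = []
            for tpm in (g.tpm_normal, g.tpm_tumor):
                mu = max(tpm * config.depth_factor, 0.01)
                p = size / (size + mu)
                counts.extend(rng.negative_binomial(size, p, size=config.n_reps)
                              .tolist())
            fh.write(f"{g.gene.gene_id}\t{g.tpm_normal:.4f}\t{g.tpm_tumor:.4f}\t"
                     + "\t".join(str(c) for c in counts) + "\n")

    # -- active marks ------------------------------------------------------
    for mark in ("h3k4me3", "h3k27ac", "h3k4me1"):
        for cond in ("normal", "tumor"):
            treat = {}
            inp = {}
            for g in truth.genes:
                tpm = g.tpm_normal if cond == "normal" else g.tpm_tumor
                jitter = float(rng.uniform(0.9, 1.1))
                value = _DEPTH(0.5 + 0.2 * tpm / 10.0) * jitter
                tss = g.gene.tss
                treat.setdefault(g.gene.chrom, []).append(
                    (max(0, tss - 1000), tss + 1000, value))
                inp.setdefault(g.gene.chrom, []).append(
                    (max(0, tss - 2000), tss + 2000, _DEPTH(0.25)))
            _write_track(outdir / f"{mark}_{cond}_treat.bedgraph", treat, header)
            _write_track(outdir / f"{mark}_{cond}_input.bedgraph", inp, header)

    # -- methylation (beta values, fixed-width runs) -----------------------
    run = config.methylation_run
    meth_normal: dict[str, list] = {}
    meth_tumor: dict[str, list] = {}
    for g in truth.genes:
        body = g.gene.body
        lo = max(0, body.start - 3000)
        hi = body.end + 3000
        if g.gene.strand == "+":
            shifted_lo, shifted_hi = g.gene.tss + 2000, g.gene.tes
        else:
            shifted_lo, shifted_hi = g.gene.tes, g.gene.tss - 2000
        for s in range(lo, hi, run):
            e = min(s + run, hi)
            beta = float(np.clip(rng.normal(config.methylation_baseline, 0.05),
                                 0.0, 1.0))
            meth_normal.setdefault(g.gene.chrom, []).append((s, e, beta))
            tb = beta
            if g.state == "activated" and shifted_lo <= s and e <= shifted_hi:
                tb = float(min(1.0, beta + config.methylation_body_shift))
            meth_tumor.setdefault(g.gene.chrom, []).append((s, e, tb))
    _write_track(outdir / "methylation_normal.bedgraph", meth_normal, header,
                 combine="mean", clamp=(0.0, 1.0))
    _write_track(outdir / "methylation_tumor.bedgraph", meth_tumor, header,
                 combine="mean", clamp=(0.0, 1.0))

    # -- track metadata and truth -----------------------------------------
    with open(outdir / "tracks.tsv", "wt", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("file\tmark\tcondition\trole\ttotal_mapped\n")
        for mark in MARKS:
            for cond in ("normal", "tumor"):
                for role in ("treat", "input"):
                    fh.write(f"{mark}_{cond}_{role}.bedgraph\t{mark}\t{cond}"
                             f"\t{role}\t{TOTAL_MAPPED}\n")
        for cond in ("normal", "tumor"):
            fh.write(f"methylation_{cond}.bedgraph\tmethylation\t{cond}"
                     f"\tbeta\t0\n")
    truth.to_json(outdir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# TADs and loops (stream 3)
# ---------------------------------------------------------------------------

def simulate_interactions(config: SimulationConfig, truth: SyntheticTruth,
                          outdir: str | Path) -> None:
    """Write a TAD BED tiling each chromosome and a loop BEDPE.

    A ``tad_span_fraction`` of planted grand domains get a TAD placed just
    inside them (so the domain covers >= 90% of it).  Loops join pairs of
    grand domains with probability ``p_in`` on top of uniform background
    loops; when ``p_in == p_out`` (null mode) only uniform loops are
    emitted, independent of domain placement.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 3)
    header = io.provenance_header(stage="simulate_interactions",
                                  seed=config.seed)
    target_size = config.chrom_length // config.tad_count
    if target_size < 2000:
        raise ValueError(
            f"tad_count={config.tad_count} exceeds chromosome capacity"
        )

    grand = truth.grand_domains()
    grand_by_chrom: dict[str, list[_PlantedDomain]] = {}
    for d in grand:
        grand_by_chrom.setdefault(d.chrom, []).append(d)

    tads: list[GenomicInterval] = []
    for chrom in config.chrom_names():
        anchors_points = []
        special: list[tuple[int, int]] = []
        for d in grand_by_chrom.get(chrom, []):
            if rng.random() < config.tad_span_fraction:
                pad = max(1, int(0.02 * d.breadth))
                special.append((d.start + pad, d.end - pad))
        special.sort()
        # drop any special TADs that collide (domains never overlap, so
        # collisions cannot happen; keep the guard anyway)
        cleaned = []
        for s, e in special:
            if not cleaned or s >= cleaned[-1][1]:
                cleaned.append((s, e))
        boundaries = [0] + [x for s, e in cleaned for x in (s, e)] \
            + [config.chrom_length]
        for a, b in zip(boundaries, boundaries[1:]):
            if b <= a:
                continue
            if (a, b) in cleaned:
                tads.append(GenomicInterval(chrom, a, b, name="tad_grand"))
            else:
                n_fill = max(1, round((b - a) / target_size))
                edges = np.linspace(a, b, n_fill + 1).astype(int)
                for s, e in zip(edges, edges[1:]):
                    if e > s:
                        tads.append(GenomicInterval(chrom, int(s), int(e),
                                                    name="tad"))
    io.write_bed(outdir / "tads.bed", tads, header=header)

    loops: list[ChromatinLoop] = []
    w = config.anchor_width

    def _uniform_anchor(chrom: str) -> GenomicInterval:
        s = int(rng.integers(0, config.chrom_length - w))
        return GenomicInterval(chrom, s, s + w)

    def _domain_anchor(d: _PlantedDomain) -> GenomicInterval:
        s = int(rng.integers(d.start, max(d.start + 1, d.end - w)))
        return GenomicInterval(d.chrom, s, min(s + w, d.end))

    n_background = config.loop_density * config.n_chroms
    for _ in range(n_background):
        chrom = config.chrom_names()[int(rng.integers(0, config.n_chroms))]
        loops.append(ChromatinLoop(_uniform_anchor(chrom),
                                   _uniform_anchor(chrom)))
    if not config.null_interactions:
        for chrom, ds in grand_by_chrom.items():
            for i in range(len(ds)):
                for j in range(i + 1, len(ds)):
                    if rng.random() < config.p_in:
                        loops.append(ChromatinLoop(_domain_anchor(ds[i]),
                                                   _domain_anchor(ds[j])))
        genes_by_chrom: dict[str, list[GeneModel]] = {}
        for g in truth.genes:
            genes_by_chrom.setdefault(g.gene.chrom, []).append(g.gene)
        for d in grand:
            if rng.random() < config.target_loop_fraction:
                cands = genes_by_chrom.get(d.chrom, [])
                if cands:
                    tgt = cands[int(rng.integers(0, len(cands)))]
                    s = max(0, tgt.tss - w // 2)
                    loops.append(ChromatinLoop(
                        _domain_anchor(d),
                        GenomicInterval(d.chrom, s, s + w),
                    ))
    io.write_bedpe(outdir / "loops.bedpe", loops, header=header)


# ---------------------------------------------------------------------------
# one-shot driver + manifest
# ---------------------------------------------------------------------------

def write_manifest(outdir: str | Path) -> Path:
    """MANIFEST.tsv listing every emitted file with its sha256."""
    outdir = Path(outdir)
    manifest = outdir / "MANIFEST.tsv"
    rows = []
    for path in sorted(outdir.iterdir()):
        if path.name == "MANIFEST.tsv" or path.is_dir():
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        rows.append((path.name, digest, path.stat().st_size))
    with open(manifest, "wt", encoding="utf-8") as fh:
        fh.write("file\tsha256\tbytes\n")
        for name, digest, size in rows:
            fh.write(f"{name}\t{digest}\t{size}\n")
    return manifest


def simulate_all(config: SimulationConfig, outdir: str | Path) -> SyntheticTruth:
    """Full synthetic run: reference + epigenome pair + interactions +
    config echo + MANIFEST."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = _build_layout(config)
    simulate_reference(config, outdir, truth=truth)
    simulate_epigenome_pair(config, outdir, truth=truth)
    simulate_interactions(config, truth, outdir)
    config.to_file(outdir / "config.txt")
    write_manifest(outdir)
    return truth
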