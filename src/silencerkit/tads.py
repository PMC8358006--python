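"""TAD and chromatin-loop integration for classified domains.

Covers the 3D-genome census (TAD overlap, anchor marking, whole-TAD
spanning), the normalized TAD position profile, loop connectivity and
multiplexity, a length-preserving permutation null for same-class
connectivity, loop-driven target-gene assignment, and enrichment-significance
correlation between two gene sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from silencerkit.core import ChromatinLoop, GeneModel, GenomicInterval, ValidationError
from silencerkit.domains import Domain
from silencerkit.stats import (
    EnrichmentRecord,
    empirical_p,
    hypergeometric_enrichment,
    rank_correlation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TadRelation",
    "PermutationResult",
    "tad_overlap_summary",
    "tad_position_profile",
    "interaction_connectivity",
    "permutation_interaction_test",
    "assign_target_genes",
    "term_enrichment_correlation",
]


@dataclass
class TadRelation:
    domain_id: str
    overlaps_tad: bool
    marks_anchor: bool
    spans_entire_tad: bool
    covered_fraction_of_tad: float

    def __post_init__(self):
        if self.spans_entire_tad and not self.overlaps_tad:
            raise ValidationError("spans_entire_tad implies overlaps_tad")


@dataclass
class PermutationResult:
    observed: int
    null_counts: list[int]
    p: float
    seed: int
    shuffle_mode: str

    @property
    def n_perm(self) -> int:
        return len(self.null_counts)


class _AnchorIndex:
    """Per-chromosome anchor arrays for vectorized overlap queries."""

    def __init__(self, loops: Sequence[ChromatinLoop]):
        # anchor id = 2*loop_index + side
        self.n_anchors = 2 * len(loops)
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for li, loop in enumerate(loops):
            for side, anchor in enumerate(loop.anchors()):
                by_chrom.setdefault(anchor.chrom, []).append(
                    (anchor.start, anchor.end, 2 * li + side)
                )
        self.chrom_arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            self.chrom_arrays[chrom] = (
                np.array([r[0] for r in recs], dtype=np.int64),
                np.array([r[1] for r in recs], dtype=np.int64),
                np.array([r[2] for r in recs], dtype=np.int64),
            )

    def overlapping_anchors(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Anchor ids overlapping [start, end) by >= 1 bp."""
        arrs = self.chrom_arrays.get(chrom)
        if arrs is None:
            return np.empty(0, dtype=np.int64)
        starts, ends, ids = arrs
        mask = (starts < end) & (ends > start)
        return ids[mask]


def _connectivity(
    intervals: Sequence[tuple[str, int, int]],
    loops: Sequence[ChromatinLoop],
    index: Optional[_AnchorIndex] = None,
) -> tuple[set[int], dict[int, int]]:
    """Same-set loop connectivity over bare intervals.

    Returns (connected interval indices, partner-anchor count per interval
    touching >= 1 loop).  An interval is connected iff some loop has one
    anchor overlapping it and the other anchor overlapping a *different*
    interval of the set; a loop with both anchors inside one interval is a
    self-loop and does not connect.
    """
    if index is None:
        index = _AnchorIndex(loops)
    # anchor id -> interval indices overlapping it
    anchor_hits: dict[int, list[int]] = {}
    for di, (chrom, start, end) in enumerate(intervals):
        for aid in index.overlapping_anchors(chrom, start, end):
            anchor_hits.setdefault(int(aid), []).append(di)
    connected: set[int] = set()
    # partner anchors are deduplicated by genomic coordinates, not loop side
    partner_anchors: dict[int, set[tuple[str, int, int]]] = {}
    for li, loop in enumerate(loops):
        a_hits = anchor_hits.get(2 * li, [])
        b_hits = anchor_hits.get(2 * li + 1, [])
        a_key = (loop.anchor1.chrom, loop.anchor1.start, loop.anchor1.end)
        b_key = (loop.anchor2.chrom, loop.anchor2.start, loop.anchor2.end)
        for di in a_hits:
            partner_anchors.setdefault(di, set()).add(b_key)
            if any(dj != di for dj in b_hits):
                connected.add(di)
        for di in b_hits:
            partner_anchors.setdefault(di, set()).add(a_key)
            if any(dj != di for dj in a_hits):
                connected.add(di)
    counts = {di: len(aids) for di, aids in partner_anchors.items()}
    return connected, counts


def _check_tads(tads: Sequence[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        ts.sort()
        for prev, nxt in zip(ts, ts[1:]):
            if nxt.start < prev.end:
                raise ValidationError(
                    f"overlapping TADs on {chrom} near {nxt.start}"
                )
    return by_chrom


def tad_overlap_summary(
    domains_by_class: Mapping[str, Sequence[Domain]],
    tads: Sequence[GenomicInterval],
    loops: Sequence[ChromatinLoop],
    coverage_threshold: float = 0.9,
) -> dict[str, list[TadRelation]]:
    """Per-class census of TAD overlap, anchor marking and whole-TAD spanning.

    ``spans_entire_tad`` is set when the domain covers >= coverage_threshold
    of some TAD's length (strict >= at the threshold).
    """
    tads_by_chrom = _check_tads(tads)
    index = _AnchorIndex(loops)
    out: dict[str, list[TadRelation]] = {}
    for label, domains in domains_by_class.items():
        relations = []
        for d in domains:
            overlaps_tad = False
            best_frac = 0.0
            for t in tads_by_chrom.get(d.chrom, ()):
                if t.start >= d.end:
                    break
                ov = d.interval.overlap_length(t)
                if ov > 0:
                    overlaps_tad = True
                    best_frac = max(best_frac, ov / t.length)
            marks_anchor = len(index.overlapping_anchors(d.chrom, d.start, d.end)) > 0
            relations.append(TadRelation(
                domain_id=d.domain_id,
                overlaps_tad=overlaps_tad,
                marks_anchor=marks_anchor,
                spans_entire_tad=best_frac >= coverage_threshold,
                covered_fraction_of_tad=best_frac,
            ))
        out[label] = relations
    return out


def tad_position_profile(
    domains_by_class: Mapping[str, Sequence[Domain]],
    tads: Sequence[GenomicInterval],
    n_bins: int = 20,
) -> dict:
    """Density of domain midpoints over TAD-normalized positions [-1, 1].

    Each domain is assigned to the TAD of maximal overlap; position 0 is the
    TAD center, -1/+1 the boundaries.  Histograms are normalized to unit
    area per class.  Domains overlapping no TAD are excluded and counted.
    """
    tads_by_chrom = _check_tads(tads)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    out: dict = {"bin_edges": edges.tolist(), "classes": {}}
    for label, domains in domains_by_class.items():
        positions = []
        excluded = 0
        for d in domains:
            best_ov, best_tad = 0, None
            for t in tads_by_chrom.get(d.chrom, ()):
                if t.start >= d.end:
                    break
                ov = d.interval.overlap_length(t)
                if ov > best_ov:
                    best_ov, best_tad = ov, t
            if best_tad is None:
                excluded += 1
                continue
            pos = 2.0 * (d.interval.midpoint - best_tad.midpoint) / best_tad.length
            positions.append(max(-1.0, min(1.0, pos)))
        if positions:
            hist, _ = np.histogram(positions, bins=edges, density=True)
        else:
            hist = np.zeros(n_bins)
        out["classes"][label] = {
            "density": hist.tolist(),
            "n_domains": len(positions),
            "n_excluded": excluded,
        }
    return out


def interaction_connectivity(
    domains_by_class: Mapping[str, Sequence[Domain]],
    loops: Sequence[ChromatinLoop],
) -> dict:
    """Per-class connectivity fraction and multiplexity histogram.

    A domain is connected when a loop joins it to a different domain of the
    same class.  Multiplexity counts distinct partner anchors reached by a
    domain's overlapping loops, bucketed 1 / 2 / >=3.
    """
    index = _AnchorIndex(loops)
    out: dict = {}
    for label, domains in domains_by_class.items():
        intervals = [(d.chrom, d.start, d.end) for d in domains]
        connected, counts = _connectivity(intervals, loops, index)
        histogram = {"1": 0, "2": 0, ">=3": 0}
        for di, c in counts.items():
            if c == 1:
                histogram["1"] += 1
            elif c == 2:
                histogram["2"] += 1
            else:
                histogram[">=3"] += 1
        out[label] = {
            "n_domains": len(domains),
            "n_connected": len(connected),
            "connected_fraction": len(connected) / len(domains) if domains else 0.0,
            "partner_anchor_counts": {
                domains[di].domain_id: c for di, c in sorted(counts.items())
            },
            "multiplexity": histogram,
        }
    return out


def permutation_interaction_test(
    grand_domains: Sequence[Domain],
    loops: Sequence[ChromatinLoop],
    chrom_sizes: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation null for the count of grand domains connected to another.

    Each permutation relocates every grand domain uniformly on its own
    chromosome with length preserved (shuffled domains may overlap each
    other), recomputes the same-set connected count, and the p-value is the
    add-one upper-tail empirical probability.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    for d in grand_domains:
        if d.chrom not in chrom_sizes:
            raise ValidationError(f"no chromosome size for {d.chrom}")
        if d.breadth > chrom_sizes[d.chrom]:
            raise ValidationError(
                f"domain {d.domain_id} longer than chromosome {d.chrom}"
            )
    index = _AnchorIndex(loops)
    intervals = [(d.chrom, d.start, d.end) for d in grand_domains]
    observed = len(_connectivity(intervals, loops, index)[0])
    rng = np.random.default_rng(seed)
    lengths = np.array([d.breadth for d in grand_domains], dtype=np.int64)
    maxstarts = np.array(
        [chrom_sizes[d.chrom] - d.breadth for d in grand_domains], dtype=np.int64
    )
    chroms = [d.chrom for d in grand_domains]
    null_counts: list[int] = []
    for _ in range(n_perm):
        starts = rng.integers(0, maxstarts + 1)
        shuffled = [
            (chroms[i], int(starts[i]), int(starts[i] + lengths[i]))
            for i in range(len(grand_domains))
        ]
        null_counts.append(len(_connectivity(shuffled, loops, index)[0]))
    p = empirical_p(observed, null_counts, tail="greater")
    return PermutationResult(
        observed=observed,
        null_counts=null_counts,
        p=p,
        seed=seed,
        shuffle_mode="uniform-per-chromosome-length-preserving",
    )


def _interval_distance(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def assign_target_genes(
    grand_domains: Sequence[Domain],
    loops: Sequence[ChromatinLoop],
    genes: Sequence[GeneModel],
    distance: int = 3000,
    marked_gene_ids: Optional[set[str]] = None,
) -> dict:
    """Loop-partner target genes of each grand domain.

    For each loop anchor overlapping a grand domain, genes whose body lies
    within ``distance`` bp of (or overlaps) the partner anchor are that
    domain's targets.  Loops with both anchors in grand domains contribute
    in both directions; targets are deduplicated per domain.
    """
    targets: dict[str, set[str]] = {d.domain_id: set() for d in grand_domains}
    index = _AnchorIndex(loops)
    did_of = {i: d.domain_id for i, d in enumerate(grand_domains)}
    # anchor id -> overlapping grand-domain indices
    anchor_hits: dict[int, list[int]] = {}
    for di, d in enumerate(grand_domains):
        for aid in index.overlapping_anchors(d.chrom, d.start, d.end):
            anchor_hits.setdefault(int(aid), []).append(di)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for li, loop in enumerate(loops):
        for side in (0, 1):
            hits = anchor_hits.get(2 * li + side, [])
            if not hits:
                continue
            partner = loop.anchors()[1 - side]
            for g in genes_by_chrom.get(partner.chrom, ()):
                dist = _interval_distance(g.body, partner)
                if dist is not None and dist <= distance:
                    for di in hits:
                        targets[did_of[di]].add(g.gene_id)
    all_targets = set().union(*targets.values()) if targets else set()
    report = {
        "n_domains_with_targets": sum(1 for s in targets.values() if s),
        "n_target_genes": len(all_targets),
    }
    if marked_gene_ids is not None:
        report["n_targets_also_marked"] = len(all_targets & marked_gene_ids)
    return {"targets": {k: sorted(v) for k, v in targets.items()},
            "target_gene_ids": sorted(all_targets),
            "report": report}


def term_enrichment_correlation(
    gene_set_a: set[str],
    gene_set_b: set[str],
    term_db: Mapping[str, set[str]],
    universe: set[str],
    p_cut: float = 0.01,
    ef_cut: float = 1.5,
    method: str = "spearman",
) -> dict:
    """Correlate -log10 enrichment p of two gene sets over shared terms.

    Per-set cumulative hypergeometric enrichment for every term; terms
    passing p < p_cut and enrichment factor > ef_cut in either set are
    retained, and the correlation runs across those terms' -log10 p values
    in both sets.  Fewer than 3 retained terms skips the correlation.
    """
    if not term_db:
        raise ValueError("term_db is empty")
    for term, members in term_db.items():
        if not members <= universe:
            raise ValueError(f"term {term} has genes outside the universe")
    a = gene_set_a & universe
    b = gene_set_b & universe
    N = len(universe)
    records_a: dict[str, EnrichmentRecord] = {}
    records_b: dict[str, EnrichmentRecord] = {}
    for term, members in term_db.items():
        K = len(members)
        records_a[term] = hypergeometric_enrichment(
            len(a & members), len(a), K, N, term_id=term)
        records_b[term] = hypergeometric_enrichment(
            len(b & members), len(b), K, N, term_id=term)

    def _passes(rec: EnrichmentRecord) -> bool:
        return rec.p_hyper < p_cut and rec.enrichment_factor > ef_cut

    shared = sorted(
        t for t in term_db
        if _passes(records_a[t]) or _passes(records_b[t])
    )
    result: dict = {
        "records_a": records_a,
        "records_b": records_b,
        "shared_terms": shared,
        "r": None,
        "p": None,
        "method": method,
    }
    if len(shared) < 3:
        logger.warning("only %d shared enriched terms; correlation skipped",
                       len(shared))
        return result
    la = [-math.log10(max(records_a[t].p_hyper, 1e-300)) for t in shared]
    lb = [-math.log10(max(records_b[t].p_hyper, 1e-300)) for t in shared]
    try:
        r, p = rank_correlation(la, lb, method=method)
    except ValueError as exc:
        logger.warning("enrichment correlation skipped: %s", exc)
        return result
    result["r"], result["p"] = r, p
    return result
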