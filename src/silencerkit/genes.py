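"""Domain-to-gene mapping and constraint / expression association.

A gene is "marked" by a domain when the domain overlaps the gene body
extended by ``extension`` bp on each side (any overlap >= 1 bp); its mark
breadth is the maximum breadth over overlapping domains and its class is
inherited from that broadest domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from silencerkit.core import GeneModel
from silencerkit.domains import Domain, GRAND
from silencerkit.stats import mann_whitney, rank_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "GeneMark",
    "ConstraintRecord",
    "map_domains_to_genes",
    "constraint_association",
    "breadth_expression_trend",
]


@dataclass
class GeneMark:
    gene_id: str
    best_domain: Optional[Domain] = None
    mark_breadth: int = 0
    breadth_quantile_bin: int = -1

    @property
    def marked(self) -> bool:
        return self.mark_breadth > 0

    @property
    def class_label(self) -> str:
        return self.best_domain.class_label if self.best_domain else "unmarked"


@dataclass(frozen=True)
class ConstraintRecord:
    gene_id: str
    missense_z: Optional[float]
    dn_ds: Optional[float]

    def __post_init__(self):
        if self.dn_ds is not None and (self.dn_ds < 0 or not np.isfinite(self.dn_ds)):
            raise ValueError(f"gene {self.gene_id}: dN/dS must be finite and >= 0")


def map_domains_to_genes(
    domains: Sequence[Domain],
    genes: Sequence[GeneModel],
    extension: int = 2000,
) -> list[GeneMark]:
    """Mark each gene with the broadest domain overlapping body +/- extension.

    Overlap is half-open: a domain ending exactly at body.start - extension
    does not mark the gene.  Returns one GeneMark per input gene, marked or
    not.
    """
    by_chrom: dict[str, list[Domain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    for ds in by_chrom.values():
        ds.sort(key=lambda d: d.start)

    marks: list[GeneMark] = []
    for gene in genes:
        body = gene.body
        lo = max(0, body.start - extension)
        hi = body.end + extension
        best: Optional[Domain] = None
        for d in by_chrom.get(gene.chrom, ()):
            if d.start >= hi:
                break
            if d.end > lo:  # overlap >= 1 bp with the extended body
                if best is None or d.breadth > best.breadth:
                    best = d
        if best is None:
            marks.append(GeneMark(gene.gene_id))
        else:
            marks.append(GeneMark(gene.gene_id, best_domain=best,
                                  mark_breadth=best.breadth))
    return marks


def constraint_association(
    marks: Sequence[GeneMark],
    constraints: Mapping[str, ConstraintRecord],
    n_bins: int = 5,
) -> dict:
    """Constraint metrics along the breadth continuum.

    Marked genes are split into ``n_bins`` equal-count bins by mark breadth;
    per-bin medians of missense Z and dN/dS are reported, plus a rank-sum
    test of grand-marked genes against all other marked genes for each
    metric (direction recorded: constrained genes have higher missense Z and
    lower dN/dS).
    """
    marked = [m for m in marks if m.marked]
    if len(marked) < 2 * n_bins:
        raise ValueError("too few marked genes for the requested binning")
    order = np.argsort([m.mark_breadth for m in marked], kind="mergesort")
    bin_of = np.zeros(len(marked), dtype=int)
    splits = np.array_split(order, n_bins)
    for b, idx in enumerate(splits):
        bin_of[idx] = b
    for m, b in zip(marked, bin_of):
        m.breadth_quantile_bin = int(b)

    result: dict = {"n_bins": n_bins, "bins": [], "tests": {}}
    for b in range(n_bins):
        genes_b = [m for m, bb in zip(marked, bin_of) if bb == b]
        mz = [constraints[m.gene_id].missense_z for m in genes_b
              if m.gene_id in constraints
              and constraints[m.gene_id].missense_z is not None]
        dn = [constraints[m.gene_id].dn_ds for m in genes_b
              if m.gene_id in constraints
              and constraints[m.gene_id].dn_ds is not None]
        result["bins"].append({
            "bin": b,
            "n_genes": len(genes_b),
            "median_breadth": float(np.median([m.mark_breadth for m in genes_b])),
            "median_missense_z": float(np.median(mz)) if mz else None,
            "median_dn_ds": float(np.median(dn)) if dn else None,
        })

    grand_ids = {m.gene_id for m in marked if m.class_label == GRAND}
    other_ids = {m.gene_id for m in marked if m.class_label != GRAND}
    for metric, attr, expected in (
        ("missense_z", "missense_z", "greater"),
        ("dn_ds", "dn_ds", "less"),
    ):
        g = [getattr(constraints[i], attr) for i in grand_ids
             if i in constraints and getattr(constraints[i], attr) is not None]
        o = [getattr(constraints[i], attr) for i in other_ids
             if i in constraints and getattr(constraints[i], attr) is not None]
        if not g or not o:
            raise ValueError(f"all genes missing metric {metric}")
        tr = mann_whitney(g, o, alternative="two-sided")
        direction = "greater" if np.median(g) > np.median(o) else "less"
        result["tests"][metric] = {
            "statistic": tr.statistic,
            "p_value": tr.p_value,
            "n_grand": tr.n1,
            "n_other": tr.n2,
            "grand_median": float(np.median(g)),
            "other_median": float(np.median(o)),
            "direction": direction,
            "expected_direction": expected,
        }
    return result


def breadth_expression_trend(
    marks: Sequence[GeneMark],
    expression: Mapping[str, float],
    n_bins: int = 20,
) -> dict:
    """Trend of expression along the mark-breadth continuum.

    Marked genes with expression are split into ``n_bins`` equal-count bins
    by mark breadth; Spearman correlation is computed between bin index and
    bin median TPM.  A negative r means broader marks repress harder.
    """
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    rows = [(m.mark_breadth, expression[m.gene_id])
            for m in marks if m.marked and m.gene_id in expression]
    if len(rows) < n_bins:
        raise ValueError(
            f"only {len(rows)} marked genes with expression; need >= {n_bins}"
        )
    rows.sort(key=lambda t: t[0])
    tpms = np.array([t[1] for t in rows], dtype=np.float64)
    breadths = np.array([t[0] for t in rows], dtype=np.float64)
    idx_splits = np.array_split(np.arange(len(rows)), n_bins)
    table = []
    medians = []
    for b, idx in enumerate(idx_splits):
        med = float(np.median(tpms[idx]))
        medians.append(med)
        table.append({
            "bin": b,
            "n_genes": int(len(idx)),
            "median_breadth": float(np.median(breadths[idx])),
            "median_tpm": med,
        })
    r, p = rank_correlation(
        np.arange(n_bins, dtype=float), np.array(medians), method="spearman"
    )
    return {"bins": table, "spearman_r": r, "p_value": p, "n_bins": n_bins}
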