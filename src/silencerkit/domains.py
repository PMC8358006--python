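"""Domain calling: merge peaks, quantify signal, classify by breadth.

The central construct is the breadth-defined silencer domain: merged
repressive-mark peaks whose broadest quantile (default top 5%, with a hard
50 kb floor) forms the "grand" class, the narrowest quantile the "narrow"
class, and a seeded random sample of the remainder the "control" class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from silencerkit.core import CoverageTrack, GenomicInterval, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Domain",
    "CallingParams",
    "merge_peaks",
    "quantify_domain_signal",
    "classify_domains",
    "metagene_matrix",
]

GRAND, TYPICAL, NARROW, CONTROL = "grand", "typical", "narrow", "control"


@dataclass
class Domain:
    """A merged peak interval with breadth, signal and a class label.

    ``control`` overlays ``typical``: control domains are a random subset of
    the typical class, kept disjoint from grand and narrow.
    """

    interval: GenomicInterval
    breadth: int
    signal_rpkm: float = 0.0
    n_source_peaks: int = 1
    class_label: str = TYPICAL
    domain_id: str = ""

    def __post_init__(self):
        if self.breadth != self.interval.length:
            raise ValidationError("breadth must equal interval length")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class CallingParams:
    merge_gap: int = 2000
    grand_quantile: float = 0.95
    min_breadth: int = 50_000
    narrow_quantile: float = 0.05
    control_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.narrow_quantile < self.grand_quantile < 1.0):
            raise ValidationError(
                "need 0 < narrow_quantile < grand_quantile < 1"
            )
        if self.merge_gap < 0:
            raise ValidationError("merge_gap must be >= 0")


def merge_peaks(
    peaks: Sequence[GenomicInterval], merge_gap: int = 2000
) -> list[Domain]:
    """Union peaks on one chromosome whose gap is <= ``merge_gap``.

    The gap between adjacent intervals is next.start - prev.end; touching or
    overlapping peaks (gap <= 0) always merge.
    """
    if merge_gap < 0:
        raise ValidationError("merge_gap must be >= 0")
    domains: list[Domain] = []
    cur: Optional[list] = None  # [chrom, start, end, count]
    for peak in sorted(peaks):
        if cur is not None and peak.chrom == cur[0] and peak.start - cur[2] <= merge_gap:
            cur[2] = max(cur[2], peak.end)
            cur[3] += 1
        else:
            if cur is not None:
                iv = GenomicInterval(cur[0], cur[1], cur[2])
                domains.append(Domain(iv, iv.length, n_source_peaks=cur[3]))
            cur = [peak.chrom, peak.start, peak.end, 1]
    if cur is not None:
        iv = GenomicInterval(cur[0], cur[1], cur[2])
        domains.append(Domain(iv, iv.length, n_source_peaks=cur[3]))
    for i, d in enumerate(domains):
        d.domain_id = f"D{i:05d}"
    return domains


def quantify_domain_signal(
    region: GenomicInterval,
    treatment: CoverageTrack,
    input_track: CoverageTrack,
) -> float:
    """Input-subtracted RPKM over a region, floored at 0."""
    if region.length <= 0:
        raise ValidationError("zero-length region")
    t = treatment.rpkm(region.chrom, region.start, region.end)
    i = input_track.rpkm(region.chrom, region.start, region.end)
    return max(0.0, t - i)


def classify_domains(
    domains: Sequence[Domain], params: CallingParams
) -> tuple[list[Domain], dict]:
    """Assign grand/narrow/control/typical labels by breadth quantile.

    grand = breadth at or above the empirical ``grand_quantile`` AND strictly
    above ``min_breadth``, capped at ceil((1 - grand_quantile) * n) with a
    deterministic tie-break (breadth desc, signal desc, chrom, start).
    narrow is the mirror image at the bottom with no breadth floor.  control
    is a seeded uniform sample of the remaining (typical) domains.

    Returns (labeled domains, threshold report dict).
    """
    n = len(domains)
    if n == 0:
        return [], {"n_domains": 0}
    if n < 20:
        logger.warning("only %d domains; breadth quantiles are unstable", n)
    breadths = np.array([d.breadth for d in domains], dtype=np.int64)
    grand_cut = float(np.quantile(breadths, params.grand_quantile))
    narrow_cut = float(np.quantile(breadths, params.narrow_quantile))
    if grand_cut < narrow_cut:
        raise ValidationError(
            f"breadth quantiles crossed: grand cut {grand_cut} < "
            f"narrow cut {narrow_cut}"
        )
    if grand_cut == narrow_cut:
        logger.warning("degenerate breadth distribution: grand and narrow "
                       "cuts coincide at %g; tie-break caps apply", grand_cut)
    # round before ceil: (1 - 0.95) * 100 is 5.000000000000004 in floats
    grand_cap = math.ceil(round((1.0 - params.grand_quantile) * n, 9))
    narrow_cap = math.ceil(round(params.narrow_quantile * n, 9))

    by_breadth_desc = sorted(
        range(n),
        key=lambda i: (-domains[i].breadth, -domains[i].signal_rpkm,
                       domains[i].chrom, domains[i].start),
    )
    grand_idx: set[int] = set()
    for i in by_breadth_desc:
        if len(grand_idx) >= grand_cap:
            break
        if domains[i].breadth >= grand_cut and domains[i].breadth > params.min_breadth:
            grand_idx.add(i)
    n_eligible = int(np.sum((breadths >= grand_cut) & (breadths > params.min_breadth)))
    if n_eligible > grand_cap:
        logger.warning(
            "grand tie-break: %d domains eligible, capped at %d",
            n_eligible, grand_cap,
        )

    by_breadth_asc = sorted(
        range(n),
        key=lambda i: (domains[i].breadth, domains[i].signal_rpkm,
                       domains[i].chrom, domains[i].start),
    )
    narrow_idx: set[int] = set()
    for i in by_breadth_asc:
        if len(narrow_idx) >= narrow_cap:
            break
        if i not in grand_idx and domains[i].breadth <= narrow_cut:
            narrow_idx.add(i)

    typical_idx = [i for i in range(n) if i not in grand_idx and i not in narrow_idx]
    rng = np.random.default_rng(params.seed)
    n_control = int(round(params.control_fraction * n))
    n_control = min(n_control, len(typical_idx))
    control_idx = set(
        rng.choice(typical_idx, size=n_control, replace=False).tolist()
    ) if n_control > 0 else set()

    labeled: list[Domain] = []
    for i, d in enumerate(domains):
        if i in grand_idx:
            label = GRAND
        elif i in narrow_idx:
            label = NARROW
        elif i in control_idx:
            label = CONTROL
        else:
            label = TYPICAL
        labeled.append(replace(d, class_label=label))

    grand_breadths = [domains[i].breadth for i in grand_idx]
    report = {
        "n_domains": n,
        "grand_quantile": params.grand_quantile,
        "grand_breadth_cut": grand_cut,
        "min_breadth": params.min_breadth,
        "n_grand": len(grand_idx),
        "grand_cap": grand_cap,
        "grand_min_breadth_realized": min(grand_breadths) if grand_breadths else None,
        "narrow_quantile": params.narrow_quantile,
        "narrow_breadth_cut": narrow_cut,
        "n_narrow": len(narrow_idx),
        "n_control": len(control_idx),
        "n_typical": len(typical_idx) - len(control_idx),
        "control_seed": params.seed,
    }
    return labeled, report


def metagene_matrix(
    domains: Sequence[Domain],
    track: CoverageTrack,
    flank: int = 3000,
    body_bins: int = 20,
    flank_bins: int = 6,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Length-normalized signal matrix over domains with fixed flanks.

    Each row is upstream-flank bins, body bins (body rescaled to
    ``body_bins`` regardless of breadth, mean-within-bin), downstream-flank
    bins.  Flanks truncated at chromosome start are recorded, not fatal.

    Returns (matrix of shape (n_domains, 2*flank_bins + body_bins),
    mean profile, list of truncation notes).
    """
    if body_bins < 3:
        raise ValidationError("body_bins must be >= 3")
    if not domains:
        raise ValidationError("metagene_matrix requires at least one domain")
    width = 2 * flank_bins + body_bins
    mat = np.zeros((len(domains), width), dtype=np.float64)
    notes: list[str] = []
    for r, d in enumerate(domains):
        left_start = d.start - flank
        if left_start < 0:
            notes.append(f"{d.domain_id or r}: upstream flank truncated")
            left_start = 0
        if left_start < d.start:
            mat[r, :flank_bins] = track.binned_means(
                d.chrom, left_start, d.start, flank_bins
            )
        mat[r, flank_bins:flank_bins + body_bins] = track.binned_means(
            d.chrom, d.start, d.end, body_bins
        )
        mat[r, flank_bins + body_bins:] = track.binned_means(
            d.chrom, d.end, d.end + flank, flank_bins
        )
    return mat, mat.mean(axis=0), notes
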