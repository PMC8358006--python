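"""Readers and writers for the plain-text genomics formats the pipeline touches.

Everything internal is 0-based half-open; BED/bedGraph/BEDPE already are, and
the tab-delimited gene tables written here use the same convention (stated in
their ``#`` headers).  Output tables are UTF-8 TSV with a ``#``-prefixed
provenance header.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from silencerkit.core import (
    ChromatinLoop,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_table",
    "write_gene_table",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gmt",
    "provenance_header",
]


def _data_lines(path: str | Path):
    """Yield (line_number, stripped_line) skipping blanks, comments, headers."""
    with open(path, "rt", encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield i, line


def _parse_int(field: str, what: str, path: str, lineno: int) -> int:
    try:
        return int(field)
    except ValueError:
        raise ParseError(f"non-integer {what}: {field!r}", str(path), lineno) from None


def _parse_float(field: str, what: str, path: str, lineno: int) -> float:
    try:
        return float(field)
    except ValueError:
        raise ParseError(f"non-numeric {what}: {field!r}", str(path), lineno) from None


def provenance_header(**params) -> str:
    """Standard ``#`` header recording version, coordinates and parameters."""
    from silencerkit import __version__

    lines = [f"# silencerkit v{__version__}", "# coordinates: 0-based half-open"]
    for key, val in params.items():
        lines.append(f"# {key}={val}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, min_fields: int = 3) -> list[GenomicInterval]:
    """Read BED3/BED6 into sorted, validated intervals (0-based half-open)."""
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < min_fields:
            raise ParseError(
                f"expected >= {min_fields} fields, got {len(fields)}",
                str(path), lineno,
            )
        chrom = fields[0]
        start = _parse_int(fields[1], "start", str(path), lineno)
        end = _parse_int(fields[2], "end", str(path), lineno)
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] != ".":
            score = _parse_float(fields[4], "score", str(path), lineno)
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
        try:
            out.append(GenomicInterval(chrom, start, end, name=name,
                                       score=score, strand=strand))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return sorted(out)


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval],
              header: str = "") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        for iv in sorted(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def read_bedpe(path: str | Path) -> list[ChromatinLoop]:
    """Read BEDPE loop records; inter-chromosomal loops are retained."""
    loops: list[ChromatinLoop] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(
                f"BEDPE needs >= 6 fields, got {len(fields)}", str(path), lineno
            )
        try:
            a1 = GenomicInterval(
                fields[0],
                _parse_int(fields[1], "start1", str(path), lineno),
                _parse_int(fields[2], "end1", str(path), lineno),
            )
            a2 = GenomicInterval(
                fields[3],
                _parse_int(fields[4], "start2", str(path), lineno),
                _parse_int(fields[5], "end2", str(path), lineno),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
        score = None
        if len(fields) > 7 and fields[7] not in (".", ""):
            score = _parse_float(fields[7], "score", str(path), lineno)
        loops.append(ChromatinLoop(a1, a2, score=score))
    if not loops:
        logger.warning("no loop records in %s", path)
    return loops


def write_bedpe(path: str | Path, loops: Iterable[ChromatinLoop],
                header: str = "") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        for i, lp in enumerate(loops):
            score = f"{lp.score:g}" if lp.score is not None else "."
            fh.write("\t".join([
                lp.anchor1.chrom, str(lp.anchor1.start), str(lp.anchor1.end),
                lp.anchor2.chrom, str(lp.anchor2.start), str(lp.anchor2.end),
                f"loop{i}", score,
            ]) + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(
    path: str | Path,
    total_mapped: Optional[int] = None,
    value_bounds: Optional[tuple[float, float]] = None,
) -> CoverageTrack:
    """Read a bedGraph into a CoverageTrack.

    Gaps imply value 0.  Overlapping runs are rejected.  ``value_bounds``
    enforces e.g. [0, 1] for methylation beta tracks.
    """
    if total_mapped is not None and total_mapped <= 0:
        raise ValidationError("total_mapped must be > 0 when given")
    track = CoverageTrack(total_mapped=total_mapped, value_bounds=value_bounds)
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(
                f"bedGraph needs 4 fields, got {len(fields)}", str(path), lineno
            )
        chrom = fields[0]
        start = _parse_int(fields[1], "start", str(path), lineno)
        end = _parse_int(fields[2], "end", str(path), lineno)
        value = _parse_float(fields[3], "value", str(path), lineno)
        try:
            track.add_run(chrom, start, end, value)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    # force overlap validation up front
    for chrom in track.chroms:
        track._finalize(chrom)
    return track


def write_bedgraph(path: str | Path, track: CoverageTrack, header: str = "") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        for chrom in track.chroms:
            for start, end, value in track.runs(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path, dialect: str = "tsv") -> list[GeneModel]:
    """Read gene models from a TSV (gene_id, chrom, strand, tss, tes) or BED12.

    BED12 genes use chromStart/chromEnd as the body; block structure is
    ignored (analyses here are gene-body level).  Duplicate gene ids are
    rejected.
    """
    if dialect not in ("tsv", "bed12"):
        raise ValueError(f"unknown gene-table dialect: {dialect}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if dialect == "bed12":
            if len(fields) < 12:
                raise ParseError(
                    f"BED12 needs 12 fields, got {len(fields)}", str(path), lineno
                )
            chrom, start, end = fields[0], fields[1], fields[2]
            gene_id, strand = fields[3], fields[5]
            start_i = _parse_int(start, "chromStart", str(path), lineno)
            end_i = _parse_int(end, "chromEnd", str(path), lineno)
            if strand == "+":
                tss, tes = start_i, end_i
            elif strand == "-":
                tss, tes = end_i, start_i
            else:
                raise ParseError(f"unknown strand {strand!r}", str(path), lineno)
        else:
            if line.lower().startswith("gene_id\t"):
                continue  # header row
            if len(fields) < 5:
                raise ParseError(
                    f"gene TSV needs 5 fields, got {len(fields)}", str(path), lineno
                )
            gene_id, chrom, strand = fields[0], fields[1], fields[2]
            tss = _parse_int(fields[3], "tss", str(path), lineno)
            tes = _parse_int(fields[4], "tes", str(path), lineno)
            if strand not in ("+", "-"):
                raise ParseError(f"unknown strand {strand!r}", str(path), lineno)
        if gene_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            genes.append(GeneModel(gene_id, chrom, strand, tss, tes))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gene_table(path: str | Path, genes: Iterable[GeneModel],
                     header: str = "") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        fh.write("gene_id\tchrom\tstrand\ttss\ttes\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tes}\n")


# ---------------------------------------------------------------------------
# chrom sizes / GMT
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError("chrom sizes needs 2 fields", str(path), lineno)
        size = _parse_int(fields[1], "size", str(path), lineno)
        if size <= 0:
            raise ValidationError(f"{path}:{lineno}: non-positive size")
        sizes[fields[0]] = size
    return sizes


def write_chrom_sizes(path: str | Path, sizes: Mapping[str, int]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_expression_table(path: str | Path) -> dict[str, dict]:
    """Expression TSV: gene_id, tpm_normal, tpm_tumor, count columns.

    Count columns are named ``count_<condition>_<i>``; returns per-gene
    dicts with tpm_normal/tpm_tumor floats and counts_normal/counts_tumor
    lists.
    """
    out: dict[str, dict] = {}
    header_cols: Optional[list[str]] = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header_cols is None:
            header_cols = fields
            if header_cols[0] != "gene_id":
                raise ParseError("expression table must start with gene_id",
                                 str(path), lineno)
            continue
        row = dict(zip(header_cols, fields))
        gene_id = row["gene_id"]
        if gene_id in out:
            raise ValidationError(f"{path}:{lineno}: duplicate gene {gene_id!r}")
        rec = {
            "tpm_normal": _parse_float(row["tpm_normal"], "tpm", str(path), lineno),
            "tpm_tumor": _parse_float(row["tpm_tumor"], "tpm", str(path), lineno),
            "counts_normal": [], "counts_tumor": [],
        }
        for col in header_cols:
            if col.startswith("count_normal_"):
                rec["counts_normal"].append(
                    _parse_float(row[col], col, str(path), lineno))
            elif col.startswith("count_tumor_"):
                rec["counts_tumor"].append(
                    _parse_float(row[col], col, str(path), lineno))
        out[gene_id] = rec
    return out


def read_constraint_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Constraint TSV: gene_id, missense_z, dn_ds; 'NA' means missing."""
    out: dict[str, tuple] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "gene_id":
            continue
        if len(fields) < 3:
            raise ParseError("constraint table needs 3 fields", str(path), lineno)
        z = None if fields[1] in ("NA", "") else _parse_float(
            fields[1], "missense_z", str(path), lineno)
        dn = None if fields[2] in ("NA", "") else _parse_float(
            fields[2], "dn_ds", str(path), lineno)
        if fields[0] in out:
            raise ValidationError(f"{path}:{lineno}: duplicate gene {fields[0]!r}")
        out[fields[0]] = (z, dn)
    return out


def read_de_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Differential-expression TSV: gene_id, log2fc, fdr."""
    out: dict[str, tuple[float, float]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "gene_id":
            continue
        if len(fields) < 3:
            raise ParseError("DE table needs 3 fields", str(path), lineno)
        if fields[0] in out:
            raise ValidationError(
                f"{path}:{lineno}: conflicting duplicate gene {fields[0]!r}"
            )
        out[fields[0]] = (
            _parse_float(fields[1], "log2fc", str(path), lineno),
            _parse_float(fields[2], "fdr", str(path), lineno),
        )
    return out


def read_track_metadata(path: str | Path) -> dict[tuple[str, str, str], dict]:
    """tracks.tsv sidecar: (mark, condition, role) -> {file, total_mapped}."""
    out: dict[tuple[str, str, str], dict] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "file":
            continue
        if len(fields) < 5:
            raise ParseError("track metadata needs 5 fields", str(path), lineno)
        out[(fields[1], fields[2], fields[3])] = {
            "file": fields[0],
            "total_mapped": _parse_int(fields[4], "total_mapped", str(path), lineno),
        }
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: term, description, then member gene ids."""
    terms: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError("GMT needs >= 3 fields", str(path), lineno)
        terms[fields[0]] = set(fields[2:])
    return terms
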