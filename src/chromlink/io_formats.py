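"""Readers and writers for the on-disk formats the pipeline touches.

All writers emit tab-separated, newline-terminated lines with no
trailing whitespace.  All readers normalize to the package's internal
0-based half-open convention; GTF and variant positions (1-based
inclusive) are converted on read.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .core import (
    GeneModel,
    GenomicInterval,
    Loop,
    promoter_interval,
    sort_intervals,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_DIALECT_MIN_COLS = {"bed3": 3, "bed6": 3, "narrowPeak": 10, "bedgraph": 4}

_SKIP_PREFIXES = ("track", "browser", "#")


class FormatError(ValueError):
    """Malformed record in an on-disk file; message names the line."""


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t")


def read_intervals(path: PathLike, dialect: str = "bed6") -> list[GenomicInterval]:
    """Read a BED3/BED6/narrowPeak/bedGraph file into sorted intervals.

    bedGraph maps column 4 to ``score``; narrowPeak maps columns 4/7 to
    name and signalValue.  track/browser/# header lines are skipped.
    """
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    min_cols = _DIALECT_MIN_COLS[dialect]
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < min_cols:
            raise FormatError(
                f"{path}:{lineno}: expected >= {min_cols} columns for "
                f"{dialect}, got {len(fields)}"
            )
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
        name: Optional[str] = None
        score: Optional[float] = None
        if dialect == "bedgraph":
            score = float(fields[3])
        elif dialect == "narrowPeak":
            name = fields[3] if fields[3] != "." else None
            score = float(fields[6])  # signalValue
        elif dialect == "bed6" and len(fields) >= 4:
            name = fields[3] if fields[3] != "." else None
            if len(fields) >= 5 and fields[4] != ".":
                score = float(fields[4])
        out.append(GenomicInterval(chrom, start, end, name=name, score=score))
    return sort_intervals(out)


def write_intervals(
    path: PathLike, intervals: Iterable[GenomicInterval], dialect: str = "bed6"
) -> None:
    with open(path, "w") as fh:
        for iv in sort_intervals(intervals):
            if dialect == "bed3":
                fields = [iv.chrom, str(iv.start), str(iv.end)]
            elif dialect == "bedgraph":
                fields = [iv.chrom, str(iv.start), str(iv.end), _fmt(iv.score or 0.0)]
            elif dialect == "narrowPeak":
                fields = [
                    iv.chrom,
                    str(iv.start),
                    str(iv.end),
                    iv.name or ".",
                    "0",
                    ".",
                    _fmt(iv.score if iv.score is not None else 0.0),
                    "-1",
                    "-1",
                    "-1",
                ]
            else:  # bed6
                fields = [
                    iv.chrom,
                    str(iv.start),
                    str(iv.end),
                    iv.name or ".",
                    "." if iv.score is None else _fmt(iv.score),
                    ".",
                ]
            fh.write("\t".join(fields) + "\n")


def _fmt(x: float) -> str:
    return f"{x:g}"


def read_loops(path: PathLike, sample_id: str) -> list[Loop]:
    """Read a BEDPE file into canonical Loops tagged with ``sample_id``.

    Inter-chromosomal records are skipped, counted and logged; the
    pipeline only consumes intra-chromosomal loops.
    """
    loops = []
    skipped = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
        c1, s1, e1, c2, s2, e2 = fields[:6]
        try:
            a1 = GenomicInterval(c1, int(s1), int(e1))
            a2 = GenomicInterval(c2, int(s2), int(e2))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if c1 != c2:
            skipped += 1
            continue
        score = None
        if len(fields) >= 8 and fields[7] not in (".", ""):
            score = float(fields[7])
        loops.append(Loop.canonical(a1, a2, score=score, samples={sample_id}))
    if skipped:
        logger.warning(
            "%s: skipped %d inter-chromosomal loop record(s)", path, skipped
        )
    return loops


def write_loops(path: PathLike, loops: Iterable[Loop]) -> None:
    rows = sorted(loops, key=lambda lp: lp.key)
    with open(path, "w") as fh:
        for lp in rows:
            fields = [
                lp.anchor1.chrom,
                str(lp.anchor1.start),
                str(lp.anchor1.end),
                lp.anchor2.chrom,
                str(lp.anchor2.start),
                str(lp.anchor2.end),
                ",".join(sorted(lp.samples)) or ".",
                "." if lp.score is None else _fmt(lp.score),
            ]
            fh.write("\t".join(fields) + "\n")


def _gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for part in attr_field.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(
    path: PathLike, promoter_up: int = 2000, promoter_down: int = 500
) -> list[GeneModel]:
    """Read gene features from a GTF into GeneModels with promoters.

    GTF coordinates are 1-based inclusive and converted to 0-based
    half-open.  Promoter windows are strand-aware (``promoter_up`` bases
    5' of the TSS, ``promoter_down`` 3'), clipped at zero.
    """
    genes: dict[str, GeneModel] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 9:
            raise FormatError(f"{path}:{lineno}: GTF needs 9 columns")
        if fields[2] != "gene":
            continue
        chrom = fields[0]
        start = int(fields[3]) - 1  # to 0-based
        end = int(fields[4])  # inclusive -> half-open
        strand = fields[6]
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: gene without strand")
        attrs = _gtf_attributes(fields[8])
        gene_id = attrs.get("gene_id")
        if not gene_id:
            raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
        if gene_id in genes:
            raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        body = GenomicInterval(chrom, start, end, name=gene_id)
        tss = start if strand == "+" else end - 1
        promoter = promoter_interval(chrom, strand, tss, promoter_up, promoter_down)
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            gene_name=attrs.get("gene_name", gene_id),
            chrom=chrom,
            strand=strand,
            body=body,
            promoter=promoter,
        )
    return sorted(genes.values(), key=lambda g: (g.chrom, g.body.start, g.gene_id))


def write_gene_models(path: PathLike, genes: Iterable[GeneModel]) -> None:
    """Write minimal GTF gene features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.body.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fields = [
                g.chrom,
                "chromlink",
                "gene",
                str(g.body.start + 1),
                str(g.body.end),
                ".",
                g.strand,
                ".",
                attrs,
            ]
            fh.write("\t".join(fields) + "\n")


def read_gmt(path: PathLike) -> dict[str, set[str]]:
    """Read a GMT file into {term: gene set}; empty terms skipped."""
    mapping: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: GMT needs term + description")
        term = fields[0]
        genes = {g for g in fields[2:] if g}
        if not genes:
            logger.warning("%s:%d: term %r has no genes; skipped", path, lineno, term)
            continue
        mapping[term] = genes
    return mapping


def write_gmt(path: PathLike, mapping: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for term in sorted(mapping):
            genes = sorted(set(mapping[term]))
            fh.write("\t".join([term, "na", *genes]) + "\n")


def read_counts(path: PathLike) -> pd.DataFrame:
    """Gene x sample counts TSV (first column = gene id index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative count entries")
    return df


def write_counts(path: PathLike, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_de_table(path: PathLike) -> pd.DataFrame:
    """Differential-expression table: gene_id, log2FC, FDR."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2FC", "FDR"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing DE columns {sorted(missing)}")
    return df


def write_de_table(path: PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)
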