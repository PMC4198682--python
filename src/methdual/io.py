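"""Readers and writers for the plain-text genomic formats the pipeline touches.

BED, bedGraph and the window-count TSV keep BED's 0-based half-open
semantics; malformed coordinates raise with the offending line number
rather than being clamped. Chromosome names are taken literally — an
optional alias map handles naming-scheme mismatches.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

from .genome import GenomicInterval, TEAnnotation, ChromHMMSegment

__all__ = [
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_repeatmasker_table",
    "read_chromhmm_bed",
    "read_bedgraph",
    "write_dmr_table",
    "read_window_counts",
    "write_window_counts",
]


def _apply_alias(chrom: str, aliases: Mapping[str, str] | None) -> str:
    return aliases.get(chrom, chrom) if aliases else chrom


def read_bed(path: str | os.PathLike, aliases: Mapping[str, str] | None = None) -> list[GenomicInterval]:
    """Read BED3+ into intervals, preserving input order.

    Track definition lines, browser lines, ``#`` comments and blank lines
    are skipped. A line whose coordinates are non-integer or violate
    ``0 <= start < end`` raises ``ValueError`` naming the 1-based line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
            try:
                iv = GenomicInterval(_apply_alias(fields[0], aliases), start, end, name, strand)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` file -> ordered mapping."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def read_repeatmasker_table(
    path: str | os.PathLike,
    columns: Mapping[str, str] | None = None,
    aliases: Mapping[str, str] | None = None,
) -> list[TEAnnotation]:
    """Read a UCSC rmsk-style TSV into TE annotations.

    ``columns`` remaps the expected header names
    (chrom/start/end/subfamily/family/class) onto the file's own header
    (e.g. ``{"subfamily": "repName", "family": "repFamily", "class": "repClass"}``).
    The subfamily -> (family, class) mapping must be consistent across rows.
    """
    colmap = {
        "chrom": "chrom", "start": "start", "end": "end",
        "subfamily": "subfamily", "family": "family", "class": "class",
    }
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    seen: dict[str, tuple[str, str]] = {}
    out: list[TEAnnotation] = []
    for _, row in df.iterrows():
        sub = str(row[colmap["subfamily"]])
        fam_cls = (str(row[colmap["family"]]), str(row[colmap["class"]]))
        if sub in seen and seen[sub] != fam_cls:
            raise ValueError(
                f"{path}: subfamily {sub} maps to both {seen[sub]} and {fam_cls}"
            )
        seen[sub] = fam_cls
        iv = GenomicInterval(
            _apply_alias(str(row[colmap["chrom"]]), aliases),
            int(row[colmap["start"]]), int(row[colmap["end"]]),
        )
        out.append(TEAnnotation(iv, sub, fam_cls[0], fam_cls[1]))
    return out


def read_chromhmm_bed(path: str | os.PathLike, cell_line: str,
                      aliases: Mapping[str, str] | None = None) -> list[ChromHMMSegment]:
    """BED4 (name = state label) -> chromatin-state segments of one cell line."""
    segs = []
    for iv in read_bed(path, aliases):
        if iv.name is None:
            raise ValueError(f"{path}: chromHMM BED requires a state label in column 4")
        segs.append(ChromHMMSegment(GenomicInterval(iv.chrom, iv.start, iv.end), iv.name, cell_line))
    return segs


def read_bedgraph(path: str | os.PathLike, aliases: Mapping[str, str] | None = None
                  ) -> list[tuple[GenomicInterval, float]]:
    """bedGraph -> (interval, value) pairs in input order."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            try:
                iv = GenomicInterval(_apply_alias(fields[0], aliases), int(fields[1]), int(fields[2]))
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            out.append((iv, value))
    return out


DMR_HEADER = [
    "chrom", "start", "end", "direction", "q_value", "support",
    "cancer_type", "tp_flag", "context", "cgi", "shore", "te", "pattern",
]


def write_dmr_table(dmrs: Sequence, path: str | os.PathLike) -> None:
    """Write consensus DMRs as a BED6+-style TSV with a ``#`` header line.

    Accepts any objects exposing ``interval``, ``direction``, ``q_value``,
    ``support``, ``cancer_type`` and ``tp_flag``; annotation columns are
    filled from identically named optional attributes. Round-trips through
    :func:`read_bed` (the header is a comment line).
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(DMR_HEADER) + "\n")
        for d in dmrs:
            iv = d.interval
            row = [
                iv.chrom, str(iv.start), str(iv.end), d.direction,
                format(d.q_value, ".6g"), str(d.support), d.cancer_type,
                str(int(bool(d.tp_flag))),
                str(getattr(d, "context", ".")),
                str(int(bool(getattr(d, "in_cgi", False)))),
                str(int(bool(getattr(d, "in_shore", False)))),
                str(int(bool(getattr(d, "in_te", False)))),
                str(getattr(d, "pattern", ".")),
            ]
            fh.write("\t".join(row) + "\n")


WINDOW_COUNT_COLUMNS = ["chrom", "start", "end", "medip", "mre", "cpg_count", "mre_site_count"]


def read_window_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Window-count TSV (chrom, start, end, medip, mre, cpg_count, mre_site_count)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WINDOW_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["medip"] < 0).any() or (df["mre"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_window_counts(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
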