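"""Readers and writers for interval tables, expression cohorts and term mappings.

Supported dialects: 6-column BED (0-based half-open, as on disk), GFF3
(1-based inclusive, converted on read), a plain TSV transcript table used
for lossless round-trips, TSV expression/metadata matrices, and GMT-like
term->genes mappings.  All conversions to the package's internal 0-based
half-open convention happen here and only here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .core import (
    BIOTYPES,
    CohortMatrix,
    GenomicInterval,
    LncArrayError,
    TermMapping,
    TranscriptRecord,
)

logger = logging.getLogger("lncarray")


def kv_log(event: str, **fields) -> None:
    """Emit one timestamped key=value log record (stage counts, decisions)."""
    payload = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("event=%s %s", event, payload)


_TSV_COLUMNS = ["transcript_id", "gene_id", "chrom", "start", "end", "strand",
                "biotype", "exon_starts", "exon_ends"]


def _check_strand(symbol: str, lineno: int, path) -> str:
    if symbol in {"+", "-", "."}:
        return symbol
    raise LncArrayError(f"{path}:{lineno}: unknown strand symbol {symbol!r}")


def _reject_duplicates(records: list[TranscriptRecord]) -> list[TranscriptRecord]:
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.transcript_id] = seen.get(rec.transcript_id, 0) + 1
    dups = [t for t, n in seen.items() if n > 1]
    if dups:
        raise LncArrayError(f"duplicated transcript_id(s): {dups[:5]}")
    return records


def read_intervals(path, format: str = "BED") -> list[TranscriptRecord]:
    """Read transcripts from ``path`` in the named dialect.

    BED is already 0-based half-open; GFF3 start/end (1-based inclusive)
    become ``start-1``/``end`` so that reading the same file twice yields
    identical intervals (the conversion is applied exactly once, on read).
    """
    fmt = format.upper()
    if fmt == "BED":
        records = _read_bed(path)
    elif fmt == "GFF3":
        records = _read_gff3(path)
    elif fmt == "TSV":
        records = _read_tsv_transcripts(path)
    else:
        raise LncArrayError(f"unknown interval format {format!r} (BED, GFF3 or TSV)")
    kv_log("read_intervals", path=path, format=fmt, n=len(records))
    return _reject_duplicates(records)


def _read_bed(path) -> list[TranscriptRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise LncArrayError(f"{path}:{lineno}: BED line has <4 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise LncArrayError(
                    f"{path}:{lineno}: non-integer BED coordinates") from None
            strand = _check_strand(parts[5], lineno, path) if len(parts) >= 6 else "."
            try:
                iv = GenomicInterval(parts[0], start, end, strand)
            except LncArrayError as exc:
                raise LncArrayError(f"{path}:{lineno}: {exc}") from None
            records.append(TranscriptRecord(
                transcript_id=parts[3], gene_id=parts[3], interval=iv))
    return records


def _read_gff3(path) -> list[TranscriptRecord]:
    transcript_kinds = {"transcript", "mRNA", "ncRNA", "lnc_RNA", "lncRNA"}
    transcripts: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise LncArrayError(f"{path}:{lineno}: GFF3 line has {len(parts)} fields, expected 9")
            chrom, _src, kind, start_s, end_s, _score, strand_s, _phase, attr_s = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise LncArrayError(f"{path}:{lineno}: non-integer GFF3 coordinates") from None
            strand = _check_strand("." if strand_s == "?" else strand_s, lineno, path)
            attrs = dict(
                item.split("=", 1) for item in attr_s.split(";") if "=" in item)
            try:
                iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            except LncArrayError as exc:
                raise LncArrayError(f"{path}:{lineno}: {exc}") from None
            if kind in transcript_kinds:
                tid = attrs.get("ID")
                if tid is None:
                    raise LncArrayError(f"{path}:{lineno}: transcript feature lacks ID attribute")
                biotype = attrs.get("biotype", "unannotated")
                if biotype not in BIOTYPES:
                    raise LncArrayError(f"{path}:{lineno}: unknown biotype {biotype!r}")
                transcripts[tid] = {
                    "gene_id": attrs.get("gene_id", attrs.get("Parent", tid)),
                    "interval": iv, "biotype": biotype}
                order.append(tid)
            elif kind == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise LncArrayError(f"{path}:{lineno}: exon lacks Parent attribute")
                exons.setdefault(parent, []).append(iv)
    records = []
    for tid in order:
        info = transcripts[tid]
        tx_exons = tuple(sorted(exons.get(tid, []), key=lambda e: e.start))
        records.append(TranscriptRecord(
            transcript_id=tid, gene_id=info["gene_id"], interval=info["interval"],
            exons=tx_exons, biotype=info["biotype"]))
    return records


def _read_tsv_transcripts(path) -> list[TranscriptRecord]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TSV_COLUMNS if c not in table.columns]
    if missing:
        raise LncArrayError(f"{path}: transcript TSV lacks columns {missing}")
    records = []
    for lineno, row in enumerate(table.itertuples(index=False), start=2):
        strand = _check_strand(row.strand, lineno, path)
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), strand)
        ex = ()
        if isinstance(row.exon_starts, str) and row.exon_starts:
            starts = [int(s) for s in row.exon_starts.split(",")]
            ends = [int(s) for s in row.exon_ends.split(",")]
            ex = tuple(GenomicInterval(row.chrom, s, e, strand)
                       for s, e in zip(starts, ends))
        records.append(TranscriptRecord(
            transcript_id=row.transcript_id, gene_id=row.gene_id,
            interval=iv, exons=ex, biotype=row.biotype))
    return records


def read_bed_regions(path):
    """Read plain BED regions (e.g. protein exons) as GenomicIntervals.

    Unlike :func:`read_intervals` no transcript structure or name
    uniqueness is implied; the name column may repeat.
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise LncArrayError(f"{path}:{lineno}: BED region needs >= 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise LncArrayError(
                    f"{path}:{lineno}: non-integer BED coordinates") from None
            strand = _check_strand(parts[5], lineno, path) if len(parts) >= 6 else "."
            try:
                regions.append(GenomicInterval(parts[0], start, end, strand))
            except LncArrayError as exc:
                raise LncArrayError(f"{path}:{lineno}: {exc}") from None
    return regions


def write_intervals(records, path, format: str = "TSV") -> None:
    fmt = format.upper()
    if fmt == "TSV":
        rows = []
        for rec in records:
            rows.append({
                "transcript_id": rec.transcript_id, "gene_id": rec.gene_id,
                "chrom": rec.interval.chrom, "start": rec.interval.start,
                "end": rec.interval.end, "strand": rec.interval.strand,
                "biotype": rec.biotype,
                "exon_starts": ",".join(str(e.start) for e in rec.exons),
                "exon_ends": ",".join(str(e.end) for e in rec.exons)})
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif fmt == "BED":
        with open(path, "w") as fh:
            for rec in records:
                iv = rec.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.transcript_id}\t0\t{iv.strand}\n")
    else:
        raise LncArrayError(f"unknown interval output format {format!r}")


# -- probe mappings (BED6 + probe id in the name column, optional target) --

def read_probe_mappings(path):
    """Read probe placements from BED-with-probe-id.

    The name column carries the probe-set id; an optional 7th column names
    the target transcript.  Multiple lines with the same probe id are that
    probe's multiple genomic placements (hence not a unique match).
    """
    from .annotation import ProbeMapping  # local import to avoid a cycle

    placements: dict[str, list] = {}
    targets: dict[str, str | None] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise LncArrayError(f"{path}:{lineno}: probe BED needs >= 6 fields")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                     _check_strand(parts[5], lineno, path))
            except (ValueError, LncArrayError) as exc:
                raise LncArrayError(f"{path}:{lineno}: {exc}") from None
            pid = parts[3]
            if pid not in placements:
                order.append(pid)
            placements.setdefault(pid, []).append(iv)
            target = parts[6] if len(parts) >= 7 and parts[6] not in ("", ".") else None
            prev = targets.get(pid)
            if prev is not None and target is not None and prev != target:
                raise LncArrayError(
                    f"{path}:{lineno}: probe {pid!r} names conflicting targets")
            targets[pid] = prev if target is None else target
    probes = [ProbeMapping(pid, tuple(placements[pid]), targets.get(pid),
                           unique_match=len(placements[pid]) == 1)
              for pid in order]
    kv_log("read_probe_mappings", path=path, n=len(probes))
    return probes


def write_probe_mappings(probes, path) -> None:
    with open(path, "w") as fh:
        for probe in probes:
            target = probe.target_transcript_id or "."
            for iv in probe.placements:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{probe.probe_set_id}"
                         f"\t0\t{iv.strand}\t{target}\n")


# -- expression cohorts ---------------------------------------------------

_BOOL_MAP = {"1": True, "0": False, "true": True, "false": False,
             "yes": True, "no": False, "t": True, "f": False}


def _parse_flag(value, column: str, sample: str):
    if pd.isna(value) or value == "":
        return pd.NA
    s = str(value).strip().lower()
    if s in _BOOL_MAP:
        return _BOOL_MAP[s]
    raise LncArrayError(f"metadata column {column!r}, sample {sample!r}: "
                        f"unparseable flag {value!r}")


def read_cohort(expr_path, meta_path=None) -> CohortMatrix:
    """Read a probes-x-samples TSV plus an optional sample-metadata TSV.

    Samples present in the matrix but absent from the metadata receive
    empty metadata records; metadata naming unknown samples is an error.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0, dtype=str)
    numeric = expr.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & expr.notna()
    if bad.to_numpy().any():
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise LncArrayError(
            f"{expr_path}: non-numeric cell at probe {expr.index[r]!r}, "
            f"sample {expr.columns[c]!r}: {expr.iat[r, c]!r}")
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
        for col in ("mycn_amplified", "relapse", "survived_5y", "stage_4s"):
            if col in meta.columns:
                meta[col] = [
                    _parse_flag(v, col, s) for s, v in meta[col].items()]
    cohort = CohortMatrix(numeric, meta)
    kv_log("read_cohort", path=expr_path, probes=cohort.n_probes,
           samples=cohort.n_samples)
    return cohort


def write_cohort(cohort: CohortMatrix, expr_path, meta_path=None) -> None:
    cohort.values.to_csv(expr_path, sep="\t", index_label="probe_id")
    if meta_path is not None:
        meta = cohort.metadata.copy()
        for col in meta.columns:
            if meta[col].dtype == object or str(meta[col].dtype) == "boolean":
                meta[col] = meta[col].map(
                    lambda v: "" if pd.isna(v) else (int(v) if isinstance(v, bool) else v))
        meta.to_csv(meta_path, sep="\t", index_label="sample_id", na_rep="")


# -- term mappings --------------------------------------------------------

def read_gmt(path, universe=None) -> TermMapping:
    """Read a GMT-like TSV: term, description, gene ids...

    If ``universe`` is None it defaults to the union of all mapped genes.
    """
    terms = {}
    genes_seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise LncArrayError(f"{path}:{lineno}: GMT line needs term, "
                                    "description and >=1 gene")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise LncArrayError(f"{path}:{lineno}: term {parts[0]!r} has no genes")
            terms[parts[0]] = genes
            genes_seen |= genes
    return TermMapping(terms=terms, universe=frozenset(universe) if universe else genes_seen)


def write_gmt(mapping: TermMapping, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(mapping.terms):
            genes = "\t".join(sorted(mapping.terms[term]))
            fh.write(f"{term}\t-\t{genes}\n")


# -- evidence tables ------------------------------------------------------

def read_two_column_tsv(path, name="evidence") -> dict:
    """Read a 2-column TSV (id, value) used for coding calls / alignment hits."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise LncArrayError(f"{path}: {name} table needs 2 columns")
    out: dict[str, list] = {}
    for key, value in zip(table[0], table[1]):
        out.setdefault(str(key), []).append(str(value))
    return out
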