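"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open throughout the package;
dialect conversions (e.g. GFF3's 1-based inclusive) happen only in
:mod:`lncarray.io`.  Expression matrices are normalized log-scale values
keyed by probe-set id and sample id, with per-sample clinical metadata
(INSS stage, MYCN amplification, relapse and 5-year-survival flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")
BIOTYPES = ("protein_coding", "annotated_ncRNA", "unannotated")

#: metadata columns every CohortMatrix carries (absent values are NA)
METADATA_COLUMNS = (
    "stage", "stage_4s", "mycn_amplified", "relapse", "survived_5y", "condition",
)


class LncArrayError(ValueError):
    """Base class for input/contract violations raised by this package."""


def parse_stage(value) -> tuple[int, bool]:
    """Normalize an INSS stage label to ``(stage, is_4s)``.

    Localized sub-stages ``2a``/``2b`` collapse to 2; the prognostically
    special metastatic stage ``4s`` is stored as 4 with a distinguishing
    flag so stage-ordered analyses can exclude it.
    """
    s = str(value).strip().lower()
    if s in {"2a", "2b"}:
        return 2, False
    if s == "4s":
        return 4, True
    try:
        stage = int(s)
    except ValueError:
        raise LncArrayError(f"unparseable INSS stage label: {value!r}") from None
    if not 1 <= stage <= 4:
        raise LncArrayError(f"INSS stage out of range 1-4: {value!r}")
    return stage, False


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise LncArrayError(f"negative start: {self}")
        if self.end <= self.start:
            raise LncArrayError(f"empty/inverted interval: {self}")
        if self.strand not in STRANDS:
            raise LncArrayError(f"unknown strand {self.strand!r} (use +, - or .)")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", same_strand: bool = False) -> bool:
        """True iff the intervals share >= 1 base (half-open arithmetic)."""
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Minimal end-to-start gap in bp; 0 for overlap/abutting; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def contains(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript with its exon structure and coding status.

    ``length_nt`` is the mature transcript length, i.e. the sum of exon
    spans; this is the L entering the length-class analysis (transcripts
    of >= 200 nt with no coding capacity count as lncRNAs).
    """

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    biotype: str = "unannotated"

    def __post_init__(self):
        if self.biotype not in BIOTYPES:
            raise LncArrayError(f"unknown biotype {self.biotype!r}")
        if not self.exons:
            # single-exon convention: the transcript body is its one exon
            object.__setattr__(self, "exons", (self.interval,))
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom or exon.strand != self.interval.strand:
                raise LncArrayError(
                    f"{self.transcript_id}: exon {exon} not on transcript interval/strand")
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise LncArrayError(
                    f"{self.transcript_id}: exon {exon} outside transcript bounds")
            if prev_end is not None and exon.start < prev_end:
                raise LncArrayError(
                    f"{self.transcript_id}: exons unsorted or overlapping at {exon}")
            prev_end = exon.end

    @property
    def length_nt(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class TermMapping:
    """term_id -> gene set over a fixed gene universe (GMT-like)."""

    terms: dict
    universe: frozenset

    def __post_init__(self):
        object.__setattr__(self, "universe", frozenset(self.universe))
        object.__setattr__(
            self, "terms", {t: frozenset(g) for t, g in self.terms.items()})
        for term, genes in self.terms.items():
            if not genes:
                raise LncArrayError(f"term {term!r} maps to no genes")
            stray = genes - self.universe
            if stray:
                raise LncArrayError(
                    f"term {term!r} maps genes outside the universe: {sorted(stray)[:5]}")


class CohortMatrix:
    """Normalized log-scale expression (probes x samples) plus sample metadata.

    Parameters
    ----------
    values
        DataFrame with probe ids as index and sample ids as columns; all
        cells finite floats (missing values are rejected, not imputed).
    metadata
        Optional DataFrame indexed by sample id.  Recognized columns are
        listed in :data:`METADATA_COLUMNS`; absent entries become NA.
    """

    def __init__(self, values: pd.DataFrame, metadata: pd.DataFrame | None = None):
        values = values.copy()
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        values.index.name = None
        values.columns.name = None
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise LncArrayError(f"duplicate probe ids: {dups[:5]}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise LncArrayError(f"duplicate sample ids: {dups[:5]}")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(values.to_numpy(dtype=float, na_value=np.nan)))
            where = (f" first at probe {values.index[bad[0][0]]!r}, "
                     f"sample {values.columns[bad[0][1]]!r}" if len(bad) else "")
            raise LncArrayError("expression matrix contains non-numeric or missing cells"
                                + where)
        self.values = values.astype(float)

        meta = pd.DataFrame(index=self.values.columns.copy())
        if metadata is not None:
            metadata = metadata.copy()
            metadata.index = metadata.index.astype(str)
            unknown = set(metadata.index) - set(self.values.columns)
            if unknown:
                raise LncArrayError(
                    f"metadata names samples absent from the matrix: {sorted(unknown)[:5]}")
            for col in metadata.columns:
                meta[col] = metadata[col].reindex(meta.index)
        for col in METADATA_COLUMNS:
            if col not in meta.columns:
                meta[col] = pd.NA
        if meta["stage"].notna().any():
            stages = meta.loc[meta["stage"].notna(), "stage"]
            parsed = stages.map(parse_stage)
            meta.loc[parsed.index, "stage"] = parsed.map(lambda t: t[0])
            flag = parsed.map(lambda t: t[1])
            # an explicit stage_4s column wins over the label-derived flag
            explicit = meta.loc[parsed.index, "stage_4s"]
            meta.loc[parsed.index, "stage_4s"] = explicit.where(explicit.notna(), flag)
        meta["stage"] = meta["stage"].astype("Int64")
        for col in ("stage_4s", "mycn_amplified", "relapse", "survived_5y"):
            meta[col] = meta[col].astype("boolean")
        self.metadata = meta

    # -- basic accessors -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __repr__(self) -> str:
        return f"CohortMatrix({self.n_probes} probes x {self.n_samples} samples)"

    # -- views ------------------------------------------------------------
    def subset(self, probes=None, samples=None) -> "CohortMatrix":
        values = self.values
        if probes is not None:
            probes = [str(p) for p in probes]
            missing = set(probes) - set(values.index)
            if missing:
                raise LncArrayError(f"unknown probes requested: {sorted(missing)[:5]}")
            values = values.loc[probes]
        if samples is not None:
            samples = [str(s) for s in samples]
            missing = set(samples) - set(values.columns)
            if missing:
                raise LncArrayError(f"unknown samples requested: {sorted(missing)[:5]}")
            values = values[samples]
        return CohortMatrix(values, self.metadata.loc[values.columns])

    def staged_samples(self, include_4s: bool = False) -> list[str]:
        """Samples with a known stage; 4s excluded by default."""
        meta = self.metadata
        mask = meta["stage"].notna()
        if not include_4s:
            mask &= ~meta["stage_4s"].fillna(False).astype(bool)
        return list(meta.index[mask])

    def restrict_non_mna(self) -> "CohortMatrix":
        """Drop samples flagged MYCN-amplified (unknown status is kept)."""
        keep = ~self.metadata["mycn_amplified"].fillna(False).astype(bool)
        return self.subset(samples=list(self.metadata.index[keep]))
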