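"""Probe-set filtration cascade selecting lncRNA candidates.

Starting from probe-set genomic mappings, a probe set is retained as an
lncRNA candidate iff it (1) maps a unique genomic location and a single
target transcript, (2) does not target an annotated protein-coding
transcript, (3) has no placement overlapping a protein exon on the same
DNA strand (antisense overlap is explicitly allowed — the geometry of
HOXD-AS1, which lies antisense to HOXD1/HOXD3), (4) passes the coding-
potential filter, and (5) targets a transcript of at least ``min_length``
nt.  Every input probe receives a complete audit record; rules are
evaluated in the fixed order above and all failing rules are listed.

External coding/alignment tools are not run here: their verdicts enter as
optional evidence tables, with a built-in open-reading-frame heuristic
(coding iff the longest forward-strand ORF is >= 100 codons and covers
>= 30% of the transcript) and a genomic-containment rule standing in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

from .core import GenomicInterval, LncArrayError, TranscriptRecord

FILTER_RULES = (
    "non_unique",
    "protein_annotated",
    "same_strand_protein_exon_overlap",
    "coding_potential",
    "below_min_length",
    "no_reference_match",
)

_IUPAC = set("ACGTUNRYSWKMBDHV")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ProbeMapping:
    """A probe set's genomic placements and uniqueness evidence."""

    probe_set_id: str
    placements: tuple
    target_transcript_id: str | None = None
    unique_match: bool = True

    def __post_init__(self):
        object.__setattr__(self, "placements", tuple(self.placements))
        if self.unique_match != (len(self.placements) == 1):
            raise LncArrayError(
                f"{self.probe_set_id}: unique_match flag inconsistent with "
                f"{len(self.placements)} placement(s)")


@dataclass(frozen=True)
class FilterAudit:
    probe_set_id: str
    outcome: str  # retained | excluded
    reasons: tuple = ()

    def __post_init__(self):
        if self.outcome not in ("retained", "excluded"):
            raise LncArrayError(f"bad audit outcome {self.outcome!r}")
        if self.outcome == "excluded" and not self.reasons:
            raise LncArrayError(f"{self.probe_set_id}: excluded without reasons")
        if self.outcome == "retained" and self.reasons:
            raise LncArrayError(f"{self.probe_set_id}: retained with reasons")
        unknown = set(self.reasons) - set(FILTER_RULES)
        if unknown:
            raise LncArrayError(f"unknown filter rule(s) {sorted(unknown)}")


@dataclass(frozen=True)
class LncRNACandidate:
    probe_set_id: str
    transcript: TranscriptRecord
    length_nt: int
    high_confidence: bool = False
    placements: tuple = ()


def _validate_sequence(sequence: str, who: str) -> str:
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _IUPAC
    if bad:
        raise LncArrayError(f"{who}: non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


def longest_orf_codons(sequence: str) -> int:
    """Codons (ATG..stop, stop excluded) of the longest forward-frame ORF."""
    seq = sequence
    best = 0
    for frame in range(3):
        start = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                best = max(best, (pos - start) // 3)
                start = None
    return best


def coding_potential(transcript: TranscriptRecord, sequence: str | None = None,
                     external_calls: dict | None = None,
                     min_codons: int = 100, min_coverage: float = 0.30) -> str:
    """'coding' or 'noncoding' for a transcript.

    An external verdict (e.g. from a dedicated coding-potential tool)
    takes precedence; otherwise the built-in ORF heuristic applies.  With
    neither evidence the transcript is presumed noncoding.
    """
    if external_calls and transcript.transcript_id in external_calls:
        verdict = external_calls[transcript.transcript_id]
        if verdict not in ("coding", "noncoding"):
            raise LncArrayError(
                f"{transcript.transcript_id}: external coding call must be "
                f"'coding' or 'noncoding', got {verdict!r}")
        return verdict
    if sequence is None:
        return "noncoding"
    seq = _validate_sequence(sequence, transcript.transcript_id)
    if len(seq) != transcript.length_nt:
        raise LncArrayError(
            f"{transcript.transcript_id}: sequence length {len(seq)} != "
            f"transcript length {transcript.length_nt}")
    codons = longest_orf_codons(seq)
    if codons >= min_codons and (codons * 3) / len(seq) >= min_coverage:
        return "coding"
    return "noncoding"


@dataclass
class CodingEvidence:
    """Pluggable coding-potential evidence: external calls win, ORF heuristic backs up."""

    external_calls: dict = field(default_factory=dict)
    sequences: dict = field(default_factory=dict)
    min_codons: int = 100
    min_coverage: float = 0.30

    def classify(self, transcript: TranscriptRecord) -> str:
        return coding_potential(
            transcript,
            sequence=self.sequences.get(transcript.transcript_id),
            external_calls=self.external_calls,
            min_codons=self.min_codons, min_coverage=self.min_coverage)


def _exon_tree(intervals) -> dict:
    trees: dict[tuple, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(iv.start, iv.end)
    return trees


def _overlaps_same_strand(placement: GenomicInterval, trees: dict) -> bool:
    tree = trees.get((placement.chrom, placement.strand))
    return bool(tree is not None and tree.overlap(placement.start, placement.end))


def filter_candidates(probes, transcripts, protein_exons,
                      coding_filter: CodingEvidence | None = None,
                      min_length: int = 200):
    """Run the filtration cascade; return (candidates, audits).

    Audits cover every input probe in input order; a probe is retained iff
    no rule fires.  A probe with no named target transcript cannot match a
    single transcript uniquely and therefore fails ``non_unique``.
    """
    coding_filter = coding_filter or CodingEvidence()
    by_id = {t.transcript_id: t for t in transcripts}
    trees = _exon_tree(protein_exons)

    candidates, audits = [], []
    for probe in probes:
        target = None
        if probe.target_transcript_id is not None:
            target = by_id.get(probe.target_transcript_id)
            if target is None:
                raise LncArrayError(
                    f"{probe.probe_set_id}: target transcript "
                    f"{probe.target_transcript_id!r} not found")
        reasons = []
        if not probe.unique_match or target is None:
            reasons.append("non_unique")
        if target is not None and target.biotype == "protein_coding":
            reasons.append("protein_annotated")
        if any(_overlaps_same_strand(p, trees) for p in probe.placements):
            reasons.append("same_strand_protein_exon_overlap")
        if target is not None and coding_filter.classify(target) == "coding":
            reasons.append("coding_potential")
        if target is not None and target.length_nt < min_length:
            reasons.append("below_min_length")

        if reasons:
            audits.append(FilterAudit(probe.probe_set_id, "excluded", tuple(reasons)))
        else:
            audits.append(FilterAudit(probe.probe_set_id, "retained"))
            candidates.append(LncRNACandidate(
                probe_set_id=probe.probe_set_id, transcript=target,
                length_nt=target.length_nt, placements=probe.placements))
    return candidates, audits


def _contained_in_exons(placement: GenomicInterval, reference: TranscriptRecord) -> bool:
    if placement.strand != reference.interval.strand:
        return False
    return any(exon.contains(placement) for exon in reference.exons)


def match_reference(candidates, reference, alignment_table: dict | None = None):
    """Set ``high_confidence`` on candidates that uniquely match a reference transcript.

    With an alignment table (probe id -> reference transcript hits) the
    table decides; otherwise a candidate matches a reference transcript
    when every placement lies within one of its exons on the same strand.
    In both routes exactly one matching reference transcript is required.
    """
    ref_ids = [r.transcript_id for r in reference]
    if len(set(ref_ids)) != len(ref_ids):
        raise LncArrayError("reference transcript ids are not unique")
    known_probes = {c.probe_set_id for c in candidates}
    if alignment_table is not None:
        ref_set = set(ref_ids)
        for probe_id, hits in alignment_table.items():
            if probe_id not in known_probes:
                raise LncArrayError(f"alignment table names unknown probe {probe_id!r}")
            for hit in hits:
                if hit not in ref_set:
                    raise LncArrayError(
                        f"alignment table names unknown reference transcript {hit!r}")

    out = []
    for cand in candidates:
        if alignment_table is not None:
            n_hits = len(set(alignment_table.get(cand.probe_set_id, ())))
        else:
            n_hits = sum(
                1 for ref in reference
                if cand.placements and all(
                    _contained_in_exons(p, ref) for p in cand.placements))
        out.append(replace(cand, high_confidence=(n_hits == 1)))
    return out
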