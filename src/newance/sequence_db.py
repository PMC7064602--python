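"""Non-canonical search-space construction and peptide classification.

The non-canonical database is built by translating expressed non-coding
transcripts in the three forward reading frames with a stop-to-stop
strategy: every segment between two stop codons (and, by default, the
open-ended segments bounded by the transcript ends) of at least eight
amino acids enters the search space.  Codons containing N translate to X
and segments are split at X so that no fabricated residue is searchable.

Identified peptides are then classified against the canonical proteome by
exact substring matching with I/L treated as equal (leucine and isoleucine
are isobaric and indistinguishable by MS).  A peptide matching only
accessions on a transposable-element whitelist stays non-canonical
(te_exception), since TEs integrated into the canonical reference are
still non-canonical by origin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from newance.io_formats import ExpressionTable, FastaEntry, Group

__all__ = [
    "OrfRecord",
    "PeptideClassification",
    "ProteomeIndex",
    "translate_three_frames",
    "build_noncanonical_db",
    "classify_peptide",
    "peptide_position_stats",
    "collapse_il",
    "orf_fasta_entries",
]

_IL_TABLE = str.maketrans("I", "L")
_SPLIT_RE = re.compile(r"[*X]")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
_CODON_MAP = dict(_STANDARD_TABLE.forward_table)
_CODON_MAP.update({codon: "*" for codon in _STANDARD_TABLE.stop_codons})


def _translate_frame(coding: str) -> str:
    """Translate an in-frame nucleotide string; codons containing N give X."""
    return "".join(
        _CODON_MAP.get(coding[i : i + 3], "X") for i in range(0, len(coding), 3)
    )


def collapse_il(sequence: str) -> str:
    """Replace I by L (isobaric residues, indistinguishable by MS)."""
    return sequence.translate(_IL_TABLE)


@dataclass(slots=True, frozen=True)
class OrfRecord:
    """A stop-to-stop ORF in one forward frame of a transcript.

    Nucleotide coordinates are 0-based, end-exclusive, and recover exactly
    the codons encoding ``peptide_seq``:
    ``end_nt - start_nt == 3 * len(peptide_seq)``.
    """

    orf_id: str
    transcript_id: str
    frame: int
    start_nt: int
    end_nt: int
    peptide_seq: str


@dataclass(slots=True)
class PeptideClassification:
    peptide: str
    status: Group
    matched_canonical_accessions: list[str] = field(default_factory=list)
    matched_noncanonical_ids: list[str] = field(default_factory=list)
    te_exception: bool = False


def translate_three_frames(
    transcript: FastaEntry,
    min_len: int = 8,
    include_terminal: bool = True,
) -> list[OrfRecord]:
    """Stop-to-stop translation of a transcript in the three forward frames.

    Parameters
    ----------
    transcript:
        Nucleotide FASTA entry (ACGTN).
    min_len:
        Minimum emitted peptide length in amino acids (default 8).
    include_terminal:
        Also emit segments bounded by the sequence ends rather than by a
        stop codon on both sides.  Reverse-complement frames are not
        searched: transcripts are single-stranded.

    Returns ORFs ordered by (frame, start_nt).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = transcript.sequence.upper()
    records: list[OrfRecord] = []
    for frame in range(3):
        n_codons = (len(seq) - frame) // 3
        if n_codons <= 0:
            continue
        coding = seq[frame : frame + 3 * n_codons]
        protein = _translate_frame(coding)
        # split on stops and on X (codons containing N); segment bounds in codons
        pos = 0
        for segment in _SPLIT_RE.split(protein):
            start_codon = pos
            pos += len(segment) + 1
            if len(segment) < min_len:
                continue
            end_codon = start_codon + len(segment)
            if not include_terminal:
                bounded_left = start_codon > 0 and protein[start_codon - 1] == "*"
                bounded_right = end_codon < n_codons and protein[end_codon] == "*"
                if not (bounded_left and bounded_right):
                    continue
            start_nt = frame + 3 * start_codon
            end_nt = frame + 3 * end_codon
            records.append(
                OrfRecord(
                    orf_id=f"orf|{transcript.accession}|F{frame}|{start_nt}-{end_nt}",
                    transcript_id=transcript.accession,
                    frame=frame,
                    start_nt=start_nt,
                    end_nt=end_nt,
                    peptide_seq=segment,
                )
            )
    return records


def build_noncanonical_db(
    transcripts: list[FastaEntry],
    expr: ExpressionTable,
    cutoff: float = 0.0,
    min_len: int = 8,
    include_terminal: bool = True,
) -> list[OrfRecord]:
    """Three-frame ORF database restricted to expressed transcripts.

    Only transcripts with expression strictly greater than ``cutoff``
    contribute (the default 0.0 keeps every detected transcript, i.e.
    FPKM > 0).  Transcripts absent from the expression table are treated
    as unexpressed.  Output order is (transcript id, frame, start).
    """
    if cutoff < 0:
        raise ValueError("expression cutoff must be >= 0")
    records: list[OrfRecord] = []
    for transcript in sorted(transcripts, key=lambda t: t.accession):
        if expr.expression(transcript.accession) > cutoff:
            records.extend(translate_three_frames(transcript, min_len, include_terminal))
    return records


def orf_fasta_entries(records: list[OrfRecord]) -> list[FastaEntry]:
    """Render ORF records as amino-acid FASTA entries."""
    return [
        FastaEntry(accession=r.orf_id, description=r.orf_id, sequence=r.peptide_seq)
        for r in records
    ]


class ProteomeIndex:
    """Exact-substring index over an I/L-collapsed protein database.

    A k-mer seed index: each k-mer of the collapsed proteome maps to its
    (protein, offset) occurrences; a query seeds on its first k-mer and
    verifies the full extension.  Queries shorter than k fall back to a
    linear scan.  Any exact-substring structure would satisfy the same
    contract.
    """

    def __init__(self, entries: list[FastaEntry], k: int = 6):
        self.k = k
        self.accessions = [e.accession for e in entries]
        self._collapsed = [collapse_il(e.sequence.upper()) for e in entries]
        self._seeds: dict[str, list[tuple[int, int]]] = {}
        for idx, seq in enumerate(self._collapsed):
            for off in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[off : off + k], []).append((idx, off))

    def find(self, peptide: str) -> list[str]:
        """Accessions containing ``peptide`` under I/L equivalence, in database order."""
        if not peptide:
            raise ValueError("empty peptide")
        query = collapse_il(peptide.upper())
        hits: set[int] = set()
        if len(query) < self.k:
            for idx, seq in enumerate(self._collapsed):
                if query in seq:
                    hits.add(idx)
        else:
            for idx, off in self._seeds.get(query[: self.k], ()):
                if self._collapsed[idx][off : off + len(query)] == query:
                    hits.add(idx)
        return [self.accessions[i] for i in sorted(hits)]


def classify_peptide(
    peptide: str,
    canonical_index: ProteomeIndex,
    te_whitelist: set[str] | frozenset[str] = frozenset(),
) -> PeptideClassification:
    """Classify a peptide as proteome-derived or non-canonical.

    An exact substring match (under I/L equivalence) to any canonical
    accession makes the peptide proteome-derived — unless every matching
    accession is on the TE whitelist, in which case the peptide is kept
    as non-canonical with ``te_exception`` set.
    """
    if not peptide:
        raise ValueError("empty peptide")
    matches = canonical_index.find(peptide)
    if not matches:
        return PeptideClassification(peptide=peptide, status=Group.noncanonical)
    if te_whitelist and all(acc in te_whitelist for acc in matches):
        return PeptideClassification(
            peptide=peptide,
            status=Group.noncanonical,
            matched_canonical_accessions=list(matches),
            te_exception=True,
        )
    return PeptideClassification(
        peptide=peptide,
        status=Group.proteome,
        matched_canonical_accessions=list(matches),
    )


def peptide_position_stats(
    peptide: str, source_seq: str, c_terminal: bool = True
) -> float:
    """Relative position of a peptide within its source protein, in [0, 1].

    The default statistic is the relative coordinate of the peptide's
    C-terminal residue: ``(start + len(peptide)) / len(source)`` for the
    first occurrence (I/L-collapsed).  With ``c_terminal=False`` the
    N-terminal coordinate ``start / len(source)`` is returned instead.
    """
    if not peptide:
        raise ValueError("empty peptide")
    if not source_seq:
        raise ValueError("empty source sequence")
    query = collapse_il(peptide.upper())
    target = collapse_il(source_seq.upper())
    start = target.find(query)
    if start < 0:
        raise ValueError("peptide does not occur in the source sequence")
    if c_terminal:
        return (start + len(peptide)) / len(source_seq)
    return start / len(source_seq)
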