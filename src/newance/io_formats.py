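"""Reading and writing of the tabular and FASTA artifacts used by the pipeline.

The native interchange format for peptide-spectrum matches (PSMs) is a plain
TSV dialect with a fixed header, so that the statistical machinery never has
to know about search-engine specific formats (pep.xml, msms.txt).  Engine A
stands for a Comet-style engine reporting (XCorr, deltaCn, spScore); engine B
for an Andromeda-style engine reporting a single score and arriving already
thresholded at its own PSM FDR.

Columns of the PSM dialect (tab-separated, ``#`` lines are comments)::

    spectrum_key  peptide  charge  xcorr  delta_cn  sp_score  engine_score
    proteins  is_decoy  group

``proteins`` is a semicolon-separated accession list.  ``is_decoy`` and
``group`` are optional: the decoy flag is otherwise derived from a
configurable accession prefix (default ``DECOY_``), and the group defaults
to ``unassigned``.  Modifications are written in bracketed mass-delta
notation, e.g. ``PEPT[+79.9663]IDE``, with deltas rounded to four decimals.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Engine",
    "Group",
    "PsmRecord",
    "PsmTable",
    "FastaEntry",
    "ExpressionTable",
    "FormatError",
    "read_psm_table",
    "write_psm_table",
    "read_fasta",
    "write_fasta",
    "read_expression_table",
    "write_results",
    "normalize_modified_peptide",
    "DEFAULT_DECOY_PREFIX",
]

DEFAULT_DECOY_PREFIX = "DECOY_"

PSM_COLUMNS = [
    "spectrum_key",
    "peptide",
    "charge",
    "xcorr",
    "delta_cn",
    "sp_score",
    "engine_score",
    "proteins",
    "is_decoy",
    "group",
]

_MANDATORY_COLUMNS = ["spectrum_key", "peptide", "charge", "proteins"]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXUBZ")
_NT_ALPHABET = set("ACGTN")

_MOD_RE = re.compile(r"\[([+-]?\d*\.?\d+)\]")


class FormatError(ValueError):
    """Raised when an input file does not conform to the declared dialect."""


class Engine(str, enum.Enum):
    engineA = "engineA"
    engineB = "engineB"


class Group(str, enum.Enum):
    proteome = "proteome"
    noncanonical = "noncanonical"
    unassigned = "unassigned"


@dataclass(slots=True)
class PsmRecord:
    """One engine's match of a spectrum to a peptide.

    ``peptide`` is the modified peptide string (uppercase residues,
    bracketed mass deltas); ``xcorr``, ``delta_cn``, ``sp_score`` carry the
    engine A score triple, ``engine_score`` the generic single score used
    for engine B and for 1D mode.
    """

    spectrum_key: str
    peptide: str
    charge: int
    xcorr: float = 0.0
    delta_cn: float = 0.0
    sp_score: float = 0.0
    engine_score: float = 0.0
    protein_ids: tuple[str, ...] = ()
    is_decoy: bool = False
    group: Group = Group.unassigned

    @property
    def bare_peptide(self) -> str:
        """Peptide sequence with modification annotations stripped."""
        return _MOD_RE.sub("", self.peptide)


@dataclass(slots=True)
class PsmTable:
    rows: list[PsmRecord]
    engine: Engine
    source_path: str = ""
    n_malformed: int = 0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def decoy_fraction(self) -> float:
        if not self.rows:
            return 0.0
        return sum(r.is_decoy for r in self.rows) / len(self.rows)


@dataclass(slots=True, frozen=True)
class FastaEntry:
    accession: str
    description: str
    sequence: str


@dataclass(slots=True)
class ExpressionTable:
    """Map transcript_id -> (gene_id, expression, unit)."""

    entries: dict[str, tuple[str, float, str]]

    def expression(self, transcript_id: str, default: float = 0.0) -> float:
        entry = self.entries.get(transcript_id)
        return entry[1] if entry is not None else default

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def normalize_modified_peptide(peptide: str) -> str:
    """Canonicalise a modified peptide string for equality comparisons.

    Residues are uppercased and bracketed mass deltas rounded to four
    decimals with an explicit sign, so that engines reporting
    ``[+79.96633]`` and ``[79.9663]`` agree on the join key.
    """

    def _round(m: re.Match) -> str:
        return f"[{float(m.group(1)):+.4f}]"

    return _MOD_RE.sub(_round, peptide.upper())


def _parse_bool(value: str) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes", "t"}


def read_psm_table(
    path: str | Path,
    engine: Engine | str = Engine.engineA,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> PsmTable:
    """Read a PSM table in the native TSV dialect.

    The decoy flag is taken from the ``is_decoy`` column when present and
    otherwise derived from ``decoy_prefix`` on the accessions.  Rows with
    an empty spectrum key or peptide are counted in ``n_malformed`` and
    dropped; a non-numeric score raises :class:`FormatError` naming the
    offending line.
    """
    path = Path(path)
    engine = Engine(engine)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return PsmTable(rows=[], engine=engine, source_path=str(path))
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    has_decoy_col = "is_decoy" in df.columns
    has_group_col = "group" in df.columns
    score_cols = ["xcorr", "delta_cn", "sp_score", "engine_score"]

    rows: list[PsmRecord] = []
    n_malformed = 0
    for i, rec in enumerate(df.itertuples(index=False)):
        rec = rec._asdict()
        spectrum_key = rec["spectrum_key"].strip()
        peptide = rec["peptide"].strip().upper()
        if not spectrum_key or not peptide:
            n_malformed += 1
            continue
        line_no = i + 2  # header is line 1
        try:
            charge = int(rec["charge"])
        except ValueError as exc:
            raise FormatError(f"{path}:{line_no}: non-integer charge {rec['charge']!r}") from exc
        if charge < 1:
            raise FormatError(f"{path}:{line_no}: charge must be >= 1, got {charge}")
        scores = {}
        for col in score_cols:
            raw = rec.get(col, "")
            if raw == "":
                scores[col] = 0.0
                continue
            try:
                value = float(raw)
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: non-numeric {col} {raw!r}") from exc
            if not math.isfinite(value):
                raise FormatError(f"{path}:{line_no}: non-finite {col}")
            scores[col] = value
        proteins = tuple(p for p in rec["proteins"].split(";") if p)
        if has_decoy_col and rec["is_decoy"] != "":
            is_decoy = _parse_bool(rec["is_decoy"])
        else:
            is_decoy = bool(proteins) and all(p.startswith(decoy_prefix) for p in proteins)
        group = Group(rec["group"]) if has_group_col and rec["group"] else Group.unassigned
        rows.append(
            PsmRecord(
                spectrum_key=spectrum_key,
                peptide=normalize_modified_peptide(peptide),
                charge=charge,
                protein_ids=proteins,
                is_decoy=is_decoy,
                group=group,
                **scores,
            )
        )
    return PsmTable(rows=rows, engine=engine, source_path=str(path), n_malformed=n_malformed)


def write_psm_table(table: PsmTable, path: str | Path) -> Path:
    """Write a PSM table in the native dialect (lossless round-trip)."""
    path = Path(path)
    records = [
        {
            "spectrum_key": r.spectrum_key,
            "peptide": r.peptide,
            "charge": r.charge,
            "xcorr": r.xcorr,
            "delta_cn": r.delta_cn,
            "sp_score": r.sp_score,
            "engine_score": r.engine_score,
            "proteins": ";".join(r.protein_ids),
            "is_decoy": r.is_decoy,
            "group": r.group.value,
        }
        for r in table.rows
    ]
    df = pd.DataFrame.from_records(records, columns=PSM_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_fasta(path: str | Path, alphabet: str = "aa") -> list[FastaEntry]:
    """Read a FASTA file, validating sequences against the declared alphabet.

    ``alphabet`` is ``"aa"`` (20 standard residues plus X/U/B/Z) or ``"nt"``
    (ACGTN).  Sequences are uppercased and line wraps removed.  Duplicate
    accessions are rejected.
    """
    if alphabet not in {"aa", "nt"}:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = _AA_ALPHABET if alphabet == "aa" else _NT_ALPHABET
    entries: list[FastaEntry] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        if accession in seen:
            raise FormatError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        sequence = str(record.seq).upper()
        if not sequence:
            raise FormatError(f"{path}: empty sequence for {accession!r}")
        for pos, ch in enumerate(sequence):
            if ch not in allowed:
                raise FormatError(
                    f"{path}: illegal {alphabet} character {ch!r} in {accession!r} at position {pos}"
                )
        entries.append(FastaEntry(accession=accession, description=record.description, sequence=sequence))
    return entries


def write_fasta(entries: Iterable[FastaEntry], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for entry in entries:
            header = entry.description if entry.description else entry.accession
            fh.write(f">{header}\n")
            seq = entry.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a transcript expression TSV (transcript_id, gene_id, value, unit)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("transcript_id", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column(s): {col}")
    entries: dict[str, tuple[str, float, str]] = {}
    for i, rec in enumerate(df.itertuples(index=False)):
        rec = rec._asdict()
        tid = rec["transcript_id"].strip()
        if tid in entries:
            raise FormatError(f"{path}: duplicate transcript_id {tid!r}")
        try:
            value = float(rec["value"])
        except ValueError as exc:
            raise FormatError(f"{path}:{i + 2}: non-numeric expression {rec['value']!r}") from exc
        if value < 0:
            raise FormatError(f"{path}:{i + 2}: negative expression value")
        entries[tid] = (rec.get("gene_id", ""), value, rec.get("unit", "FPKM") or "FPKM")
    return ExpressionTable(entries=entries)


def write_results(
    psms: PsmTable | Sequence[PsmRecord],
    classifications: Sequence,
    path: str | Path,
) -> Path:
    """Write the final per-PSM results table.

    Every PSM peptide must have a classification (see
    :mod:`newance.sequence_db`).  Rows are sorted by (spectrum_key, peptide)
    so repeated runs produce byte-identical files.
    """
    rows = list(psms.rows if isinstance(psms, PsmTable) else psms)
    by_peptide = {c.peptide: c for c in classifications}
    records = []
    for r in rows:
        cls = by_peptide.get(r.bare_peptide)
        if cls is None:
            raise ValueError(f"no classification for peptide {r.bare_peptide!r}")
        records.append(
            {
                "spectrum_key": r.spectrum_key,
                "peptide": r.peptide,
                "charge": r.charge,
                "group": cls.status.value if isinstance(cls.status, Group) else str(cls.status),
                "xcorr": r.xcorr,
                "delta_cn": r.delta_cn,
                "sp_score": r.sp_score,
                "matched_accessions": ";".join(cls.matched_canonical_accessions),
            }
        )
    columns = [
        "spectrum_key",
        "peptide",
        "charge",
        "group",
        "xcorr",
        "delta_cn",
        "sp_score",
        "matched_accessions",
    ]
    df = pd.DataFrame.from_records(records, columns=columns)
    df = df.sort_values(["spectrum_key", "peptide"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
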