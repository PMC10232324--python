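"""Protein records, annotation tables, and their file formats.

Sequences come in as FASTA; labels come in as a delimited table with
columns ``id``, ``is_enzyme``, ``ec_list`` (semicolon-separated EC
strings) and an optional ISO-8601 ``date`` used for chronological
train/test splitting.  The sequence alphabet is the 20 standard amino
acids plus ``X``; ambiguous or nonstandard residue codes (B, Z, U, O, J,
anything else alphabetic) normalise to ``X`` and ``*``/gap characters
are stripped, so unusual sequences are representable rather than
rejected.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .ec import ECNumber, format_ec, parse_ec

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "ProteinRecord",
    "AnnotationTable",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"

_STRIP = set("*-. ")


def normalize_sequence(raw: str) -> str:
    """Upper-case, strip stop/gap characters, map nonstandard letters to X."""
    out = []
    for ch in raw.upper():
        if ch in _STRIP or ch.isspace():
            continue
        out.append(ch if ch in AMINO_ACIDS else "X")
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: id, normalized sequence, and (optionally) labels."""

    id: str
    sequence: str
    is_enzyme: bool | None = None
    ec_numbers: tuple[ECNumber, ...] = ()
    date_added: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r} has out-of-alphabet symbols {sorted(bad)}; "
                "normalize first"
            )
        if self.is_enzyme is False and self.ec_numbers:
            raise ValueError(f"non-enzyme record {self.id!r} carries EC numbers")
        if self.is_enzyme is True and not self.ec_numbers:
            raise ValueError(f"enzyme record {self.id!r} has no EC numbers")
        if len(set(self.ec_numbers)) != len(self.ec_numbers):
            raise ValueError(f"record {self.id!r} has duplicate EC numbers")


@dataclass
class AnnotationTable:
    """An ordered collection of :class:`ProteinRecord` with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, rid: str) -> ProteinRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def vocabulary(self) -> list[ECNumber]:
        """Sorted distinct EC numbers present in the table."""
        return sorted({ec for r in self.records for ec in r.ec_numbers})

    def subset(self, ids) -> "AnnotationTable":
        wanted = set(ids)
        return AnnotationTable([r for r in self.records if r.id in wanted])


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA, returning ``(id, normalized_sequence)`` pairs.

    The id is the first whitespace-delimited header token.  Duplicate ids
    and records whose sequence normalises to empty are errors.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r}")
        seen.add(rid)
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"FASTA record {rid!r} has no sequence")
        pairs.append((rid, seq))
    if not pairs and not seen:
        # Bio.SeqIO silently yields nothing for empty files
        with open(path) as fh:
            if not fh.read().strip():
                raise ValueError(f"empty FASTA file: {path}")
    return pairs


def write_fasta(pairs, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in pairs:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_bool(value) -> bool:
    text = str(value).strip().lower()
    if text in {"1", "true", "yes"}:
        return True
    if text in {"0", "false", "no"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as an enzyme flag")


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_annotations(path, sequences: dict[str, str] | None = None) -> AnnotationTable:
    """Read an annotation table (CSV or TSV, auto-detected from the header).

    Expected columns: ``id``, ``is_enzyme``, ``ec_list`` (semicolon-joined
    EC strings, empty for non-enzymes), optional ``date`` (ISO-8601),
    optional ``sequence``.  Sequences may instead be supplied via the
    ``sequences`` mapping (e.g. from :func:`read_fasta`).

    Raises a consistency error naming the offending record ids when the
    enzyme flag disagrees with the EC list.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"id", "is_enzyme", "ec_list"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")

    inconsistent: list[str] = []
    records: list[ProteinRecord] = []
    for row in df.itertuples(index=False):
        rid = str(row.id).strip()
        flag = _parse_bool(row.is_enzyme)
        ec_text = str(row.ec_list).strip()
        ecs = tuple(
            parse_ec(tok) for tok in (t.strip() for t in ec_text.split(";")) if tok
        )
        if flag != bool(ecs):
            inconsistent.append(rid)
            continue
        date = None
        if "date" in df.columns:
            raw = str(getattr(row, "date")).strip()
            if raw:
                date = _dt.date.fromisoformat(raw)
        if sequences is not None and rid in sequences:
            seq = sequences[rid]
        elif "sequence" in df.columns and str(getattr(row, "sequence")).strip():
            seq = normalize_sequence(str(getattr(row, "sequence")))
        else:
            raise ValueError(f"no sequence available for record {rid!r}")
        records.append(
            ProteinRecord(
                id=rid, sequence=seq, is_enzyme=flag, ec_numbers=ecs, date_added=date
            )
        )
    if inconsistent:
        raise ValueError(
            "enzyme flag inconsistent with EC list for records: "
            + ", ".join(inconsistent)
        )
    return AnnotationTable(records)


def write_annotations(table: AnnotationTable, path, sep: str = ",") -> None:
    """Write a table re-readable bit-identically by :func:`read_annotations`."""
    buf = io.StringIO()
    buf.write(sep.join(["id", "is_enzyme", "ec_list", "date", "sequence"]) + "\n")
    for r in table:
        ec_text = ";".join(format_ec(ec) for ec in r.ec_numbers)
        date = r.date_added.isoformat() if r.date_added else ""
        flag = "" if r.is_enzyme is None else str(int(r.is_enzyme))
        buf.write(sep.join([r.id, flag, ec_text, date, r.sequence]) + "\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())
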