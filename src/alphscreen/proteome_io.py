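"""FASTA ingestion and tabular output.

Reads proteome FASTA files in the UniProt reference-proteome dialect
(``>db|ACCESSION|NAME ... OS=Organism name OX=taxid ...``), the TriTrypDB
dialect (``>GeneID | organism=Name | ...``) and plain headers (first
whitespace-delimited token as id).  Gzip-compressed input is handled
transparently.  All tables are written as TSV with a fixed column order so
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .annotator import AlphAnnotation
from .screener import ScreenOutcome

__all__ = [
    "ProteomeRecord",
    "FastaFormatError",
    "read_proteome",
    "outcomes_to_frame",
    "annotations_to_frame",
    "write_table",
    "read_group_map",
    "OUTCOME_COLUMNS",
    "ANNOTATION_COLUMNS",
]

logger = logging.getLogger("alphscreen")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (with a line number where known)."""


@dataclass(frozen=True)
class ProteomeRecord:
    """One protein sequence with the header fields the screen consumes."""

    record_id: str
    description: str
    sequence: str
    organism_name: str | None = None
    taxon_id: int | None = None


_UNIPROT_ID = re.compile(r"^(?:sp|tr)\|([^|\s]+)\|\S+")
_OS = re.compile(r"\bOS=(.+?)(?=\s+(?:OX|GN|PE|SV)=|$)")
_OX = re.compile(r"\bOX=(\d+)")
_TRITRYP_ORGANISM = re.compile(r"\borganism=([^|]+?)(?:\s*\||\s*$)")


def _parse_header(record_id: str, description: str) -> tuple[str, str | None, int | None]:
    """(accession/id, organism, taxon id) from the two SeqIO header parts."""
    organism: str | None = None
    taxon: int | None = None
    match = _UNIPROT_ID.match(record_id)
    accession = match.group(1) if match else record_id
    os_match = _OS.search(description)
    if os_match:
        organism = os_match.group(1).strip()
    ox_match = _OX.search(description)
    if ox_match:
        taxon = int(ox_match.group(1))
    if organism is None:
        tri = _TRITRYP_ORGANISM.search(description)
        if tri:
            organism = tri.group(1).strip().replace("_", " ")
    return accession, organism, taxon


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _validate_fasta_text(text: str, path) -> None:
    """Structural check with line numbers: header lines must carry an id and
    every record must have sequence content."""
    header_line = None
    seen_sequence = True  # no dangling header yet
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if not seen_sequence:
                raise FastaFormatError(
                    f"{path}: record at line {header_line} has no sequence"
                )
            if len(stripped) == 1:
                raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
            header_line = lineno
            seen_sequence = False
        else:
            if header_line is None:
                raise FastaFormatError(
                    f"{path}: sequence data before any header at line {lineno}"
                )
            seen_sequence = True
    if not seen_sequence:
        raise FastaFormatError(f"{path}: record at line {header_line} has no sequence")


def read_proteome(path) -> Iterator[ProteomeRecord]:
    """Stream records from a (possibly gzipped) proteome FASTA file.

    Header dialects are detected per record; duplicate ids get a stable
    ``__dupN`` suffix with a logged warning; sequences are uppercased
    (``*`` and other non-standard codes are kept — they simply never match
    a motif position).
    """
    with _open_text(path) as handle:
        text = handle.read()
    _validate_fasta_text(text, path)
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        accession, organism, taxon = _parse_header(rec.id, rec.description)
        count = seen.get(accession, 0)
        seen[accession] = count + 1
        if count:
            disambiguated = f"{accession}__dup{count}"
            logger.warning(
                "%s: duplicate record id %r renamed to %r", path, accession, disambiguated
            )
            accession = disambiguated
        yield ProteomeRecord(
            record_id=accession,
            description=rec.description,
            sequence=str(rec.seq).upper(),
            organism_name=organism,
            taxon_id=taxon,
        )


# ---------------------------------------------------------------------------
# Tabular output

OUTCOME_COLUMNS: tuple[str, ...] = (
    "protein_id",
    "status",
    "missing_index",
    "truncated_terminal",
    *(f"m{k}_{field}" for k in range(1, 7) for field in ("start", "match", "flavour")),
    "d12",
    "d23",
    "d34",
    "d45",
    "d56",
    "extended_count",
    "notes",
)

ANNOTATION_COLUMNS: tuple[str, ...] = (
    "protein_id",
    "organism",
    "protein_length",
    "n_term_len",
    "cat_domain_start",
    "cat_domain_end",
    "cat_domain_len",
    "c_term_len",
    "d12",
    "d23",
    "d34",
    "d45",
    "d56",
    "extended_count",
)


def outcomes_to_frame(outcomes: Iterable[ScreenOutcome]) -> pd.DataFrame:
    """One row per outcome; motif starts are 1-based inclusive."""
    rows = []
    for outcome in outcomes:
        row: dict = {
            "protein_id": outcome.protein_id,
            "status": outcome.status,
            "missing_index": outcome.missing_index,
            "truncated_terminal": outcome.truncated_terminal,
            "extended_count": None,
            "notes": outcome.notes,
        }
        hits = ()
        if outcome.call is not None:
            hits = outcome.call.hits
            row["extended_count"] = outcome.call.extended_count
            for name, value in zip(("d12", "d23", "d34", "d45", "d56"),
                                   outcome.call.distances):
                row[name] = value
        elif outcome.partial_hits:
            hits = outcome.partial_hits
        for hit in hits:
            row[f"m{hit.motif_index}_start"] = hit.start + 1
            row[f"m{hit.motif_index}_match"] = hit.matched
            row[f"m{hit.motif_index}_flavour"] = hit.flavour_used
        rows.append(row)
    frame = pd.DataFrame(rows, columns=OUTCOME_COLUMNS)
    int_columns = [
        "missing_index",
        *(f"m{k}_start" for k in range(1, 7)),
        "d12", "d23", "d34", "d45", "d56",
        "extended_count",
    ]
    for column in int_columns:
        frame[column] = pd.to_numeric(frame[column]).astype("Int64")
    return frame


def annotations_to_frame(
    annotations: Iterable[AlphAnnotation],
    organisms: dict | None = None,
) -> pd.DataFrame:
    """One row per annotation; ``organisms`` optionally maps protein id to
    an organism label."""
    organisms = organisms or {}
    rows = []
    for ann in annotations:
        row = {
            "protein_id": ann.protein_id,
            "organism": organisms.get(ann.protein_id),
            "protein_length": ann.protein_length,
            "n_term_len": ann.n_term_len,
            "cat_domain_start": ann.cat_domain_start,
            "cat_domain_end": ann.cat_domain_end,
            "cat_domain_len": ann.cat_domain_len,
            "c_term_len": ann.c_term_len,
            "extended_count": ann.extended_count,
        }
        for name, value in zip(("d12", "d23", "d34", "d45", "d56"), ann.distances):
            row[name] = value
        rows.append(row)
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_table(frame: pd.DataFrame, path) -> None:
    """Write a TSV with header, LF line endings and no index column, so
    identical frames give byte-identical files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_group_map(path) -> dict[str, str]:
    """Two-column plain-text mapping organism/proteome identifier → group
    label.  Columns are tab- or whitespace-separated; ``#`` starts a
    comment."""
    mapping: dict[str, str] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t") if "\t" in stripped else stripped.split(None, 1)
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two columns, got {stripped!r}"
                )
            key, group = parts[0].strip(), parts[1].strip()
            if key in mapping and mapping[key] != group:
                raise ValueError(f"{path}: organism {key!r} mapped to two groups")
            mapping[key] = group
    return mapping
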