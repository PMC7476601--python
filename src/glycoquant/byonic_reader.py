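"""Reader for glycopeptide identification exports (Byonic-style).

Turns one delimited export file into structured PSM rows: the UniProtKB
accession is pulled out of the free-text protein name, decoy and contaminant
entries are discarded, the numeric MS2 scan number is extracted, and the
modified peptide string (``X.SEQ[+delta].Z``) is parsed into residues plus
positioned delta masses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .glycan_model import (
    AMINO_ACIDS,
    GlycanComposition,
    GlycanParseError,
    ModifiedPeptide,
    parse_glycan_field,
)

__all__ = [
    "IdentRow",
    "ReadStats",
    "TableFormatError",
    "PeptideParseError",
    "ScanParseError",
    "extract_accession",
    "is_excluded",
    "extract_scan",
    "parse_peptide",
    "read_ident_file",
]

logger = logging.getLogger(__name__)


class TableFormatError(ValueError):
    """An input table is missing a required column."""


class PeptideParseError(ValueError):
    """A modified peptide string could not be parsed."""


class ScanParseError(ValueError):
    """A scan-number cell contained no scan number."""


# The UniProtKB accession pattern (both the 6-character and the extended
# 10-character form), bounded so it does not fire inside longer
# alphanumeric tokens such as entry names.
UNIPROT_ACCESSION_RE = re.compile(
    r"(?<![0-9A-Za-z])"
    r"(?:[OPQ][0-9][A-Z0-9]{3}[0-9]"
    r"|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})"
    r"(?![0-9A-Za-z])"
)

DEFAULT_CONTAMINANT_MARKERS = ("common contaminant",)
DECOY_MARKER = ">reverse"


def extract_accession(protein_name: str) -> str:
    """Return the first UniProtKB accession found in a protein name.

    When no substring matches the accession pattern the whole protein name
    is returned unchanged, so every row keeps a usable grouping identity
    (custom constructs, non-UniProt databases).  The function is idempotent.
    """
    m = UNIPROT_ACCESSION_RE.search(protein_name)
    return m.group(0) if m else protein_name


def is_excluded(
    protein_name: str,
    contaminant_markers: Sequence[str] = DEFAULT_CONTAMINANT_MARKERS,
) -> bool:
    """True for decoy ("Reverse") and contaminant database entries.

    Decoys follow the ``>Reverse`` prefix convention of reversed-sequence
    entries; contaminants are recognised by a configurable list of
    case-insensitive markers (default: "common contaminant").
    """
    lowered = protein_name.lower()
    if DECOY_MARKER in lowered or lowered.startswith("reverse "):
        return True
    return any(marker.lower() in lowered for marker in contaminant_markers)


def extract_scan(scan_text: Union[str, int, float]) -> int:
    """Extract the MS2 scan number from the scan column.

    Accepts a bare integer, ``"Scan 12345"``, and the dotted spectrum-title
    dialect ``"file.12345.12345.2"`` (start scan . end scan . charge), where
    the repeated scan field is taken.
    """
    if isinstance(scan_text, int):
        return scan_text
    if isinstance(scan_text, float) and scan_text == int(scan_text):
        return int(scan_text)
    s = str(scan_text).strip()
    if s.isdigit():
        return int(s)
    parts = s.split(".")
    if len(parts) >= 3 and parts[-2].isdigit() and parts[-3].isdigit():
        return int(parts[-2])
    numbers = re.findall(r"\d+", s)
    if numbers:
        return int(numbers[-1])
    raise ScanParseError(f"no scan number in {scan_text!r}")


_FLANKED_RE = re.compile(r"^([A-Z\-])\.(.+)\.([A-Z\-])$", re.DOTALL)
_DELTA_RE = re.compile(r"^[+\-−]?\d+(?:\.\d+)?$")


def parse_peptide(text: str, start: Optional[int] = None) -> ModifiedPeptide:
    """Parse an ``X.SEQ.Z`` modified peptide string.

    Bracketed delta masses (``[+1444.5339]``, ``[-17.0265]``) follow the
    residue they modify; positions are counted over unmodified residues
    only.  Flanking residues may be ``-`` at protein termini.
    """
    s = text.strip()
    m = _FLANKED_RE.match(s)
    if m:
        flank_n, body, flank_c = m.group(1), m.group(2), m.group(3)
    else:
        flank_n, body, flank_c = "-", s, "-"
    residues: list[str] = []
    mods: list[tuple[int, float]] = []
    i = 0
    while i < len(body):
        ch = body[i]
        if ch == "[":
            end = body.find("]", i)
            if end < 0:
                raise PeptideParseError(f"unbalanced bracket in {text!r}")
            raw = body[i + 1 : end].replace("−", "-")
            if not _DELTA_RE.match(raw):
                raise PeptideParseError(f"non-numeric delta mass {raw!r} in {text!r}")
            if not residues:
                raise PeptideParseError(f"modification before first residue in {text!r}")
            mods.append((len(residues), float(raw)))
            i = end + 1
        elif ch.upper() in AMINO_ACIDS:
            residues.append(ch.upper())
            i += 1
        else:
            raise PeptideParseError(f"unexpected character {ch!r} in {text!r}")
    if not residues:
        raise PeptideParseError(f"empty peptide in {text!r}")
    return ModifiedPeptide(
        sequence="".join(residues),
        mods=tuple(mods),
        flank_n=flank_n,
        flank_c=flank_c,
        start=start,
    )


@dataclass
class IdentRow:
    """One identification (PSM) row after parsing and filtering."""

    protein_name: str
    master_id: str
    peptide: ModifiedPeptide
    glycan_text: str
    glycans: list[GlycanComposition]
    score: float
    scan: int
    calc_mz: float
    source_file: str = ""
    mod_types: str = ""


@dataclass
class ReadStats:
    """Per-file audit of what the reader kept and dropped."""

    total: int = 0
    decoy_or_contaminant: int = 0
    inconsistent_glycan: int = 0
    unparsable: int = 0
    kept: int = 0


# header-driven column lookup; exports differ in punctuation across versions
COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "protein_name": ("protein name",),
    "scan": ("scan number", "scan #"),
    "peptide": ("peptide",),
    "glycans": ("glycans nhfagna", "glycans"),
    "mod_types": ("modification type(s)", "modification type"),
    "score": ("score",),
    "calc_mz": ("calc. m/z", "calc. mass (m/z)", "calc mz"),
    "start": ("starting position", "start position"),
}

REQUIRED_COLUMNS = ("protein_name", "scan", "peptide", "score", "calc_mz")


def resolve_columns(
    columns: Iterable[str],
    synonyms: dict[str, tuple[str, ...]],
    required: Sequence[str],
    filename: str = "",
) -> dict[str, str]:
    """Map logical field names to actual header names, case-insensitively."""
    lookup = {str(c).strip().lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for logical, names in synonyms.items():
        for name in names:
            if name in lookup:
                resolved[logical] = lookup[name]
                break
    missing = [r for r in required if r not in resolved]
    if missing:
        raise TableFormatError(
            f"{filename or 'input table'}: missing required column(s) {missing}; "
            f"found headers {sorted(lookup)}"
        )
    return resolved


def read_delimited(path: Union[str, Path]) -> pd.DataFrame:
    """Read a CSV or TSV export, sniffing the delimiter from the header."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def _mentions_glycan(mod_types: str) -> bool:
    return "glycan" in mod_types.lower()


def read_ident_file(
    path: Union[str, Path],
    source_file: str = "",
    contaminant_markers: Sequence[str] = DEFAULT_CONTAMINANT_MARKERS,
) -> tuple[list[IdentRow], ReadStats, dict[str, str]]:
    """Parse one identification export.

    Returns the kept rows, read statistics, and a ``master_id -> display
    protein name`` map (first-seen name per accession, so rows from
    different isoform entries of the same protein group under one id).
    Decoy/contaminant rows are removed before any grouping; malformed rows
    are logged and skipped, never fatal.
    """
    path = Path(path)
    df = read_delimited(path)
    cols = resolve_columns(df.columns, COLUMN_SYNONYMS, REQUIRED_COLUMNS, path.name)
    stats = ReadStats(total=len(df))
    rows: list[IdentRow] = []
    display_names: dict[str, str] = {}
    label = source_file or path.stem
    for idx in df.index:
        get = lambda logical, default="": (
            str(df.at[idx, cols[logical]]).strip() if logical in cols else default
        )
        protein_name = get("protein_name")
        if is_excluded(protein_name, contaminant_markers):
            stats.decoy_or_contaminant += 1
            continue
        glycan_text = get("glycans")
        mod_types = get("mod_types")
        if _mentions_glycan(mod_types) and not glycan_text:
            stats.inconsistent_glycan += 1
            logger.warning(
                "%s row %s: modification type indicates a glycan but the "
                "glycans column is blank; row skipped",
                path.name,
                idx,
            )
            continue
        try:
            start_text = get("start")
            start = int(float(start_text)) if start_text else None
            peptide = parse_peptide(get("peptide"), start=start)
            glycans = parse_glycan_field(glycan_text)
            scan = extract_scan(get("scan"))
            score = float(get("score") or 0.0)
            calc_mz = float(get("calc_mz"))
        except (PeptideParseError, ScanParseError, GlycanParseError, ValueError) as exc:
            stats.unparsable += 1
            logger.warning("%s row %s: %s; row skipped", path.name, idx, exc)
            continue
        master_id = extract_accession(protein_name)
        display_names.setdefault(master_id, protein_name)
        rows.append(
            IdentRow(
                protein_name=protein_name,
                master_id=master_id,
                peptide=peptide,
                glycan_text=glycan_text,
                glycans=glycans,
                score=score,
                scan=scan,
                calc_mz=calc_mz,
                source_file=label,
                mod_types=mod_types,
            )
        )
    stats.kept = len(rows)
    logger.info(
        "%s: %d rows read, %d decoy/contaminant removed, %d inconsistent, "
        "%d unparsable, %d kept",
        path.name,
        stats.total,
        stats.decoy_or_contaminant,
        stats.inconsistent_glycan,
        stats.unparsable,
        stats.kept,
    )
    return rows, stats, display_names
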