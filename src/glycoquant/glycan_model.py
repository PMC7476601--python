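"""Glycan compositions, theoretical masses, and glycosite assignment.

A glycan is represented here purely as a monosaccharide *composition* — a
multiset of residue classes (HexNAc, Hex, Fuc, NeuAc, ...) — because that is
all a composition-based glycopeptide search reports.  Topology (linkage,
branching) is out of scope.

The theoretical monoisotopic mass of a composition is the sum of the residue
masses (the mass each monosaccharide contributes once condensed into a
glycan, i.e. the free sugar minus one water).  That mass is what lets us map
a bracketed delta mass printed on a modified peptide string back to the
glycan that produced it, and therefore to the modified residue: the mod
whose delta mass matches the composition mass (within a small tolerance) is
the glycosylation site.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Iterator, Optional

__all__ = [
    "MONOSACCHARIDE_MASSES",
    "GlycanComposition",
    "ModifiedPeptide",
    "SiteAssignment",
    "GlycanParseError",
    "SiteAssignmentError",
    "UnassignableGlycanError",
    "AmbiguousSiteError",
    "parse_composition",
    "parse_glycan_field",
    "composition_mass",
    "assign_glycan_sites",
]

# Monoisotopic residue masses (Da): the mass added to a peptide per
# monosaccharide after loss of water on glycosidic bond formation.
# HexNAc = C8H13NO5, Hex = C6H10O5, Fuc (deoxyhexose) = C6H10O4,
# NeuAc = C11H17NO8, NeuGc = C11H17NO9, Pent = C5H8O4,
# Sulfo = SO3, Phospho = HPO3.
MONOSACCHARIDE_MASSES: dict[str, float] = {
    "HexNAc": 203.079372520,
    "Hex": 162.052823418,
    "Fuc": 146.057908799,
    "NeuAc": 291.095416506,
    "NeuGc": 307.090331126,
    "Pent": 132.042258735,
    "Sulfo": 79.956814859,
    "Phospho": 79.966330521,
}

# Canonical rendering order: the common N-/O-glycan constituents first, then
# the remaining names alphabetically, so equal compositions always render to
# the same string.
CANONICAL_ORDER: tuple[str, ...] = (
    "HexNAc",
    "Hex",
    "Fuc",
    "NeuAc",
    "NeuGc",
    "Pent",
    "Phospho",
    "Sulfo",
)

# Case-insensitive name lookup, including the dHex synonym for Fuc.
_NAME_LOOKUP: dict[str, str] = {name.lower(): name for name in MONOSACCHARIDE_MASSES}
_NAME_LOOKUP["dhex"] = "Fuc"

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_TOLERANCE_DA = 0.05


class GlycanParseError(ValueError):
    """A glycan composition string could not be parsed."""


class SiteAssignmentError(ValueError):
    """Base class for glycosite assignment failures."""


class UnassignableGlycanError(SiteAssignmentError):
    """No modification delta mass matched a glycan's theoretical mass."""


class AmbiguousSiteError(SiteAssignmentError):
    """Two modifications matched a glycan's mass equally well."""


def _canonical_name(token: str) -> str:
    try:
        return _NAME_LOOKUP[token.lower()]
    except KeyError:
        raise GlycanParseError(f"unknown monosaccharide name: {token!r}") from None


_TOKEN_RE = re.compile(r"([A-Za-z]+)\((-?\d+)\)")
_WELLFORMED_RE = re.compile(r"(?:[A-Za-z]+\(-?\d+\))+")


class GlycanComposition(Mapping):
    """Immutable monosaccharide → count multiset.

    The all-zero (empty) composition is valid and denotes an unglycosylated
    peptide; its mass is 0 and it renders to the empty string.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Optional[Mapping[str, int]] = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for name, count in source.items():
                canonical = _canonical_name(name)
                if int(count) != count:
                    raise GlycanParseError(f"non-integer count for {name}: {count!r}")
                count = int(count)
                if count < 0:
                    raise GlycanParseError(f"negative count for {name}: {count}")
                if count:
                    merged[canonical] = merged.get(canonical, 0) + count
        self._counts = {n: merged[n] for n in CANONICAL_ORDER if n in merged}
        self._hash = hash(tuple(self._counts.items()))

    @classmethod
    def empty(cls) -> "GlycanComposition":
        return cls()

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        """Parse one ``Name(count)`` token string, e.g. ``HexNAc(2)Hex(3)``.

        Blank text yields the empty (unglycosylated) composition.
        """
        s = re.sub(r"\s+", "", text or "")
        if not s:
            return cls()
        m = _WELLFORMED_RE.fullmatch(s)
        if m is None:
            # locate the first offending stretch for the error message
            consumed = 0
            probe = _WELLFORMED_RE.match(s)
            if probe:
                consumed = probe.end()
            raise GlycanParseError(
                f"malformed glycan composition near {s[consumed:consumed + 20]!r}"
            )
        counts: dict[str, int] = {}
        for name, num in _TOKEN_RE.findall(s):
            canonical = _canonical_name(name)
            counts[canonical] = counts.get(canonical, 0) + int(num)
        return cls(counts)

    # -- Mapping interface ------------------------------------------------
    def __getitem__(self, name: str) -> int:
        return self._counts.get(_canonical_name(name), 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, name: object) -> bool:
        try:
            return self[str(name)] > 0
        except GlycanParseError:
            return False

    # -- identity ---------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanComposition):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return self._hash

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        if not isinstance(other, GlycanComposition):
            return NotImplemented
        merged = dict(self._counts)
        for name, count in other._counts.items():
            merged[name] = merged.get(name, 0) + count
        return GlycanComposition(merged)

    # -- derived quantities -------------------------------------------------
    @property
    def mass(self) -> float:
        """Theoretical monoisotopic mass in Da (0.0 for the empty composition)."""
        return sum(MONOSACCHARIDE_MASSES[n] * c for n, c in self._counts.items())

    @property
    def is_empty(self) -> bool:
        return not self._counts

    @property
    def sort_key(self) -> tuple[int, ...]:
        """Counts in canonical order; sorts the empty composition first."""
        return tuple(self._counts.get(n, 0) for n in CANONICAL_ORDER)

    @property
    def label(self) -> str:
        """Human-readable label for tables ("Unglycosylated" for the empty one)."""
        return str(self) if self._counts else "Unglycosylated"

    def __str__(self) -> str:
        return "".join(f"{n}({c})" for n, c in self._counts.items())

    def __repr__(self) -> str:
        return f"GlycanComposition({str(self)!r})"


def parse_composition(text: str) -> GlycanComposition:
    """Parse a single glycan composition string (blank → unglycosylated)."""
    return GlycanComposition.parse(text)


def parse_glycan_field(text: str) -> list[GlycanComposition]:
    """Parse a glycans column cell, which may list several glycans.

    Multiple glycans on one row are separated by commas or semicolons.
    Blank cells yield an empty list (no glycan on the peptide).
    """
    if text is None:
        return []
    parts = [p.strip() for p in re.split(r"[,;]", str(text)) if p.strip()]
    return [GlycanComposition.parse(p) for p in parts]


def composition_mass(composition: GlycanComposition) -> float:
    """Theoretical monoisotopic mass of a composition in Da."""
    return composition.mass


# ---------------------------------------------------------------------------
# Modified peptides and site assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with flanking residues and positioned delta-mass mods.

    ``mods`` holds ``(position, delta_mass)`` pairs; positions are 1-based
    over the unmodified residues.  ``start`` is the 1-based protein
    coordinate of the first residue, when the search engine reported one.
    Delta masses keep their printed sign (deamidation +0.9840, pyro-Glu
    -17.0265).
    """

    sequence: str
    mods: tuple[tuple[int, float], ...] = ()
    flank_n: str = "-"
    flank_c: str = "-"
    start: Optional[int] = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-amino-acid residues in sequence: {sorted(bad)}")
        for pos, _ in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"mod position {pos} outside peptide of length {len(self.sequence)}"
                )

    def render(self) -> str:
        """Render back to the ``X.SEQ[+delta].Z`` export convention."""
        by_pos: dict[int, list[float]] = {}
        for pos, delta in self.mods:
            by_pos.setdefault(pos, []).append(delta)
        parts = []
        for i, residue in enumerate(self.sequence, start=1):
            parts.append(residue)
            for delta in by_pos.get(i, ()):
                parts.append(f"[{delta:+.4f}]")
        return f"{self.flank_n}.{''.join(parts)}.{self.flank_c}"


@dataclass(frozen=True)
class SiteAssignment:
    """One glycan placed on one residue of a peptide."""

    composition: GlycanComposition
    peptide_position: int
    protein_position: Optional[int] = None
    residue: str = ""


def assign_glycan_sites(
    peptide: ModifiedPeptide,
    glycans: list[GlycanComposition],
    tol: float = DEFAULT_TOLERANCE_DA,
) -> list[SiteAssignment]:
    """Place each glycan on the modified residue whose delta mass matches.

    For every glycan the candidate mods are those whose delta mass lies
    within ``tol`` Da of the composition's theoretical mass; the closest
    match wins and is consumed, so two identical glycans land on two
    different residues.  Mods that match no glycan (oxidation, deamidation,
    carbamidomethyl, pyro-Glu, ...) are simply left alone.

    Raises :class:`UnassignableGlycanError` when a glycan matches no mod and
    :class:`AmbiguousSiteError` when two mods match one glycan equally well.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    assignments: list[SiteAssignment] = []
    available = list(peptide.mods)
    for comp in glycans:
        if comp.is_empty:
            continue
        target = comp.mass
        candidates = sorted(
            (abs(delta - target), pos, idx)
            for idx, (pos, delta) in enumerate(available)
            if abs(delta - target) <= tol
        )
        if not candidates:
            raise UnassignableGlycanError(
                f"no modification within {tol} Da of {comp} "
                f"(mass {target:.4f}) on peptide {peptide.sequence}"
            )
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            raise AmbiguousSiteError(
                f"two modifications match {comp} equally well "
                f"(delta distance {candidates[0][0]:.4f} Da) on peptide "
                f"{peptide.sequence}"
            )
        _, pos, idx = candidates[0]
        available.pop(idx)
        protein_pos = peptide.start + pos - 1 if peptide.start is not None else None
        assignments.append(
            SiteAssignment(
                composition=comp,
                peptide_position=pos,
                protein_position=protein_pos,
                residue=peptide.sequence[pos - 1],
            )
        )
    return assignments
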