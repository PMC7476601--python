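"""Join, filter, deduplicate, and aggregate glycopeptide quantities.

The flow mirrors how a label-free DDA glycoproteomics quantification works:

1. each identification row is joined to the MS1 precursor area of its scan;
   rows without an area or below the score cutoff are removed;
2. redundant PSMs (the same precursor fragmented repeatedly) are collapsed
   to one *unique PSM* per (unmodified sequence, glycan composition,
   calculated m/z, and — in site mode — glycosylation site), keeping the
   highest-area one;
3. unique-PSM areas are summed per glycoform anchor (a protein site, or a
   proteolytic peptide form) to give each glycoform's total AUC per sample;
4. per anchor and sample the glycoform proportions are computed with and
   without the unglycosylated peptidoform, and site occupancy as the
   glycosylated fraction of the total signal.

Site mode merges all peptide variants (missed cleavages, charge states,
non-glycan modifications) covering one assigned residue; peptide mode keeps
each proteolytic peptide form separate and ignores within-peptide site
assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .byonic_reader import IdentRow
from .glycan_model import (
    DEFAULT_TOLERANCE_DA,
    GlycanComposition,
    SiteAssignment,
    SiteAssignmentError,
    assign_glycan_sites,
)

__all__ = [
    "PSMRecord",
    "SiteAnchor",
    "PeptideAnchor",
    "GlycoformKey",
    "FilterStats",
    "DEFAULT_SCORE_CUTOFF",
    "join_and_filter",
    "annotate_sites",
    "select_unique_psms",
    "aggregate_auc",
    "compute_proportions",
    "build_wide_table",
    "build_occupancy_table",
]

logger = logging.getLogger(__name__)

DEFAULT_SCORE_CUTOFF = 200.0

MULTI_GLYCAN = "multi_glycan"
UNASSIGNABLE = "unassignable_glycan"
NO_PROTEIN_SITE = "no_protein_site"


@dataclass
class PSMRecord:
    """One identification joined to its precursor area."""

    ident: IdentRow
    area: float
    sample: str
    assignments: tuple[SiteAssignment, ...] = ()
    flags: frozenset[str] = frozenset()

    @property
    def composition(self) -> GlycanComposition:
        """Combined glycan composition of the row (empty = unglycosylated)."""
        total = GlycanComposition.empty()
        for g in self.ident.glycans:
            total = total + g
        return total

    @property
    def sequence(self) -> str:
        return self.ident.peptide.sequence


@dataclass(frozen=True, order=True)
class SiteAnchor:
    """A glycosylation site in protein coordinates (1-based)."""

    master_id: str
    position: int
    residue: str = ""

    def describe(self) -> str:
        return f"{self.residue}{self.position}"


@dataclass(frozen=True, order=True)
class PeptideAnchor:
    """A proteolytic peptide form (unmodified sequence + start coordinate)."""

    master_id: str
    sequence: str
    start: int = -1  # -1 when the export reported no starting position

    def describe(self) -> str:
        return f"{self.sequence}@{self.start}" if self.start > 0 else self.sequence


Anchor = Union[SiteAnchor, PeptideAnchor]


@dataclass(frozen=True, order=True)
class GlycoformKey:
    """Identity of one quantified row: protein, anchor, glycan composition."""

    master_id: str
    anchor: Anchor
    composition_key: tuple[int, ...]
    composition_str: str

    @classmethod
    def make(cls, anchor: Anchor, composition: GlycanComposition) -> "GlycoformKey":
        return cls(
            master_id=anchor.master_id,
            anchor=anchor,
            composition_key=composition.sort_key,
            composition_str=str(composition),
        )

    @property
    def composition_label(self) -> str:
        return self.composition_str or "Unglycosylated"


@dataclass
class FilterStats:
    """Row counts through the join/filter/dedup stages."""

    input_rows: int = 0
    removed_no_area: int = 0
    removed_low_score: int = 0
    kept: int = 0
    flagged_multi_glycan: int = 0
    flagged_unassignable: int = 0
    excluded_site_mode: int = 0
    unique_psms: int = 0


def join_and_filter(
    ident_rows: Sequence[IdentRow],
    area_map: Mapping[int, float],
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
    sample: str = "",
) -> tuple[list[PSMRecord], FilterStats]:
    """Attach precursor areas by scan number and apply the score cutoff.

    Rows whose scan has no area in the map are removed (no imputation), as
    are rows scoring below ``score_cutoff``.  Removal counts are returned
    for the audit trail.
    """
    stats = FilterStats(input_rows=len(ident_rows))
    records: list[PSMRecord] = []
    for row in ident_rows:
        area = area_map.get(row.scan)
        if area is None or not area > 0:
            stats.removed_no_area += 1
            continue
        if row.score < score_cutoff:
            stats.removed_low_score += 1
            continue
        records.append(PSMRecord(ident=row, area=area, sample=sample or row.source_file))
    stats.kept = len(records)
    logger.info(
        "sample %s: %d rows in, %d without area, %d below score %.6g, %d kept",
        sample,
        stats.input_rows,
        stats.removed_no_area,
        stats.removed_low_score,
        score_cutoff,
        stats.kept,
    )
    return records, stats


def annotate_sites(
    records: Iterable[PSMRecord],
    tol: float = DEFAULT_TOLERANCE_DA,
    stats: Optional[FilterStats] = None,
) -> list[PSMRecord]:
    """Assign glycans to residues on every record, flagging failures.

    Rows listing more than one glycan are flagged ``multi_glycan`` (the
    one-glycan-per-peptide search setting is the supported path); rows whose
    glycan mass matches no modification delta are flagged
    ``unassignable_glycan``.  Flagged rows stay in the list — peptide-mode
    quantification can still use them — but site mode excludes them.
    """
    annotated: list[PSMRecord] = []
    for rec in records:
        flags: set[str] = set()
        assignments: tuple[SiteAssignment, ...] = ()
        glycans = rec.ident.glycans
        if len(glycans) > 1:
            flags.add(MULTI_GLYCAN)
            logger.warning(
                "scan %d (%s): %d glycans on one peptide; excluded from "
                "site-specific quantification",
                rec.ident.scan,
                rec.sample,
                len(glycans),
            )
        if glycans:
            try:
                assignments = tuple(assign_glycan_sites(rec.ident.peptide, glycans, tol))
            except SiteAssignmentError as exc:
                flags.add(UNASSIGNABLE)
                logger.warning(
                    "scan %d (%s): %s; excluded from site-specific quantification",
                    rec.ident.scan,
                    rec.sample,
                    exc,
                )
            else:
                if any(a.protein_position is None for a in assignments):
                    flags.add(NO_PROTEIN_SITE)
        rec.assignments = assignments
        rec.flags = frozenset(flags)
        annotated.append(rec)
        if stats is not None:
            if MULTI_GLYCAN in flags:
                stats.flagged_multi_glycan += 1
            if UNASSIGNABLE in flags:
                stats.flagged_unassignable += 1
    return annotated


def _site_tuple(rec: PSMRecord) -> tuple[int, ...]:
    return tuple(sorted(a.protein_position for a in rec.assignments))


def _dedup_key(rec: PSMRecord, mode: str):
    base = (
        rec.sample,
        rec.ident.master_id,
        rec.sequence,
        rec.composition.sort_key,
        round(rec.ident.calc_mz, 4),
    )
    if mode == "site":
        return base + (_site_tuple(rec),)
    return base


def _usable_in_site_mode(rec: PSMRecord) -> bool:
    if rec.flags & {MULTI_GLYCAN, UNASSIGNABLE, NO_PROTEIN_SITE}:
        return False
    if not rec.ident.glycans and rec.ident.peptide.start is None:
        return False  # unglycosylated peptide with no coordinates: no anchor
    return True


def select_unique_psms(
    records: Sequence[PSMRecord],
    mode: str = "site",
    stats: Optional[FilterStats] = None,
) -> list[PSMRecord]:
    """Collapse redundant PSMs to one unique PSM per precursor group.

    Groups share (sample, protein, unmodified sequence, glycan composition,
    calculated m/z) — plus the assigned site in site mode, so differently
    placed but otherwise identical glycans stay apart.  Within a group the
    highest-area PSM wins; ties fall back to higher score, then lower scan
    number, making the choice independent of input order.
    """
    if mode not in ("site", "peptide"):
        raise ValueError(f"unknown mode {mode!r}")
    best: dict[tuple, PSMRecord] = {}
    excluded = 0
    for rec in records:
        if mode == "site" and not _usable_in_site_mode(rec):
            excluded += 1
            continue
        key = _dedup_key(rec, mode)
        incumbent = best.get(key)
        if incumbent is None or (
            (rec.area, rec.ident.score, -rec.ident.scan)
            > (incumbent.area, incumbent.ident.score, -incumbent.ident.scan)
        ):
            best[key] = rec
    unique = sorted(
        best.values(), key=lambda r: (r.sample, r.ident.master_id, r.ident.scan)
    )
    if stats is not None:
        stats.excluded_site_mode += excluded
        stats.unique_psms = len(unique)
    if excluded:
        logger.info("%d flagged/unanchorable records excluded in site mode", excluded)
    return unique


def _peptide_anchor(rec: PSMRecord) -> PeptideAnchor:
    start = rec.ident.peptide.start
    return PeptideAnchor(
        master_id=rec.ident.master_id,
        sequence=rec.sequence,
        start=start if start is not None else -1,
    )


def aggregate_auc(
    unique_records: Sequence[PSMRecord],
    mode: str = "site",
) -> dict[tuple[GlycoformKey, str], float]:
    """Sum unique-PSM areas into total AUC per glycoform anchor and sample.

    In site mode every glycosylated record contributes its area to the
    anchor of its assigned residue, merging charge states, missed-cleavage
    forms, and non-glycan modification variants.  An unglycosylated peptide
    contributes (under the empty composition) to every known glycosite it
    spans — a site counts as known when it was observed glycosylated
    anywhere in the experiment.  In peptide mode the anchor is the
    proteolytic peptide form itself.
    """
    if mode not in ("site", "peptide"):
        raise ValueError(f"unknown mode {mode!r}")
    auc: dict[tuple[GlycoformKey, str], float] = {}

    def add(key: GlycoformKey, sample: str, area: float) -> None:
        auc[(key, sample)] = auc.get((key, sample), 0.0) + area

    ordered = sorted(
        unique_records, key=lambda r: (r.sample, r.ident.master_id, r.ident.scan)
    )
    if mode == "peptide":
        for rec in ordered:
            key = GlycoformKey.make(_peptide_anchor(rec), rec.composition)
            add(key, rec.sample, rec.area)
        return auc

    # site mode: collect the glycosite census first (across all samples)
    known_sites: dict[str, dict[int, str]] = {}
    for rec in ordered:
        for a in rec.assignments:
            known_sites.setdefault(rec.ident.master_id, {})[a.protein_position] = (
                a.residue
            )
    for rec in ordered:
        if rec.ident.glycans:
            for a in rec.assignments:
                anchor = SiteAnchor(
                    master_id=rec.ident.master_id,
                    position=a.protein_position,
                    residue=a.residue,
                )
                add(GlycoformKey.make(anchor, a.composition), rec.sample, rec.area)
        else:
            start = rec.ident.peptide.start
            if start is None:
                continue
            span = range(start, start + len(rec.sequence))
            for pos, residue in known_sites.get(rec.ident.master_id, {}).items():
                if pos in span:
                    anchor = SiteAnchor(
                        master_id=rec.ident.master_id, position=pos, residue=residue
                    )
                    add(
                        GlycoformKey.make(anchor, GlycanComposition.empty()),
                        rec.sample,
                        rec.area,
                    )
    return auc


def compute_proportions(
    auc_map: Mapping[tuple[GlycoformKey, str], float],
) -> pd.DataFrame:
    """Glycoform proportions per anchor and sample, with occupancy.

    For each (sample, protein, anchor) the proportion of every glycoform is
    computed twice: over all signal including the unglycosylated form
    (``proportion_with_unglyc``) and over glycosylated signal only
    (``proportion_without_unglyc``, undefined for the unglycosylated row).
    Occupancy is the glycosylated fraction of the total — equivalently one
    minus the unglycosylated form's with-proportion.  Glycosylation status
    is assumed not to bias detection efficiency.  Anchors absent from a
    sample simply have no rows there; nothing is imputed.
    """
    groups: dict[tuple[Anchor, str], list[tuple[GlycoformKey, float]]] = {}
    for (key, sample), area in auc_map.items():
        groups.setdefault((key.anchor, sample), []).append((key, area))
    rows = []
    for (anchor, sample), members in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        members.sort(key=lambda ka: ka[0].composition_key)
        total_all = sum(area for _, area in members)
        total_glyc = sum(area for key, area in members if any(key.composition_key))
        occupancy = total_glyc / total_all if total_all > 0 else float("nan")
        for key, area in members:
            glycosylated = any(key.composition_key)
            rows.append(
                {
                    "master_id": key.master_id,
                    "anchor": anchor,
                    "anchor_label": anchor.describe(),
                    "composition": key.composition_label,
                    "sample": sample,
                    "auc": area,
                    "proportion_with_unglyc": area / total_all if total_all > 0 else float("nan"),
                    "proportion_without_unglyc": (
                        area / total_glyc if glycosylated and total_glyc > 0 else float("nan")
                    ),
                    "occupancy": occupancy,
                    "_key": key,
                }
            )
    columns = [
        "master_id",
        "anchor",
        "anchor_label",
        "composition",
        "sample",
        "auc",
        "proportion_with_unglyc",
        "proportion_without_unglyc",
        "occupancy",
        "_key",
    ]
    return pd.DataFrame(rows, columns=columns)


def _annotation_frame(
    keys: Sequence[GlycoformKey], protein_names: Optional[Mapping[str, str]]
) -> pd.DataFrame:
    names = protein_names or {}
    return pd.DataFrame(
        {
            "master_id": [k.master_id for k in keys],
            "protein_name": [names.get(k.master_id, "") for k in keys],
            "anchor": [k.anchor.describe() for k in keys],
            "composition": [k.composition_label for k in keys],
        }
    )


def build_wide_table(
    long_df: pd.DataFrame,
    samples: Sequence[str],
    protein_names: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Pivot the long proportions table to one row per glycoform.

    Columns come in three blocks — AUC, proportion with, and proportion
    without the unglycosylated form — one column per sample within each
    block, preceded by the annotation columns.  Keys missing from a sample
    stay blank (NaN), distinguishing "not observed" from a true zero.  Row
    order is deterministic: protein, anchor, then composition.
    """
    if long_df.empty:
        cols = ["master_id", "protein_name", "anchor", "composition"]
        for block in ("auc", "proportion_with_unglyc", "proportion_without_unglyc"):
            cols += [f"{block}_{s}" for s in samples]
        return pd.DataFrame(columns=cols)
    keys = sorted(
        long_df["_key"].unique(),
        key=lambda k: (k.master_id, k.anchor, k.composition_key),
    )
    index = {k: i for i, k in enumerate(keys)}
    out = _annotation_frame(keys, protein_names)
    for block in ("auc", "proportion_with_unglyc", "proportion_without_unglyc"):
        for sample in samples:
            col = pd.Series([float("nan")] * len(keys), name=f"{block}_{sample}")
            sub = long_df[long_df["sample"] == sample]
            for key, value in zip(sub["_key"], sub[block]):
                col.iat[index[key]] = value
            out[f"{block}_{sample}"] = col
    return out


def build_occupancy_table(
    long_df: pd.DataFrame,
    samples: Sequence[str],
    protein_names: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """One row per anchor, one occupancy column per sample."""
    cols = ["master_id", "protein_name", "anchor"] + [
        f"occupancy_{s}" for s in samples
    ]
    if long_df.empty:
        return pd.DataFrame(columns=cols)
    names = protein_names or {}
    anchors = sorted({k.anchor for k in long_df["_key"]})
    index = {a: i for i, a in enumerate(anchors)}
    out = pd.DataFrame(
        {
            "master_id": [a.master_id for a in anchors],
            "protein_name": [names.get(a.master_id, "") for a in anchors],
            "anchor": [a.describe() for a in anchors],
        }
    )
    for sample in samples:
        col = pd.Series([float("nan")] * len(anchors), name=f"occupancy_{sample}")
        sub = long_df[long_df["sample"] == sample]
        for anchor, occ in zip(sub["anchor"], sub["occupancy"]):
            col.iat[index[anchor]] = occ
        out[f"occupancy_{sample}"] = col
    return out
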