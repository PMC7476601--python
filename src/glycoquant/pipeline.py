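"""End-to-end orchestration: sample map in, quantification tables out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import byonic_reader, pd_reader, quantify
from .quantify import DEFAULT_SCORE_CUTOFF, FilterStats
from .glycan_model import DEFAULT_TOLERANCE_DA

__all__ = [
    "ConfigError",
    "SamplePair",
    "PipelineResult",
    "load_sample_map",
    "load_protein_names",
    "load_groups",
    "run_pipeline",
    "write_outputs",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"  # fixed output precision for reproducible diffs


class ConfigError(ValueError):
    """A configuration problem that prevents the run from starting."""


@dataclass
class SamplePair:
    """One sample: an identification export paired with an area export."""

    ident: Path
    area: Path
    label: str
    group: str = ""


@dataclass
class PipelineResult:
    """All quantification tables from one pipeline run."""

    mode: str
    samples: list[str]
    long: pd.DataFrame  # tidy per-(key, sample) rows incl. proportions
    wide: pd.DataFrame  # one row per glycoform, sample blocks as columns
    occupancy: pd.DataFrame  # one row per anchor, occupancy per sample
    stats: dict[str, FilterStats] = field(default_factory=dict)
    read_stats: dict[str, byonic_reader.ReadStats] = field(default_factory=dict)
    display_names: dict[str, str] = field(default_factory=dict)


def load_sample_map(path: Union[str, Path]) -> list[SamplePair]:
    """Read a sample map CSV with columns ident, area, sample[, group].

    File paths are resolved relative to the map's own directory.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"sample map not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("ident", "area", "sample"):
        if required not in cols:
            raise ConfigError(
                f"{path.name}: sample map needs columns ident, area, sample "
                f"(optional group); found {sorted(cols)}"
            )
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            SamplePair(
                ident=(path.parent / str(row[cols["ident"]]).strip()),
                area=(path.parent / str(row[cols["area"]]).strip()),
                label=str(row[cols["sample"]]).strip(),
                group=str(row[cols["group"]]).strip() if "group" in cols else "",
            )
        )
    validate_pairs(pairs)
    return pairs


def validate_pairs(pairs: Sequence[SamplePair]) -> None:
    if not pairs:
        raise ConfigError("sample map is empty")
    labels = [p.label for p in pairs]
    duplicates = {l for l in labels if labels.count(l) > 1}
    if duplicates:
        raise ConfigError(f"duplicate sample labels: {sorted(duplicates)}")
    missing = [str(f) for p in pairs for f in (p.ident, p.area) if not Path(f).exists()]
    if missing:
        raise ConfigError(f"input file(s) not found: {missing}")


def load_protein_names(path: Union[str, Path]) -> dict[str, str]:
    """Offline accession → protein name map (CSV/TSV, two columns)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ConfigError(f"{path}: name map needs two columns (accession, name)")
    acc_col, name_col = df.columns[:2]
    return {str(a).strip(): str(n).strip() for a, n in zip(df[acc_col], df[name_col])}


def load_groups(path: Union[str, Path]) -> dict[str, str]:
    """Sample → group map from a CSV/TSV with 'sample' and 'group' columns."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    if "sample" not in cols or "group" not in cols:
        raise ConfigError(f"{path}: groups file needs 'sample' and 'group' columns")
    return {
        str(row[cols["sample"]]).strip(): str(row[cols["group"]]).strip()
        for _, row in df.iterrows()
        if str(row[cols["group"]]).strip()
    }


def run_pipeline(
    pairs: Sequence[SamplePair],
    mode: str = "site",
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
    tolerance: float = DEFAULT_TOLERANCE_DA,
    protein_names: Optional[Mapping[str, str]] = None,
) -> PipelineResult:
    """Run the full quantification over all samples.

    Per sample: read and filter identifications, index areas, join, assign
    glycosites; then pool everything, select unique PSMs, aggregate AUC per
    glycoform anchor, and compute proportions/occupancy.  Bad rows are
    logged and skipped; only configuration problems raise.
    """
    if mode not in ("site", "peptide"):
        raise ConfigError(f"unknown mode {mode!r} (use 'site' or 'peptide')")
    validate_pairs(pairs)
    all_records = []
    stats: dict[str, FilterStats] = {}
    read_stats: dict[str, byonic_reader.ReadStats] = {}
    display_names: dict[str, str] = {}
    for pair in pairs:
        rows, rstats, names = byonic_reader.read_ident_file(pair.ident, pair.label)
        for acc, name in names.items():
            display_names.setdefault(acc, name)
        area_map = pd_reader.parse_area_table(pair.area)
        records, fstats = quantify.join_and_filter(
            rows, area_map, score_cutoff=score_cutoff, sample=pair.label
        )
        quantify.annotate_sites(records, tol=tolerance, stats=fstats)
        all_records.extend(records)
        stats[pair.label] = fstats
        read_stats[pair.label] = rstats
    samples = [p.label for p in pairs]
    unique = quantify.select_unique_psms(all_records, mode=mode)
    auc = quantify.aggregate_auc(unique, mode=mode)
    long = quantify.compute_proportions(auc)
    # first-seen export names as fallback; the offline map wins where present
    merged_names = {**display_names, **dict(protein_names or {})}
    wide = quantify.build_wide_table(long, samples, merged_names)
    occupancy = quantify.build_occupancy_table(long, samples, merged_names)
    return PipelineResult(
        mode=mode,
        samples=samples,
        long=long,
        wide=wide,
        occupancy=occupancy,
        stats=stats,
        read_stats=read_stats,
        display_names=merged_names,
    )


def write_outputs(result: PipelineResult, outdir: Union[str, Path]) -> dict[str, Path]:
    """Write the AUC, proportion, and occupancy CSVs for one run.

    Output is deterministic: fixed row order, fixed six-significant-digit
    float formatting, and blank cells for keys unobserved in a sample.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mode = result.mode
    annotation = ["master_id", "protein_name", "anchor", "composition"]
    auc_cols = annotation + [f"auc_{s}" for s in result.samples]
    prop_cols = annotation + [
        f"proportion_with_unglyc_{s}" for s in result.samples
    ] + [f"proportion_without_unglyc_{s}" for s in result.samples]
    paths = {
        "auc": outdir / f"auc_{mode}.csv",
        "proportions": outdir / f"proportions_{mode}.csv",
        "occupancy": outdir / f"occupancy_{mode}.csv",
    }
    result.wide[auc_cols].to_csv(paths["auc"], index=False, float_format=FLOAT_FORMAT)
    result.wide[prop_cols].to_csv(
        paths["proportions"], index=False, float_format=FLOAT_FORMAT
    )
    result.occupancy.to_csv(paths["occupancy"], index=False, float_format=FLOAT_FORMAT)
    for name, p in paths.items():
        logger.info("wrote %s table: %s", name, p)
    return paths
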