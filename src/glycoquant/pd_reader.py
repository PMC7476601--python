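"""Reader for precursor-area exports (Proteome-Discoverer-style).

The export links each identified MS2 scan ("First Scan") to the MS1
chromatographic peak area of its precursor — the label-free abundance proxy
used downstream.  Only the scan → area mapping is needed here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import pandas as pd

from .byonic_reader import extract_scan, resolve_columns

__all__ = ["parse_area_table"]

logger = logging.getLogger(__name__)

AREA_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "first_scan": ("first scan", "firstscan"),
    "area": ("area", "precursor area"),
}


def parse_area_table(path: Union[str, Path]) -> dict[int, float]:
    """Parse an area export into a ``first scan -> area`` map.

    Blank, non-numeric, and zero areas are treated as absent (the
    integrator writes 0 when it fails); rows without an area simply do not
    enter the map, so the identifications they would back are dropped at
    the join.  When several rows report the same scan the maximum area is
    kept — the same preference the unique-PSM selection applies — to avoid
    double counting one precursor.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = resolve_columns(
        df.columns, AREA_COLUMN_SYNONYMS, ("first_scan", "area"), path.name
    )
    areas: dict[int, float] = {}
    skipped = 0
    for idx in df.index:
        area_text = str(df.at[idx, cols["area"]]).strip()
        try:
            area = float(area_text)
        except ValueError:
            area = float("nan")
        if not area > 0:  # catches NaN, 0 and negatives
            skipped += 1
            continue
        scan = extract_scan(df.at[idx, cols["first_scan"]])
        if scan not in areas or area > areas[scan]:
            areas[scan] = area
    logger.info(
        "%s: %d rows, %d without a usable area, %d scans mapped",
        path.name,
        len(df),
        skipped,
        len(areas),
    )
    return areas
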