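"""Region labelling, exclusion rules, and descriptive summaries.

A region is labelled by its dominant religion and dominant anthrome:

* religion — Christian (Muslim) when that faith exceeds 75% of the sum of
  Christian + Muslim believers; Mixed otherwise.  Regions where
  Christian + Muslim believers are under 50% of the total population are
  excluded (no shared weekly day of rest), as are regions with missing
  religion data.
* anthrome — the single aggregated class covering at least 50% of the
  region's area, else Mixed.

Regions with cumulative fire density below 0.1 counts·km⁻² over the study
period are removed before the religion-based exclusions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .region_data import ANTHROME_CLASSES, FireCountPanel, RegionRecord

logger = logging.getLogger(__name__)

#: Minimum cumulative fire density (counts per km² over the whole study
#: period) for a region to enter the analysis.
DENSITY_THRESHOLD = 0.1

#: Dominance threshold on the Christian share of Christian+Muslim believers.
RELIGION_DOMINANCE = 0.75

#: Minimum Christian+Muslim share of the total population.
ABRAHAMIC_MINIMUM = 0.5

#: Dominance threshold on anthrome area fraction ("at least 50%", inclusive).
ANTHROME_DOMINANCE = 0.5

#: Deterministic preference order for the measure-zero 0.5/0.5 anthrome tie.
_ANTHROME_TIE_ORDER = ("Cropland", "Natural", "Rangeland", "Settled")


class ReligionLabel(str, Enum):
    CHRISTIAN = "Christian"
    MUSLIM = "Muslim"
    MIXED = "Mixed"
    EXCLUDED = "Excluded"
    MISSING_DATA = "MissingData"


class AnthromeLabel(str, Enum):
    CROPLAND = "Cropland"
    NATURAL = "Natural"
    RANGELAND = "Rangeland"
    SETTLED = "Settled"
    MIXED = "Mixed"


def classify_religion(frac_christian: float, frac_muslim: float) -> ReligionLabel:
    """Label a region by dominant religion from population shares.

    The dominance rule is scale-invariant (it uses the Christian share of
    Christian+Muslim believers); only the 50%-of-total-population exclusion
    depends on the absolute level.
    """
    if np.isnan(frac_christian) or np.isnan(frac_muslim):
        return ReligionLabel.MISSING_DATA
    if frac_christian < 0 or frac_muslim < 0:
        raise ValueError(f"negative religion fraction ({frac_christian}, {frac_muslim})")
    total = frac_christian + frac_muslim
    if total < ABRAHAMIC_MINIMUM:
        return ReligionLabel.EXCLUDED
    share_christian = frac_christian / total
    if share_christian > RELIGION_DOMINANCE:
        return ReligionLabel.CHRISTIAN
    if 1.0 - share_christian > RELIGION_DOMINANCE:
        return ReligionLabel.MUSLIM
    return ReligionLabel.MIXED


def classify_anthrome(fracs: dict[str, float]) -> AnthromeLabel:
    """Label a region by the anthrome class covering >= 50% of its area."""
    vals = {cls: float(fracs.get(cls, 0.0)) for cls in ANTHROME_CLASSES}
    if any(v < 0 for v in vals.values()):
        raise ValueError(f"negative anthrome fraction in {fracs}")
    total = sum(vals.values())
    if abs(total - 1.0) > 1e-3:
        raise ValueError(f"anthrome fractions sum to {total:.4f}, expected 1")
    dominant = [cls for cls in _ANTHROME_TIE_ORDER if vals[cls] >= ANTHROME_DOMINANCE]
    if not dominant:
        return AnthromeLabel.MIXED
    if len(dominant) > 1:  # only possible at exactly 0.5/0.5
        logger.warning(
            "anthrome tie between %s; using preference order %s",
            dominant,
            " > ".join(_ANTHROME_TIE_ORDER),
        )
    return AnthromeLabel(dominant[0])


def label_regions(records: list[RegionRecord]) -> pd.DataFrame:
    """Religion and anthrome labels for every region, as a data frame."""
    rows = [
        (
            r.region_id,
            classify_religion(r.frac_christian, r.frac_muslim).value,
            classify_anthrome(r.anthrome_fracs).value,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=["region_id", "religion_label", "anthrome_label"])


@dataclass
class ExclusionReport:
    """Outcome of the three exclusion rules, applied in order."""

    retained: list[RegionRecord]
    excluded: pd.DataFrame  # columns: region_id, rule
    counts: dict[str, int]  # rule -> number of regions removed

    RULES = ("low_fire_density", "religion_share_below_50pct", "missing_religion_data")


def apply_exclusions(records: list[RegionRecord], panel: FireCountPanel) -> ExclusionReport:
    """Apply the three exclusion rules in their documented order.

    Order: (1) cumulative fire density below :data:`DENSITY_THRESHOLD`;
    (2) Christian+Muslim share of total population below 50%; (3) missing
    religion data.  A region is attributed to the first rule it fails.
    """
    retained: list[RegionRecord] = []
    excluded_rows: list[tuple[str, str]] = []
    counts = {rule: 0 for rule in ExclusionReport.RULES}
    for rec in records:
        density = panel.total_count(rec.region_id) / rec.area_km2
        if density < DENSITY_THRESHOLD:
            rule = "low_fire_density"
        else:
            label = classify_religion(rec.frac_christian, rec.frac_muslim)
            if label is ReligionLabel.EXCLUDED:
                rule = "religion_share_below_50pct"
            elif label is ReligionLabel.MISSING_DATA:
                rule = "missing_religion_data"
            else:
                retained.append(rec)
                continue
        counts[rule] += 1
        excluded_rows.append((rec.region_id, rule))
    report = ExclusionReport(
        retained=retained,
        excluded=pd.DataFrame(excluded_rows, columns=["region_id", "rule"]),
        counts=counts,
    )
    logger.info(
        "exclusions: %s; retained %d of %d regions", counts, len(retained), len(records)
    )
    return report


def weekday_minimum(panel: FireCountPanel, region_id: str) -> tuple[int, bool]:
    """Weekday (1..7) with the fewest counts summed across years.

    Ties resolve to the smallest weekday index with the tie flag set.
    """
    totals = panel.weekday_totals(region_id)
    idx = int(np.argmin(totals))
    tie = int((totals == totals[idx]).sum()) > 1
    return idx + 1, tie


def weekday_minima(panel: FireCountPanel) -> pd.DataFrame:
    """Per-region weekday minimum table (pipeline output)."""
    rows = []
    for rid in panel.region_ids:
        w, tie = weekday_minimum(panel, rid)
        rows.append((rid, w, tie))
    return pd.DataFrame(rows, columns=["region_id", "weekday_min", "tie"])


RELIGION_ROWS = ("Christian", "Muslim", "Mixed")
ANTHROME_COLS = ("Cropland", "Natural", "Rangeland", "Settled", "Mixed")


def crosstab_regions(labels: pd.DataFrame) -> pd.DataFrame:
    """Counts of regions by (anthrome × religion) with margins.

    Rows are anthrome classes, columns religion classes, mirroring the
    descriptive table of the analysis; a ``Total`` row and column hold the
    margins.  Input must contain only analysable religion labels.
    """
    bad = set(labels["religion_label"]) - set(RELIGION_ROWS)
    if bad:
        raise ValueError(f"unlabelled or excluded regions present: religion labels {sorted(bad)}")
    bad_a = set(labels["anthrome_label"]) - set(ANTHROME_COLS)
    if bad_a:
        raise ValueError(f"unknown anthrome labels {sorted(bad_a)}")
    table = pd.DataFrame(0, index=list(ANTHROME_COLS), columns=list(RELIGION_ROWS))
    for _, row in labels.iterrows():
        table.loc[row["anthrome_label"], row["religion_label"]] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def anthrome_shares(crosstab: pd.DataFrame) -> pd.Series:
    """Percentage of retained regions in each anthrome class."""
    total = crosstab.loc["Total", "Total"]
    shares = 100.0 * crosstab.loc[list(ANTHROME_COLS), "Total"] / total
    shares.name = "percent_of_regions"
    return shares
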