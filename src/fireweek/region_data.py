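"""Region tables, adjacency graphs, and fire-count panels.

The analysis operates on three plain-text inputs:

* ``regions.csv`` — one row per administrative region with its area (km²),
  religion shares of the total population, and area fractions of the four
  aggregated anthrome (anthropogenic biome) classes.
* ``adjacency.csv`` — one undirected contiguity edge per row.
* ``counts.csv`` — long-form fire counts per (region, year, weekday),
  weekdays coded 1=Monday … 7=Sunday.

Religion shares may be missing (empty cells).  Missingness is semantically
distinct from a zero share: downstream classification excludes regions with
no religion data rather than treating them as having no believers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Aggregated anthrome classes used throughout the analysis.
ANTHROME_CLASSES = ("Cropland", "Natural", "Rangeland", "Settled")

#: Weekday labels, index 1..7.
WEEKDAY_NAMES = {1: "Mon", 2: "Tue", 3: "Wed", 4: "Thu", 5: "Fri", 6: "Sat", 7: "Sun"}

_FRACTION_SUM_TOL = 1e-3  # tolerated slack on anthrome fractions summing to 1

REGION_COLUMNS = [
    "region_id",
    "area_km2",
    "frac_christian",
    "frac_muslim",
    "frac_other",
    "frac_cropland",
    "frac_natural",
    "frac_rangeland",
    "frac_settled",
]


@dataclass
class RegionRecord:
    """One administrative region.

    ``frac_christian``/``frac_muslim``/``frac_other`` are shares of the total
    population and may be NaN (missing religion data).  ``anthrome_fracs``
    maps each aggregated anthrome class to its area fraction; the four
    fractions must sum to 1 within a small tolerance.
    """

    region_id: str
    area_km2: float
    frac_christian: float
    frac_muslim: float
    frac_other: float = float("nan")
    anthrome_fracs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.area_km2 > 0):
            raise ValueError(
                f"region {self.region_id!r}: area_km2 must be positive, got {self.area_km2}"
            )
        for name in ("frac_christian", "frac_muslim", "frac_other"):
            val = getattr(self, name)
            if not math.isnan(val) and not (0.0 <= val <= 1.0):
                raise ValueError(f"region {self.region_id!r}: {name}={val} outside [0, 1]")
        rel_sum = np.nansum([self.frac_christian, self.frac_muslim, self.frac_other])
        if rel_sum > 1.0 + _FRACTION_SUM_TOL:
            raise ValueError(
                f"region {self.region_id!r}: religion fractions sum to {rel_sum:.4f} > 1"
            )
        missing = set(ANTHROME_CLASSES) - set(self.anthrome_fracs)
        if missing:
            raise ValueError(f"region {self.region_id!r}: missing anthrome classes {sorted(missing)}")
        for cls, val in self.anthrome_fracs.items():
            if not (0.0 <= val <= 1.0 + 1e-12):
                raise ValueError(f"region {self.region_id!r}: anthrome {cls}={val} outside [0, 1]")
        total = sum(self.anthrome_fracs[c] for c in ANTHROME_CLASSES)
        if abs(total - 1.0) > _FRACTION_SUM_TOL:
            raise ValueError(
                f"region {self.region_id!r}: anthrome fractions sum to {total:.4f}, expected 1"
            )

    @property
    def religion_missing(self) -> bool:
        """True when Christian or Muslim shares are unavailable."""
        return math.isnan(self.frac_christian) or math.isnan(self.frac_muslim)


class AdjacencyGraph:
    """Undirected contiguity graph over region ids.

    Wraps a :class:`networkx.Graph`; guarantees symmetry (undirected), no
    self-loops, and that every region appears as a node (isolated nodes are
    allowed).  Connected components are exposed because the intrinsic CAR
    model is improper per component.
    """

    def __init__(self, region_ids: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        ids = list(region_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids in adjacency graph")
        self.region_ids: list[str] = ids
        known = set(ids)
        g = nx.Graph()
        g.add_nodes_from(ids)
        for a, b in edges:
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown region id")
            if a == b:
                continue  # ignore self-loops rather than storing them
            g.add_edge(a, b)
        self.graph = g
        self.components: list[set[str]] = [set(c) for c in nx.connected_components(g)]

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_minus_k(self) -> int:
        """Rank of the ICAR precision: nodes minus connected components."""
        return self.graph.number_of_nodes() - self.n_components

    def edge_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges as integer index arrays into ``region_ids`` order."""
        pos = {rid: i for i, rid in enumerate(self.region_ids)}
        if self.graph.number_of_edges() == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        ei, ej = zip(*((pos[a], pos[b]) for a, b in self.graph.edges()))
        return np.asarray(ei, dtype=np.int64), np.asarray(ej, dtype=np.int64)

    def subgraph(self, keep_ids: Sequence[str]) -> "AdjacencyGraph":
        keep = set(keep_ids)
        edges = [(a, b) for a, b in self.graph.edges() if a in keep and b in keep]
        return AdjacencyGraph(list(keep_ids), edges)


class FireCountPanel:
    """Dense integer fire counts indexed by (region, weekday 1..7, year).

    Internally a ``(n_regions, 7, n_years)`` integer array; every
    region × weekday × year cell is present, zeros explicit.
    """

    def __init__(self, counts: np.ndarray, region_ids: Sequence[str], years: Sequence[int]):
        counts = np.asarray(counts)
        if counts.ndim != 3 or counts.shape[1] != 7:
            raise ValueError(f"counts must have shape (n_regions, 7, n_years), got {counts.shape}")
        if counts.shape[0] != len(region_ids) or counts.shape[2] != len(years):
            raise ValueError("counts shape inconsistent with region_ids / years")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.region_ids = list(region_ids)
        self.years = list(years)
        self._pos = {rid: i for i, rid in enumerate(self.region_ids)}

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def region_index(self, region_id: str) -> int:
        try:
            return self._pos[region_id]
        except KeyError:
            raise KeyError(f"unknown region id {region_id!r}") from None

    def total_count(self, region_id: str) -> int:
        """Counts accumulated over all weekdays and years for one region."""
        return int(self.counts[self.region_index(region_id)].sum())

    def weekday_totals(self, region_id: str) -> np.ndarray:
        """Length-7 vector of counts summed across years."""
        return self.counts[self.region_index(region_id)].sum(axis=1)

    def subset(self, keep_ids: Sequence[str]) -> "FireCountPanel":
        idx = [self.region_index(r) for r in keep_ids]
        return FireCountPanel(self.counts[idx], list(keep_ids), self.years)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, rid in enumerate(self.region_ids):
            for w in range(7):
                for t, year in enumerate(self.years):
                    rows.append((rid, year, w + 1, int(self.counts[i, w, t])))
        return pd.DataFrame(rows, columns=["region_id", "year", "weekday", "count"])


# ---------------------------------------------------------------------------
# readers / writers


def read_region_table(path) -> list[RegionRecord]:
    """Read ``regions.csv`` into records; empty religion cells stay missing."""
    df = pd.read_csv(path, dtype={"region_id": str})
    missing_cols = set(REGION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    if df["region_id"].duplicated().any():
        dup = df.loc[df["region_id"].duplicated(), "region_id"].iloc[0]
        raise ValueError(f"{path}: duplicate region_id {dup!r}")
    records = []
    for row_number, row in df.iterrows():
        try:
            rec = RegionRecord(
                region_id=row["region_id"],
                area_km2=float(row["area_km2"]),
                frac_christian=float(row["frac_christian"]) if pd.notna(row["frac_christian"]) else float("nan"),
                frac_muslim=float(row["frac_muslim"]) if pd.notna(row["frac_muslim"]) else float("nan"),
                frac_other=float(row["frac_other"]) if pd.notna(row["frac_other"]) else float("nan"),
                anthrome_fracs={
                    "Cropland": float(row["frac_cropland"]),
                    "Natural": float(row["frac_natural"]),
                    "Rangeland": float(row["frac_rangeland"]),
                    "Settled": float(row["frac_settled"]),
                },
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {row_number} (region_id={row['region_id']!r}): {exc}") from exc
        records.append(rec)
    return records


def write_region_table(records: Iterable[RegionRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "region_id": r.region_id,
                "area_km2": r.area_km2,
                "frac_christian": r.frac_christian,
                "frac_muslim": r.frac_muslim,
                "frac_other": r.frac_other,
                "frac_cropland": r.anthrome_fracs["Cropland"],
                "frac_natural": r.anthrome_fracs["Natural"],
                "frac_rangeland": r.anthrome_fracs["Rangeland"],
                "frac_settled": r.anthrome_fracs["Settled"],
            }
        )
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, index=False)


def read_fire_counts(path, regions: Sequence[str] | Sequence[RegionRecord], years: Sequence[int] | None = None) -> FireCountPanel:
    """Read long-form ``counts.csv`` into a dense panel.

    Absent (region, year, weekday) combinations are filled with zero and
    reported in a log message; duplicates, unknown regions, or weekdays
    outside 1..7 raise.
    """
    region_ids = [r.region_id if isinstance(r, RegionRecord) else r for r in regions]
    df = pd.read_csv(path, dtype={"region_id": str})
    required = {"region_id", "year", "weekday", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad_wd = df[(df["weekday"] < 1) | (df["weekday"] > 7)]
    if len(bad_wd):
        raise ValueError(f"{path}: weekday {bad_wd['weekday'].iloc[0]} outside 1..7 (row {bad_wd.index[0]})")
    known = set(region_ids)
    unknown = df[~df["region_id"].isin(known)]
    if len(unknown):
        raise ValueError(f"{path}: unknown region_id {unknown['region_id'].iloc[0]!r} (row {unknown.index[0]})")
    if df.duplicated(subset=["region_id", "year", "weekday"]).any():
        dup = df[df.duplicated(subset=["region_id", "year", "weekday"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate record for ({dup['region_id']}, {dup['year']}, {dup['weekday']})"
        )
    if years is None:
        years = sorted(df["year"].unique())
    years = [int(y) for y in years]
    return panel_from_long(df, region_ids, years, source=str(path))


def panel_from_long(df: pd.DataFrame, region_ids: Sequence[str], years: Sequence[int], source: str = "<memory>") -> FireCountPanel:
    """Build a dense :class:`FireCountPanel` from long-form records."""
    year_pos = {int(y): t for t, y in enumerate(years)}
    pos = {rid: i for i, rid in enumerate(region_ids)}
    counts = np.zeros((len(region_ids), 7, len(years)), dtype=np.int64)
    n_filled = len(region_ids) * 7 * len(years) - len(df)
    for _, row in df.iterrows():
        y = int(row["year"])
        if y not in year_pos:
            raise ValueError(f"{source}: year {y} outside requested years {list(years)}")
        counts[pos[row["region_id"]], int(row["weekday"]) - 1, year_pos[y]] = int(row["count"])
    if n_filled > 0:
        logger.info("%s: %d absent (region, year, weekday) cells filled with 0", source, n_filled)
    return FireCountPanel(counts, region_ids, years)


def write_fire_counts(panel: FireCountPanel, path) -> None:
    panel.to_long().to_csv(path, index=False)


def read_adjacency(path, region_ids: Sequence[str]) -> AdjacencyGraph:
    """Read a two-column undirected edge list CSV."""
    df = pd.read_csv(path, dtype=str)
    required = {"region_id_a", "region_id_b"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    edges = list(zip(df["region_id_a"], df["region_id_b"]))
    return AdjacencyGraph(region_ids, edges)


def write_adjacency(graph: AdjacencyGraph, path) -> None:
    pd.DataFrame(sorted(graph.graph.edges()), columns=["region_id_a", "region_id_b"]).to_csv(
        path, index=False
    )


def build_adjacency(
    region_ids: Sequence[str],
    edges: Iterable[tuple[str, str]] | None = None,
    polygons: Mapping[str, object] | None = None,
) -> AdjacencyGraph:
    """Build the contiguity graph from an edge list or from polygons.

    Polygon mode derives queen contiguity (shared boundary, including a
    single shared point) and requires ``shapely``; values may be shapely
    geometries or GeoJSON-like mapping objects.
    """
    if (edges is None) == (polygons is None):
        raise ValueError("provide exactly one of `edges` or `polygons`")
    if edges is not None:
        return AdjacencyGraph(region_ids, edges)
    try:
        from shapely.geometry import shape as _shape
        from shapely.geometry.base import BaseGeometry
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("polygon ingestion requires the optional `shapely` dependency") from exc
    geoms = {}
    for rid in region_ids:
        if rid not in polygons:
            raise ValueError(f"no polygon provided for region {rid!r}")
        g = polygons[rid]
        geoms[rid] = g if isinstance(g, BaseGeometry) else _shape(g)
    derived = []
    ids = list(region_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            # queen contiguity: any shared boundary, including a single point
            if geoms[a].touches(geoms[b]) or geoms[a].overlaps(geoms[b]):
                derived.append((a, b))
    return AdjacencyGraph(ids, derived)


# ---------------------------------------------------------------------------
# anthrome aggregation

_FINE_TO_AGGREGATED = {
    "dense settlements": "Settled",
    "dense": "Settled",
    "villages": "Settled",
    "croplands": "Cropland",
    "cropland": "Cropland",
    "rangelands": "Rangeland",
    "rangeland": "Rangeland",
    "forested": "Natural",
    "forest": "Natural",
    "wildlands": "Natural",
    "wildland": "Natural",
}


def aggregate_anthromes(raw_fracs: Mapping[str, float]) -> dict[str, float]:
    """Collapse fine anthrome classes to the four aggregated classes.

    Dense Settlements + Villages -> Settled; Forested + Wildlands -> Natural;
    Croplands and Rangelands pass through.  Output is renormalised to sum to
    exactly 1 provided the input total is within tolerance of 1.
    """
    out = {cls: 0.0 for cls in ANTHROME_CLASSES}
    for key, val in raw_fracs.items():
        if val < 0:
            raise ValueError(f"anthrome fraction {key!r}={val} is negative")
        norm = key.strip().lower().replace("_", " ")
        if norm not in _FINE_TO_AGGREGATED:
            raise ValueError(f"unknown fine anthrome class {key!r}")
        out[_FINE_TO_AGGREGATED[norm]] += float(val)
    total = sum(out.values())
    if abs(total - 1.0) > _FRACTION_SUM_TOL:
        raise ValueError(f"anthrome fractions sum to {total:.4f}, expected 1 within tolerance")
    return {cls: val / total for cls, val in out.items()}
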