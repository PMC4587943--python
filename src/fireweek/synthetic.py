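"""Synthetic region systems and fire-count panels.

The generator emulates the structure the analysis assumes: a lattice of
contiguous regions with log-normal areas, spatially clustered religion and
anthrome composition (a northern Muslim belt, a southern Christian block,
and a mixing zone between them), an intrinsic-CAR spatial field on the
contiguity graph, and yearly weekday fire counts drawn from a negative
binomial whose log-mean carries religion-specific weekday deficits —
Sunday in Christian regions, Friday in Muslim regions, both about −0.21 on
the log scale by default, matching the magnitude the croplands analysis is
designed to detect.

Counts are sampled through a gamma–Poisson mixture, keeping the generator
independent of the pmf code it is used to test.  All outputs are
deterministic functions of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .classification import label_regions
from .region_data import (
    ANTHROME_CLASSES,
    AdjacencyGraph,
    FireCountPanel,
    RegionRecord,
)

#: Weekday index of the Christian and Muslim rest days.
SUNDAY, FRIDAY = 7, 5


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults mirror the real study's design where it is known: nine annual
    replicates of seven weekday counts per region, a few hundred regions on
    a contiguity graph, and rest-day deficits of 0.21 on the log scale.
    ``base_log_density`` is the log fire count per km² per weekday-year in a
    reference cell; with the default median area (2,000 km²) it yields on
    the order of a hundred fires per region-weekday-year, comfortably above
    the 0.1 km⁻² cumulative-density inclusion threshold.
    """

    rows: int = 10
    cols: int = 10
    contiguity: str = "rook"  # or "queen"
    n_years: int = 9
    religion_clustering: float = 0.9  # 0 = spatially independent labels
    mixing_band: float = 1.0  # half-width of the mixed-religion zone, in graph hops
    anthrome_weights: Mapping[str, float] | None = None  # None -> mixed default
    anthrome_concentration: float = 2.0
    area_median_km2: float = 2000.0
    area_log_sd: float = 0.5
    base_log_density: float = -3.0
    sunday_deficit: float = 0.21
    friday_deficit: float = 0.21
    weekday_effects: Mapping[int, float] | None = None  # extra common weekday terms
    religion_effects: Mapping[str, float] | None = None  # religion main effects
    true_theta: float = 3.0
    true_tau: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.rows < 2 or self.cols < 2:
            raise ValueError("lattice must be at least 2x2")
        if self.true_theta <= 0 or self.true_tau <= 0:
            raise ValueError("true_theta and true_tau must be positive")
        if not 0.0 <= self.religion_clustering <= 1.0:
            raise ValueError("religion_clustering must lie in [0, 1]")
        if self.contiguity not in ("rook", "queen"):
            raise ValueError("contiguity must be 'rook' or 'queen'")


@dataclass
class TruthRecord:
    """Ground truth attached to a simulated panel, for recovery tests."""

    cell_log_means: dict[tuple[str, int], float]  # (religion, weekday) -> effect
    coefficients: dict[str, float]  # corner-coded truth for the R+W+R:W design
    theta: float
    tau: float
    z: np.ndarray
    labels: pd.DataFrame
    log_areas: np.ndarray


def _lattice_graph(rows: int, cols: int, contiguity: str) -> tuple[list[str], list[tuple[str, str]]]:
    def rid(r, c):
        return f"r{r:02d}c{c:02d}"

    ids = [rid(r, c) for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            if r + 1 < rows:
                edges.append((rid(r, c), rid(r + 1, c)))
            if c + 1 < cols:
                edges.append((rid(r, c), rid(r, c + 1)))
            if contiguity == "queen":
                if r + 1 < rows and c + 1 < cols:
                    edges.append((rid(r, c), rid(r + 1, c + 1)))
                if r + 1 < rows and c - 1 >= 0:
                    edges.append((rid(r, c), rid(r + 1, c - 1)))
    return ids, edges


def _religion_labels(config: SimulationConfig, graph: nx.Graph, ids: list[str], rng) -> dict[str, str]:
    """Two-seed region growing: Muslim north, Christian south, mixed band."""
    rows, cols = config.rows, config.cols
    muslim_seed = f"r{0:02d}c{cols // 2:02d}"
    christian_seed = f"r{rows - 1:02d}c{cols // 2:02d}"
    d_mus = nx.single_source_shortest_path_length(graph, muslim_seed)
    d_chr = nx.single_source_shortest_path_length(graph, christian_seed)
    labels = {}
    for rid in ids:
        gap = d_mus.get(rid, 10**6) - d_chr.get(rid, 10**6) + rng.normal(0.0, 0.75)
        if abs(gap) <= config.mixing_band:
            grown = "Mixed"
        else:
            grown = "Muslim" if gap < 0 else "Christian"
        if rng.random() < config.religion_clustering:
            labels[rid] = grown
        else:
            labels[rid] = ("Christian", "Muslim", "Mixed")[rng.integers(3)]
    return labels


def _religion_fractions(label: str, rng) -> tuple[float, float, float]:
    """Population shares that classify back to the intended label."""
    if label == "Christian":
        fc = rng.uniform(0.62, 0.9)
        fm = rng.uniform(0.0, min(fc / 3.2, 1.0 - fc))  # Christian share > 0.76
    elif label == "Muslim":
        fm = rng.uniform(0.62, 0.9)
        fc = rng.uniform(0.0, min(fm / 3.2, 1.0 - fm))
    else:  # Mixed: joint share >= 0.5, neither faith above 75% of the pair
        total = rng.uniform(0.6, 0.92)
        share = rng.uniform(0.3, 0.7)
        fc, fm = total * share, total * (1.0 - share)
    other = max(0.0, min(1.0 - fc - fm, rng.uniform(0.0, 0.15)))
    return float(fc), float(fm), float(other)


_DEFAULT_ANTHROME_WEIGHTS = {"Cropland": 0.45, "Natural": 0.2, "Rangeland": 0.2, "Settled": 0.15}


def _anthrome_fractions(config: SimulationConfig, rng) -> dict[str, float]:
    weights = dict(config.anthrome_weights or _DEFAULT_ANTHROME_WEIGHTS)
    active = [c for c in ANTHROME_CLASSES if weights.get(c, 0.0) > 0.0]
    if len(active) == 1:
        return {c: (1.0 if c in active else 0.0) for c in ANTHROME_CLASSES}
    conc = np.array([config.anthrome_concentration * weights[c] for c in active])
    draw = rng.dirichlet(conc)
    fracs = {c: 0.0 for c in ANTHROME_CLASSES}
    for c, v in zip(active, draw):
        fracs[c] = float(v)
    return fracs


def generate_regions(config: SimulationConfig) -> tuple[list[RegionRecord], AdjacencyGraph]:
    """Lattice region system with clustered religion/anthrome composition."""
    rng = np.random.default_rng(config.seed)
    ids, edges = _lattice_graph(config.rows, config.cols, config.contiguity)
    graph = AdjacencyGraph(ids, edges)
    labels = _religion_labels(config, graph.graph, ids, rng)
    records = []
    for rid in ids:
        fc, fm, fo = _religion_fractions(labels[rid], rng)
        records.append(
            RegionRecord(
                region_id=rid,
                area_km2=float(np.exp(np.log(config.area_median_km2) + config.area_log_sd * rng.normal())),
                frac_christian=fc,
                frac_muslim=fm,
                frac_other=fo,
                anthrome_fracs=_anthrome_fractions(config, rng),
            )
        )
    return records, graph


def sample_icar_field(graph: AdjacencyGraph, tau: float, seed, size: int | None = None) -> np.ndarray:
    """Draws from the intrinsic GMRF with precision ``τ·(D − W)``.

    Sampled per connected component via the eigendecomposition of the
    component Laplacian restricted to its non-null eigenspace; sums to zero
    exactly within each component.  Single-node components get 0.  Returns
    shape ``(n,)`` when ``size`` is None, else ``(size, n)``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_draws = 1 if size is None else size
    pos = {rid: i for i, rid in enumerate(graph.region_ids)}
    z = np.zeros((n_draws, len(graph.region_ids)))
    for comp in graph.components:
        nodes = sorted(pos[r] for r in comp)
        if len(nodes) < 2:
            continue
        sub = [graph.region_ids[i] for i in nodes]
        lap = nx.laplacian_matrix(graph.graph.subgraph(sub), nodelist=sub).toarray().astype(float)
        lam, vec = np.linalg.eigh(lap)
        keep = lam > 1e-10
        eps = rng.standard_normal((n_draws, int(keep.sum())))
        zc = (eps / np.sqrt(tau * lam[keep])) @ vec[:, keep].T
        zc -= zc.mean(axis=1, keepdims=True)  # exact sum-to-zero (numerical safety)
        z[:, nodes] = zc
    return z[0] if size is None else z


def true_cell_effects(config: SimulationConfig) -> dict[tuple[str, int], float]:
    """Religion × weekday log-mean effects net of offset, intercept, and z."""
    wd = dict(config.weekday_effects or {})
    rel = dict(config.religion_effects or {})
    effects = {}
    for religion in ("Christian", "Muslim", "Mixed"):
        for w in range(1, 8):
            e = wd.get(w, 0.0) + rel.get(religion, 0.0)
            if religion == "Christian" and w == SUNDAY:
                e -= config.sunday_deficit
            if religion == "Muslim" and w == FRIDAY:
                e -= config.friday_deficit
            effects[(religion, w)] = e
    return effects


def true_coefficients(config: SimulationConfig) -> dict[str, float]:
    """Corner-coded truth for the saturated religion × weekday design.

    Uses the documented level order (Christian and Monday as references),
    matching the coefficient names of a fitted ``R + W + R:W`` model.
    """
    eff = true_cell_effects(config)
    a0 = config.base_log_density + eff[("Christian", 1)]
    coefs = {"Intercept": a0}
    for rel in ("Muslim", "Mixed"):
        coefs[f"R[{rel}]"] = eff[(rel, 1)] - eff[("Christian", 1)]
    for w in range(2, 8):
        coefs[f"W[{w}]"] = eff[("Christian", w)] - eff[("Christian", 1)]
    for rel in ("Muslim", "Mixed"):
        for w in range(2, 8):
            coefs[f"R[{rel}]:W[{w}]"] = (
                eff[(rel, w)] - eff[("Christian", w)] - eff[(rel, 1)] + eff[("Christian", 1)]
            )
    return coefs


def simulate_counts(
    records: list[RegionRecord],
    graph: AdjacencyGraph,
    config: SimulationConfig,
) -> tuple[FireCountPanel, TruthRecord]:
    """Negative-binomial weekday counts with the configured weekly cycle.

    ``ln μ_{iW} = ln(area_i) + base_log_density + effect(religion_i, W) + z_i``
    with ``z`` a fresh ICAR draw; ``n_years`` independent NB replicates per
    region-weekday are drawn via a gamma–Poisson mixture.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    labels = label_regions(records)
    effects = true_cell_effects(config)
    z = sample_icar_field(graph, config.true_tau, rng)
    n = len(records)
    log_areas = np.log([r.area_km2 for r in records])
    religion = labels["religion_label"].to_numpy()
    log_mu = np.empty((n, 7))
    for i in range(n):
        rel = religion[i] if religion[i] in ("Christian", "Muslim", "Mixed") else "Mixed"
        for w in range(1, 8):
            log_mu[i, w - 1] = log_areas[i] + config.base_log_density + effects[(rel, w)] + z[i]
    if np.any(log_mu > np.log(1e12)):
        raise ValueError("simulated mean exceeds 1e12; lower base_log_density or areas")
    mu = np.exp(log_mu)
    lam = rng.gamma(config.true_theta, mu[:, :, None] / config.true_theta, size=(n, 7, config.n_years))
    counts = rng.poisson(lam)
    panel = FireCountPanel(counts, [r.region_id for r in records], list(range(2003, 2003 + config.n_years)))
    truth = TruthRecord(
        cell_log_means=effects,
        coefficients=true_coefficients(config),
        theta=config.true_theta,
        tau=config.true_tau,
        z=z,
        labels=labels,
        log_areas=log_areas,
    )
    return panel, truth


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: regions, graph, labels, panel, truth."""
    records, graph = generate_regions(config)
    panel, truth = simulate_counts(records, graph, config)
    return records, graph, truth.labels, panel, truth


# ---------------------------------------------------------------------------
# deterministic fixtures


def join_count_same_label(labels: Mapping[str, str], graph: AdjacencyGraph) -> int:
    """Number of edges joining two regions with the same label."""
    return sum(1 for a, b in graph.graph.edges() if labels[a] == labels[b])


_TABLE1_CELLS = {  # (anthrome, religion) -> number of retained regions
    ("Cropland", "Christian"): 69,
    ("Cropland", "Muslim"): 47,
    ("Cropland", "Mixed"): 48,
    ("Natural", "Christian"): 27,
    ("Natural", "Muslim"): 0,
    ("Natural", "Mixed"): 5,
    ("Rangeland", "Christian"): 30,
    ("Rangeland", "Muslim"): 14,
    ("Rangeland", "Mixed"): 12,
    ("Settled", "Christian"): 48,
    ("Settled", "Muslim"): 4,
    ("Settled", "Mixed"): 5,
    ("Mixed", "Christian"): 42,
    ("Mixed", "Muslim"): 7,
    ("Mixed", "Mixed"): 14,
}

_TABLE4_RAW_PVALUES = [
    0.00000, 0.00000, 0.00036, 0.00000, 0.00319, 0.00000,  # Chr:Sun vs other weekdays
    0.00000, 0.00000, 0.00000, 0.00000, 0.00000, 0.00000,  # Mus:Fri vs other weekdays
    0.00000,  # Chr:Sun - Mus:Fri
    0.00000,  # Chr:Sun - Mix:Sun
    0.57856,  # Mus:Fri - Mix:Fri
]

FIXTURE_NAMES = ("exclusions-554", "table4-pvalues", "tiny-fit")


def _religion_fracs_for(label: str) -> tuple[float, float]:
    return {
        "Christian": (0.80, 0.10),
        "Muslim": (0.10, 0.80),
        "Mixed": (0.45, 0.45),
        "Excluded": (0.30, 0.15),  # joint share 0.45 < 0.5
    }[label]


def _anthrome_fracs_for(label: str) -> dict[str, float]:
    if label == "Mixed":
        return {"Cropland": 0.3, "Natural": 0.3, "Rangeland": 0.2, "Settled": 0.2}
    fracs = {c: 0.1 for c in ANTHROME_CLASSES}
    fracs[label] = 0.7
    return fracs


def _exclusions_fixture() -> tuple[list[RegionRecord], FireCountPanel]:
    """554 regions engineered so 161/19/2 fail the three exclusion rules.

    The 372 retained regions reproduce the study's religion × anthrome
    cross-tabulation cell counts.  Retained regions accumulate 630 counts
    over 1,000 km² (density 0.63); low-fire regions accumulate 63 (0.063,
    below the 0.1 threshold).  Synthetic stand-in for the real GADM/WRD
    region system, which is out of scope.
    """
    records: list[RegionRecord] = []
    rows: list[tuple[str, int, int, int]] = []
    years = list(range(2003, 2012))

    def add_region(rid: str, religion: str, anthrome: str, per_cell: int, missing=False):
        fc, fm = (float("nan"), float("nan")) if missing else _religion_fracs_for(religion)
        records.append(
            RegionRecord(
                region_id=rid,
                area_km2=1000.0,
                frac_christian=fc,
                frac_muslim=fm,
                frac_other=0.0 if missing else 0.05,
                anthrome_fracs=_anthrome_fracs_for(anthrome),
            )
        )
        for year in years:
            for w in range(1, 8):
                rows.append((rid, year, w, per_cell))

    k = 0
    for (anthrome, religion), count in _TABLE1_CELLS.items():
        for _ in range(count):
            add_region(f"keep{k:03d}", religion, anthrome, per_cell=10)
            k += 1
    for i in range(161):
        add_region(f"lowfire{i:03d}", "Christian", "Cropland", per_cell=1)
    for i in range(19):
        add_region(f"traditional{i:02d}", "Excluded", "Cropland", per_cell=10)
    for i in range(2):
        add_region(f"nodata{i}", "Christian", "Cropland", per_cell=10, missing=True)

    df = pd.DataFrame(rows, columns=["region_id", "year", "weekday", "count"])
    from .region_data import panel_from_long

    panel = panel_from_long(df, [r.region_id for r in records], years, source="exclusions-554")
    return records, panel


def make_fixture(name: str):
    """Deterministic bundled fixtures (generated in memory, never shipped).

    * ``"exclusions-554"`` — (records, panel): 554 regions, 161/19/2
      exclusions, 372 retained matching the study's crosstab cells.
    * ``"table4-pvalues"`` — the 15 raw contour probabilities of the
      published contrast table, in reporting order.
    * ``"tiny-fit"`` — small end-to-end dataset: dict with records, graph,
      labels, panel, truth and its config (3×3 lattice, 2 years).
    """
    if name == "exclusions-554":
        return _exclusions_fixture()
    if name == "table4-pvalues":
        return np.array(_TABLE4_RAW_PVALUES)
    if name == "tiny-fit":
        config = SimulationConfig(
            rows=3,
            cols=3,
            n_years=2,
            anthrome_weights={"Cropland": 1.0},
            seed=20030101,
        )
        records, graph, labels, panel, truth = simulate_dataset(config)
        return {
            "config": config,
            "records": records,
            "graph": graph,
            "labels": labels,
            "panel": panel,
            "truth": truth,
        }
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
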