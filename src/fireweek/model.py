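"""Negative-binomial regression with an intrinsic CAR spatial effect.

The observation model for the yearly fire count :math:`Y_{iW}` of region
*i* on weekday *W* is negative binomial with shape :math:`\\theta` and mean
:math:`\\mu_{iW}`,

.. math::

    \\ln \\mu_{iW} = \\ln(\\mathrm{area}_i) + x_{iW}^\\top \\alpha + z_i,

where the design row :math:`x_{iW}` carries corner-constrained dummies for
the religion (R), weekday (W) and anthrome (A) factors and their requested
interactions, and :math:`z` is an intrinsic conditional autoregressive
(ICAR) random field on the region contiguity graph with precision
:math:`\\tau`.  The ICAR density is improper: up to a constant its log is
``((n - k)/2)·ln τ − (τ/2)·Σ_{i~j} (z_i − z_j)²`` with *n* nodes and *k*
connected components, identified by a sum-to-zero constraint per component.

Annual counts are conditionally independent replicates sharing
:math:`\\mu_{iW}`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .region_data import AdjacencyGraph, FireCountPanel

#: Fixed, documented factor level orders (first level = reference).
RELIGION_LEVELS = ("Christian", "Muslim", "Mixed")
WEEKDAY_LEVELS = (1, 2, 3, 4, 5, 6, 7)
ANTHROME_LEVELS = ("Cropland", "Natural", "Rangeland", "Settled", "Mixed")

_TERM_ORDER = ("A", "R", "W", "R:W", "R:A", "W:A", "R:W:A")
_MAIN_OF = {
    "R:W": {"R", "W"},
    "R:A": {"R", "A"},
    "W:A": {"W", "A"},
    "R:W:A": {"R", "W", "A"},
}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a set of fixed-effect terms plus the ICAR flag.

    Serialised as e.g. ``"R + W + R:W + ICAR"``.
    """

    terms: frozenset[str] = frozenset()
    include_icar: bool = False

    def __post_init__(self):
        unknown = self.terms - set(_TERM_ORDER)
        if unknown:
            raise ValueError(f"unknown model terms {sorted(unknown)}")
        for term, mains in _MAIN_OF.items():
            if term in self.terms and not mains <= self.terms:
                raise ValueError(f"interaction {term} requires main effects {sorted(mains)}")

    @classmethod
    def from_string(cls, text: str) -> "ModelSpec":
        parts = [p.strip() for p in text.split("+") if p.strip()]
        icar = False
        terms = set()
        for p in parts:
            if p.upper() == "ICAR":
                icar = True
            elif p == "1":  # intercept-only placeholder
                continue
            else:
                key = ":".join(q.strip().upper() for q in p.split(":"))
                terms.add(key)
        return cls(frozenset(terms), icar)

    def to_string(self) -> str:
        parts = [t for t in ("R", "W", "A") if t in self.terms]
        parts += [t for t in ("R:W", "R:A", "W:A", "R:W:A") if t in self.terms]
        if self.include_icar:
            parts.append("ICAR")
        return " + ".join(parts) if parts else "1"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass
class PriorSpec:
    """Weakly-informative priors for the fixed effects and hyperparameters.

    ``alpha_sd`` is the per-coefficient normal prior standard deviation;
    ``log_theta`` gets a normal prior and the ICAR precision ``tau`` a
    gamma prior (shape, rate).
    """

    alpha_sd: float = 31.6
    log_theta_mean: float = 0.0
    log_theta_sd: float = 10.0
    tau_shape: float = 1.0
    tau_rate: float = 5e-5

    def __post_init__(self):
        if min(self.alpha_sd, self.log_theta_sd, self.tau_shape, self.tau_rate) <= 0:
            raise ValueError("all prior scales must be positive")


@dataclass
class Parameters:
    """One point in parameter space: fixed effects, NB shape, ICAR field."""

    alpha: np.ndarray
    theta: float
    tau: float = 1.0
    z: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def is_valid(self) -> bool:
        return self.theta > 0 and self.tau > 0 and np.all(np.isfinite(self.alpha))


# ---------------------------------------------------------------------------
# design matrices


def _dummies(values: np.ndarray, levels: Sequence) -> tuple[np.ndarray, list[str]]:
    """Corner-constrained (drop-first) dummy columns for one factor."""
    known = set(levels)
    bad = set(np.unique(values)) - known
    if bad:
        raise ValueError(f"factor values {sorted(map(str, bad))} not in levels {list(levels)}")
    cols = np.column_stack([(values == lv).astype(float) for lv in levels[1:]])
    return cols, [str(lv) for lv in levels[1:]]


def design_matrix(
    religion: np.ndarray,
    weekday: np.ndarray,
    spec: ModelSpec,
    anthrome: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Corner-constrained design matrix for the requested terms.

    Interaction columns are elementwise products of the main-effect dummy
    columns.  Column order: intercept, A, R, W, R:W, R:A, W:A, R:W:A.
    """
    n = len(religion)
    if "A" in spec.terms or "R:A" in spec.terms or "W:A" in spec.terms:
        if anthrome is None:
            raise ValueError("spec includes anthrome terms but no anthrome labels were given")
    blocks = [np.ones((n, 1))]
    names = ["Intercept"]
    dummies = {}
    labels = {}
    if "A" in spec.terms:
        dummies["A"], labels["A"] = _dummies(np.asarray(anthrome), ANTHROME_LEVELS)
    if "R" in spec.terms:
        dummies["R"], labels["R"] = _dummies(np.asarray(religion), RELIGION_LEVELS)
    if "W" in spec.terms:
        dummies["W"], labels["W"] = _dummies(np.asarray(weekday), WEEKDAY_LEVELS)
    for term in _TERM_ORDER:
        if term not in spec.terms:
            continue
        factors = term.split(":")
        if len(factors) == 1:
            blocks.append(dummies[term])
            names += [f"{term}[{lab}]" for lab in labels[term]]
        else:
            col_sets = [list(range(dummies[f].shape[1])) for f in factors]
            prod_cols = []
            for combo in itertools.product(*col_sets):
                col = np.ones(n)
                for f, ci in zip(factors, combo):
                    col = col * dummies[f][:, ci]
                prod_cols.append(col)
                names.append(":".join(f"{f}[{labels[f][ci]}]" for f, ci in zip(factors, combo)))
            blocks.append(np.column_stack(prod_cols))
    return np.concatenate(blocks, axis=1), names


def design_for_regions(labels: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Design over the region-major (region × weekday) observation grid.

    Row ``i*7 + (w-1)`` corresponds to region ``labels.iloc[i]`` on weekday
    ``w``; all seven weekdays are expanded for every region.
    """
    religion = np.repeat(labels["religion_label"].to_numpy(), 7)
    anthrome = (
        np.repeat(labels["anthrome_label"].to_numpy(), 7)
        if "anthrome_label" in labels.columns
        else None
    )
    weekday = np.tile(np.arange(1, 8), len(labels))
    return design_matrix(religion, weekday, spec, anthrome)


def cell_design_row(spec: ModelSpec, religion: str, weekday: int) -> np.ndarray:
    """Design row of a single (religion, weekday) cell mean.

    Anthrome factors, when present in the spec, are held at their reference
    level (all anthrome dummies zero), so anthrome contributions cancel in
    within-anthrome contrasts.
    """
    row, _ = design_matrix(
        np.asarray([religion]),
        np.asarray([weekday]),
        spec,
        np.asarray([ANTHROME_LEVELS[0]]) if "A" in spec.terms else None,
    )
    return row[0]


# ---------------------------------------------------------------------------
# densities


def nb_log_pmf(y, mu, theta) -> np.ndarray | float:
    """Log pmf of the negative binomial with mean ``mu`` and shape ``theta``.

    Computed with log-gamma functions; stable for counts up to ~1e7.
    """
    y_arr = np.asarray(y)
    if np.any(y_arr < 0) or not np.all(y_arr == np.floor(y_arr)):
        raise ValueError("y must be a non-negative integer")
    y_arr = y_arr.astype(float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    log_mu_plus_theta = np.log(mu + theta)
    out = (
        gammaln(y_arr + theta)
        - gammaln(theta)
        - gammaln(y_arr + 1.0)
        + y_arr * (np.log(mu) - log_mu_plus_theta)
        + theta * (np.log(theta) - log_mu_plus_theta)
    )
    return out if out.ndim else float(out)


def linear_predictor(
    design: np.ndarray,
    alpha: np.ndarray,
    log_offsets: np.ndarray,
    z_expanded: np.ndarray | None = None,
    return_mu: bool = False,
) -> np.ndarray:
    """Per-observation log-mean ``ln μ = ln(area) + X·α + z``."""
    design = np.asarray(design, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    log_offsets = np.asarray(log_offsets, dtype=float)
    if design.shape[1] != alpha.shape[0]:
        raise ValueError(f"design has {design.shape[1]} columns but alpha has {alpha.shape[0]}")
    if design.shape[0] != log_offsets.shape[0]:
        raise ValueError("log_offsets length does not match design rows")
    eta = log_offsets + design @ alpha
    if z_expanded is not None:
        z_expanded = np.asarray(z_expanded, dtype=float)
        if z_expanded.shape[0] != design.shape[0]:
            raise ValueError("z_expanded length does not match design rows")
        eta = eta + z_expanded
    return np.exp(eta) if return_mu else eta


def icar_quadratic(z: np.ndarray, graph: AdjacencyGraph) -> float:
    """Pairwise ICAR penalty ``Σ_{(i,j) in edges} (z_i − z_j)²``.

    Equals ``zᵀ (D − W) z`` for the graph Laplacian ``D − W``; invariant to
    adding a constant within each connected component.
    """
    z = np.asarray(z, dtype=float)
    if z.shape[0] != len(graph.region_ids):
        raise ValueError("z length does not match graph nodes")
    ei, ej = graph.edge_index_arrays()
    if len(ei) == 0:
        return 0.0
    return float(np.sum((z[ei] - z[ej]) ** 2))


def icar_log_density(z: np.ndarray, tau: float, graph: AdjacencyGraph) -> float:
    """Improper ICAR log-density up to an additive constant."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return 0.5 * graph.n_minus_k * np.log(tau) - 0.5 * tau * icar_quadratic(z, graph)


def log_likelihood(
    panel: FireCountPanel,
    spec: ModelSpec,
    params: Parameters,
    labels: pd.DataFrame,
    log_areas: np.ndarray,
) -> float:
    """Full NB log-likelihood over every (region, weekday, year) cell.

    ``μ_{iW}`` is shared across the yearly replicates of a region-weekday.
    ``log_areas`` is per region, in the order of ``panel.region_ids``;
    ``labels`` must be aligned to the same order.
    """
    if list(labels["region_id"]) != list(panel.region_ids):
        raise ValueError("labels not aligned with panel region order")
    X, _ = design_for_regions(labels, spec)
    n = panel.n_regions
    log_off = np.repeat(np.asarray(log_areas, dtype=float), 7)
    if spec.include_icar:
        z = np.asarray(params.z, dtype=float)
        if z.shape[0] != n:
            raise ValueError("params.z length does not match panel regions")
        z_exp = np.repeat(z, 7)
    else:
        z_exp = None
    eta = linear_predictor(X, params.alpha, log_off, z_exp)
    mu = np.exp(eta)  # (n*7,)
    y = panel.counts.reshape(n * 7, panel.n_years)
    return float(nb_log_pmf(y, mu[:, None], params.theta).sum())


def log_posterior(
    panel: FireCountPanel,
    spec: ModelSpec,
    params: Parameters,
    priors: PriorSpec,
    graph: AdjacencyGraph,
    labels: pd.DataFrame,
    log_areas: np.ndarray,
) -> float:
    """Unnormalised log-posterior: likelihood + ICAR density + priors.

    The prior on the NB shape is placed on ``ln θ`` (the sampling scale);
    the density is therefore with respect to ``(α, ln θ, τ, z)``.  Invalid
    parameter values (θ ≤ 0, τ ≤ 0) return ``-inf``.
    """
    if not params.is_valid():
        return float("-inf")
    lp = log_likelihood(panel, spec, params, labels, log_areas)
    lp += -0.5 * float(np.sum((params.alpha / priors.alpha_sd) ** 2))
    lt = np.log(params.theta)
    lp += -0.5 * ((lt - priors.log_theta_mean) / priors.log_theta_sd) ** 2
    if spec.include_icar:
        lp += icar_log_density(params.z, params.tau, graph)
        lp += (priors.tau_shape - 1.0) * np.log(params.tau) - priors.tau_rate * params.tau
    return float(lp)
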