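"""Posterior sampling, DIC, and model selection.

The sampler is an adaptive Metropolis-within-Gibbs scheme with four blocks:

* ``α`` — joint Metropolis-adjusted Langevin (MALA) proposal,
  preconditioned by the penalised-IRLS Fisher information at
  initialisation and re-adapted to the empirical posterior covariance
  during burn-in (Haario-style); adaptation is frozen after burn-in to
  preserve detailed balance;
* ``ln θ`` — scalar random walk (step adapted toward 44% acceptance);
* ``z`` — single-site random-walk updates, vectorised over the colour
  classes of a greedy graph colouring (nodes of one colour share no edge,
  so their full conditionals are mutually independent given the rest);
* ``τ`` — conjugate Gibbs draw from
  ``Gamma(shape + (n−k)/2, rate + q(z)/2)`` where ``q`` is the ICAR
  quadratic form.

After every sweep the spatial field is recentred to sum to zero per
connected component; on a connected graph the subtracted mean is added to
the intercept, which leaves the likelihood exactly invariant.

Efficiency notes: the yearly replicates share μ, so the μ-dependent part of
the likelihood collapses over years (only the θ-update needs the full
per-observation log-gamma terms), and the log-likelihood of every retained
draw is stored so that DIC needs no re-sweep over the sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import arviz as az
import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.special import gammaln

from . import model as _model
from .model import ModelSpec, Parameters, PriorSpec
from .region_data import AdjacencyGraph, FireCountPanel


@dataclass
class MCMCConfig:
    """Sampler configuration (defaults sized for desk-scale synthetic runs)."""

    n_chains: int = 4
    n_iter: int = 5000
    n_burn: int = 2000
    thin: int = 2
    seed: int = 0
    fix_theta: float | None = None  # fix the NB shape (testing / toy oracles)

    def __post_init__(self):
        if self.n_iter <= self.n_burn:
            raise ValueError("n_iter must exceed n_burn")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.n_burn + self.thin - 1) // self.thin


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, shaped (chain, draw, ...)."""

    alpha: np.ndarray  # (C, S, p)
    log_theta: np.ndarray  # (C, S)
    tau: np.ndarray  # (C, S)
    z: np.ndarray  # (C, S, n) — width 0 when the model has no ICAR term
    loglik: np.ndarray  # (C, S) log-likelihood of each retained draw
    coef_names: list[str]
    region_ids: list[str]
    spec: ModelSpec
    seed: int
    accept_rates: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def alpha_flat(self) -> np.ndarray:
        return self.alpha.reshape(-1, self.alpha.shape[2])

    def theta_flat(self) -> np.ndarray:
        return np.exp(self.log_theta.reshape(-1))

    def z_flat(self) -> np.ndarray:
        return self.z.reshape(-1, self.z.shape[2])

    def save(self, prefix) -> None:
        """Persist draws as a flat CSV plus a JSON sidecar."""
        prefix = Path(prefix)
        C, S, p = self.alpha.shape
        cols = {"chain": np.repeat(np.arange(C), S), "draw": np.tile(np.arange(S), C)}
        for j, name in enumerate(self.coef_names):
            cols[f"alpha:{name}"] = self.alpha[:, :, j].reshape(-1)
        cols["log_theta"] = self.log_theta.reshape(-1)
        cols["tau"] = self.tau.reshape(-1)
        for j, rid in enumerate(self.region_ids if self.z.shape[2] else []):
            cols[f"z:{rid}"] = self.z[:, :, j].reshape(-1)
        cols["loglik"] = self.loglik.reshape(-1)
        pd.DataFrame(cols).to_csv(prefix.with_suffix(".csv"), index=False)
        meta = {
            "spec": self.spec.to_string(),
            "coef_names": self.coef_names,
            "region_ids": self.region_ids,
            "seed": self.seed,
            "accept_rates": self.accept_rates,
            "warnings": self.warnings,
            "shape": [C, S, p],
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix) -> "PosteriorSamples":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        df = pd.read_csv(prefix.with_suffix(".csv"))
        C, S, p = meta["shape"]
        alpha = np.stack(
            [df[f"alpha:{n}"].to_numpy().reshape(C, S) for n in meta["coef_names"]], axis=2
        )
        zcols = [c for c in df.columns if c.startswith("z:")]
        z = (
            np.stack([df[c].to_numpy().reshape(C, S) for c in zcols], axis=2)
            if zcols
            else np.zeros((C, S, 0))
        )
        return cls(
            alpha=alpha,
            log_theta=df["log_theta"].to_numpy().reshape(C, S),
            tau=df["tau"].to_numpy().reshape(C, S),
            z=z,
            loglik=df["loglik"].to_numpy().reshape(C, S),
            coef_names=meta["coef_names"],
            region_ids=meta["region_ids"],
            spec=ModelSpec.from_string(meta["spec"]),
            seed=meta["seed"],
            accept_rates=meta["accept_rates"],
            warnings=meta["warnings"],
        )


@dataclass
class FitResult:
    spec: ModelSpec
    samples: PosteriorSamples
    dic: float
    p_d: float
    dbar: float
    diagnostics: pd.DataFrame


class _FitData:
    """Precomputed arrays shared by every chain of one model fit."""

    def __init__(
        self,
        panel: FireCountPanel,
        labels: pd.DataFrame,
        log_areas: np.ndarray,
        graph: AdjacencyGraph,
        spec: ModelSpec,
    ):
        if list(labels["region_id"]) != list(panel.region_ids):
            raise ValueError("labels not aligned with panel region order")
        if spec.include_icar and list(graph.region_ids) != list(panel.region_ids):
            raise ValueError("graph not aligned with panel region order")
        self.spec = spec
        self.n = panel.n_regions
        self.T = panel.n_years
        self.X, self.coef_names = _model.design_for_regions(labels, spec)
        self.p = self.X.shape[1]
        self.m = self.n * 7
        self.log_off = np.repeat(np.asarray(log_areas, dtype=float), 7)
        self.region_of_row = np.repeat(np.arange(self.n), 7)
        Y = panel.counts.reshape(self.m, self.T).astype(float)
        self.Y = Y
        self.Ysum = Y.sum(axis=1)
        self.total = float(Y.sum())
        self.gl_y1 = float(gammaln(Y + 1.0).sum())
        self.region_ids = list(panel.region_ids)
        if spec.include_icar:
            self.ei, self.ej = graph.edge_index_arrays()
            self.n_minus_k = graph.n_minus_k
            self.connected = graph.n_components == 1
            deg = np.zeros(self.n)
            rows, cols, vals = [], [], []
            for a, b in zip(self.ei, self.ej):
                deg[a] += 1
                deg[b] += 1
                rows += [a, b]
                cols += [b, a]
                vals += [1.0, 1.0]
            self.deg = deg
            self.W = csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))
            # region-level design columns (constant across weekdays within a
            # region, e.g. religion/anthrome dummies) are confounded with the
            # spatial field; translation moves sample along that ridge
            X3 = self.X.reshape(self.n, 7, self.p)
            region_const = np.all(X3 == X3[:, :1, :], axis=1).all(axis=0)
            self.trans_cols = []
            ei_, ej_ = self.ei, self.ej
            for j in range(1, self.p):
                if region_const[j]:
                    u = X3[:, 0, j]
                    du = u[ei_] - u[ej_]
                    c2 = float(du @ du)
                    if c2 > 0:
                        self.trans_cols.append((j, u, du, c2))
            coloring = nx.coloring.greedy_color(graph.graph, strategy="largest_first")
            pos = {rid: i for i, rid in enumerate(self.region_ids)}
            colors: dict[int, list[int]] = {}
            for rid, c in coloring.items():
                i = pos[rid]
                if deg[i] > 0:  # isolated nodes keep z = 0
                    colors.setdefault(c, []).append(i)
            self.color_nodes = [np.sort(np.array(v)) for _, v in sorted(colors.items())]
            self.color_rows = [
                (c[:, None] * 7 + np.arange(7)).ravel() for c in self.color_nodes
            ]
            self.color_W = [self.W[c] for c in self.color_nodes]
            comps = [np.array(sorted(pos[r] for r in comp)) for comp in graph.components]
            self.components = [c for c in comps if len(c) > 1]

    # --- likelihood pieces -------------------------------------------------

    def mu_part(self, eta: np.ndarray, theta: float, lt: float) -> float:
        """μ-dependent part of the log-likelihood (θ-terms constant)."""
        lse = np.logaddexp(eta, lt)
        return float(self.Ysum @ eta - (self.Ysum + self.T * theta) @ lse)

    def full_loglik(self, eta: np.ndarray, lt: float) -> float:
        theta = np.exp(lt)
        lse = np.logaddexp(eta, lt)
        return float(
            gammaln(self.Y + theta).sum()
            - self.m * self.T * gammaln(theta)
            - self.gl_y1
            + self.Ysum @ (eta - lse)
            + self.T * theta * (self.m * lt - lse.sum())
        )

    def grad_alpha(self, eta: np.ndarray, theta: float, lt: float, alpha: np.ndarray, inv_avar: float) -> np.ndarray:
        """Gradient of the log-posterior in α at fixed (θ, z)."""
        sig = np.exp(eta - np.logaddexp(eta, lt))  # μ/(μ+θ)
        g_eta = self.Ysum - (self.Ysum + self.T * theta) * sig
        return self.X.T @ g_eta - alpha * inv_avar

    def irls_init(self, theta: float, inv_avar: float, alpha0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Penalised IRLS fit of the NB mean model (z = 0).

        Returns the approximate posterior mode of α and the Cholesky factor
        of the inverse Fisher information, used to initialise chains and to
        precondition the MALA proposal.
        """
        alpha = alpha0.copy()
        y_bar = np.maximum(self.Ysum / self.T, 1e-8)
        ridge = inv_avar * np.eye(self.p)
        for _ in range(12):
            eta = np.clip(self.log_off + self.X @ alpha, -30.0, 30.0)
            mu = np.exp(eta)
            w = mu * theta / (mu + theta)  # NB Fisher weight, log link
            work = (eta - self.log_off) + (y_bar - mu) / mu
            F = (self.X * w[:, None]).T @ self.X + ridge
            alpha_new = np.linalg.solve(F, (self.X * w[:, None]).T @ work)
            if not np.all(np.isfinite(alpha_new)):
                break
            if np.max(np.abs(alpha_new - alpha)) < 1e-8:
                alpha = alpha_new
                break
            alpha = alpha_new
        eta = np.clip(self.log_off + self.X @ alpha, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu * theta / (mu + theta)
        F = (self.X * w[:, None]).T @ self.X + ridge
        chol = np.linalg.cholesky(np.linalg.inv(F))
        return alpha, chol


def _run_chain(data: _FitData, priors: PriorSpec, cfg: MCMCConfig, seed_seq) -> dict:
    rng = np.random.default_rng(seed_seq)
    n, p, T = data.n, data.p, data.T
    icar = data.spec.include_icar

    inv_avar = 1.0 / priors.alpha_sd**2
    alpha0 = np.zeros(p)
    mean_count = max(data.total / (data.m * T), 0.1)
    alpha0[0] = np.log(mean_count) - np.mean(data.log_off)
    lt = np.log(cfg.fix_theta) if cfg.fix_theta is not None else 0.0
    theta = np.exp(lt)
    try:
        alpha, chol = data.irls_init(theta, inv_avar, alpha0)
    except np.linalg.LinAlgError:
        alpha, chol = alpha0, np.eye(p)
    alpha = alpha + 0.05 * (chol @ rng.standard_normal(p))  # overdisperse chain starts
    tau = 1.0
    z = np.zeros(n)
    eta_fixed = data.log_off + data.X @ alpha
    eta = eta_fixed + (z[data.region_of_row] if icar else 0.0)

    cur_mu_ll = data.mu_part(eta, theta, lt)
    if not np.isfinite(cur_mu_ll):
        raise RuntimeError(
            f"non-finite posterior at initialisation (alpha0={alpha[0]:.3f}); "
            "check counts and offsets"
        )

    # adaptation state
    log_step = np.log(1.2)  # MALA step in preconditioned coordinates
    a_mean = alpha.copy()
    a_M2 = np.zeros((p, p))
    lt_step = 0.3
    z_steps = [0.5] * (len(data.color_nodes) if icar else 0)
    trans_steps = [0.5] * (len(data.trans_cols) if icar else 0)
    acc = {"alpha": 0, "theta": 0, "z": 0.0, "z_n": 0}

    S = cfg.n_draws
    out_alpha = np.empty((S, p))
    out_lt = np.empty(S)
    out_tau = np.empty(S)
    out_z = np.empty((S, n if icar else 0))
    out_ll = np.empty(S)
    s_idx = 0

    from scipy.linalg import solve_triangular

    for t in range(cfg.n_iter):
        adapting = t < cfg.n_burn

        # --- alpha block: preconditioned MALA ------------------------------
        # (θ, z and the recentering shift all change the gradient, so it is
        # recomputed each sweep rather than cached across blocks)
        cur_grad = data.grad_alpha(eta, theta, lt, alpha, inv_avar)
        step = np.exp(log_step)
        half = 0.5 * step * step
        xi = rng.standard_normal(p)
        drift = chol @ (chol.T @ cur_grad)
        prop = alpha + half * drift + step * (chol @ xi)
        eta_fixed_prop = data.log_off + data.X @ prop
        eta_prop = eta_fixed_prop + (z[data.region_of_row] if icar else 0.0)
        new_mu_ll = data.mu_part(eta_prop, theta, lt)
        accepted = False
        if np.isfinite(new_mu_ll):
            prop_grad = data.grad_alpha(eta_prop, theta, lt, prop, inv_avar)
            back = alpha - prop - half * (chol @ (chol.T @ prop_grad))
            xi_back = solve_triangular(chol, back, lower=True) / step
            delta = (
                new_mu_ll
                - cur_mu_ll
                - 0.5 * inv_avar * (prop @ prop - alpha @ alpha)
                + 0.5 * (xi @ xi - xi_back @ xi_back)
            )
            accepted = np.log(rng.random()) < delta
        if accepted:
            alpha, eta_fixed, eta = prop, eta_fixed_prop, eta_prop
            cur_mu_ll = new_mu_ll
            if t >= cfg.n_burn:
                acc["alpha"] += 1
        if adapting:
            log_step += min(0.05, 2.0 / np.sqrt(t + 1)) * ((1.0 if accepted else 0.0) - 0.574)

        # --- theta block ---------------------------------------------------
        if cfg.fix_theta is None:
            lt_prop = lt + lt_step * rng.standard_normal()
            cur_full = data.full_loglik(eta, lt)
            new_full = data.full_loglik(eta, lt_prop)
            delta = (
                new_full
                - cur_full
                - 0.5 * ((lt_prop - priors.log_theta_mean) ** 2 - (lt - priors.log_theta_mean) ** 2)
                / priors.log_theta_sd**2
            )
            accepted = np.log(rng.random()) < delta
            if accepted:
                lt = lt_prop
                theta = np.exp(lt)
                cur_mu_ll = data.mu_part(eta, theta, lt)
                if t >= cfg.n_burn:
                    acc["theta"] += 1
            if adapting:
                lt_step *= np.exp(min(0.05, 2.0 / np.sqrt(t + 1)) * ((1.0 if accepted else 0.0) - 0.44))

        # --- z blocks (colour classes) ------------------------------------
        if icar:
            ys_t = data.Ysum + T * theta
            for ci, nodes in enumerate(data.color_nodes):
                rows = data.color_rows[ci]
                zc = z[nodes]
                d = z_steps[ci] * rng.standard_normal(len(nodes))
                zc_prop = zc + d
                eta_old = eta[rows]
                eta_new = eta_old + np.repeat(d, 7)
                dll = (
                    data.Ysum[rows] * (eta_new - eta_old)
                    - ys_t[rows] * (np.logaddexp(eta_new, lt) - np.logaddexp(eta_old, lt))
                ).reshape(-1, 7).sum(axis=1)
                s_nbr = data.color_W[ci] @ z
                dprior = -0.5 * tau * (data.deg[nodes] * (zc_prop**2 - zc**2) - 2.0 * d * s_nbr)
                mask = np.log(rng.random(len(nodes))) < dll + dprior
                if np.any(mask):
                    z[nodes[mask]] = zc_prop[mask]
                    upd = (nodes[mask][:, None] * 7 + np.arange(7)).ravel()
                    eta[upd] += np.repeat(d[mask], 7)
                if t >= cfg.n_burn:
                    acc["z"] += float(mask.sum())
                    acc["z_n"] += len(nodes)
                if adapting:
                    rate = float(mask.mean()) if len(nodes) else 0.44
                    z_steps[ci] *= np.exp(min(0.05, 2.0 / np.sqrt(t + 1)) * (rate - 0.44))

            cur_mu_ll = data.mu_part(eta, theta, lt)  # z moved; refresh cache

            # --- translation moves along the confounding ridge -------------
            # shift mass between a region-level coefficient and the spatial
            # field; the likelihood is exactly invariant (η unchanged), so
            # acceptance depends only on the ICAR and coefficient priors
            for k, (j, u, du, c2) in enumerate(data.trans_cols):
                d = trans_steps[k] * rng.standard_normal()
                zd = z[data.ei] - z[data.ej]
                c1 = float(zd @ du)
                dq = -2.0 * d * c1 + d * d * c2
                delta = -0.5 * tau * dq - 0.5 * inv_avar * (2.0 * alpha[j] * d + d * d)
                t_acc = np.log(rng.random()) < delta
                if t_acc:
                    alpha[j] += d
                    z -= d * u
                    eta_fixed += d * data.X[:, j]  # η itself is unchanged
                if adapting:
                    trans_steps[k] *= np.exp(
                        min(0.05, 2.0 / np.sqrt(t + 1)) * ((1.0 if t_acc else 0.0) - 0.44)
                    )

            # --- tau: conjugate Gibbs -------------------------------------
            q = float(np.sum((z[data.ei] - z[data.ej]) ** 2))
            tau = rng.gamma(priors.tau_shape + 0.5 * data.n_minus_k, 1.0 / (priors.tau_rate + 0.5 * q))

            # --- recenter per component -----------------------------------
            if data.connected:
                m0 = z.mean()
                z -= m0
                alpha[0] += m0
                eta_fixed += m0  # eta unchanged: shift moved from z to intercept
            else:
                for comp in data.components:
                    z[comp] -= z[comp].mean()
                eta = eta_fixed + z[data.region_of_row]
                cur_mu_ll = data.mu_part(eta, theta, lt)

        if t >= cfg.n_burn and (t - cfg.n_burn) % cfg.thin == 0:
            out_alpha[s_idx] = alpha
            out_lt[s_idx] = lt
            out_tau[s_idx] = tau
            if icar:
                out_z[s_idx] = z
            out_ll[s_idx] = data.full_loglik(eta, lt)
            s_idx += 1

    kept = cfg.n_iter - cfg.n_burn
    return {
        "alpha": out_alpha[:s_idx],
        "log_theta": out_lt[:s_idx],
        "tau": out_tau[:s_idx],
        "z": out_z[:s_idx],
        "loglik": out_ll[:s_idx],
        "acc_alpha": acc["alpha"] / kept,
        "acc_theta": acc["theta"] / kept if cfg.fix_theta is None else float("nan"),
        "acc_z": acc["z"] / acc["z_n"] if acc["z_n"] else float("nan"),
        "steps": {
            "alpha": float(np.exp(log_step)),
            "lt": float(lt_step),
            "z": [float(s) for s in z_steps],
            "trans": [float(s) for s in trans_steps],
        },
    }


def fit_mcmc(
    panel: FireCountPanel,
    labels: pd.DataFrame,
    log_areas: np.ndarray,
    graph: AdjacencyGraph,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorSamples:
    """Draw from the posterior of one candidate model.

    Deterministic given ``config.seed`` (chains use independent spawned
    streams).  For models without the ICAR term the spatial field stays at
    zero and ``τ`` is never updated.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    data = _FitData(panel, labels, log_areas, graph, spec)
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [_run_chain(data, priors, config, s) for s in seqs]
    samples = PosteriorSamples(
        alpha=np.stack([c["alpha"] for c in chains]),
        log_theta=np.stack([c["log_theta"] for c in chains]),
        tau=np.stack([c["tau"] for c in chains]),
        z=np.stack([c["z"] for c in chains]),
        loglik=np.stack([c["loglik"] for c in chains]),
        coef_names=data.coef_names,
        region_ids=data.region_ids,
        spec=spec,
        seed=config.seed,
        accept_rates={
            name: (float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan"))
            for name, vals in (
                ("alpha", [c["acc_alpha"] for c in chains]),
                ("theta", [c["acc_theta"] for c in chains]),
                ("z", [c["acc_z"] for c in chains]),
            )
        },
    )
    if samples.n_chains >= 2:
        rhats = np.atleast_1d(az.rhat(az.convert_to_dataset(samples.alpha))["x"].values)
        worst = float(np.nanmax(rhats))
        if worst > 1.1:
            msg = f"max split R-hat {worst:.3f} > 1.1; chains may not have converged"
            samples.warnings.append(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return samples


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for (chain, draw) draws."""
    return float(az.rhat(az.convert_to_dataset(np.asarray(draws)))["x"].values)


def effective_sample_size(draws: np.ndarray) -> float:
    return float(az.ess(az.convert_to_dataset(np.asarray(draws)))["x"].values)


def compute_dic(
    samples: PosteriorSamples,
    panel: FireCountPanel,
    spec: ModelSpec,
    labels: pd.DataFrame,
    log_areas: np.ndarray,
) -> tuple[float, float, float]:
    """Deviance information criterion ``(dic, p_d, dbar)``.

    ``dbar`` is the posterior mean of the deviance ``D = −2·loglik``
    (conditional on the spatial field); ``p_d = dbar − D(point)`` with the
    point estimate taken at the posterior means of ``α`` and ``z`` and at
    ``θ = exp(mean ln θ)``.
    """
    if samples.loglik.size < 100:
        raise ValueError("DIC requires at least 100 retained draws")
    dbar = float(np.mean(-2.0 * samples.loglik))
    alpha_bar = samples.alpha.reshape(-1, samples.alpha.shape[2]).mean(axis=0)
    theta_point = float(np.exp(samples.log_theta.mean()))
    z_bar = (
        samples.z.reshape(-1, samples.z.shape[2]).mean(axis=0)
        if samples.z.shape[2]
        else np.zeros(panel.n_regions)
    )
    point = Parameters(alpha=alpha_bar, theta=theta_point, tau=float(samples.tau.mean()), z=z_bar)
    d_point = -2.0 * _model.log_likelihood(panel, spec, point, labels, log_areas)
    p_d = dbar - d_point
    return dbar + p_d, p_d, dbar


def posterior_summary(samples: PosteriorSamples, transform=None) -> pd.DataFrame:
    """Per-parameter mean, sd, equal-tailed 95% CI, split R-hat and ESS."""
    p = samples.alpha.shape[2]
    tracked = [(samples.coef_names[j], samples.alpha[:, :, j]) for j in range(p)]
    tracked.append(("theta", np.exp(samples.log_theta)))
    if samples.z.shape[2]:
        tracked.append(("tau", samples.tau))
    if transform is not None:
        tracked = [(name, np.asarray(transform(d))) for name, d in tracked]
    stacked = np.stack([d for _, d in tracked], axis=2)  # (C, S, k)
    if samples.n_chains >= 2:
        ds = az.convert_to_dataset(stacked)
        rhats = np.atleast_1d(az.rhat(ds)["x"].values)
        esss = np.atleast_1d(az.ess(ds)["x"].values)
    else:
        rhats = esss = np.full(len(tracked), np.nan)
    rows = []
    for k, (name, draws) in enumerate(tracked):
        flat = draws.reshape(-1)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append((name, flat.mean(), flat.std(ddof=1), lo, hi, float(rhats[k]), float(esss[k])))
    return pd.DataFrame(
        rows, columns=["parameter", "mean", "sd", "ci_low", "ci_high", "rhat", "ess"]
    )


def select_model(
    panel: FireCountPanel,
    labels: pd.DataFrame,
    log_areas: np.ndarray,
    graph: AdjacencyGraph,
    candidates: Sequence[ModelSpec | str],
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> tuple[pd.DataFrame, ModelSpec, dict[str, FitResult]]:
    """Fit every candidate and rank by DIC (ascending; lowest wins).

    Failed candidates are recorded with a warning and excluded from the
    ranking.  Returns the ranked table, the best spec, and the fits.
    """
    specs = [ModelSpec.from_string(c) if isinstance(c, str) else c for c in candidates]
    if len(specs) < 1:
        raise ValueError("need at least one candidate model")
    rows = []
    fits: dict[str, FitResult] = {}
    for spec in specs:
        try:
            samples = fit_mcmc(panel, labels, log_areas, graph, spec, priors, config)
            dic, p_d, dbar = compute_dic(samples, panel, spec, labels, log_areas)
            diag = posterior_summary(samples)
            fits[spec.to_string()] = FitResult(spec, samples, dic, p_d, dbar, diag)
            rows.append((spec.to_string(), dic, p_d, dbar))
        except Exception as exc:  # noqa: BLE001 - candidate failure is recoverable
            warnings.warn(f"candidate {spec.to_string()!r} failed: {exc}", RuntimeWarning, stacklevel=2)
    if not rows:
        raise RuntimeError("every candidate model failed to fit")
    table = pd.DataFrame(rows, columns=["model", "dic", "p_d", "dbar"]).sort_values(
        "dic", kind="stable", ignore_index=True
    )
    best = ModelSpec.from_string(table.loc[0, "model"])
    return table, best, fits
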