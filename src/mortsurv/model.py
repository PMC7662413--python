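"""Hierarchical Bayesian Poisson model for small-area mortality, fitted by MCMC.

The death count in cell (area i, age group j, year t) is modelled as

    y_ijt ~ Poisson(lambda_ijt * Pop_ijt)
    log lambda_ijt = a0 + alpha_j + gamma_i + zeta_t + phi_d(i)
                     + omega_it + delta_ij + kappa_jt + nu_d(i),t

where d(i) is the deprivation decile of area i. Priors: first-order random
walks (RW1) on the age, year and decile main effects alpha, zeta, phi and on
the time profiles of the age-time (kappa) and decile-time (nu) interactions;
an intrinsic conditional autoregressive (ICAR) prior on the spatial effect
gamma; exchangeable (i.i.d.) normal priors on the unstructured space-time
(omega) and space-age (delta) interactions; a vague normal prior on the
intercept a0; Gamma hyperpriors on every precision.

Inference is Metropolis-within-Gibbs: precisions have conjugate Gamma full
conditionals; each Gaussian field is updated by vectorized single-site
Metropolis moves (elements whose full conditionals are mutually independent
— a graph-coloring / odd-even schedule for the structured priors — are
proposed simultaneously), with per-field step sizes adapted during burn-in
only. Sum-to-zero constraints are enforced after every sweep by re-centering
each component and transferring the removed means up the hierarchy (into the
parent main effect or the intercept) so that the linear predictor, and hence
the likelihood, is unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import AdjacencyGraph, MortalityDataset

__all__ = [
    "Components",
    "ModelConfig",
    "PosteriorSamples",
    "rw1_structure",
    "icar_structure",
    "linear_predictor",
    "eta_grid",
    "log_likelihood",
    "fit",
    "convergence_report",
]

FIELD_NAMES = ("alpha", "gamma", "zeta", "phi", "omega", "delta", "kappa", "nu")
PRECISION_NAMES = tuple(f"tau_{f}" for f in FIELD_NAMES)


def rw1_structure(n: int) -> np.ndarray:
    """RW1 precision structure matrix: quadratic form sum_k (x[k+1]-x[k])^2.

    Tridiagonal, rank n-1, null space spanned by the constant vector.
    """
    if n < 2:
        raise ValueError("RW1 structure requires n >= 2")
    r = np.zeros((n, n))
    idx = np.arange(n - 1)
    r[idx, idx] += 1.0
    r[idx + 1, idx + 1] += 1.0
    r[idx, idx + 1] -= 1.0
    r[idx + 1, idx] -= 1.0
    return r


def icar_structure(graph: AdjacencyGraph) -> np.ndarray:
    """Graph Laplacian: degree on the diagonal, -1 per edge.

    Quadratic form sum over edges (x_i - x_j)^2; rank = nodes - components.
    """
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    lap = np.zeros((n, n))
    for i, j in graph.edges():
        lap[i, i] += 1.0
        lap[j, j] += 1.0
        lap[i, j] -= 1.0
        lap[j, i] -= 1.0
    return lap


@dataclass
class Components:
    """One realization (draw or truth) of every model component.

    ``decile_index`` is the 0-based decile of each area, resolving the
    deprivation subscript d(i).
    """

    a0: float
    alpha: np.ndarray  # (J,)
    gamma: np.ndarray  # (I,)
    zeta: np.ndarray   # (T,)
    phi: np.ndarray    # (D,)
    omega: np.ndarray  # (I, T)
    delta: np.ndarray  # (I, J)
    kappa: np.ndarray  # (J, T)
    nu: np.ndarray     # (D, T)
    decile_index: np.ndarray  # (I,)

    @classmethod
    def zeros(cls, I: int, J: int, T: int, D: int, decile_index, a0: float = 0.0):
        return cls(
            a0=a0, alpha=np.zeros(J), gamma=np.zeros(I), zeta=np.zeros(T),
            phi=np.zeros(D), omega=np.zeros((I, T)), delta=np.zeros((I, J)),
            kappa=np.zeros((J, T)), nu=np.zeros((D, T)),
            decile_index=np.asarray(decile_index, dtype=int),
        )


def linear_predictor(components: Components, i: int, j: int, t: int) -> float:
    """Log mortality rate for one cell; d is resolved through the area's decile."""
    c = components
    I, T = c.omega.shape
    J = c.alpha.shape[0]
    if not (0 <= i < I and 0 <= j < J and 0 <= t < T):
        raise IndexError(f"cell index ({i}, {j}, {t}) out of range")
    d = int(c.decile_index[i])
    return float(
        c.a0 + c.alpha[j] + c.gamma[i] + c.zeta[t] + c.phi[d]
        + c.omega[i, t] + c.delta[i, j] + c.kappa[j, t] + c.nu[d, t]
    )


def eta_grid(components: Components) -> np.ndarray:
    """Full (I, J, T) grid of log rates; vectorized form of linear_predictor."""
    c = components
    d = c.decile_index
    return (
        c.a0
        + c.alpha[None, :, None]
        + c.gamma[:, None, None]
        + c.zeta[None, None, :]
        + c.phi[d][:, None, None]
        + c.omega[:, None, :]
        + c.delta[:, :, None]
        + c.kappa[None, :, :]
        + c.nu[d][:, None, :]
    )


def log_likelihood(components: Components, data: MortalityDataset) -> float:
    """Poisson log likelihood over cells with positive population.

    Cells with zero population contribute exactly zero.
    """
    eta = eta_grid(components)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    mask = data.population > 0
    mu = np.exp(eta[mask]) * data.population[mask]
    y = data.deaths[mask]
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


@dataclass
class ModelConfig:
    """Hyperpriors, constraint tolerance and MCMC settings.

    Precisions get Gamma(shape, rate) hyperpriors; the intercept a0 a normal
    prior with mean 0 and variance ``intercept_prior_var``. ``n_iter`` kept
    draws per chain follow ``burn_in`` adaptation iterations; adaptation
    targets acceptance rate ``target_accept`` and is frozen after burn-in.
    """

    prior_shape: float = 1.0
    prior_rate: float = 0.01
    intercept_prior_var: float = 1.0e6
    constraint_tol: float = 1.0e-8
    n_chains: int = 2
    burn_in: int = 500
    n_iter: int = 500
    thin: int = 1
    target_accept: float = 0.44
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 100:
            raise ValueError("at least 100 kept iterations per chain are required")
        if self.prior_shape <= 0 or self.prior_rate <= 0 or self.intercept_prior_var <= 0:
            raise ValueError("hyperprior parameters must be positive")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")
        if self.thin < 1 or self.n_chains < 1 or self.burn_in < 0:
            raise ValueError("invalid MCMC settings")


@dataclass
class PosteriorSamples:
    """S kept MCMC draws of every component and precision, across chains.

    Field arrays are stacked over chains in order; ``chain`` labels each draw.
    """

    a0: np.ndarray            # (S,)
    alpha: np.ndarray         # (S, J)
    gamma: np.ndarray         # (S, I)
    zeta: np.ndarray          # (S, T)
    phi: np.ndarray           # (S, D)
    omega: np.ndarray         # (S, I, T)
    delta: np.ndarray         # (S, I, J)
    kappa: np.ndarray         # (S, J, T)
    nu: np.ndarray            # (S, D, T)
    precisions: dict[str, np.ndarray]  # name -> (S,)
    chain: np.ndarray         # (S,) chain index per draw
    acceptance: dict[str, float]       # mean post-burn-in acceptance per block
    area_ids: list[str]
    age_groups: list[tuple[int, int | None]]
    years: list[int]
    decile_index: np.ndarray  # (I,)
    sex: str = "female"

    @property
    def n_draws(self) -> int:
        return self.a0.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain.max()) + 1 if self.n_draws else 0

    def draw(self, s: int) -> Components:
        return Components(
            a0=float(self.a0[s]), alpha=self.alpha[s], gamma=self.gamma[s],
            zeta=self.zeta[s], phi=self.phi[s], omega=self.omega[s],
            delta=self.delta[s], kappa=self.kappa[s], nu=self.nu[s],
            decile_index=self.decile_index,
        )

    def save(self, directory) -> None:
        """Persist as per-component flat CSV tables plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "n_draws": int(self.n_draws),
            "sex": self.sex,
            "area_ids": list(self.area_ids),
            "age_groups": [[g[0], g[1]] for g in self.age_groups],
            "years": [int(y) for y in self.years],
            "decile_index": [int(d) for d in self.decile_index],
            "acceptance": {k: float(v) for k, v in self.acceptance.items()},
            "components": {},
        }
        arrays = {"a0": self.a0[:, None], "chain": self.chain[:, None]}
        for name in FIELD_NAMES:
            arr = getattr(self, name)
            arrays[name] = arr.reshape(self.n_draws, -1)
            manifest["components"][name] = list(arr.shape[1:])
        for name, vals in self.precisions.items():
            arrays[name] = vals[:, None]
        for name, flat in arrays.items():
            pd.DataFrame(flat).to_csv(directory / f"{name}.csv", index=False)
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        S = manifest["n_draws"]

        def arr(name):
            return pd.read_csv(directory / f"{name}.csv").to_numpy()

        fields = {}
        for name in FIELD_NAMES:
            shape = tuple(manifest["components"][name])
            fields[name] = arr(name).reshape((S, *shape))
        precisions = {p: arr(p)[:, 0] for p in PRECISION_NAMES}
        return cls(
            a0=arr("a0")[:, 0], precisions=precisions,
            chain=arr("chain")[:, 0].astype(int),
            acceptance=manifest["acceptance"],
            area_ids=manifest["area_ids"],
            age_groups=[(g[0], g[1]) for g in manifest["age_groups"]],
            years=manifest["years"],
            decile_index=np.array(manifest["decile_index"], dtype=int),
            sex=manifest["sex"],
            **fields,
        )


def _checkerboard(n: int) -> list[np.ndarray]:
    idx = np.arange(n)
    return [idx[idx % 2 == 0], idx[idx % 2 == 1]]


def _graph_coloring(graph: AdjacencyGraph) -> list[np.ndarray]:
    import networkx as nx

    coloring = nx.coloring.greedy_color(graph.to_networkx(), strategy="largest_first")
    n_colors = max(coloring.values()) + 1
    return [
        np.array(sorted(i for i, c in coloring.items() if c == col), dtype=int)
        for col in range(n_colors)
    ]


class _StepSize:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, init: float, target: float):
        self.log_s = np.log(init)
        self.target = target
        self.k = 0

    @property
    def value(self) -> float:
        return float(np.exp(self.log_s))

    def adapt(self, accept_rate: float) -> None:
        self.k += 1
        self.log_s += (accept_rate - self.target) / np.sqrt(self.k)
        self.log_s = float(np.clip(self.log_s, -12.0, 3.0))


class _ChainState:
    """Mutable sampler state for a single chain."""

    def __init__(self, data: MortalityDataset, graph: AdjacencyGraph,
                 config: ModelConfig, rng: np.random.Generator):
        self.rng = rng
        self.cfg = config
        I, J, T = data.deaths.shape
        D = data.n_deciles
        self.I, self.J, self.T, self.D = I, J, T, D
        self.dix = data.decile_index
        self.y = data.deaths.astype(float)
        self.pop = data.population
        self.mask = self.pop > 0

        # decile membership indicator (D, I)
        self.Z = np.zeros((D, I))
        self.Z[self.dix, np.arange(I)] = 1.0

        # structure matrices and their diagonals
        self.R_J = rw1_structure(J)
        self.R_T = rw1_structure(T)
        self.R_D = rw1_structure(D)
        self.L = icar_structure(graph)
        self.colors = _graph_coloring(graph)
        self.par_J = _checkerboard(J)
        self.par_T = _checkerboard(T)
        self.par_D = _checkerboard(D)

        # fixed data aggregates of y
        self.Y_j = self.y.sum(axis=(0, 2))
        self.Y_i = self.y.sum(axis=(1, 2))
        self.Y_t = self.y.sum(axis=(0, 1))
        self.Y_it = self.y.sum(axis=1)
        self.Y_ij = self.y.sum(axis=2)
        self.Y_jt = self.y.sum(axis=0)
        self.Y_d = self.Z @ self.Y_i
        self.Y_dt = self.Z @ self.Y_it
        self.Y_tot = self.y.sum()

        # initial state: empirical intercept, flat fields, moderate precisions
        total_pop = self.pop.sum()
        crude = max(self.y.sum(), 0.5) / total_pop
        self.c = Components.zeros(I, J, T, D, self.dix, a0=float(np.log(crude)))
        self.tau = {name: 10.0 for name in PRECISION_NAMES}

        # prior ranks for the conjugate Gamma updates (dimension of the
        # constrained support of each intrinsic / centered component)
        self.rank = {
            "tau_alpha": J - 1, "tau_zeta": T - 1, "tau_phi": D - 1,
            "tau_gamma": I - graph.n_components(),
            "tau_omega": I * T - 1, "tau_delta": I * J - 1,
            "tau_kappa": (J - 1) * (T - 1), "tau_nu": (D - 1) * (T - 1),
        }

        self.mu = np.where(self.mask, np.exp(eta_grid(self.c)) * self.pop, 0.0)
        self.steps = {
            name: _StepSize(0.1, config.target_accept)
            for name in ("a0",) + FIELD_NAMES
        }
        self.accept_log = {name: [] for name in self.steps}

    # ---- quadratic forms -------------------------------------------------
    def _quad(self, name: str) -> float:
        c = self.c
        if name == "tau_alpha":
            return float(c.alpha @ self.R_J @ c.alpha)
        if name == "tau_zeta":
            return float(c.zeta @ self.R_T @ c.zeta)
        if name == "tau_phi":
            return float(c.phi @ self.R_D @ c.phi)
        if name == "tau_gamma":
            return float(c.gamma @ self.L @ c.gamma)
        if name == "tau_omega":
            return float(np.sum(c.omega ** 2))
        if name == "tau_delta":
            return float(np.sum(c.delta ** 2))
        if name == "tau_kappa":
            return float(np.sum((c.kappa @ self.R_T) * c.kappa))
        if name == "tau_nu":
            return float(np.sum((c.nu @ self.R_T) * c.nu))
        raise KeyError(name)

    def update_precisions(self) -> None:
        for name in PRECISION_NAMES:
            shape = self.cfg.prior_shape + 0.5 * self.rank[name]
            rate = self.cfg.prior_rate + 0.5 * self._quad(name)
            self.tau[name] = float(self.rng.gamma(shape, 1.0 / rate))

    # ---- Metropolis updates ---------------------------------------------
    def _mh_subset(self, x, sel, Yagg, Magg, prior_delta, step, scale_mu):
        """Vectorized single-site MH on x[sel]; returns acceptance count."""
        d = np.zeros_like(x)
        d[sel] = self.rng.normal(0.0, step, size=np.shape(x[sel]))
        logr = Yagg * d - Magg * np.expm1(d) + prior_delta(d)
        u = np.log(self.rng.random(size=np.shape(x)))
        acc = (u < logr) & (d != 0.0)
        if np.any(acc):
            dx = np.where(acc, d, 0.0)
            x += dx
            scale_mu(dx)
        sel_size = np.size(x[sel])
        return int(np.count_nonzero(acc)), sel_size

    def update_a0(self) -> float:
        step = self.steps["a0"].value
        d = float(self.rng.normal(0.0, step))
        a0_new = self.c.a0 + d
        logr = (
            self.Y_tot * d - self.mu.sum() * np.expm1(d)
            - 0.5 * (a0_new ** 2 - self.c.a0 ** 2) / self.cfg.intercept_prior_var
        )
        if np.log(self.rng.random()) < logr:
            self.c.a0 = a0_new
            self.mu *= np.exp(d)
            return 1.0
        return 0.0

    def update_alpha(self) -> float:
        c, tau = self.c, self.tau["tau_alpha"]
        n_acc = n_tot = 0
        step = self.steps["alpha"].value
        for sel in self.par_J:
            M_j = self.mu.sum(axis=(0, 2))
            q = self.R_J @ c.alpha
            diag = np.diag(self.R_J)

            def prior_delta(d):
                return -0.5 * tau * (2.0 * d * q + diag * d ** 2)

            def scale(dx):
                self.mu *= np.exp(dx)[None, :, None]

            a, t = self._mh_subset(c.alpha, sel, self.Y_j, M_j, prior_delta, step, scale)
            n_acc += a
            n_tot += t
        return n_acc / n_tot

    def update_zeta(self) -> float:
        c, tau = self.c, self.tau["tau_zeta"]
        n_acc = n_tot = 0
        step = self.steps["zeta"].value
        for sel in self.par_T:
            M_t = self.mu.sum(axis=(0, 1))
            q = self.R_T @ c.zeta
            diag = np.diag(self.R_T)

            def prior_delta(d):
                return -0.5 * tau * (2.0 * d * q + diag * d ** 2)

            def scale(dx):
                self.mu *= np.exp(dx)[None, None, :]

            a, t = self._mh_subset(c.zeta, sel, self.Y_t, M_t, prior_delta, step, scale)
            n_acc += a
            n_tot += t
        return n_acc / n_tot

    def update_phi(self) -> float:
        c, tau = self.c, self.tau["tau_phi"]
        n_acc = n_tot = 0
        step = self.steps["phi"].value
        for sel in self.par_D:
            M_i = self.mu.sum(axis=(1, 2))
            M_d = self.Z @ M_i
            q = self.R_D @ c.phi
            diag = np.diag(self.R_D)

            def prior_delta(d):
                return -0.5 * tau * (2.0 * d * q + diag * d ** 2)

            def scale(dx):
                self.mu *= np.exp(dx[self.dix])[:, None, None]

            a, t = self._mh_subset(c.phi, sel, self.Y_d, M_d, prior_delta, step, scale)
            n_acc += a
            n_tot += t
        return n_acc / n_tot

    def update_gamma(self) -> float:
        c, tau = self.c, self.tau["tau_gamma"]
        n_acc = n_tot = 0
        step = self.steps["gamma"].value
        diag = np.diag(self.L)
        for sel in self.colors:
            M_i = self.mu.sum(axis=(1, 2))
            q = self.L @ c.gamma

            def prior_delta(d):
                return -0.5 * tau * (2.0 * d * q + diag * d ** 2)

            def scale(dx):
                self.mu *= np.exp(dx)[:, None, None]

            a, t = self._mh_subset(c.gamma, sel, self.Y_i, M_i, prior_delta, step, scale)
            n_acc += a
            n_tot += t
        return n_acc / n_tot

    def update_omega(self) -> float:
        c, tau = self.c, self.tau["tau_omega"]
        step = self.steps["omega"].value
        M_it = self.mu.sum(axis=1)
        sel = np.ones_like(c.omega, dtype=bool)

        def prior_delta(d):
            return -0.5 * tau * (2.0 * c.omega * d + d ** 2)

        def scale(dx):
            self.mu *= np.exp(dx)[:, None, :]

        a, t = self._mh_subset(c.omega, sel, self.Y_it, M_it, prior_delta, step, scale)
        return a / t

    def update_delta(self) -> float:
        c, tau = self.c, self.tau["tau_delta"]
        step = self.steps["delta"].value
        M_ij = self.mu.sum(axis=2)
        sel = np.ones_like(c.delta, dtype=bool)

        def prior_delta(d):
            return -0.5 * tau * (2.0 * c.delta * d + d ** 2)

        def scale(dx):
            self.mu *= np.exp(dx)[:, :, None]

        a, t = self._mh_subset(c.delta, sel, self.Y_ij, M_ij, prior_delta, step, scale)
        return a / t

    def update_kappa(self) -> float:
        c, tau = self.c, self.tau["tau_kappa"]
        n_acc = n_tot = 0
        step = self.steps["kappa"].value
        diag = np.diag(self.R_T)
        for tsel in self.par_T:
            sel = np.zeros_like(c.kappa, dtype=bool)
            sel[:, tsel] = True
            M_jt = self.mu.sum(axis=0)
            q = c.kappa @ self.R_T

            def prior_delta(d):
                return -0.5 * tau * (2.0 * d * q + diag[None, :] * d ** 2)

            def scale(dx):
                self.mu *= np.exp(dx)[None, :, :]

            a, t = self._mh_subset(c.kappa, sel, self.Y_jt, M_jt, prior_delta, step, scale)
            n_acc += a
            n_tot += t
        return n_acc / n_tot

    def update_nu(self) -> float:
        c, tau = self.c, self.tau["tau_nu"]
        n_acc = n_tot = 0
        step = self.steps["nu"].value
        diag = np.diag(self.R_T)
        for tsel in self.par_T:
            sel = np.zeros_like(c.nu, dtype=bool)
            sel[:, tsel] = True
            M_it = self.mu.sum(axis=1)
            M_dt = self.Z @ M_it
            q = c.nu @ self.R_T

            def prior_delta(d):
                return -0.5 * tau * (2.0 * d * q + diag[None, :] * d ** 2)

            def scale(dx):
                self.mu *= np.exp(dx[self.dix])[:, None, :]

            a, t = self._mh_subset(c.nu, sel, self.Y_dt, M_dt, prior_delta, step, scale)
            n_acc += a
            n_tot += t
        return n_acc / n_tot

    # ---- constraints -----------------------------------------------------
    def recenter(self) -> None:
        """Enforce sum-to-zero constraints, keeping the linear predictor fixed.

        Means removed from interactions are transferred into the matching
        main effects, and main-effect means into the intercept, so eta (and
        the likelihood, and mu) are exactly unchanged.
        """
        c = self.c
        # joint (grand-mean) centering of the unstructured interactions
        for f in ("omega", "delta"):
            arr = getattr(c, f)
            g = arr.mean()
            arr -= g
            c.a0 += g
        # double centering of the structured interactions
        for f, main in (("kappa", "alpha"), ("nu", "phi")):
            arr = getattr(c, f)
            r = arr.mean(axis=1)           # per-row mean over t
            col = arr.mean(axis=0)         # per-t mean over rows
            g = arr.mean()
            arr -= r[:, None]
            arr -= col[None, :]
            arr += g
            getattr(c, main)[:] += r
            c.zeta += col
            c.a0 -= g
        # main effects into the intercept
        for f in ("alpha", "gamma", "zeta", "phi"):
            arr = getattr(c, f)
            m = arr.mean()
            arr -= m
            c.a0 += m

    def sweep(self, adapting: bool) -> None:
        rates = {
            "a0": self.update_a0(),
            "alpha": self.update_alpha(),
            "gamma": self.update_gamma(),
            "zeta": self.update_zeta(),
            "phi": self.update_phi(),
            "omega": self.update_omega(),
            "delta": self.update_delta(),
            "kappa": self.update_kappa(),
            "nu": self.update_nu(),
        }
        self.recenter()
        self.update_precisions()
        if not np.all(np.isfinite(self.mu)):
            raise RuntimeError("divergent chain: non-finite Poisson means")
        # recompute mu periodically to stop incremental drift
        if adapting:
            for name, rate in rates.items():
                self.steps[name].adapt(rate)
        else:
            for name, rate in rates.items():
                self.accept_log[name].append(rate)


def fit(data: MortalityDataset, graph: AdjacencyGraph, config: ModelConfig) -> PosteriorSamples:
    """Run MCMC and return kept posterior draws of every component.

    Raises on a single-area dataset (the spatial prior is undefined on one
    node) and on a disconnected adjacency graph.
    """
    if data.n_areas < 2:
        raise ValueError("spatial ICAR prior is undefined for a single area")
    if graph.n_nodes != data.n_areas:
        raise ValueError("graph node count does not match dataset area count")
    if not graph.is_connected():
        raise ValueError("adjacency graph must be connected")

    I, J, T = data.deaths.shape
    D = data.n_deciles
    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(config.n_chains)

    keep_total = config.n_chains * config.n_iter
    out = {
        "a0": np.empty(keep_total),
        "alpha": np.empty((keep_total, J)), "gamma": np.empty((keep_total, I)),
        "zeta": np.empty((keep_total, T)), "phi": np.empty((keep_total, D)),
        "omega": np.empty((keep_total, I, T)), "delta": np.empty((keep_total, I, J)),
        "kappa": np.empty((keep_total, J, T)), "nu": np.empty((keep_total, D, T)),
    }
    precisions = {p: np.empty(keep_total) for p in PRECISION_NAMES}
    chain_lab = np.empty(keep_total, dtype=int)
    acceptance: dict[str, float] = {}

    s = 0
    for ci, seed_seq in enumerate(chain_seeds):
        rng = np.random.default_rng(seed_seq)
        state = _ChainState(data, graph, config, rng)
        for it in range(config.burn_in):
            state.sweep(adapting=True)
            if it % 200 == 199:  # guard against multiplicative round-off drift
                state.mu = np.where(
                    state.mask, np.exp(eta_grid(state.c)) * state.pop, 0.0
                )
        kept = 0
        it = 0
        while kept < config.n_iter:
            state.sweep(adapting=False)
            it += 1
            if it % config.thin == 0:
                c = state.c
                out["a0"][s] = c.a0
                for name in FIELD_NAMES:
                    out[name][s] = getattr(c, name)
                for p in PRECISION_NAMES:
                    precisions[p][s] = state.tau[p]
                chain_lab[s] = ci
                s += 1
                kept += 1
            if it % 200 == 0:
                state.mu = np.where(
                    state.mask, np.exp(eta_grid(state.c)) * state.pop, 0.0
                )
        for name, log in state.accept_log.items():
            key = f"chain{ci}:{name}"
            acceptance[key] = float(np.mean(log)) if log else float("nan")
        if all(r == 0.0 for r in state.accept_log["a0"]):
            raise RuntimeError("divergent chain: every intercept proposal rejected")

    return PosteriorSamples(
        a0=out["a0"], alpha=out["alpha"], gamma=out["gamma"], zeta=out["zeta"],
        phi=out["phi"], omega=out["omega"], delta=out["delta"], kappa=out["kappa"],
        nu=out["nu"], precisions=precisions, chain=chain_lab, acceptance=acceptance,
        area_ids=list(data.area_ids), age_groups=list(data.age_groups),
        years=list(data.years), decile_index=data.decile_index, sex=data.sex,
    )


def _scalar_summaries(samples: PosteriorSamples) -> dict[str, np.ndarray]:
    """Scalar chains tracked by the convergence diagnostics.

    Fields are summarized by their cross-element standard deviation (their
    mean is pinned to zero by the sum-to-zero constraints).
    """
    out = {"a0": samples.a0}
    for name in FIELD_NAMES:
        arr = getattr(samples, name).reshape(samples.n_draws, -1)
        out[f"sd_{name}"] = arr.std(axis=1)
    for p, vals in samples.precisions.items():
        out[p] = vals
    return out


def convergence_report(samples: PosteriorSamples) -> pd.DataFrame:
    """Split-chain scale reduction (R-hat) and bulk ESS per scalar summary.

    Requires at least two chains; rows with R-hat > 1.1 are flagged.
    """
    import arviz as az

    n_chains = samples.n_chains
    if n_chains < 2:
        raise ValueError("convergence report requires at least 2 chains")
    rows = []
    for name, vals in _scalar_summaries(samples).items():
        per_chain = np.stack(
            [vals[samples.chain == c] for c in range(n_chains)]
        )
        rhat = float(az.rhat(per_chain))
        ess = float(az.ess(per_chain))
        rows.append({"parameter": name, "rhat": rhat, "ess": ess, "flagged": rhat > 1.1})
    return pd.DataFrame(rows)
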