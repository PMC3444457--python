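"""Continuous-time recurrent neural network (CTRNN) gene-network model.

The regulatory dynamics are the standard CTRNN

    tau_i * dg_i/dt = -g_i + sum_j W_ij * sigma(g_j + theta_j) + I_i(t)

where ``g_i(t)`` is the (rescaled) expression of gene *i*, ``tau_i`` a
per-gene time constant in hours, ``W_ij`` the signed influence of source
gene *j* on target *i*, ``theta_j`` a per-source activation offset, and
``sigma`` the logistic sigmoid.  Positive fitted weights are read as
activation, negative as inhibition.  The external input ``I_i(t)`` defaults
to zero: the injury perturbation is carried entirely by the initial
condition at 0 h.

An alternative placement of the nonlinearity, ``sigma`` applied to the
summed input with a per-target offset, is available via
``activation="summed"``.

Parameters are estimated by a real-coded genetic algorithm (tournament
selection, blend crossover, bounded Gaussian mutation, elitism) minimising
the mean squared error between simulated and observed trajectories plus an
L1 sparsity penalty on the weights.  The fit is exposed statsmodels-style:
build a :class:`CTRNN` model from data, call :meth:`CTRNN.fit`, and work
with the returned :class:`CTRNNResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Sequence
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import ExpressionMatrix, InteractionCatalog, NetworkEdge

ACTIVATION_MODES = ("source", "summed")


@dataclass
class CTRNNModel:
    """A parameterised CTRNN: weights, time constants, offsets, input."""

    gene_ids: list[str]
    W: np.ndarray  # (n, n), W[i, j] = influence of gene j on gene i
    tau: np.ndarray  # (n,) hours, > 0
    theta: np.ndarray  # (n,)
    external_input: Callable[[float], np.ndarray] | None = None
    activation: str = "source"

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        self.W = np.asarray(self.W, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}, got {self.W.shape}")
        if self.tau.shape != (n,) or self.theta.shape != (n,):
            raise ValueError("tau and theta must be length-n vectors")
        if not np.isfinite(self.W).all():
            raise ValueError("W must be finite")
        if (self.tau <= 0).any():
            raise ValueError("all time constants must be positive")
        if self.activation not in ACTIVATION_MODES:
            raise ValueError(f"activation must be one of {ACTIVATION_MODES}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _rhs(g: np.ndarray, t: float, model: CTRNNModel) -> np.ndarray:
    if model.activation == "source":
        drive = model.W @ expit(g + model.theta)
    else:
        drive = expit(model.W @ g + model.theta)
    if model.external_input is not None:
        drive = drive + model.external_input(t)
    return (-g + drive) / model.tau


def _grid_indices(observation_times: np.ndarray, step: float) -> np.ndarray:
    ratios = observation_times / step
    rounded = np.rint(ratios)
    if np.any(np.abs(ratios - rounded) > 1e-9 * np.maximum(1.0, np.abs(ratios))):
        bad = observation_times[np.argmax(np.abs(ratios - rounded))]
        raise ValueError(f"step {step} does not divide observation time {bad}")
    return rounded.astype(int)


def simulate_trajectories(
    model: CTRNNModel,
    g0: Sequence[float],
    observation_times: Sequence[float],
    step: float = 0.05,
) -> np.ndarray:
    """Integrate the CTRNN with classical fixed-step RK4.

    Integration runs on a dense grid from t=0; observation times must lie on
    the grid (``step`` must divide each of them) and outputs are read off by
    grid restriction.  Returns a genes × times array.
    """
    times = np.asarray(observation_times, dtype=float)
    if times.size and times[0] < 0:
        raise ValueError("observation times must be non-negative")
    if step <= 0:
        raise ValueError("step must be positive")
    idx = _grid_indices(times, step)
    n_steps = int(idx.max()) if idx.size else 0
    g = np.asarray(g0, dtype=float).copy()
    if g.shape != (model.n_genes,):
        raise ValueError("g0 has wrong length")
    out = np.empty((model.n_genes, times.size))
    lookup = {k: col for col, k in enumerate(idx)}
    if 0 in lookup:
        out[:, lookup[0]] = g
    for k in range(n_steps):
        t = k * step
        k1 = _rhs(g, t, model)
        k2 = _rhs(g + 0.5 * step * k1, t + 0.5 * step, model)
        k3 = _rhs(g + 0.5 * step * k2, t + 0.5 * step, model)
        k4 = _rhs(g + step * k3, t + step, model)
        g = g + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if (k + 1) in lookup:
            out[:, lookup[k + 1]] = g
    return out


def _simulate_population(
    W: np.ndarray,
    tau: np.ndarray,
    theta: np.ndarray,
    g0: np.ndarray,
    grid_idx: np.ndarray,
    n_steps: int,
    step: float,
    activation: str,
) -> np.ndarray:
    """RK4 for a whole population of models at once.

    W is (P, n, n); tau, theta are (P, n); g0 is (n,).  Returns (P, n, T).
    Used by the GA so each generation costs one vectorised integration.
    """
    P, n = tau.shape
    g = np.broadcast_to(g0, (P, n)).copy()
    out = np.empty((P, n, grid_idx.size))
    lookup = {k: col for col, k in enumerate(grid_idx)}
    if 0 in lookup:
        out[:, :, lookup[0]] = g

    if activation == "source":

        def f(state: np.ndarray) -> np.ndarray:
            act = expit(state + theta)
            return (-state + np.einsum("pij,pj->pi", W, act)) / tau

    else:

        def f(state: np.ndarray) -> np.ndarray:
            return (-state + expit(np.einsum("pij,pj->pi", W, state) + theta)) / tau

    for k in range(n_steps):
        k1 = f(g)
        k2 = f(g + 0.5 * step * k1)
        k3 = f(g + 0.5 * step * k2)
        k4 = f(g + step * k3)
        g = g + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if (k + 1) in lookup:
            out[:, :, lookup[k + 1]] = g
    return out


# -- genetic algorithm configuration ------------------------------------------


@dataclass
class GAConfig:
    """Settings of the real-coded genetic algorithm.

    ``mutation_sd_frac`` scales the Gaussian mutation step to a fraction of
    each parameter's bound width; the step is annealed geometrically to
    ``mutation_sd_final_frac`` over the generations, so the search explores
    coarsely early and refines late.  ``catalog_seed_fraction`` of the initial
    population is seeded with weights supported on the prior catalog (signs
    from the catalogued interaction types), reflecting that the network is
    built from expression data *and* known pathway interactions; the rest is
    random so novel ("computed") edges can emerge.
    ``regression_seed_fraction`` of the population starts from a warm-start
    individual obtained by per-target linearised regression (each gene's
    ODE driven by the observed source trajectories), which gives the
    coupled search a foothold on large panels.
    """

    population_size: int = 200
    generations: int = 500
    crossover_rate: float = 0.7
    mutation_rate: float = 0.1
    mutation_sd_frac: float = 0.1
    mutation_sd_final_frac: float = 0.005
    elitism: int = 2
    tournament_size: int = 3
    sparsity_lambda: float = 0.002
    weight_bounds: tuple[float, float] = (-5.0, 5.0)
    tau_bounds: tuple[float, float] = (0.1, 10.0)
    theta_bounds: tuple[float, float] = (-5.0, 5.0)
    blx_alpha: float = 0.5
    prune_eps: float = 0.0
    catalog_seed_fraction: float = 0.25
    regression_seed_fraction: float = 0.25
    restrict_to_catalog: bool = False
    n_runs: int = 1
    step: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.population_size >= self.elitism >= 1):
            raise ValueError("population_size >= elitism >= 1 required")
        for lo, hi in (self.weight_bounds, self.tau_bounds, self.theta_bounds):
            if not hi > lo:
                raise ValueError("parameter bounds must be non-degenerate")
        if self.tau_bounds[0] <= 0:
            raise ValueError("tau bounds must be positive")


class FitnessTrace(NamedTuple):
    generation: np.ndarray
    best_fitness: np.ndarray


def rescale_profiles(
    observed: np.ndarray, feature_range: tuple[float, float] = (0.05, 0.95)
) -> np.ndarray:
    """Per-gene min–max rescaling of a genes × times matrix.

    Sigmoid dynamics live on bounded states, so each gene's time course is
    mapped into ``feature_range``; a constant profile maps to the rest
    state 0.  Only signs and relative magnitudes of fitted weights are
    meaningful after this rescaling — absolute weight scales are not.
    """
    lo, hi = feature_range
    mins = observed.min(axis=1, keepdims=True)
    maxs = observed.max(axis=1, keepdims=True)
    span = maxs - mins
    flat = span[:, 0] == 0
    span[flat] = 1.0
    scaled = lo + (hi - lo) * (observed - mins) / span
    # a constant profile carries no temporal signal: place it at the
    # model's rest state (0), which zero incoming weight holds exactly
    scaled[flat] = 0.0
    return scaled


class CTRNN:
    """CTRNN model of a gene panel's time-course expression.

    Parameters
    ----------
    observed
        genes × times array of per-time replicate means, already rescaled to
        the sigmoid's working range (use :meth:`from_expression` to go
        straight from an :class:`ExpressionMatrix`).
    times
        Strictly increasing observation times in hours.
    gene_ids
        Optional identifiers (defaults to ``g0..g{n-1}``).
    catalog
        Optional prior interaction catalog used for seeding the GA and for
        edge provenance.
    """

    def __init__(
        self,
        observed: np.ndarray,
        times: Sequence[float],
        gene_ids: Sequence[str] | None = None,
        catalog: InteractionCatalog | None = None,
        activation: str = "source",
    ) -> None:
        self.observed = np.asarray(observed, dtype=float)
        self.times = np.asarray(times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 3:
            raise ValueError("need at least 3 observation times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if self.observed.ndim != 2 or self.observed.shape[1] != self.times.size:
            raise ValueError("observed must be genes x times")
        n = self.observed.shape[0]
        self.gene_ids = list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(n)]
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length mismatch")
        if n > 60:
            warnings.warn(
                f"fitting a CTRNN to {n} genes; GA dimensionality grows as n^2 "
                "and recovery degrades beyond ~60 genes"
            )
        self.catalog = catalog
        if activation not in ACTIVATION_MODES:
            raise ValueError(f"activation must be one of {ACTIVATION_MODES}")
        self.activation = activation

    @classmethod
    def from_expression(
        cls,
        matrix: ExpressionMatrix,
        genes: Sequence[str] | None = None,
        catalog: InteractionCatalog | None = None,
        feature_range: tuple[float, float] | str | None = "auto",
        activation: str = "source",
    ) -> "CTRNN":
        """Build the model from per-time replicate means.

        ``feature_range``: a (lo, hi) tuple min–max rescales each gene into
        that band; ``None`` fits the values as they are; ``"auto"``
        (default) rescales to (0.05, 0.95) only when the panel leaves the
        sigmoid's dynamic range — per-gene rescaling is an affine change of
        coordinates the CTRNN cannot absorb exactly, so data already on a
        bounded scale are fitted natively.
        """
        sub = matrix.subset(genes) if genes is not None else matrix
        means = sub.mean_by_time()
        observed = means.to_numpy(dtype=float)
        if feature_range == "auto":
            feature_range = (
                None if observed.min() > -1.5 and observed.max() < 2.5 else (0.05, 0.95)
            )
        if feature_range is not None:
            observed = rescale_profiles(observed, feature_range)
        return cls(observed, means.columns.to_numpy(float), sub.gene_ids, catalog, activation)

    # -- GA fitting ------------------------------------------------------------

    def _catalog_mask(self) -> np.ndarray | None:
        if self.catalog is None:
            return None
        n = len(self.gene_ids)
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        mask = np.zeros((n, n), dtype=bool)
        for rec in self.catalog:
            if rec.source in pos and rec.target in pos:
                mask[pos[rec.target], pos[rec.source]] = True
        return mask

    def _seed_individual(
        self, rng: np.random.Generator, mask: np.ndarray
    ) -> np.ndarray:
        """Weight matrix supported on catalog edges with catalog-consistent signs."""
        n = len(self.gene_ids)
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        W = np.zeros((n, n))
        for rec in self.catalog:  # type: ignore[union-attr]
            if rec.source not in pos or rec.target not in pos:
                continue
            mag = rng.uniform(0.5, 2.0)
            if rec.type == "activation":
                sign = 1.0
            elif rec.type == "inhibition":
                sign = -1.0
            else:
                sign = rng.choice([-1.0, 1.0])
            W[pos[rec.target], pos[rec.source]] = sign * mag
        return W

    def _regression_seed(
        self,
        tau_candidates: tuple[float, ...] = (0.3, 0.6, 1.2, 2.5, 5.0),
        max_extra_sources: int = 0,
        grid_step: float = 0.05,
        weight_cap: float = 4.5,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Warm-start (W, tau, theta) from a per-target linearised fit.

        Driving each gene's ODE with the *observed* source trajectories
        decouples the rows: for a fixed tau the solution is linear in the
        incoming weights, so each row reduces to a small least-squares
        problem on the catalog support (optionally extended greedily).
        Novel edges are left to the GA's own variation: greedy extras were
        found to destabilise the coupled dynamics.  theta starts at 0.
        """
        n, T = self.observed.shape
        times = self.times
        tg = np.arange(0.0, times[-1] + grid_step / 2, grid_step)
        Gd = np.vstack([np.interp(tg, times, self.observed[i]) for i in range(n)])
        A = expit(Gd)
        obs_idx = np.rint(times / grid_step).astype(int)
        mask = self._catalog_mask()

        # exponential-kernel responses per candidate tau:
        # B solves tau*B' = -B + A, B(0)=0, on the dense grid
        per_tau = []
        for tau in tau_candidates:
            a = np.exp(-grid_step / tau)
            B = np.zeros_like(A)
            for k in range(len(tg) - 1):
                B[:, k + 1] = a * B[:, k] + (1 - a) * 0.5 * (A[:, k] + A[:, k + 1])
            per_tau.append((tau, B[:, obs_idx], np.exp(-times / tau)))

        W = np.zeros((n, n))
        tau_out = np.ones(n)
        for i in range(n):
            base_support = (
                list(np.flatnonzero(mask[i])) if mask is not None else []
            )
            best = None  # (score, tau, support, weights)
            for tau, Bobs, decay in per_tau:
                y = self.observed[i] - decay * self.observed[i, 0]
                support = list(base_support)

                def solve(sup):
                    if not sup:
                        return np.zeros(0), float(np.sum(y**2))
                    X = Bobs[sup].T  # T x |sup|
                    w, *_ = np.linalg.lstsq(
                        X.T @ X + 1e-6 * np.eye(len(sup)), X.T @ y, rcond=None
                    )
                    resid = y - X @ w
                    return w, float(np.sum(resid**2))

                w, score = solve(support)
                for _ in range(max_extra_sources):
                    resid = y - (Bobs[support].T @ w if support else 0.0)
                    gains = Bobs @ resid
                    gains[support] = 0.0
                    j = int(np.argmax(np.abs(gains)))
                    trial = support + [j]
                    w_trial, score_trial = solve(trial)
                    if score_trial < score * 0.95:  # only keep clear improvements
                        support, w, score = trial, w_trial, score_trial
                    else:
                        break
                if best is None or score < best[0]:
                    best = (score, tau, list(support), w.copy())
            _, tau_i, support, w = best
            tau_out[i] = tau_i
            if support:
                W[i, support] = np.clip(w, -weight_cap, weight_cap)
        return W, tau_out, np.zeros(n)

    def fit(self, config: GAConfig | None = None, **overrides) -> "CTRNNResults":
        """Estimate (W, tau, theta) by the genetic algorithm.

        The initial state is fixed to the observed first time point.  The
        fitness of an individual is
        ``-(MSE of simulated vs observed) - sparsity_lambda * sum|W|``.
        Fully deterministic for a fixed ``config.seed``.

        With ``config.n_runs > 1`` the GA is restarted from independent
        derived seeds and the reported weight matrix is the element-wise
        (signed) mean over the runs' best individuals: averaging over
        restarts is the standard way to separate reproducible structure
        from run-idiosyncratic weights in evolutionary network inference.
        ``tau``/``theta`` come from the best-fitness run, whose model is
        also kept as ``results.best_model``.
        """
        if config is None:
            config = GAConfig()
        if overrides:
            config = replace(config, **overrides)
        runs = []
        for r in range(config.n_runs):
            run_cfg = replace(config, seed=(config.seed + 9973 * r) % (2**31), n_runs=1)
            runs.append(self._fit_single(run_cfg))
        best = max(runs, key=lambda res: res.fitness_trace.best_fitness[-1])
        if config.n_runs == 1:
            return best
        W_mean = np.mean([res.model.W for res in runs], axis=0)
        consensus = CTRNNModel(
            list(self.gene_ids),
            W_mean,
            best.model.tau.copy(),
            best.model.theta.copy(),
            activation=self.activation,
        )
        sim = simulate_trajectories(
            consensus, self.observed[:, 0], self.times, step=config.step
        )
        return CTRNNResults(
            model=consensus,
            config=config,
            fitness_trace=best.fitness_trace,
            mse=float(np.mean((sim - self.observed) ** 2)),
            observed=self.observed,
            times=self.times,
            catalog=self.catalog,
            best_model=best.model,
            run_models=[res.model for res in runs],
        )

    def _fit_single(self, config: GAConfig) -> "CTRNNResults":
        rng = np.random.default_rng(config.seed)
        n = len(self.gene_ids)
        P = config.population_size
        wlo, whi = config.weight_bounds
        tlo, thi = config.tau_bounds
        olo, ohi = config.theta_bounds

        grid_idx = _grid_indices(self.times, config.step)
        n_steps = int(grid_idx.max())
        g0 = self.observed[:, 0]

        mask = self._catalog_mask()
        if config.restrict_to_catalog and mask is None:
            raise ValueError("restrict_to_catalog requires a catalog")

        # initial population
        W = rng.uniform(max(wlo, -1.0), min(whi, 1.0), size=(P, n, n))
        tau = rng.uniform(tlo, min(thi, 5.0), size=(P, n))
        theta = rng.uniform(max(olo, -1.0), min(ohi, 1.0), size=(P, n))
        n_cat = (
            int(round(config.catalog_seed_fraction * P)) if mask is not None else 0
        )
        for i in range(n_cat):
            W[i] = self._seed_individual(rng, mask)
        n_reg = int(round(config.regression_seed_fraction * P))
        if n_reg > 0 and P - n_cat > 0:
            n_reg = min(n_reg, P - n_cat)
            W_reg, tau_reg, theta_reg = self._regression_seed(
                grid_step=config.step, weight_cap=0.9 * max(abs(wlo), abs(whi))
            )
            # mild damping keeps the decoupled estimate stable once coupled
            W_reg = 0.7 * W_reg
            tau_reg = np.clip(tau_reg, tlo, thi)
            for k in range(n_reg):
                i = n_cat + k
                W[i] = W_reg
                tau[i] = tau_reg
                theta[i] = theta_reg
                if k > 0:  # jittered copies keep warm-start diversity
                    W[i] = np.clip(W[i] + rng.normal(0, 0.05, (n, n)), wlo, whi)
                    tau[i] = np.clip(tau[i] * rng.uniform(0.8, 1.25, n), tlo, thi)
        if config.restrict_to_catalog:
            W *= mask

        obs = self.observed[None, :, :]
        widths = {"W": whi - wlo, "tau": thi - tlo, "theta": ohi - olo}
        decay = config.mutation_sd_final_frac / config.mutation_sd_frac
        n_anneal = max(config.generations - 1, 1)

        def evaluate(Wp, taup, thetap):
            sim = _simulate_population(
                Wp, taup, thetap, g0, grid_idx, n_steps, config.step, self.activation
            )
            mse = np.mean((sim - obs) ** 2, axis=(1, 2))
            # L1 on the weight sum: each edge must buy at least lambda*|w|
            # of MSE to survive
            penalty = config.sparsity_lambda * np.abs(Wp).sum(axis=(1, 2))
            return -(mse + penalty), mse

        trace = np.empty(config.generations)
        best = None  # (fitness, W, tau, theta, mse)
        fitness, mse = evaluate(W, tau, theta)
        for gen in range(config.generations):
            order = np.argsort(fitness)[::-1]
            if best is None or fitness[order[0]] > best[0]:
                i = order[0]
                best = (fitness[i], W[i].copy(), tau[i].copy(), theta[i].copy(), mse[i])
            trace[gen] = best[0]
            if gen == config.generations - 1:
                break

            elites = order[: config.elitism]
            n_children = P - config.elitism
            # tournament selection for two parent pools
            cand = rng.integers(0, P, size=(2, n_children, config.tournament_size))
            winners = cand[
                np.arange(2)[:, None],
                np.arange(n_children)[None, :],
                np.argmax(fitness[cand], axis=2),
            ]
            p1, p2 = winners[0], winners[1]

            def cross(a: np.ndarray) -> np.ndarray:
                x1, x2 = a[p1], a[p2]
                do = rng.random(n_children) < config.crossover_rate
                u = rng.uniform(
                    -config.blx_alpha, 1 + config.blx_alpha, size=x1.shape
                )
                child = np.where(
                    do.reshape((-1,) + (1,) * (x1.ndim - 1)),
                    u * x1 + (1 - u) * x2,
                    x1,
                )
                return child

            cW, ctau, ctheta = cross(W), cross(tau), cross(theta)

            sd_frac = config.mutation_sd_frac * decay ** (gen / n_anneal)

            def mutate(x: np.ndarray, width: float, lo: float, hi: float) -> np.ndarray:
                m = rng.random(x.shape) < config.mutation_rate
                x = x + m * rng.normal(0.0, sd_frac * width, size=x.shape)
                return np.clip(x, lo, hi)

            cW = mutate(cW, widths["W"], wlo, whi)
            if config.prune_eps > 0:
                # snap near-zero weights to exact zero: together with the
                # L1 term this lets edges actually disappear, keeping W
                # sparse instead of carpeted with mutation noise (used for
                # large panels; on small well-determined problems a dense
                # W recovers edge signs better)
                cW[np.abs(cW) < config.prune_eps] = 0.0
            ctau = mutate(ctau, widths["tau"], tlo, thi)
            ctheta = mutate(ctheta, widths["theta"], olo, ohi)
            if config.restrict_to_catalog:
                cW *= mask

            W = np.concatenate([W[elites], cW])
            tau = np.concatenate([tau[elites], ctau])
            theta = np.concatenate([theta[elites], ctheta])
            fitness, mse = evaluate(W, tau, theta)

        model = CTRNNModel(
            list(self.gene_ids), best[1], best[2], best[3], activation=self.activation
        )
        return CTRNNResults(
            model=model,
            config=config,
            fitness_trace=FitnessTrace(np.arange(config.generations), trace),
            mse=float(best[4]),
            observed=self.observed,
            times=self.times,
            catalog=self.catalog,
        )


def fit_ctrnn_ga(
    observed: np.ndarray,
    times: Sequence[float],
    config: GAConfig | None = None,
    catalog: InteractionCatalog | None = None,
    gene_ids: Sequence[str] | None = None,
) -> tuple[CTRNNModel, FitnessTrace]:
    """Functional wrapper: fit a CTRNN and return (model, fitness trace)."""
    res = CTRNN(observed, times, gene_ids=gene_ids, catalog=catalog).fit(config)
    return res.model, res.fitness_trace


# -- edge extraction and network summaries ------------------------------------


def classify_interaction(weight: float, catalog_type: str | None = None) -> str:
    """Interaction label for a fitted weight.

    A catalogued binding/association annotation is kept regardless of the
    weight sign; otherwise negative weight means inhibition and positive
    activation.
    """
    if weight == 0:
        raise ValueError("cannot classify a zero weight")
    if catalog_type == "binding/association":
        return catalog_type
    return "inhibition" if weight < 0 else "activation"


def extract_edges(
    model: CTRNNModel,
    catalog: InteractionCatalog | None = None,
    rel_threshold: float = 0.10,
    abs_threshold: float = 0.10,
) -> list[NetworkEdge]:
    """Threshold the fitted weight matrix into signed, provenance-tagged edges.

    Keeps off-diagonal entries with |W[i,j]| >= rel_threshold * max|W|
    (relative thresholding — absolute weight scales are arbitrary after
    rescaling) that also clear ``abs_threshold``, a noise floor below which
    weights are indistinguishable from zero given the stochastic search
    (default 1% of the default weight-bound range).  An edge already in the
    catalog is tagged "database"; one that emerged only from the fit is
    tagged "computed".  Self-loops are dropped.
    """
    W = model.W
    off = ~np.eye(model.n_genes, dtype=bool)
    if not np.any(W[off] != 0):
        return []
    cutoff = max(rel_threshold * np.abs(W[off]).max(), abs_threshold)
    edges = []
    for i in range(model.n_genes):  # target
        for j in range(model.n_genes):  # source
            if i == j:
                continue
            w = W[i, j]
            if w == 0 or abs(w) < cutoff:
                continue
            src, tgt = model.gene_ids[j], model.gene_ids[i]
            ctype = catalog.type_of(src, tgt) if catalog is not None else None
            provenance = "database" if ctype is not None else "computed"
            edges.append(
                NetworkEdge(src, tgt, float(w), classify_interaction(w, ctype), provenance)
            )
    return edges


def rank_regulators(edges: Sequence[NetworkEdge]) -> pd.DataFrame:
    """Score each node by summed |outgoing weight| — its downstream influence.

    Returns a DataFrame (gene_id, out_weight_sum, out_degree, rank) sorted
    by descending out-weight, ties broken by out-degree then gene id; nodes
    tied on both score and degree share the minimal rank.
    """
    nodes: dict[str, list[float]] = {}
    for e in edges:
        nodes.setdefault(e.source, [0.0, 0])
        nodes.setdefault(e.target, [0.0, 0])
        nodes[e.source][0] += abs(e.weight)
        nodes[e.source][1] += 1
    if not nodes:
        return pd.DataFrame(columns=["gene_id", "out_weight_sum", "out_degree", "rank"])
    frame = pd.DataFrame(
        [(g, s, int(d)) for g, (s, d) in nodes.items()],
        columns=["gene_id", "out_weight_sum", "out_degree"],
    )
    frame = frame.sort_values(
        ["out_weight_sum", "out_degree", "gene_id"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    ranks = np.arange(1, len(frame) + 1)
    key = list(zip(frame["out_weight_sum"], frame["out_degree"]))
    for i in range(1, len(frame)):
        if key[i] == key[i - 1]:
            ranks[i] = ranks[i - 1]
    frame["rank"] = ranks
    return frame


class SubNetwork(NamedTuple):
    nodes: frozenset[str]
    edges: tuple[NetworkEdge, ...]


def decompose_subnetworks(edges: Sequence[NetworkEdge]) -> list[SubNetwork]:
    """Weakly connected components of the edge graph, largest first."""
    graph = nx.DiGraph()
    for e in edges:
        graph.add_edge(e.source, e.target)
    comps = sorted(
        nx.weakly_connected_components(graph),
        key=lambda c: (-len(c), min(c)),
    )
    out = []
    for comp in comps:
        members = tuple(e for e in edges if e.source in comp)
        out.append(SubNetwork(frozenset(comp), members))
    return out


@dataclass
class CTRNNResults:
    """Fitted CTRNN: parameters, fit quality, and network summaries."""

    model: CTRNNModel
    config: GAConfig
    fitness_trace: FitnessTrace
    mse: float
    observed: np.ndarray
    times: np.ndarray
    catalog: InteractionCatalog | None = None
    best_model: CTRNNModel | None = None  # best single run when n_runs > 1
    run_models: list[CTRNNModel] | None = None

    def simulate(self, observation_times: Sequence[float] | None = None) -> np.ndarray:
        times = self.times if observation_times is None else observation_times
        return simulate_trajectories(
            self.model, self.observed[:, 0], times, step=self.config.step
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.simulate()

    def extract_edges(self, rel_threshold: float = 0.10) -> list[NetworkEdge]:
        return extract_edges(self.model, self.catalog, rel_threshold)

    def rank_regulators(self, rel_threshold: float = 0.10) -> pd.DataFrame:
        return rank_regulators(self.extract_edges(rel_threshold))

    def subnetworks(self, rel_threshold: float = 0.10) -> list[SubNetwork]:
        return decompose_subnetworks(self.extract_edges(rel_threshold))

    def summary(self, rel_threshold: float = 0.10, top: int = 10) -> str:
        edges = self.extract_edges(rel_threshold)
        regs = rank_regulators(edges)
        by_prov = pd.Series([e.provenance for e in edges]).value_counts()
        lines = [
            "CTRNN network fit",
            "=" * 60,
            f"genes: {self.model.n_genes}    time points: {self.times.size}",
            f"GA: population {self.config.population_size}, "
            f"generations {self.config.generations}, seed {self.config.seed}",
            f"final MSE: {self.mse:.6g}    "
            f"final fitness: {self.fitness_trace.best_fitness[-1]:.6g}",
            f"edges kept at rel_threshold={rel_threshold}: {len(edges)} "
            f"(database {by_prov.get('database', 0)}, "
            f"computed {by_prov.get('computed', 0)})",
            f"sub-networks: {len(self.subnetworks(rel_threshold))}",
            "",
            "Top regulators (summed |outgoing weight|):",
            regs.head(top).to_string(index=False)
            if len(regs)
            else "  (no edges above threshold)",
        ]
        return "\n".join(lines)
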