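"""Flux evaluation, ODE integration and observable evaluation.

The state obeys dx/dt = S v(x, theta, u) with x(0) = x0(theta, u).  Inputs
u(t) are piecewise constant, so integration restarts at every breakpoint;
within a segment the right-hand side is autonomous in u.  The default solver
is LSODA (stiff-capable, switching automatically), at tolerances well below
the thresholds any downstream statistic uses.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

from .expressions import lambdify_vector, sym
from .model import BRNModel, ExperimentCondition, ModelError, stoichiometric_matrix

log = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    """Integration failed; carries the last time reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class SolverConfig:
    rtol: float = 1e-8
    atol: float = 1e-10
    mxstep: int = 50_000
    negative_tol: float = 1e-8  # states in (-negative_tol, 0) are clamped to 0


@dataclass
class StateTrajectory:
    t: np.ndarray  # (n_t,)
    x: np.ndarray  # (n_t, n_x)
    experiment_id: str
    theta: np.ndarray

    @property
    def n_t(self) -> int:
        return len(self.t)


@dataclass
class FluxTrajectory:
    t: np.ndarray
    v: np.ndarray  # (n_t, n_r)
    experiment_id: str


# ---------------------------------------------------------------------------
# elementary rate laws


def mass_action_flux(x: Sequence[float], kappa: float, reactant_stoich: Sequence[float]) -> float:
    """v = kappa * prod_i x_i^{s_i} with the convention 0**0 == 1."""
    x = np.asarray(x, float)
    s = np.asarray(reactant_stoich, float)
    if np.any(x < 0):
        raise ValueError("mass-action flux requires nonnegative concentrations")
    with np.errstate(divide="ignore"):
        terms = np.where(s == 0, 1.0, x**s)
    return float(kappa * np.prod(terms))


def michaelis_menten_flux(x_i: float, kappa_max: float, kappa: float) -> float:
    """v = kappa_max * x / (kappa + x): saturating, bounded by kappa_max."""
    if x_i < 0:
        raise ValueError("substrate concentration must be nonnegative")
    return float(kappa_max * x_i / (kappa + x_i))


# ---------------------------------------------------------------------------
# compiled model functions


def _compiled(model: BRNModel):
    """Lazily compile flux vector, RHS, initial condition and output map."""
    cache = model._cache
    if "flux_fn" not in cache:
        exprs = [r.rate_expr() for r in model.reactions]
        cache["flux_fn"] = lambdify_vector(exprs, model.species_ids, model.parameters, model.inputs)
        S = stoichiometric_matrix(model)
        cache["S"] = S.astype(float)
        # dx/dt = S v compiled as one expression vector: no per-call matmul
        rhs_exprs = [sum(int(S[i, j]) * exprs[j] for j in range(model.n_r)) for i in range(model.n_x)]
        cache["rhs_fn"] = lambdify_vector(rhs_exprs, model.species_ids, model.parameters, model.inputs)
        cache["x0_fn"] = lambdify_vector(
            [s.initial_expr for s in model.species], [], model.parameters, model.inputs
        )
    return cache


def evaluate_fluxes(
    model: BRNModel,
    x: Sequence[float] | np.ndarray,
    theta: Mapping[str, float] | Sequence[float],
    u: Sequence[float] = (),
    t: float = 0.0,
) -> np.ndarray:
    """Flux vector v(x, theta, u); broadcasts over arrays of states."""
    cache = _compiled(model)
    th = model.theta_vector(theta)
    x = np.asarray(x, float)
    vals = cache["flux_fn"](list(np.atleast_2d(x).T) if x.ndim > 1 else list(x), list(th), list(u), t)
    out = np.array([np.broadcast_to(v, x.shape[:-1] or ()) for v in vals], float)
    return np.moveaxis(out, 0, -1) if x.ndim > 1 else out.reshape(-1)


def initial_state(model: BRNModel, theta, u: Sequence[float]) -> np.ndarray:
    cache = _compiled(model)
    th = model.theta_vector(theta)
    x0 = np.array(cache["x0_fn"]([], list(th), list(u), 0.0), float)
    if not np.all(np.isfinite(x0)) or np.any(x0 < 0):
        raise ModelError(f"initial condition must be finite and nonnegative, got {x0}")
    return x0


def _integrate_states(
    model: BRNModel,
    theta: np.ndarray,
    experiment: ExperimentCondition,
    t_grid: np.ndarray,
    cfg: SolverConfig,
) -> np.ndarray:
    """Integrate over t_grid, restarting at every input breakpoint."""
    cache = _compiled(model)
    rhs_fn = cache["rhs_fn"]
    th = list(theta)

    u0 = experiment.input_values_at(float(t_grid[0]))
    x = initial_state(model, theta, u0)
    out = np.empty((len(t_grid), model.n_x))
    out[0] = x

    seg_edges = np.concatenate(
        ([t_grid[0]], experiment.breakpoints(float(t_grid[0]), float(t_grid[-1])), [t_grid[-1]])
    )
    pos = 1  # next t_grid index to fill
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        u = list(experiment.input_values_at(float(a)))

        def rhs(xv, tv):
            return rhs_fn(xv, th, u, tv)

        idx_end = int(np.searchsorted(t_grid, b, side="right"))
        seg_times = np.concatenate(([a], t_grid[pos:idx_end], [] if t_grid[idx_end - 1] == b else [b]))
        if len(seg_times) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=UserWarning)
            try:
                ys, info = odeint(
                    rhs, x, seg_times, rtol=cfg.rtol, atol=cfg.atol, mxstep=cfg.mxstep,
                    full_output=True, printmessg=False,
                )
            except Exception as exc:
                raise SimulationError(
                    f"integration failed in experiment {experiment.id!r} near t={a:g}: {exc}",
                    last_time=float(a),
                ) from exc
        if info["message"] != "Integration successful.":
            tcur = float(info["tcur"][-1]) if len(info.get("tcur", [])) else float(a)
            raise SimulationError(
                f"integration failed in experiment {experiment.id!r}: {info['message']} "
                f"(last successful time {tcur:g})",
                last_time=tcur,
            )
        n_grid = idx_end - pos
        if n_grid:
            out[pos : pos + n_grid] = ys[1 : 1 + n_grid]
        pos = idx_end
        x = ys[-1]
    if np.min(out) < 0:
        worst = float(np.min(out))
        if worst < -cfg.negative_tol:
            raise SimulationError(
                f"state became negative ({worst:.3e}) beyond tolerance in experiment {experiment.id!r}"
            )
        log.warning("clamping slightly negative states (min %.3e) to zero", worst)
        np.clip(out, 0.0, None, out=out)
    return out


def simulate(
    model: BRNModel,
    theta: Mapping[str, float] | Sequence[float],
    experiment: ExperimentCondition,
    t_grid: Sequence[float],
    solver: SolverConfig | None = None,
) -> tuple[StateTrajectory, FluxTrajectory]:
    """Simulate one experimental condition and return state + flux courses."""
    cfg = solver or SolverConfig()
    th = model.theta_vector(theta)
    t_grid = np.asarray(t_grid, float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ModelError("t_grid must be strictly increasing with at least two points")
    x = _integrate_states(model, th, experiment, t_grid, cfg)
    # fluxes along the grid, vectorized (inputs piecewise constant per point)
    cache = _compiled(model)
    U = np.array([experiment.input_values_at(float(t)) for t in t_grid])  # (n_t, n_u)
    vals = cache["flux_fn"](list(x.T), list(th), list(U.T) if U.size else [], t_grid)
    v = np.column_stack([np.broadcast_to(col, (len(t_grid),)) for col in vals]) if model.n_r else np.empty((len(t_grid), 0))
    return (
        StateTrajectory(t=t_grid, x=x, experiment_id=experiment.id, theta=th),
        FluxTrajectory(t=t_grid, v=v, experiment_id=experiment.id),
    )


def simulate_states(
    model: BRNModel,
    theta,
    experiment: ExperimentCondition,
    t_grid: Sequence[float],
    solver: SolverConfig | None = None,
) -> np.ndarray:
    """States only, no trajectory objects — the fast path for likelihoods."""
    cfg = solver or SolverConfig()
    th = model.theta_vector(theta)
    return _integrate_states(model, th, experiment, np.asarray(t_grid, float), cfg)


# ---------------------------------------------------------------------------
# observables


def evaluate_outputs(
    model: BRNModel,
    traj: StateTrajectory | np.ndarray,
    theta: Mapping[str, float] | Sequence[float],
) -> np.ndarray:
    """Observable courses y(t) (n_t x n_y); log10 transforms are applied last."""
    x = traj.x if isinstance(traj, StateTrajectory) else np.asarray(traj, float)
    th = model.theta_vector(theta)
    th_by_name = dict(zip(model.parameters, th))
    n_t = x.shape[0]
    y = np.empty((n_t, len(model.observables)))
    for k, obs in enumerate(model.observables):
        col = np.zeros(n_t)
        for sid, w in obs.weights.items():
            col = col + w * x[:, model.species_index(sid)]
        if obs.scale is not None:
            col = th_by_name[obs.scale] * col
        if obs.log10:
            if np.any(col <= 0):
                bad = int(np.argmax(col <= 0))
                t_bad = traj.t[bad] if isinstance(traj, StateTrajectory) else bad
                raise ModelError(
                    f"observable {obs.id!r}: log10 of nonpositive value at t={t_bad}"
                )
            col = np.log10(col)
        y[:, k] = col
    return y
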