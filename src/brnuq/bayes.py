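"""Gaussian likelihood, log-posterior and adaptive-Metropolis MCMC.

Sampling runs in log10(theta) coordinates — the natural scale for strictly
positive kinetic constants — with a diagonal random-walk proposal whose scale
is adapted during burn-in toward roughly 25% acceptance.  The posterior is
unnormalized: p(D) cancels in the Metropolis ratio and is never computed.
"""
from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import SimulationError, SolverConfig, evaluate_outputs, simulate_states
from .model import BRNModel, ExperimentCondition, ModelError

log = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


class PriorError(ValueError):
    pass


@dataclass(frozen=True)
class PriorComponent:
    """One parameter's prior, specified on the log10 scale.

    kinds: ``log10_uniform(lo, hi)`` — flat on [lo, hi] in log10 units;
    ``log10_normal(mu, sigma)`` — normal on log10(theta); ``fixed(value)`` —
    a point mass at a known linear-scale value (excluded from sampling).
    """

    kind: str
    a: float
    b: float = 0.0

    def __post_init__(self):
        if self.kind not in ("log10_uniform", "log10_normal", "fixed"):
            raise PriorError(f"unknown prior kind {self.kind!r}")
        if self.kind == "log10_uniform" and self.b <= self.a:
            raise PriorError("log10_uniform needs lo < hi")
        if self.kind == "log10_normal" and self.b <= 0:
            raise PriorError("log10_normal needs sigma > 0")
        if self.kind == "fixed" and self.a <= 0:
            raise PriorError("fixed value must be positive")

    def log_density(self, z: float) -> float:
        if self.kind == "log10_uniform":
            return -math.log(self.b - self.a) if self.a <= z <= self.b else -math.inf
        if self.kind == "log10_normal":
            r = (z - self.a) / self.b
            return -0.5 * (r * r + _LOG_2PI) - math.log(self.b)
        raise PriorError("fixed parameters have no sampling density")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "log10_uniform":
            return rng.uniform(self.a, self.b, n)
        if self.kind == "log10_normal":
            return rng.normal(self.a, self.b, n)
        return np.full(n, math.log10(self.a))

    def midpoint(self) -> float:
        if self.kind == "log10_uniform":
            return 0.5 * (self.a + self.b)
        if self.kind == "log10_normal":
            return self.a
        return math.log10(self.a)


@dataclass
class Prior:
    components: dict[str, PriorComponent]

    @classmethod
    def from_json(cls, path: str | Path) -> "Prior":
        obj = json.loads(Path(path).read_text())
        comps = {}
        for name, spec in obj.items():
            params = spec.get("params", [])
            comps[name] = PriorComponent(spec["type"], *[float(p) for p in params])
        return cls(comps)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.components)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n, c in self.components.items() if c.kind != "fixed")

    def log_density_log10(self, z: Mapping[str, float] | Sequence[float]) -> float:
        """Joint log-density over the free parameters in log10 coordinates."""
        free = self.free_names
        if not isinstance(z, Mapping):
            z = dict(zip(free, z))
        total = 0.0
        for name in free:
            total += self.components[name].log_density(float(z[name]))
            if total == -math.inf:
                return -math.inf
        return total

    def sample_log10(self, rng: np.random.Generator, n: int) -> pd.DataFrame:
        return pd.DataFrame({name: c.sample(rng, n) for name, c in self.components.items()})

    def theta_linear(self, z_free: Sequence[float]) -> dict[str, float]:
        """Assemble the full linear-scale theta from free log10 coords."""
        theta = {n: 10.0 ** float(v) for n, v in zip(self.free_names, z_free)}
        for name, c in self.components.items():
            if c.kind == "fixed":
                theta[name] = c.a
        return theta


# ---------------------------------------------------------------------------
# likelihood / posterior


def log_likelihood(
    model: BRNModel,
    theta: Mapping[str, float] | Sequence[float],
    experiments: Sequence[ExperimentCondition] | None = None,
    solver: SolverConfig | None = None,
) -> float:
    """Sum of Gaussian log-densities of residuals over every experiment's data.

    A simulation failure is treated as zero likelihood (-inf) with a logged
    diagnostic, so MCMC simply rejects such proposals.
    """
    experiments = model.experiments if experiments is None else experiments
    obs_index = {o: k for k, o in enumerate(model.observable_ids)}
    total = 0.0
    for exp in experiments:
        if exp.dataset is None:
            continue
        times = exp.dataset.times
        sim_grid = np.concatenate(([0.0], times)) if times[0] > 0 else times
        if len(sim_grid) < 2:
            sim_grid = np.concatenate((sim_grid, [sim_grid[-1] + 1.0]))
        try:
            x = simulate_states(model, theta, exp, sim_grid, solver)
            y = evaluate_outputs(model, x, theta)
        except (SimulationError, ModelError) as exc:
            log.info("simulation failed at proposed theta (%s); likelihood -> -inf", exc)
            return -math.inf
        tbl = exp.dataset.table.dropna(subset=["value"])
        ti = np.searchsorted(sim_grid, tbl["time"].to_numpy(float))
        oi = np.array([obs_index[o] for o in tbl["observable"]])
        values = tbl["value"].to_numpy(float)
        sds = tbl["sd"].to_numpy(float)
        r = (values - y[ti, oi]) / sds
        total += float(np.sum(-0.5 * (r * r + _LOG_2PI) - np.log(sds)))
    return total


def log_posterior(
    model: BRNModel,
    theta: Mapping[str, float] | Sequence[float],
    prior: Prior,
    experiments: Sequence[ExperimentCondition] | None = None,
    solver: SolverConfig | None = None,
) -> float:
    """Unnormalized log p(theta|D) = log p(D|theta) + log p(theta).

    ``theta`` is on the linear scale; the prior density is evaluated at
    log10(theta) (the sampling coordinates).
    """
    if isinstance(theta, Mapping):
        theta_map = dict(theta)
    else:
        theta_map = dict(zip(model.parameters, np.asarray(theta, float)))
    if any(v <= 0 for v in theta_map.values()):
        return -math.inf
    z = {n: math.log10(theta_map[n]) for n in prior.free_names}
    lp = prior.log_density_log10(z)
    if lp == -math.inf:
        return -math.inf
    return lp + log_likelihood(model, theta_map, experiments, solver)


# ---------------------------------------------------------------------------
# parameter samples


@dataclass
class ParameterSample:
    """n_s x n_theta draws with scale bookkeeping and chain metadata."""

    draws: pd.DataFrame  # columns = parameter names
    scale: str = "log10"  # "log10" | "linear"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scale not in ("log10", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if len(self.draws) < 2:
            raise ValueError("a parameter sample needs at least two draws")
        if len(set(self.draws.columns)) != len(self.draws.columns):
            raise ValueError("duplicate parameter names")
        if self.scale == "linear" and (self.draws.to_numpy() <= 0).any():
            raise ValueError("linear-scale draws must be strictly positive")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.draws.columns)

    @property
    def n_s(self) -> int:
        return len(self.draws)

    def to_scale(self, scale: str) -> "ParameterSample":
        if scale == self.scale:
            return self
        if scale == "linear":
            return ParameterSample(10.0**self.draws, "linear", dict(self.meta))
        return ParameterSample(np.log10(self.draws), "log10", dict(self.meta))

    def linear(self) -> "ParameterSample":
        return self.to_scale("linear")

    def log10(self) -> "ParameterSample":
        return self.to_scale("log10")


def write_sample(sample: ParameterSample, path: str | Path) -> None:
    """CSV with a ``# scale=...`` comment line; 17 significant digits."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# scale={sample.scale}\n")
    sample.draws.to_csv(buf, index=False, float_format="%.17g")
    path.write_text(buf.getvalue())


def read_sample(path: str | Path, model: BRNModel | None = None) -> ParameterSample:
    """Read a sample from delimited text (comma or whitespace separated)."""
    path = Path(path)
    scale = "linear"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        if "scale=" in first:
            scale = first.split("scale=")[1].strip()
    header_line = first if not first.startswith("#") else None
    if header_line is None:
        with open(path) as fh:
            fh.readline()
            header_line = fh.readline()
    sep = "," if "," in header_line else r"\s+"
    df = pd.read_csv(path, comment="#", sep=sep, float_precision="round_trip")
    if model is not None:
        have, want = set(df.columns), set(model.parameters)
        if have != want:
            extra, missing = sorted(have - want), sorted(want - have)
            raise ModelError(
                f"sample columns do not match model parameters; extra={extra}, missing={missing}"
            )
        df = df[list(model.parameters)]
    return ParameterSample(df, scale=scale)


# ---------------------------------------------------------------------------
# adaptive Metropolis


@dataclass
class MCMCConfig:
    n_steps: int = 50_000
    burn_in: int | None = None  # default: n_steps // 2
    thinning: int = 1
    seed: int = 0
    init: Mapping[str, float] | None = None  # log10-scale start; default prior midpoint
    target_accept: float = 0.25
    adapt_interval: int = 50
    initial_step: float = 0.1

    @property
    def burn(self) -> int:
        return self.n_steps // 2 if self.burn_in is None else self.burn_in


def adaptive_metropolis(
    log_target: Callable[[np.ndarray], float],
    z0: np.ndarray,
    cfg: MCMCConfig,
) -> tuple[np.ndarray, float]:
    """Random-walk Metropolis with a diagonal proposal adapted during burn-in.

    Returns the full chain (n_steps x d) and the post-burn-in acceptance rate.
    The global proposal scale follows a Robbins-Monro recursion toward the
    target acceptance; per-coordinate scales are re-estimated from the chain
    halfway through burn-in.
    """
    rng = np.random.default_rng(cfg.seed)
    d = len(z0)
    z = np.asarray(z0, float).copy()
    lp = log_target(z)
    if not np.isfinite(lp):
        raise ValueError("log target is not finite at the initial point")
    chain = np.empty((cfg.n_steps, d))
    step = np.full(d, cfg.initial_step)
    scale = 1.0
    accepts_window = 0
    accepts_post = 0
    window_rates: list[float] = []
    for i in range(cfg.n_steps):
        prop = z + rng.normal(0.0, scale * step, d)
        lp_prop = log_target(prop)
        if math.log(rng.uniform()) < lp_prop - lp:
            z, lp = prop, lp_prop
            accepts_window += 1
            if i >= cfg.burn:
                accepts_post += 1
        chain[i] = z
        if (i + 1) % cfg.adapt_interval == 0 and i < cfg.burn:
            rate = accepts_window / cfg.adapt_interval
            window_rates.append(rate)
            scale *= math.exp(rate - cfg.target_accept)
            accepts_window = 0
            if i + 1 == cfg.burn // 2:
                sd = chain[: i + 1].std(axis=0)
                floor = max(sd.max(), cfg.initial_step) * 1e-3
                step = np.maximum(sd, floor)
    post = max(cfg.n_steps - cfg.burn, 1)
    rate_post = accepts_post / post
    if window_rates and rate_post == 0.0 and max(window_rates, default=0.0) == 0.0:
        raise RuntimeError(
            "chain never accepted a proposal; rescale the proposal (initial_step) "
            "or check the target"
        )
    return chain, rate_post


def run_mcmc(
    model: BRNModel,
    prior: Prior,
    experiments: Sequence[ExperimentCondition] | None = None,
    cfg: MCMCConfig | None = None,
    solver: SolverConfig | None = None,
) -> ParameterSample:
    """Sample the posterior over the prior's free parameters in log10 space.

    Fixed parameters appear in the returned sample as constant columns, so
    the draws always align with the model's full parameter vector.
    """
    cfg = cfg or MCMCConfig()
    if cfg.n_steps <= cfg.burn:
        raise ValueError("n_steps must exceed burn_in")
    experiments = model.experiments if experiments is None else tuple(experiments)
    free = prior.free_names
    missing = [p for p in model.parameters if p not in prior.components]
    if missing:
        raise PriorError(f"prior missing parameters {missing}")

    def target(z: np.ndarray) -> float:
        lp = prior.log_density_log10(z)
        if lp == -math.inf:
            return -math.inf
        theta = prior.theta_linear(z)
        return lp + log_likelihood(model, theta, experiments, solver)

    if cfg.init is not None:
        z0 = np.array([cfg.init[n] for n in free], float)
    else:
        z0 = np.array([prior.components[n].midpoint() for n in free])
    chain, acc = adaptive_metropolis(target, z0, cfg)
    kept = chain[cfg.burn :: cfg.thinning]
    df = pd.DataFrame(kept, columns=list(free))
    for name, c in prior.components.items():
        if c.kind == "fixed":
            df[name] = math.log10(c.a)
    order = [p for p in model.parameters if p in df.columns]
    df = df[order]
    meta = {
        "seed": cfg.seed,
        "n_steps": cfg.n_steps,
        "burn_in": cfg.burn,
        "thinning": cfg.thinning,
        "acceptance_rate": acc,
        "free_parameters": list(free),
    }
    log.info("MCMC finished: %d kept draws, acceptance %.3f", len(df), acc)
    return ParameterSample(df, scale="log10", meta=meta)
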