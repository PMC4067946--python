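"""Self-contained fixture models and synthetic datasets.

Three small networks cover every rate-law and graph branch of the package:

``decay``
    one species, one mass-action sink — closed form x(t) = x0 exp(-k t);
``conserved_pair``
    an isomerization A <-> B written as two irreversible reactions, with the
    left null vector (1, 1) of S, so total mass is conserved;
``mm_cascade``
    an input-driven three-step cascade with a two-parameter Michaelis-Menten
    step, an enzyme modifier (hyper-edge), a sum-of-states observable and two
    experimental conditions that differ in their input u(t).

``conjugate_toy`` is a linear-Gaussian model (constant state equal to a
parameter, observed through log10) whose posterior is available in closed
form — the independent oracle for the MCMC machinery.

Synthetic measurements follow the package's data model: independent Gaussian
noise with known SD added to noiseless simulated outputs at the stated times.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .bayes import Prior, PriorComponent
from .expressions import GeneralRate, MassAction, MichaelisMenten, sym
from .kinetics import evaluate_outputs, simulate_states
from .model import (
    BRNModel,
    Dataset,
    ExperimentCondition,
    InputChannel,
    ObservableDef,
    Reaction,
    Species,
)

FIXTURE_NAMES = ("decay", "conserved_pair", "mm_cascade")

# measurement schedule shared by the dynamic fixtures: 6 times x 2 observables
# per experiment = 12 data points for mm_cascade's first condition
_MM_TIMES = (0.5, 1.0, 2.0, 4.0, 7.0, 10.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Ground truth and noise model for synthetic data generation."""

    name: str
    theta_true: Mapping[str, float]
    sigma: float
    times: tuple[float, ...]
    seed: int = 7


def make_model(name: str) -> BRNModel:
    """Build a named fixture model (experiments carry inputs but no data)."""
    if name == "decay":
        return BRNModel(
            species=(Species("A", "A", 1.0),),
            reactions=(Reaction("deg", {"A": 1}, {}, MassAction("k")),),
            parameters=("k",),
            observables=(ObservableDef("yA", {"A": 1.0}),),
            experiments=(ExperimentCondition("e1"),),
            name="decay",
        )
    if name == "conserved_pair":
        return BRNModel(
            species=(Species("A", "A", 1.0), Species("B", "B", 0.0)),
            reactions=(
                Reaction("fwd", {"A": 1}, {"B": 1}, MassAction("k1")),
                Reaction("rev", {"B": 1}, {"A": 1}, MassAction("k2")),
            ),
            parameters=("k1", "k2"),
            observables=(ObservableDef("yA", {"A": 1.0}), ObservableDef("ytot", {"A": 1.0, "B": 1.0})),
            experiments=(ExperimentCondition("e1"),),
            name="conserved_pair",
        )
    if name == "mm_cascade":
        species = (
            Species("X1", "substrate", 0.0),
            Species("X2", "intermediate", 0.0),
            Species("X3", "product", 0.0),
            Species("E", "enzyme", 1.0),
        )
        reactions = (
            Reaction("production", {}, {"X1": 1}, GeneralRate(sym("k_in") * sym("u1"), ("k_in",))),
            Reaction("conversion", {"X1": 1}, {"X2": 1}, MichaelisMenten("X1", "vmax2", "km2")),
            Reaction(
                "catalysis",
                {"X2": 1},
                {"X3": 1},
                GeneralRate(sym("k3") * sym("X2") * sym("E"), ("k3",)),
                modifiers=frozenset({"E"}),
            ),
            Reaction("export", {"X3": 1}, {}, MassAction("k4")),
        )
        observables = (
            ObservableDef("y1", {"X1": 1.0, "X2": 1.0}),
            ObservableDef("y2", {"X3": 1.0}),
        )
        experiments = (
            ExperimentCondition("e1", (InputChannel("u1", (0.0,), (1.0,)),)),
            ExperimentCondition("e2", (InputChannel("u1", (0.0, 5.0), (1.0, 0.2)),)),
        )
        return BRNModel(
            species=species,
            reactions=reactions,
            parameters=("k_in", "vmax2", "km2", "k3", "k4"),
            observables=observables,
            experiments=experiments,
            inputs=("u1",),
            name="mm_cascade",
        )
    raise KeyError(f"unknown fixture model {name!r}; choose from {FIXTURE_NAMES}")


def default_spec(name: str, seed: int = 7) -> FixtureSpec:
    if name == "decay":
        return FixtureSpec(name, {"k": 1.0}, sigma=0.02, times=_MM_TIMES, seed=seed)
    if name == "conserved_pair":
        return FixtureSpec(name, {"k1": 1.0, "k2": 0.5}, sigma=0.02, times=_MM_TIMES, seed=seed)
    if name == "mm_cascade":
        theta = {"k_in": 1.0, "vmax2": 2.0, "km2": 1.0, "k3": 0.5, "k4": 0.3}
        return FixtureSpec(name, theta, sigma=0.05, times=_MM_TIMES, seed=seed)
    raise KeyError(f"unknown fixture model {name!r}")


def fixture_prior(name: str, mode: str = "full") -> Prior:
    """Log10-uniform, one decade either side of the true value.

    ``mode='recovery'`` frees only (vmax2, km2, k4) of mm_cascade and fixes
    the rest at truth — the three-free-parameter estimation study.
    """
    spec = default_spec(name)
    comps: dict[str, PriorComponent] = {}
    free = set(spec.theta_true)
    if mode == "recovery":
        if name != "mm_cascade":
            raise ValueError("recovery mode is defined for mm_cascade")
        free = {"vmax2", "km2", "k4"}
    elif mode != "full":
        raise ValueError(f"unknown prior mode {mode!r}")
    for p, v in spec.theta_true.items():
        if p in free:
            c = math.log10(v)
            comps[p] = PriorComponent("log10_uniform", c - 1.0, c + 1.0)
        else:
            comps[p] = PriorComponent("fixed", v)
    return Prior(comps)


def make_data(model: BRNModel, spec: FixtureSpec | None = None) -> BRNModel:
    """Attach seeded noisy synthetic datasets to every experiment.

    Simulates at theta*, evaluates the observables at the measurement times,
    and adds independent N(0, sigma^2) noise.
    """
    spec = spec or default_spec(model.name)
    rng = np.random.default_rng(spec.seed)
    theta = dict(spec.theta_true)
    conds = []
    for exp in model.experiments:
        times = np.asarray(spec.times, float)
        sim_grid = np.concatenate(([0.0], times)) if times[0] > 0 else times
        x = simulate_states(model, theta, exp, sim_grid)
        y = evaluate_outputs(model, x, theta)
        offset = len(sim_grid) - len(times)
        rows = []
        for k, obs in enumerate(model.observables):
            noise = rng.normal(0.0, spec.sigma, len(times))
            for l, tl in enumerate(times):
                rows.append(
                    {
                        "time": float(tl),
                        "observable": obs.id,
                        "value": float(y[offset + l, k] + noise[l]),
                        "sd": spec.sigma,
                    }
                )
        table = pd.DataFrame(rows, columns=["time", "observable", "value", "sd"])
        conds.append(ExperimentCondition(exp.id, exp.inputs, Dataset(table)))
    return model.with_experiments(conds)


def make_conjugate_toy(
    n_data: int = 10,
    sigma: float = 0.2,
    prior_mu: float = 0.0,
    prior_sd: float = 1.0,
    z_true: float = 0.3,
    seed: int = 11,
) -> tuple[BRNModel, Prior, dict[str, float]]:
    """Linear-Gaussian toy: y = log10(theta0) + noise, conjugate posterior.

    The single state is constant at x = theta0, observed through log10, so
    each datum is z* + eps with z* = log10(theta0).  With a normal prior on
    z = log10(theta0) the posterior is the standard Gaussian conjugate:
    precision 1/sd0^2 + n/sigma^2.  Returns (model-with-data, prior, closed
    form {post_mean, post_sd} in log10 units).
    """
    model = BRNModel(
        species=(Species("C", "C", sym("theta0")),),
        reactions=(),
        parameters=("theta0",),
        observables=(ObservableDef("ylog", {"C": 1.0}, log10=True),),
        experiments=(ExperimentCondition("e1"),),
        name="conjugate_toy",
    )
    rng = np.random.default_rng(seed)
    times = np.arange(1.0, n_data + 1.0)
    values = z_true + rng.normal(0.0, sigma, n_data)
    table = pd.DataFrame(
        {"time": times, "observable": "ylog", "value": values, "sd": sigma}
    )
    model = model.with_experiments([ExperimentCondition("e1", dataset=Dataset(table))])
    prior = Prior({"theta0": PriorComponent("log10_normal", prior_mu, prior_sd)})
    prec = 1.0 / prior_sd**2 + n_data / sigma**2
    post_sd = prec**-0.5
    post_mean = (prior_mu / prior_sd**2 + values.sum() / sigma**2) / prec
    return model, prior, {"post_mean": float(post_mean), "post_sd": float(post_sd)}


# ---------------------------------------------------------------------------
# file emission (the `fixtures generate` CLI path)


def experiment_to_json(model: BRNModel, exp: ExperimentCondition, include_observables: bool = True) -> dict:
    obj: dict = {"id": exp.id, "inputs": {}}
    for ch in exp.inputs:
        obj["inputs"][ch.id] = {"times": list(ch.times), "values": list(ch.values)}
    if include_observables:
        obj["observables"] = [
            {"id": o.id, "weights": dict(o.weights), "scale": o.scale, "log10": o.log10}
            for o in model.observables
        ]
    if exp.dataset is not None:
        obj["data"] = exp.dataset.table.to_dict(orient="records")
    return obj


def generate_fixture_files(name: str, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write SBML + experiment JSON + data CSV + prior JSON + true-theta CSV."""
    from .sbml import write_sbml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = default_spec(name, seed=seed)
    model = make_data(make_model(name), spec)
    paths: dict[str, Path] = {}
    sbml_path = out / f"{name}.xml"
    write_sbml(model, sbml_path, parameter_values=spec.theta_true)
    paths["sbml"] = sbml_path
    for exp in model.experiments:
        p = out / f"{name}_{exp.id}.json"
        p.write_text(json.dumps(experiment_to_json(model, exp), indent=1))
        paths[f"experiment_{exp.id}"] = p
        csv_path = out / f"{name}_{exp.id}_data.csv"
        exp.dataset.table.to_csv(csv_path, index=False)
        paths[f"data_{exp.id}"] = csv_path
    prior = fixture_prior(name)
    prior_obj = {
        n: {"type": c.kind, "params": [c.a] if c.kind == "fixed" else [c.a, c.b]}
        for n, c in prior.components.items()
    }
    prior_path = out / f"{name}_prior.json"
    prior_path.write_text(json.dumps(prior_obj, indent=1))
    paths["prior"] = prior_path
    theta_path = out / f"{name}_theta_true.csv"
    pd.DataFrame([spec.theta_true]).to_csv(theta_path, index=False)
    paths["theta_true"] = theta_path
    return paths
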