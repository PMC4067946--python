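"""Domain types for biochemical reaction networks.

A model couples species (nodes), reactions (directed links with rate laws and
optional modifier hyper-edges), a strictly positive parameter vector theta,
observables (weighted sums of states, optionally scaled and log10-transformed)
and experimental conditions (piecewise-constant inputs u(t) plus measured
data).  The stoichiometric matrix S (n_x x n_r) holds the net molecule change
per reaction, S_ij = s^(p)_ij - s^(r)_ij; modifiers never contribute to S.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import sympy as sp

from .expressions import (
    GeneralRate,
    MassAction,
    MichaelisMenten,
    RateLaw,
    RateLawError,
    check_symbols as _check_symbols,
    sym,
)

ENV_NODE = "__env__"  # shared source/sink node for boundary reactions


class ModelError(ValueError):
    pass


def check_symbols(expr, species_ids, parameter_ids, input_ids, context) -> None:
    try:
        _check_symbols(expr, species_ids, parameter_ids, input_ids, context)
    except RateLawError as exc:
        raise ModelError(str(exc)) from None


class LookupError_(KeyError):
    """Unknown element id."""


@dataclass(frozen=True)
class Species:
    id: str
    name: str = ""
    initial: sp.Expr | float = 0.0

    @property
    def initial_expr(self) -> sp.Expr:
        return sp.sympify(self.initial)


@dataclass(frozen=True)
class Reaction:
    id: str
    reactant_stoich: Mapping[str, int] = field(default_factory=dict)
    product_stoich: Mapping[str, int] = field(default_factory=dict)
    rate_law: RateLaw = field(default_factory=lambda: GeneralRate(sp.Integer(0)))
    modifiers: frozenset[str] = frozenset()
    name: str = ""

    def rate_expr(self) -> sp.Expr:
        return self.rate_law.expression(self.reactant_stoich)

    @property
    def parameters(self) -> tuple[str, ...]:
        return self.rate_law.parameters


@dataclass(frozen=True)
class ObservableDef:
    """y_k = [scale *] sum_i w_i x_i, optionally log10-transformed last.

    With a log10 transform the output may legitimately be negative even
    though concentrations are not.
    """

    id: str
    weights: Mapping[str, float]
    scale: str | None = None  # parameter id
    log10: bool = False

    @property
    def member_species(self) -> frozenset[str]:
        return frozenset(s for s, w in self.weights.items() if w != 0)

    def __post_init__(self) -> None:
        if not self.member_species:
            raise ModelError(f"observable {self.id!r} has no member species")


@dataclass(frozen=True)
class InputChannel:
    """Piecewise-constant input: value[i] holds on [times[i], times[i+1])."""

    id: str
    times: tuple[float, ...] = (0.0,)
    values: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values) or not self.times:
            raise ModelError(f"input {self.id!r}: times/values length mismatch")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ModelError(f"input {self.id!r}: breakpoints must strictly increase")

    def value_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.values[max(idx, 0)]


@dataclass(frozen=True)
class Dataset:
    """Long-form measurements: one row per (time, observable) with value and sd."""

    table: pd.DataFrame  # columns: time, observable, value, sd

    def __post_init__(self) -> None:
        required = {"time", "observable", "value", "sd"}
        if not required.issubset(self.table.columns):
            raise ModelError(f"dataset needs columns {sorted(required)}")
        present = self.table.dropna(subset=["value"])
        if (present["sd"] <= 0).any() or present["sd"].isna().any():
            raise ModelError("a positive noise SD is required wherever a value is present")
        if (self.table["time"] < 0).any():
            raise ModelError("measurement times must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.table["time"].to_numpy(float))

    @property
    def n_points(self) -> int:
        return int(self.table["value"].notna().sum())


@dataclass(frozen=True)
class ExperimentCondition:
    id: str
    inputs: tuple[InputChannel, ...] = ()
    dataset: Dataset | None = None

    def input_values_at(self, t: float) -> np.ndarray:
        return np.array([ch.value_at(t) for ch in self.inputs], float)

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        pts = sorted({bt for ch in self.inputs for bt in ch.times if t0 < bt < t1})
        return np.array(pts, float)


@dataclass
class BRNModel:
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    parameters: tuple[str, ...]
    observables: tuple[ObservableDef, ...] = ()
    experiments: tuple[ExperimentCondition, ...] = ()
    inputs: tuple[str, ...] = ()  # input channel ids (n_u)
    name: str = "model"

    def __post_init__(self) -> None:
        self.validate()
        self._cache: dict = {}

    # -- lookups -------------------------------------------------------
    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def observable_ids(self) -> tuple[str, ...]:
        return tuple(o.id for o in self.observables)

    @property
    def n_x(self) -> int:
        return len(self.species)

    @property
    def n_r(self) -> int:
        return len(self.reactions)

    def species_index(self, sid: str) -> int:
        try:
            return self.species_ids.index(sid)
        except ValueError:
            raise LookupError_(f"unknown species {sid!r}") from None

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise LookupError_(f"unknown reaction {rid!r}")

    def observable(self, oid: str) -> ObservableDef:
        for o in self.observables:
            if o.id == oid:
                return o
        raise LookupError_(f"unknown observable {oid!r}")

    def experiment(self, eid: str) -> ExperimentCondition:
        for e in self.experiments:
            if e.id == eid:
                return e
        raise LookupError_(f"unknown experiment {eid!r}")

    def theta_vector(self, theta: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        if isinstance(theta, Mapping):
            missing = [p for p in self.parameters if p not in theta]
            if missing:
                raise ModelError(f"theta missing parameters {missing}")
            vec = np.array([theta[p] for p in self.parameters], float)
        else:
            vec = np.asarray(theta, float)
            if vec.shape != (len(self.parameters),):
                raise ModelError(
                    f"theta has shape {vec.shape}, expected ({len(self.parameters)},)"
                )
        return vec

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ModelError("species ids are not unique")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelError("reaction ids are not unique")
        if len(set(self.parameters)) != len(self.parameters):
            raise ModelError("parameter names are not unique")
        sids = set(ids)
        for r in self.reactions:
            for smap, side in ((r.reactant_stoich, "reactant"), (r.product_stoich, "product")):
                for s, c in smap.items():
                    if s not in sids:
                        raise ModelError(f"reaction {r.id!r}: unknown {side} species {s!r}")
                    if int(c) != c or c < 0:
                        raise ModelError(
                            f"reaction {r.id!r}: stoichiometric coefficients must be "
                            f"nonnegative integers, got {c!r} for {s!r}"
                        )
            expr = r.rate_expr()
            check_symbols(expr, ids, self.parameters, self.inputs, f"reaction {r.id!r}")
            free = {s.name for s in expr.free_symbols}
            for m in r.modifiers:
                if m not in sids:
                    raise ModelError(f"reaction {r.id!r}: unknown modifier {m!r}")
                if m not in free:
                    raise ModelError(f"reaction {r.id!r}: modifier {m!r} absent from rate law")
                if r.reactant_stoich.get(m, 0) or r.product_stoich.get(m, 0):
                    raise ModelError(
                        f"reaction {r.id!r}: modifier {m!r} must have zero stoichiometry"
                    )
            for p in r.parameters:
                if p not in self.parameters:
                    raise ModelError(f"reaction {r.id!r}: unknown parameter {p!r}")
        for s in self.species:
            check_symbols(s.initial_expr, [], self.parameters, self.inputs, f"species {s.id!r} initial")
        for o in self.observables:
            for s in o.weights:
                if s not in sids:
                    raise ModelError(f"observable {o.id!r}: unknown species {s!r}")
            if o.scale is not None and o.scale not in self.parameters:
                raise ModelError(f"observable {o.id!r}: unknown scale parameter {o.scale!r}")

    def with_experiments(self, experiments: Iterable[ExperimentCondition]) -> "BRNModel":
        return replace(self, experiments=tuple(experiments))


# ---------------------------------------------------------------------------
# stoichiometry and graph


def stoichiometric_matrix(model: BRNModel) -> np.ndarray:
    """Net stoichiometry S (n_x x n_r): product minus reactant coefficients."""
    S = np.zeros((model.n_x, model.n_r), dtype=int)
    for j, r in enumerate(model.reactions):
        for s, c in r.reactant_stoich.items():
            S[model.species_index(s), j] -= int(c)
        for s, c in r.product_stoich.items():
            S[model.species_index(s), j] += int(c)
    return S


@dataclass
class NetworkGraph:
    """Attributed multi-layer graph: species nodes, reaction links, modifier
    hyper-edges and observable hulls over member-species sets."""

    graph: nx.MultiDiGraph
    links: tuple[tuple[str, str, str], ...]  # (source, target, reaction id)
    hyper_edges: tuple[tuple[str, str], ...]  # (species id, reaction id)
    output_hulls: dict[str, frozenset[str]]
    static_attrs: dict = field(default_factory=dict)
    dynamic_attrs: dict = field(default_factory=dict)

    def degree(self, node: str) -> int:
        d = self.graph.degree(node)
        d += sum(1 for s, _ in self.hyper_edges if s == node)
        return d

    def reaction_links(self, rid: str) -> list[tuple[str, str]]:
        return [(a, b) for a, b, r in self.links if r == rid]


def build_graph(model: BRNModel) -> NetworkGraph:
    """Node-link view of the network.

    Each reaction contributes one link per (reactant, product) pair; boundary
    reactions (no reactants or no products) are anchored at a shared
    environment node so every reaction yields at least one link.
    """
    g = nx.MultiDiGraph()
    for s in model.species:
        g.add_node(s.id, kind="species", name=s.name or s.id)
    links: list[tuple[str, str, str]] = []
    need_env = any(not r.reactant_stoich or not r.product_stoich for r in model.reactions)
    if need_env:
        g.add_node(ENV_NODE, kind="env", name="environment")
    for r in model.reactions:
        sources = [s for s, c in r.reactant_stoich.items() if c] or [ENV_NODE]
        targets = [s for s, c in r.product_stoich.items() if c] or [ENV_NODE]
        for a in sources:
            for b in targets:
                g.add_edge(a, b, key=r.id, reaction=r.id, parameters=",".join(r.parameters))
                links.append((a, b, r.id))
    hyper = tuple((m, r.id) for r in model.reactions for m in sorted(r.modifiers))
    hulls = {o.id: o.member_species for o in model.observables}
    return NetworkGraph(graph=g, links=tuple(links), hyper_edges=hyper, output_hulls=hulls)


def select_linked(model: BRNModel, element: str) -> dict[str, set[str]]:
    """Single-hop linked-element sets used by the coordinated views.

    parameter -> reactions referencing it; species -> observables containing it
    and reactions touching it (stoichiometry or modifier); observable -> member
    species; reaction -> its rate-law parameters.
    """
    out: dict[str, set[str]] = {"species": set(), "reactions": set(), "observables": set(), "parameters": set()}
    if element in model.parameters:
        out["reactions"] = {r.id for r in model.reactions if element in r.parameters}
        return out
    if element in model.species_ids:
        out["observables"] = {o.id for o in model.observables if element in o.member_species}
        out["reactions"] = {
            r.id
            for r in model.reactions
            if r.reactant_stoich.get(element, 0)
            or r.product_stoich.get(element, 0)
            or element in r.modifiers
        }
        return out
    if element in model.observable_ids:
        out["species"] = set(model.observable(element).member_species)
        return out
    if element in model.reaction_ids:
        out["parameters"] = set(model.reaction(element).parameters)
        return out
    raise LookupError_(f"unknown element {element!r}")


def write_graphml(graph: NetworkGraph, path: str | Path) -> None:
    g = graph.graph.copy()
    for sid, rid in graph.hyper_edges:
        g.add_edge(sid, rid if g.has_node(rid) else f"reaction:{rid}", kind="modifier")
    for oid, members in graph.output_hulls.items():
        for m in members:
            g.nodes[m].setdefault("outputs", "")
            tag = g.nodes[m]["outputs"]
            g.nodes[m]["outputs"] = f"{tag},{oid}" if tag else oid
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# experiment sidecar files


def _channels_from_json(obj: Mapping) -> tuple[InputChannel, ...]:
    chans = []
    for cid, spec in obj.items():
        chans.append(
            InputChannel(id=cid, times=tuple(float(x) for x in spec["times"]), values=tuple(float(x) for x in spec["values"]))
        )
    return tuple(chans)


def _observables_from_json(items: Sequence[Mapping]) -> tuple[ObservableDef, ...]:
    return tuple(
        ObservableDef(
            id=o["id"],
            weights={k: float(v) for k, v in o["weights"].items()},
            scale=o.get("scale"),
            log10=bool(o.get("log10", False)),
        )
        for o in items
    )


def load_experiment(path: str | Path, model: BRNModel | None = None) -> tuple[ExperimentCondition, tuple[ObservableDef, ...]]:
    """Read an experiment description (JSON sidecar).

    Keys: ``id``, ``inputs`` ({channel: {times, values}}), optional
    ``observables`` and optional ``data`` (long-form records with time,
    observable, value, sd).  Returns the condition and any observables the file
    defines; if ``model`` is given, observable/species references are checked.
    """
    path = Path(path)
    obj = json.loads(path.read_text())
    inputs = _channels_from_json(obj.get("inputs", {}))
    observables = _observables_from_json(obj.get("observables", []))
    dataset = None
    if obj.get("data"):
        dataset = Dataset(pd.DataFrame.from_records(obj["data"])[["time", "observable", "value", "sd"]])
    cond = ExperimentCondition(id=obj.get("id", path.stem), inputs=inputs, dataset=dataset)
    if model is not None:
        known = set(model.observable_ids) | {o.id for o in observables}
        if dataset is not None:
            bad = sorted(set(dataset.table["observable"]) - known)
            if bad:
                raise ModelError(f"experiment {cond.id!r}: data for unknown observables {bad}")
    return cond, observables


def load_data_csv(path: str | Path) -> Dataset:
    """Measurements as CSV with header ``time,observable,value,sd``."""
    df = pd.read_csv(path)
    return Dataset(df[["time", "observable", "value", "sd"]])


def attach_experiments(model: BRNModel, paths: Sequence[str | Path]) -> BRNModel:
    """Load sidecar experiment files and return a model carrying them.

    Observable definitions found in the files are merged (first definition
    wins; conflicting redefinitions raise).
    """
    conds: list[ExperimentCondition] = []
    obs: dict[str, ObservableDef] = {o.id: o for o in model.observables}
    for p in paths:
        cond, new_obs = load_experiment(p)
        for o in new_obs:
            if o.id in obs and obs[o.id] != o:
                raise ModelError(f"conflicting definitions for observable {o.id!r}")
            obs.setdefault(o.id, o)
        conds.append(cond)
    input_ids = sorted({ch.id for c in conds for ch in c.inputs} | set(model.inputs))
    m = replace(model, observables=tuple(obs.values()), experiments=tuple(conds), inputs=tuple(input_ids))
    return m
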