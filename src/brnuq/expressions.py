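"""Symbolic rate laws and compiled numeric evaluation.

Rate laws are stored symbolically (sympy) so that SBML kinetic laws, structural
pattern detection (mass action, Michaelis-Menten) and fast numeric evaluation
all share one representation.  Species, parameters and input channels are plain
``sympy.Symbol`` objects keyed by their model id; time is the symbol ``t``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import sympy as sp

TIME = sp.Symbol("t")


def sym(name: str) -> sp.Symbol:
    return sp.Symbol(name)


class RateLawError(ValueError):
    """A rate law references unknown symbols or is structurally invalid."""


@dataclass(frozen=True)
class MassAction:
    """v = kappa * prod_i x_i^{s_r[i]}; kappa is a single rate coefficient.

    The reactant orders come from the reaction's reactant stoichiometry, so
    the law itself only names its parameter.
    """

    parameter: str

    @property
    def parameters(self) -> tuple[str, ...]:
        return (self.parameter,)

    def expression(self, reactant_stoich: Mapping[str, int]) -> sp.Expr:
        expr: sp.Expr = sym(self.parameter)
        for species_id, coeff in reactant_stoich.items():
            if coeff:
                expr = expr * sym(species_id) ** int(coeff)
        return expr


@dataclass(frozen=True)
class MichaelisMenten:
    """v = vmax * x / (km + x) for a single substrate x."""

    substrate: str
    vmax: str
    km: str

    @property
    def parameters(self) -> tuple[str, ...]:
        return (self.vmax, self.km)

    def expression(self, reactant_stoich: Mapping[str, int]) -> sp.Expr:
        x = sym(self.substrate)
        return sym(self.vmax) * x / (sym(self.km) + x)


@dataclass(frozen=True)
class GeneralRate:
    """An arbitrary flux expression with an explicit parameter order.

    The order matters downstream: link segmentation in the graph view assigns
    the first parameter to the link start and the last to the arrowhead.
    """

    expr: sp.Expr
    parameters: tuple[str, ...] = field(default=())

    def expression(self, reactant_stoich: Mapping[str, int]) -> sp.Expr:
        return self.expr


RateLaw = MassAction | MichaelisMenten | GeneralRate


def classify_rate_law(
    expr: sp.Expr,
    reactant_stoich: Mapping[str, int],
    species_ids: Sequence[str],
    parameter_ids: Sequence[str],
) -> RateLaw:
    """Structurally detect mass-action or Michaelis-Menten form.

    Anything that does not match exactly becomes a :class:`GeneralRate` whose
    parameter order follows the model's parameter ordering.
    """
    params = set(parameter_ids)
    species = set(species_ids)
    # mass action: expr / prod(x^s_r) is a single parameter symbol
    monomial: sp.Expr = sp.Integer(1)
    for sid, coeff in reactant_stoich.items():
        if coeff:
            monomial *= sym(sid) ** int(coeff)
    candidate = sp.simplify(sp.cancel(expr / monomial))
    if isinstance(candidate, sp.Symbol) and candidate.name in params:
        return MassAction(candidate.name)
    # Michaelis-Menten: vmax * x / (km + x) for one substrate species x
    a, b = sp.Wild("a"), sp.Wild("b")
    for sid in sorted(s.name for s in expr.free_symbols if s.name in species):
        x = sym(sid)
        match = expr.match(a * x / (b + x))
        if match is None:
            continue
        va, vb = match[a], match[b]
        if (
            isinstance(va, sp.Symbol)
            and isinstance(vb, sp.Symbol)
            and va.name in params
            and vb.name in params
        ):
            return MichaelisMenten(substrate=sid, vmax=va.name, km=vb.name)
    used = [p for p in parameter_ids if sym(p) in expr.free_symbols]
    return GeneralRate(expr, tuple(used))


def check_symbols(
    expr: sp.Expr,
    species_ids: Sequence[str],
    parameter_ids: Sequence[str],
    input_ids: Sequence[str],
    context: str,
) -> None:
    allowed = set(species_ids) | set(parameter_ids) | set(input_ids) | {TIME.name}
    unknown = sorted(s.name for s in expr.free_symbols if s.name not in allowed)
    if unknown:
        raise RateLawError(f"{context}: unbound symbol(s) {', '.join(unknown)}")


def lambdify_vector(
    exprs: Sequence[sp.Expr],
    species_ids: Sequence[str],
    parameter_ids: Sequence[str],
    input_ids: Sequence[str],
):
    """Compile a list of expressions to ``f(x, theta, u, t) -> list``.

    ``x``, ``theta`` and ``u`` are sequences in model order; broadcasting over
    numpy arrays works, so a whole time course can be evaluated in one call.
    """
    args = (
        [sym(s) for s in species_ids],
        [sym(p) for p in parameter_ids],
        [sym(c) for c in input_ids],
        TIME,
    )
    return sp.lambdify(args, list(exprs), modules="numpy")
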