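# Methods

## Model class and scope

`brnuq` treats a biochemical reaction network as an ODE system `dx/dt =
S v(x, θ, u)` with nonnegative states (concentrations), nonnegative fluxes,
strictly positive parameters and piecewise-constant experimental inputs
`u(t)`. Three rate-law forms are recognized structurally: mass action
(`v_j = κ_j ∏ x_i^{s(r)_ij}`, with `0^0 := 1` so absent reactants with zero
coefficient do not annihilate the product), single-substrate
Michaelis–Menten (`v_j = κ_{j,max} x / (κ_j + x)`), and a validated general
expression with an explicit parameter order. Modifiers are species that
appear in a rate expression with zero stoichiometry; they become directed
hyper-edges in the network graph and never contribute to `S`.

SBML support is deliberately restricted to the Level 2/3 core constructs
this model class needs: species with numeric initial concentrations or
initial assignments, global parameters, and reactions with kinetic-law
MathML. Events, algebraic/assignment rules, delays, constraints and function
definitions raise an explicit unsupported-feature error — content is never
silently dropped. Reversible reactions are split into forward/backward
irreversible halves by sign-separating the expanded kinetic law, keeping all
fluxes nonnegative. Two conventions are ours and are used by the bundled
fixtures: SBML global parameters marked `constant="false"` are interpreted
as input channels `u`, and observables/input time courses/measurements live
in a JSON sidecar per experiment (`inputs`, `observables`, `data`), since
core SBML carries none of these.

## Numerics

Integration uses LSODA (stiff/non-stiff switching) with `rtol = 1e-8`,
`atol = 1e-10` — two to four orders below any tolerance asserted downstream.
The right-hand side `S v` is compiled symbolically once per model, so
repeated likelihood evaluations avoid per-call expression interpretation.
Integration restarts at every input breakpoint because piecewise-constant
inputs make the derivative discontinuous there. States in `(−1e-8, 0)` are
clamped to zero with a logged warning; anything more negative is a hard
error. Simulation failure at a proposed parameter vector is treated as zero
likelihood (the chain rejects and continues), with a logged diagnostic.

## Inference

The posterior is sampled in `log10(θ)` — the natural scale for strictly
positive kinetic constants — by a single-chain random-walk Metropolis
sampler with a diagonal Gaussian proposal. During burn-in (default: the
first half of the chain) the global proposal scale follows a Robbins–Monro
recursion toward 25% acceptance, and per-coordinate scales are re-estimated
once from the interim chain's marginal SDs. After burn-in the proposal is
frozen, so the kept draws target the exact posterior. Priors are
`log10_uniform(lo, hi)` (flat in log10 units), `log10_normal(μ, σ)` (normal
on log10 θ), or `fixed(value)` (held constant, excluded from sampling but
reported as a constant column so samples always align with the model's full
parameter vector). Noise SDs are known inputs; estimating them is out of
scope. Convergence reporting is limited to the acceptance rate plus the
chain itself — anything further (R-hat, ESS) is left to external tools.

The sampler is validated against a conjugate linear-Gaussian toy (a constant
state equal to a parameter, observed through log10, for which the posterior
is available in closed form), against prior-only sampling (no data), and by
parameter recovery on synthetic cascade data.

## Ensembles and summaries

Each posterior draw is simulated per experimental condition, giving aligned
state/flux/output trajectory ensembles (row α ↔ θ^(α)); draws whose
simulation fails are dropped with their indices logged, and more than 5%
failures abort, since the ensemble would no longer represent the sample.
Summaries are pointwise: mean, unbiased SD, median and a percentile band,
default `[P5, P95]` (the 90% Bayesian confidence interval). Percentiles use
sorted linear interpolation so they are reproducible bit for bit. Band
coverage is therefore 90% by construction up to ties — except in degenerate
cells where the band has zero width (a deterministic initial condition, or
an element constant across draws such as a conserved enzyme): there every
member lies on the band and the coverage fraction is trivially 1. Coverage
assessments consequently restrict to cells with positive band width.

Dependency screening offers Pearson matrices in four contexts (parameter
draws; ensemble members at a selected time point, snapped to the nearest
grid point with a logged note; mean or SD time courses across elements) and
a pairwise PCA eigenvalue-ratio matrix: for each standardized column pair,
`λ_min/λ_max` of the 2×2 covariance, which equals `(1−|r|)/(1+|r|)` — 0 for
a perfectly determined direction, 1 for independence. This pairwise
definition is the simplest PCA-based measure consistent with its purpose;
it is recorded here because the quantity is named, not defined, in the
visualization literature this package follows. Zero-variance columns yield
NaN sentinels rather than arbitrary numbers.

Histograms intended for side-by-side comparison share one bin width: the
maximum Freedman–Diaconis width over the selected parameters, falling back
to `range/⌈√n_s⌉` (logged) when every selection has zero IQR. Drastic-change
detection for animation flags frame `t` of element `i` when
`|s_i(t) − s_i(t−1)| > threshold · range_t(s_i)` with default threshold 0.2;
the rule and default are our own — flat elements are never flagged.

## Views

Interactivity (brushing, flashing highlights, check boxes, time slider) is
replaced by declarative selection lists and ordered frame sequences, which
preserves every computational behavior while staying scriptable: the
single-hop linked-element map (parameter → reactions, species → observables
and touching reactions, observable → member species, reaction → parameters)
is a plain function, and animation is a directory of zero-padded frames with
change-flagged elements outlined. Links with k-parameter rate laws split
into k equal-length segments, first parameter at the link start, last at the
arrowhead; observable member sets are drawn as padded convex hulls. The
univariate colormaps are sequential/diverging ColorBrewer-named palettes;
the bivariate (mean, SD) map is the product of two 4-level single-hue ramps
quantized to a 4×4 grid — one documented construction among many possible.
Layout is seeded force-directed (or user coordinates), and every figure gets
a JSON sidecar of its plotted numbers, so tests never parse images; SVG
output is byte-deterministic (fixed hash salt, no embedded dates).

## Fixtures and what they do (not) show

The bundled generators produce models small enough (≤ 6 species) that
brute-force oracles — fixed-step RK4 integration, exhaustive per-point
likelihood sums, sort-and-interpolate percentiles — run in seconds: `decay`
(closed form `e^{−κt}`), `conserved_pair` (left null vector (1,1) of S, so
total mass is conserved), and `mm_cascade` (production driven by `u(t)`, a
two-parameter MM step, an enzyme modifier hyper-edge, a sum-of-states
observable, two conditions differing in input). Ground truth for
`mm_cascade` is `k_in = 1, vmax2 = 2, km2 = 1, k3 = 0.5, k4 = 0.3` with
measurement SD 0.05 at six times per observable and condition, and priors
are log10-uniform one decade either side of truth; the recovery study frees
(`vmax2`, `km2`, `k4`) and fixes the rest. These choices define the study
conditions used throughout the tests and the acceptance script (1000-draw
ensembles on a 100-point grid; 20000-step conjugate and 50000-step recovery
chains), and they run comfortably on one CPU.

Synthetic data are exactly the package's own noise model — independent
Gaussian noise with known SD on noiseless simulated outputs. Passing tests
therefore demonstrate internal consistency and correct mathematics, not
robustness to what real data add: misspecified rate laws, non-Gaussian or
correlated errors, unknown noise scales, unobserved confounding conditions.
The published 113-parameter JAK2/STAT5 benchmark is supported as an input
(its structural check runs when a user supplies the SBML) but is not
emulated.

## Known limitations

Single chain (no parallel tempering or multi-chain diagnostics); no
profile-likelihood intervals; no stochastic (SDE/CTMC) simulation; no
steady-state or sensitivity analysis; graph layout beyond the seeded default
is the user's responsibility; the SBML writer covers only the fixtures'
round-trip subset.
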