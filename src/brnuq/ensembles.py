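"""Uncertainty propagation and ensemble summaries.

A parameter sample {theta^(a)} induces, per experimental condition, samples of
state, flux and output trajectories obtained by simulating every draw.  The
summaries here — pointwise mean/SD/median/percentile bands, Pearson and
PCA-eigenvalue-ratio matrices, shared-bin-width histograms and drastic-change
flags — are what the static views render.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .bayes import ParameterSample
from .kinetics import SimulationError, SolverConfig, evaluate_outputs, simulate
from .model import BRNModel, ExperimentCondition, ModelError

log = logging.getLogger(__name__)

Kind = Literal["state", "flux", "output"]


@dataclass
class TrajectoryEnsemble:
    kind: Kind
    values: np.ndarray  # (n_s, n_t, dim)
    t: np.ndarray
    experiment_id: str
    labels: tuple[str, ...]
    draw_indices: np.ndarray | None = None  # surviving rows of the sample

    @property
    def n_s(self) -> int:
        return self.values.shape[0]

    def at_time(self, t_k: float) -> tuple[np.ndarray, float]:
        """Slice (n_s x dim) at the grid point nearest to t_k."""
        i = int(np.argmin(np.abs(self.t - t_k)))
        if not math.isclose(float(self.t[i]), t_k, rel_tol=0.0, abs_tol=1e-12):
            log.info("t_k=%g off the grid; using nearest grid point %g", t_k, self.t[i])
        return self.values[:, i, :], float(self.t[i])


@dataclass
class EnsembleSet:
    states: TrajectoryEnsemble
    fluxes: TrajectoryEnsemble
    outputs: TrajectoryEnsemble


def propagate(
    model: BRNModel,
    sample: ParameterSample,
    experiment: ExperimentCondition,
    t_grid: Sequence[float],
    solver: SolverConfig | None = None,
    max_failure_fraction: float = 0.05,
) -> EnsembleSet:
    """Simulate every draw of the sample and stack the trajectories.

    Draws whose simulation fails are dropped (logged); more than
    ``max_failure_fraction`` failures abort, since the ensemble would no
    longer represent the sample.  Results are independent of evaluation
    order, so the loop is embarrassingly parallel by contract.
    """
    names = sample.names
    missing = [p for p in model.parameters if p not in names]
    if missing:
        raise ModelError(f"sample missing parameters {missing}")
    theta_lin = sample.linear().draws[list(model.parameters)].to_numpy()
    t_grid = np.asarray(t_grid, float)
    xs, vs, ys, kept = [], [], [], []
    for a in range(len(theta_lin)):
        try:
            st, fl = simulate(model, theta_lin[a], experiment, t_grid, solver)
            y = evaluate_outputs(model, st, theta_lin[a]) if model.observables else np.empty((len(t_grid), 0))
        except (SimulationError, ModelError) as exc:
            log.warning("dropping draw %d: %s", a, exc)
            continue
        xs.append(st.x)
        vs.append(fl.v)
        ys.append(y)
        kept.append(a)
    n_fail = len(theta_lin) - len(kept)
    if n_fail > max_failure_fraction * len(theta_lin):
        raise SimulationError(
            f"{n_fail}/{len(theta_lin)} draws failed to simulate (> {max_failure_fraction:.0%})"
        )
    idx = np.array(kept, int)
    return EnsembleSet(
        states=TrajectoryEnsemble("state", np.stack(xs), t_grid, experiment.id, model.species_ids, idx),
        fluxes=TrajectoryEnsemble("flux", np.stack(vs), t_grid, experiment.id, model.reaction_ids, idx),
        outputs=TrajectoryEnsemble("output", np.stack(ys), t_grid, experiment.id, model.observable_ids, idx),
    )


# ---------------------------------------------------------------------------
# summary statistics


@dataclass
class SummaryStats:
    """Pointwise mean, unbiased SD, median and a percentile band per element."""

    t: np.ndarray
    labels: tuple[str, ...]
    mean: np.ndarray  # (n_t, dim)
    sd: np.ndarray
    median: np.ndarray
    p_low: np.ndarray
    p_high: np.ndarray
    percentiles: tuple[float, float] = (5.0, 95.0)
    kind: str = "state"
    experiment_id: str = ""

    def series(self, statistic: str) -> np.ndarray:
        return getattr(self, statistic)


def summarize(ensemble: TrajectoryEnsemble, percentiles: tuple[float, float] = (5.0, 95.0)) -> SummaryStats:
    """Default band is [P5, P95] — the 90% Bayesian confidence interval."""
    vals = ensemble.values
    if vals.shape[0] < 2:
        raise ValueError("summaries need at least two sample members")
    lo, hi = percentiles
    p = np.percentile(vals, [lo, 50.0, hi], axis=0)  # linear interpolation
    return SummaryStats(
        t=ensemble.t,
        labels=ensemble.labels,
        mean=vals.mean(axis=0),
        sd=vals.std(axis=0, ddof=1),
        median=p[1],
        p_low=p[0],
        p_high=p[2],
        percentiles=(float(lo), float(hi)),
        kind=ensemble.kind,
        experiment_id=ensemble.experiment_id,
    )


def band_coverage(ensemble: TrajectoryEnsemble, stats: SummaryStats) -> np.ndarray:
    """Pointwise fraction of members inside [p_low, p_high]: (n_t, dim)."""
    v = ensemble.values
    inside = (v >= stats.p_low[None]) & (v <= stats.p_high[None])
    return inside.mean(axis=0)


# ---------------------------------------------------------------------------
# correlation structure


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    labels: tuple[str, ...]
    context: str = "parameters"


@dataclass
class EigenRatioMatrix:
    """Pairwise PCA collinearity: lambda_min/lambda_max of each standardized
    2x2 covariance; 0 means a perfectly determined direction, 1 independence."""

    values: np.ndarray
    labels: tuple[str, ...]
    context: str = "parameters"


def pearson_matrix(columns: np.ndarray | pd.DataFrame, labels: Sequence[str] | None = None, context: str = "parameters") -> CorrelationMatrix:
    """Pearson product-moment coefficients; zero-variance columns yield NaN."""
    if isinstance(columns, pd.DataFrame):
        labels = labels or tuple(columns.columns)
        columns = columns.to_numpy(float)
    cols = np.asarray(columns, float)
    if cols.ndim != 2 or cols.shape[1] < 2:
        raise ValueError("need an n_s x d matrix with d >= 2")
    d = cols.shape[1]
    sd = cols.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("zero-variance columns at indices %s; coefficients set to NaN", np.flatnonzero(degenerate))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(cols, rowvar=False)
    r = np.asarray(r, float)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, np.where(degenerate, np.nan, 1.0))
    r = np.clip(r, -1.0, 1.0)
    labels = tuple(labels) if labels is not None else tuple(f"c{i}" for i in range(d))
    return CorrelationMatrix(r, labels, context)


def eigen_ratio_matrix(columns: np.ndarray | pd.DataFrame, labels: Sequence[str] | None = None, context: str = "parameters") -> EigenRatioMatrix:
    """For each pair: standardize, eigendecompose the 2x2 covariance and
    report lambda_min/lambda_max (equals (1-|r|)/(1+|r|))."""
    if isinstance(columns, pd.DataFrame):
        labels = labels or tuple(columns.columns)
        columns = columns.to_numpy(float)
    cols = np.asarray(columns, float)
    if cols.ndim != 2 or cols.shape[1] < 2:
        raise ValueError("need an n_s x d matrix with d >= 2")
    d = cols.shape[1]
    sd = cols.std(axis=0, ddof=1)
    out = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            if sd[i] == 0 or sd[j] == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            zi = (cols[:, i] - cols[:, i].mean()) / sd[i]
            zj = (cols[:, j] - cols[:, j].mean()) / sd[j]
            cov = np.cov(np.column_stack([zi, zj]), rowvar=False)
            eig = np.linalg.eigvalsh(cov)
            out[i, j] = out[j, i] = float(max(eig[0], 0.0) / eig[1]) if eig[1] > 0 else np.nan
    labels = tuple(labels) if labels is not None else tuple(f"c{i}" for i in range(d))
    return EigenRatioMatrix(out, labels, context)


def correlation_contexts(
    source: ParameterSample | TrajectoryEnsemble,
    context: str,
    t_k: float | None = None,
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> CorrelationMatrix:
    """Correlations in the paper's four contexts.

    ``parameters``: across sample draws (log10 scale);
    ``at_time``: across ensemble members at the grid point nearest t_k;
    ``mean_course`` / ``sd_course``: between elements' summary time series.
    """
    if context == "parameters":
        if not isinstance(source, ParameterSample):
            raise ValueError("context 'parameters' needs a ParameterSample")
        return pearson_matrix(source.log10().draws, context="parameters")
    if not isinstance(source, TrajectoryEnsemble):
        raise ValueError(f"context {context!r} needs a TrajectoryEnsemble")
    if context == "at_time":
        if t_k is None:
            raise ValueError("context 'at_time' needs t_k")
        sliced, t_used = source.at_time(t_k)
        return pearson_matrix(sliced, source.labels, context=f"at_time t={t_used:g}")
    if context in ("mean_course", "sd_course"):
        stats = summarize(source, percentiles)
        series = stats.mean if context == "mean_course" else stats.sd
        return pearson_matrix(series, source.labels, context=context)
    raise ValueError(f"unknown context {context!r}")


# ---------------------------------------------------------------------------
# histograms with a shared bin width


@dataclass
class HistogramSet:
    labels: tuple[str, ...]
    bin_edges: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    bin_width: float


def _fd_width(col: np.ndarray) -> float:
    q75, q25 = np.percentile(col, [75, 25])
    return 2.0 * (q75 - q25) / len(col) ** (1.0 / 3.0)


def common_histograms(sample: ParameterSample, selection: Sequence[str] | None = None) -> HistogramSet:
    """Histograms comparable across parameters: one shared bin width, taken
    as the maximum Freedman-Diaconis width over the selection."""
    df = sample.draws
    selection = tuple(selection) if selection else tuple(df.columns)
    if not selection:
        raise ValueError("empty selection")
    missing = [s for s in selection if s not in df.columns]
    if missing:
        raise KeyError(f"unknown parameters {missing}")
    n = len(df)
    widths = [_fd_width(df[c].to_numpy(float)) for c in selection]
    width = max(widths)
    if width <= 0:
        full_range = max(float(df[c].max() - df[c].min()) for c in selection)
        width = full_range / math.ceil(math.sqrt(n)) if full_range > 0 else 1.0
        log.warning("zero IQR for every selected parameter; falling back to range-based width %g", width)
    edges, counts = {}, {}
    for c in selection:
        col = df[c].to_numpy(float)
        lo = float(col.min())
        n_bins = max(1, math.ceil((float(col.max()) - lo) / width)) if col.max() > lo else 1
        e = lo + width * np.arange(n_bins + 1)
        if e[-1] < col.max():
            e = np.append(e, e[-1] + width)
        counts[c], edges[c] = np.histogram(col, bins=e)[0], e
    return HistogramSet(selection, edges, counts, width)


# ---------------------------------------------------------------------------
# drastic-change detection for animation


@dataclass
class ChangeFlags:
    flags: np.ndarray  # (n_t, dim) bool; frame 0 never flagged
    labels: tuple[str, ...]
    statistic: str
    threshold: float


def detect_changes(stats: SummaryStats, statistic: str = "mean", threshold: float = 0.2) -> ChangeFlags:
    """Flag frames whose statistic jumps by more than ``threshold`` times the
    element's full dynamic range; flat elements are never flagged."""
    if statistic not in ("mean", "sd"):
        raise ValueError("statistic must be 'mean' or 'sd'")
    series = stats.series(statistic)
    if series.shape[0] < 2:
        raise ValueError("change detection needs at least two frames")
    rng = series.max(axis=0) - series.min(axis=0)
    diffs = np.abs(np.diff(series, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(rng > 0, diffs / rng, 0.0)
    flags = np.zeros(series.shape, dtype=bool)
    flags[1:] = rel > threshold
    return ChangeFlags(flags, stats.labels, statistic, threshold)
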