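"""Static renderings of the standard uncertainty views.

Every renderer writes a figure file plus a machine-readable JSON sidecar
(`<figure>.json`) holding the plotted numbers, so figure content is testable
without image parsing.  Renders are deterministic given inputs, layout seed
and palette (fixed SVG hash salt, no embedded dates).
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from matplotlib import colormaps
from scipy.spatial import ConvexHull

from .bayes import ParameterSample
from .ensembles import (
    ChangeFlags,
    CorrelationMatrix,
    EigenRatioMatrix,
    SummaryStats,
    TrajectoryEnsemble,
)
from .model import BRNModel, Dataset, NetworkGraph

log = logging.getLogger(__name__)

plt.rcParams["svg.hashsalt"] = "brnuq"

_FORMATS = ("png", "svg", "pdf")
_SERIES_CYCLE = plt.rcParams["axes.prop_cycle"].by_key()["color"]


def _save(fig: plt.Figure, out: str | Path) -> Path:
    out = Path(out)
    if out.suffix.lstrip(".").lower() not in _FORMATS:
        raise ValueError(f"output format must be one of {_FORMATS}, got {out.suffix!r}")
    kwargs = {"metadata": {"Date": None}} if out.suffix == ".svg" else {}
    fig.savefig(out, **kwargs)
    plt.close(fig)
    return out


def _sidecar(out: Path, payload: dict) -> Path:
    side = out.with_suffix(out.suffix + ".json")
    side.write_text(json.dumps(payload, indent=1, default=_jsonable))
    return side


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# color mapping


@dataclass
class ColorMapSpec:
    """Statistic-to-color mapping for graph links/nodes and table cells.

    Univariate maps send one statistic (mean or sd) through a sequential
    palette.  The bivariate map encodes (mean, sd) jointly as the product of
    two 4-level single-hue ramps (blue for the first statistic, red for the
    second), quantized to a 4x4 color grid.
    """

    kind: str = "univariate"  # "univariate" | "bivariate"
    statistics: tuple[str, ...] = ("mean",)
    palette: str = "YlGnBu"
    vmin: dict = field(default_factory=dict)  # per-statistic fixed range
    vmax: dict = field(default_factory=dict)
    _ranges: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.kind not in ("univariate", "bivariate"):
            raise ValueError(f"unknown colormap kind {self.kind!r}")
        if self.kind == "bivariate" and len(self.statistics) != 2:
            raise ValueError("bivariate maps require exactly two statistics")
        if self.kind == "univariate" and len(self.statistics) != 1:
            raise ValueError("univariate maps take exactly one statistic")

    def fit(self, values: Mapping[str, np.ndarray]) -> "ColorMapSpec":
        for stat in self.statistics:
            arr = np.asarray(values[stat], float)
            lo = self.vmin.get(stat, float(np.nanmin(arr)))
            hi = self.vmax.get(stat, float(np.nanmax(arr)))
            if stat in self.vmin or stat in self.vmax:
                if lo > np.nanmin(arr) or hi < np.nanmax(arr):
                    log.info("fixed range [%g, %g] clamps data for %s", lo, hi, stat)
            self._ranges[stat] = (lo, hi if hi > lo else lo + 1.0)
        return self

    def _norm(self, stat: str, value: float) -> float:
        lo, hi = self._ranges.get(stat, (0.0, 1.0))
        return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))

    def color(self, **stat_values: float):
        if self.kind == "univariate":
            stat = self.statistics[0]
            return colormaps[self.palette](self._norm(stat, stat_values[stat]))
        s1, s2 = self.statistics
        level1 = min(int(self._norm(s1, stat_values[s1]) * 4), 3)
        level2 = min(int(self._norm(s2, stat_values[s2]) * 4), 3)
        ramp1 = colormaps["Blues"](0.25 + level1 * 0.25)
        ramp2 = colormaps["Reds"](0.25 + level2 * 0.25)
        rgb = tuple(a * b for a, b in zip(ramp1[:3], ramp2[:3]))
        return (*rgb, 1.0)


def parameter_stats(sample: ParameterSample) -> pd.DataFrame:
    """Per-parameter mean and unbiased SD on the log10 scale."""
    df = sample.log10().draws
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


# ---------------------------------------------------------------------------
# graph view


def layout_positions(
    graph: NetworkGraph, seed: int = 0, coords: Mapping[str, Sequence[float]] | None = None
) -> dict[str, np.ndarray]:
    """Deterministic force-directed layout, overridable by user coordinates."""
    if coords is not None:
        return {n: np.asarray(coords[n], float) for n in graph.graph.nodes}
    return nx.spring_layout(graph.graph, seed=seed)


def _hull_polygon(points: np.ndarray, pad: float = 0.08) -> np.ndarray:
    """Padded convex hull around node positions (works for 1 or 2 points)."""
    ring = np.column_stack(
        [np.cos(np.linspace(0, 2 * math.pi, 16, endpoint=False)), np.sin(np.linspace(0, 2 * math.pi, 16, endpoint=False))]
    )
    cloud = np.concatenate([p + pad * ring for p in np.atleast_2d(points)])
    hull = ConvexHull(cloud)
    return cloud[hull.vertices]


def _segment_points(a: np.ndarray, b: np.ndarray, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
    cuts = np.linspace(0, 1, k + 1)
    return [(a + (b - a) * c0, a + (b - a) * c1) for c0, c1 in zip(cuts[:-1], cuts[1:])]


def render_graph(
    graph: NetworkGraph,
    model: BRNModel,
    out: str | Path,
    state_stats: SummaryStats | None = None,
    flux_stats: SummaryStats | None = None,
    param_stats: pd.DataFrame | None = None,
    cmap: ColorMapSpec | None = None,
    frame: int | None = None,
    edge_attr: str = "parameters",
    layout_seed: int = 0,
    coords: Mapping[str, Sequence[float]] | None = None,
    highlight: Sequence[str] = (),
    title: str | None = None,
) -> Path:
    """Node-link view with statistic-to-color mapping.

    Nodes are colored by the state statistic; links either by the flux
    statistic or split into one equal-length segment per rate-law parameter
    (first parameter at the link start, last at the arrowhead).  Observable
    member sets are drawn as semitransparent hulls.
    """
    if edge_attr not in ("parameters", "fluxes"):
        raise ValueError("edge_attr must be 'parameters' or 'fluxes'")
    cmap = cmap or ColorMapSpec()
    stat = cmap.statistics[0]
    fr = 0 if frame is None else int(frame)
    pos = layout_positions(graph, layout_seed, coords)
    payload: dict = {
        "view": "graph",
        "edge_attr": edge_attr,
        "frame": frame,
        "highlight": list(highlight),
        "nodes": {},
        "segments": {},
        "hulls": {},
    }

    node_vals: dict[str, dict[str, float]] = {}
    if state_stats is not None:
        for i, lab in enumerate(state_stats.labels):
            node_vals[lab] = {"mean": float(state_stats.mean[fr, i]), "sd": float(state_stats.sd[fr, i])}
        cmap.fit({s: np.array([v[s] for v in node_vals.values()]) for s in cmap.statistics})
    link_vals: dict[str, dict[str, float]] = {}
    if edge_attr == "parameters":
        if param_stats is None:
            raise ValueError("edge_attr='parameters' requires param_stats")
        src = param_stats
        link_vals = {p: {"mean": float(src.loc[p, "mean"]), "sd": float(src.loc[p, "sd"])} for p in src.index}
    elif flux_stats is not None:
        for i, lab in enumerate(flux_stats.labels):
            link_vals[lab] = {"mean": float(flux_stats.mean[fr, i]), "sd": float(flux_stats.sd[fr, i])}
    link_cmap = ColorMapSpec(cmap.kind, cmap.statistics, cmap.palette)
    if link_vals:
        link_cmap.fit({s: np.array([v[s] for v in link_vals.values()]) for s in cmap.statistics})

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.set_axis_off()
    hull_colors = _SERIES_CYCLE
    for ci, (oid, members) in enumerate(sorted(graph.output_hulls.items())):
        pts = np.array([pos[m] for m in members])
        poly = _hull_polygon(pts)
        ax.fill(poly[:, 0], poly[:, 1], color=hull_colors[ci % len(hull_colors)], alpha=0.2, zorder=0)
        payload["hulls"][oid] = {"members": sorted(members), "polygon": poly}

    for a, b, rid in graph.links:
        rxn = model.reaction(rid)
        pa, pb = pos[a], pos[b]
        if edge_attr == "parameters":
            params = rxn.parameters
            missing = [p for p in params if p not in link_vals]
            if missing:
                raise ValueError(f"missing statistics for displayed parameters {missing}")
            segs = _segment_points(pa, pb, max(len(params), 1))
            seg_meta = []
            for p, (s0, s1) in zip(params, segs):
                color = link_cmap.color(**link_vals[p])
                ax.plot([s0[0], s1[0]], [s0[1], s1[1]], color=color, lw=2.5, zorder=1,
                        solid_capstyle="butt")
                seg_meta.append({"parameter": p, **link_vals[p]})
            payload["segments"][f"{rid}:{a}->{b}"] = seg_meta
        else:
            if flux_stats is not None and rid not in link_vals:
                raise ValueError(f"missing flux statistics for reaction {rid!r}")
            vals = link_vals.get(rid)
            color = link_cmap.color(**vals) if vals else (0.6, 0.6, 0.6, 1.0)
            ax.plot([pa[0], pb[0]], [pa[1], pb[1]], color=color, lw=2.5, zorder=1)
            payload["segments"][f"{rid}:{a}->{b}"] = [{"reaction": rid, **(vals or {})}]
        ax.annotate(
            "", xy=pb, xytext=pb - 0.12 * (pb - pa) / max(np.linalg.norm(pb - pa), 1e-9),
            arrowprops={"arrowstyle": "-|>", "color": "0.25", "lw": 1.0}, zorder=2,
        )
    for sid, rid in graph.hyper_edges:
        links = graph.reaction_links(rid)
        mid = np.mean([np.add(pos[a], pos[b]) / 2 for a, b in links], axis=0)
        ax.plot([pos[sid][0], mid[0]], [pos[sid][1], mid[1]], ls="--", color="0.4", lw=1.2, zorder=1)

    for node in graph.graph.nodes:
        kind = graph.graph.nodes[node].get("kind", "species")
        if kind == "env":
            ax.scatter(*pos[node], s=60, marker="s", color="0.8", edgecolor="0.4", zorder=3)
            continue
        vals = node_vals.get(node)
        color = cmap.color(**vals) if vals else (0.85, 0.85, 0.85, 1.0)
        edge = "crimson" if node in highlight else "0.2"
        lw = 2.5 if node in highlight else 0.8
        ax.scatter(*pos[node], s=350, color=color, edgecolor=edge, linewidth=lw, zorder=3)
        ax.annotate(node, pos[node], ha="center", va="center", fontsize=8, zorder=4)
        if vals:
            payload["nodes"][node] = vals
    if title:
        ax.set_title(title)
    out = _save(fig, out)
    _sidecar(out, payload)
    return out


def render_animation(
    graph: NetworkGraph,
    model: BRNModel,
    out_dir: str | Path,
    state_stats: SummaryStats,
    flux_stats: SummaryStats | None = None,
    cmap: ColorMapSpec | None = None,
    flags: ChangeFlags | None = None,
    edge_attr: str = "fluxes",
    layout_seed: int = 0,
    fmt: str = "png",
) -> list[Path]:
    """One frame per grid time; flagged elements get a highlight outline."""
    t = state_stats.t
    if len(t) == 0:
        raise ValueError("empty time grid")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(t) - 1)))
    paths = []
    for fr in range(len(t)):
        hl: list[str] = []
        if flags is not None:
            hl = [lab for i, lab in enumerate(flags.labels) if flags.flags[fr, i]]
        p = render_graph(
            graph,
            model,
            out_dir / f"frame_{fr:0{width}d}.{fmt}",
            state_stats=state_stats,
            flux_stats=flux_stats,
            cmap=cmap,
            frame=fr,
            edge_attr=edge_attr,
            layout_seed=layout_seed,
            highlight=hl,
            title=f"t = {t[fr]:g}",
        )
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# line plots


def render_lines(
    stats_list: SummaryStats | Sequence[SummaryStats],
    out: str | Path,
    mode: str = "within_experiment",
    selection: Sequence[str] | None = None,
    data: Dataset | Sequence[Dataset | None] | None = None,
) -> Path:
    """Median lines framed by semitransparent percentile bands.

    ``within_experiment``: one experiment, several elements (deselected ones
    omitted).  ``between_experiment``: one element across experiments, one
    band-framed series per condition.  Measured values appear as dots in the
    series color, only at their measurement times.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    payload: dict = {"view": "lines", "mode": mode, "series": []}
    if mode == "within_experiment":
        stats = stats_list if isinstance(stats_list, SummaryStats) else stats_list[0]
        labels = list(selection) if selection else list(stats.labels)
        missing = [l for l in labels if l not in stats.labels]
        if missing:
            raise KeyError(f"unknown elements {missing}")
        if len(labels) > 10:
            log.warning("%d series: colors become difficult to distinguish", len(labels))
        for ci, lab in enumerate(labels):
            i = stats.labels.index(lab)
            color = _SERIES_CYCLE[ci % len(_SERIES_CYCLE)]
            ax.plot(stats.t, stats.median[:, i], color=color, label=lab)
            ax.fill_between(stats.t, stats.p_low[:, i], stats.p_high[:, i], color=color, alpha=0.25, lw=0)
            entry = {
                "label": lab,
                "experiment": stats.experiment_id,
                "t": stats.t,
                "median": stats.median[:, i],
                "p_low": stats.p_low[:, i],
                "p_high": stats.p_high[:, i],
            }
            if data is not None and isinstance(data, Dataset):
                pts = data.table[(data.table["observable"] == lab) & data.table["value"].notna()]
                ax.plot(pts["time"], pts["value"], "o", color=color, ms=4)
                entry["data_t"] = pts["time"].to_numpy()
                entry["data_values"] = pts["value"].to_numpy()
            payload["series"].append(entry)
    elif mode == "between_experiment":
        if isinstance(stats_list, SummaryStats):
            stats_list = [stats_list]
        if not selection or len(selection) != 1:
            raise ValueError("between_experiment mode takes exactly one selected element")
        lab = selection[0]
        if len(stats_list) > 10:
            log.warning("%d series: colors become difficult to distinguish", len(stats_list))
        datasets = list(data) if isinstance(data, (list, tuple)) else [None] * len(stats_list)
        for ci, stats in enumerate(stats_list):
            i = stats.labels.index(lab)
            color = _SERIES_CYCLE[ci % len(_SERIES_CYCLE)]
            ax.plot(stats.t, stats.median[:, i], color=color, label=stats.experiment_id)
            ax.fill_between(stats.t, stats.p_low[:, i], stats.p_high[:, i], color=color, alpha=0.25, lw=0)
            entry = {
                "label": lab,
                "experiment": stats.experiment_id,
                "t": stats.t,
                "median": stats.median[:, i],
                "p_low": stats.p_low[:, i],
                "p_high": stats.p_high[:, i],
            }
            ds = datasets[ci] if ci < len(datasets) else None
            if ds is not None:
                pts = ds.table[(ds.table["observable"] == lab) & ds.table["value"].notna()]
                ax.plot(pts["time"], pts["value"], "o", color=color, ms=4)
                entry["data_t"] = pts["time"].to_numpy()
                entry["data_values"] = pts["value"].to_numpy()
            payload["series"].append(entry)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ax.set_xlabel("time")
    ax.legend(fontsize=8)
    out = _save(fig, out)
    _sidecar(out, payload)
    return out


# ---------------------------------------------------------------------------
# scatter, matrix, table


def render_scatter(
    source: ParameterSample | TrajectoryEnsemble,
    pair: tuple[str, str],
    out: str | Path,
    t_k: float | None = None,
) -> Path:
    """One point per sample member; log10 axes for parameter pairs."""
    a, b = pair
    if isinstance(source, ParameterSample):
        df = source.log10().draws
        for lab in pair:
            if lab not in df.columns:
                raise KeyError(f"unknown parameter {lab!r}")
        xs, ys = df[a].to_numpy(), df[b].to_numpy()
        xlabel, ylabel = f"log10 {a}", f"log10 {b}"
        context = "parameters"
    else:
        if t_k is None:
            raise ValueError("dynamic kinds require the selected time point t_k")
        sliced, t_used = source.at_time(t_k)
        labels = list(source.labels)
        for lab in pair:
            if lab not in labels:
                raise KeyError(f"unknown {source.kind} element {lab!r}")
        xs = sliced[:, labels.index(a)]
        ys = sliced[:, labels.index(b)]
        xlabel, ylabel = a, b
        context = f"{source.kind} at t={t_used:g}"
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(xs, ys, "o", ms=3, alpha=0.6)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(context, fontsize=9)
    out = _save(fig, out)
    _sidecar(out, {"view": "scatter", "pair": list(pair), "context": context, "x": xs, "y": ys, "n": len(xs)})
    return out


def render_matrix(matrix: CorrelationMatrix | EigenRatioMatrix, out: str | Path) -> Path:
    """Heatmap with per-cell numeric values; correlations use a signed
    diverging scale, eigenvalue ratios a sequential one."""
    vals = matrix.values
    is_corr = isinstance(matrix, CorrelationMatrix)
    fig, ax = plt.subplots(figsize=(0.6 * len(matrix.labels) + 2,) * 2)
    if is_corr:
        im = ax.imshow(vals, cmap="RdBu_r", vmin=-1, vmax=1)
    else:
        im = ax.imshow(vals, cmap="YlGnBu", vmin=0, vmax=1)
    ax.set_xticks(range(len(matrix.labels)), matrix.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.labels)), matrix.labels, fontsize=7)
    cell_text = []
    for i in range(vals.shape[0]):
        row = []
        for j in range(vals.shape[1]):
            txt = "" if np.isnan(vals[i, j]) else f"{vals[i, j]:.2f}"
            row.append(txt)
            if txt:
                ax.text(j, i, txt, ha="center", va="center", fontsize=6)
        cell_text.append(row)
    fig.colorbar(im, shrink=0.8)
    ax.set_title(matrix.context, fontsize=9)
    fig.tight_layout()
    out = _save(fig, out)
    _sidecar(
        out,
        {
            "view": "matrix",
            "matrix_kind": "pearson" if is_corr else "eigen_ratio",
            "context": matrix.context,
            "labels": list(matrix.labels),
            "values": vals,
            "cell_text": cell_text,
        },
    )
    return out


def render_table(sample: ParameterSample, out: str | Path, cmap: ColorMapSpec | None = None) -> tuple[Path, Path]:
    """Parameter mean/SD table (log10 scale): CSV plus a color-coded figure.

    Cells are colored with the same maps as the graph links, so extreme
    means/SDs carry the palette endpoints.
    """
    stats = parameter_stats(sample)
    out = Path(out)
    csv_path = out.with_suffix(".csv")
    stats.to_csv(csv_path, index_label="parameter", float_format="%.17g")
    mean_map = cmap or ColorMapSpec("univariate", ("mean",))
    sd_map = ColorMapSpec("univariate", ("sd",), palette=mean_map.palette)
    mean_map.fit({"mean": stats["mean"].to_numpy()})
    sd_map.fit({"sd": stats["sd"].to_numpy()})
    fig, ax = plt.subplots(figsize=(4, 0.35 * len(stats) + 1))
    ax.set_axis_off()
    cell_colors = [
        [mean_map.color(mean=m), sd_map.color(sd=s)] for m, s in zip(stats["mean"], stats["sd"])
    ]
    tbl = ax.table(
        cellText=[[f"{m:.4g}", f"{s:.4g}"] for m, s in zip(stats["mean"], stats["sd"])],
        rowLabels=list(stats.index),
        colLabels=["mean(log10)", "sd(log10)"],
        cellColours=cell_colors,
        loc="center",
    )
    tbl.auto_set_font_size(False)
    tbl.set_fontsize(8)
    fig_path = _save(fig, out)
    _sidecar(
        fig_path,
        {
            "view": "table",
            "parameters": list(stats.index),
            "mean": stats["mean"].to_numpy(),
            "sd": stats["sd"].to_numpy(),
            "cell_colors": [[list(c) for c in row] for row in cell_colors],
        },
    )
    return fig_path, csv_path
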