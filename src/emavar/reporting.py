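"""Human-readable outputs: text summary, model table, graph, time plots.

The Granger summary graph follows the print legend used for idiographic
dynamic networks: one node per variable, a directed edge per Granger
association, pen width proportional to the share of valid models carrying
the association (width = 1 + 4 * proportion) and line style encoding the
sign — solid for positive, dashed for negative, dash-dot for mixed signs
within a model, dotted for models disagreeing with each other. Colors are
additionally emitted for renderers that support them.
"""

from __future__ import annotations

import re
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data_io import EmaDataset
from .granger import GrangerSummary
from .model_search import SearchResult

__all__ = [
    "render_text",
    "render_graph",
    "dot_counts",
    "render_graph_svg",
    "render_time_plots",
    "models_table",
    "write_report_bundle",
]

PEN_WIDTH_BASE = 1.0
PEN_WIDTH_SPAN = 4.0
EDGE_STYLE = {
    "positive": "solid",
    "negative": "dashed",
    "mixed_within": "dashdot",
    "mixed_across": "dotted",
}
EDGE_COLOR = {
    "positive": "green",
    "negative": "red",
    "mixed_within": "orange",
    "mixed_across": "gray",
}


def render_text(search: SearchResult, summary: GrangerSummary | None = None) -> str:
    """Textual summary of the model-selection run."""
    if summary is None:
        summary = search.granger or GrangerSummary(edges=(), n_valid_models=0)
    lines = []
    pct = search.tested_percentage
    lines.append(
        f"{search.tested} VAR models out of {search.enumerated} possible "
        f"combinations were tested ({pct:.1f}%)."
    )
    lines.append(f"{search.skipped_redundant} models were not tested due to redundancy.")
    lines.append(
        f"Of the {search.tested} models tested, {len(search.valid_models)} "
        f"met the assumptions of stability, white noise, homoscedasticity and normality."
    )
    lines.append(f"Models ordered by ascending {search.criterion_used}.")
    if search.valid_models:
        spec, fit, _rep = search.valid_models[0]
        lines.append(
            f"Best model: {spec.describe()} with an AIC of {fit.aic:.2f} "
            f"and a BIC of {fit.bic:.2f}."
        )
    if summary.is_none:
        lines.append("Granger causality summary: none.")
    else:
        lines.append("Granger causality summary:")
        for edge in summary.edges:
            lines.append(
                f"  {edge.cause} -> {edge.effect}: sign {edge.sign_class}, "
                f"found in {100 * edge.proportion:.0f}% of valid models "
                f"(best-model p = {edge.best_model_p:.3g})"
            )
    return "\n".join(lines) + "\n"


def render_graph(summary: GrangerSummary, variables: list[str] | None = None) -> str:
    """DOT (graphviz dialect) document for the Granger summary graph."""
    nodes = list(variables) if variables else sorted(
        {e.cause for e in summary.edges} | {e.effect for e in summary.edges}
    )
    lines = ["digraph granger {"]
    for node in nodes:
        lines.append(f'  "{node}";')
    for edge in sorted(summary.edges, key=lambda e: (e.cause, e.effect)):
        width = PEN_WIDTH_BASE + PEN_WIDTH_SPAN * edge.proportion
        style = EDGE_STYLE[edge.sign_class]
        color = EDGE_COLOR[edge.sign_class]
        lines.append(
            f'  "{edge.cause}" -> "{edge.effect}" '
            f'[penwidth={width:.2f}, style={style}, color={color}, '
            f'label="{edge.proportion:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


_DOT_EDGE = re.compile(r'^\s*"([^"]+)"\s*->\s*"([^"]+)"')
_DOT_NODE = re.compile(r'^\s*"([^"]+)"\s*(\[[^\]]*\])?\s*;')


def dot_counts(dot: str) -> tuple[int, int]:
    """(node count, edge count) of a DOT digraph document.

    Minimal reader for the dialect ``render_graph`` emits (quoted node
    statements and quoted ``a -> b [...]`` edge statements).
    """
    nodes: set[str] = set()
    edges = 0
    for line in dot.splitlines():
        m = _DOT_EDGE.match(line)
        if m:
            edges += 1
            nodes.update(m.groups())
            continue
        m = _DOT_NODE.match(line)
        if m:
            nodes.add(m.group(1))
    return len(nodes), edges


def render_graph_svg(summary: GrangerSummary, path: str | Path, variables=None) -> Path:
    """Draw the summary graph to an SVG with matplotlib (circular layout)."""
    nodes = list(variables) if variables else sorted(
        {e.cause for e in summary.edges} | {e.effect for e in summary.edges}
    )
    fig, ax = plt.subplots(figsize=(5, 5))
    angles = np.linspace(0, 2 * np.pi, len(nodes), endpoint=False) if nodes else []
    pos = {n: (np.cos(a), np.sin(a)) for n, a in zip(nodes, angles)}
    style_map = {"solid": "-", "dashed": "--", "dashdot": "-.", "dotted": ":"}
    for edge in summary.edges:
        (x0, y0), (x1, y1) = pos[edge.cause], pos[edge.effect]
        ax.annotate(
            "",
            xy=(x1, y1),
            xytext=(x0, y0),
            arrowprops=dict(
                arrowstyle="-|>",
                lw=PEN_WIDTH_BASE + PEN_WIDTH_SPAN * edge.proportion,
                linestyle=style_map[EDGE_STYLE[edge.sign_class]],
                color=EDGE_COLOR[edge.sign_class],
                shrinkA=25,
                shrinkB=25,
            ),
        )
    for n, (x, y) in pos.items():
        ax.text(x, y, n, ha="center", va="center",
                bbox=dict(boxstyle="round", fc="white", ec="black"))
    ax.set_xlim(-1.6, 1.6)
    ax.set_ylim(-1.6, 1.6)
    ax.axis("off")
    path = Path(path)
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path


def render_time_plots(
    dataset: EmaDataset,
    selection: list[str],
    outdir: str | Path,
    outlier_days: dict[str, list[int]] | None = None,
) -> list[Path]:
    """One SVG time plot per selected variable (raw values vs 1-based day)."""
    if not selection:
        raise ValueError("no variables selected for plotting")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    days = np.arange(1, dataset.T + 1)
    for var in selection:
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.plot(days, dataset.values[var].to_numpy(), lw=1)
        if outlier_days and outlier_days.get(var):
            for day in outlier_days[var]:
                ax.axvline(day, color="red", ls=":", lw=1)
        ax.set_xlabel("day")
        ax.set_ylabel(var)
        ax.set_xlim(1, dataset.T)
        fig.tight_layout()
        path = outdir / f"timeplot_{var}.svg"
        fig.savefig(path, format="svg")
        plt.close(fig)
        paths.append(path)
    return paths


def models_table(search: SearchResult) -> pd.DataFrame:
    """One row per enumerated spec with fit, diagnostics and bookkeeping."""
    rows = []
    for rec in search.records:
        row = {
            "spec": rec["spec"],
            "status": rec["status"],
            "valid": rec.get("valid"),
            "rank": rec.get("rank"),
            "k": rec.get("k"),
            "logL": rec.get("logL"),
            "AIC": rec.get("AIC"),
            "BIC": rec.get("BIC"),
            "n_constraints": rec.get("n_constraints"),
            "dominated_by": rec.get("dominated_by"),
            "reason": rec.get("reason"),
        }
        for block in ("white_noise_p", "homoscedasticity_p", "normality_p"):
            for var, p in (rec.get(block) or {}).items():
                row[f"{block[:-2]}_{var}_p"] = p
        row["max_eigenvalue_modulus"] = rec.get("max_eigenvalue_modulus")
        rows.append(row)
    return pd.DataFrame(rows)


def write_report_bundle(
    outdir: str | Path,
    dataset: EmaDataset,
    search: SearchResult,
    svg: bool = True,
) -> dict[str, Path]:
    """Write report.txt, models.csv/json, granger.json/dot(+svg), time plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = search.granger
    files: dict[str, Path] = {}
    files["report"] = outdir / "report.txt"
    files["report"].write_text(render_text(search, summary))
    table = models_table(search)
    files["models_csv"] = outdir / "models.csv"
    table.to_csv(files["models_csv"], index=False)
    files["models_json"] = outdir / "models.json"
    files["models_json"].write_text(search.to_json())
    files["granger_json"] = outdir / "granger.json"
    files["granger_json"].write_text(summary.to_json())
    dot = render_graph(summary, variables=dataset.variable_names)
    files["granger_dot"] = outdir / "granger.dot"
    files["granger_dot"].write_text(dot)
    if svg:
        files["granger_svg"] = render_graph_svg(
            summary, outdir / "granger.svg", variables=dataset.variable_names
        )
    top_outliers = None
    if search.valid_models:
        spec = search.valid_models[0][0]
        top_outliers = {
            var: list(days)
            for var, days in zip(dataset.variable_names, spec.outlier_days)
        }
    for path in render_time_plots(dataset, dataset.variable_names, outdir, top_outliers):
        files[path.stem] = path
    return files
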