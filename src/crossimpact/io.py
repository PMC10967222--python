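"""Readers, writers, network export and plotting.

Two interchangeable on-disk forms carry the scores:

* a **long-format score CSV** with columns
  ``source,target,score,motivation,group,stage`` — one row per scored
  ordered pair per workflow stage; and
* a **wide matrix CSV**: first column holds the goal code, the remaining
  columns are the goal codes in the same order, cells are the integer
  weights (diagonal cells 0 or empty).

The canonical machine-readable output is a JSON report; plots (heatmap,
focal-goal bubble charts) are views of it and are never parsed back.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError
from .influence import FocalGoalReport, InfluenceSummary, PerturbationResult
from .model import (
    STAGES,
    CrossImpactMatrix,
    GoalSet,
    ScoreRecord,
    classify_interactions,
    normalize_goal_id,
)

SCORE_COLUMNS = ("source", "target", "score", "motivation", "group", "stage")


def read_scores_csv(path) -> list[ScoreRecord]:
    """Read a long-format score CSV into validated records.

    Errors name the offending data row (1-based, excluding the header).
    """
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in SCORE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        for i, row in enumerate(reader, start=1):
            raw = row["score"].strip()
            try:
                score = int(raw)
            except ValueError:
                raise ParseError(
                    f"score {raw!r} is not an integer on the seven-point scale",
                    row=i,
                )
            try:
                records.append(
                    ScoreRecord(
                        source=row["source"],
                        target=row["target"],
                        score=score,
                        motivation=row["motivation"],
                        group=row["group"],
                        stage=row["stage"].strip().lower(),
                    )
                )
            except ValidationError as exc:
                raise ParseError(str(exc), row=i) from exc
    return records


def write_scores_csv(records: Iterable[ScoreRecord], path) -> None:
    """Write records to the long-format score CSV (UTF-8, lossless)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCORE_COLUMNS)
        for r in records:
            writer.writerow([r.source, r.target, r.score, r.motivation, r.group, r.stage])


def read_matrix_csv(path, labels=None) -> CrossImpactMatrix:
    """Read a wide matrix CSV into a :class:`CrossImpactMatrix`.

    The column order must equal the row order; the diagonal must be 0 or
    empty.  Row and column labels define the goal set.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    row_goals = [normalize_goal_id(g) for g in df.index]
    col_goals = [normalize_goal_id(g) for g in df.columns]
    if len(row_goals) != len(col_goals):
        raise FormatError(
            f"{path}: matrix is not square ({len(row_goals)} rows, "
            f"{len(col_goals)} columns)"
        )
    if row_goals != col_goals:
        raise FormatError(
            f"{path}: column labels must equal row labels in the same order"
        )
    G = len(row_goals)
    w = np.zeros((G, G), dtype=np.int64)
    for i in range(G):
        for j in range(G):
            cell = str(df.iat[i, j]).strip()
            if i == j:
                if cell not in ("", "0"):
                    raise FormatError(
                        f"{path}: diagonal cell ({row_goals[i]}, {row_goals[j]}) "
                        f"must be 0 or empty, got {cell!r}"
                    )
                continue
            try:
                w[i, j] = int(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: cell ({row_goals[i]}, {col_goals[j]}) is not an "
                    f"integer: {cell!r}"
                )
    try:
        return CrossImpactMatrix(GoalSet(row_goals, labels), w)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_matrix_csv(matrix: CrossImpactMatrix, path) -> None:
    """Write the wide matrix CSV (integer cells, zero diagonal)."""
    goals = list(matrix.goal_set.goals)
    df = pd.DataFrame(matrix.weights, index=goals, columns=goals)
    df.to_csv(path)


def to_graph(matrix: CrossImpactMatrix, keep_zeros: bool = False):
    """Directed graph of the matrix: one edge per (nonzero) weight.

    Node attributes: code, label, out_degree, in_degree.  Edge
    attributes: integer weight and sign (``promoting``/``restricting``;
    ``none`` only when ``keep_zeros``).
    """
    import networkx as nx

    from .influence import in_degree, out_degree

    g = nx.DiGraph()
    for code in matrix.goal_set.goals:
        g.add_node(
            code,
            code=code,
            label=matrix.goal_set.label(code),
            out_degree=out_degree(matrix, code),
            in_degree=in_degree(matrix, code),
        )
    for s, t in matrix.goal_set.ordered_pairs():
        w = matrix[s, t]
        if w == 0 and not keep_zeros:
            continue
        sign = "promoting" if w > 0 else "restricting" if w < 0 else "none"
        g.add_edge(s, t, weight=w, sign=sign)
    return g


NETWORK_FORMATS = ("graphml", "dot", "edgelist")


def export_network(
    matrix: CrossImpactMatrix, path, format: str, keep_zeros: bool = False
) -> None:
    """Export the interaction network as GraphML, DOT or edge-list CSV.

    Zero-weight pairs are omitted by default (only actual interactions
    are drawn); ``keep_zeros`` restores them.
    """
    import networkx as nx

    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValidationError(
            f"unknown network format {format!r}; choose from {NETWORK_FORMATS}"
        )
    g = to_graph(matrix, keep_zeros=keep_zeros)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        _write_dot(g, path)
    else:
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight", "sign"])
            for s, t, data in g.edges(data=True):
                writer.writerow([s, t, data["weight"], data["sign"]])


def _write_dot(g, path: Path) -> None:
    # Minimal Graphviz DOT writer; avoids a pydot/pygraphviz dependency.
    def q(s):
        return '"' + str(s).replace('"', r"\"") + '"'

    lines = ["digraph crossimpact {"]
    for n, data in g.nodes(data=True):
        attrs = ", ".join(f"{k}={q(v)}" for k, v in sorted(data.items()))
        lines.append(f"  {q(n)} [{attrs}];")
    for s, t, data in g.edges(data=True):
        attrs = ", ".join(f"{k}={q(v)}" for k, v in sorted(data.items()))
        lines.append(f"  {q(s)} -> {q(t)} [{attrs}];")
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def report_dict(
    matrix: CrossImpactMatrix,
    summary: InfluenceSummary,
    focal_report: FocalGoalReport | None = None,
    perturbation: PerturbationResult | None = None,
) -> dict:
    """Assemble every numeric output into one JSON-serializable dict."""
    restricting, none, promoting = classify_interactions(matrix)
    out = {
        "goals": list(matrix.goal_set.goals),
        "n_goals": matrix.n_goals,
        "n_pairs": matrix.n_goals * (matrix.n_goals - 1),
        "classification": {
            "restricting": restricting,
            "no_influence": none,
            "promoting": promoting,
        },
        "summary": {
            g: {
                "out_degree": summary.out_degrees[g],
                "in_degree": summary.in_degrees[g],
                "total_influence": summary.total_influences[g],
                "rank_first_order": summary.rank_first_order[g],
                "rank_total": summary.rank_total[g],
            }
            for g in summary.goals
        },
    }
    if focal_report is not None:
        out["focal"] = {
            "goal": focal_report.focal,
            "direct_on": dict(focal_report.direct_on),
            "direct_from": dict(focal_report.direct_from),
            "net_on": dict(focal_report.net_on),
            "net_from": dict(focal_report.net_from),
            "feedback_pairs": list(focal_report.feedback_pairs),
        }
    if perturbation is not None:
        out["perturbation"] = {
            "n_replicates": perturbation.n_replicates,
            "noise_spec": perturbation.noise_spec,
            "metric": perturbation.metric,
            # fixed precision keeps reports byte-identical across runs
            "retention_frequency": {
                g: round(f, 6) for g, f in perturbation.retention_frequency.items()
            },
            "rank_distribution": {
                g: {str(r): n for r, n in d.items()}
                for g, d in perturbation.rank_distribution.items()
            },
        }
    return out


def write_report_json(report: dict, path) -> None:
    """Write the JSON report deterministically (sorted keys, fixed layout)."""
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def plot_heatmap(matrix: CrossImpactMatrix, path) -> None:
    """Cross-impact heatmap with marginal row/column sums.

    Diverging blue–white–red scale anchored symmetrically at ±3 — the
    instrument's range, not the data's — so zero is always the white
    midpoint and color is comparable across studies.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    goals = list(matrix.goal_set.goals)
    w = matrix.weights
    row_sums = w.sum(axis=1)
    col_sums = w.sum(axis=0)

    fig, ax = plt.subplots(figsize=(0.55 * len(goals) + 2, 0.55 * len(goals) + 2))
    im = ax.imshow(w, cmap="RdBu", vmin=-3, vmax=3)
    ax.set_xticks(range(len(goals)))
    ax.set_xticklabels(goals, rotation=90, fontsize=8)
    ax.set_yticks(range(len(goals)))
    ax.set_yticklabels(goals, fontsize=8)
    ax.set_xlabel("influenced goal (column sum below)")
    ax.set_ylabel("influencing goal (row sum right)")
    for i, rs in enumerate(row_sums):
        ax.text(len(goals) - 0.3, i, str(int(rs)), va="center", fontsize=7)
    for j, cs in enumerate(col_sums):
        ax.text(j, len(goals) - 0.3, str(int(cs)), ha="center", fontsize=7, rotation=90)
    fig.colorbar(im, ax=ax, label="interaction score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_focal_bubbles(report: FocalGoalReport, path) -> None:
    """Bubble charts of direct and net influence of/on the focal goal.

    Bubble area scales with the magnitude of the signed influence and
    color follows the same diverging promoting/restricting scale as the
    heatmap.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    partners = [g for g in report.direct_on]
    panels = [
        ("direct influence on others", report.direct_on),
        ("net influence on others", report.net_on),
        ("direct influence from others", report.direct_from),
        ("net influence from others", report.net_from),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(12, 7), sharex=True)
    for ax, (title, values) in zip(axes.ravel(), panels):
        vals = np.array([values[g] for g in partners], dtype=float)
        vmax = max(1.0, np.abs(vals).max())
        sizes = 40 + 400 * np.abs(vals) / vmax
        ax.scatter(
            range(len(partners)), vals, s=sizes, c=vals,
            cmap="RdBu", vmin=-vmax, vmax=vmax, edgecolors="k", linewidths=0.4,
        )
        ax.axhline(0, color="grey", lw=0.6)
        ax.set_title(f"{report.focal}: {title}", fontsize=10)
        ax.set_xticks(range(len(partners)))
        ax.set_xticklabels(partners, rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_reports(
    matrix: CrossImpactMatrix,
    summary: InfluenceSummary,
    focal_report: FocalGoalReport | None,
    out_dir,
    perturbation: PerturbationResult | None = None,
) -> dict[str, Path]:
    """Emit the JSON report, the heatmap and (if focal) the bubble charts.

    Returns a name → path map of everything written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create output directory {out_dir}: {exc}") from exc
    paths: dict[str, Path] = {}
    report = report_dict(matrix, summary, focal_report, perturbation)
    paths["report"] = out_dir / "report.json"
    write_report_json(report, paths["report"])
    paths["heatmap"] = out_dir / "heatmap.png"
    plot_heatmap(matrix, paths["heatmap"])
    if focal_report is not None:
        paths["focal_bubbles"] = out_dir / f"focal_{focal_report.focal}.png"
        plot_focal_bubbles(focal_report, paths["focal_bubbles"])
    return paths
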