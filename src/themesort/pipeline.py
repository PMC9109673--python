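"""End-to-end pipeline: files in, consensus themes and reports out.

Orchestrates read -> validate -> network -> detect -> (optional
refinement) -> agreement -> exports. All machine-readable outputs are
deterministic for a fixed input and seed; the run report records the
package version, the configuration echo and the seed so a run can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from . import __version__
from .agreement import agreement_report
from .consensus import (
    ConsensusPartition,
    CreateTheme,
    MoveQuote,
    RenameTheme,
    RetainTheme,
    apply_refinement,
    detect_communities,
    theme_set_from_partition,
)
from .corpus import (
    SortStudy,
    read_corpus,
    read_sort_table,
    validate_study,
)
from .errors import ConfigError, LayoutError, ThemesortError
from .network import CooccurrenceNetwork, build_network, export_network

log = logging.getLogger("themesort")

#: fixed >= 10 colour palette for community colouring (matplotlib tab20)
PALETTE = [matplotlib.colors.to_hex(c) for c in plt.get_cmap("tab20").colors]


@dataclass
class RunConfig:
    """Configuration of one pipeline run. Precedence: CLI > file > defaults."""

    sorts_path: str
    corpus_path: str
    coder_path: str | None = None
    refinement_path: str | None = None
    resolution: float = 1.0
    seed: int = 0
    denominator: str = "theme"
    require_complete: bool = False
    out_dir: str = "themesort_out"
    log_level: str = "INFO"


@dataclass
class LayoutResult:
    """Deterministic 2-D embedding for diagram export.

    Edge attraction scales with co-occurrence weight, so quotes grouped
    together by many raters sit close; node colour indexes the community.
    """

    coordinates: dict[int, tuple[float, float]]
    color_index: dict[int, int]
    edge_widths: dict[tuple[int, int], int]


def compute_layout(
    net: CooccurrenceNetwork,
    partition: ConsensusPartition | None = None,
    seed: int = 0,
) -> LayoutResult:
    """Seeded force-directed layout; identical coordinates for same inputs."""
    if net.n_nodes == 0:
        raise LayoutError("cannot lay out an empty network")
    if net.n_nodes == 1:
        coords = {net.node_ids[0]: (0.0, 0.0)}
    else:
        pos = nx.spring_layout(net.graph, weight="weight", seed=seed)
        coords = {n: (float(x), float(y)) for n, (x, y) in pos.items()}
    if partition is not None:
        color = {
            n: (partition.assignment[n] - 1) % len(PALETTE) for n in net.graph.nodes
        }
    else:
        color = {n: 0 for n in net.graph.nodes}
    widths = {
        (min(i, j), max(i, j)): int(d["weight"])
        for i, j, d in net.graph.edges(data=True)
    }
    for xy in coords.values():
        if not (np.isfinite(xy[0]) and np.isfinite(xy[1])):  # pragma: no cover
            raise LayoutError("non-finite coordinate produced")
    return LayoutResult(coordinates=coords, color_index=color, edge_widths=widths)


def save_layout(
    layout: LayoutResult,
    net: CooccurrenceNetwork,
    svg_path: str | Path,
    csv_path: str | Path,
) -> None:
    """Write the diagram (SVG) and the raw coordinates (CSV)."""
    import csv as _csv

    with Path(csv_path).open("w", newline="", encoding="utf-8") as fh:
        writer = _csv.writer(fh, lineterminator="\n")
        writer.writerow(["quote_id", "x", "y", "color_index"])
        for n in sorted(layout.coordinates):
            x, y = layout.coordinates[n]
            writer.writerow([n, f"{x:.6f}", f"{y:.6f}", layout.color_index[n]])

    fig, ax = plt.subplots(figsize=(8, 8))
    max_w = max(layout.edge_widths.values(), default=1)
    for (i, j), w in sorted(layout.edge_widths.items()):
        xi, yi = layout.coordinates[i]
        xj, yj = layout.coordinates[j]
        ax.plot([xi, xj], [yi, yj], color="0.6", lw=2.5 * w / max_w, zorder=1)
    xs = [layout.coordinates[n][0] for n in sorted(layout.coordinates)]
    ys = [layout.coordinates[n][1] for n in sorted(layout.coordinates)]
    cs = [PALETTE[layout.color_index[n]] for n in sorted(layout.coordinates)]
    ax.scatter(xs, ys, c=cs, s=120, zorder=2, edgecolors="black", linewidths=0.5)
    for n in sorted(layout.coordinates):
        x, y = layout.coordinates[n]
        ax.annotate(str(n), (x, y), fontsize=6, ha="center", va="center", zorder=3)
    ax.set_axis_off()
    fig.savefig(svg_path, format="svg", bbox_inches="tight")
    plt.close(fig)


def load_refinement_actions(path: str | Path) -> list:
    """Parse a refinement script (JSON list of action objects)."""
    kinds = {
        "CreateTheme": CreateTheme,
        "MoveQuote": MoveQuote,
        "RenameTheme": RenameTheme,
        "RetainTheme": RetainTheme,
    }
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    actions = []
    for entry in raw:
        kind = entry.pop("action", None)
        if kind not in kinds:
            raise ConfigError(f"unknown refinement action kind {kind!r}")
        actions.append(kinds[kind](**entry))
    return actions


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artefacts to ``out_dir``.

    Returns the run report (also written as ``report.json``). Raises a
    :class:`~themesort.errors.ThemesortError` subclass naming the failing
    stage on any error.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage read_sort_table: %s", config.sorts_path)
    sorts = read_sort_table(config.sorts_path)
    corpus = read_corpus(config.corpus_path)
    study = SortStudy(corpus=corpus, sorts=sorts)

    log.info("stage validate_study")
    findings = validate_study(study, require_complete=config.require_complete)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise ConfigError(
            "validate_study found errors: " + "; ".join(f.message for f in errors[:5])
        )
    for f in findings:
        log.warning("validate_study: %s", f.message)

    log.info("stage build_network")
    net = build_network(study)
    export_network(net, "edge-tsv", out / "edges.tsv")

    log.info("stage detect_communities (resolution=%s seed=%s)", config.resolution, config.seed)
    partition = detect_communities(net, resolution=config.resolution, seed=config.seed)
    export_network(net, "graphml", out / "network.graphml", partition=partition)
    partition.to_json(out / "partition.json")

    if config.refinement_path:
        log.info("stage apply_refinement: %s", config.refinement_path)
        actions = load_refinement_actions(config.refinement_path)
        themes = apply_refinement(partition, actions, net=net)
    else:
        themes = theme_set_from_partition(partition)
        themes.modularity_value = partition.modularity_value
    themes.to_csv(out / "themes.csv")
    themes.to_json(out / "themes.json", resolution=config.resolution, seed=config.seed)

    agreement_block = {"status": "skipped", "reason": "no coder file given"}
    if config.coder_path:
        log.info("stage agreement_report: %s", config.coder_path)
        coder_sorts = read_sort_table(config.coder_path)
        if len(coder_sorts) != 1:
            raise ConfigError(
                f"coder file must contain exactly one rater, found {len(coder_sorts)}"
            )
        report = agreement_report(themes, coder_sorts[0], denominator=config.denominator)
        report.to_json(out / "agreement.json")
        agreement_block = {
            "status": "computed",
            "overall_percent": report.overall_percent,
            "per_theme_percent": report.per_theme_percent,
            "ari": report.ari,
            "nmi": report.nmi,
        }

    log.info("stage compute_layout")
    layout = compute_layout(net, partition, seed=config.seed)
    save_layout(layout, net, out / "layout.svg", out / "layout.csv")

    run_report = {
        "version": __version__,
        "python": platform.python_version(),
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_quotes": corpus.n_quotes,
        "n_raters": study.n_raters,
        "n_communities": partition.n_communities,
        "modularity": partition.modularity_value,
        "theme_sizes": {label: len(m) for label, m in themes.themes.items()},
        "agreement": agreement_block,
        "warnings": [f.message for f in findings],
    }
    (out / "report.json").write_text(
        json.dumps(run_report, indent=2) + "\n", encoding="utf-8"
    )
    (out / "report.md").write_text(generate_report(run_report) + "\n", encoding="utf-8")
    log.info("pipeline complete: %s", out)
    return run_report


def generate_report(run_report: dict) -> str:
    """Render the run report as human-readable markdown."""
    lines = [
        "# Consensus theme report",
        "",
        f"- Quotes: {run_report['n_quotes']}",
        f"- Raters: {run_report['n_raters']}",
        f"- Communities detected: {run_report['n_communities']}",
        f"- Modularity Q: {run_report['modularity']:.4f}",
        "",
        "## Theme sizes",
        "",
    ]
    for label, size in run_report["theme_sizes"].items():
        lines.append(f"- {label}: {size}")
    agreement = run_report.get("agreement", {})
    lines += ["", "## Agreement with independent coder", ""]
    if agreement.get("status") == "computed":
        lines.append(f"- Overall: {agreement['overall_percent']:.1f}%")
        for label, pct in agreement["per_theme_percent"].items():
            lines.append(f"- {label}: {pct:.1f}%")
        lines.append(f"- ARI: {agreement['ari']:.3f}, NMI: {agreement['nmi']:.3f}")
    else:
        lines.append(f"- skipped ({agreement.get('reason', 'not requested')})")
    return "\n".join(lines)
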