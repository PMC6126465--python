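"""Graphics: annotated dendrograms, merging-level layouts, subtrees, CC1/2 curves.

All plots are written as PNG (SVG/PS optional); the information content —
LCV/aLCV labels, per-node statistics — matters here, not the exact layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

from .cellclust import Dendrogram

__all__ = [
    "AnnotationTable",
    "plot_dendrogram",
    "plot_merging_levels",
    "plot_subtree",
    "plot_cc_half",
]


@dataclass
class AnnotationTable:
    """Per-node merging statistics for subtree annotation.

    ``rows`` maps node_id -> dict with any of: completeness (%), r_meas,
    res_cc (Angstrom).
    """

    rows: dict = field(default_factory=dict)

    @classmethod
    def from_results(cls, results: dict) -> "AnnotationTable":
        rows = {}
        for node_id, result in results.items():
            st = result.stats
            rows[node_id] = {
                "completeness": st.completeness,
                "r_meas": st.r_meas,
                "res_cc": st.res_cc,
            }
        return cls(rows=rows)


def _save(fig, path: Path, formats: Sequence[str]) -> list[Path]:
    path = Path(path)
    written = []
    for ext in formats:
        out = path.with_suffix(f".{ext}")
        fig.savefig(out, dpi=110)
        written.append(out)
    plt.close(fig)
    return written


def _leaf_positions(dendro: Dendrogram) -> dict[int, float]:
    """x-coordinate of each leaf serial in the scipy dendrogram layout."""
    d = scipy_dendrogram(dendro.linkage_matrix, no_plot=True)
    order = [dendro.leaves[i] for i in d["leaves"]]
    return {serial: 5.0 + 10.0 * i for i, serial in enumerate(order)}


def _node_positions(dendro: Dendrogram) -> dict[int, tuple[float, float]]:
    """(x, height) of every leaf and internal node in dendrogram layout."""
    pos: dict[int, tuple[float, float]] = {}
    leaf_x = _leaf_positions(dendro)
    for serial, x in leaf_x.items():
        pos[serial] = (x, 0.0)
    for nd in dendro.nodes:
        xa = pos[nd.children[0]][0]
        xb = pos[nd.children[1]][0]
        pos[nd.node_id] = (0.5 * (xa + xb), nd.height)
    return pos


def plot_dendrogram(
    dendro: Dendrogram,
    annotate_top: int = 5,
    path: str | Path = "tree.png",
    formats: Sequence[str] = ("png",),
) -> list[Path]:
    """Full dendrogram with 'LCV% (aLCV A)' labels on the top clusters."""
    fig, ax = plt.subplots(figsize=(max(6, dendro.n_leaves * 0.18), 5))
    scipy_dendrogram(
        dendro.linkage_matrix,
        labels=dendro.leaves,
        ax=ax,
        color_threshold=0.0,
        link_color_func=lambda _k: "tab:blue",
    )
    pos = _node_positions(dendro)
    top = sorted(dendro.nodes, key=lambda nd: nd.height, reverse=True)[:annotate_top]
    for nd in top:
        x, h = pos[nd.node_id]
        ax.annotate(
            f"{nd.lcv:.2f} ({nd.alcv:.2f})",
            xy=(x, h),
            xytext=(0, 4),
            textcoords="offset points",
            ha="center",
            fontsize=8,
            color="red",
        )
    ax.set_ylabel("merge height")
    ax.set_xlabel("dataset serial")
    fig.tight_layout()
    return _save(fig, Path(path), formats)


def plot_merging_levels(
    dendro: Dendrogram,
    path: str | Path = "levels.png",
    formats: Sequence[str] = ("png",),
) -> list[Path]:
    """Nodes drawn at their merging level (member-count rank), not height.

    Boxes at the same level are clusters with equal numbers of datasets;
    each box is annotated with its node number and aLCV.
    """
    pos = _node_positions(dendro)
    fig, ax = plt.subplots(figsize=(max(6, dendro.n_leaves * 0.25), 5))
    level = {nd.node_id: nd.merge_level for nd in dendro.nodes}
    for serial in dendro.leaves:
        level[serial] = 0
    for nd in dendro.nodes:
        x, _ = pos[nd.node_id]
        for child in nd.children:
            cx, _ = pos[child]
            ax.plot([cx, x], [level[child], nd.merge_level], color="0.6", lw=0.8, zorder=1)
    for serial in dendro.leaves:
        ax.annotate(
            str(serial), xy=(pos[serial][0], 0), ha="center", va="top", fontsize=7
        )
    for nd in dendro.nodes:
        x, _ = pos[nd.node_id]
        ax.annotate(
            f"{nd.node_id}\n{nd.alcv:.2f}",
            xy=(x, nd.merge_level),
            ha="center",
            va="center",
            fontsize=7,
            bbox=dict(boxstyle="round", facecolor="0.85", edgecolor="0.4"),
            zorder=2,
        )
    ax.set_ylabel("merging level (datasets in cluster - 1)")
    ax.set_xticks([])
    ax.set_ylim(-0.8, max(level.values()) + 0.8)
    fig.tight_layout()
    return _save(fig, Path(path), formats)


def _subtree_ids(dendro: Dendrogram, node_id: int, levels: int) -> set[int]:
    keep = {node_id}
    frontier = [(node_id, 0)]
    while frontier:
        ident, depth = frontier.pop()
        if ident in dendro.cells or depth >= levels:
            continue
        nd = dendro.node(ident)
        for child in nd.children:
            keep.add(child)
            frontier.append((child, depth + 1))
    return keep


def plot_subtree(
    dendro: Dendrogram,
    node_id: int,
    levels: int,
    annotations: AnnotationTable | None = None,
    path: str | Path = "subtree.png",
    formats: Sequence[str] = ("png",),
) -> list[Path]:
    """Subtree rooted at node_id, truncated ``levels`` merges down.

    Each displayed node is annotated with whatever statistics the annotation
    table holds for it (completeness, R_meas, CC1/2 resolution).
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    n = dendro.n_leaves
    if not n + 1 <= node_id <= 2 * n - 1:
        raise KeyError(f"unknown cluster {node_id} (leaves cannot be plotted alone)")
    keep = _subtree_ids(dendro, node_id, levels)
    pos = _node_positions(dendro)
    fig, ax = plt.subplots(figsize=(8, 5))
    for ident in keep:
        if ident in dendro.cells:
            continue
        nd = dendro.node(ident)
        x, h = pos[ident]
        for child in nd.children:
            if child not in keep:
                continue
            cx, ch = pos[child]
            ax.plot([cx, cx, x], [ch, h, h], color="tab:blue", lw=1.0)
        label = f"{ident}\naLCV {nd.alcv:.2f}"
        if annotations and ident in annotations.rows:
            row = annotations.rows[ident]
            extra = []
            if row.get("completeness") is not None:
                extra.append(f"C {row['completeness']:.1f}%")
            if row.get("r_meas") is not None:
                extra.append(f"Rmeas {row['r_meas']:.3f}")
            if row.get("res_cc") is not None:
                extra.append(f"dCC {row['res_cc']:.2f}")
            label += "\n" + " ".join(extra)
        ax.annotate(
            label,
            xy=(x, h),
            ha="center",
            va="bottom",
            fontsize=7,
            bbox=dict(boxstyle="round", facecolor="lightyellow", edgecolor="0.4"),
        )
    for ident in keep:
        if ident in dendro.cells:
            x, h = pos[ident]
            ax.annotate(str(ident), xy=(x, h), ha="center", va="top", fontsize=7)
    ax.set_ylabel("merge height")
    ax.set_xticks([])
    fig.tight_layout()
    return _save(fig, Path(path), formats)


def plot_cc_half(
    results: Sequence,
    path: str | Path = "cc_half.png",
    labels: Sequence[str] | None = None,
    threshold: float = 0.3,
    formats: Sequence[str] = ("png",),
) -> list[Path]:
    """CC1/2 versus resolution, one curve per merge result."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, result in enumerate(results):
        shells = result.stats.per_shell
        label = labels[i] if labels else (result.tag or f"group {i + 1}")
        ax.plot(shells["s_mid"], shells["cc_half"], marker="o", ms=3, label=label)
    ax.axhline(threshold, color="0.4", ls="--", lw=0.8)
    smin, smax = ax.get_xlim()
    ticks = ax.get_xticks()
    ax.set_xticks(ticks[(ticks > 0)])
    ax.set_xticklabels([f"{1 / math.sqrt(t):.2f}" for t in ticks if t > 0])
    ax.set_xlim(smin, smax)
    ax.set_xlabel("resolution d (A)")
    ax.set_ylabel("CC1/2")
    ax.set_ylim(-0.1, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return _save(fig, Path(path), formats)
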