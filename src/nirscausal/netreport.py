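"""Assembly, classification and export of significant-edge directed networks.

After edge-level inference, the significant edges for one effect (age, race,
or race-by-age interaction) form a directed network over the 46-channel
montage.  Edges are classified by area pair (intra-frontal, intra-occipital,
frontal->occipital, occipital->frontal) and - for interaction edges - by
developmental trend subtype, obtained from the per-condition least-squares
slopes of the edge weight on age:

* positive NORE-age family (own-race difference grows with age):
  own slope up while the other-race slope is flat, or own up / other down;
* negative family (other-race difference grows): other up / own flat, or
  other up / own down.

A slope counts as "up"/"down" only when its two-sided p < 0.05, otherwise it
is "flat"; sign patterns outside the four families are reported as
unclassified rather than forced into a subtype.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .channels import ChannelInfo, EdgeClass, classify_edge, default_channels

__all__ = [
    "TrendSubtype",
    "NetworkEdge",
    "GCNetwork",
    "classify_trend",
    "assemble_network",
    "export_graph",
    "read_graph",
    "plot_network",
]


class TrendSubtype(str, Enum):
    pos_own_up_other_flat = "pos_own_up_other_flat"
    pos_own_up_other_down = "pos_own_up_other_down"
    neg_other_up_own_flat = "neg_other_up_own_flat"
    neg_other_up_own_down = "neg_other_up_own_down"


@dataclass(frozen=True)
class NetworkEdge:
    from_ch: int
    to_ch: int
    edge_class: EdgeClass
    trend: str | None = None  # TrendSubtype value, "increasing"/"decreasing", or None
    nore_r: float = np.nan
    boot_mean_eta2: float = np.nan


@dataclass
class GCNetwork:
    """Significant directed edges for one effect, with classification counts."""

    effect: str
    edges: list[NetworkEdge] = field(default_factory=list)

    @property
    def class_counts(self) -> Counter:
        return Counter(e.edge_class for e in self.edges)

    @property
    def trend_counts(self) -> Counter:
        return Counter(e.trend for e in self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "effect": self.effect,
                "from": e.from_ch,
                "to": e.to_ch,
                "edge_class": e.edge_class.value,
                "trend": e.trend if e.trend is not None else "unclassified",
                "nore_r": e.nore_r,
                "boot_mean_eta2": e.boot_mean_eta2,
            }
            for e in sorted(self.edges, key=lambda e: (e.from_ch, e.to_ch))
        ]
        return pd.DataFrame(
            rows, columns=["effect", "from", "to", "edge_class", "trend",
                           "nore_r", "boot_mean_eta2"]
        )


def _slope_call(y: np.ndarray, age: np.ndarray, alpha: float = 0.05) -> str:
    """'up', 'down' or 'flat' from the least-squares slope of y on age."""
    res = sps.linregress(age, y)
    if res.pvalue < alpha and res.slope > 0:
        return "up"
    if res.pvalue < alpha and res.slope < 0:
        return "down"
    return "flat"


def classify_trend(y_own, y_other, age, alpha: float = 0.05) -> TrendSubtype | None:
    """Developmental-trend subtype of an interaction-significant edge.

    Returns ``None`` (unclassified) when neither condition shows a
    significant slope or the sign pattern matches none of the four subtypes.
    """
    y_own = np.asarray(y_own, dtype=float)
    y_other = np.asarray(y_other, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.var(y_own - y_other) == 0:
        return None
    own_call = _slope_call(y_own, age, alpha)
    other_call = _slope_call(y_other, age, alpha)
    d = y_own - y_other
    r = np.corrcoef(age, d)[0, 1] if np.var(d) > 0 else 0.0
    if r > 0:
        if own_call == "up" and other_call == "flat":
            return TrendSubtype.pos_own_up_other_flat
        if own_call == "up" and other_call == "down":
            return TrendSubtype.pos_own_up_other_down
    elif r < 0:
        if other_call == "up" and own_call == "flat":
            return TrendSubtype.neg_other_up_own_flat
        if other_call == "up" and own_call == "down":
            return TrendSubtype.neg_other_up_own_down
    return None


def assemble_network(
    stats: pd.DataFrame,
    effect: str,
    weights_own: np.ndarray | None = None,
    weights_other: np.ndarray | None = None,
    ages: np.ndarray | None = None,
    edges: Sequence[tuple[int, int]] | None = None,
) -> GCNetwork:
    """Collect the significant edges of one effect into a :class:`GCNetwork`.

    ``stats`` is the long-format edge table (columns from, to, effect,
    significant, nore_r, boot_mean_eta2).  When the per-participant weight
    matrices (N x E, matching ``edges``) and ages are supplied, each edge is
    labeled with its age trend: the four interaction subtypes for the
    interaction effect, or the sign of the condition-mean age slope for the
    age effect.
    """
    sub = stats[(stats["effect"] == effect) & stats["significant"]]
    edge_index = {tuple(e): k for k, e in enumerate(edges)} if edges is not None else {}
    net = GCNetwork(effect=effect)
    for _, row in sub.sort_values(["from", "to"]).iterrows():
        pair = (int(row["from"]), int(row["to"]))
        trend: str | None = None
        if pair in edge_index and ages is not None:
            k = edge_index[pair]
            own = weights_own[:, k]
            other = weights_other[:, k]
            if effect == "interaction":
                sub_t = classify_trend(own, other, ages)
                trend = sub_t.value if sub_t is not None else None
            elif effect == "age":
                mean_w = 0.5 * (own + other)
                slope = sps.linregress(ages, mean_w).slope
                trend = "increasing" if slope > 0 else "decreasing"
        net.edges.append(
            NetworkEdge(
                from_ch=pair[0],
                to_ch=pair[1],
                edge_class=classify_edge(*pair),
                trend=trend,
                nore_r=float(row.get("nore_r", np.nan)),
                boot_mean_eta2=float(row.get("boot_mean_eta2", np.nan)),
            )
        )
    return net


def _as_graph(network: GCNetwork, channels: Sequence[ChannelInfo]) -> nx.DiGraph:
    g = nx.DiGraph(effect=network.effect)
    for ch in channels:
        g.add_node(
            ch.id,
            mni_x=float(ch.mni[0]), mni_y=float(ch.mni[1]), mni_z=float(ch.mni[2]),
            ba=int(ch.ba), aal=ch.aal, region=ch.region.value,
            hemisphere=ch.hemisphere.value,
        )
    for e in sorted(network.edges, key=lambda e: (e.from_ch, e.to_ch)):
        g.add_edge(
            e.from_ch, e.to_ch,
            edge_class=e.edge_class.value,
            trend=e.trend if e.trend is not None else "unclassified",
            nore_r=float(e.nore_r) if np.isfinite(e.nore_r) else 0.0,
            boot_mean_eta2=(float(e.boot_mean_eta2)
                            if np.isfinite(e.boot_mean_eta2) else 0.0),
        )
    return g


def export_graph(network: GCNetwork, path: str | Path,
                 channels: Sequence[ChannelInfo] | None = None) -> tuple[Path, Path]:
    """Write the network as GraphML plus a flat TSV edge list.

    Node attributes carry the montage metadata (MNI, BA, AAL, region,
    hemisphere); edge attributes carry class, trend and statistics.  Output
    ordering is stable (sorted by (from, to)), so identical inputs yield
    byte-identical files.  Returns (graphml_path, tsv_path).
    """
    channels = channels if channels is not None else default_channels()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    graphml = path.with_suffix(".graphml")
    tsv = path.with_suffix(".tsv")
    try:
        nx.write_graphml(_as_graph(network, channels), graphml)
        network.summary_frame().to_csv(tsv, sep="\t", index=False,
                                       float_format="%.10g")
    except OSError as exc:
        raise OSError(f"failed to export network to {path}: {exc}") from exc
    return graphml, tsv


def read_graph(graphml_path: str | Path) -> GCNetwork:
    """Re-read an exported GraphML file into a :class:`GCNetwork`."""
    g = nx.read_graphml(graphml_path)
    net = GCNetwork(effect=g.graph.get("effect", ""))
    for u, v, attrs in g.edges(data=True):
        trend = attrs.get("trend", "unclassified")
        net.edges.append(
            NetworkEdge(
                from_ch=int(u), to_ch=int(v),
                edge_class=EdgeClass(attrs["edge_class"]),
                trend=None if trend == "unclassified" else trend,
                nore_r=float(attrs.get("nore_r", np.nan)),
                boot_mean_eta2=float(attrs.get("boot_mean_eta2", np.nan)),
            )
        )
    return net


def plot_network(network: GCNetwork, path: str | Path,
                 channels: Sequence[ChannelInfo] | None = None) -> Path:
    """Simple montage diagram: channels scattered at (MNI x, z), directed
    arrows for the network's edges, colored by trend."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    channels = channels if channels is not None else default_channels()
    pos = {c.id: (c.mni[0], c.mni[2] - (120 if c.region.value == "occipital" else 0))
           for c in channels}
    colors = {
        "increasing": "tab:red", "decreasing": "tab:blue",
        TrendSubtype.pos_own_up_other_flat.value: "tab:red",
        TrendSubtype.pos_own_up_other_down.value: "tab:green",
        TrendSubtype.neg_other_up_own_flat.value: "tab:blue",
        TrendSubtype.neg_other_up_own_down.value: "tab:purple",
    }
    fig, ax = plt.subplots(figsize=(6, 8))
    xs = [pos[c.id][0] for c in channels]
    ys = [pos[c.id][1] for c in channels]
    ax.scatter(xs, ys, s=60, c="lightgray", edgecolors="k", zorder=2)
    for c in channels:
        ax.annotate(str(c.id), pos[c.id], fontsize=6, ha="center", va="center",
                    zorder=3)
    for e in network.edges:
        x0, y0 = pos[e.from_ch]
        x1, y1 = pos[e.to_ch]
        ax.annotate(
            "", xy=(x1, y1), xytext=(x0, y0),
            arrowprops=dict(arrowstyle="->",
                            color=colors.get(e.trend, "gray"), lw=1.2),
            zorder=1,
        )
    ax.set_title(f"{network.effect} effect: {network.n_edges} edges")
    ax.set_xlabel("MNI x (mm)")
    ax.set_ylabel("frontal (top) / occipital (bottom)")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
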