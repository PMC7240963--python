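"""Assembly and summarization of class-annotated correlation networks.

Edges are correlation pairs surviving a coefficient cutoff and a p-value
cutoff. The trait/trait convention is a strict cutoff (|r| > 0.3); the
trait/transcript convention is inclusive (|r| >= 0.40) — ``build_network``
exposes both via ``r_inclusive``. Networks are :class:`networkx.Graph`
objects whose nodes carry the trait annotation (group/class/subclass) and
whose edges carry r, p, n and sign; filter provenance lives in the graph
attributes.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrelationResult
from .errors import AnnotationCoverageError, ConfigError

#: controlled vocabulary for the top-level trait grouping
TRAIT_GROUPS = frozenset(
    {"primary", "secondary", "lipid", "volatile", "phenotype", "transcript"}
)


class TraitAnnotation:
    """trait id -> (group, class, subclass) mapping with a controlled group vocabulary."""

    def __init__(self, frame: pd.DataFrame):
        required = {"group", "class", "subclass"}
        if not required.issubset(frame.columns):
            raise ValueError(f"annotation frame needs columns {sorted(required)}")
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate trait annotations: {dupes}")
        bad = set(frame["group"]) - TRAIT_GROUPS
        if bad:
            raise ValueError(f"unknown trait groups {sorted(bad)}; allowed: {sorted(TRAIT_GROUPS)}")
        self.frame = frame.copy()

    def __contains__(self, trait: str) -> bool:
        return trait in self.frame.index

    def __len__(self) -> int:
        return len(self.frame)

    def group_of(self, trait: str) -> str:
        return str(self.frame.at[trait, "group"])

    def class_of(self, trait: str) -> str:
        return str(self.frame.at[trait, "class"])

    def subclass_of(self, trait: str) -> str:
        return str(self.frame.at[trait, "subclass"])

    def require_coverage(self, traits: Iterable[str]) -> None:
        missing = [t for t in traits if t not in self.frame.index]
        if missing:
            raise AnnotationCoverageError(missing)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitAnnotation":
        frame = pd.read_csv(path, sep="\t", index_col="trait", dtype=str)
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="trait")


Network = nx.Graph  # nodes: trait + annotation attrs; edges: r, p, n, sign


def build_network(
    cr: CorrelationResult,
    ann: TraitAnnotation,
    r_cutoff: float = 0.3,
    p_cutoff: float = 0.05,
    r_inclusive: bool = False,
    keep_isolated: bool = False,
) -> Network:
    """Filter a correlation result into an annotated network.

    An edge survives iff p < p_cutoff and |r| > r_cutoff (or >= when
    ``r_inclusive``). Isolated (edge-less) traits are dropped unless
    ``keep_isolated``. Every trait in ``cr`` must be annotated.
    """
    if cr.mode == "self":
        traits = list(cr.r.columns)
        candidate_pairs = [
            (a, b) for i, a in enumerate(traits) for b in traits[i + 1 :]
        ]
        all_traits = traits
    else:
        candidate_pairs = [
            (a, b) for a in cr.r.index for b in cr.r.columns if a != b
        ]
        all_traits = list(cr.r.index) + [c for c in cr.r.columns if c not in cr.r.index]
    ann.require_coverage(all_traits)

    net = nx.Graph(
        r_cutoff=float(r_cutoff),
        p_cutoff=float(p_cutoff),
        r_inclusive=bool(r_inclusive),
        mode=cr.mode,
    )

    def _add_node(t: str) -> None:
        net.add_node(t, group=ann.group_of(t), **{"class": ann.class_of(t)},
                     subclass=ann.subclass_of(t))

    if keep_isolated:
        for t in all_traits:
            _add_node(t)
    for a, b in candidate_pairs:
        r = float(cr.r.at[a, b])
        p = float(cr.p.at[a, b])
        if math.isnan(r) or math.isnan(p):
            continue
        passes_r = abs(r) >= r_cutoff if r_inclusive else abs(r) > r_cutoff
        if not (passes_r and p < p_cutoff):
            continue
        for t in (a, b):
            if t not in net:
                _add_node(t)
        net.add_edge(a, b, r=r, p=p, n=int(cr.n.at[a, b]), sign=1 if r > 0 else -1)
    return net


def class_pair_summary(net: Network) -> pd.DataFrame:
    """Edge counts and percent-positive per unordered annotation-class pair.

    Within-class pairs (classA == classB) are included. Percentages are kept
    at full precision here; use :func:`class_pair_matrix` for the
    integer-rounded report layout. An empty network yields an empty frame.
    """
    rows: dict[tuple[str, str], dict] = {}
    total = net.number_of_edges()
    for a, b, attrs in net.edges(data=True):
        key = tuple(sorted((net.nodes[a]["class"], net.nodes[b]["class"])))
        rec = rows.setdefault(key, {"count": 0, "positive": 0, "negative": 0})
        rec["count"] += 1
        rec["positive" if attrs["sign"] > 0 else "negative"] += 1
    records = []
    for (ca, cb), rec in sorted(rows.items()):
        records.append(
            {
                "class_a": ca,
                "class_b": cb,
                "count": rec["count"],
                "positive": rec["positive"],
                "negative": rec["negative"],
                "percent_positive": 100.0 * rec["positive"] / rec["count"],
                "share_percent": 100.0 * rec["count"] / total,
            }
        )
    return pd.DataFrame(
        records,
        columns=["class_a", "class_b", "count", "positive", "negative",
                 "percent_positive", "share_percent"],
    )


def class_pair_matrix(summary: pd.DataFrame, classes: list[str] | None = None) -> pd.DataFrame:
    """Square classes × classes matrix of integer-rounded percent-positive.

    Mirrors the published report layout: symmetric, NaN where a class pair
    has no edges.
    """
    if classes is None:
        classes = sorted(set(summary["class_a"]) | set(summary["class_b"]))
    mat = pd.DataFrame(np.nan, index=classes, columns=classes)
    for _, row in summary.iterrows():
        val = float(np.rint(row["percent_positive"]))
        mat.at[row["class_a"], row["class_b"]] = val
        mat.at[row["class_b"], row["class_a"]] = val
    return mat


def network_stats(net: Network) -> dict:
    """Node/edge counts, overall percent-positive, and per-group breakdowns."""
    n_edges = net.number_of_edges()
    n_pos = sum(1 for *_, s in net.edges(data="sign") if s > 0)
    groups: dict[str, int] = {}
    for _, g in net.nodes(data="group"):
        groups[g] = groups.get(g, 0) + 1
    pair_counts: dict[tuple[str, str], int] = {}
    for a, b in net.edges():
        key = tuple(sorted((net.nodes[a]["group"], net.nodes[b]["group"])))
        pair_counts[key] = pair_counts.get(key, 0) + 1
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": n_edges,
        "n_positive": n_pos,
        "n_negative": n_edges - n_pos,
        "percent_positive": (100.0 * n_pos / n_edges) if n_edges else float("nan"),
        "nodes_per_group": groups,
        "edge_share_per_group_pair": {
            k: 100.0 * v / n_edges for k, v in sorted(pair_counts.items())
        },
    }


# ---------------------------------------------------------------------------
# export / import

_EDGE_COLUMNS = ["trait_a", "trait_b", "r", "p", "n", "sign"]


def export_network(net: Network, fmt: str, path: str | Path) -> None:
    """Write the network as ``graphml``, ``sif`` or ``edge_tsv``.

    GraphML carries node annotation and edge statistics as attributes; SIF
    uses interaction labels ``pos``/``neg``; the edge TSV round-trips exactly
    (17 significant digits on floats).
    """
    path = Path(path)
    if fmt == "graphml":
        clean = nx.Graph(**{k: v for k, v in net.graph.items()
                            if isinstance(v, (str, int, float, bool))})
        clean.add_nodes_from(net.nodes(data=True))
        clean.add_edges_from(net.edges(data=True))
        nx.write_graphml(clean, path)
    elif fmt == "sif":
        lines = [
            f"{a}\t{'pos' if attrs['sign'] > 0 else 'neg'}\t{b}"
            for a, b, attrs in sorted(net.edges(data=True))
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "edge_tsv":
        frame = pd.DataFrame(
            [
                (a, b, attrs["r"], attrs["p"], attrs["n"], attrs["sign"])
                for a, b, attrs in sorted(net.edges(data=True))
            ],
            columns=_EDGE_COLUMNS,
        )
        frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ConfigError(f"unknown export format: {fmt!r}")


def read_edge_tsv(path: str | Path, ann: TraitAnnotation | None = None) -> Network:
    """Rebuild a network from an edge TSV; annotate nodes when ``ann`` given."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    net = nx.Graph()
    for row in frame.itertuples(index=False):
        for t in (row.trait_a, row.trait_b):
            if ann is not None and t not in net:
                net.add_node(t, group=ann.group_of(t), **{"class": ann.class_of(t)},
                             subclass=ann.subclass_of(t))
        net.add_edge(row.trait_a, row.trait_b, r=float(row.r), p=float(row.p),
                     n=int(row.n), sign=int(row.sign))
    return net
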