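"""Metabolite–transcript integration: bipartite networks, heatmap selection,
candidate-gene ranking.

Transcript abundances are correlated against metabolite (typically lipid)
profiles across the shared genotype lines; the stricter inclusive cutoff
|r| >= 0.40 (p < 0.05) defines the bipartite network. Any transcript with at
least one surviving edge becomes a candidate gene, ranked by how many
metabolites it connects to and how strongly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .correlation import CorrelationResult, correlate_between
from .network import Network, TraitAnnotation, build_network
from .preprocess import TraitMatrix

TRANSCRIPT_R_CUTOFF = 0.40


def trait_transcript_network(
    metab: TraitMatrix,
    expr: TraitMatrix,
    ann: TraitAnnotation,
    min_n: int = 10,
    B: int = 20_000,
    seed: int = 0,
    r_cutoff: float = TRANSCRIPT_R_CUTOFF,
    p_cutoff: float = 0.05,
) -> Network:
    """Bipartite trait × transcript network at the inclusive |r| >= 0.40 cutoff.

    The underlying :class:`CorrelationResult` is stored on
    ``net.graph["_correlation_result"]`` for heatmap selection.
    """
    cr = correlate_between(metab, expr, min_n=min_n, B=B, seed=seed)
    net = build_network(cr, ann, r_cutoff=r_cutoff, p_cutoff=p_cutoff, r_inclusive=True)
    net.graph["_correlation_result"] = cr
    return net


def select_heatmap(
    net: Network,
    cr: CorrelationResult,
    order: str = "alpha",
) -> pd.DataFrame:
    """Rectangular r matrix over traits/transcripts with >= 1 surviving edge.

    Selected rows and columns keep *all* their r values, including
    sub-threshold ones, so the heatmap shows the full correlation context of
    every selected trait and transcript. ``order`` is ``"alpha"``
    (deterministic alphabetical) or ``"cluster"`` (average-linkage on
    correlation distance).
    """
    with_edge = {node for node in net.nodes if net.degree(node) > 0}
    rows = sorted(t for t in cr.r.index if t in with_edge)
    cols = sorted(t for t in cr.r.columns if t in with_edge)
    mat = cr.r.loc[rows, cols]
    if order == "cluster" and len(rows) > 2 and len(cols) > 2:
        filled = mat.fillna(0.0)
        row_order = leaves_list(linkage(pdist(filled.to_numpy(), metric="correlation"),
                                        method="average"))
        col_order = leaves_list(linkage(pdist(filled.to_numpy().T, metric="correlation"),
                                        method="average"))
        mat = mat.iloc[row_order, col_order]
    elif order not in ("alpha", "cluster"):
        raise ValueError(f"unknown heatmap order: {order!r}")
    return mat


@dataclass
class CandidateGene:
    """A transcript with at least one surviving metabolite link."""

    transcript: str
    links: list[tuple[str, float, float, int]]  # (trait, r, p, sign)
    n_links: int
    n_positive: int
    n_negative: int
    max_abs_r: float
    dominant_class: str


def rank_candidates(net: Network) -> list[CandidateGene]:
    """One candidate per linked transcript, sorted by (n_links desc,
    max |r| desc, transcript id asc). Dominant class is the most common
    annotation class among linked traits (alphabetical tie-break)."""
    candidates: list[CandidateGene] = []
    transcripts = [n for n, g in net.nodes(data="group") if g == "transcript"]
    for t in transcripts:
        links = []
        for nbr in net.neighbors(t):
            attrs = net.edges[t, nbr]
            links.append((nbr, attrs["r"], attrs["p"], attrs["sign"]))
        if not links:
            continue
        links.sort(key=lambda l: (-abs(l[1]), l[0]))
        class_counts = Counter(net.nodes[trait]["class"] for trait, *_ in links)
        top = max(class_counts.values())
        dominant = min(c for c, v in class_counts.items() if v == top)
        candidates.append(
            CandidateGene(
                transcript=t,
                links=links,
                n_links=len(links),
                n_positive=sum(1 for l in links if l[3] > 0),
                n_negative=sum(1 for l in links if l[3] < 0),
                max_abs_r=max(abs(l[1]) for l in links),
                dominant_class=dominant,
            )
        )
    candidates.sort(key=lambda c: (-c.n_links, -c.max_abs_r, c.transcript))
    return candidates


def candidates_to_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript": c.transcript,
                "n_links": c.n_links,
                "n_pos": c.n_positive,
                "n_neg": c.n_negative,
                "max_abs_r": c.max_abs_r,
                "dominant_class": c.dominant_class,
                "linked_traits": ";".join(trait for trait, *_ in c.links),
            }
            for c in candidates
        ],
        columns=["transcript", "n_links", "n_pos", "n_neg", "max_abs_r",
                 "dominant_class", "linked_traits"],
    )


def write_candidates(candidates: list[CandidateGene], path: str | Path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def join_tissues(per_tissue: dict[str, list[CandidateGene]]) -> pd.DataFrame:
    """Report transcripts found as candidates in several independent runs
    (e.g. fruit and leaf), with per-tissue link counts."""
    rows: dict[str, dict] = {}
    for tissue, cands in per_tissue.items():
        for c in cands:
            rows.setdefault(c.transcript, {})[f"n_links_{tissue}"] = c.n_links
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame.index.name = "transcript"
    frame["n_tissues"] = frame.notna().sum(axis=1)
    return frame
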