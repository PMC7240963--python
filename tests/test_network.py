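"""Network assembly, class-pair summaries and export round trips."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ilnet import (
    TraitAnnotation,
    build_network,
    class_pair_matrix,
    class_pair_summary,
    export_network,
    network_stats,
    read_edge_tsv,
)
from ilnet.correlation import CorrelationResult
from ilnet.errors import AnnotationCoverageError, ConfigError


def make_cr(traits, pairs):
    """Square CorrelationResult from {(a, b): (r, p)} with n=50 elsewhere NaN."""
    k = len(traits)
    r = pd.DataFrame(np.nan, index=traits, columns=traits)
    p = pd.DataFrame(np.nan, index=traits, columns=traits)
    n = pd.DataFrame(50, index=traits, columns=traits)
    np.fill_diagonal(r.values, 1.0)
    for (a, b), (rv, pv) in pairs.items():
        r.at[a, b] = r.at[b, a] = rv
        p.at[a, b] = p.at[b, a] = pv
    return CorrelationResult(r=r, p=p, n=n, meta={"mode": "self", "min_n": 10})


def make_ann(mapping):
    frame = pd.DataFrame(
        [(t, g, c, "sub") for t, (g, c) in mapping.items()],
        columns=["trait", "group", "class", "subclass"],
    ).set_index("trait")
    return TraitAnnotation(frame)


@pytest.fixture
def four_pair_cr():
    traits = ["a", "b", "c", "d"]
    pairs = {
        ("a", "b"): (0.5, 0.01),
        ("a", "c"): (-0.4, 0.01),
        ("a", "d"): (0.2, 0.01),
        ("b", "c"): (0.5, 0.6),
    }
    ann = make_ann({t: ("lipid", "TAG") for t in traits})
    return make_cr(traits, pairs), ann


def test_strict_cutoff_filters_exactly(four_pair_cr):
    cr, ann = four_pair_cr
    net = build_network(cr, ann, r_cutoff=0.3, p_cutoff=0.05)
    assert set(map(frozenset, net.edges())) == {frozenset("ab"), frozenset("ac")}
    assert net.edges["a", "c"]["sign"] == -1


def test_cutoff_boundary_semantics():
    traits = ["x", "y", "z"]
    pairs = {("x", "y"): (0.3, 0.001), ("x", "z"): (0.40, 0.001)}
    ann = make_ann({t: ("lipid", "TAG") for t in traits})
    cr = make_cr(traits, pairs)
    strict = build_network(cr, ann, r_cutoff=0.3, p_cutoff=0.05)
    assert not strict.has_edge("x", "y")  # "higher than 0.3" is strict
    inclusive = build_network(cr, ann, r_cutoff=0.40, p_cutoff=0.05, r_inclusive=True)
    assert inclusive.has_edge("x", "z")  # ">= 0.40" keeps the boundary


def test_unannotated_trait_lists_offenders(four_pair_cr):
    cr, _ = four_pair_cr
    ann = make_ann({"a": ("lipid", "TAG"), "b": ("lipid", "TAG")})
    with pytest.raises(AnnotationCoverageError) as exc:
        build_network(cr, ann)
    assert exc.value.missing == ["c", "d"]


def test_keep_isolated_retains_edge_free_nodes(four_pair_cr):
    cr, ann = four_pair_cr
    assert "d" not in build_network(cr, ann)
    net = build_network(cr, ann, keep_isolated=True)
    assert "d" in net and net.degree("d") == 0


def test_annotation_vocabulary_enforced():
    with pytest.raises(ValueError, match="unknown trait group"):
        make_ann({"a": ("mystery", "TAG")})


def test_class_pair_summary_arithmetic():
    traits = [f"t{i}" for i in range(6)]
    ann = make_ann({t: ("lipid", "A" if i < 3 else "B") for i, t in enumerate(traits)})
    pairs = {
        ("t0", "t3"): (0.5, 0.01), ("t0", "t4"): (0.6, 0.01),
        ("t1", "t3"): (0.7, 0.01), ("t2", "t5"): (-0.5, 0.01),
        ("t0", "t1"): (0.9, 0.01),
    }
    net = build_network(make_cr(traits, pairs), ann)
    summary = class_pair_summary(net).set_index(["class_a", "class_b"])
    ab = summary.loc[("A", "B")]
    assert ab["count"] == 4 and ab["positive"] == 3 and ab["negative"] == 1
    assert ab["percent_positive"] == 75.0
    assert summary["positive"].add(summary["negative"]).equals(summary["count"])
    assert summary["share_percent"].sum() == pytest.approx(100.0)
    assert summary["count"].sum() == network_stats(net)["n_edges"]
    mat = class_pair_matrix(summary.reset_index())
    assert mat.at["A", "B"] == 75 and mat.at["B", "A"] == 75


def test_network_stats_percentages():
    traits = [f"t{i}" for i in range(5)]
    ann = make_ann({t: ("lipid", "TAG") for t in traits})
    combos = list(itertools.combinations(traits, 2))
    pairs = {c: (0.8 if i < 6 else -0.8, 0.001) for i, c in enumerate(combos)}
    stats = network_stats(build_network(make_cr(traits, pairs), ann))
    assert stats["n_edges"] == 10 and stats["percent_positive"] == 60.0
    assert sum(stats["edge_share_per_group_pair"].values()) == pytest.approx(100.0)


def test_empty_network_summary_and_stats():
    traits = ["a", "b"]
    ann = make_ann({t: ("lipid", "TAG") for t in traits})
    net = build_network(make_cr(traits, {("a", "b"): (0.1, 0.9)}), ann)
    assert class_pair_summary(net).empty
    stats = network_stats(net)
    assert stats["n_edges"] == 0 and math.isnan(stats["percent_positive"])


@pytest.mark.parametrize("seed", range(3))
def test_filter_monotonicity(seed):
    """Raising the r cutoff or lowering the p cutoff never adds edges."""
    rng = np.random.default_rng(seed)
    traits = [f"t{i}" for i in range(8)]
    pairs = {
        (a, b): (float(rng.uniform(-1, 1)), float(rng.uniform(0, 0.2)))
        for a, b in itertools.combinations(traits, 2)
    }
    ann = make_ann({t: ("lipid", "TAG") for t in traits})
    cr = make_cr(traits, pairs)
    def edge_set(net):
        return set(map(frozenset, net.edges()))

    loose = edge_set(build_network(cr, ann, r_cutoff=0.2, p_cutoff=0.1))
    tight_r = edge_set(build_network(cr, ann, r_cutoff=0.5, p_cutoff=0.1))
    tight_p = edge_set(build_network(cr, ann, r_cutoff=0.2, p_cutoff=0.01))
    assert tight_r <= loose and tight_p <= loose


@pytest.fixture
def export_net(four_pair_cr):
    cr, ann = four_pair_cr
    return build_network(cr, ann), ann


def test_edge_tsv_roundtrip_is_exact(tmp_path, export_net):
    net, ann = export_net
    path = tmp_path / "edges.tsv"
    export_network(net, "edge_tsv", path)
    back = read_edge_tsv(path, ann)
    assert set(map(frozenset, back.edges())) == set(map(frozenset, net.edges()))
    for a, b in net.edges():
        assert back.edges[a, b] == net.edges[a, b]


def test_sif_has_one_line_per_edge(tmp_path, export_net):
    net, _ = export_net
    path = tmp_path / "net.sif"
    export_network(net, "sif", path)
    lines = path.read_text().splitlines()
    assert len(lines) == net.number_of_edges()
    assert all(line.split("\t")[1] in ("pos", "neg") for line in lines)


def test_graphml_roundtrip_preserves_attributes(tmp_path, export_net):
    net, _ = export_net
    path = tmp_path / "net.graphml"
    export_network(net, "graphml", path)
    back = nx.read_graphml(path)
    assert set(map(frozenset, back.edges())) == set(map(frozenset, net.edges()))
    for a, b in net.edges():
        assert back.edges[a, b]["r"] == net.edges[a, b]["r"]
        assert back.edges[a, b]["sign"] == net.edges[a, b]["sign"]
    for node in net.nodes():
        assert back.nodes[node]["class"] == net.nodes[node]["class"]


def test_unknown_export_format_rejected(tmp_path, export_net):
    net, _ = export_net
    with pytest.raises(ConfigError, match="format"):
        export_network(net, "gexf", tmp_path / "x")
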