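"""Spearman coefficient and permutation p-value contracts."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, strategies as st

from ilnet import correlate_all, correlate_between, perm_pvalue, spearman
from ilnet.errors import AlignmentError, ConfigError
from ilnet.preprocess import TraitMatrix
from ilnet import SyntheticConfig, aggregate_replicates, generate_expression, \
    generate_population, log_standardize


def _tm(frame: pd.DataFrame) -> TraitMatrix:
    support = frame.notna().astype(int)
    return TraitMatrix(frame, support, {c: "raw" for c in frame.columns})


# ---------------------------------------------------------------------- rho

def test_identity_and_reversal():
    assert spearman([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0
    assert spearman([1, 2, 3, 4], [4, 3, 2, 1]) == -1.0


def test_undefined_markers():
    assert math.isnan(spearman([1, 2], [3, 4]))            # < 3 pairs
    assert math.isnan(spearman([1, 1, 1, 1], [1, 2, 3, 4]))  # flat ranks
    assert math.isnan(spearman([1, np.nan, 2], [1, 2, np.nan]))  # 1 complete pair


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("with_ties", [False, True])
def test_matches_rank_then_pearson_oracle(seed, with_ties):
    """Independent oracle: scipy's Spearman (mid-ranks on ties) to 1e-12."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(10)
    y = rng.standard_normal(10)
    if with_ties:
        x = np.round(x)  # force duplicates
        y = np.round(y)
    expected = scipy.stats.spearmanr(x, y).statistic
    assert spearman(x, y) == pytest.approx(expected, abs=1e-12)


@given(st.lists(st.integers(-500, 500), min_size=5, max_size=15, unique=True),
       st.sampled_from(["exp", "cube", "affine"]))
def test_invariant_under_strictly_monotone_transforms(xs, transform):
    rng = np.random.default_rng(7)
    y = rng.standard_normal(len(xs))
    x = np.array(xs, dtype=float)
    fx = {"exp": np.exp(x / 50), "cube": x ** 3, "affine": 3 * x + 2}[transform]
    assert spearman(fx, y) == pytest.approx(spearman(x, y), abs=1e-12)


# ------------------------------------------------------------------ p-values

def test_exhaustive_p_for_perfect_concordance_is_2_over_120():
    # only the identity and the full reversal of 5 ranks reach |rho| = 1
    p = perm_pvalue([1, 2, 3, 4, 5], [10, 20, 30, 40, 50], mode="exhaustive")
    assert p == pytest.approx(2 / 120, abs=1e-15)


def test_add_one_bound_and_config_errors():
    rng = np.random.default_rng(0)
    x, y = rng.standard_normal(12), rng.standard_normal(12)
    p = perm_pvalue(x, y, B=100, seed=1)
    assert p >= 1 / 101
    with pytest.raises(ConfigError, match="B >= 100"):
        perm_pvalue(x, y, B=50)
    with pytest.raises(ConfigError, match="exhaustive"):
        perm_pvalue(rng.standard_normal(12), rng.standard_normal(12), mode="exhaustive")


@pytest.mark.parametrize("seed", range(4))
def test_monte_carlo_agrees_with_exhaustive_small_n(seed):
    """For n=7 the Monte-Carlo estimate must sit within 3 binomial SEs of the
    exact enumeration over 5040 permutations."""
    rng = np.random.default_rng(seed)
    x, y = rng.standard_normal(7), rng.standard_normal(7)
    p_ex = perm_pvalue(x, y, mode="exhaustive")
    B = 20_000
    p_mc = perm_pvalue(x, y, B=B, seed=seed + 100)
    se = math.sqrt(p_ex * (1 - p_ex) / B)
    assert abs(p_mc - p_ex) <= 3 * se + 1 / (B + 1)


def test_pvalue_requires_defined_rho():
    with pytest.raises(ValueError, match="undefined"):
        perm_pvalue([1, 1, 1, 1], [1, 2, 3, 4])


# ------------------------------------------------------------- matrix modes

def test_correlate_all_contract():
    rng = np.random.default_rng(3)
    frame = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
    cr = correlate_all(_tm(frame), min_n=5, B=200, seed=0)
    assert cr.r.shape == (3, 3)
    pd.testing.assert_frame_equal(cr.r, cr.r.T)
    assert (np.diag(cr.r) == 1.0).all()
    off = cr.p.where(~np.eye(3, dtype=bool)).stack()
    assert ((off > 0) & (off <= 1)).all()
    assert len(cr.pairs()) == 3  # C(3,2)


def test_correlate_all_is_seed_deterministic():
    rng = np.random.default_rng(4)
    frame = pd.DataFrame(rng.standard_normal((25, 4)), columns=list("abcd"))
    c1 = correlate_all(_tm(frame), min_n=5, B=300, seed=9)
    c2 = correlate_all(_tm(frame), min_n=5, B=300, seed=9)
    pd.testing.assert_frame_equal(c1.p, c2.p)


def test_insufficient_overlap_yields_nan_marker_not_exception():
    frame = pd.DataFrame({
        "a": [1.0, 2.0, 3.0, np.nan, np.nan, np.nan],
        "b": [np.nan, np.nan, np.nan, 1.0, 2.0, 3.0],
    })
    cr = correlate_all(_tm(frame), min_n=3, B=200, seed=0)
    assert math.isnan(cr.r.at["a", "b"]) and math.isnan(cr.p.at["a", "b"])
    assert cr.n.at["a", "b"] == 0


def test_between_self_gives_unit_diagonal_and_disjoint_errors():
    rng = np.random.default_rng(5)
    frame = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"),
                         index=[f"L{i}" for i in range(20)])
    tm = _tm(frame)
    cr = correlate_between(tm, tm, min_n=5, B=200, seed=0)
    assert cr.mode == "between"
    for c in "abc":
        assert cr.r.at[c, c] == 1.0
    other = TraitMatrix(frame.set_axis([f"M{i}" for i in range(20)]),
                        tm.support.set_axis([f"M{i}" for i in range(20)]),
                        tm.transforms)
    with pytest.raises(AlignmentError):
        correlate_between(tm, other, min_n=5, B=200, seed=0)


def test_correlation_result_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(8)
    frame = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
    cr = correlate_all(_tm(frame), min_n=5, B=200, seed=2)
    from ilnet.correlation import read_correlation_result, write_correlation_result
    write_correlation_result(cr, tmp_path / "cr")
    back = read_correlation_result(tmp_path / "cr")
    pd.testing.assert_frame_equal(cr.r, back.r)
    pd.testing.assert_frame_equal(cr.p, back.p)
    pd.testing.assert_frame_equal(cr.n, back.n)
    assert cr.meta == back.meta


def test_planted_transcript_link_recovered_at_74_lines():
    """A rho=0.8 transcript-trait link across 74 shared lines shows up with
    r > 0.6 and p < 0.05."""
    cfg = SyntheticConfig(
        n_lines=76,
        class_spec=(("lipid", "TAG", "s", 3),),
        replicate_range=(3, 4),
        missing_rate=0.0,
        n_transcripts=2,
        planted_links=(("g1", "TAG_1", 0.8),),
        seed=12,
    )
    table, _, truth = generate_population(cfg)
    expr = generate_expression(cfg, truth)
    metab = log_standardize(aggregate_replicates(table))
    emat = log_standardize(aggregate_replicates(expr))
    metab.values = metab.values.iloc[:74]  # 74 of 76 lines shared
    metab.support = metab.support.iloc[:74]
    cr = correlate_between(metab, emat, min_n=10, B=2000, seed=1)
    assert cr.meta["n_shared_lines"] == 74
    assert cr.r.at["TAG_1", "g1"] > 0.6
    assert cr.p.at["TAG_1", "g1"] < 0.05
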