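"""Spearman rank correlation with permutation-test p-values.

Spearman's rho is computed as the Pearson correlation of mid-ranks (average
ranks on ties). Significance comes from a permutation test: the pairing
between the two vectors is broken by permuting one vector's ranks, either
exhaustively (all n! re-pairings, feasible for n <= 8) or by Monte-Carlo
sampling with the add-one estimator p = (1 + #{|rho_b| >= |rho_obs|}) / (B + 1),
which is conservative and never returns zero. Both tails count: the null is
sign-agnostic because networks keep positive and negative edges alike.

``correlate_all`` / ``correlate_between`` apply this to every column pair of
one or two trait matrices with pairwise-complete deletion of missing cells,
using a deterministic per-pair random substream derived from (seed, i, j) so
a run is reproducible regardless of evaluation order.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AlignmentError, ConfigError
from .preprocess import TraitMatrix

#: |rho_perm| >= |rho_obs| is decided up to this slack to make tied statistics
#: (e.g. the reversal of a perfectly concordant pair) count as extreme.
_RHO_TIE_TOL = 1e-12

DEFAULT_PERMUTATIONS = 20_000
DEFAULT_MIN_N = 10
#: exhaustive enumeration allowed while n! does not exceed this (8! = 40320)
DEFAULT_EXHAUSTIVE_CEILING = 40_320


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def _rank_scores(v: np.ndarray) -> np.ndarray | None:
    """Mid-ranks centered and scaled to unit population variance, or None if flat."""
    r = rankdata(v)
    r = r - r.mean()
    s = math.sqrt(float(np.mean(r * r)))
    if s == 0.0:
        return None
    return r / s


def spearman(x, y) -> float:
    """Spearman's rho of two paired vectors; NaN when undefined.

    Undefined when fewer than 3 complete pairs remain after pairwise deletion
    of missing entries, or when either vector is constant (zero rank variance).
    """
    xc, yc = _complete_pairs(x, y)
    if xc.size < 3:
        return float("nan")
    zx = _rank_scores(xc)
    zy = _rank_scores(yc)
    if zx is None or zy is None:
        return float("nan")
    rho = float(np.mean(zx * zy))
    rho = float(np.clip(rho, -1.0, 1.0))
    if 1.0 - abs(rho) < 1e-12:  # snap float dust on exactly (anti)monotone data
        rho = math.copysign(1.0, rho)
    return rho


def perm_pvalue(
    x,
    y,
    B: int = DEFAULT_PERMUTATIONS,
    mode: Literal["exhaustive", "monte_carlo"] = "monte_carlo",
    seed: int | np.random.SeedSequence | None = None,
    exhaustive_ceiling: int = DEFAULT_EXHAUSTIVE_CEILING,
) -> float:
    """Two-sided permutation p-value for Spearman's rho.

    Exhaustive mode enumerates all n! permutations of y's ranks (the observed
    pairing is one of them, so p >= 1/n!). Monte-Carlo mode draws B random
    permutations and applies the add-one estimator, so p >= 1/(B+1).
    """
    xc, yc = _complete_pairs(x, y)
    rho_obs = spearman(xc, yc)
    if math.isnan(rho_obs):
        raise ValueError("spearman(x, y) is undefined; p-value unavailable")
    n = xc.size
    zx = _rank_scores(xc)
    zy = _rank_scores(yc)
    threshold = abs(rho_obs) - _RHO_TIE_TOL

    if mode == "exhaustive":
        n_perms = math.factorial(n)
        if n_perms > exhaustive_ceiling:
            raise ConfigError(
                f"exhaustive mode needs n! <= {exhaustive_ceiling}; got n={n}"
            )
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        rho_all = zy[perms] @ zx / n
        return float(np.mean(np.abs(rho_all) >= threshold))

    if mode == "monte_carlo":
        if B < 100:
            raise ConfigError(f"monte_carlo mode requires B >= 100; got B={B}")
        rng = np.random.default_rng(seed)
        idx = rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)
        rho_b = zy[idx] @ zx / n
        exceed = int(np.count_nonzero(np.abs(rho_b) >= threshold))
        return float((1 + exceed) / (B + 1))

    raise ConfigError(f"unknown permutation mode: {mode!r}")


@dataclass
class CorrelationResult:
    """Aligned coefficient / p-value / pair-sample-size matrices.

    ``r`` and ``p`` are NaN where fewer than ``meta['min_n']`` complete pairs
    exist (or where rho is undefined). For self-correlation (``mode='self'``)
    the matrices are symmetric with a unit diagonal in ``r``; the diagonal p
    is NaN (a trait against itself carries no test). For ``mode='between'``
    the matrices are rectangular, rows = first matrix's traits.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    meta: dict = field(default_factory=dict)
    q: pd.DataFrame | None = None  # BH-adjusted p, only when requested

    @property
    def mode(self) -> str:
        return self.meta.get("mode", "self")

    def pairs(self) -> pd.DataFrame:
        """Long-form table of the unordered (self) or row×column (between) pairs."""
        records = []
        if self.mode == "self":
            cols = list(self.r.columns)
            for i, a in enumerate(cols):
                for b in cols[i + 1 :]:
                    records.append((a, b, self.r.at[a, b], self.p.at[a, b], self.n.at[a, b]))
        else:
            for a in self.r.index:
                for b in self.r.columns:
                    records.append((a, b, self.r.at[a, b], self.p.at[a, b], self.n.at[a, b]))
        return pd.DataFrame(records, columns=["trait_a", "trait_b", "r", "p", "n"])


def _pair_seed(seed: int, i: int, j: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(int(i), int(j)))


def _pair_stats(
    xc: np.ndarray, yc: np.ndarray, B: int, ss: np.random.SeedSequence
) -> tuple[float, float]:
    rho = spearman(xc, yc)
    if math.isnan(rho):
        return float("nan"), float("nan")
    p = perm_pvalue(xc, yc, B=B, mode="monte_carlo", seed=ss)
    return rho, p


def _apply_bh(p: pd.DataFrame, symmetric: bool) -> pd.DataFrame:
    from statsmodels.stats.multitest import multipletests

    q = p.copy()
    if symmetric:
        cols = list(p.columns)
        idx_pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
        flat = np.array([p.at[a, b] for a, b in idx_pairs])
    else:
        idx_pairs = [(a, b) for a in p.index for b in p.columns]
        flat = np.array([p.at[a, b] for a, b in idx_pairs])
    defined = np.isfinite(flat)
    adj = np.full(flat.shape, np.nan)
    if defined.any():
        adj[defined] = multipletests(flat[defined], method="fdr_bh")[1]
    for (a, b), val in zip(idx_pairs, adj):
        q.at[a, b] = val
        if symmetric:
            q.at[b, a] = val
    return q


def correlate_all(
    m: TraitMatrix,
    min_n: int = DEFAULT_MIN_N,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    adjust: Literal["none", "bh"] = "none",
) -> CorrelationResult:
    """All-against-all Spearman correlation of one matrix's traits.

    Missing cells are handled by pairwise-complete deletion; a pair with
    fewer than ``min_n`` complete observations gets NaN r and p (an undefined
    marker, never an exception). Each pair's Monte-Carlo permutations come
    from a substream seeded by (seed, i, j), so results do not depend on
    evaluation order.
    """
    traits = list(m.values.columns)
    data = m.values.to_numpy(dtype=float)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    for i in range(k):
        nmat[i, i] = int(np.isfinite(data[:, i]).sum())
        r[i, i] = 1.0
    for i in range(k):
        xi = data[:, i]
        for j in range(i + 1, k):
            yj = data[:, j]
            mask = np.isfinite(xi) & np.isfinite(yj)
            n_ij = int(mask.sum())
            nmat[i, j] = nmat[j, i] = n_ij
            if n_ij < min_n:
                continue
            rho, pv = _pair_stats(xi[mask], yj[mask], B, _pair_seed(seed, i, j))
            r[i, j] = r[j, i] = rho
            p[i, j] = p[j, i] = pv
    frames = [pd.DataFrame(a, index=traits, columns=traits) for a in (r, p)]
    result = CorrelationResult(
        r=frames[0],
        p=frames[1],
        n=pd.DataFrame(nmat, index=traits, columns=traits),
        meta={"mode": "self", "B": B, "seed": seed, "min_n": min_n,
              "perm_mode": "monte_carlo", "adjust": adjust},
    )
    if adjust == "bh":
        result.q = _apply_bh(result.p, symmetric=True)
    elif adjust != "none":
        raise ConfigError(f"unknown adjust mode: {adjust!r}")
    return result


def correlate_between(
    a: TraitMatrix,
    b: TraitMatrix,
    min_n: int = DEFAULT_MIN_N,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    adjust: Literal["none", "bh"] = "none",
) -> CorrelationResult:
    """Rectangular Spearman correlation between two matrices' traits.

    The matrices are aligned on their shared genotype lines; an empty (or
    sub-``min_n``) intersection raises :class:`AlignmentError`.
    """
    shared = sorted(set(a.values.index) & set(b.values.index))
    if len(shared) == 0:
        raise AlignmentError("no genotype lines shared between the two matrices")
    if len(shared) < min_n:
        raise AlignmentError(
            f"only {len(shared)} shared lines; min_n={min_n} required"
        )
    av = a.values.loc[shared].to_numpy(dtype=float)
    bv = b.values.loc[shared].to_numpy(dtype=float)
    rows = list(a.values.columns)
    cols = list(b.values.columns)
    r = np.full((len(rows), len(cols)), np.nan)
    p = np.full((len(rows), len(cols)), np.nan)
    nmat = np.zeros((len(rows), len(cols)), dtype=int)
    for i in range(len(rows)):
        xi = av[:, i]
        for j in range(len(cols)):
            yj = bv[:, j]
            mask = np.isfinite(xi) & np.isfinite(yj)
            n_ij = int(mask.sum())
            nmat[i, j] = n_ij
            if n_ij < min_n:
                continue
            rho, pv = _pair_stats(xi[mask], yj[mask], B, _pair_seed(seed, i, j))
            r[i, j] = rho
            p[i, j] = pv
    result = CorrelationResult(
        r=pd.DataFrame(r, index=rows, columns=cols),
        p=pd.DataFrame(p, index=rows, columns=cols),
        n=pd.DataFrame(nmat, index=rows, columns=cols),
        meta={"mode": "between", "B": B, "seed": seed, "min_n": min_n,
              "perm_mode": "monte_carlo", "adjust": adjust,
              "n_shared_lines": len(shared)},
    )
    if adjust == "bh":
        result.q = _apply_bh(result.p, symmetric=False)
    elif adjust != "none":
        raise ConfigError(f"unknown adjust mode: {adjust!r}")
    return result


# ---------------------------------------------------------------------------
# serialization: three aligned TSV matrices + JSON metadata sidecar


def write_correlation_result(cr: CorrelationResult, prefix: str | Path) -> None:
    prefix = str(prefix)
    cr.r.to_csv(prefix + ".r.tsv", sep="\t", float_format="%.17g")
    cr.p.to_csv(prefix + ".p.tsv", sep="\t", float_format="%.17g")
    cr.n.to_csv(prefix + ".n.tsv", sep="\t")
    Path(prefix + ".meta.json").write_text(json.dumps(cr.meta, indent=1, sort_keys=True))


def read_correlation_result(prefix: str | Path) -> CorrelationResult:
    prefix = str(prefix)
    r = pd.read_csv(prefix + ".r.tsv", sep="\t", index_col=0, float_precision="round_trip")
    p = pd.read_csv(prefix + ".p.tsv", sep="\t", index_col=0, float_precision="round_trip")
    n = pd.read_csv(prefix + ".n.tsv", sep="\t", index_col=0).astype(int)
    meta = json.loads(Path(prefix + ".meta.json").read_text())
    return CorrelationResult(r=r, p=p, n=n, meta=meta)
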