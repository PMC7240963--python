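"""Replicate aggregation, log transform and z-scoring of trait tables.

A *replicate table* is a long-form :class:`pandas.DataFrame` with columns
``line, group, replicate, trait, value`` — one row per measured replicate of
one trait on one genotype line. ``group`` is the genotype group of the line
(e.g. ``REF``, ``IL_1``, ``PEN``) and is carried through untouched.

A :class:`TraitMatrix` is the lines × traits matrix the correlation stage
consumes: replicate means, optionally natural-log transformed and z-scored
per trait. Missing cells are NaN; a per-cell support count records how many
replicates were averaged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError

logger = logging.getLogger(__name__)

REPLICATE_COLUMNS = ("line", "group", "replicate", "trait", "value")

#: transform flags a TraitMatrix column may carry
RAW = "raw"
STANDARDIZED = "standardized"
LOG_STANDARDIZED = "log-standardized"
_STANDARDIZED_FLAGS = frozenset({STANDARDIZED, LOG_STANDARDIZED})


def _axes(df: pd.DataFrame) -> pd.DataFrame:
    return df.rename_axis(index="line", columns="trait")


def validate_replicate_table(table: pd.DataFrame) -> None:
    """Check the replicate-table contract; raise ``ValueError`` on violation."""
    missing = [c for c in REPLICATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"replicate table missing columns: {missing}")
    if len(table) == 0:
        raise EmptyInputError("replicate table has no records")
    values = table["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("replicate table contains non-finite values")
    if (table["replicate"] < 1).any():
        raise ValueError("replicate indices must be >= 1")
    if table.duplicated(subset=["line", "replicate", "trait"]).any():
        raise ValueError("(line, replicate, trait) combinations must be unique")


@dataclass
class TraitMatrix:
    """Lines × traits matrix with per-cell replicate support and transform flags.

    Attributes
    ----------
    values : DataFrame
        Rows are genotype lines, columns traits; NaN marks a missing cell.
    support : DataFrame
        Same shape; integer count of replicates behind each cell (0 where
        missing). Season merging sums these.
    transforms : dict
        Per-trait flag: ``"raw"``, ``"standardized"`` or ``"log-standardized"``.
    """

    values: pd.DataFrame
    support: pd.DataFrame
    transforms: dict[str, str] = field(default_factory=dict)

    @property
    def lines(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def is_standardized(self) -> bool:
        return all(t in _STANDARDIZED_FLAGS for t in self.transforms.values())

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(self.values.copy(), self.support.copy(), dict(self.transforms))


def aggregate_replicates(raw: pd.DataFrame) -> TraitMatrix:
    """Collapse replicate records to per-(line, trait) arithmetic means.

    Cells with no records are NaN with support 0. Idempotent on data that
    already has a single replicate per (line, trait).
    """
    validate_replicate_table(raw)
    values = raw.pivot_table(index="line", columns="trait", values="value", aggfunc="mean")
    support = (
        raw.pivot_table(index="line", columns="trait", values="value", aggfunc="count")
        .reindex(index=values.index, columns=values.columns)
        .fillna(0)
        .astype(int)
    )
    values = values.sort_index(axis=0).sort_index(axis=1)
    support = support.loc[values.index, values.columns]
    transforms = {t: RAW for t in values.columns}
    return TraitMatrix(_axes(values), _axes(support), transforms)


def log_standardize(
    m: TraitMatrix,
    pseudo: float = 1e-9,
    skip_log: Iterable[str] = (),
) -> TraitMatrix:
    """Map each trait x -> ln(x + pseudo), then z-score over non-missing cells.

    Traits listed in ``skip_log`` (typically phenotypic counts/lengths, where
    a log scale is not meaningful) are z-scored without the log step. The
    z-score uses the sample (n-1) standard deviation. Traits with fewer than
    3 non-missing cells or zero variance are dropped with a logged warning.
    """
    if pseudo < 0:
        raise ValueError("pseudo must be >= 0")
    skip = set(skip_log)
    out_cols: dict[str, pd.Series] = {}
    transforms: dict[str, str] = {}
    kept: list[str] = []
    for trait in m.values.columns:
        col = m.values[trait].astype(float)
        obs = col.dropna()
        if trait in skip:
            transformed = col
            flag = STANDARDIZED
        else:
            if (obs <= -pseudo).any():
                raise ValueError(
                    f"trait {trait!r} has values <= -pseudo; cannot log-transform"
                )
            transformed = np.log(col + pseudo)
            flag = LOG_STANDARDIZED
        obs_t = transformed.dropna()
        if len(obs_t) < 3:
            logger.warning("dropping trait %r: fewer than 3 non-missing values", trait)
            continue
        sd = obs_t.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("dropping trait %r: zero variance after transform", trait)
            continue
        out_cols[trait] = (transformed - obs_t.mean()) / sd
        transforms[trait] = flag
        kept.append(trait)
    values = pd.DataFrame(out_cols, index=m.values.index)[kept]
    support = m.support[kept].copy()
    return TraitMatrix(_axes(values), _axes(support), transforms)


def merge_seasons(per_season: Sequence[TraitMatrix]) -> TraitMatrix:
    """Average standardized values per (line, trait) across seasons.

    Each season contributes on the z-score scale so seasons with different
    raw scales weigh equally; support counts are summed. A trait measured in
    one season only passes through unchanged.
    """
    if len(per_season) == 0:
        raise EmptyInputError("merge_seasons requires at least one matrix")
    transforms: dict[str, str] = {}
    for tm in per_season:
        if not tm.is_standardized():
            raise ValueError("all matrices must be standardized before merging")
        for trait, flag in tm.transforms.items():
            if transforms.setdefault(trait, flag) != flag:
                raise ValueError(
                    f"conflicting transform flags for trait {trait!r}: "
                    f"{transforms[trait]} vs {flag}"
                )
    lines = sorted({ln for tm in per_season for ln in tm.values.index})
    traits = sorted(transforms)
    total = pd.DataFrame(0.0, index=lines, columns=traits)
    seasons = pd.DataFrame(0, index=lines, columns=traits)
    support = pd.DataFrame(0, index=lines, columns=traits)
    for tm in per_season:
        vals = tm.values.reindex(index=lines, columns=traits)
        present = vals.notna()
        total += vals.fillna(0.0)
        seasons += present.astype(int)
        support += tm.support.reindex(index=lines, columns=traits).fillna(0).astype(int)
    values = total.where(seasons > 0) / seasons.where(seasons > 0)
    return TraitMatrix(_axes(values), _axes(support), transforms)


# ---------------------------------------------------------------------------
# serialization


def write_trait_matrix(tm: TraitMatrix, path: str | Path) -> None:
    """Write values as TSV plus a JSON sidecar with transforms and support."""
    path = Path(path)
    tm.values.to_csv(path, sep="\t", index_label="line", float_format="%.17g")
    sidecar = {
        "transforms": tm.transforms,
        "support": {t: tm.support[t].to_dict() for t in tm.support.columns},
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_trait_matrix(path: str | Path) -> TraitMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="line", float_precision="round_trip")
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    support = pd.DataFrame(
        {t: pd.Series(v) for t, v in meta["support"].items()},
        index=values.index,
        columns=values.columns,
    ).fillna(0).astype(int)
    return TraitMatrix(_axes(values), _axes(support), dict(meta["transforms"]))
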