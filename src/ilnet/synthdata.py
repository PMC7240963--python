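"""Synthetic introgression-line trait and transcript panels with known structure.

The generator emulates the shape of an IL metabolic survey: ~76 genotype
lines measured on several platforms (metabolite classes, lipids, volatiles,
phenotypes) with heterogeneous replicate counts (1–12 per line and
platform), positive abundance values, and a few percent of missing
replicates. Correlation structure is planted through a Gaussian copula on
line-level latent means: traits within a class share a class factor tuned so
that the population Spearman correlation of line means hits the requested
rho; classes may be coupled through correlated factors with either sign.
Replicate values are log-normal around the line mean, so the downstream
log-transform recovers the latent scale and Spearman (rank-based) is
unaffected by the monotone map.

Transcript panels are generated on the same lines: selected transcripts are
coupled to a named trait's latent score at a requested rho (either sign),
and genotype-group fold changes (e.g. a 20-fold elevation in the wild-like
group) multiply the raw abundances of that group's lines.

Everything planted — correlated pairs, independent ("null") pairs,
transcript–trait links, group effects — is reported in a
:class:`SyntheticTruth` so downstream recovery can be scored.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

#: default class taxonomy: (group, class, subclass, n_traits)
DEFAULT_CLASS_SPEC: tuple[tuple[str, str, str, int], ...] = (
    ("lipid", "TAG", "storage-lipid", 10),
    ("lipid", "phospholipid", "membrane-lipid", 10),
    ("primary", "amino-acid", "polar-primary", 10),
    ("secondary", "flavonoids", "polar-secondary", 10),
    ("phenotype", "yield-related", "whole-plant", 10),
)

GENOTYPE_GROUPS = ("REF", "IL_1", "PEN")


def spearman_to_pearson(rho: float) -> float:
    """Latent (bivariate-normal) Pearson r that yields Spearman rho_s = rho."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic IL panel.

    ``intra_class_rho`` and the rho of inter-class blocks / planted links are
    *Spearman* targets on the line-mean scale; the generator converts them to
    latent Pearson correlations internally. ``noise_sd`` is the replicate
    noise on the natural-log scale; ``line_sd`` the between-line latent
    spread of traits and ``transcript_line_sd`` that of transcripts.
    """

    n_lines: int = 76
    replicate_range: tuple[int, int] = (1, 12)
    class_spec: Sequence[tuple[str, str, str, int]] = DEFAULT_CLASS_SPEC
    intra_class_rho: float = 0.7
    inter_class_blocks: Sequence[tuple[str, str, float, int]] = ()
    n_transcripts: int = 20
    planted_links: Sequence[tuple[str, str, float]] = ()
    group_fold_changes: Sequence[tuple[str, str, float]] = ()
    noise_sd: float = 0.25
    missing_rate: float = 0.05
    line_sd: float = 1.0
    transcript_line_sd: float = 0.6
    expr_replicate_range: tuple[int, int] = (3, 4)
    group_sizes: tuple[int, int, int] | None = None  # REF, IL_1, PEN
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 4:
            raise ConfigError("n_lines must be >= 4")
        lo, hi = self.replicate_range
        if not (1 <= lo <= hi):
            raise ConfigError("replicate_range must satisfy 1 <= lo <= hi")
        lo, hi = self.expr_replicate_range
        if not (1 <= lo <= hi):
            raise ConfigError("expr_replicate_range must satisfy 1 <= lo <= hi")
        if not self.class_spec:
            raise ConfigError("class_spec must list at least one class")
        for entry in self.class_spec:
            if len(entry) != 4 or entry[3] < 1:
                raise ConfigError("class_spec entries are (group, class, subclass, n_traits>=1)")
        if not (0.0 <= self.intra_class_rho < 1.0):
            raise ConfigError("intra_class_rho must be in [0, 1)")
        classes = {c for _, c, _, _ in self.class_spec}
        for ca, cb, rho, sign in self.inter_class_blocks:
            if ca not in classes or cb not in classes:
                raise ConfigError(f"inter_class_blocks references unknown class {ca!r}/{cb!r}")
            if not (0.0 < abs(rho) < 1.0):
                raise ConfigError("inter_class_blocks rho must satisfy 0 < |rho| < 1")
            if sign not in (-1, 1):
                raise ConfigError("inter_class_blocks sign must be -1 or +1")
            if self.intra_class_rho == 0.0:
                raise ConfigError("inter_class_blocks require intra_class_rho > 0")
        for _, _, rho in self.planted_links:
            if not (0.0 < abs(rho) < 1.0):
                raise ConfigError("planted_links rho must satisfy 0 < |rho| < 1")
        seen = set()
        for t, _, _ in self.planted_links:
            if t in seen:
                raise ConfigError(f"planted_links lists transcript {t!r} more than once")
            seen.add(t)
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.group_sizes is not None:
            if len(self.group_sizes) != 3 or sum(self.group_sizes) != self.n_lines:
                raise ConfigError("group_sizes must be three counts summing to n_lines")

    def trait_names(self) -> list[str]:
        names = []
        for _, cls, _, k in self.class_spec:
            names.extend(f"{cls}_{i}" for i in range(1, k + 1))
        return names

    def transcript_names(self) -> list[str]:
        return [f"g{i}" for i in range(1, self.n_transcripts + 1)]


@dataclass
class SyntheticTruth:
    """Planted structure of one generated panel.

    ``planted_edges`` / ``null_pairs`` partition the unordered trait pairs;
    ``trait_latents`` (lines × traits latent z-scores) is kept in memory only
    so :func:`generate_expression` can couple transcripts to traits — it is
    not serialized, so a truth loaded from JSON cannot seed expression
    generation.
    """

    planted_edges: set[tuple[str, str, int, float]] = field(default_factory=set)
    planted_gene_links: set[tuple[str, str, int, float]] = field(default_factory=set)
    null_pairs: set[tuple[str, str]] = field(default_factory=set)
    group_effects: set[tuple[str, str, float]] = field(default_factory=set)
    line_groups: dict[str, str] = field(default_factory=dict)
    trait_latents: pd.DataFrame | None = None

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _, _ in self.planted_edges}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_edges": sorted(self.planted_edges),
            "planted_gene_links": sorted(self.planted_gene_links),
            "null_pairs": sorted(self.null_pairs),
            "group_effects": sorted(self.group_effects),
            "line_groups": self.line_groups,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_edges={tuple(e) for e in payload["planted_edges"]},
            planted_gene_links={tuple(e) for e in payload["planted_gene_links"]},
            null_pairs={tuple(p) for p in payload["null_pairs"]},
            group_effects={tuple(g) for g in payload["group_effects"]},
            line_groups=dict(payload["line_groups"]),
        )


def _assign_groups(config: SyntheticConfig) -> tuple[list[str], dict[str, str]]:
    lines = [f"L{i:03d}" for i in range(1, config.n_lines + 1)]
    if config.group_sizes is not None:
        n_ref, n_il, n_pen = config.group_sizes
    else:
        n_ref = n_pen = max(2, round(config.n_lines * 0.16))
        n_il = config.n_lines - n_ref - n_pen
        if n_il < 0:
            n_ref = n_pen = config.n_lines // 3
            n_il = config.n_lines - n_ref - n_pen
    groups = ["REF"] * n_ref + ["IL_1"] * n_il + ["PEN"] * n_pen
    return lines, dict(zip(lines, groups))


def _factor_correlation(config: SyntheticConfig) -> tuple[np.ndarray, dict[str, int]]:
    """Correlation matrix of the per-class latent factors (PSD-repaired)."""
    class_names = [c for _, c, _, _ in config.class_spec]
    idx = {c: i for i, c in enumerate(class_names)}
    k = len(class_names)
    F = np.eye(k)
    a = spearman_to_pearson(config.intra_class_rho)  # shared factor loading^2
    for ca, cb, rho, sign in config.inter_class_blocks:
        target = sign * spearman_to_pearson(abs(rho))
        f = target / a  # cross-trait corr = a * F[ca, cb]
        if abs(f) > 1.0:
            raise ConfigError(
                f"inter_class_blocks ({ca}, {cb}): |rho| exceeds what "
                f"intra_class_rho={config.intra_class_rho} permits"
            )
        F[idx[ca], idx[cb]] = F[idx[cb], idx[ca]] = f
    # repair to positive semi-definite if block combinations conflict
    w, v = np.linalg.eigh(F)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        F = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(F))
        F = F / np.outer(d, d)
    return F, idx


def _latent_traits(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Line-level latent z-scores per trait implementing the copula blocks."""
    lines, _ = _assign_groups(config)
    F, idx = _factor_correlation(config)
    chol = np.linalg.cholesky(F + 1e-12 * np.eye(F.shape[0]))
    factors = rng.standard_normal((config.n_lines, F.shape[0])) @ chol.T
    a = spearman_to_pearson(config.intra_class_rho)
    load = math.sqrt(a)
    resid = math.sqrt(max(0.0, 1.0 - a))
    cols: dict[str, np.ndarray] = {}
    for _, cls, _, k in config.class_spec:
        f = factors[:, idx[cls]]
        for i in range(1, k + 1):
            eps = rng.standard_normal(config.n_lines)
            cols[f"{cls}_{i}"] = load * f + resid * eps if a > 0 else eps
    return pd.DataFrame(cols, index=lines)


def _truth_pairs(config: SyntheticConfig) -> tuple[set, set]:
    trait_class = {}
    for _, cls, _, k in config.class_spec:
        for i in range(1, k + 1):
            trait_class[f"{cls}_{i}"] = cls
    a = spearman_to_pearson(config.intra_class_rho)
    cross: dict[tuple[str, str], tuple[int, float]] = {}
    for ca, cb, rho, sign in config.inter_class_blocks:
        cross[tuple(sorted((ca, cb)))] = (sign, abs(rho))
    planted: set[tuple[str, str, int, float]] = set()
    nulls: set[tuple[str, str]] = set()
    names = config.trait_names()
    for ta, tb in itertools.combinations(names, 2):
        ca, cb = trait_class[ta], trait_class[tb]
        if ca == cb:
            if config.intra_class_rho > 0:
                planted.add((ta, tb, 1, config.intra_class_rho))
            else:
                nulls.add((ta, tb))
        elif tuple(sorted((ca, cb))) in cross:
            sign, rho = cross[tuple(sorted((ca, cb)))]
            planted.add((ta, tb, sign, rho))
        else:
            nulls.add((ta, tb))
    return planted, nulls


def _replicate_records(
    trait: str,
    log_means: np.ndarray,
    lines: list[str],
    line_groups: dict[str, str],
    rep_counts: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    total = int(rep_counts.sum())
    line_idx = np.repeat(np.arange(len(lines)), rep_counts)
    rep_idx = np.concatenate([np.arange(1, c + 1) for c in rep_counts])
    values = np.exp(log_means[line_idx] + noise_sd * rng.standard_normal(total))
    line_arr = np.array(lines, dtype=object)[line_idx]
    return pd.DataFrame(
        {
            "line": line_arr,
            "group": [line_groups[l] for l in line_arr],
            "replicate": rep_idx,
            "trait": trait,
            "value": values,
        }
    )


def generate_population(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a replicate table, trait annotation and planted truth.

    Replicate counts are drawn uniformly from ``replicate_range`` per
    (line, platform) where a platform is the annotation group — mirroring a
    survey where, say, GC-MS and lipidomics runs replicate differently.
    Individual replicate records are then dropped with ``missing_rate``
    probability. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    lines, line_groups = _assign_groups(config)
    latents = _latent_traits(config, rng)

    platforms = sorted({g for g, _, _, _ in config.class_spec})
    rep_counts = {
        plat: rng.integers(config.replicate_range[0], config.replicate_range[1] + 1,
                           size=config.n_lines)
        for plat in platforms
    }
    frames = []
    ann_records = []
    for group, cls, subclass, k in config.class_spec:
        for i in range(1, k + 1):
            trait = f"{cls}_{i}"
            ann_records.append({"trait": trait, "group": group, "class": cls,
                                "subclass": subclass})
            base = rng.normal(5.0, 1.0)  # per-trait abundance offset (log scale)
            log_means = base + config.line_sd * latents[trait].to_numpy()
            frames.append(
                _replicate_records(trait, log_means, lines, line_groups,
                                   rep_counts[group], config.noise_sd, rng)
            )
    table = pd.concat(frames, ignore_index=True)
    if config.missing_rate > 0:
        keep = rng.random(len(table)) >= config.missing_rate
        if not keep.any():
            raise ConfigError("missing_rate removed every record")
        table = table.loc[keep].reset_index(drop=True)
    table = table.sort_values(["trait", "line", "replicate"], kind="mergesort").reset_index(drop=True)

    annotation = pd.DataFrame(ann_records).set_index("trait")
    planted, nulls = _truth_pairs(config)
    truth = SyntheticTruth(
        planted_edges=planted,
        null_pairs=nulls,
        line_groups=line_groups,
        trait_latents=latents,
    )
    return table, annotation, truth


def generate_expression(config: SyntheticConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Generate a transcript replicate table on the same lines.

    Planted (transcript, trait) links couple the transcript's line latent to
    the trait's latent at the requested Spearman rho (sign respected);
    ``group_fold_changes`` multiply raw abundances of the named genotype
    group's lines and are recorded in ``truth.group_effects``. Transcripts
    without a planted link are independent of every trait by construction.
    """
    config.validate()
    if truth.trait_latents is None:
        raise ConfigError(
            "truth lacks trait_latents (was it loaded from JSON?); "
            "generate_population must supply the truth"
        )
    links = {t: (trait, rho) for t, trait, rho in config.planted_links}
    for t, (trait, _) in links.items():
        if trait not in truth.trait_latents.columns:
            raise ConfigError(f"planted_links trait {trait!r} not in generated traits")
        if t not in config.transcript_names():
            raise ConfigError(f"planted_links transcript {t!r} not in transcript panel")
    folds: dict[str, list[tuple[str, float]]] = {}
    for t, grp, fold in config.group_fold_changes:
        if grp not in set(truth.line_groups.values()):
            raise ConfigError(f"group_fold_changes group {grp!r} not a genotype group")
        if fold <= 0:
            raise ConfigError("group_fold_changes fold must be > 0")
        folds.setdefault(t, []).append((grp, fold))

    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    lines = list(truth.trait_latents.index)
    n = len(lines)
    rep_counts = rng.integers(config.expr_replicate_range[0],
                              config.expr_replicate_range[1] + 1, size=n)
    frames = []
    for name in config.transcript_names():
        eps = rng.standard_normal(n)
        if name in links:
            trait, rho = links[name]
            r_lat = spearman_to_pearson(rho)
            z = r_lat * truth.trait_latents[trait].to_numpy() + math.sqrt(1 - r_lat**2) * eps
            truth.planted_gene_links.add((name, trait, 1 if rho > 0 else -1, abs(rho)))
        else:
            z = eps
        base = rng.normal(5.0, 1.0)
        log_means = base + config.transcript_line_sd * z
        frame = _replicate_records(name, log_means, lines, truth.line_groups,
                                   rep_counts, config.noise_sd, rng)
        for grp, fold in folds.get(name, []):
            frame.loc[frame["group"] == grp, "value"] *= fold
            truth.group_effects.add((name, grp, fold))
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(["trait", "line", "replicate"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# serialization


def write_replicate_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_replicate_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="trait")


def config_to_json(config: SyntheticConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=1, default=list))
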