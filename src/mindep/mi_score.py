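"""Metabolic-independence scoring and group comparisons.

The metabolic-independence (MI) score of a genome is the sum of its
pathwise completeness values over a fixed set of marker modules (the
biosynthetic modules enriched in good colonizers). A genome whose score
reaches ``threshold_fraction x |module set|`` is classified as having high
metabolic independence (HMI); otherwise low (LMI). The threshold fraction
defaults to 0.8 and is always reported alongside the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, wilcoxon

from .errors import ValidationError, ZeroVarianceError

__all__ = [
    "ModuleSet",
    "MiConfig",
    "MiScore",
    "mi_score",
    "mi_scores",
    "group_compare",
    "category_summary",
    "group_profile",
]


@dataclass(frozen=True)
class ModuleSet:
    """An ordered marker-module set with optional category annotations.

    ``categories`` maps module id to a tuple of class strings (a module may
    belong to several, e.g. both biosynthesis and amino acid metabolism).
    """

    module_ids: tuple
    categories: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "module_ids", tuple(self.module_ids))
        if len(set(self.module_ids)) != len(self.module_ids):
            raise ValidationError("duplicate module ids in module set")

    def __len__(self) -> int:
        return len(self.module_ids)


@dataclass(frozen=True)
class MiConfig:
    """HMI/LMI decision rule: threshold = threshold_fraction x |module set|."""

    threshold_fraction: float = 0.8

    def __post_init__(self):
        if not 0.0 < self.threshold_fraction <= 1.0:
            raise ValidationError("threshold_fraction must be in (0,1]")


DEFAULT_MI_CONFIG = MiConfig()


@dataclass(frozen=True)
class MiScore:
    genome_id: str
    score: float
    classification: str
    threshold_used: float


def mi_score(
    matrix: pd.DataFrame,
    genome_id: str,
    module_set: ModuleSet,
    config: MiConfig = DEFAULT_MI_CONFIG,
) -> MiScore:
    """Sum of completeness over the module set, with the HMI/LMI call."""
    missing = [m for m in module_set.module_ids if m not in matrix.columns]
    if missing:
        raise ValidationError(f"modules missing from matrix: {missing}")
    if genome_id not in matrix.index:
        raise ValidationError(f"genome {genome_id} not in matrix")
    score = float(matrix.loc[genome_id, list(module_set.module_ids)].sum())
    threshold = config.threshold_fraction * len(module_set)
    classification = "HMI" if score >= threshold else "LMI"
    return MiScore(genome_id, score, classification, threshold)


def mi_scores(
    matrix: pd.DataFrame,
    module_set: ModuleSet,
    config: MiConfig = DEFAULT_MI_CONFIG,
) -> pd.DataFrame:
    """MI scores for every genome in the matrix."""
    rows = [mi_score(matrix, g, module_set, config) for g in matrix.index]
    return pd.DataFrame(
        {
            "score": [r.score for r in rows],
            "classification": [r.classification for r in rows],
            "threshold": [r.threshold_used for r in rows],
        },
        index=pd.Index(matrix.index, name="genome"),
    )


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
    method: str = "asymptotic",
) -> Tuple[float, float]:
    """Wilcoxon comparison of two samples.

    Unpaired: Mann-Whitney rank-sum with continuity correction under the
    normal approximation (``method="exact"`` switches to the exact
    permutation null, used for small-sample cross-checks). Paired: the
    signed-rank statistic V (sum of ranks of positive differences, zeros
    dropped, R convention) with a continuity-corrected normal p-value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("each sample needs at least 3 values")
    if paired:
        if a.size != b.size:
            raise ValidationError("paired comparison needs equal lengths")
        d = a - b
        d = d[d != 0]
        if d.size == 0:
            raise ZeroVarianceError("all paired differences are zero")
        ranks = rankdata(np.abs(d))
        v_stat = float(ranks[d > 0].sum())
        res = wilcoxon(
            a, b, zero_method="wilcox", correction=True,
            alternative="two-sided",
            method="approx" if method == "asymptotic" else "exact",
        )
        return v_stat, float(res.pvalue)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise ZeroVarianceError("all values are tied; rank test undefined")
    res = mannwhitneyu(
        a, b, use_continuity=True, alternative="two-sided",
        method="asymptotic" if method == "asymptotic" else "exact",
    )
    return float(res.statistic), float(res.pvalue)


def category_summary(module_set: ModuleSet) -> pd.DataFrame:
    """Counts and percentages per category over the module set.

    A module can carry several categories, so percentages are computed
    against the module-set size and may sum to more than 100%.
    """
    counts: dict = {}
    for module_id in module_set.module_ids:
        for cat in module_set.categories.get(module_id, ()):
            counts[cat] = counts.get(cat, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["category", "count", "percent"])
    n = len(module_set)
    rows = [
        (cat, count, 100.0 * count / n)
        for cat, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def group_profile(
    matrix: pd.DataFrame,
    module_set: ModuleSet,
    genome_groups: Mapping[str, str],
    genome_individuals: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Completeness distributions over the module set, per group (and
    optionally per individual).

    Each genome contributes one completeness value per marker module; rows
    report the mean and median of those values per group/individual.
    """
    missing = [m for m in module_set.module_ids if m not in matrix.columns]
    if missing:
        raise ValidationError(f"modules missing from matrix: {missing}")
    unassigned = [g for g in matrix.index if g not in genome_groups]
    if unassigned:
        raise ValidationError(f"genomes without a group: {unassigned}")
    sub = matrix[list(module_set.module_ids)]

    def _summaries(mapping: Mapping[str, str], level: str):
        frame = pd.Series({g: mapping[g] for g in sub.index})
        out = []
        for name, members in sorted(frame.groupby(frame).groups.items()):
            vals = sub.loc[list(members)].to_numpy(dtype=float).ravel()
            out.append(
                (level, name, float(np.mean(vals)), float(np.median(vals)),
                 len(members), vals.size)
            )
        return out

    rows = _summaries(genome_groups, "group")
    if genome_individuals is not None:
        rows += _summaries(genome_individuals, "individual")
    return pd.DataFrame(
        rows,
        columns=[
            "level", "name", "mean_completeness", "median_completeness",
            "n_genomes", "n_values",
        ],
    )
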