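"""Per-module enrichment between genome groups.

A module "occurs" in a genome when its pathwise completeness reaches the
presence threshold (0.75 by default). For each module, per-group occurrence
counts are compared with a Rao score statistic: with pooled occurrence
p-hat = sum(n_present) / sum(n_total),

    score = sum_g n_g * (p_g - p_hat)^2 / (p_hat * (1 - p_hat))

which is the score (Lagrange-multiplier) test of the intercept-only binomial
GLM against the group-saturated one, and coincides with the Pearson
chi-square statistic of the occurrence contingency table. p-values come from
the upper tail of chi-square with (G - 1) degrees of freedom; q-values are
Benjamini-Hochberg. A module is "enriched" in its associated group (the
group with the highest occurrence proportion) when q < q_max, its mean
completeness in that group reaches ``min_completeness``, and its occurrence
proportion there reaches ``min_group_presence``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ValidationError

__all__ = [
    "EnrichmentCriteria",
    "module_occurrence",
    "rao_score_test",
    "bh_fdr",
    "enrichment_table",
    "enriched_modules",
]


@dataclass(frozen=True)
class EnrichmentCriteria:
    """Thresholds defining occurrence and the enrichment call.

    q_max: q-value must be strictly below this (default 0.05).
    min_completeness: minimum mean completeness in the associated group.
    min_group_presence: minimum occurrence proportion in the associated group.
    presence_threshold: completeness at or above this counts as occurrence.
    """

    q_max: float = 0.05
    min_completeness: float = 0.75
    min_group_presence: float = 0.50
    presence_threshold: float = 0.75

    def __post_init__(self):
        for name in ("q_max", "min_completeness", "min_group_presence",
                     "presence_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1]")


DEFAULT_CRITERIA = EnrichmentCriteria()


def module_occurrence(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    criteria: EnrichmentCriteria = DEFAULT_CRITERIA,
) -> pd.DataFrame:
    """Occurrence counts per (module, group).

    ``matrix`` is the genome x module completeness grid; ``groups`` maps
    every genome id to its group. Returns a long frame with columns
    module_id, group, n_present, n_total.
    """
    missing = [g for g in matrix.index if g not in groups]
    if missing:
        raise ValidationError(f"genomes without a group: {missing}")
    labels = pd.Series({g: groups[g] for g in matrix.index}, name="group")
    present = (matrix >= criteria.presence_threshold)
    records = []
    for group, members in sorted(labels.groupby(labels).groups.items()):
        block = present.loc[list(members)]
        n_total = len(members)
        for module_id in matrix.columns:
            records.append(
                (module_id, group, int(block[module_id].sum()), n_total)
            )
    return pd.DataFrame(
        records, columns=["module_id", "group", "n_present", "n_total"]
    )


def rao_score_test(
    n_present: Sequence[int], n_total: Sequence[int]
) -> tuple:
    """Rao score statistic and p-value for per-group occurrence counts.

    Returns ``(score, p)``. When the pooled occurrence is 0 or 1 the
    binomial variance vanishes and the test is degenerate; by convention the
    result is ``(0.0, 1.0)``.
    """
    present = np.asarray(n_present, dtype=float)
    total = np.asarray(n_total, dtype=float)
    if present.shape != total.shape or present.size < 2:
        raise ValidationError("need matching counts for at least 2 groups")
    if (total < 1).any():
        raise ValidationError("every group needs n_total >= 1")
    if ((present < 0) | (present > total)).any():
        raise ValidationError("need 0 <= n_present <= n_total")
    p_hat = present.sum() / total.sum()
    if p_hat <= 0.0 or p_hat >= 1.0:
        return 0.0, 1.0
    p_g = present / total
    score = float((total * (p_g - p_hat) ** 2).sum() / (p_hat * (1.0 - p_hat)))
    p_value = float(chi2.sf(score, df=present.size - 1))
    return score, p_value


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must be in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    criteria: EnrichmentCriteria = DEFAULT_CRITERIA,
) -> pd.DataFrame:
    """Full per-module enrichment statistics.

    Returns a frame indexed by module_id with columns: enrichment_score,
    p_value, q_value, associated_groups (comma-joined argmax-proportion
    groups), and per-group ``proportion_<g>`` / ``mean_completeness_<g>``.
    """
    occurrence = module_occurrence(matrix, groups, criteria)
    group_names = sorted(occurrence["group"].unique())
    wide_present = occurrence.pivot(index="module_id", columns="group",
                                    values="n_present")
    wide_total = occurrence.pivot(index="module_id", columns="group",
                                  values="n_total")
    wide_present = wide_present.loc[matrix.columns, group_names]
    wide_total = wide_total.loc[matrix.columns, group_names]

    labels = pd.Series({g: groups[g] for g in matrix.index})
    mean_comp = matrix.groupby(labels).mean().T  # modules x groups

    scores, pvals = [], []
    for module_id in matrix.columns:
        score, p = rao_score_test(
            wide_present.loc[module_id].to_numpy(),
            wide_total.loc[module_id].to_numpy(),
        )
        scores.append(score)
        pvals.append(p)
    qvals = bh_fdr(pvals) if pvals else np.array([])

    proportions = wide_present / wide_total
    associated = []
    for module_id in matrix.columns:
        row = proportions.loc[module_id]
        best = row.max()
        associated.append(",".join(sorted(row.index[row == best])))

    out = pd.DataFrame(
        {
            "enrichment_score": scores,
            "p_value": pvals,
            "q_value": qvals,
            "associated_groups": associated,
        },
        index=pd.Index(matrix.columns, name="module_id"),
    )
    for g in group_names:
        out[f"proportion_{g}"] = proportions[g]
        out[f"mean_completeness_{g}"] = mean_comp[g]
    return out


def enriched_modules(
    table: pd.DataFrame,
    criteria: EnrichmentCriteria = DEFAULT_CRITERIA,
) -> Dict[str, List[str]]:
    """Modules passing the enrichment criteria, per associated group.

    A module counts as enriched in a group iff that group is (one of) its
    associated groups, q_value < q_max (strict), the group's mean
    completeness >= min_completeness, and its occurrence proportion
    >= min_group_presence.
    """
    result: Dict[str, List[str]] = {}
    for module_id, row in table.iterrows():
        if not row["q_value"] < criteria.q_max:
            continue
        for group in str(row["associated_groups"]).split(","):
            if row[f"mean_completeness_{group}"] < criteria.min_completeness:
                continue
            if row[f"proportion_{group}"] < criteria.min_group_presence:
                continue
            result.setdefault(group, []).append(module_id)
    return result
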