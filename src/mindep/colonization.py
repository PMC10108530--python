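"""Colonization phenotyping of donor populations in FMT recipients.

For each (genome, recipient) pair where the genome was detected in the donor
stool sample used for the transplant, a phenotype is assigned:

* ``not_applicable`` — the genome was not detected in the transplant sample,
  so colonization cannot be assessed for this pair;
* ``not_colonized`` — donor-detected, but never detected in the recipient in
  any sample taken more than ``post_fmt_min_days`` (default 7) days post-FMT;
* ``colonized`` — detected post-window, and at least one strain-level
  subpopulation present in the transplant sample and absent from every
  pre-FMT recipient sample was detected in the recipient post-window;
* ``undetermined`` — detected post-window but no discriminating
  subpopulation exists (e.g., the genome and all of its donor subpopulations
  were already present pre-FMT, or subpopulation evidence is unavailable at
  the required coverage).

Genome-level good/poor colonizer classification uses raw detection only:
*good* colonizers are donor-detected and post-window detected in **all**
recipients; *poor* colonizers are donor-detected but post-window absent in at
least ``poor_min_recipients`` recipients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .detection import DEFAULT_THRESHOLDS, DetectionThresholds
from .errors import SeparationError, ValidationError

__all__ = [
    "ColonizationRules",
    "ColonizationCall",
    "OUTCOMES",
    "filter_subpopulations",
    "assign_phenotype",
    "assign_phenotypes",
    "build_recipient_summary",
    "classify_good_poor",
    "classify_all",
    "select_representatives",
    "colonization_regression",
]

OUTCOMES = ("colonized", "not_colonized", "undetermined", "not_applicable")

META_COLUMNS = (
    "sample_id",
    "subject_id",
    "role",
    "day_relative_to_fmt",
    "donor_subject",
    "transplant_sample",
    "delivery",
)


@dataclass(frozen=True)
class ColonizationRules:
    """Decision thresholds for colonization phenotyping.

    post_fmt_min_days: a recipient sample counts as post-window only if its
        day relative to FMT is strictly greater than this (default 7).
    subpop_min_proportion: subpopulations explaining less than this fraction
        of a genome's population in a sample are discarded (the rule is
        "less than", so exactly 1% is retained).
    scg_coverage_min: subpopulation evidence is used only where single-copy
        core-gene coverage is at least this (10X default).
    good_requires_all_recipients: number of recipients in which donor- and
        post-window detection must hold for a good-colonizer call.
    poor_min_recipients: minimum number of recipients with donor detection
        but no post-window detection for a poor-colonizer call.
    """

    post_fmt_min_days: int = 7
    subpop_min_proportion: float = 0.01
    scg_coverage_min: float = 10.0
    good_requires_all_recipients: int = 5
    poor_min_recipients: int = 3

    def __post_init__(self):
        if self.post_fmt_min_days < 0:
            raise ValidationError("post_fmt_min_days must be >= 0")
        if not 0 <= self.subpop_min_proportion <= 1:
            raise ValidationError("subpop_min_proportion must be in [0,1]")
        if self.scg_coverage_min < 0:
            raise ValidationError("scg_coverage_min must be >= 0")
        if self.good_requires_all_recipients < 1 or self.poor_min_recipients < 1:
            raise ValidationError("recipient counts must be positive")


DEFAULT_RULES = ColonizationRules()


@dataclass(frozen=True)
class ColonizationCall:
    genome_id: str
    recipient_id: str
    outcome: str
    evidence: str

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")


# ---------------------------------------------------------------------------
# subpopulation filtering
# ---------------------------------------------------------------------------


def filter_subpopulations(
    profiles: pd.DataFrame,
    rules: ColonizationRules = DEFAULT_RULES,
    coverage_ok: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Apply the proportion and coverage filters to subpopulation profiles.

    ``profiles`` has columns genome_id, subpop_id, sample_id, proportion.
    Rows with proportion < ``subpop_min_proportion`` are removed. When
    ``coverage_ok`` (a boolean genome x sample frame) is given, every row of
    a (genome, sample) cell whose flag is False — or absent from the frame —
    is removed, since subpopulation evidence is unreliable there.
    """
    required = {"genome_id", "subpop_id", "sample_id", "proportion"}
    missing = required - set(profiles.columns)
    if missing:
        raise ValidationError(f"subpopulation table missing columns: {sorted(missing)}")
    prop = profiles["proportion"].to_numpy(dtype=float)
    if ((prop < 0) | (prop > 1)).any():
        raise ValidationError("subpopulation proportions must be in [0,1]")
    sums = profiles.groupby(["genome_id", "sample_id"])["proportion"].sum()
    if (sums > 1 + 1e-6).any():
        bad = sums[sums > 1 + 1e-6].index[0]
        raise ValidationError(f"proportions for {bad} sum to more than 1")

    keep = prop >= rules.subpop_min_proportion
    out = profiles.loc[keep]
    if coverage_ok is not None:
        def _ok(row):
            g, s = row.genome_id, row.sample_id
            if g in coverage_ok.index and s in coverage_ok.columns:
                return bool(coverage_ok.at[g, s])
            return False

        mask = [_ok(row) for row in out.itertuples()]
        out = out.loc[mask]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-pair phenotype
# ---------------------------------------------------------------------------


def _recipient_context(meta: pd.DataFrame, recipient_id: str, rules: ColonizationRules):
    rows = meta[(meta["subject_id"] == recipient_id) & (meta["role"] == "recipient")]
    if rows.empty:
        raise ValidationError(f"recipient {recipient_id} has no samples in metadata")
    transplant = rows["transplant_sample"].dropna().unique()
    if len(transplant) != 1:
        raise ValidationError(
            f"recipient {recipient_id} must have exactly one transplant sample"
        )
    days = rows["day_relative_to_fmt"].astype(float)
    pre = rows.loc[days < 0, "sample_id"].tolist()
    post = rows.loc[days > rules.post_fmt_min_days, "sample_id"].tolist()
    if not pre:
        raise ValidationError(f"recipient {recipient_id} lacks a pre-FMT sample")
    if not post:
        raise ValidationError(
            f"recipient {recipient_id} lacks a sample beyond day {rules.post_fmt_min_days}"
        )
    return transplant[0], pre, post


def _det(detection: pd.DataFrame, genome_id: str, sample_id: str) -> float:
    if genome_id not in detection.index:
        raise ValidationError(f"genome {genome_id} not in detection table")
    if sample_id not in detection.columns:
        raise ValidationError(f"sample {sample_id} not in detection table")
    return float(detection.at[genome_id, sample_id])


def assign_phenotype(
    genome_id: str,
    recipient_id: str,
    detection: pd.DataFrame,
    subpops: pd.DataFrame,
    meta: pd.DataFrame,
    rules: ColonizationRules = DEFAULT_RULES,
    thresholds: DetectionThresholds = DEFAULT_THRESHOLDS,
) -> ColonizationCall:
    """Assign a colonization phenotype to one (genome, recipient) pair.

    ``subpops`` must already be filtered (see :func:`filter_subpopulations`);
    a subpopulation is considered present in a sample iff a filtered row
    exists for it.
    """
    transplant, pre, post = _recipient_context(meta, recipient_id, rules)

    if _det(detection, genome_id, transplant) < thresholds.detection_min:
        return ColonizationCall(
            genome_id, recipient_id, "not_applicable",
            "not_detected_in_transplant_sample",
        )

    post_hits = [
        s for s in post
        if _det(detection, genome_id, s) >= thresholds.detection_min
    ]
    if not post_hits:
        return ColonizationCall(
            genome_id, recipient_id, "not_colonized",
            f"no_detection_after_day_{rules.post_fmt_min_days}",
        )

    rows = subpops[subpops["genome_id"] == genome_id]
    sp_donor = set(rows.loc[rows["sample_id"] == transplant, "subpop_id"])
    if not sp_donor:
        return ColonizationCall(
            genome_id, recipient_id, "undetermined",
            "no_donor_subpopulation_evidence",
        )
    sp_pre = set(rows.loc[rows["sample_id"].isin(pre), "subpop_id"])
    sp_post = set(rows.loc[rows["sample_id"].isin(post), "subpop_id"])
    discriminating = (sp_donor & sp_post) - sp_pre
    if discriminating:
        return ColonizationCall(
            genome_id, recipient_id, "colonized",
            "discriminating_subpopulation:" + min(discriminating),
        )
    return ColonizationCall(
        genome_id, recipient_id, "undetermined", "no_discriminating_subpopulation"
    )


def assign_phenotypes(
    detection: pd.DataFrame,
    subpops: pd.DataFrame,
    meta: pd.DataFrame,
    rules: ColonizationRules = DEFAULT_RULES,
    thresholds: DetectionThresholds = DEFAULT_THRESHOLDS,
    genomes: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Phenotype every (genome, recipient) pair; returns a tidy frame."""
    recipients = sorted(
        meta.loc[meta["role"] == "recipient", "subject_id"].unique()
    )
    genome_ids = sorted(genomes) if genomes is not None else list(detection.index)
    records = []
    for g in genome_ids:
        for r in recipients:
            call = assign_phenotype(g, r, detection, subpops, meta, rules, thresholds)
            records.append(
                (call.genome_id, call.recipient_id, call.outcome, call.evidence)
            )
    return pd.DataFrame(
        records, columns=["genome_id", "recipient_id", "outcome", "evidence"]
    )


# ---------------------------------------------------------------------------
# good / poor colonizers
# ---------------------------------------------------------------------------


def build_recipient_summary(
    detection: pd.DataFrame,
    meta: pd.DataFrame,
    rules: ColonizationRules = DEFAULT_RULES,
    thresholds: DetectionThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per (genome, recipient) raw-detection summary used for classification.

    Columns: genome_id, recipient_id, donor_detected (in the transplant
    sample), post_window_detected (in any sample > post_fmt_min_days).
    """
    recipients = sorted(meta.loc[meta["role"] == "recipient", "subject_id"].unique())
    records = []
    for r in recipients:
        transplant, _, post = _recipient_context(meta, r, rules)
        for g in detection.index:
            donor_det = _det(detection, g, transplant) >= thresholds.detection_min
            post_det = any(
                _det(detection, g, s) >= thresholds.detection_min for s in post
            )
            records.append((g, r, donor_det, post_det))
    return pd.DataFrame(
        records,
        columns=["genome_id", "recipient_id", "donor_detected", "post_window_detected"],
    )


def classify_good_poor(
    genome_summary: pd.DataFrame, rules: ColonizationRules = DEFAULT_RULES
) -> str:
    """Classify one genome as ``good``, ``poor`` or ``neither``.

    ``genome_summary`` holds one row per recipient with boolean columns
    ``donor_detected`` and ``post_window_detected``. Good and poor are
    mutually exclusive by construction.
    """
    n = len(genome_summary)
    if n < rules.good_requires_all_recipients:
        raise ValidationError(
            f"need at least {rules.good_requires_all_recipients} recipients, got {n}"
        )
    donor = genome_summary["donor_detected"].to_numpy(dtype=bool)
    post = genome_summary["post_window_detected"].to_numpy(dtype=bool)
    if (donor & post).all():
        return "good"
    if int((donor & ~post).sum()) >= rules.poor_min_recipients:
        return "poor"
    return "neither"


def classify_all(
    summary: pd.DataFrame, rules: ColonizationRules = DEFAULT_RULES
) -> pd.Series:
    """Apply :func:`classify_good_poor` per genome; returns a label Series."""
    labels = {
        g: classify_good_poor(sub, rules)
        for g, sub in summary.groupby("genome_id", sort=True)
    }
    return pd.Series(labels, name="colonizer_class")


def select_representatives(
    good_set: Iterable[str],
    prevalence_in_reference_group: Mapping[str, float],
    n_target: int,
) -> list:
    """Most-prevalent ``n_target`` genomes from the good set.

    Ties at the cutoff are broken by lexicographic genome id.
    """
    good = sorted(set(good_set))
    if n_target > len(good):
        raise ValidationError(
            f"n_target {n_target} exceeds good-set size {len(good)}"
        )
    missing = [g for g in good if g not in prevalence_in_reference_group]
    if missing:
        raise ValidationError(f"no prevalence for genomes: {missing}")
    ranked = sorted(good, key=lambda g: (-prevalence_in_reference_group[g], g))
    return ranked[:n_target]


# ---------------------------------------------------------------------------
# dose / prevalence regression
# ---------------------------------------------------------------------------


def colonization_regression(
    pairs: pd.DataFrame,
    predictors: Sequence[str] = ("prevalence", "donor_dose"),
    outcome_col: str = "outcome",
) -> pd.DataFrame:
    """Joint logistic model of binary colonization outcome on standardized
    predictors; per-predictor Wald tests.

    Returns a frame indexed by predictor with columns slope, se, z, p.
    Raises :class:`SeparationError` when the likelihood has no finite
    maximizer (perfect or quasi-perfect separation).
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    y = pairs[outcome_col].astype(float).to_numpy()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("outcomes must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValidationError("both outcome classes must be present")
    X = pairs[list(predictors)].astype(float)
    if not np.isfinite(X.to_numpy()).all():
        raise ValidationError("predictors must be finite")
    std = X.std(ddof=0)
    if (std == 0).any():
        raise ValidationError(
            f"constant predictor(s): {list(std.index[std == 0])}"
        )
    Xz = (X - X.mean()) / std
    design = sm.add_constant(Xz)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            result = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(str(exc)) from exc
    if not result.mle_retvals.get("converged", False) or (
        np.abs(result.params.to_numpy()) > 30
    ).any():
        raise SeparationError("logistic fit did not converge to finite estimates")
    out = pd.DataFrame(
        {
            "slope": result.params,
            "se": result.bse,
            "z": result.params / result.bse,
            "p": result.pvalues,
        }
    )
    return out.loc[list(predictors)]
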