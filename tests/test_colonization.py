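"""Colonization phenotyping, good/poor classification, dose/prevalence model."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mindep.colonization import (
    ColonizationRules,
    assign_phenotype,
    build_recipient_summary,
    classify_all,
    classify_good_poor,
    colonization_regression,
    filter_subpopulations,
    select_representatives,
)
from mindep.detection import DetectionThresholds
from mindep.errors import SeparationError, ValidationError

RULES = ColonizationRules()
THRESH = DetectionThresholds()


# ---------------------------------------------------------------------------
# subpopulation filters
# ---------------------------------------------------------------------------


def _profiles(rows):
    return pd.DataFrame(
        rows, columns=["genome_id", "subpop_id", "sample_id", "proportion"]
    )


class TestFilterSubpopulations:
    def test_sub_one_percent_dropped(self):
        prof = _profiles([("g", "a", "s", 0.995), ("g", "b", "s", 0.005)])
        out = filter_subpopulations(prof, RULES)
        assert list(out["subpop_id"]) == ["a"]

    def test_exactly_one_percent_retained(self):
        prof = _profiles([("g", "a", "s", 0.99), ("g", "b", "s", 0.01)])
        out = filter_subpopulations(prof, RULES)
        assert set(out["subpop_id"]) == {"a", "b"}

    def test_low_coverage_cell_dropped_entirely(self):
        prof = _profiles([("g", "a", "s1", 0.6), ("g", "b", "s1", 0.4),
                          ("g", "a", "s2", 1.0)])
        cov_ok = pd.DataFrame({"s1": [False], "s2": [True]}, index=["g"])
        out = filter_subpopulations(prof, RULES, cov_ok)
        assert list(out["sample_id"]) == ["s2"]

    def test_proportions_must_sum_to_at_most_one(self):
        prof = _profiles([("g", "a", "s", 0.8), ("g", "b", "s", 0.4)])
        with pytest.raises(ValidationError):
            filter_subpopulations(prof, RULES)


# ---------------------------------------------------------------------------
# per-pair phenotype: exhaustive decision table
# ---------------------------------------------------------------------------

META = pd.DataFrame(
    [
        ("T", "D01", "donor", 0, None, None, None),
        ("P", "R01", "recipient", -1, "D01", "T", "pill"),
        ("D8", "R01", "recipient", 8, "D01", "T", "pill"),
        ("D30", "R01", "recipient", 30, "D01", "T", "pill"),
    ],
    columns=[
        "sample_id", "subject_id", "role", "day_relative_to_fmt",
        "donor_subject", "transplant_sample", "delivery",
    ],
)


def _scenario(donor_det, pre_det, post_det, donor_evidence, discriminating):
    """Build detection + filtered subpops for one decision-table branch."""
    hi, lo = 0.9, 0.02
    detection = pd.DataFrame(
        {
            "T": [hi if donor_det else lo],
            "P": [hi if pre_det else lo],
            "D8": [hi if post_det else lo],
            "D30": [lo],
        },
        index=["g"],
    )
    rows = []
    if donor_evidence:
        # sp1 always in the donor; discriminating iff absent pre-FMT
        rows.append(("g", "sp1", "T", 1.0))
        if post_det:
            rows.append(("g", "sp1", "D8", 1.0))
        if pre_det:
            rows.append(("g", "sp1", "P", 1.0))
            if discriminating:
                # a second donor strain that only shows up post-FMT
                rows[0] = ("g", "sp1", "T", 0.6)
                rows.append(("g", "sp2", "T", 0.4))
                rows.append(("g", "sp2", "D8", 0.4))
    subpops = _profiles(rows)
    return detection, subpops


# every combination of the four detection/evidence axes maps to one outcome
TRUTH_TABLE = []
for donor_det in (False, True):
    for pre_det in (False, True):
        for post_det in (False, True):
            for evidence in (False, True):
                for disc in (False, True):
                    if not donor_det:
                        expected = "not_applicable"
                    elif not post_det:
                        expected = "not_colonized"
                    elif not evidence:
                        expected = "undetermined"
                    elif not pre_det:
                        expected = "colonized"  # vacuously absent pre-FMT
                    elif disc:
                        expected = "colonized"
                    else:
                        expected = "undetermined"
                    TRUTH_TABLE.append(
                        (donor_det, pre_det, post_det, evidence, disc, expected)
                    )


@pytest.mark.parametrize(
    "donor_det,pre_det,post_det,evidence,disc,expected", TRUTH_TABLE
)
def test_phenotype_decision_table(donor_det, pre_det, post_det, evidence, disc,
                                  expected):
    detection, subpops = _scenario(donor_det, pre_det, post_det, evidence, disc)
    call = assign_phenotype("g", "R01", detection, subpops, META, RULES, THRESH)
    assert call.outcome == expected, call.evidence


def test_missing_pre_or_post_sample_names_recipient():
    meta = META[META["sample_id"] != "P"]
    detection, subpops = _scenario(True, False, True, True, False)
    with pytest.raises(ValidationError, match="R01"):
        assign_phenotype("g", "R01", detection, subpops, meta, RULES, THRESH)


def test_day_seven_sample_is_not_post_window():
    meta = META.copy()
    meta.loc[meta["sample_id"] == "D8", "day_relative_to_fmt"] = 7
    detection, subpops = _scenario(True, False, True, True, False)
    call = assign_phenotype("g", "R01", detection, subpops, meta, RULES, THRESH)
    assert call.outcome == "not_colonized"


# ---------------------------------------------------------------------------
# good / poor classification
# ---------------------------------------------------------------------------


def _summary(donor, post):
    return pd.DataFrame(
        {
            "genome_id": "g",
            "recipient_id": [f"R{i}" for i in range(len(donor))],
            "donor_detected": donor,
            "post_window_detected": post,
        }
    )


class TestClassifyGoodPoor:
    def test_good_requires_all_recipients(self):
        assert classify_good_poor(_summary([True] * 5, [True] * 5)) == "good"

    def test_poor_needs_three_failures(self):
        s = _summary([True] * 5, [False, False, False, True, True])
        assert classify_good_poor(s) == "poor"

    def test_neither_between_the_two(self):
        s = _summary([True] * 5, [False, False, True, True, True])
        assert classify_good_poor(s) == "neither"

    def test_undetected_in_donor_blocks_good(self):
        s = _summary([True, True, True, True, False], [True] * 5)
        assert classify_good_poor(s) == "neither"

    def test_too_few_recipients_rejected(self):
        with pytest.raises(ValidationError):
            classify_good_poor(_summary([True] * 3, [True] * 3))

    def test_never_both_good_and_poor(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            s = _summary(rng.random(5) < 0.7, rng.random(5) < 0.5)
            assert classify_good_poor(s) in ("good", "poor", "neither")


class TestSelectRepresentatives:
    def test_most_prevalent_selected(self):
        assert select_representatives(
            {"a", "b", "c"}, {"a": 0.9, "b": 0.5, "c": 0.7}, 2
        ) == ["a", "c"]

    def test_tie_broken_lexicographically(self):
        assert select_representatives(
            {"a", "b", "c"}, {"a": 0.9, "b": 0.5, "c": 0.5}, 2
        ) == ["a", "b"]

    def test_identity_when_n_equals_size(self):
        assert set(
            select_representatives({"a", "b"}, {"a": 0.1, "b": 0.2}, 2)
        ) == {"a", "b"}

    def test_oversized_target_rejected(self):
        with pytest.raises(ValidationError):
            select_representatives({"a"}, {"a": 1.0}, 2)


# ---------------------------------------------------------------------------
# planted-label recovery on the synthetic cohort
# ---------------------------------------------------------------------------


def test_cohort_labels_recovered_without_noise(small_dataset, small_cfg):
    cohort = small_dataset["cohort"]
    summary = build_recipient_summary(cohort.detection, cohort.meta, RULES, THRESH)
    labels = classify_all(summary, RULES)
    expected = {
        g: info["expected_class"] for g, info in cohort.truth["genomes"].items()
    }
    assert all(labels[g] == expected[g] for g in labels.index)


# ---------------------------------------------------------------------------
# dose / prevalence logistic regression
# ---------------------------------------------------------------------------


def _planted_pairs(rng, n=200, beta_prev=1.5, beta_dose=0.2):
    prev = rng.uniform(0, 1, n)
    dose = rng.lognormal(2.0, 1.0, n)
    z_prev = (prev - prev.mean()) / prev.std()
    z_dose = (dose - dose.mean()) / dose.std()
    p = expit(-0.2 + beta_prev * z_prev + beta_dose * z_dose)
    return pd.DataFrame(
        {
            "outcome": (rng.random(n) < p).astype(int),
            "prevalence": prev,
            "donor_dose": dose,
        }
    )


class TestColonizationRegression:
    def test_planted_effect_recovered_within_two_se(self):
        rng = np.random.default_rng(3)
        pairs = _planted_pairs(rng)
        fit = colonization_regression(pairs)
        row = fit.loc["prevalence"]
        assert row["slope"] > 0
        assert abs(row["slope"] - 1.5) <= 2 * row["se"]
        assert row["p"] < 1e-3

    def test_null_labels_rarely_significant(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(30):
            pairs = _planted_pairs(rng, beta_prev=0.0, beta_dose=0.0)
            fit = colonization_regression(pairs)
            hits += fit.loc["prevalence", "p"] < 0.05
        assert hits <= 5

    def test_perfect_separation_flagged(self):
        prev = np.linspace(0, 1, 40)
        pairs = pd.DataFrame(
            {
                "outcome": (prev > 0.5).astype(int),
                "prevalence": prev,
                "donor_dose": np.linspace(1, 2, 40),
            }
        )
        with pytest.raises(SeparationError):
            colonization_regression(pairs)

    def test_single_class_rejected(self):
        pairs = pd.DataFrame(
            {"outcome": [1, 1, 1], "prevalence": [0.1, 0.2, 0.3],
             "donor_dose": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValidationError):
            colonization_regression(pairs)
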