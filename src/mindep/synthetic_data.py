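"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline end to end without any downloads:

* :func:`gen_module_definitions` — random module definitions exercising every
  grammar feature (alternatives, complexes, non-essential components, gaps,
  one level of nesting), each over its own pool of KOs;
* :func:`gen_genome_annotations` — genome x KO tables where a planted subset
  of modules is differentially complete between genome groups (a genome
  carries the full KO set of one random route with a group-specific
  probability, otherwise a sparse strict subset);
* :func:`gen_fmt_cohort` — an FMT sampling timeline (donor, recipients with
  pre- and post-transplant samples, healthy reference samples) with planted
  good/poor colonizer genomes, bimodal detection values, strain-level
  subpopulation profiles and coverage summaries arranged so that every
  branch of the colonization decision tree is exercised, plus a truth table.

All randomness flows through ``numpy.random.default_rng`` seeded from
``SimConfig.seed`` via fixed per-generator substreams, so a given seed
reproduces outputs byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from . import moddef
from .errors import ValidationError

__all__ = ["SimConfig", "Cohort", "gen_module_definitions",
           "gen_genome_annotations", "gen_fmt_cohort", "simulate"]


CATEGORY_POOL = (
    "Amino acid metabolism",
    "Cofactor and vitamin metabolism",
    "Carbohydrate metabolism",
    "Nucleotide metabolism",
    "Lipid metabolism",
    "Energy metabolism",
)

# colonization branch cases beyond planted good/poor colonizers
OTHER_CASES = (
    "not_applicable",        # absent from the transplant sample
    "undetermined_prefmt",   # already present pre-FMT with the donor strain
    "undetermined_lowcov",   # subpop evidence below the coverage floor
    "undetermined_lowprop",  # only a sub-1% subpopulation discriminates
    "sporadic",              # colonizes some recipients, fails in 1-2
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults mirror the analysis this package implements: 443 modules of
    which 33 are planted as differentially complete, 20 genomes per
    colonizer group with occurrence probabilities 0.95 (good) vs 0.10
    (poor), five FMT recipients sampled pre-FMT (day -1) and on days 7, 30,
    90 and 180 post-FMT, and bimodal detection with presence near 0.9 and
    absence near 0.02 (absence is sampled near but not exactly zero so the
    0.25 detection threshold is genuinely exercised).
    """

    seed: int = 0
    n_modules: int = 443
    n_planted: int = 33
    n_genomes_per_group: int = 20
    occurrence_probs: tuple = (0.95, 0.10)   # (p_good, p_poor)
    background_prob: float = 0.30
    kos_per_module: tuple = (3, 8)
    detection_mixture: tuple = (0.5, 0.9, 0.02)  # (p_present, present_mean, absent_mean)
    detection_present_sd: float = 0.05
    detection_absent_sd: float = 0.02
    n_recipients: int = 5
    pre_fmt_day: int = -1
    post_fmt_days: tuple = (7, 30, 90, 180)
    colonizer_fractions: tuple = (0.4, 0.4, 0.2)  # good, poor, other cases
    n_cohort_genomes: int = 50
    n_reference_samples: int = 20
    subpop_dirichlet_alpha: float = 5.0

    def __post_init__(self):
        probs = (
            *self.occurrence_probs, self.background_prob,
            self.detection_mixture[0], *self.colonizer_fractions,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("probabilities must be in [0,1]")
        counts = (
            self.n_modules, self.n_planted, self.n_genomes_per_group,
            self.n_recipients, self.n_cohort_genomes, self.n_reference_samples,
        )
        if any(c < 1 for c in counts):
            raise ValidationError("counts must be positive")
        if self.n_planted > self.n_modules:
            raise ValidationError("n_planted cannot exceed n_modules")
        lo, hi = self.kos_per_module
        if lo < 1 or hi < lo:
            raise ValidationError("bad kos_per_module range")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


# ---------------------------------------------------------------------------
# module definitions
# ---------------------------------------------------------------------------


def _build_definition(rng: np.random.Generator, kos: list) -> str:
    """Assemble a definition string that consumes the given KO pool."""
    kos = list(kos)
    parts = []
    used_gap = False
    while kos:
        roll = rng.random()
        if roll < 0.10 and not used_gap and parts:
            parts.append("--")
            used_gap = True
            continue
        if roll < 0.30 and len(kos) >= 2:
            # enzyme complex of 2-3 subunits, sometimes one non-essential
            size = int(min(len(kos), rng.integers(2, 4)))
            members = [kos.pop(0) for _ in range(size)]
            joiners = ["+"] * (size - 1)
            if size >= 2 and rng.random() < 0.3:
                joiners[-1] = "-"
            text = members[0]
            for join, ko in zip(joiners, members[1:]):
                text += join + ko
            parts.append(text)
        elif roll < 0.55 and len(kos) >= 2:
            # 2-4 alternative branches; sometimes one branch is a sequence
            n_branches = int(min(len(kos), rng.integers(2, 5)))
            branches = [kos.pop(0) for _ in range(n_branches)]
            if kos and rng.random() < 0.3:
                branches[-1] = f"({branches[-1]} {kos.pop(0)})"
            parts.append("(" + ",".join(branches) + ")")
        else:
            parts.append(kos.pop(0))
    if not parts:
        raise ValidationError("definition construction consumed no KOs")
    return " ".join(parts)


def gen_module_definitions(cfg: SimConfig) -> pd.DataFrame:
    """Random module definitions; columns module_id, definition, category.

    Every 50th module appends a nested reference to the preceding module
    (one level of nesting). Category strings follow the semicolon-joined
    flat-file convention.
    """
    rng = _rng(cfg, 1)
    ko_counter = 1
    records = []
    for i in range(cfg.n_modules):
        module_id = f"M{i + 1:05d}"
        lo, hi = cfg.kos_per_module
        n_kos = int(rng.integers(lo, hi + 1))
        kos = [f"K{ko_counter + j:05d}" for j in range(n_kos)]
        ko_counter += n_kos
        definition = _build_definition(rng, kos)
        if i % 50 == 25:
            definition += f" M{i:05d}"  # reference the previous module
        n_cats = int(rng.integers(1, 3))
        cats = sorted(
            rng.choice(len(CATEGORY_POOL), size=n_cats, replace=False).tolist()
        )
        category = "; ".join(CATEGORY_POOL[c] for c in cats)
        records.append((module_id, definition, category))
    return pd.DataFrame(records, columns=["module_id", "definition", "category"])


def _parse_registry(definitions: pd.DataFrame) -> dict:
    return {
        row.module_id: moddef.parse_definition(row.module_id, row.definition)
        for row in definitions.itertuples()
    }


def _nesting_ids(definitions: pd.DataFrame) -> set:
    """Modules that reference another module, plus the referenced ones."""
    involved = set()
    for row in definitions.itertuples():
        refs = [
            tok for tok in row.definition.replace("(", " ").replace(")", " ").split()
            if moddef.MODULE_RE.fullmatch(tok)
        ]
        if refs:
            involved.add(row.module_id)
            involved.update(refs)
    return involved


def planted_module_ids(cfg: SimConfig, definitions: pd.DataFrame) -> list:
    """Deterministic choice of the planted (differential) modules.

    Modules involved in nesting are excluded so that each planted module's
    KO pool is independent of every other module's. Modules containing a
    ``--`` gap step are also excluded: a gap caps attainable completeness
    below 1, so such a module cannot express the planted effect (a genome
    carrying the full KO set of a route must score a complete module).
    Gaps and nesting stay exercised through the background modules.
    """
    rng = _rng(cfg, 2)
    excluded = _nesting_ids(definitions)
    gapped = {
        row.module_id
        for row in definitions.itertuples()
        if "--" in row.definition.split() or " -- " in row.definition
    }
    excluded |= gapped
    eligible = [m for m in definitions["module_id"] if m not in excluded]
    if len(eligible) < cfg.n_planted:
        raise ValidationError("not enough nesting-free modules to plant")
    idx = rng.choice(len(eligible), size=cfg.n_planted, replace=False)
    return sorted(eligible[i] for i in idx)


# ---------------------------------------------------------------------------
# genome annotations
# ---------------------------------------------------------------------------


def _path_ko_sets(registry: dict, module_id: str) -> list:
    paths = moddef.enumerate_paths(registry[module_id], registry)
    out = []
    for path in paths:
        kos = set()
        for step in path:
            if isinstance(step, moddef.Atom):
                kos.add(step.ko)
            elif isinstance(step, moddef.Complex):
                kos.update(ko for ko, _ in step.components)
        out.append(sorted(kos))
    return out


def gen_genome_annotations(
    cfg: SimConfig,
    definitions: pd.DataFrame,
    groups: Optional[Mapping[str, str]] = None,
):
    """Genome KO-annotation table with planted group-differential modules.

    ``groups`` maps genome id to ``good``/``poor``/anything else; the
    defaults build ``n_genomes_per_group`` genomes per colonizer group. For
    a planted module, a genome receives the full KO set of one random route
    with its group's occurrence probability (good/poor; other groups use the
    background), otherwise a sparse strict subset of that route. Non-planted
    modules use the shared background probability in every group.

    Returns ``(annotations, groups, truth)`` where ``annotations`` has
    columns genome, gene_callers_id, ko and ``truth`` records the planted
    module ids.
    """
    rng = _rng(cfg, 3)
    if groups is None:
        groups = {
            **{f"good_{i:03d}": "good" for i in range(cfg.n_genomes_per_group)},
            **{f"poor_{i:03d}": "poor" for i in range(cfg.n_genomes_per_group)},
        }
    registry = _parse_registry(definitions)
    planted = set(planted_module_ids(cfg, definitions))
    path_sets = {m: _path_ko_sets(registry, m) for m in definitions["module_id"]}
    p_good, p_poor = cfg.occurrence_probs

    rows = []
    gene_id = 0
    for genome in sorted(groups):
        group = groups[genome]
        kos: set = set()
        for module_id in definitions["module_id"]:
            if module_id in planted:
                p = p_good if group == "good" else (
                    p_poor if group == "poor" else cfg.background_prob
                )
            else:
                p = cfg.background_prob
            choices = path_sets[module_id]
            path = choices[int(rng.integers(len(choices)))]
            if not path:
                continue
            if rng.random() < p:
                kos.update(path)
            else:
                keep = [ko for ko in path if rng.random() < 0.35]
                if len(keep) == len(path):  # force a strict subset
                    keep = keep[:-1]
                kos.update(keep)
        for ko in sorted(kos):
            rows.append((genome, gene_id, ko))
            gene_id += 1
    annotations = pd.DataFrame(rows, columns=["genome", "gene_callers_id", "ko"])
    truth = {"planted_modules": sorted(planted)}
    return annotations, dict(groups), truth


# ---------------------------------------------------------------------------
# FMT cohort
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    meta: pd.DataFrame
    detection: pd.DataFrame
    subpops: pd.DataFrame
    scg_coverage: pd.DataFrame
    truth: Dict


def _case_assignments(cfg: SimConfig) -> dict:
    f_good, f_poor, _ = cfg.colonizer_fractions
    n = cfg.n_cohort_genomes
    n_good = int(round(f_good * n))
    n_poor = int(round(f_poor * n))
    n_other = n - n_good - n_poor
    if n_good < 1 or n_poor < 1 or n_other < len(OTHER_CASES):
        raise ValidationError(
            "cohort too small to plant every colonization branch case"
        )
    cases = {}
    idx = 0
    for _ in range(n_good):
        cases[f"g{idx:04d}"] = "good"
        idx += 1
    for _ in range(n_poor):
        cases[f"g{idx:04d}"] = "poor"
        idx += 1
    for j in range(n_other):
        cases[f"g{idx:04d}"] = OTHER_CASES[j % len(OTHER_CASES)]
        idx += 1
    return cases


def gen_fmt_cohort(cfg: SimConfig) -> Cohort:
    """Synthetic FMT cohort: metadata, detection, subpopulations, coverage,
    and a planted truth table covering every decision-tree branch."""
    rng = _rng(cfg, 4)
    cases = _case_assignments(cfg)
    genomes = sorted(cases)

    donor = "D01"
    transplant_sample = "D01_S000"
    donor_samples = [("D01_Sm30", -30), (transplant_sample, 0), ("D01_Sp30", 30)]
    meta_rows = [
        (s, donor, "donor", d, "", "", "") for s, d in donor_samples
    ]
    recipients = [f"R{i + 1:02d}" for i in range(cfg.n_recipients)]
    rec_samples: Dict[str, Dict[str, list]] = {}
    for i, rec in enumerate(recipients):
        delivery = "pill" if i % 2 == 0 else "colonoscopy"
        pre = [(f"{rec}_d{cfg.pre_fmt_day:+04d}", cfg.pre_fmt_day)]
        post = [(f"{rec}_d{d:+04d}", d) for d in cfg.post_fmt_days]
        for s, d in pre + post:
            meta_rows.append(
                (s, rec, "recipient", d, donor, transplant_sample, delivery)
            )
        rec_samples[rec] = {
            "pre": [s for s, _ in pre],
            "post_window": [s for s, d in post if d > 7],
            "post_all": [s for s, _ in post],
        }
    reference_samples = [f"REF_{i + 1:03d}" for i in range(cfg.n_reference_samples)]
    for s in reference_samples:
        meta_rows.append((s, s, "reference", "", "", "", ""))
    meta = pd.DataFrame(
        meta_rows,
        columns=[
            "sample_id", "subject_id", "role", "day_relative_to_fmt",
            "donor_subject", "transplant_sample", "delivery",
        ],
    )
    all_samples = meta["sample_id"].tolist()

    p_present, present_mean, absent_mean = cfg.detection_mixture

    def draw(present: bool) -> float:
        if present:
            v = rng.normal(present_mean, cfg.detection_present_sd)
        else:
            v = rng.normal(absent_mean, cfg.detection_absent_sd)
        return float(np.clip(v, 0.0, 1.0))

    # intended presence layout; realized detection values add mixture noise
    presence = pd.DataFrame(False, index=genomes, columns=all_samples)
    truth_genomes: Dict[str, Dict] = {}
    ref_prob = {"good": 0.8, "poor": 0.15, "not_applicable": 0.3}

    for genome in genomes:
        case = cases[genome]
        pairs: Dict[str, str] = {}
        for s, _ in donor_samples:
            presence.at[genome, s] = True
        if case == "not_applicable":
            presence.at[genome, transplant_sample] = False
        failed: list = []
        if case == "poor":
            failed = list(recipients[:3])
            failed += [r for r in recipients[3:] if rng.random() < 0.5]
        elif case == "sporadic":
            n_fail = int(rng.integers(1, 3))  # 1-2 failures: neither class
            failed = list(rng.choice(recipients, size=n_fail, replace=False))
        for rec in recipients:
            samples = rec_samples[rec]
            if case == "not_applicable":
                pairs[rec] = "not_applicable"
                continue
            pre_present = case in ("undetermined_prefmt", "undetermined_lowprop")
            post_present = rec not in failed
            for s in samples["pre"]:
                presence.at[genome, s] = pre_present
            for s in samples["post_all"]:
                presence.at[genome, s] = post_present
            if not post_present:
                pairs[rec] = "not_colonized"
            elif case in ("undetermined_prefmt", "undetermined_lowcov",
                          "undetermined_lowprop"):
                pairs[rec] = "undetermined"
            else:
                pairs[rec] = "colonized"
        for s in reference_samples:
            presence.at[genome, s] = rng.random() < ref_prob.get(case, 0.4)
        if case in ("good", "undetermined_prefmt", "undetermined_lowcov",
                    "undetermined_lowprop"):
            expected_class = "good"   # raw-detection rule sees all recipients
        elif case == "poor":
            expected_class = "poor"
        else:
            expected_class = "neither"
        truth_genomes[genome] = {
            "case": case,
            "expected_class": expected_class,
            "pairs": pairs,
        }

    detection = pd.DataFrame(
        [
            [draw(bool(presence.at[g, s])) for s in all_samples]
            for g in genomes
        ],
        index=pd.Index(genomes, name="genome"),
        columns=all_samples,
    )

    # single-copy core-gene coverage: high where present, except the
    # low-coverage branch case which stays below the 10X floor everywhere
    scg = pd.DataFrame(0.0, index=pd.Index(genomes, name="genome"),
                       columns=all_samples)
    for g in genomes:
        low = cases[g] == "undetermined_lowcov"
        for s in all_samples:
            if presence.at[g, s]:
                if low:
                    scg.at[g, s] = float(rng.uniform(3.0, 8.0))
                else:
                    scg.at[g, s] = float(max(12.0, rng.normal(50.0, 10.0)))
            else:
                scg.at[g, s] = float(rng.uniform(0.0, 0.5))

    # subpopulation profiles: rows only where the genome is present
    pre_sample_ids = {
        s for rec in recipients for s in rec_samples[rec]["pre"]
    }
    sp_rows = []
    alpha = cfg.subpop_dirichlet_alpha

    def _quantize(props: np.ndarray) -> np.ndarray:
        # keep proportions valid after the 4-decimal table rendering
        q = np.round(props, 4)
        excess = q.sum() - 1.0
        if excess > 0:
            q[int(np.argmax(q))] -= excess
        return np.round(q, 4)

    for g in genomes:
        case = cases[g]
        if case in ("undetermined_prefmt", "undetermined_lowprop"):
            n_sub = 1
        else:
            n_sub = int(rng.integers(1, 4))
        sub_ids = [f"{g}_sp{j + 1}" for j in range(n_sub)]
        tiny_id = f"{g}_sp_tiny"
        # the low-proportion branch case plants a discriminating
        # subpopulation that only ever occurs below the 1% floor (and never
        # pre-FMT), so the proportion filter is what forces "undetermined"
        add_tiny_everywhere = case == "undetermined_lowprop"
        tiny_elsewhere = case not in ("undetermined_prefmt",) and rng.random() < 0.2
        for s in all_samples:
            if not presence.at[g, s]:
                continue
            props = rng.dirichlet([alpha] * n_sub) if n_sub > 1 else np.array([1.0])
            with_tiny = (
                add_tiny_everywhere and s not in pre_sample_ids
            ) or tiny_elsewhere
            if with_tiny:
                full = _quantize(np.append(props * (1.0 - 0.005), 0.005))
                for sub, p in zip(sub_ids + [tiny_id], full):
                    sp_rows.append((g, sub, s, float(p)))
            else:
                for sub, p in zip(sub_ids, _quantize(props)):
                    sp_rows.append((g, sub, s, float(p)))
    subpops = pd.DataFrame(
        sp_rows, columns=["genome_id", "subpop_id", "sample_id", "proportion"]
    )

    truth = {
        "cases": {g: truth_genomes[g]["case"] for g in genomes},
        "genomes": truth_genomes,
        "planted_class_counts": {
            c: sum(1 for g in genomes if truth_genomes[g]["expected_class"] == c)
            for c in ("good", "poor", "neither")
        },
        "reference_samples": reference_samples,
    }
    return Cohort(meta=meta, detection=detection, subpops=subpops,
                  scg_coverage=scg, truth=truth)


# ---------------------------------------------------------------------------
# one-call simulation
# ---------------------------------------------------------------------------


def simulate(cfg: SimConfig):
    """Generate a coherent dataset for the full pipeline.

    The cohort's planted colonizer classes drive the annotation groups, so
    colonization phenotyping, enrichment and MI scoring can run end to end
    on one dataset. Returns ``(definitions, annotations, groups, cohort,
    truth)``; ``truth`` merges the annotation and cohort truth tables.
    """
    definitions = gen_module_definitions(cfg)
    cohort = gen_fmt_cohort(cfg)
    groups = {
        g: info["expected_class"]
        for g, info in cohort.truth["genomes"].items()
    }
    annotations, groups, ann_truth = gen_genome_annotations(
        cfg, definitions, groups
    )
    truth = {**cohort.truth, **ann_truth, "groups": groups}
    return definitions, annotations, groups, cohort, truth


def write_truth(truth: Dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
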