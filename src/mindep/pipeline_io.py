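"""Readers, writers, run configuration and end-to-end orchestration.

All tables are tab-separated UTF-8 with a header row; floats are rendered to
4 decimals; genome and sample ids are opaque strings. Every table this
module writes starts with a ``#`` comment line recording the tool version,
the seed and a hash of the run configuration, and every reader skips ``#``
comment lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .colonization import (
    ColonizationRules,
    assign_phenotypes,
    build_recipient_summary,
    classify_all,
    filter_subpopulations,
    select_representatives,
)
from .detection import DetectionThresholds, prevalence
from .enrichment import EnrichmentCriteria, enriched_modules, enrichment_table
from .errors import ValidationError
from .mi_score import MiConfig, ModuleSet, group_compare, category_summary, mi_scores
from .moddef import (
    CompletenessPolicy,
    GenomeAnnotations,
    ModuleDefinition,
    completeness_matrix,
    parse_definition,
)

logger = logging.getLogger("mindep")

__all__ = [
    "RunConfig",
    "read_module_flatfile",
    "read_module_definitions_tsv",
    "read_ko_annotations",
    "read_detection_tsv",
    "read_metadata_tsv",
    "read_subpops_tsv",
    "read_coverage_tsv",
    "write_tsv",
    "run_fmt_analysis",
    "run_supplementary_reproduction",
]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_module_flatfile(path) -> Tuple[List[ModuleDefinition], Dict[str, tuple]]:
    """Parse KEGG-style flat-file records (ENTRY/DEFINITION/CLASS, ``///``).

    DEFINITION lines of a record are concatenated; CLASS strings are split
    on semicolons into category tuples. Returns (definitions, categories).
    """
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise ValidationError(f"{path}: empty module flat file")
    definitions: List[ModuleDefinition] = []
    categories: Dict[str, tuple] = {}
    entry = None
    def_parts: List[str] = []
    class_parts: List[str] = []
    current_key = None

    def _finish(line_no: int):
        nonlocal entry, def_parts, class_parts
        if entry is None:
            return
        if not def_parts:
            raise ValidationError(
                f"{path}: record {entry} (ending line {line_no}) has no DEFINITION"
            )
        definitions.append(parse_definition(entry, " ".join(def_parts)))
        if class_parts:
            cats = tuple(
                c.strip() for c in " ".join(class_parts).split(";") if c.strip()
            )
            categories[entry] = cats
        entry, def_parts, class_parts = None, [], []

    for line_no, raw in enumerate(text.splitlines(), start=1):
        if raw.startswith("///"):
            _finish(line_no)
            current_key = None
            continue
        if not raw.strip():
            continue
        if raw[0] != " ":
            parts = raw.split(None, 1)
            current_key = parts[0]
            value = parts[1] if len(parts) > 1 else ""
        else:
            value = raw.strip()
        if current_key == "ENTRY":
            if entry is not None:
                raise ValidationError(
                    f"{path}: record {entry} not terminated before line {line_no}"
                )
            entry = value.split()[0]
        elif current_key == "DEFINITION":
            def_parts.append(value)
        elif current_key == "CLASS":
            class_parts.append(value)
    _finish(line_no=len(text.splitlines()))
    if not definitions:
        raise ValidationError(f"{path}: no module records found")
    return definitions, categories


def read_module_definitions_tsv(path) -> Tuple[List[ModuleDefinition], Dict[str, tuple]]:
    """Two-column (plus optional category) TSV of module definitions."""
    frame = _read_table(path, dtype=str)
    required = {"module_id", "definition"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    definitions = [
        parse_definition(row.module_id, row.definition)
        for row in frame.itertuples()
    ]
    categories: Dict[str, tuple] = {}
    if "category" in frame.columns:
        for row in frame.itertuples():
            if isinstance(row.category, str) and row.category.strip():
                categories[row.module_id] = tuple(
                    c.strip() for c in row.category.split(";") if c.strip()
                )
    return definitions, categories


def read_ko_annotations(path) -> List[GenomeAnnotations]:
    """KO annotation TSV (genome, gene_callers_id, ko, ...); one
    :class:`GenomeAnnotations` per genome, KOs deduplicated."""
    frame = _read_table(path, dtype=str)
    missing = {"genome", "ko"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        GenomeAnnotations(genome_id=genome, kos=frozenset(sub["ko"]))
        for genome, sub in frame.groupby("genome", sort=True)
    ]


def read_detection_tsv(path) -> pd.DataFrame:
    """Detection matrix TSV: rows genomes, columns samples."""
    return _read_table(path, index_col=0).astype(float)


def read_coverage_tsv(path) -> pd.DataFrame:
    return _read_table(path, index_col=0).astype(float)


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = _read_table(path, dtype={"sample_id": str, "subject_id": str})
    required = {"sample_id", "subject_id", "role", "day_relative_to_fmt"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return meta


def read_subpops_tsv(path) -> pd.DataFrame:
    frame = _read_table(path)
    missing = {"genome_id", "subpop_id", "sample_id", "proportion"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return frame


def read_groups_tsv(path) -> Dict[str, str]:
    frame = _read_table(path, dtype=str)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: need (genome, group) columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_tsv(
    frame: pd.DataFrame,
    path,
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
    index: bool = True,
) -> None:
    """Write a TSV with a provenance comment line and 4-decimal floats."""
    header = f"# mindep {__version__}"
    if seed is not None:
        header += f" seed={seed}"
    if config_hash is not None:
        header += f" config={config_hash}"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, sep="\t", float_format="%.4f", index=index)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Paths and thresholds for an end-to-end FMT analysis run."""

    definitions_path: str
    annotations_path: str
    detection_path: str
    subpops_path: str
    metadata_path: str
    scg_coverage_path: str
    out_dir: str
    truth_path: Optional[str] = None
    seed: int = 0
    thresholds: DetectionThresholds = field(default_factory=DetectionThresholds)
    rules: ColonizationRules = field(default_factory=ColonizationRules)
    criteria: EnrichmentCriteria = field(default_factory=EnrichmentCriteria)
    mi: MiConfig = field(default_factory=MiConfig)
    policy: CompletenessPolicy = field(default_factory=CompletenessPolicy)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # output location is not analysis config
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = dict(data)
        for key, klass in (
            ("thresholds", DetectionThresholds),
            ("rules", ColonizationRules),
            ("criteria", EnrichmentCriteria),
            ("mi", MiConfig),
            ("policy", CompletenessPolicy),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# end-to-end FMT analysis
# ---------------------------------------------------------------------------


def run_fmt_analysis(cfg: RunConfig) -> dict:
    """Run detection -> colonization -> representative selection ->
    completeness -> enrichment -> MI scoring, writing artifacts to
    ``cfg.out_dir`` and returning the run summary."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    for p in (cfg.definitions_path, cfg.annotations_path, cfg.detection_path,
              cfg.subpops_path, cfg.metadata_path, cfg.scg_coverage_path):
        if not Path(p).exists():
            raise ValidationError(f"input file missing: {p}")

    def _stage(name: str, message: str):
        logger.info("[%s] %s", name, message)

    _stage("load", "reading inputs")
    definitions, categories = read_module_definitions_tsv(cfg.definitions_path)
    genomes = read_ko_annotations(cfg.annotations_path)
    detection = read_detection_tsv(cfg.detection_path)
    subpops = read_subpops_tsv(cfg.subpops_path)
    meta = read_metadata_tsv(cfg.metadata_path)
    scg = read_coverage_tsv(cfg.scg_coverage_path)

    _stage("colonization", "filtering subpopulations and phenotyping pairs")
    coverage_ok = scg >= cfg.rules.scg_coverage_min
    filtered = filter_subpopulations(subpops, cfg.rules, coverage_ok)
    calls = assign_phenotypes(
        detection, filtered, meta, cfg.rules, cfg.thresholds
    )
    write_tsv(calls, out_dir / "colonization_calls.tsv", cfg.seed, chash,
              index=False)

    summary_table = build_recipient_summary(detection, meta, cfg.rules,
                                            cfg.thresholds)
    labels = classify_all(summary_table, cfg.rules)
    good = sorted(labels.index[labels == "good"])
    poor = sorted(labels.index[labels == "poor"])
    if not good or not poor:
        raise ValidationError(
            "colonization stage produced an empty good or poor set"
        )

    _stage("selection", f"{len(good)} good / {len(poor)} poor colonizers")
    reference_samples = meta.loc[meta["role"] == "reference", "sample_id"].tolist()
    selected_good = good
    if len(good) > len(poor) and reference_samples:
        prev = {
            g: prevalence(g, reference_samples, detection, cfg.thresholds)
            for g in good
        }
        selected_good = select_representatives(good, prev, len(poor))
    label_frame = labels.rename_axis("genome").to_frame()
    label_frame["selected"] = label_frame.index.isin(
        set(selected_good) | set(poor)
    )
    write_tsv(label_frame, out_dir / "colonizer_classes.tsv", cfg.seed, chash)

    _stage("completeness", "building the completeness matrix")
    keep = set(selected_good) | set(poor)
    matrix = completeness_matrix(
        [g for g in genomes if g.genome_id in keep], definitions, cfg.policy
    )
    write_tsv(matrix, out_dir / "completeness_matrix.tsv", cfg.seed, chash)

    _stage("enrichment", "testing modules between good and poor colonizers")
    groups = {g: ("good" if g in set(selected_good) else "poor") for g in matrix.index}
    table = enrichment_table(matrix, groups, cfg.criteria)
    write_tsv(table, out_dir / "enrichment.tsv", cfg.seed, chash)
    enriched = enriched_modules(table, cfg.criteria)
    enriched_good = enriched.get("good", [])

    _stage("mi_score", f"{len(enriched_good)} modules enriched in good colonizers")
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": chash,
        "thresholds": dataclasses.asdict(cfg.thresholds),
        "rules": dataclasses.asdict(cfg.rules),
        "criteria": dataclasses.asdict(cfg.criteria),
        "mi": dataclasses.asdict(cfg.mi),
        "n_genomes_detected": int(detection.shape[0]),
        "n_recipients": int(
            meta.loc[meta["role"] == "recipient", "subject_id"].nunique()
        ),
        "outcome_counts": calls["outcome"].value_counts().to_dict(),
        "n_good": len(good),
        "n_poor": len(poor),
        "n_good_selected": len(selected_good),
        "n_modules": int(matrix.shape[1]),
        "n_enriched_good": len(enriched_good),
        "enriched_good": sorted(enriched_good),
    }
    if enriched_good:
        module_set = ModuleSet(
            tuple(sorted(enriched_good)),
            {m: categories.get(m, ()) for m in enriched_good},
        )
        full_matrix = completeness_matrix(genomes, definitions, cfg.policy)
        scores = mi_scores(full_matrix, module_set, cfg.mi)
        write_tsv(scores, out_dir / "mi_scores.tsv", cfg.seed, chash)
        summary["mi_threshold"] = float(
            cfg.mi.threshold_fraction * len(module_set)
        )
        summary["n_hmi"] = int((scores["classification"] == "HMI").sum())
        summary["n_lmi"] = int((scores["classification"] == "LMI").sum())

    if cfg.truth_path:
        with open(cfg.truth_path, "r", encoding="utf-8") as fh:
            truth = json.load(fh)
        summary["recovery"] = _recovery_stats(truth, calls, labels, enriched_good)

    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _stage("done", "wrote artifacts")
    return summary


def _recovery_stats(truth: dict, calls: pd.DataFrame, labels: pd.Series,
                    enriched_good: list) -> dict:
    out: dict = {}
    genomes = truth.get("genomes", {})
    if genomes:
        expected = {g: info["expected_class"] for g, info in genomes.items()}
        shared = [g for g in labels.index if g in expected]
        agree = sum(1 for g in shared if labels[g] == expected[g])
        out["class_recovery_pct"] = 100.0 * agree / len(shared) if shared else None
        pair_truth = {
            (g, r): o
            for g, info in genomes.items()
            for r, o in info["pairs"].items()
        }
        hits = total = 0
        for row in calls.itertuples():
            key = (row.genome_id, row.recipient_id)
            if key in pair_truth:
                total += 1
                hits += row.outcome == pair_truth[key]
        out["outcome_agreement_pct"] = 100.0 * hits / total if total else None
    planted = set(truth.get("planted_modules", []))
    if planted:
        found = planted & set(enriched_good)
        out["planted_module_sensitivity_pct"] = 100.0 * len(found) / len(planted)
        out["enrichment_false_discoveries"] = len(set(enriched_good) - planted)
    return out


# ---------------------------------------------------------------------------
# supplementary-table style reproduction
# ---------------------------------------------------------------------------

SUPP9_COLUMNS = ("genome_id", "group", "genome_length_bp", "completion_pct",
                 "module_id", "module_completeness", "category")
SUPP10_COLUMNS = ("genome_id", "group", "module_id", "module_completeness")


def _apply_column_map(frame: pd.DataFrame,
                      column_map: Optional[Mapping[str, str]]) -> pd.DataFrame:
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    return frame


def run_supplementary_reproduction(
    supp9_path,
    supp10_path,
    criteria: EnrichmentCriteria = EnrichmentCriteria(),
    column_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Recompute the headline summary quantities from long-format
    genome/module tables.

    ``supp9_path``: per-genome module completeness for the good/poor
    colonizer comparison, long format with columns genome_id, group
    (good|poor), genome_length_bp, completion_pct, module_id,
    module_completeness and optional category. ``supp10_path``: module
    completeness for donor-HMI/donor-LMI/healthy/IBD genome groups, columns
    genome_id, group, module_id, module_completeness. ``column_map`` maps
    actual header names onto these expected ones. Returns a tidy report
    with one recomputed quantity per row.
    """
    rows: List[tuple] = []

    s9 = _apply_column_map(_read_table(supp9_path), column_map)
    missing = {"genome_id", "group", "module_id", "module_completeness"} - set(s9.columns)
    if missing:
        raise ValidationError(f"{supp9_path}: missing columns {sorted(missing)}")

    per_genome = s9.drop_duplicates("genome_id").set_index("genome_id")
    for group, sub in per_genome.groupby("group"):
        if "genome_length_bp" in sub:
            rows.append((f"mean_genome_size_mbp_{group}",
                         float(sub["genome_length_bp"].mean()) / 1e6))
        if "completion_pct" in sub:
            rows.append((f"mean_completion_pct_{group}",
                         float(sub["completion_pct"].mean())))

    matrix = s9.pivot(index="genome_id", columns="module_id",
                      values="module_completeness").fillna(0.0)
    groups = per_genome["group"].to_dict()
    table = enrichment_table(matrix, groups, criteria)
    enriched = enriched_modules(table, criteria)
    enriched_good = sorted(enriched.get("good", []))
    rows.append(("n_enriched_good", float(len(enriched_good))))

    if "category" in s9.columns and enriched_good:
        cats = {
            m: tuple(c.strip() for c in str(v).split(";") if c.strip())
            for m, v in s9.drop_duplicates("module_id")
            .set_index("module_id")["category"]
            .items()
            if isinstance(v, str)
        }
        mset = ModuleSet(tuple(enriched_good),
                         {m: cats.get(m, ()) for m in enriched_good})
        for record in category_summary(mset).itertuples():
            rows.append((f"pct_enriched_{record.category}",
                         round(record.percent, 1)))

    vals = {
        group: sub["module_completeness"].to_numpy(dtype=float)
        for group, sub in s9.groupby("group")
    }
    if {"good", "poor"} <= set(vals):
        stat, p = group_compare(vals["good"], vals["poor"])
        rows.append(("wilcoxon_good_vs_poor_stat", float(stat)))
        rows.append(("wilcoxon_good_vs_poor_p", float(p)))

    s10 = _apply_column_map(_read_table(supp10_path), column_map)
    missing = {"genome_id", "group", "module_id", "module_completeness"} - set(s10.columns)
    if missing:
        raise ValidationError(f"{supp10_path}: missing columns {sorted(missing)}")
    means = {}
    for group, sub in s10.groupby("group"):
        mean = float(sub["module_completeness"].mean())
        means[group] = sub["module_completeness"].to_numpy(dtype=float)
        rows.append((f"mean_module_completeness_{group}", mean))
    ibd_groups = [g for g in means if str(g).startswith("ibd")]
    if ibd_groups and "donor_hmi" in means:
        ibd = np.concatenate([means[g] for g in ibd_groups])
        stat, p = group_compare(means["donor_hmi"], ibd)
        rows.append(("wilcoxon_hmi_vs_ibd_p", float(p)))
        if "healthy" in means:
            stat, p = group_compare(means["healthy"], ibd)
            rows.append(("wilcoxon_healthy_vs_ibd_p", float(p)))

    return pd.DataFrame(rows, columns=["quantity", "value"])
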