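"""End-to-end pipeline driver, configuration, and dataset-composition reports.

``run_pipeline`` wires the modules together: parse the frozen ontology, read
and filter snapshots, compute growth and the NK/LK/PK partition, estimate
(or load) information accretion, prepare predictions, sweep the threshold
grid, and emit tidy result tables — one observation per row — with optional
bootstrap confidence intervals and batch evaluation over successive
snapshots.

``benchmark_composition_stats`` reproduces the arithmetic a benchmark
reports about its own dataset (setting totals, the partial-knowledge share,
and the expansion the PK setting brings over NK+LK) from a plain counts
file; the packaged file carries the published CAFA5 evaluation counts.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import importlib.resources
import logging
import os
from collections.abc import Sequence
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import accretion, annotations, evaluation
from .ontology import ASPECTS, parse_obo

logger = logging.getLogger(__name__)

ASPECT_COLUMNS = ("terms_bpo", "terms_cco", "terms_mfo")


# ----------------------------------------------------------- dataset counts


def packaged_counts_path() -> str:
    """Path to the published evaluation-composition counts shipped with the package."""
    return str(
        importlib.resources.files("funcbench").joinpath("data/cafa5_dataset_counts.tsv")
    )


def load_dataset_counts(path: str | None = None) -> pd.DataFrame:
    """Load a (dataset, setting, proteins, terms-per-aspect) counts table."""
    df = pd.read_csv(path or packaged_counts_path(), sep="\t", comment="#")
    required = {"dataset", "setting", "proteins", *ASPECT_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts file missing column(s) {sorted(missing)}")
    df["terms_total"] = df[list(ASPECT_COLUMNS)].sum(axis=1)
    return df


def benchmark_composition_stats(counts: pd.DataFrame | None = None) -> dict[str, float]:
    """Totals and derived percentages from a dataset-composition counts table.

    Per-setting term totals are summed across aspects and settings for each
    dataset; the partial-knowledge share, the unpublished-evaluation shares,
    and the annotation/protein expansion contributed by the PK setting over
    NK+LK are derived from those marginals.
    """
    if counts is None:
        counts = load_dataset_counts()
    out: dict[str, float] = {}
    settings = counts[counts["setting"].isin(["NK", "LK", "PK"])]
    for dataset, sub in settings.groupby("dataset"):
        out[f"{dataset}_total_annotations"] = float(sub["terms_total"].sum())

    full = settings[settings["dataset"] == "full"].set_index("setting")
    full_total = float(full["terms_total"].sum())
    nk_lk_terms = float(full.loc[["NK", "LK"], "terms_total"].sum())
    nk_lk_proteins = float(full.loc[["NK", "LK"], "proteins"].sum())
    out["pk_share_pct"] = float(full.loc["PK", "terms_total"]) / full_total * 100.0

    dedup = counts[(counts["dataset"] == "full") & (counts["setting"] == "total")]
    if not dedup.empty:
        total_proteins = float(dedup["proteins"].iloc[0])
        out["pk_annotation_expansion_pct"] = (full_total - nk_lk_terms) / nk_lk_terms * 100.0
        out["pk_protein_expansion_pct"] = (
            (total_proteins - nk_lk_proteins) / nk_lk_proteins * 100.0
        )

    if "unpublished_total_annotations" in out:
        out["unpublished_share_of_evaluation_pct"] = (
            out["unpublished_total_annotations"] / full_total * 100.0
        )
    post = counts[counts["dataset"] == "post_t0_unique"].set_index("setting")
    if {"all", "published_after_t0"}.issubset(post.index):
        out["post_t0_published_share_pct"] = (
            float(post.loc["published_after_t0", "terms_total"])
            / float(post.loc["all", "terms_total"])
            * 100.0
        )
    return out


# ----------------------------------------------------------------- pipeline


@dataclass
class RunConfig:
    """Declarative pipeline configuration (paths plus evaluation options)."""

    obo: str = ""
    t0: str = ""
    te: list[str] = field(default_factory=list)  # one or more successive snapshots
    predictions: list[str] = field(default_factory=list)
    ia: str = ""  # optional precomputed IA table; empty -> estimate from t0
    targets: str = ""  # optional plain identifier list
    settings: list[str] = field(default_factory=lambda: list(evaluation.SETTINGS))
    aspects: list[str] = field(default_factory=lambda: list(ASPECTS))
    weightings: list[str] = field(default_factory=lambda: ["unweighted", "ia"])
    averagings: list[str] = field(default_factory=lambda: ["micro", "macro"])
    grid_step: float = 0.01
    propagate_predictions: bool = True
    evidence_codes: list[str] = field(
        default_factory=lambda: sorted(annotations.EXPERIMENTAL_CODES)
    )
    min_reference_date: str = ""  # keep only annotations published strictly after
    bootstrap: int = 0
    level: float = 0.95
    seed: int = 0
    out_dir: str = ""

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Load from a flat key-value (YAML) file; unknown keys are an error."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for path in [self.obo, self.t0, *self.te, *self.predictions]:
            if path and not os.path.exists(path):
                raise FileNotFoundError(path)
        if self.bootstrap and self.seed is None:
            raise ValueError("bootstrap requested without a seed")


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute parse -> filter -> growth -> partition -> IA -> evaluate.

    Returns tidy tables: ``results`` (one row per model x snapshot x setting
    x aspect x metric), ``summary`` (dataset composition per snapshot).
    Identical configurations give identical outputs.  With several te
    snapshots the evaluation repeats against each, emulating re-evaluation
    over successive database releases.
    """
    config.validate()
    grid = [round(config.grid_step * i, 10) for i in range(1, int(1 / config.grid_step) + 1)]
    min_date = config.min_reference_date or None

    logger.info("stage=ontology path=%s", config.obo)
    graph = parse_obo(config.obo)
    t0 = annotations.read_annotations(
        config.t0, graph, evidence_filter=config.evidence_codes, snapshot_tag="t0"
    )
    logger.info("stage=t0 proteins=%d", len(t0))

    if config.ia:
        ia = accretion.IATable.from_tsv(config.ia)
    else:
        ia = accretion.compute_ia(t0, graph)
    logger.info("stage=ia terms=%d corpus=%d", len(ia), ia.corpus_size)

    target_list: set[str] | None = None
    if config.targets:
        with open(config.targets) as fh:
            target_list = {line.strip() for line in fh if line.strip()}

    results = []
    summaries = []
    for te_path in config.te:
        te = annotations.read_annotations(
            te_path, graph, evidence_filter=config.evidence_codes,
            min_reference_date=min_date, snapshot_tag=os.path.basename(te_path),
        )
        growth = annotations.snapshot_growth(t0, te, graph)
        partition = evaluation.partition_settings(t0, growth, graph)
        if target_list is not None:
            partition = evaluation.EvaluationPartition(
                [e for e in partition if e.protein in target_list],
                graph_version=partition.graph_version,
            )
        logger.info("stage=partition snapshot=%s entries=%d", te.snapshot_tag, len(partition))
        summary = evaluation.summarize_dataset(partition, ia)
        summary.insert(0, "snapshot", te.snapshot_tag)
        summaries.append(summary)

        for pred_path in config.predictions:
            preds = evaluation.PredictionSet.from_file(
                pred_path, model_tag=os.path.splitext(os.path.basename(pred_path))[0]
            )
            prepared = evaluation.prepare_predictions(
                preds, graph, partition, propagate=config.propagate_predictions
            )
            table = evaluation.evaluate_model(
                prepared, partition, graph, ia=ia,
                settings=config.settings, aspects=config.aspects,
                weightings=config.weightings, averagings=config.averagings,
                grid=grid, bootstrap=config.bootstrap, level=config.level,
                seed=config.seed,
            )
            table.insert(0, "snapshot", te.snapshot_tag)
            results.append(table)
            logger.info("stage=evaluate snapshot=%s model=%s rows=%d",
                        te.snapshot_tag, preds.model_tag, len(table))

    out = {
        "results": pd.concat(results, ignore_index=True) if results else pd.DataFrame(),
        "summary": pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame(),
    }
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        for name, df in out.items():
            df.to_csv(os.path.join(config.out_dir, f"{name}.tsv"), sep="\t", index=False)
    return out
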