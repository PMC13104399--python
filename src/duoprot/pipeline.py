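"""End-to-end orchestration: ingest/simulate -> preprocess -> differential ->
LDA subset ranking -> ROC/correlation screening -> cross-validated pairs.

Each stage is individually importable; this module wires them in the fixed
analysis order, writes every tabular output, and records a run manifest
(parameters, seeds, per-stage protein counts) so the protein funnel is
auditable on any input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, io_maxquant, preprocess, screening, subset_lda
from .crossval import CvSpec, enumerate_pairs_and_count_perfect
from .matrix import ProteinMatrix
from .preprocess import PreprocessParams
from .synthetic import GroundTruth, SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)

CONTRASTS = ("N_vs_P", "N_vs_D", "P_vs_D")


@dataclass
class PipelineConfig:
    protein_groups: str | None = None
    sample_sheet: str | None = None
    synthetic: SyntheticSpec | None = None
    params: PreprocessParams = field(default_factory=PreprocessParams)
    rule: differential.SignificanceRule = field(
        default_factory=differential.SignificanceRule)
    subset_sizes: tuple[int, ...] = (2, 3, 4, 5)
    max_candidates: int = 23
    corr_threshold: float = 0.6
    cv: CvSpec = field(default_factory=CvSpec)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        file_input = self.protein_groups is not None
        if file_input == (self.synthetic is not None):
            raise ValueError("provide exactly one of a proteinGroups file "
                             "or a synthetic spec")
        if file_input and self.sample_sheet is None:
            raise ValueError("a proteinGroups input needs a sample sheet")


@dataclass
class PipelineResult:
    matrix: ProteinMatrix
    report: preprocess.PreprocessReport
    diff_table: pd.DataFrame
    significant: pd.DataFrame
    candidates: list[str]
    lda_fit: subset_lda.LdaFit
    ranking: subset_lda.SubsetRanking
    frequency: subset_lda.FrequencyRanking | None
    corr: screening.CorrelationScreen
    roc_table: pd.DataFrame
    cv_outcomes: pd.DataFrame
    cv_perfect_count: int
    cv_frequency: dict[str, int]
    truth: GroundTruth | None
    manifest: dict


def _load_input(config: PipelineConfig) -> tuple[ProteinMatrix, GroundTruth | None]:
    if config.synthetic is not None:
        matrix, truth = generate_dataset(config.synthetic)
        return matrix, truth
    design = io_maxquant.read_sample_sheet(config.sample_sheet)
    return io_maxquant.read_protein_groups(config.protein_groups, design), None


def candidate_matrix(matrix: ProteinMatrix, significant: pd.DataFrame,
                     max_candidates: int) -> list[str]:
    """Candidate panel: the significant proteins, capped at the
    ``max_candidates`` smallest omnibus p-values (the study works with a
    panel of 23)."""
    return list(significant["protein_id"].head(max_candidates))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    matrix, truth = _load_input(config)
    design = matrix.design

    params = PreprocessParams(**{**asdict(config.params), "seed": config.seed})
    processed, report = preprocess.preprocess_pipeline(matrix, params)

    diff_table = differential.run_differential(processed, alpha=config.rule.alpha)
    significant = differential.select_significant(diff_table, config.rule)
    candidates = candidate_matrix(processed, significant, config.max_candidates)
    if len(candidates) < 2:
        raise RuntimeError("differential stage yielded fewer than 2 candidate "
                           "proteins; nothing to rank")

    sub = processed.subset_proteins(candidates)
    X = sub.values.to_numpy(dtype=float).T  # samples x proteins
    labels = design.labels

    lda_fit = subset_lda.fit_lda(X, labels)
    sizes = tuple(k for k in config.subset_sizes if k <= len(candidates))
    ranking = subset_lda.subset_search(X, labels, candidates, sizes=sizes)
    frequency = None
    if ranking.perfect_at_minimal:
        omnibus = dict(zip(significant["protein_id"], significant["omnibus_p"]))
        frequency = subset_lda.rank_by_frequency(ranking.perfect_at_minimal,
                                                 tiebreak_p=omnibus)

    corr = screening.pearson_pair_screen(processed, candidates,
                                         threshold=config.corr_threshold)
    roc_table = screening.screening_table(processed, candidates)

    cv_spec = CvSpec(**{**asdict(config.cv), "base_seed": config.seed})
    cv_outcomes, cv_perfect, cv_freq = enumerate_pairs_and_count_perfect(
        X, labels, candidates, cv_spec)

    manifest = {
        "seed": config.seed,
        "design": design.counts(),
        "preprocess": asdict(params),
        "significance_rule": asdict(config.rule),
        "subset_sizes": list(sizes),
        "max_candidates": config.max_candidates,
        "corr_threshold": config.corr_threshold,
        "cv": asdict(cv_spec),
        "cv_seeds": cv_spec.seeds,
        "funnel": {
            "n_input": report.n_input,
            "n_after_flag_removal": report.n_after_flag_removal,
            "n_after_filter": report.n_after_filter,
            "n_significant": int(len(significant)),
            "n_candidates": len(candidates),
        },
        "lda": {
            "ld1_proportion": float(lda_fit.ld_proportions[0]),
            "full_panel_accuracy": lda_fit.accuracy,
            "minimal_perfect_size": ranking.minimal_size,
            "n_perfect_at_minimal": len(ranking.perfect_at_minimal),
        },
        "screening": {"n_strong_pairs": int(len(corr.strong_pairs))},
        "crossval": {"n_pairs": int((cv_outcomes["n_features"] == 2).sum()),
                     "n_perfect_pairs": cv_perfect},
    }

    result = PipelineResult(
        matrix=processed, report=report, diff_table=diff_table,
        significant=significant, candidates=candidates, lda_fit=lda_fit,
        ranking=ranking, frequency=frequency, corr=corr, roc_table=roc_table,
        cv_outcomes=cv_outcomes, cv_perfect_count=cv_perfect,
        cv_frequency=cv_freq, truth=truth, manifest=manifest,
    )
    if config.outdir is not None:
        write_outputs(result, Path(config.outdir))
    return result


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    w = io_maxquant.write_table
    with open(outdir / "preprocess_report.json", "w") as fh:
        json.dump(result.report.to_json_dict(), fh, indent=2)
    w(result.diff_table, outdir / "differential.tsv")
    w(result.significant, outdir / "significant.tsv")
    for contrast in CONTRASTS:
        if f"raw_p_{contrast}" in result.diff_table.columns:
            w(differential.volcano_table(result.diff_table, contrast),
              outdir / f"volcano_{contrast}.tsv")
    w(result.ranking.to_frame(only_perfect=True), outdir / "subsets_perfect.tsv")
    if result.frequency is not None:
        w(result.frequency.table, outdir / "subset_frequency.tsv")
    w(subset_lda.biplot_export(result.lda_fit, result.matrix.design.labels,
                               list(result.matrix.design.samples)),
      outdir / "biplot.tsv")
    w(result.corr.corr, outdir / "correlations.tsv", index=True)
    w(result.corr.strong_pairs, outdir / "strong_pairs.tsv")
    w(result.roc_table, outdir / "roc_table.tsv")
    w(result.cv_outcomes, outdir / "cv_pairs.tsv")
    with open(outdir / "cv_summary.json", "w") as fh:
        json.dump({"n_perfect_pairs": result.cv_perfect_count,
                   "frequency": result.cv_frequency}, fh, indent=2)
    if result.truth is not None:
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(result.truth.to_json_dict(), fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
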