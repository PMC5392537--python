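"""End-to-end orchestration and cohort-level evaluation.

Wires the stages together: synthetic cohort (or a provided beta matrix) →
cross-dataset normalization → marker screening and stepwise selection →
linear baseline → staged GRNN optimisation → sensitivity analysis, plus
the external validations: monozygotic-twin cohorts, disease cohorts, and
the sequencing validation loop (triplicate FASTQ → quantification →
standard-curve and array harmonisation → blind prediction).

Every run writes a manifest (config, seeds, package version, data hash)
sufficient to re-execute deterministic stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .calibration import (
    cross_dataset_normalize,
    fit_standard_curve,
    apply_standard_curve,
    ngs_to_array_normalize,
)
from .cohort import default_cohort_spec, generate_cohort
from .grnn import (
    GRNNModel,
    SplitSpec,
    grnn_predict,
    make_split,
    sensitivity_analysis,
    stage1_split_search,
    stage2_fixed_blind,
    stage3_replicates,
)
from .io import beta_columns, write_beta_matrix
from .panel import MarkerPanel
from .reads import DEFAULT_MIN_READS, quantify, simulate_reads
from .stats import (
    evaluate_predictions,
    fit_linear_age_model,
    predict_linear,
    screen_markers,
    stepwise_select,
)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "evaluate_twins",
    "evaluate_cohorts",
    "ngs_validation_loop",
    "simulate_ngs_batches",
    "iter_ngs_batches",
    "PipelineError",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    n_samples: int = 1156
    normalization_mode: str = "per-cpg"
    min_reads: int = DEFAULT_MIN_READS
    proportions: tuple[float, ...] = (0.5, 0.6, 0.7)
    stage1_repeats: int = 2
    stage2_resamples: int = 3
    replicates: int = 10
    run_sensitivity: bool = True
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    matrix: pd.DataFrame
    ground_truth: dict
    screen: pd.DataFrame
    stepwise: object
    linear_model: object
    linear_report: object
    grnn_model: GRNNModel
    grnn_split: SplitSpec
    replicate_summary: pd.DataFrame
    sensitivity: object | None
    manifest: dict


def _matrix_hash(matrix: pd.DataFrame) -> str:
    payload = matrix.round(10).to_csv().encode()
    return hashlib.sha256(payload).hexdigest()


def run_pipeline(config: RunConfig, matrix: pd.DataFrame | None = None) -> PipelineResult:
    """Execute the full analysis on a synthetic (default) or given cohort."""
    if matrix is None:
        spec = default_cohort_spec(n_samples=config.n_samples, seed=config.seed)
        matrix, truth = generate_cohort(spec)
    else:
        truth = {}
    normalized = cross_dataset_normalize(matrix, mode=config.normalization_mode)

    screen = screen_markers(normalized)
    selection = stepwise_select(normalized)
    if not selection.selected:
        raise PipelineError("stepwise selection returned no markers")
    linear_model = fit_linear_age_model(normalized, cpgs=selection.selected)
    linear_report = evaluate_predictions(
        normalized["age"], predict_linear(linear_model, normalized)
    )

    cpgs = list(selection.selected)
    stage1 = stage1_split_search(
        normalized, cpgs=cpgs, proportions=config.proportions,
        repeats=config.stage1_repeats, seed=config.seed,
    )
    stage2 = stage2_fixed_blind(
        normalized, stage1.spec, cpgs=cpgs,
        resamples=config.stage2_resamples, seed=config.seed + 1,
    )
    replicates, summary, _ = stage3_replicates(
        normalized, stage2.spec, cpgs=cpgs, k=config.replicates,
        seed=config.seed + 2,
    )
    best_model = stage2.model

    sensitivity = None
    if config.run_sensitivity:
        _, _, blind_ids = make_split(normalized.index, stage2.spec)
        blind = normalized.loc[list(blind_ids)]
        sensitivity = sensitivity_analysis(
            replicates, blind[cpgs], blind["age"].to_numpy()
        )

    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "matrix_sha256": _matrix_hash(matrix),
        "selected_cpgs": list(selection.selected),
        "split": {
            "p_train": stage2.spec.p_train,
            "p_verify": stage2.spec.p_verify,
            "p_blind": stage2.spec.p_blind,
            "seed": stage2.spec.seed,
        },
        "sigma": float(np.asarray(best_model.sigma)),
        "linear": linear_report.to_dict(),
        "replicate_summary": summary.reset_index().to_dict(orient="records"),
    }
    result = PipelineResult(
        matrix=normalized, ground_truth=truth, screen=screen, stepwise=selection,
        linear_model=linear_model, linear_report=linear_report,
        grnn_model=best_model, grnn_split=stage2.spec,
        replicate_summary=summary, sensitivity=sensitivity, manifest=manifest,
    )
    if config.output_dir:
        _write_artifacts(result, Path(config.output_dir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(result.matrix, outdir / "cohort.tsv")
    result.screen.to_csv(outdir / "marker_screen.tsv", sep="\t")
    result.grnn_model.to_json(outdir / "grnn_model.json")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(result.ground_truth, fh, indent=1)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1)
    if result.sensitivity is not None:
        result.sensitivity.table.to_csv(outdir / "sensitivity.tsv", sep="\t")


# ---------------------------------------------------------------------------
# External cohort evaluations
# ---------------------------------------------------------------------------


def evaluate_twins(model: GRNNModel, twin_matrix: pd.DataFrame) -> dict:
    """Blind predictions for twin pairs.

    Reports per-sample errors, the within-pair prediction difference
    (mean ± SD) and a paired t-test across pair members. Identical
    predictions within every pair make the t-test degenerate; this is
    reported as p=1 with a flag.
    """
    if "pair_id" not in twin_matrix.columns:
        raise PipelineError("twin matrix lacks pair_id labels")
    sizes = twin_matrix.groupby("pair_id").size()
    odd = sizes[sizes != 2]
    if len(odd):
        raise PipelineError(f"unpaired twin samples in pairs: {list(odd.index)}")
    pred = grnn_predict(model, twin_matrix)
    frame = twin_matrix[["age", "pair_id"]].copy()
    frame["predicted"] = pred
    report = evaluate_predictions(frame["age"], frame["predicted"])
    ordered = frame.sort_values("pair_id", kind="stable")
    first = ordered.iloc[0::2]["predicted"].to_numpy()
    second = ordered.iloc[1::2]["predicted"].to_numpy()
    diffs = np.abs(first - second)
    degenerate = bool(np.allclose(first, second))
    if degenerate:
        t_p = 1.0
    else:
        t_p = float(sps.ttest_rel(first, second).pvalue)
    return {
        "n_pairs": int(len(first)),
        "mae": report.mae,
        "sd_abs_error": report.sd_abs_error,
        "within_pair_diff_mean": float(diffs.mean()),
        "within_pair_diff_sd": float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0,
        "paired_t_p": t_p,
        "degenerate_t_test": degenerate,
        "per_sample": frame,
    }


def evaluate_cohorts(model: GRNNModel, cohorts: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-cohort MAE/R² table (healthy vs disease vs blood disease, etc.)."""
    rows = []
    for label, matrix in cohorts.items():
        if matrix is None or len(matrix) == 0:
            warnings.warn(f"cohort {label!r} is empty: skipped")
            continue
        missing = [c for c in model.input_cpgs if c not in matrix.columns]
        if missing:
            raise PipelineError(f"cohort {label!r} missing model CpGs: {missing}")
        pred = grnn_predict(model, matrix)
        report = evaluate_predictions(matrix["age"], pred)
        rows.append(
            dict(cohort=label, n=report.n, mae=report.mae,
                 r_squared=report.r_squared, within_10yr=report.within_10yr)
        )
    return pd.DataFrame(rows).set_index("cohort")


# ---------------------------------------------------------------------------
# NGS validation loop
# ---------------------------------------------------------------------------


def simulate_ngs_batches(
    panel: MarkerPanel,
    donor_betas: pd.DataFrame,
    n_replicates: int = 3,
    n_fragments: int = 2000,
    conversion_rate: float = 0.99,
    seq_error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list]:
    """Triplicate read batches per donor from their true marker betas.

    ``donor_betas`` rows are donors, columns are the panel's marker ids
    (the value is used for every CpG of that amplicon).
    """
    rng = np.random.default_rng(seed)
    batches: dict[str, list] = {}
    for donor, row in donor_betas.iterrows():
        true = {m: float(row[m]) for m in panel.amplicons if m in row.index}
        batches[donor] = [
            simulate_reads(
                panel, true, n_fragments=n_fragments,
                conversion_rate=conversion_rate, seq_error_rate=seq_error_rate,
                seed=int(rng.integers(0, 2**31 - 1)), sample_id=f"{donor}r{rep}",
            )
            for rep in range(n_replicates)
        ]
    return batches


def iter_ngs_batches(
    panel: MarkerPanel,
    donor_betas: pd.DataFrame,
    n_replicates: int = 3,
    n_fragments: int = 2000,
    conversion_rate: float = 0.99,
    seq_error_rate: float = 0.0,
    seed: int = 0,
):
    """Lazy variant of :func:`simulate_ngs_batches`: yields one donor's
    triplicate batches at a time (memory stays flat for large panels)."""
    rng = np.random.default_rng(seed)
    for donor, row in donor_betas.iterrows():
        true = {m: float(row[m]) for m in panel.amplicons if m in row.index}
        yield donor, [
            simulate_reads(
                panel, true, n_fragments=n_fragments,
                conversion_rate=conversion_rate, seq_error_rate=seq_error_rate,
                seed=int(rng.integers(0, 2**31 - 1)), sample_id=f"{donor}r{rep}",
            )
            for rep in range(n_replicates)
        ]


def ngs_validation_loop(
    model: GRNNModel,
    panel: MarkerPanel,
    replicate_batches,
    reference_matrix: pd.DataFrame | None = None,
    true_ages: dict[str, float] | pd.Series | None = None,
    standard_curves: dict | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    require_all_markers: bool = True,
) -> dict:
    """Quantify replicates, average, harmonise onto the array scale, predict.

    Per donor: each replicate FASTQ batch is quantified; per marker the
    target-CpG corrected beta is averaged over replicates that pass the
    coverage filter (a failing replicate is dropped with a warning; a
    marker failing in all replicates refuses the prediction by default).
    Averaged betas go through the standard curves (when given) and, when a
    reference matrix is supplied, the array mean-shift harmonisation, then
    into the model as a blind test.

    ``replicate_batches`` is a mapping donor → list of read batches, or a
    lazy iterable of (donor, batches) pairs (batches are consumed donor by
    donor, keeping memory flat for large validation sets).
    """
    rows = {}
    items = (
        replicate_batches.items()
        if hasattr(replicate_batches, "items")
        else replicate_batches
    )
    for donor, batches in items:
        per_marker: dict[str, list[float]] = {m: [] for m in panel.amplicons}
        for batch in batches:
            calls = quantify(batch, panel, min_reads=min_reads)
            targets = calls[calls["is_target"]]
            for _, row in targets.iterrows():
                if row["pass_coverage"] and not np.isnan(row["corrected_beta"]):
                    per_marker[row["marker"]].append(float(row["corrected_beta"]))
                else:
                    warnings.warn(
                        f"{donor}: replicate failed coverage for {row['marker']}"
                    )
        betas = {}
        failed = [m for m, v in per_marker.items() if not v]
        if failed:
            if require_all_markers:
                raise PipelineError(
                    f"{donor}: all replicates failed coverage for markers {failed}"
                )
            warnings.warn(f"{donor}: no passing replicate for {failed}")
        for m, values in per_marker.items():
            if values:
                betas[m] = float(np.mean(values))
        if standard_curves:
            betas = {
                m: apply_standard_curve(standard_curves[m], b)
                if m in standard_curves else b
                for m, b in betas.items()
            }
        rows[donor] = betas
    ngs_frame = pd.DataFrame.from_dict(rows, orient="index")
    if reference_matrix is not None:
        harmonised = ngs_to_array_normalize(ngs_frame, reference_matrix)
    else:
        harmonised = ngs_frame
    predictions = grnn_predict(model, harmonised)
    result = {
        "betas": ngs_frame,
        "harmonised": harmonised,
        "predicted": pd.Series(predictions, index=ngs_frame.index),
    }
    if true_ages is not None:
        ages = pd.Series(true_ages).loc[ngs_frame.index]
        result["report"] = evaluate_predictions(ages, predictions)
    return result


def fit_standard_curves_from_reads(
    panel: MarkerPanel,
    levels=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_fragments: int = 2000,
    conversion_rate: float = 0.99,
    seed: int = 0,
) -> dict:
    """Standard curves from simulated known-methylation standards."""
    observed: dict[str, list[float]] = {m: [] for m in panel.amplicons}
    rng = np.random.default_rng(seed)
    for level in levels:
        batch = simulate_reads(
            panel, {m: level for m in panel.amplicons}, n_fragments=n_fragments,
            conversion_rate=conversion_rate, seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=f"std{int(level * 100)}",
        )
        calls = quantify(batch, panel, min_reads=1)
        targets = calls[calls["is_target"]].set_index("marker")
        for m in panel.amplicons:
            observed[m].append(float(targets.loc[m, "corrected_beta"]))
    return {
        m: fit_standard_curve(np.asarray(levels), np.asarray(observed[m]), cpg_id=m)
        for m in panel.amplicons
    }
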