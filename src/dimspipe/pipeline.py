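"""End-to-end pipeline orchestration and the machine-checkable QA checklist.

The pipeline produces the dataset series of the benchmark workflow:
per-replicate stitched peak lists (SPL) are collapsed per sample (RFPL),
aligned into a raw matrix, filtered (blank, sample, missing-value — with
the blank and sample filters repeated after missing-value exclusion) into
the sample-filtered peak matrix (SFPM), and then processed along three
branches of increasing complexity:

* branch a: PQN -> KNN -> GLOG                   (no batch correction)
* branch b: PQN -> BATCH -> KNN -> GLOG
* branch c: PQN -> BATCH -> CLEAN -> KNN -> GLOG

Every stage's matrix is written as a data/meta/peak text triple under the
output directory, along with the provenance log, batch-fit and cleaning
tables and a QC report per branch.  A run is a pure function of (input,
config, seed): rerunning with the same seed reproduces the artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import PeakMatrix, RunConfig
from .filtering import (
    align_samples,
    blank_filter,
    missing_value_filter,
    replicate_filter,
    sample_filter,
)
from .io_formats import read_spl, write_matrix, write_provenance
from .normalize_correct import (
    batchfits_to_frame,
    cleaning_to_frame,
    glog,
    knn_impute,
    pqn,
    qc_rsc,
    spectral_clean,
)
from .qc_metrics import QCReport, qc_report
from .synthetic_data import StudyDesign, TruthParams, make_design, simulate_matrix

STAGE_NAMES = {
    "sfpm": "SFPM",
    "a_pqn": "SFPM_PQN",
    "a_knn": "SFPM_PQN_KNN",
    "a_glog": "SFPM_PQN_KNN_GLOG",
    "b_batch": "SFPM_PQN_BATCH",
    "b_knn": "SFPM_PQN_BATCH_KNN",
    "b_glog": "SFPM_PQN_BATCH_KNN_GLOG",
    "c_clean": "SFPM_PQN_BATCH_CLEAN",
    "c_knn": "SFPM_PQN_BATCH_CLEAN_KNN",
    "c_glog": "SFPM_PQN_BATCH_CLEAN_KNN_GLOG",
}


@dataclass
class PipelineResult:
    """All stage artifacts of one run, keyed as in :data:`STAGE_NAMES`."""

    config: RunConfig
    matrices: dict = field(default_factory=dict)   # stage key -> PeakMatrix
    reports: dict = field(default_factory=dict)    # branch -> QCReport
    batch_fits: pd.DataFrame | None = None
    cleaning: pd.DataFrame | None = None
    pre_filter_matrix: PeakMatrix | None = None    # aligned matrix incl. blanks
    removed_samples: list = field(default_factory=list)
    rfpls: dict = field(default_factory=dict)


def _filter_matrix(raw: PeakMatrix, config: RunConfig) -> tuple[PeakMatrix, list[str]]:
    """Blank + sample + missing-value filtering, with the blank and sample
    filters repeated after missing-value exclusion."""
    has_blanks = bool(raw.blank_ids)
    pm = raw
    if has_blanks:
        pm = blank_filter(pm, ratio=config.blank_ratio, drop_blanks=False)
    pm = sample_filter(pm, presence=config.sample_presence)
    pm, removed = missing_value_filter(pm, sd_mult=config.missing_sd_mult)
    if has_blanks:
        pm = blank_filter(pm, ratio=config.blank_ratio, drop_blanks=True)
    pm = sample_filter(pm, presence=config.sample_presence)
    return pm, removed


def _run_branches(result: PipelineResult, sfpm: PeakMatrix, config: RunConfig) -> None:
    mats = result.matrices
    mats["sfpm"] = sfpm
    normalized = pqn(sfpm)
    mats["a_pqn"] = normalized
    mats["a_knn"] = knn_impute(normalized, k=config.knn_k)
    mats["a_glog"] = glog(mats["a_knn"], lam=config.glog_lambda)

    if not normalized.qc_ids:
        raise RuntimeError(
            "batch-correction stage requires QC samples, but none remain in "
            "the matrix; check the study design and upstream filters"
        )
    corrected, fits = qc_rsc(normalized)
    result.batch_fits = batchfits_to_frame(fits)
    mats["b_batch"] = corrected
    mats["b_knn"] = knn_impute(corrected, k=config.knn_k)
    mats["b_glog"] = glog(mats["b_knn"], lam=config.glog_lambda)

    cleaned, records = spectral_clean(
        corrected, kw_alpha=config.kw_alpha, wsr_alpha=config.wsr_alpha,
        rsd_max=config.rsd_max,
    )
    result.cleaning = cleaning_to_frame(records)
    mats["c_clean"] = cleaned
    mats["c_knn"] = knn_impute(cleaned, k=config.knn_k)
    mats["c_glog"] = glog(mats["c_knn"], lam=config.glog_lambda)

    result.reports["a"] = qc_report(mats["a_pqn"], pca_matrix=mats["a_glog"])
    result.reports["b"] = qc_report(mats["b_batch"], pca_matrix=mats["b_glog"])
    result.reports["c"] = qc_report(mats["c_clean"], pca_matrix=mats["c_glog"])


def run_pipeline(
    config: RunConfig | None = None,
    source: str = "simulate",
    outdir=None,
    design: StudyDesign | None = None,
    truth_params: TruthParams | None = None,
    spl_files: dict | None = None,
    samples: pd.DataFrame | None = None,
    matrix: PeakMatrix | None = None,
) -> PipelineResult:
    """Run the full workflow from one of three entry points.

    ``source`` selects the input: ``"simulate"`` generates a study with
    the built-in generator (using ``design``/``truth_params`` or their
    defaults and ``config.seed``); ``"spl"`` starts from per-replicate
    stitched peak lists (``spl_files``: sample_id -> list of SPL paths,
    plus the ``samples`` metadata table); ``"matrix"`` starts from an
    aligned raw matrix (``matrix``).  Stage artifacts are written under
    ``outdir`` when given.
    """
    config = config or RunConfig()
    result = PipelineResult(config=config)

    if source == "simulate":
        design = design or make_design(seed=config.seed)
        raw, _truth = simulate_matrix(design, truth_params, seed=config.seed)
    elif source == "spl":
        if spl_files is None or samples is None:
            raise ValueError("spl source requires spl_files and samples")
        rfpls = {}
        for sid, paths in spl_files.items():
            pls = [read_spl(p, sample_id=sid, replicate_index=i + 1)
                   for i, p in enumerate(paths)]
            rfpls[sid] = replicate_filter(
                pls, mz_tolerance_ppm=config.mz_tolerance_ppm,
                min_present=config.replicate_min,
            )
        result.rfpls = rfpls
        raw = align_samples(rfpls, samples, mz_tolerance_ppm=config.mz_tolerance_ppm)
    elif source == "matrix":
        if matrix is None:
            raise ValueError("matrix source requires a matrix")
        raw = matrix
    else:
        raise ValueError(f"unknown source {source!r}")

    result.pre_filter_matrix = raw
    sfpm, removed = _filter_matrix(raw, config)
    result.removed_samples = removed
    _run_branches(result, sfpm, config)

    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def write_artifacts(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, pm in result.matrices.items():
        name = STAGE_NAMES[key]
        write_matrix(
            pm,
            outdir / f"{name}_data.tsv",
            outdir / f"{name}_meta.tsv",
            outdir / f"{name}_peak.tsv",
        )
    final = result.matrices["c_glog"]
    write_provenance(final.history, outdir / "provenance.tsv")
    if result.batch_fits is not None:
        result.batch_fits.to_csv(outdir / "batch_fits.tsv", sep="\t", index=False)
    if result.cleaning is not None:
        result.cleaning.to_csv(outdir / "cleaning_report.tsv", sep="\t", index=False)
    for branch, report in result.reports.items():
        rows = [{"batch": b, "median_rsd_qc": v}
                for b, v in report.per_batch_rsd_qc.items()]
        rows.append({"batch": "all", "median_rsd_qc": report.overall_rsd_qc})
        pd.DataFrame(rows).to_csv(
            outdir / f"qc_rsd_{branch}.tsv", sep="\t", index=False
        )
        report.per_group_rsd_biol.rename("median_rsd_biol").to_csv(
            outdir / f"biol_rsd_{branch}.tsv", sep="\t"
        )
        if report.pca is not None:
            report.pca.to_csv(outdir / f"pca_scores_{branch}.tsv", sep="\t")
    result.config.to_yaml(outdir / "config.yaml")


# ---------------------------------------------------------------------------
# Eight-step QA checklist
# ---------------------------------------------------------------------------

def checklist(
    result: PipelineResult,
    esi_failures: set | None = None,
    tic_outliers: set | None = None,
) -> dict[str, bool]:
    """Verify the eight quality criteria on a completed run.

    Checks that no electrospray failure or TIC outlier survived, that
    every retained peak met the replicate rule (when peak lists were the
    input), the sample-presence rule, the blank-ratio rule, that the
    missing-value threshold was enforced, that batch correction ran, and
    that every feature surviving spectral cleaning has QC RSD within the
    ceiling.  Returns {check name: pass}.
    """
    if not result.matrices:
        raise ValueError("empty artifact set: run the pipeline first")
    config = result.config
    sfpm = result.matrices["sfpm"]
    retained = set(sfpm.samples.index)
    checks: dict[str, bool] = {}

    checks["electrospray"] = not (esi_failures and esi_failures & retained)
    checks["tic_outliers"] = not (tic_outliers and tic_outliers & retained)

    if result.rfpls:
        checks["replicate_rule"] = all(
            (pl.num_spectra >= config.replicate_min).all()
            for pl in result.rfpls.values()
        )
    else:
        checks["replicate_rule"] = True

    bios = sfpm.biological_ids
    frac = sfpm.intensities.loc[bios].notna().mean(axis=0)
    checks["sample_presence"] = bool((frac >= config.sample_presence - 1e-12).all())

    pre = result.pre_filter_matrix
    if pre is not None and pre.blank_ids:
        blanks, bios_pre = pre.blank_ids, pre.biological_ids
        shared = [c for c in sfpm.intensities.columns if c in pre.intensities.columns]
        blank_med = pre.intensities.loc[blanks, shared].median(axis=0, skipna=True)
        bio_med = pre.intensities.loc[bios_pre, shared].median(axis=0, skipna=True)
        seen = pre.intensities.loc[blanks, shared].notna().any(axis=0)
        violation = seen & (blank_med >= config.blank_ratio * bio_med)
        checks["blank_rule"] = not bool(violation.any())
    else:
        checks["blank_rule"] = True

    # the filter is single-pass: enforce that every sample it flagged is gone
    # and that the filter stage actually ran
    ran = any(h.stage == "missing_value_filter" for h in sfpm.history)
    checks["missing_value_threshold"] = ran and not (
        set(result.removed_samples) & retained
    )

    checks["batch_correction"] = any(
        h.stage == "qc_rsc" for h in result.matrices["b_batch"].history
    )

    cleaned = result.matrices["c_clean"]
    qcs = cleaned.qc_ids
    if qcs:
        sub = cleaned.intensities.loc[qcs]
        n = sub.notna().sum(axis=0)
        rsd = 100.0 * sub.std(axis=0, ddof=1) / sub.mean(axis=0)
        checks["spectral_cleaning"] = bool(
            (rsd[n >= 3] <= config.rsd_max + 1e-9).all()
        )
    else:
        checks["spectral_cleaning"] = False
    return checks
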