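"""Quality-assessment metrics: RSD summaries, missing-value profiles, PCA.

The study's reproducibility surface rests on two relative-standard-
deviation summaries, both reported as percentages:

* median RSD over QC samples (RSD over the pooled-QC injections of each
  feature, summarised by the median over features) — per batch and pooled
  over all batches.  The pooled value exceeding the per-batch values is
  the signature of batch-to-batch drift; batch correction should pull it
  back toward the within-batch level.
* median RSD over repeated biological measurements — each biological
  sample is measured once per batch, so its repeat group supplies an
  independent check on any QC-driven correction.

All metrics use the n-1 standard deviation and exclude features with
fewer than three observations in the relevant subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PeakMatrix


def rsd_per_feature(
    pm: PeakMatrix, sample_ids: list[str], min_n: int = 3
) -> pd.Series:
    """Per-feature RSD (%) over a sample subset; NaN below ``min_n`` obs."""
    if not sample_ids:
        raise ValueError("empty sample subset")
    sub = pm.intensities.loc[sample_ids]
    n = sub.notna().sum(axis=0)
    mean = sub.mean(axis=0, skipna=True)
    sd = sub.std(axis=0, ddof=1, skipna=True)
    rsd = 100.0 * sd / mean
    rsd[n < min_n] = np.nan
    return rsd


def median_rsd_qc(pm: PeakMatrix, min_n: int = 3) -> tuple[dict[int, float], float]:
    """Median QC RSD per batch and pooled over all batches."""
    qcs = pm.qc_ids
    if not qcs:
        raise ValueError("no QC samples in the matrix")
    per_batch: dict[int, float] = {}
    for b in sorted(pm.samples["batch"].unique()):
        ids = [s for s in qcs if pm.samples.loc[s, "batch"] == b]
        if not ids:
            per_batch[int(b)] = np.nan
            continue
        rsd = rsd_per_feature(pm, ids, min_n=min_n)
        per_batch[int(b)] = float(rsd.median(skipna=True))
    overall = float(rsd_per_feature(pm, qcs, min_n=min_n).median(skipna=True))
    return per_batch, overall


def rsd_biol(pm: PeakMatrix, min_n: int = 3) -> tuple[pd.Series, float]:
    """Median RSD per biological repeat group, and their mean.

    Each repeat group links the repeated measurements (one per batch) of
    one biological sample; groups with fewer than three surviving
    measurements are reported as NaN and excluded from the mean.
    """
    bios = pm.biological_ids
    groups = pm.samples.loc[bios, "repeat_group"]
    medians = {}
    for g in sorted(groups.unique()):
        ids = list(groups.index[groups == g])
        if len(ids) < min_n:
            medians[g] = np.nan
            continue
        rsd = rsd_per_feature(pm, ids, min_n=min_n)
        medians[g] = float(rsd.median(skipna=True))
    series = pd.Series(medians).sort_index()
    return series, float(series.mean(skipna=True))


def missing_profile(
    pm: PeakMatrix, sd_mult: float = 2.0
) -> tuple[pd.Series, float]:
    """Per-sample missing percentage (QC + biological) and the exclusion
    threshold mean + ``sd_mult`` SD."""
    ids = [s for s in pm.samples.index
           if pm.samples.loc[s, "sample_type"] in ("QC", "biological")]
    pct = pm.intensities.loc[ids].isna().mean(axis=1) * 100.0
    sd = pct.std(ddof=1)
    thr = float(pct.mean() + sd_mult * (sd if np.isfinite(sd) else 0.0))
    return pct, thr


def pca_scores(
    pm: PeakMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean-centred PCA scores with a deterministic sign convention.

    The matrix must be imputed (no missing cells).  Columns are mean
    centred but not variance scaled (the preceding glog already
    stabilises variance); scores come from the SVD, and each component is
    signed so that its largest-magnitude loading is positive.  Returns the
    scores (samples x components) and the explained-variance ratios.
    """
    X = pm.intensities.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA requires an imputed matrix")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    for i in range(n_components):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u[:, :n_components] * s[:n_components]
    var = s**2 / (X.shape[0] - 1)
    explained = var[:n_components] / var.sum()
    frame = pd.DataFrame(
        scores, index=pm.intensities.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, explained


@dataclass
class QCReport:
    """The full quality-assessment surface for one processed matrix."""

    per_batch_rsd_qc: dict[int, float]
    overall_rsd_qc: float
    per_group_rsd_biol: pd.Series
    mean_rsd_biol: float
    missing_pct: pd.Series
    missing_threshold: float
    pca: pd.DataFrame | None = None
    explained_variance: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def qc_report(
    pm: PeakMatrix, pca_matrix: PeakMatrix | None = None, n_components: int = 2
) -> QCReport:
    """Assemble the QC report; PCA runs on ``pca_matrix`` when given
    (typically the imputed + glog matrix) and is skipped otherwise unless
    ``pm`` itself is complete."""
    per_batch, overall = median_rsd_qc(pm)
    per_group, mean_biol = rsd_biol(pm)
    pct, thr = missing_profile(pm)
    scores = explained = None
    target = pca_matrix if pca_matrix is not None else pm
    if not target.intensities.isna().any().any():
        scores, explained = pca_scores(target, n_components=n_components)
    return QCReport(
        per_batch_rsd_qc=per_batch,
        overall_rsd_qc=overall,
        per_group_rsd_biol=per_group,
        mean_rsd_biol=mean_biol,
        missing_pct=pct,
        missing_threshold=thr,
        pca=scores,
        explained_variance=explained,
    )
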