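"""Normalisation, QC-based batch correction, spectral cleaning, imputation
and variance stabilisation.

* :func:`pqn` — probabilistic quotient normalisation against the QC median
  spectrum, removing per-sample dilution differences.
* :func:`qc_rsc` — QC-robust-spline correction: per feature and batch, a
  smooth trend is fitted to the QC intensities versus injection order and
  divided out, then batches are re-scaled to a common QC level.  This
  removes both within-batch drift and batch-to-batch level shifts.
* :func:`spectral_clean` — three feature-rejection rules applied after
  batch correction: (1) the QC-to-biological intensity ratio is
  inconsistent between batches (Kruskal-Wallis, alpha 1e-4); (2) the QC
  level is far from the biological level overall (Wilcoxon signed rank,
  alpha 1e-14); (3) the QC relative standard deviation exceeds 20%.
* :func:`knn_impute` — K-nearest-neighbour imputation of missing cells in
  sample space (k=5, distance-weighted, standardised features).
* :func:`glog` — generalised logarithm y = ln((x + sqrt(x^2 + lambda))/2),
  with lambda optionally chosen to decouple QC spread from QC mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from sklearn.impute import KNNImputer

from .core import PeakMatrix


# ---------------------------------------------------------------------------
# PQN
# ---------------------------------------------------------------------------

def pqn(pm: PeakMatrix, min_shared: int = 10, return_factors: bool = False):
    """Probabilistic quotient normalisation against the QC median spectrum.

    The reference spectrum is the per-feature median over the QC samples
    (missing excluded).  Each sample is divided by the median of its
    intensity/reference quotients over co-observed features, so a uniformly
    double-concentrated sample is scaled by exactly 2.  Missing cells stay
    missing.  Samples sharing fewer than ``min_shared`` features with the
    reference are still normalised from what is available, with a warning.
    """
    qcs = pm.qc_ids
    if not qcs:
        raise ValueError("PQN requires at least one QC sample for the reference")
    reference = pm.intensities.loc[qcs].median(axis=0, skipna=True)
    factors = pd.Series(1.0, index=pm.intensities.index)
    data = pm.intensities.copy()
    for sid in data.index:
        row = data.loc[sid]
        shared = row.notna() & reference.notna() & (reference > 0)
        n_shared = int(shared.sum())
        if n_shared == 0:
            warnings.warn(f"sample {sid}: no features shared with the PQN reference",
                          stacklevel=2)
            continue
        if n_shared < min_shared:
            warnings.warn(
                f"sample {sid}: only {n_shared} features shared with the PQN "
                "reference; factor estimated from those", stacklevel=2,
            )
        factors[sid] = float((row[shared] / reference[shared]).median())
        data.loc[sid] = row / factors[sid]
    out = PeakMatrix(data, pm.samples.copy(), list(pm.history))
    out.log("pqn", (), "probabilistic quotient normalisation (QC median reference)")
    if return_factors:
        return out, factors
    return out


# ---------------------------------------------------------------------------
# QC-RSC batch correction
# ---------------------------------------------------------------------------

@dataclass
class BatchFit:
    """Fit summary for one (feature, batch) correction."""

    feature_mz: float
    batch: int
    mpa: float                  # median peak intensity of the batch's QCs
    model: str                  # constant / linear / spline(s=...)
    status: str                 # corrected / fallback-median / uncorrectable


class _TrendModel:
    """Candidate QC-trend models of increasing flexibility, fit on log scale."""

    def __init__(self, kind: str, s_frac: float | None = None):
        self.kind = kind
        self.s_frac = s_frac

    def fit(self, x: np.ndarray, y: np.ndarray):
        if self.kind == "constant":
            c = float(np.median(y))
            return lambda t: np.full_like(np.asarray(t, float), c)
        if self.kind == "linear":
            coef = np.polyfit(x, y, 1)
            return lambda t: np.polyval(coef, np.asarray(t, float))
        # smoothing spline; s is a fraction of the linear-fit residual RSS
        m = len(x)
        k = min(3, m - 1)
        resid = y - np.polyval(np.polyfit(x, y, 1), x)
        rss = float(resid @ resid)
        s = max(rss * self.s_frac, 1e-12)
        spl = UnivariateSpline(x, y, k=k, s=s)
        return lambda t: spl(np.asarray(t, float))

    def __repr__(self):
        if self.kind == "spline":
            return f"spline(s_frac={self.s_frac})"
        return self.kind


# ordered smooth -> flexible; ties in cross-validation go to the smoother fit
_CANDIDATES = [
    _TrendModel("constant"),
    _TrendModel("linear"),
    _TrendModel("spline", 0.5),
    _TrendModel("spline", 0.1),
]


def _select_trend(x: np.ndarray, y: np.ndarray):
    """Leave-one-out cross-validation over the candidate trend models.

    Uses the one-standard-error rule: among the candidates, the smoothest
    one whose CV error is within one standard error of the minimum wins.
    This keeps drift-free (null) data on the constant model instead of
    letting a flexible spline chase noise.
    """
    n = len(x)
    results = []
    for cand in _CANDIDATES:
        if cand.kind == "spline" and n < 5:
            continue  # LOO would leave too few points for a cubic
        errs = []
        ok = True
        for i in range(n):
            mask = np.arange(n) != i
            try:
                pred = cand.fit(x[mask], y[mask])(x[i])
            except Exception:
                ok = False
                break
            errs.append((float(pred) - y[i]) ** 2)
        if not ok:
            continue
        errs = np.asarray(errs)
        se = float(errs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        results.append((cand, float(errs.mean()), se))
    if not results:
        return _CANDIDATES[0]
    best_mean, best_se = min((m, s) for _, m, s in results)
    for cand, mean, _ in results:  # candidates ordered smooth -> flexible
        if mean <= best_mean + best_se:
            return cand
    return results[0][0]


def dedup_consecutive_qcs(samples: pd.DataFrame) -> list[str]:
    """QC ids to use for trend fitting: consecutive same-batch QCs are
    collapsed to the first, to avoid over-weighting the spline ends."""
    ordered = samples.sort_values("run_order")
    keep: list[str] = []
    prev_was_qc = False
    prev_batch = None
    for sid, row in ordered.iterrows():
        if row["sample_type"] == "QC":
            if not (prev_was_qc and row["batch"] == prev_batch):
                keep.append(sid)
            prev_was_qc = True
        else:
            prev_was_qc = False
        prev_batch = row["batch"]
    return keep


def qc_rsc(
    pm: PeakMatrix,
    min_qc: int = 4,
) -> tuple[PeakMatrix, list[BatchFit]]:
    """QC-robust-spline batch correction.

    Per feature and batch, a trend is fitted to the batch's QC log
    intensities versus run order — the model (constant, linear or cubic
    smoothing spline) and its smoothing weight are selected by
    leave-one-out cross-validation over that batch's QCs, with ties broken
    toward the smoother candidate.  Every sample in the batch is divided by
    the trend at its run order (clipped to the QC-anchored range) and
    re-scaled to the batch QC median (MPA); batches are then aligned by
    scaling each so its corrected QC median equals the overall corrected QC
    median.  Batches with fewer than ``min_qc`` usable QC values fall back
    to constant median scaling; a feature with no QC data anywhere is left
    unchanged and flagged uncorrectable.
    """
    qcs = pm.qc_ids
    if not qcs:
        raise ValueError("QC-RSC requires QC samples")
    fit_qcs = [s for s in dedup_consecutive_qcs(pm.samples) if s in pm.intensities.index]
    run_order = pm.samples["run_order"]
    batches = sorted(pm.samples["batch"].unique())
    data = pm.intensities.copy()
    values = data.to_numpy(copy=True)
    col_index = {c: j for j, c in enumerate(data.columns)}
    row_index = {s: i for i, s in enumerate(data.index)}

    fits: list[BatchFit] = []
    uncorrectable: list[float] = []
    qc_rows_all = np.array([row_index[s] for s in qcs])
    # per-batch index structures, hoisted out of the per-feature loop
    batch_info = []
    for b in batches:
        batch_ids = list(pm.samples.index[pm.samples["batch"] == b])
        rows = np.array([row_index[s] for s in batch_ids])
        qc_fit_ids = [s for s in fit_qcs if pm.samples.loc[s, "batch"] == b]
        fit_rows = np.array([row_index[s] for s in qc_fit_ids], dtype=int)
        fit_x = np.array([run_order[s] for s in qc_fit_ids], dtype=float)
        batch_qcs = [s for s in qcs if pm.samples.loc[s, "batch"] == b]
        qc_rows = np.array([row_index[s] for s in batch_qcs], dtype=int)
        t_all = run_order[batch_ids].to_numpy(float)
        batch_info.append((int(b), rows, fit_rows, fit_x, qc_rows, t_all))

    for feat in data.columns:
        j = col_index[feat]
        col = values[:, j]
        if np.all(np.isnan(col[qc_rows_all])):
            uncorrectable.append(feat)
            for b, *_ in batch_info:
                fits.append(BatchFit(feat, b, np.nan, "none", "uncorrectable"))
            continue
        corrected = col.copy()
        for b, rows, fit_rows, fit_x, qc_rows, t_all in batch_info:
            qc_y = col[fit_rows] if fit_rows.size else np.array([])
            obs = ~np.isnan(qc_y)
            qc_x, qc_y = fit_x[obs], qc_y[obs]
            mpa_vals = col[qc_rows] if qc_rows.size else np.array([])
            mpa = float(np.nanmedian(mpa_vals)) if mpa_vals.size and not np.all(
                np.isnan(mpa_vals)) else np.nan
            if qc_x.size >= min_qc:
                order = np.argsort(qc_x)
                qc_x, qc_y = qc_x[order], qc_y[order]
                model = _select_trend(qc_x, np.log(qc_y))
                trend_fn = model.fit(qc_x, np.log(qc_y))
                t = np.clip(t_all, qc_x[0], qc_x[-1])
                trend = np.exp(trend_fn(t))
                corrected[rows] = col[rows] / trend * mpa
                fits.append(BatchFit(feat, b, mpa, repr(model), "corrected"))
            elif qc_x.size >= 1:
                med = float(np.median(qc_y))
                corrected[rows] = col[rows] / med * mpa
                fits.append(BatchFit(feat, b, mpa, "constant", "fallback-median"))
            else:
                fits.append(BatchFit(feat, b, mpa, "none", "uncorrectable"))
        # inter-batch alignment to the overall QC median
        qc_corr = corrected[qc_rows_all]
        overall = np.nanmedian(qc_corr) if not np.all(np.isnan(qc_corr)) else np.nan
        if np.isfinite(overall):
            for b, rows, _, _, qc_rows, _ in batch_info:
                if not qc_rows.size or np.all(np.isnan(corrected[qc_rows])):
                    continue
                m_b = np.nanmedian(corrected[qc_rows])
                if np.isfinite(m_b) and m_b > 0:
                    corrected[rows] *= overall / m_b
        values[:, j] = corrected

    out_data = pd.DataFrame(values, index=data.index, columns=data.columns)
    out = PeakMatrix(out_data, pm.samples.copy(), list(pm.history))
    out.log(
        "qc_rsc", uncorrectable,
        "QC-robust-spline batch correction; listed features uncorrectable",
    )
    return out, fits


def batchfits_to_frame(fits: list[BatchFit]) -> pd.DataFrame:
    """Tabulate batch-correction fits (feature m/z, per-batch MPA, model)."""
    return pd.DataFrame(
        [
            {"mz": f.feature_mz, "batch": f.batch, "mpa": f.mpa,
             "model": f.model, "status": f.status}
            for f in fits
        ]
    )


# ---------------------------------------------------------------------------
# Spectral cleaning
# ---------------------------------------------------------------------------

@dataclass
class CleaningRecord:
    feature_mz: float
    rule: str           # batch-inconsistency / qc-bias / high-rsd
    statistic: float
    value: float        # p-value for the rank tests, RSD for rule 3


def spectral_clean(
    pm: PeakMatrix,
    kw_alpha: float = 1e-4,
    wsr_alpha: float = 1e-14,
    rsd_max: float = 20.0,
) -> tuple[PeakMatrix, list[CleaningRecord]]:
    """Remove unreliable features after batch correction.

    Rule 1 (batch inconsistency): for each feature, QC intensities are
    divided by their batch's biological median and grouped by batch; a
    Kruskal-Wallis test p-value below ``kw_alpha`` indicates the
    QC/biological relationship differs between batches (e.g. the peak was
    not truly detected in the QCs of some batch) and the feature is
    removed.  Rule 2 (QC bias): a Wilcoxon signed-rank test of the QC
    intensities against the overall biological median below ``wsr_alpha``
    indicates the QCs do not represent the biological average.  Rule 3:
    the feature's QC relative standard deviation exceeds ``rsd_max`` %.
    Rules run in order 1-2-3 and only the first trigger is recorded.
    Degenerate inputs (zero variance, all-tied ranks) retain the feature.
    """
    qcs = pm.qc_ids
    bios = pm.biological_ids
    if not qcs or not bios:
        raise ValueError("spectral cleaning requires QC and biological samples")
    batches = sorted(pm.samples["batch"].unique())
    records: list[CleaningRecord] = []
    removed: list[float] = []
    qc_frame = pm.intensities.loc[qcs]
    bio_frame = pm.intensities.loc[bios]
    qc_batch = pm.samples.loc[qcs, "batch"]
    bio_batch = pm.samples.loc[bios, "batch"]

    for feat in pm.intensities.columns:
        qc_vals = qc_frame[feat]
        bio_vals = bio_frame[feat]

        # rule 1: per-batch QC / biological-median ratios
        groups = []
        for b in batches:
            bv = bio_vals[bio_batch == b].dropna()
            qv = qc_vals[qc_batch == b].dropna()
            if len(qv) == 0:
                continue  # batch with no QC observations is excluded
            bmed = bv.median() if len(bv) else np.nan
            if not np.isfinite(bmed) or bmed <= 0:
                continue
            groups.append((qv / bmed).to_numpy())
        if len(groups) >= 2:
            flat = np.concatenate(groups)
            if np.ptp(flat) > 0:
                try:
                    stat, p = stats.kruskal(*groups)
                except ValueError:
                    stat, p = np.nan, 1.0
                if p < kw_alpha:
                    removed.append(feat)
                    records.append(CleaningRecord(feat, "batch-inconsistency", stat, p))
                    continue

        # rule 2: QC level vs the overall biological median
        overall_bio = bio_vals.dropna().median()
        diffs = (qc_vals.dropna() - overall_bio).to_numpy()
        diffs = diffs[diffs != 0]
        if np.isfinite(overall_bio) and diffs.size >= 1 and np.ptp(diffs) >= 0:
            try:
                stat, p = stats.wilcoxon(diffs, method="approx")
            except ValueError:
                stat, p = np.nan, 1.0
            if p < wsr_alpha:
                removed.append(feat)
                records.append(CleaningRecord(feat, "qc-bias", stat, p))
                continue

        # rule 3: QC precision
        qv = qc_vals.dropna()
        if len(qv) >= 3 and qv.mean() > 0:
            rsd = 100.0 * qv.std(ddof=1) / qv.mean()
            if rsd > rsd_max:
                removed.append(feat)
                records.append(CleaningRecord(feat, "high-rsd", rsd, rsd))
                continue

    out = pm.drop_features(
        removed, "spectral_clean",
        f"cleaning rules (KW<{kw_alpha:g} | WSR<{wsr_alpha:g} | RSD>{rsd_max:g}%)",
    )
    return out, records


def cleaning_to_frame(records: list[CleaningRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mz": r.feature_mz, "rule": r.rule, "statistic": r.statistic,
             "value": r.value}
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

def knn_impute(pm: PeakMatrix, k: int = 5) -> PeakMatrix:
    """Impute missing cells from the k nearest samples.

    Features are standardised (observed mean 0, SD 1), neighbours are found
    by Euclidean distance over co-observed features, and each missing cell
    receives the distance-weighted mean of the k nearest samples that
    observed that feature; values are then returned to the original scale.
    Observed cells are never modified.
    """
    data = pm.intensities
    obs_count = data.notna().sum(axis=0)
    dead = list(data.columns[obs_count == 0])
    if dead:
        raise ValueError(f"feature(s) with no observed values: {dead[:5]}")
    mu = data.mean(axis=0, skipna=True)
    sd = data.std(axis=0, ddof=1, skipna=True).replace(0, 1.0).fillna(1.0)
    z = (data - mu) / sd
    imputer = KNNImputer(n_neighbors=k, weights="distance", metric="nan_euclidean")
    filled = pd.DataFrame(imputer.fit_transform(z), index=data.index,
                          columns=data.columns)
    restored = filled * sd + mu
    restored[data.notna()] = data
    # weighted means can only interpolate observed (positive) values, but
    # guard against float round-off at the low end
    restored = restored.clip(lower=np.nextafter(0, 1))
    out = PeakMatrix(restored, pm.samples.copy(), list(pm.history))
    out.log("knn_impute", (), f"KNN imputation, k={k}, distance-weighted")
    return out


# ---------------------------------------------------------------------------
# Generalised logarithm
# ---------------------------------------------------------------------------

def glog_transform(x, lam: float):
    """y = ln((x + sqrt(x^2 + lambda)) / 2); reduces to ln(x) at lambda=0."""
    if lam < 0:
        raise ValueError("glog lambda must be >= 0")
    x = np.asarray(x, dtype=float)
    return np.log((x + np.sqrt(x * x + lam)) / 2.0)


def choose_glog_lambda(pm: PeakMatrix, n_grid: int = 25) -> float:
    """Grid-search lambda minimising the QC mean/SD dependence.

    Objective: after transforming, compute each feature's standard
    deviation and mean over the QC samples and take the absolute Spearman
    rank correlation between them; a variance-stabilising lambda makes the
    spread independent of the mean.  The grid spans lambda from
    (1e-2 x the smallest QC mean)^2 to (1e2 x the largest)^2.
    """
    qcs = pm.qc_ids
    if len(qcs) < 3:
        raise ValueError("lambda selection needs >= 3 QC samples")
    qc = pm.intensities.loc[qcs]
    means = qc.mean(axis=0).to_numpy()
    lo = max(np.nanmin(means) * 1e-2, 1e-6)
    hi = np.nanmax(means) * 1e2
    grid = np.logspace(2 * np.log10(lo), 2 * np.log10(hi), n_grid)
    best_lam, best_obj = grid[0], np.inf
    for lam in grid:
        t = glog_transform(qc.to_numpy(), lam)
        m = t.mean(axis=0)
        s = t.std(axis=0, ddof=1)
        keep = np.isfinite(m) & np.isfinite(s)
        if keep.sum() < 3:
            continue
        rho = abs(stats.spearmanr(m[keep], s[keep]).statistic)
        if np.isfinite(rho) and rho < best_obj:
            best_lam, best_obj = float(lam), float(rho)
    return best_lam


def glog(pm: PeakMatrix, lam: float | None = None) -> PeakMatrix:
    """Apply the generalised logarithm cellwise to an imputed matrix.

    Requires no missing cells.  ``lam=None`` selects lambda by
    :func:`choose_glog_lambda`.  Transformed values may be non-positive,
    so the result is returned as a plain DataFrame-backed matrix whose
    positivity invariant no longer applies; downstream consumers (PCA,
    statistics) treat it as real-valued.
    """
    if pm.intensities.isna().any().any():
        raise ValueError("glog requires an imputed (no-missing) matrix")
    if lam is None:
        lam = choose_glog_lambda(pm)
    transformed = pd.DataFrame(
        glog_transform(pm.intensities.to_numpy(), lam),
        index=pm.intensities.index, columns=pm.intensities.columns,
    )
    out = PeakMatrix.__new__(PeakMatrix)
    out.intensities = transformed
    out.samples = pm.samples.copy()
    out.history = list(pm.history)
    out.log("glog", (), f"generalised logarithm, lambda={lam:.6g}")
    return out
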