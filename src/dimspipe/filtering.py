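"""Data-quality filters: electrospray, TIC, replicate, blank, sample and
missing-value filtering, plus cross-sample m/z alignment into the matrix.

The filters implement the multi-step quality checklist of the benchmark
workflow, in pipeline order:

1. electrospray check — a sample whose spray current collapses (a
   sustained run of zero total-ion-count scans in any replicate) is removed
   wholesale, all three replicates.
2. TIC filter — each sample's seven-value median-TIC profile (one value
   per SIM window) is screened by PCA; samples outlying on PC2 are removed.
3. replicate filter — a peak must appear in at least 2 of the 3 replicate
   injections of a sample to be retained; retained peaks carry the mean
   m/z and mean intensity over the replicates that detected them.
4. alignment — per-sample peak lists are amalgamated into a samples x
   features matrix by single-linkage gap clustering of the pooled m/z axis.
5. blank filter — a feature is a contaminant (removed) when its median
   blank intensity is at least one third of its median biological
   intensity.
6. sample filter — a feature must be present in at least 80% of the
   biological samples.
7. missing-value filter — samples whose missing-value percentage exceeds
   the cohort mean + 2 SD are removed; the pipeline then repeats the blank
   and sample filters on the reduced matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .core import PeakList, PeakMatrix, ReplicateFilteredPeakList

N_WINDOWS = 7


@dataclass
class TicProfile:
    """Seven median-TIC values (one per SIM window) for one replicate."""

    sample_id: str
    replicate_index: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_WINDOWS,):
            raise ValueError(f"expected {N_WINDOWS} TIC values, got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("TIC values must be >= 0")


# ---------------------------------------------------------------------------
# 1. Electrospray failure
# ---------------------------------------------------------------------------

def electrospray_check(
    tic_traces: Mapping[str, Sequence[np.ndarray]],
    zero_run: int = 3,
    eps: float = 0.0,
) -> dict[str, bool]:
    """Pass/fail per sample from per-scan TIC traces of each replicate.

    A sample fails when any of its replicates contains a run of at least
    ``zero_run`` consecutive scans with TIC <= ``eps`` (a sustained
    electrospray drop-out); an isolated zero scan is tolerated.  Failure of
    one replicate removes the whole sample.
    """
    result: dict[str, bool] = {}
    for sample_id, traces in tic_traces.items():
        ok = True
        for trace in traces:
            trace = np.asarray(trace, dtype=float)
            if trace.size == 0:
                raise ValueError(f"empty TIC trace for sample {sample_id}")
            below = trace <= eps
            run = best = 0
            for b in below:
                run = run + 1 if b else 0
                best = max(best, run)
            if best >= zero_run:
                ok = False
                break
        result[sample_id] = ok
    return result


# ---------------------------------------------------------------------------
# 2. TIC filter
# ---------------------------------------------------------------------------

def tic_filter(profiles: Sequence[TicProfile], sd_mult: float = 2.0) -> set[str]:
    """Identify technical-outlier samples from their TIC profiles.

    Replicate profiles are averaged per sample, the resulting 7-value
    arrays are mean-centred and decomposed by PCA, and a sample is flagged
    when the magnitude of its second-component score exceeds the mean of
    all |PC2| scores by more than ``sd_mult`` standard deviations — an
    automated stand-in for the visual PC2-based outlier call.
    """
    by_sample: dict[str, list[np.ndarray]] = {}
    for p in profiles:
        by_sample.setdefault(p.sample_id, []).append(p.values)
    ids = sorted(by_sample)
    if len(ids) < 10:
        raise ValueError(f"need >= 10 sample profiles for PCA, got {len(ids)}")
    X = np.array([np.mean(by_sample[s], axis=0) for s in ids])
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        return set()
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    pc2 = np.abs(Xc @ vt[1])
    thr = pc2.mean() + sd_mult * pc2.std(ddof=1)
    return {s for s, v in zip(ids, pc2) if v > thr}


# ---------------------------------------------------------------------------
# m/z gap clustering (shared by replicate filter and alignment)
# ---------------------------------------------------------------------------

def _gap_clusters(mz: np.ndarray, tolerance_ppm: float) -> np.ndarray:
    """Single-linkage 1-D clusters: break where the gap exceeds the ppm
    tolerance (evaluated at the local m/z).  Input must be sorted."""
    if mz.size == 0:
        return np.array([], dtype=int)
    gaps = np.diff(mz)
    breaks = gaps > tolerance_ppm * 1e-6 * mz[1:]
    return np.concatenate([[0], np.cumsum(breaks)])


# ---------------------------------------------------------------------------
# 3. Replicate filter
# ---------------------------------------------------------------------------

def replicate_filter(
    peaklists: Sequence[PeakList],
    mz_tolerance_ppm: float = 1.5,
    min_present: int = 2,
) -> ReplicateFilteredPeakList:
    """Collapse a sample's replicate peak lists to its consensus list.

    Only flagged (non-noise) peaks participate.  Peaks are clustered
    across replicates by the ppm gap rule; a cluster spanning at least
    ``min_present`` distinct replicates emits one peak at the mean m/z with
    the mean intensity over the replicates that detected it.
    """
    if len(peaklists) > 3:
        raise ValueError(f"expected at most 3 replicates, got {len(peaklists)}")
    if not peaklists:
        raise ValueError("no peak lists given")
    mz_all, int_all, rep_all = [], [], []
    for pl in peaklists:
        fl = pl.flagged()
        mz_all.append(fl.mz)
        int_all.append(fl.intensity)
        rep_all.append(np.full(len(fl), pl.replicate_index))
    mz = np.concatenate(mz_all)
    inten = np.concatenate(int_all)
    rep = np.concatenate(rep_all)
    order = np.argsort(mz, kind="stable")
    mz, inten, rep = mz[order], inten[order], rep[order]
    labels = _gap_clusters(mz, mz_tolerance_ppm)

    out_mz, out_int, out_n = [], [], []
    for lab in range(labels[-1] + 1 if labels.size else 0):
        sel = labels == lab
        n_reps = len(np.unique(rep[sel]))
        if n_reps >= min_present:
            out_mz.append(mz[sel].mean())
            out_int.append(inten[sel].mean())
            out_n.append(n_reps)
    order = np.argsort(out_mz, kind="stable")
    return ReplicateFilteredPeakList(
        np.array(out_mz)[order],
        np.array(out_int)[order],
        np.array(out_n, dtype=int)[order],
        sample_id=peaklists[0].sample_id,
    )


# ---------------------------------------------------------------------------
# 4. Alignment into a matrix
# ---------------------------------------------------------------------------

def align_samples(
    rfpls: Mapping[str, ReplicateFilteredPeakList],
    samples: pd.DataFrame,
    mz_tolerance_ppm: float = 1.5,
) -> PeakMatrix:
    """Amalgamate per-sample consensus lists into a samples x features matrix.

    All m/z values are pooled and clustered by the single-linkage gap rule;
    each cluster becomes one feature whose representative m/z is the
    intensity-weighted mean of its members.  A sample absent from a cluster
    gets a missing cell; a sample contributing several peaks to one cluster
    contributes its most intense one.  Emits a warning for clusters whose
    span exceeds three times the tolerance (likely under-resolved).
    """
    ids = list(samples.index)
    if len(ids) < 2:
        raise ValueError("need >= 2 samples to align")
    missing = [s for s in ids if s not in rfpls]
    if missing:
        raise ValueError(f"no peak list for sample(s): {missing}")
    mz_all, int_all, sid_all = [], [], []
    for j, sid in enumerate(ids):
        pl = rfpls[sid]
        mz_all.append(pl.mz)
        int_all.append(pl.intensity)
        sid_all.append(np.full(len(pl), j))
    mz = np.concatenate(mz_all)
    inten = np.concatenate(int_all)
    sidx = np.concatenate(sid_all)
    order = np.argsort(mz, kind="stable")
    mz, inten, sidx = mz[order], inten[order], sidx[order]
    labels = _gap_clusters(mz, mz_tolerance_ppm)
    n_clusters = labels[-1] + 1 if labels.size else 0

    data = np.full((len(ids), n_clusters), np.nan)
    feat_mz = np.empty(n_clusters)
    for lab in range(n_clusters):
        sel = labels == lab
        cmz, cint, csid = mz[sel], inten[sel], sidx[sel]
        span_ppm = (cmz.max() - cmz.min()) / cmz.mean() * 1e6
        if span_ppm > 3 * mz_tolerance_ppm:
            warnings.warn(
                f"cluster at m/z {cmz.mean():.5f} spans {span_ppm:.2f} ppm "
                f"(> 3x tolerance); consider a tighter tolerance",
                stacklevel=2,
            )
        feat_mz[lab] = np.average(cmz, weights=cint) if cint.sum() > 0 else cmz.mean()
        for s, v in zip(csid, cint):
            if np.isnan(data[s, lab]) or v > data[s, lab]:
                data[s, lab] = v
    order = np.argsort(feat_mz, kind="stable")
    intensities = pd.DataFrame(
        data[:, order], index=samples.index, columns=feat_mz[order]
    )
    pm = PeakMatrix(intensities, samples.copy())
    pm.log("align", (), f"aligned {len(ids)} samples into {n_clusters} features")
    return pm


# ---------------------------------------------------------------------------
# 5. Blank filter
# ---------------------------------------------------------------------------

def blank_filter(
    pm: PeakMatrix, ratio: float = 1.0 / 3.0, drop_blanks: bool = True
) -> PeakMatrix:
    """Remove contaminant features using the blank samples.

    A feature is removed when its median intensity across the blanks is at
    least ``ratio`` times its median intensity across the biological
    samples (missing cells excluded from both medians); a feature absent
    from every blank is retained.  The blanks themselves are dropped from
    the matrix afterwards unless ``drop_blanks`` is False.
    """
    blanks = pm.blank_ids
    bios = pm.biological_ids
    if not bios:
        raise ValueError("blank filter requires biological samples")
    if not blanks:
        raise ValueError("blank filter requires at least one blank sample")
    blank_med = pm.intensities.loc[blanks].median(axis=0, skipna=True)
    bio_med = pm.intensities.loc[bios].median(axis=0, skipna=True)
    seen_in_blank = pm.intensities.loc[blanks].notna().any(axis=0)
    contaminant = seen_in_blank & (blank_med >= ratio * bio_med)
    # features never seen in biological samples but present in blanks are
    # contaminants by construction
    contaminant |= seen_in_blank & bio_med.isna()
    removed = list(pm.intensities.columns[contaminant.to_numpy()])
    out = pm.drop_features(
        removed, "blank_filter",
        f"median blank intensity >= {ratio:.4g} x median biological intensity",
    )
    if drop_blanks:
        out = out.drop_samples(blanks, "blank_filter", "blank samples dropped after use")
    return out


# ---------------------------------------------------------------------------
# 6. Sample filter
# ---------------------------------------------------------------------------

def sample_filter(pm: PeakMatrix, presence: float = 0.80) -> PeakMatrix:
    """Keep features present in at least ``presence`` of biological samples.

    QC samples are not counted toward presence.  The comparison is
    inclusive: with 20 biological samples and the default threshold, a
    feature observed in exactly 16 is retained.
    """
    bios = pm.biological_ids
    if not bios:
        raise ValueError("sample filter requires biological samples")
    frac = pm.intensities.loc[bios].notna().mean(axis=0)
    removed = list(pm.intensities.columns[(frac < presence - 1e-12).to_numpy()])
    return pm.drop_features(
        removed, "sample_filter",
        f"present in < {presence:.0%} of biological samples",
    )


# ---------------------------------------------------------------------------
# 7. Missing-value filter
# ---------------------------------------------------------------------------

def missing_value_filter(
    pm: PeakMatrix, sd_mult: float = 2.0
) -> tuple[PeakMatrix, list[str]]:
    """Remove samples with an outlying percentage of missing values.

    The per-sample missing percentage is computed over the QC and
    biological samples; the exclusion threshold is the mean plus
    ``sd_mult`` standard deviations, and samples strictly above it are
    removed.  Applied once (no iteration); the pipeline re-runs the blank
    and sample filters afterwards.
    """
    ids = [s for s in pm.samples.index
           if pm.samples.loc[s, "sample_type"] in ("QC", "biological")]
    pct = pm.intensities.loc[ids].isna().mean(axis=1) * 100.0
    thr = pct.mean() + sd_mult * pct.std(ddof=1)
    if np.isnan(thr):  # single sample: no spread to judge against
        thr = np.inf
    removed = list(pct.index[pct > thr])
    out = pm.drop_samples(
        removed, "missing_value_filter",
        f"missing % > mean + {sd_mult:g} SD ({thr:.2f}%)",
    )
    return out, removed
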