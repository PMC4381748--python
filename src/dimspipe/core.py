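"""Core data containers for the DIMS processing pipeline.

The containers mirror the artefacts a direct-infusion FT-ICR metabolomics
study produces on its way from raw transients to a statistics-ready matrix:

* :class:`PeakList` — one peak list per technical replicate (the "SPL"
  stage), holding m/z (or frequency, before calibration), intensity,
  signal-to-noise ratio and a binary non-noise flag per peak.
* :class:`ReplicateFilteredPeakList` — the per-sample consensus of the
  triplicate injections (the "RFPL" stage).
* :class:`PeakMatrix` — the samples x features intensity matrix with
  explicit missing values, sample metadata and an append-only history of
  every removal decision (the "SFPM" stage and its descendants).
* :class:`RunConfig` — every pipeline threshold in one serialisable place.

Missing intensities are represented by NaN in memory and by empty cells on
disk; zero is a legal intensity distinct from missing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

#: In-memory marker for a missing intensity. Distinct from zero.
MISSING = float("nan")

SAMPLE_TYPES = ("biological", "QC", "blank")
CLASS_LABELS = ("cow", "sheep", "none")

#: Column order of the sample-metadata table.
META_COLUMNS = [
    "sample_id",
    "sample_type",
    "batch",
    "run_order",
    "class_label",
    "repeat_group",
]


class FormatError(ValueError):
    """A file did not conform to the declared text format."""


class CalibrationUnavailable(RuntimeError):
    """Too few calibrants matched to fit an internal mass calibration."""


def is_missing(x) -> np.ndarray:
    """Elementwise test for the missing-value marker."""
    return np.isnan(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class Peak:
    """A single picked peak.

    ``mz`` holds the mass-to-charge ratio in Da after calibration, or the
    cyclotron frequency in Hz before it.  ``noise_flag`` is 1 when the peak
    exceeded the SNR threshold and 0 otherwise; flag-0 peaks are carried
    through peak lists so that thresholding decisions remain auditable.
    """

    mz: float
    intensity: float
    snr: float = 0.0
    noise_flag: int = 1

    def __post_init__(self):
        if not self.mz > 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")
        if self.snr < 0:
            raise ValueError(f"snr must be >= 0, got {self.snr}")
        if self.noise_flag not in (0, 1):
            raise ValueError(f"noise_flag must be 0 or 1, got {self.noise_flag}")


@dataclass
class PeakList:
    """Array-backed ordered peak list for one replicate injection."""

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    noise_flag: np.ndarray
    sample_id: str = ""
    replicate_index: int = 1

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        self.noise_flag = np.asarray(self.noise_flag, dtype=int)
        n = len(self.mz)
        if not (len(self.intensity) == len(self.snr) == len(self.noise_flag) == n):
            raise ValueError("peak-list columns have unequal lengths")
        if n and not np.all(self.mz > 0):
            raise ValueError("all mz values must be positive")
        if n and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz values must be strictly ascending and unique")
        if n and (np.any(self.intensity < 0) or np.any(self.snr < 0)):
            raise ValueError("intensities and SNRs must be non-negative")
        if n and not np.isin(self.noise_flag, (0, 1)).all():
            raise ValueError("noise_flag entries must be 0 or 1")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def peaks(self) -> list[Peak]:
        return [
            Peak(m, i, s, int(f))
            for m, i, s, f in zip(self.mz, self.intensity, self.snr, self.noise_flag)
        ]

    @classmethod
    def from_peaks(
        cls, peaks: Iterable[Peak], sample_id: str = "", replicate_index: int = 1
    ) -> "PeakList":
        peaks = list(peaks)
        return cls(
            mz=np.array([p.mz for p in peaks]),
            intensity=np.array([p.intensity for p in peaks]),
            snr=np.array([p.snr for p in peaks]),
            noise_flag=np.array([p.noise_flag for p in peaks]),
            sample_id=sample_id,
            replicate_index=replicate_index,
        )

    def flagged(self) -> "PeakList":
        """Return only the peaks that passed the SNR threshold."""
        keep = self.noise_flag == 1
        return PeakList(
            self.mz[keep],
            self.intensity[keep],
            self.snr[keep],
            self.noise_flag[keep],
            sample_id=self.sample_id,
            replicate_index=self.replicate_index,
        )


@dataclass
class ReplicateFilteredPeakList:
    """Per-sample consensus peak list after the two-of-three replicate rule.

    ``num_spectra`` records in how many of the replicate injections each
    retained peak was detected.
    """

    mz: np.ndarray
    intensity: np.ndarray
    num_spectra: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.num_spectra = np.asarray(self.num_spectra, dtype=int)
        n = len(self.mz)
        if not (len(self.intensity) == len(self.num_spectra) == n):
            raise ValueError("RFPL columns have unequal lengths")
        if n and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz values must be strictly ascending and unique")
        if n and np.any(self.num_spectra < 1):
            raise ValueError("num_spectra must be >= 1")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class CalibrantList:
    """Internal-calibration reference masses: (label, theoretical m/z)."""

    entries: tuple

    def __post_init__(self):
        labels = [e[0] for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("calibrant labels must be unique")
        for label, mz in self.entries:
            if not float(mz) > 0:
                raise ValueError(f"calibrant {label!r} has non-positive m/z")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def mz(self) -> np.ndarray:
        return np.array([float(e[1]) for e in self.entries])


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one injected sample (all three replicates)."""

    sample_id: str
    sample_type: str
    batch: int
    run_order: int
    class_label: str = "none"
    repeat_group: str = ""

    def __post_init__(self):
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.batch < 1 or self.run_order < 1:
            raise ValueError("batch and run_order must be >= 1")
        if (self.sample_type == "biological") == (self.class_label == "none"):
            raise ValueError(
                "class must be 'none' exactly for non-biological samples "
                f"(got {self.sample_type}/{self.class_label})"
            )


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Build the sample-metadata table, indexed by sample_id."""
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "sample_type": r.sample_type,
                "batch": r.batch,
                "run_order": r.run_order,
                "class_label": r.class_label,
                "repeat_group": r.repeat_group,
            }
            for r in records
        ],
        columns=META_COLUMNS,
    )
    if df["run_order"].duplicated().any():
        raise ValueError("run_order values must be unique within a study")
    if df["sample_id"].duplicated().any():
        raise ValueError("sample_id values must be unique")
    return df.set_index("sample_id", drop=False)


@dataclass
class HistoryEntry:
    stage: str
    n_removed: int
    reason: str
    items: tuple = ()


@dataclass
class PeakMatrix:
    """Samples x features intensity matrix with metadata and provenance.

    ``intensities`` is a DataFrame whose index is sample_id (in run order)
    and whose columns are the representative feature m/z values, strictly
    ascending. Cells are positive floats or NaN (missing). ``samples`` is
    the metadata table from :func:`records_to_frame`. ``history`` is the
    append-only log of every filtering decision applied so far.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self):
        if list(self.intensities.index) != list(self.samples.index):
            raise ValueError("intensity rows do not match sample metadata")
        cols = np.asarray(self.intensities.columns, dtype=float)
        if len(cols) and not np.all(np.diff(cols) > 0):
            raise ValueError("feature m/z values must be strictly ascending")
        vals = self.intensities.to_numpy(dtype=float)
        if vals.size and np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("all observed intensities must be positive")

    # -- convenience views ----------------------------------------------
    @property
    def features(self) -> np.ndarray:
        return np.asarray(self.intensities.columns, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def ids_of_type(self, sample_type: str) -> list[str]:
        mask = self.samples["sample_type"] == sample_type
        return list(self.samples.index[mask])

    @property
    def qc_ids(self) -> list[str]:
        return self.ids_of_type("QC")

    @property
    def biological_ids(self) -> list[str]:
        return self.ids_of_type("biological")

    @property
    def blank_ids(self) -> list[str]:
        return self.ids_of_type("blank")

    def copy(self) -> "PeakMatrix":
        return PeakMatrix(
            self.intensities.copy(), self.samples.copy(), list(self.history)
        )

    # -- provenance ------------------------------------------------------
    def log(self, stage: str, items: Sequence, reason: str) -> None:
        self.history.append(
            HistoryEntry(stage=stage, n_removed=len(items), reason=reason,
                         items=tuple(items))
        )

    def drop_features(self, feature_mz: Sequence[float], stage: str, reason: str
                      ) -> "PeakMatrix":
        out = self.copy()
        out.intensities = out.intensities.drop(columns=list(feature_mz))
        out.log(stage, feature_mz, reason)
        return out

    def drop_samples(self, sample_ids: Sequence[str], stage: str, reason: str
                     ) -> "PeakMatrix":
        out = self.copy()
        out.intensities = out.intensities.drop(index=list(sample_ids))
        out.samples = out.samples.drop(index=list(sample_ids))
        out.log(stage, sample_ids, reason)
        return out


@dataclass
class RunConfig:
    """All pipeline thresholds, serialisable to/from YAML.

    Defaults follow the processing settings of the benchmark workflow:
    SNR threshold 3.5, peaks kept when present in >= 2 of 3 replicates,
    blank contamination ratio 1/3, 80% sample presence, missing-value
    exclusion at mean + 2 SD, Kruskal-Wallis alpha 1e-4, signed-rank alpha
    1e-14, QC RSD ceiling 20%.
    """

    snr_threshold: float = 3.5
    replicate_min: int = 2
    n_replicates: int = 3
    blank_ratio: float = 1.0 / 3.0
    sample_presence: float = 0.80
    missing_sd_mult: float = 2.0
    kw_alpha: float = 1e-4
    wsr_alpha: float = 1e-14
    rsd_max: float = 20.0
    knn_k: int = 5
    glog_lambda: float | None = None  # None -> choose by grid search
    mz_tolerance_ppm: float = 1.5
    calibrant_tolerance_ppm: float = 6.5
    tic_sd_mult: float = 2.0
    esi_zero_run: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.snr_threshold:
            raise ValueError("snr_threshold must be positive")
        if not 1 <= self.replicate_min <= self.n_replicates:
            raise ValueError("replicate_min must be in [1, n_replicates]")
        if not 0 < self.blank_ratio <= 1:
            raise ValueError("blank_ratio must be in (0, 1]")
        if not 0 < self.sample_presence <= 1:
            raise ValueError("sample_presence must be in (0, 1]")
        for name in ("kw_alpha", "wsr_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.rsd_max <= 0:
            raise ValueError("rsd_max must be positive")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.glog_lambda is not None and self.glog_lambda < 0:
            raise ValueError("glog_lambda must be >= 0")
        if self.mz_tolerance_ppm <= 0 or self.calibrant_tolerance_ppm <= 0:
            raise ValueError("ppm tolerances must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
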