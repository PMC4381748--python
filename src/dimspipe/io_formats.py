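"""Readers and writers for the pipeline's text formats.

Formats
-------
SPL (stitched peak list)
    Four tab-separated columns per replicate: ``m/z``, ``Intensity``,
    ``SNR``, ``non-noise flag`` (1 = passed the SNR threshold, 0 = failed;
    failed peaks are kept in the file for auditability).
RFPL (replicate-filtered peak list)
    Three columns per sample: ``mz``, ``intensity`` (mean over the
    replicates the peak was detected in) and ``num spectra (peak flagged)``.
Peak matrix (SFPM family)
    Three delimited tables — data (samples x features, empty cell =
    missing), meta (sample metadata) and peak (feature m/z list) — or,
    alternatively, one .xlsx workbook with sheets named data/meta/peak.
Calibrant list
    Two columns: formula+adduct label, theoretical m/z.

m/z values are written to 6 decimal places and intensities/SNRs to 6
significant figures; all readers accept both tab and general whitespace
delimiters.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CalibrantList,
    FormatError,
    HistoryEntry,
    PeakList,
    PeakMatrix,
    ReplicateFilteredPeakList,
    META_COLUMNS,
)

MZ_FMT = "{:.6f}"
INT_FMT = "{:.6g}"

SPL_HEADER = "m/z\tIntensity\tSNR\tnon-noise flag"
RFPL_HEADER = "mz\tintensity\tnum spectra (peak flagged)"


def _parse_float(token: str, path, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}: line {lineno}: bad {what} value {token!r}") from None


# ---------------------------------------------------------------------------
# SPL
# ---------------------------------------------------------------------------

def write_spl(peaklist: PeakList, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(SPL_HEADER + "\n")
        for m, i, s, f in zip(
            peaklist.mz, peaklist.intensity, peaklist.snr, peaklist.noise_flag
        ):
            fh.write(
                f"{MZ_FMT.format(m)}\t{INT_FMT.format(i)}\t{INT_FMT.format(s)}\t{int(f)}\n"
            )


def read_spl(path, sample_id: str = "", replicate_index: int = 1) -> PeakList:
    """Read a stitched peak list; flag-0 rows are preserved, not dropped."""
    path = Path(path)
    mz, inten, snr, flag = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if lineno == 1 and line.split()[0].lower() in ("m/z", "mz"):
                continue
            tokens = line.split()
            if len(tokens) != 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(tokens)}"
                )
            mz.append(_parse_float(tokens[0], path, lineno, "m/z"))
            inten.append(_parse_float(tokens[1], path, lineno, "intensity"))
            snr.append(_parse_float(tokens[2], path, lineno, "SNR"))
            if tokens[3] not in ("0", "1"):
                raise FormatError(f"{path}: line {lineno}: bad flag {tokens[3]!r}")
            flag.append(int(tokens[3]))
    mz = np.array(mz)
    order = np.arange(len(mz))
    if len(mz) > 1 and np.any(np.diff(mz) <= 0):
        warnings.warn(f"{path}: m/z not strictly ascending; sorting", stacklevel=2)
        order = np.argsort(mz, kind="stable")
    return PeakList(
        mz[order],
        np.array(inten)[order],
        np.array(snr)[order],
        np.array(flag)[order],
        sample_id=sample_id,
        replicate_index=replicate_index,
    )


# ---------------------------------------------------------------------------
# RFPL
# ---------------------------------------------------------------------------

def write_rfpl(rfpl: ReplicateFilteredPeakList, path) -> None:
    with open(path, "w") as fh:
        fh.write(RFPL_HEADER + "\n")
        for m, i, n in zip(rfpl.mz, rfpl.intensity, rfpl.num_spectra):
            fh.write(f"{MZ_FMT.format(m)}\t{INT_FMT.format(i)}\t{int(n)}\n")


def read_rfpl(path, sample_id: str = "") -> ReplicateFilteredPeakList:
    path = Path(path)
    mz, inten, nspec = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if lineno == 1 and line.split()[0].lower() in ("mz", "m/z"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if len(tokens) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(tokens)}"
                )
            mz.append(_parse_float(tokens[0], path, lineno, "m/z"))
            inten.append(_parse_float(tokens[1], path, lineno, "intensity"))
            nspec.append(int(_parse_float(tokens[2], path, lineno, "num spectra")))
    return ReplicateFilteredPeakList(
        np.array(mz), np.array(inten), np.array(nspec), sample_id=sample_id
    )


# ---------------------------------------------------------------------------
# Peak matrix (data/meta/peak triple)
# ---------------------------------------------------------------------------

def write_matrix(pm: PeakMatrix, data_path, meta_path, peak_path) -> None:
    data = pm.intensities.copy()
    data.columns = [MZ_FMT.format(c) for c in pm.features]
    data.index.name = "sample_id"
    data.to_csv(data_path, sep="\t", float_format="%.6g", na_rep="")
    pm.samples[META_COLUMNS].to_csv(meta_path, sep="\t", index=False)
    peaks = pd.DataFrame({"mz": [MZ_FMT.format(c) for c in pm.features]})
    peaks.to_csv(peak_path, sep="\t", index=False)


def _build_matrix(data: pd.DataFrame, meta: pd.DataFrame, peak: pd.DataFrame
                  ) -> PeakMatrix:
    if data.shape[1] != len(peak):
        raise FormatError(
            f"data has {data.shape[1]} features but peak table lists {len(peak)}"
        )
    if data.shape[0] != len(meta):
        raise FormatError(
            f"data has {data.shape[0]} samples but meta table lists {len(meta)}"
        )
    meta = meta.copy()
    if "class_label" not in meta.columns and "class" in meta.columns:
        meta = meta.rename(columns={"class": "class_label"})
    meta["class_label"] = (
        meta.get("class_label", pd.Series(["none"] * len(meta)))
        .fillna("none")
        .replace("", "none")
    )
    if "repeat_group" not in meta.columns:
        meta["repeat_group"] = ""
    meta["repeat_group"] = meta["repeat_group"].fillna("")
    bad = ~meta["sample_type"].isin(("biological", "QC", "blank"))
    if bad.any():
        raise FormatError(
            f"unknown sample_type token(s): {sorted(meta.loc[bad, 'sample_type'].unique())}"
        )
    meta = meta[META_COLUMNS].astype(
        {"batch": int, "run_order": int, "sample_id": str}
    )
    meta = meta.set_index("sample_id", drop=False)
    data = data.copy()
    data.columns = peak["mz"].astype(float).to_numpy()
    data.index = meta.index
    return PeakMatrix(data.astype(float), meta)


def read_matrix(data_path, meta_path, peak_path) -> PeakMatrix:
    """Read the three-table peak-matrix interchange format."""
    data = pd.read_csv(data_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    peak = pd.read_csv(peak_path, sep="\t")
    return _build_matrix(data, meta, peak)


def read_matrix_xlsx(path) -> PeakMatrix:
    """Read a peak-matrix workbook with data/meta/peak sheets."""
    data = pd.read_excel(path, sheet_name="data", index_col=0)
    meta = pd.read_excel(path, sheet_name="meta")
    peak = pd.read_excel(path, sheet_name="peak")
    return _build_matrix(data, meta, peak)


def write_matrix_xlsx(pm: PeakMatrix, path) -> None:
    data = pm.intensities.copy()
    data.columns = [MZ_FMT.format(c) for c in pm.features]
    data.index.name = "sample_id"
    with pd.ExcelWriter(path) as writer:
        data.to_excel(writer, sheet_name="data")
        pm.samples[META_COLUMNS].to_excel(writer, sheet_name="meta", index=False)
        pd.DataFrame({"mz": pm.features}).to_excel(
            writer, sheet_name="peak", index=False
        )


# ---------------------------------------------------------------------------
# Calibrants
# ---------------------------------------------------------------------------

def read_calibrants(path) -> CalibrantList:
    path = Path(path)
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.rsplit(None, 1)
            if len(tokens) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(tokens)}"
                )
            label = tokens[0].strip()
            mz = _parse_float(tokens[1], path, lineno, "theoretical m/z")
            entries.append((label, mz))
    return CalibrantList(tuple(entries))


def write_calibrants(calibrants: CalibrantList, path) -> None:
    with open(path, "w") as fh:
        for label, mz in calibrants.entries:
            fh.write(f"{label}\t{MZ_FMT.format(mz)}\n")


# ---------------------------------------------------------------------------
# Provenance log
# ---------------------------------------------------------------------------

def write_provenance(history: Sequence[HistoryEntry], path, append: bool = False
                     ) -> None:
    """Write the removal history as append-only tab-delimited text."""
    mode = "a" if append else "w"
    new_file = not (append and Path(path).exists())
    with open(path, mode) as fh:
        if new_file:
            fh.write("stage\tn_removed\treason\titems\n")
        for entry in history:
            items = ";".join(str(x) for x in entry.items)
            fh.write(f"{entry.stage}\t{entry.n_removed}\t{entry.reason}\t{items}\n")


def read_provenance(path) -> list[HistoryEntry]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            stage, n_removed, reason, items = line.rstrip("\n").split("\t")
            out.append(
                HistoryEntry(
                    stage=stage,
                    n_removed=int(n_removed),
                    reason=reason,
                    items=tuple(items.split(";")) if items else (),
                )
            )
    return out
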