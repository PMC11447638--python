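"""Domain containers and file I/O for the EEG temporal-dynamics pipeline.

The pipeline operates on ROI-level (source-space) time series.  Three
containers move through it:

``Recording``
    a channels/ROIs x samples matrix with a sampling rate, labels and an
    acquisition-centre identifier;
``RoiMap``
    the merging of 82 atlas regions into 10 lobar regions of interest;
``CohortFeatureTable``
    a thin wrapper over a pandas DataFrame with one row per subject,
    holding country-level predictors (Gini, GDP), demographics, cognition,
    signal-quality fields and the named EEG outcome columns.

The canonical on-disk exchange format for recordings is a tab-separated
matrix (channels as columns, header row of labels, a ``# fs=<Hz>`` comment
line); EDF is supported read-only through :mod:`mne`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("neurodyn")

#: predictor / quality columns written first, in this order; outcome columns
#: follow alphabetically.
PREDICTOR_COLUMNS = ["country", "gini", "gdp", "age", "sex", "education", "mmse"]
QUALITY_COLUMNS = ["oqd", "oqd_category", "n_channels", "fs_original", "reference_code"]


class FormatError(ValueError):
    """Raised when a file does not parse under its declared format."""


class ConfigurationError(ValueError):
    """Raised when required configuration (e.g. the sampling rate) is missing."""


def log_stage(stage: str, **params) -> None:
    """One structured log line per pipeline stage."""
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    logger.info("stage=%s %s", stage, kv)


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel/ROI time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage-like values; arbitrary units after z-scoring.
    fs : float
        Sampling rate in Hz, > 0.
    labels : list of str
        Unique channel/ROI names, one per row.
    centre_id : str
        Acquisition-site identifier (used for per-centre harmonisation).
    meta : dict
        Free-form provenance record.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    centre_id: str = "default"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal number of rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not self.meta.get("allow_missing", False) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray | None = None, **kw) -> "Recording":
        return Recording(
            data=self.data.copy() if data is None else data,
            fs=kw.get("fs", self.fs),
            labels=kw.get("labels", list(self.labels)),
            centre_id=kw.get("centre_id", self.centre_id),
            meta={**self.meta, **kw.get("meta", {})},
        )


def read_recording(path: str | Path, format: str = "tsv-matrix", fs: float | None = None,
                   centre_id: str = "default") -> Recording:
    """Read a recording from disk.

    Parameters
    ----------
    path : path
        Input file.
    format : {"tsv-matrix", "edf"}
        ``tsv-matrix``: tab-separated, header row of channel labels, one
        column per channel, sampling rate in a leading ``# fs=<Hz>`` comment
        or via the `fs` argument.  ``edf``: European Data Format, read with
        mne; channel order preserved.
    fs : float, optional
        Sampling rate override for TSV files without an fs header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data()
        return Recording(
            data=data, fs=float(raw.info["sfreq"]), labels=list(raw.ch_names),
            centre_id=centre_id, meta={"source": str(path), "format": "edf"},
        )
    if format != "tsv-matrix":
        raise ValueError(f"unknown format {format!r}")

    header_fs = None
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                break
            stripped = line[1:].strip()
            if stripped.startswith("fs="):
                header_fs = float(stripped[3:])
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"cannot parse {path} as TSV matrix: {exc}") from exc
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"non-numeric cell in TSV matrix {path}")
    rate = header_fs if header_fs is not None else fs
    if rate is None:
        raise ConfigurationError(f"sampling rate not given for {path} (no '# fs=' header)")
    return Recording(
        data=values.T, fs=float(rate), labels=list(df.columns),
        centre_id=centre_id, meta={"source": str(path), "format": "tsv-matrix"},
    )


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as the canonical TSV matrix (columns = channels)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write("\t".join(rec.labels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter="\t", fmt="%.12g")
    return path


# ---------------------------------------------------------------------------
# ROI map
# ---------------------------------------------------------------------------

# 82-region default: the 90-region AAL parcellation without the bilateral
# deep-grey nuclei (caudate, putamen, pallidum, thalamus), merged into five
# lobar ROIs per hemisphere.
_AAL_LOBES = {
    "frontal": [
        "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
        "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
        "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
        "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    ],
    "cingulate": ["Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post"],
    "temporal": [
        "Hippocampus", "ParaHippocampal", "Amygdala", "Fusiform", "Heschl",
        "Temporal_Sup", "Temporal_Pole_Sup", "Temporal_Mid",
        "Temporal_Pole_Mid", "Temporal_Inf",
    ],
    "parietal": [
        "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
        "Angular", "Precuneus", "Paracentral_Lobule",
    ],
    "occipital": [
        "Calcarine", "Cuneus", "Lingual", "Occipital_Sup", "Occipital_Mid",
        "Occipital_Inf",
    ],
}

ALL_ROIS_LABEL = "all_rois"


def default_region_to_roi() -> dict[str, str]:
    """82 atlas region names -> 10 lobar ROI names (``<lobe>_<left|right>``)."""
    mapping: dict[str, str] = {}
    for lobe, regions in _AAL_LOBES.items():
        for region in regions:
            for side, suffix in (("left", "_L"), ("right", "_R")):
                mapping[region + suffix] = f"{lobe}_{side}"
    return mapping


@dataclass
class RoiMap:
    """Mapping from atlas-region names to ROI names."""

    region_to_roi: dict[str, str]
    strict: bool = True

    def __post_init__(self) -> None:
        rois = sorted(set(self.region_to_roi.values()))
        if self.strict:
            if len(self.region_to_roi) != 82:
                raise ValueError(
                    f"strict ROI map must cover 82 regions, got {len(self.region_to_roi)}"
                )
            if len(rois) != 10:
                raise ValueError(f"strict ROI map must define 10 ROIs, got {len(rois)}")
        self.rois = rois

    @property
    def n_regions(self) -> int:
        return len(self.region_to_roi)

    def members(self, roi: str) -> list[str]:
        return [r for r, v in self.region_to_roi.items() if v == roi]


def load_roi_map(path: str | Path | None = None, strict: bool = True) -> RoiMap:
    """Load a two-column (region<TAB>roi) map, or the built-in default.

    A region listed twice is a validation error.  With ``strict=False`` a
    custom toy map of any size is accepted.
    """
    if path is None:
        return RoiMap(default_region_to_roi(), strict=strict)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"expected 'region<TAB>roi', got {line!r}")
            region, roi = parts
            if region in mapping:
                raise ValueError(f"region {region!r} mapped twice")
            mapping[region] = roi
    return RoiMap(mapping, strict=strict)


# ---------------------------------------------------------------------------
# Cohort feature table
# ---------------------------------------------------------------------------

class CohortFeatureTable:
    """One row per subject: predictors, quality fields and EEG outcomes.

    A thin validating wrapper over a DataFrame indexed by ``subject_id``.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.name != "subject_id":
            if "subject_id" in df.columns:
                df = df.set_index("subject_id")
            else:
                raise ValueError("table requires a subject_id index or column")
        if df.index.duplicated().any():
            raise ValueError("duplicate subject_id")
        if "gini" in df.columns:
            g = df["gini"].dropna()
            if ((g < 0) | (g > 100)).any():
                raise ValueError("gini must lie in [0, 100]")
        if "mmse" in df.columns:
            m = df["mmse"].dropna()
            if ((m < 0) | (m > 30)).any():
                raise ValueError("mmse must lie in [0, 30]")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def outcome_columns(self) -> list[str]:
        known = set(PREDICTOR_COLUMNS) | set(QUALITY_COLUMNS)
        return sorted(c for c in self.df.columns if c not in known)

    def ordered_columns(self) -> list[str]:
        pred = [c for c in PREDICTOR_COLUMNS if c in self.df.columns]
        qual = [c for c in QUALITY_COLUMNS if c in self.df.columns]
        return pred + qual + self.outcome_columns


def write_feature_table(table: CohortFeatureTable, path: str | Path) -> Path:
    """Write the cohort table as CSV with a stable column order.

    Predictors first, then quality fields, then outcomes alphabetically.
    Numeric values keep 12 significant digits; missing values are empty
    cells, not ``nan`` text.  Write-read-write is byte-stable.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    out = table.df[table.ordered_columns()]
    out.to_csv(path, float_format="%.12g", na_rep="")
    return path


def read_feature_table(path: str | Path) -> CohortFeatureTable:
    df = pd.read_csv(path, index_col="subject_id")
    return CohortFeatureTable(df)
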