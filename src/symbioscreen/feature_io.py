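"""Feature-table I/O and pre-screening hygiene.

An untargeted LC-MS experiment yields, per ion mode, a matrix of feature
intensities (one row per m/z-retention-time feature, one column per sample)
plus feature metadata and a sample -> group map.  Before any differential
screening the table is cleaned in three steps:

1. :func:`qc_filter` keeps features that are technically reproducible
   (low relative standard deviation across pooled-QC injections) and
   reasonably present across the biological samples;
2. :func:`impute_missing` replaces absent values with half the feature's
   minimum observed intensity;
3. :func:`normalize` rescales samples to a common total or median intensity.

Intensities are stored on the linear scale; ``NaN`` encodes an absent value.
All present intensities must be strictly positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

KNOWN_GROUPS = ("LB", "QC", "B108", "B253", "B263", "B313", "B424", "B505", "B585")
ION_MODES = ("positive", "negative")

#: Tokens parsed as an absent intensity on read.
NA_TOKENS = ("", "NA", "NaN", "nan")


def make_feature_id(mz: float, rt_seconds: float) -> str:
    """Feature identifier ``M<mz>T<rt>`` with round-half-up integer parts.

    ``make_feature_id(190.0499, 192.2) == "M190T192"``.
    """
    if not (math.isfinite(mz) and math.isfinite(rt_seconds)):
        raise InputError("mz and rt_seconds must be finite")
    if mz <= 0 or rt_seconds < 0:
        raise InputError("require mz > 0 and rt_seconds >= 0")
    # round-half-up, not banker's rounding
    return f"M{math.floor(mz + 0.5)}T{math.floor(rt_seconds + 0.5)}"


@dataclass(frozen=True)
class FeatureMeta:
    """Metadata of one LC-MS feature."""

    feature_id: str
    mz: float
    rt_seconds: float
    ion_mode: str

    def __post_init__(self) -> None:
        if self.ion_mode not in ION_MODES:
            raise InputError(f"unknown ion mode {self.ion_mode!r}")
        if not (self.mz > 0 and self.rt_seconds >= 0):
            raise InputError("require mz > 0 and rt_seconds >= 0")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str
    replicate: int = 0


@dataclass(frozen=True)
class QcFilterConfig:
    """Thresholds for QC-based feature filtering.

    max_qc_rsd
        Maximum relative standard deviation (sample SD / mean, n-1
        denominator) across the pooled-QC injections.  Default 0.30,
        the conventional untargeted-metabolomics cut.
    min_presence_fraction
        Minimum fraction of non-QC samples in which the feature must be
        present.  Default 0.5.
    """

    max_qc_rsd: float = 0.30
    min_presence_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("max_qc_rsd", "min_presence_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InputError(f"{name} must be in (0, 1], got {v}")


@dataclass
class FeatureTable:
    """Features x samples intensity matrix with metadata.

    Attributes
    ----------
    features : pandas.DataFrame
        Indexed by ``feature_id`` with columns ``mz``, ``rt_seconds``,
        ``ion_mode``.
    samples : pandas.DataFrame
        Indexed by ``sample_id`` with columns ``group``, ``replicate``.
    intensities : pandas.DataFrame
        Rows align with ``features``, columns with ``samples``.  ``NaN``
        marks an absent value; present values are strictly positive.
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if list(self.intensities.index) != list(self.features.index):
            raise InputError("intensity rows do not match feature metadata")
        if list(self.intensities.columns) != list(self.samples.index):
            raise InputError("intensity columns do not match sample metadata")
        if self.features.index.duplicated().any():
            dup = self.features.index[self.features.index.duplicated()][0]
            raise InputError(f"duplicate feature_id {dup!r}")
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise InputError(f"duplicate sample_id {dup!r}")
        modes = set(self.features["ion_mode"])
        if len(modes) > 1:
            raise InputError(f"mixed ion modes in one table: {sorted(modes)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            bad = np.argwhere((vals <= 0) & np.isfinite(vals))[0]
            raise InputError(
                "intensities must be positive or absent; "
                f"found {vals[bad[0], bad[1]]!r} at feature "
                f"{self.features.index[bad[0]]!r}, sample "
                f"{self.samples.index[bad[1]]!r}"
            )

    # -- convenience ----------------------------------------------------
    @property
    def ion_mode(self) -> str:
        return str(self.features["ion_mode"].iloc[0]) if len(self.features) else "positive"

    def group_samples(self, group: str) -> list[str]:
        ids = list(self.samples.index[self.samples["group"] == group])
        return ids

    def subset_groups(self, groups: list[str]) -> "FeatureTable":
        keep = self.samples["group"].isin(groups)
        if not keep.any():
            raise InputError(f"no samples in groups {groups}")
        return FeatureTable(
            features=self.features.copy(),
            samples=self.samples.loc[keep].copy(),
            intensities=self.intensities.loc[:, keep.to_numpy()].copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), self.samples.copy(), self.intensities.copy()
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.features.equals(other.features)
            and self.samples.equals(other.samples)
            and self.intensities.equals(other.intensities)
        )


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _sniff_delimiter(path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_group_map(path) -> dict[str, str]:
    """Two-column delimited file ``sample_id, group`` -> dict."""
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"group map {path} needs two columns (sample_id, group)")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "group"]
    return dict(zip(df["sample_id"], df["group"]))


def read_feature_table(path, group_map) -> FeatureTable:
    """Read a delimited feature table.

    Layout: header row, then one feature per row with columns
    ``feature_id, mz, rt_seconds, ion_mode`` followed by one column per
    sample.  ``group_map`` is a ``sample_id -> group`` mapping or a path to
    a two-column delimited file.  Empty cells and ``NA`` are absent values.
    """
    if not isinstance(group_map, dict):
        group_map = read_group_map(group_map)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(
        path, sep=sep, na_values=list(NA_TOKENS), keep_default_na=False, dtype=str
    )
    required = ["feature_id", "mz", "rt_seconds", "ion_mode"]
    if list(df.columns[:4]) != required:
        raise InputError(
            f"{path}: first four columns must be {required}, got {list(df.columns[:4])}"
        )
    sample_ids = list(df.columns[4:])
    if not sample_ids:
        raise InputError(f"{path}: no sample columns")
    missing = [s for s in sample_ids if s not in group_map]
    if missing:
        raise InputError(f"{path}: samples missing from group map: {missing}")

    features = pd.DataFrame(
        {
            "mz": df["mz"].astype(float).to_numpy(),
            "rt_seconds": df["rt_seconds"].astype(float).to_numpy(),
            "ion_mode": df["ion_mode"].to_numpy(),
        },
        index=pd.Index(df["feature_id"], name="feature_id"),
    )
    groups = [group_map[s] for s in sample_ids]
    reps: dict[str, int] = {}
    replicate = []
    for g in groups:
        reps[g] = reps.get(g, 0) + 1
        replicate.append(reps[g])
    samples = pd.DataFrame(
        {"group": groups, "replicate": replicate},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    inten = df[sample_ids].astype(float)
    inten.index = features.index
    try:
        return FeatureTable(features, samples, inten)
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_feature_table(table: FeatureTable, path, group_map_path=None, sep="\t") -> None:
    """Write a table in the format :func:`read_feature_table` reads."""
    out = table.features.reset_index()[["feature_id", "mz", "rt_seconds", "ion_mode"]]
    inten = table.intensities.reset_index(drop=True)
    out = pd.concat([out, inten], axis=1)
    out.to_csv(path, sep=sep, index=False, na_rep="NA")
    if group_map_path is not None:
        gm = table.samples.reset_index()[["sample_id", "group"]]
        gm.to_csv(group_map_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Hygiene steps
# ---------------------------------------------------------------------------

def qc_rsd(table: FeatureTable) -> pd.Series:
    """Per-feature relative standard deviation across QC samples (sample SD / mean)."""
    qc_ids = table.group_samples("QC")
    if len(qc_ids) < 2:
        raise InputError("qc_filter requires at least 2 QC samples")
    qc = table.intensities[qc_ids]
    mean = qc.mean(axis=1, skipna=True)
    sd = qc.std(axis=1, ddof=1, skipna=True)
    return sd / mean


def qc_filter(table: FeatureTable, config: QcFilterConfig | None = None) -> FeatureTable:
    """Keep features reproducible in QC and present in biological samples.

    Retains a feature when its QC RSD is <= ``max_qc_rsd`` and it is present
    (non-absent) in at least ``min_presence_fraction`` of non-QC samples.
    Feature order is preserved.
    """
    config = config or QcFilterConfig()
    rsd = qc_rsd(table)
    bio_ids = [s for s in table.samples.index if table.samples.loc[s, "group"] != "QC"]
    presence = table.intensities[bio_ids].notna().mean(axis=1)
    keep = (rsd.fillna(np.inf) <= config.max_qc_rsd) & (
        presence >= config.min_presence_fraction
    )
    kept = FeatureTable(
        table.features.loc[keep.to_numpy()].copy(),
        table.samples.copy(),
        table.intensities.loc[keep.to_numpy()].copy(),
    )
    logger.info(
        "qc_filter: %d -> %d features (max_qc_rsd=%.3g, min_presence=%.3g)",
        len(table.features), len(kept.features),
        config.max_qc_rsd, config.min_presence_fraction,
    )
    return kept


def impute_missing(table: FeatureTable) -> FeatureTable:
    """Replace absent values by half the feature's minimum present intensity.

    Features absent in every sample are dropped (logged at WARNING).
    """
    inten = table.intensities.copy()
    all_absent = inten.isna().all(axis=1)
    if all_absent.any():
        logger.warning(
            "impute_missing: dropping %d features absent in every sample",
            int(all_absent.sum()),
        )
        inten = inten.loc[~all_absent.to_numpy()]
    fill = inten.min(axis=1, skipna=True) / 2.0
    inten = inten.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    features = table.features.loc[inten.index].copy()
    return FeatureTable(features, table.samples.copy(), inten)


def normalize(table: FeatureTable, method: str = "total_intensity") -> FeatureTable:
    """Scale each sample so its summary statistic equals the across-sample mean.

    ``total_intensity`` uses the per-sample sum, ``median`` the per-sample
    median; ``none`` is the identity.  Requires an imputed table.
    """
    if method == "none":
        return table.copy()
    if method not in ("total_intensity", "median"):
        raise InputError(f"unknown normalization method {method!r}")
    if table.intensities.isna().any().any():
        raise InputError("normalize requires an imputed table (no absent values)")
    stat = (
        table.intensities.sum(axis=0)
        if method == "total_intensity"
        else table.intensities.median(axis=0)
    )
    if (stat <= 0).any():
        bad = stat.index[stat <= 0][0]
        raise InputError(f"sample {bad!r} has non-positive {method} statistic")
    target = stat.mean()
    scaled = table.intensities * (target / stat)
    return FeatureTable(table.features.copy(), table.samples.copy(), scaled)
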