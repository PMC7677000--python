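"""The two-step candidate-metabolite screening cascade.

Per ion mode and producing strain:

* **Step I** (:func:`differential_vs_medium`) — features significantly
  upregulated at least ``fc_lb_min``-fold (default 2) in the strain's
  culture supernatant relative to the growth medium, with Welch-t
  ``p < alpha`` and PLS-DA ``VIP >= vip_min`` (default 2) from the
  strain-vs-medium model.
* **Union** (:func:`merge_union`) — the strain's step-I feature set is
  merged with the non-protective control strain's (B313) step-I set, so
  step II can also demote features the control produces.
* **Step II** (:func:`ratio_filter_vs_control`) — features of the union
  whose strain/B313 abundance ratio is at least ``ratio_b313_min``
  (default 10), again requiring significance and VIP from the
  strain-vs-B313 model.

Fold-change ratios are computed on the linear normalized intensities
(arithmetic group means); p-values come from Welch's t-test on log10
intensities.  :func:`run_cascade` composes the steps over all strains and
both ion modes into one candidate table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, InputError
from .feature_io import FeatureTable
from .multivariate import plsda_fit, vip_scores

logger = logging.getLogger(__name__)

CONTROL_STRAIN = "B313"
MEDIUM_GROUP = "LB"


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the screening cascade (defaults as used in practice:
    2-fold vs medium, p < 0.05, VIP >= 2, 10-fold vs the control strain)."""

    fc_lb_min: float = 2.0
    alpha: float = 0.05
    vip_min: float = 2.0
    ratio_b313_min: float = 10.0
    n_components: int = 2
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if min(self.fc_lb_min, self.vip_min, self.ratio_b313_min) <= 0:
            raise InputError("thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise InputError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class DifferentialRecord:
    feature_id: str
    ratio_vs_ref: float
    p_value: float
    vip: float
    passes: bool


class FeatureSet(NamedTuple):
    """An ordered feature-id set tied to one ion mode."""

    ids: tuple[str, ...]
    ion_mode: str


def _group_stats(table: FeatureTable, strain: str, reference: str,
                 config: ScreenConfig):
    """Per-feature linear ratio, Welch p (log10) and VIP for strain vs reference."""
    for g in (strain, reference):
        if not table.group_samples(g):
            raise InputError(f"group {g!r} missing from table")
    sub = table.subset_groups([strain, reference])
    inten = sub.intensities
    if inten.isna().any().any():
        raise InputError("screening requires an imputed table")
    a = inten[sub.group_samples(strain)].to_numpy(dtype=float)
    b = inten[sub.group_samples(reference)].to_numpy(dtype=float)
    mean_b = b.mean(axis=1)
    if np.any(mean_b <= 0):
        raise ComputationError(f"non-positive {reference} group mean encountered")
    ratio = a.mean(axis=1) / mean_b
    with np.errstate(invalid="ignore"):
        p = stats.ttest_ind(np.log10(a), np.log10(b), axis=1, equal_var=False).pvalue
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both edge case
    if config.bh_correction:
        p = multipletests(p, method="fdr_bh")[1]
    labels = sub.samples["group"].to_list()
    model = plsda_fit(sub, labels, n_components=config.n_components)
    vip = vip_scores(model).reindex(sub.features.index).fillna(0.0).to_numpy()
    return list(sub.features.index), ratio, p, vip


def differential_vs_medium(
    table: FeatureTable, strain: str, config: ScreenConfig | None = None
) -> list[DifferentialRecord]:
    """Step I: strain-vs-medium differential features.

    ``passes`` is true when ratio >= ``fc_lb_min``, p < ``alpha`` and
    VIP >= ``vip_min`` (VIP from the strain-vs-medium PLS-DA).
    """
    config = config or ScreenConfig()
    ids, ratio, p, vip = _group_stats(table, strain, MEDIUM_GROUP, config)
    records = [
        DifferentialRecord(
            fid, float(r), float(pv), float(v),
            bool(r >= config.fc_lb_min and pv < config.alpha and v >= config.vip_min),
        )
        for fid, r, pv, v in zip(ids, ratio, p, vip)
    ]
    n_pass = sum(r.passes for r in records)
    logger.info("step I %s vs %s: %d/%d features pass", strain, MEDIUM_GROUP,
                n_pass, len(records))
    return records


def passing_set(records: Iterable[DifferentialRecord], ion_mode: str) -> FeatureSet:
    return FeatureSet(tuple(r.feature_id for r in records if r.passes), ion_mode)


def merge_union(set_strain: FeatureSet, set_b313: FeatureSet) -> FeatureSet:
    """Stable-order union: strain features first, then novel control features."""
    if set_strain.ion_mode != set_b313.ion_mode:
        raise InputError(
            f"ion mode mismatch: {set_strain.ion_mode!r} vs {set_b313.ion_mode!r}"
        )
    seen = set(set_strain.ids)
    merged = list(set_strain.ids) + [f for f in set_b313.ids if f not in seen]
    return FeatureSet(tuple(merged), set_strain.ion_mode)


def ratio_filter_vs_control(
    table: FeatureTable,
    union_set: FeatureSet,
    strain: str,
    config: ScreenConfig | None = None,
) -> list[DifferentialRecord]:
    """Step II: keep union features >= ``ratio_b313_min``-fold above the
    control strain, with p < ``alpha`` and VIP >= ``vip_min`` from the
    strain-vs-control model."""
    config = config or ScreenConfig()
    if union_set.ion_mode != table.ion_mode:
        raise InputError("union set ion mode does not match table")
    ids, ratio, p, vip = _group_stats(table, strain, CONTROL_STRAIN, config)
    by_id = {fid: (r, pv, v) for fid, r, pv, v in zip(ids, ratio, p, vip)}
    records = []
    for fid in union_set.ids:
        if fid not in by_id:
            raise InputError(f"union feature {fid!r} not in table")
        r, pv, v = by_id[fid]
        records.append(
            DifferentialRecord(
                fid, float(r), float(pv), float(v),
                bool(r >= config.ratio_b313_min and pv < config.alpha
                     and v >= config.vip_min),
            )
        )
    logger.info("step II %s vs %s: %d/%d union features retained", strain,
                CONTROL_STRAIN, sum(r.passes for r in records), len(records))
    return records


CANDIDATE_COLUMNS = [
    "feature_id", "rt_seconds", "mz", "ion_mode",
    "ratio_vs_b313", "p_value", "vip", "strain",
]


def run_cascade(
    tables: dict[str, FeatureTable],
    strains: list[str] | None = None,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Full cascade over ion modes and strains -> candidate table.

    ``tables`` maps ion mode to a QC-filtered, imputed, normalized feature
    table.  ``strains`` defaults to every non-LB/QC/B313 group present.
    Output columns: feature_id, rt_seconds, mz, ion_mode, ratio_vs_b313,
    p_value, vip, strain.
    """
    config = config or ScreenConfig()
    rows = []
    for mode in sorted(tables):
        table = tables[mode]
        if table.ion_mode != mode:
            raise InputError(f"table under key {mode!r} has ion mode {table.ion_mode!r}")
        mode_strains = strains or [
            g for g in dict.fromkeys(table.samples["group"])
            if g not in ("LB", "QC", CONTROL_STRAIN)
        ]
        control_step1 = passing_set(
            differential_vs_medium(table, CONTROL_STRAIN, config), mode
        )
        for strain in mode_strains:
            step1 = passing_set(differential_vs_medium(table, strain, config), mode)
            union = merge_union(step1, control_step1)
            for rec in ratio_filter_vs_control(table, union, strain, config):
                if not rec.passes:
                    continue
                meta = table.features.loc[rec.feature_id]
                rows.append(
                    {
                        "feature_id": rec.feature_id,
                        "rt_seconds": float(meta["rt_seconds"]),
                        "mz": float(meta["mz"]),
                        "ion_mode": mode,
                        "ratio_vs_b313": rec.ratio_vs_ref,
                        "p_value": rec.p_value,
                        "vip": rec.vip,
                        "strain": strain,
                    }
                )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
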