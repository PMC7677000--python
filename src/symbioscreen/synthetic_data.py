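"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators mirror the four experimental data types consumed downstream:

* :func:`simulate_feature_table` — multi-group log-normal LC-MS feature
  tables with planted differential features, pooled-QC replicates and
  uniform missingness;
* :func:`simulate_quant_dataset` — pooled-larvae extract concentrations,
  the exact inverse of the body-surface conversion plus multiplicative
  noise;
* :func:`simulate_bioassay` — binomial conidial-germination counts and
  normal colony diameters under a monotone dose-effect model;
* :func:`simulate_survival` — exponential event times interval-censored on
  the observation grid, right-censored at the horizon.

Every generator draws all randomness from one ``numpy`` generator seeded
per call; identical seed and configuration give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import load_compound_library
from .errors import InputError
from .feature_io import FeatureTable, make_feature_id

DEFAULT_GROUPS = ("LB", "QC", "B108", "B253", "B263", "B313", "B424", "B505", "B585")


@dataclass(frozen=True)
class SimFeatureConfig:
    """Study design of one simulated feature table.

    Six replicates per group reflects the design of the culture-supernatant
    metabolomics experiment.  Intensities are log10-normal: feature j in
    group g has log10 intensity ``N(mu_j + offset_jg, baseline_log_sd)``
    where ``mu_j`` is a per-feature baseline around ``baseline_log_mean``
    and the offset encodes planted fold changes.
    """

    n_features_per_mode: int = 200
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_reps_per_group: int = 6
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 0.15
    qc_noise_sd: float = 0.05
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps_per_group < 2:
            raise InputError("n_reps_per_group must be >= 2")
        if not 0 <= self.missing_rate < 1:
            raise InputError("missing_rate must be in [0, 1)")
        if "LB" not in self.groups or "QC" not in self.groups:
            raise InputError("groups must include 'LB' and 'QC'")
        if self.n_features_per_mode < 1:
            raise InputError("need at least one feature")


@dataclass(frozen=True)
class PlantedCandidate:
    """A feature planted as truly differential for some strains.

    The planted feature's mean is ``fc_vs_lb`` times the LB baseline in each
    target strain, and the non-protective control strain B313 receives a
    mean such that strain/B313 equals ``fc_vs_b313``.
    """

    feature_index: int
    target_strains: tuple[str, ...]
    fc_vs_lb: float
    fc_vs_b313: float
    compound_cas: str = ""

    def __post_init__(self) -> None:
        if not self.target_strains:
            raise InputError("target_strains must be nonempty")
        for fc in (self.fc_vs_lb, self.fc_vs_b313):
            if not (math.isfinite(fc) and fc > 0):
                raise InputError("fold changes must be finite and positive")


@dataclass(frozen=True)
class TruthSet:
    planted: tuple[PlantedCandidate, ...]
    seed: int

    def __post_init__(self) -> None:
        idx = [p.feature_index for p in self.planted]
        if len(idx) != len(set(idx)):
            raise InputError("planted feature_index values must be unique")

    def to_frame(self, feature_ids: list[str]) -> pd.DataFrame:
        rows = []
        for p in self.planted:
            for strain in p.target_strains:
                rows.append(
                    {
                        "feature_id": feature_ids[p.feature_index],
                        "strain": strain,
                        "fc_vs_lb": p.fc_vs_lb,
                        "fc_vs_b313": p.fc_vs_b313,
                        "cas": p.compound_cas,
                    }
                )
        return pd.DataFrame(rows, columns=["feature_id", "strain", "fc_vs_lb",
                                           "fc_vs_b313", "cas"])


def simulate_feature_table(
    config: SimFeatureConfig,
    planted: list[PlantedCandidate] = (),
    ion_mode: str = "positive",
) -> tuple[FeatureTable, TruthSet]:
    """Simulate one ion mode's feature table plus its ground truth.

    QC samples are the per-feature grand mean of all biological samples
    perturbed by ``qc_noise_sd`` on the log10 scale.  Missing entries are
    planted uniformly at ``missing_rate`` but never in QC columns of
    planted features.  A planted candidate carrying a CAS number found in
    the packaged compound library receives that compound's adduct m/z (with
    sub-ppm jitter) so annotation works end to end.
    """
    rng = np.random.default_rng(config.seed)
    n_feat = config.n_features_per_mode
    for p in planted:
        if not 0 <= p.feature_index < n_feat:
            raise InputError(f"planted index {p.feature_index} out of range")
        for s in p.target_strains:
            if s not in config.groups:
                raise InputError(f"unknown group label {s!r} in planted candidate")
            if s in ("LB", "QC"):
                raise InputError("target_strains must be strain labels, not LB/QC")

    strains = [g for g in config.groups if g not in ("LB", "QC")]
    bio_groups = ["LB"] + strains
    n_reps = config.n_reps_per_group

    # per-feature baseline log10 mean, spread so features differ in abundance
    mu = config.baseline_log_mean + rng.normal(0.0, 0.5, size=n_feat)

    # log10 fold-change offsets per feature x biological group
    offsets = pd.DataFrame(0.0, index=range(n_feat), columns=bio_groups)
    for p in planted:
        up = math.log10(p.fc_vs_lb)
        for s in p.target_strains:
            offsets.loc[p.feature_index, s] = up
        if "B313" in bio_groups and "B313" not in p.target_strains:
            offsets.loc[p.feature_index, "B313"] = up - math.log10(p.fc_vs_b313)

    columns, groups_out, data = [], [], []
    for g in bio_groups:
        log_mean = mu + offsets[g].to_numpy()
        vals = 10 ** rng.normal(
            log_mean[:, None], config.baseline_log_sd, size=(n_feat, n_reps)
        )
        data.append(vals)
        columns += [f"{g}_{r + 1}" for r in range(n_reps)]
        groups_out += [g] * n_reps
    bio = np.concatenate(data, axis=1)

    # QC: noisy per-feature grand mean of the biological samples
    grand = bio.mean(axis=1)
    qc = grand[:, None] * 10 ** rng.normal(
        0.0, config.qc_noise_sd, size=(n_feat, n_reps)
    )
    columns += [f"QC_{r + 1}" for r in range(n_reps)]
    groups_out += ["QC"] * n_reps
    matrix = np.concatenate([bio, qc], axis=1)

    if config.missing_rate > 0:
        mask = rng.random(matrix.shape) < config.missing_rate
        planted_rows = np.array([p.feature_index for p in planted], dtype=int)
        qc_cols = np.array([c.startswith("QC_") for c in columns])
        if planted_rows.size:
            mask[np.ix_(planted_rows, qc_cols)] = False
        matrix = np.where(mask, np.nan, matrix)

    # feature m/z & RT; planted features with a known CAS get the real adduct m/z
    mz = rng.uniform(70.0, 600.0, size=n_feat)
    rt = rng.uniform(30.0, 900.0, size=n_feat)
    by_cas = {c.cas: c for c in load_compound_library()}
    for p in planted:
        if p.compound_cas and p.compound_cas in by_cas:
            true_mz = by_cas[p.compound_cas].adduct_mz(ion_mode)
            mz[p.feature_index] = true_mz * (1 + rng.uniform(-2e-6, 2e-6))

    feature_ids, seen = [], set()
    for j in range(n_feat):
        fid = make_feature_id(mz[j], rt[j])
        while fid in seen:  # collisions are rare; jitter RT to keep ids unique
            rt[j] += 1.0
            fid = make_feature_id(mz[j], rt[j])
        seen.add(fid)
        feature_ids.append(fid)

    features = pd.DataFrame(
        {"mz": mz, "rt_seconds": rt, "ion_mode": ion_mode},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    samples = pd.DataFrame(
        {
            "group": groups_out,
            "replicate": [int(c.rsplit("_", 1)[1]) for c in columns],
        },
        index=pd.Index(columns, name="sample_id"),
    )
    intensities = pd.DataFrame(matrix, index=features.index, columns=samples.index)
    table = FeatureTable(features, samples, intensities)
    return table, TruthSet(tuple(planted), config.seed)


# ---------------------------------------------------------------------------
# Pooled-extract quantification data
# ---------------------------------------------------------------------------

def simulate_quant_dataset(
    true_conc_by_group: dict[str, tuple[float, float]],
    cv: float = 0.1,
    n_reps: int = 5,
    seed: int = 0,
    n_larvae: int = 20,
    extract_volume_l: float = 0.0015,
    water_mass_mg: float = 0.0920,
) -> pd.DataFrame:
    """Pooled-extract concentrations implied by true body-surface values.

    ``true_conc_by_group`` maps metabolite -> (axenic, nonaxenic) true
    body-surface concentration in mg/liter.  The forward model pools
    ``n_larvae`` larvae into ``extract_volume_l`` liters of wash water, so
    the extract concentration is ``C * water_mass_mg*1e-6 * n_larvae /
    extract_volume_l``; replicates get multiplicative log-normal noise with
    coefficient of variation ``cv``.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    if cv < 0:
        raise InputError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1 + cv**2)) if cv > 0 else 0.0
    rows = []
    for metabolite, (axenic, nonaxenic) in true_conc_by_group.items():
        for group, conc in (("axenic", axenic), ("nonaxenic", nonaxenic)):
            if conc < 0:
                raise InputError(f"negative concentration for {metabolite!r}")
            extract = conc * (water_mass_mg * 1e-6) * n_larvae / extract_volume_l
            noise = (
                np.exp(rng.normal(-sigma**2 / 2, sigma, size=n_reps))
                if sigma > 0
                else np.ones(n_reps)
            )
            for r in range(n_reps):
                rows.append(
                    {
                        "metabolite": metabolite,
                        "group": group,
                        "replicate": r + 1,
                        "extract_conc_mg_per_l": extract * noise[r],
                        "n_larvae": n_larvae,
                        "extract_volume_l": extract_volume_l,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dose-response bioassay data
# ---------------------------------------------------------------------------

def simulate_bioassay(
    dose_multipliers: list[float],
    effect_model,
    n_reps: int = 6,
    seed: int = 0,
    assay: str = "germination",
    n_conidia: int = 100,
    control_germination: float = 0.8,
    control_diameter_mm: float = 43.0,
    plug_diameter_mm: float = 3.0,
    diameter_sd_mm: float = 0.5,
) -> pd.DataFrame:
    """Dose-response measurements under a monotone effect model.

    ``effect_model(dose_multiplier)`` returns the response fraction relative
    to control (1 at dose 0).  Germination: binomial counts out of
    ``n_conidia`` with success probability ``control_germination *
    effect_model(dose)``.  Growth: normal colony diameters whose net extent
    (diameter minus plug) scales with the effect.
    """
    if assay not in ("germination", "growth"):
        raise InputError(f"unknown assay {assay!r}")
    if any(m < 0 for m in dose_multipliers):
        raise InputError("dose multipliers must be >= 0")
    if abs(effect_model(0) - 1) > 1e-12:
        raise InputError("effect_model(0) must equal 1")
    rng = np.random.default_rng(seed)
    doses = [0.0] + [float(m) for m in dose_multipliers if m > 0]
    rows = []
    for dose in doses:
        eff = float(effect_model(dose))
        if assay == "germination":
            p = control_germination * eff
            if not 0 <= p <= 1:
                raise InputError(
                    f"effect_model gives germination probability {p} outside [0, 1]"
                )
            counts = rng.binomial(n_conidia, p, size=n_reps)
            values = counts / n_conidia
        else:
            net = (control_diameter_mm - plug_diameter_mm) * eff
            values = plug_diameter_mm + np.maximum(
                rng.normal(net, diameter_sd_mm, size=n_reps), 0.0
            )
        for r in range(n_reps):
            rows.append({"assay": assay, "dose_level": dose, "replicate": r + 1,
                         "value": float(values[r])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Survival data
# ---------------------------------------------------------------------------

def simulate_survival(
    group_hazards: dict[str, float],
    n_per_group: int = 45,
    horizon_days: int = 14,
    obs_interval_days: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times observed on a fixed-interval grid.

    Deaths are recorded at the first observation day on or after the true
    event time; subjects alive at ``horizon_days`` are censored there.
    Returns records of (subject_id, group, time_days, event).
    """
    if horizon_days <= 0 or obs_interval_days <= 0:
        raise InputError("horizon and observation interval must be positive")
    if any(h < 0 for h in group_hazards.values()):
        raise InputError("hazards must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, hazard in group_hazards.items():
        if hazard > 0:
            times = rng.exponential(1.0 / hazard, size=n_per_group)
        else:
            times = np.full(n_per_group, np.inf)
        for i, t in enumerate(times):
            if t <= horizon_days:
                obs = math.ceil(t / obs_interval_days) * obs_interval_days
                rows.append({"subject_id": f"{group}_{i + 1}", "group": group,
                             "time_days": float(min(obs, horizon_days)), "event": 1})
            else:
                rows.append({"subject_id": f"{group}_{i + 1}", "group": group,
                             "time_days": float(horizon_days), "event": 0})
    return pd.DataFrame(rows)
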