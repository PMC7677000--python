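"""End-to-end driver: simulate -> qc -> screen -> annotate -> quantify ->
cocktail -> bioassay -> survival.

:func:`run_all` chains every stage on synthetic inputs (or user-supplied
tables), writes all intermediate tables under an output directory and
returns a report dictionary plus a machine-readable manifest carrying the
seeds and a hash of the configuration, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import contextlib
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, cocktail_bioassay, feature_io, quantify, screening
from . import survival_stats, synthetic_data
from .errors import InputError

logger = logging.getLogger(__name__)


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "symbioscreen_run",
    "log_level": "INFO",
    "simulate": {
        "n_features_per_mode": 120,
        "n_reps_per_group": 6,
        "baseline_log_sd": 0.15,
        "qc_noise_sd": 0.05,
        "missing_rate": 0.02,
        "n_planted_per_mode": 3,
        "planted_fc_vs_lb": 8.0,
        "planted_fc_vs_b313": 32.0,
    },
    "qc": {"max_qc_rsd": 0.30, "min_presence_fraction": 0.5},
    "screen": {"fc_lb_min": 2.0, "alpha": 0.05, "vip_min": 2.0,
               "ratio_b313_min": 10.0, "n_components": 2},
    "annotate": {"tol_ppm": 10.0},
    "quantify": {"water_mass_mg": 0.0920, "cv": 0.05, "n_reps": 5},
    "cocktail": {"source_group": "nonaxenic", "inclusion_threshold": 0.1},
    "bioassay": {"n_reps": 6},
    "survival": {"n_per_group": 45, "horizon_days": 14, "obs_interval_days": 2,
                 "hazard_bb": 0.15, "hazard_protected": 0.03},
}


def load_config(path=None) -> dict:
    """DEFAULT_CONFIG, deep-merged with an optional YAML file."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _demo_planted(sim_cfg: dict, mode: str) -> list[synthetic_data.PlantedCandidate]:
    """Plant a few true candidates carrying real compound identities so
    annotation resolves end to end."""
    library = [c for c in annotation.load_compound_library() if not c.is_nutrient]
    strains = ("B108", "B253", "B263", "B424", "B505", "B585")
    n = int(sim_cfg["n_planted_per_mode"])
    offset = 0 if mode == "positive" else n
    planted = []
    for i in range(n):
        compound = library[(offset + i) % len(library)]
        planted.append(
            synthetic_data.PlantedCandidate(
                feature_index=i,
                target_strains=(strains[(offset + i) % len(strains)],),
                fc_vs_lb=float(sim_cfg["planted_fc_vs_lb"]),
                fc_vs_b313=float(sim_cfg["planted_fc_vs_b313"]),
                compound_cas=compound.cas,
            )
        )
    return planted


@contextlib.contextmanager
def _stage(name: str):
    """Re-raise any stage failure with the stage name attached; partial
    outputs written before the failure are retained on disk."""
    try:
        yield
    except Exception as exc:
        raise InputError(f"stage {name!r} failed: {exc}") from exc


def run_all(config: dict | None = None, out_dir=None) -> dict:
    """Execute every stage; returns the run report (also written as JSON)."""
    config = config or load_config()
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    report: dict = {"stages": {}}

    # --- simulate + screen per ion mode --------------------------------
    tables = {}
    truth_frames = []
    for k, mode in enumerate(("positive", "negative")):
        sim_cfg = config["simulate"]
        cfg = synthetic_data.SimFeatureConfig(
            n_features_per_mode=int(sim_cfg["n_features_per_mode"]),
            n_reps_per_group=int(sim_cfg["n_reps_per_group"]),
            baseline_log_sd=float(sim_cfg["baseline_log_sd"]),
            qc_noise_sd=float(sim_cfg["qc_noise_sd"]),
            missing_rate=float(sim_cfg["missing_rate"]),
            seed=seed + k,
        )
        planted = _demo_planted(sim_cfg, mode)
        table, truth = synthetic_data.simulate_feature_table(cfg, planted, mode)
        feature_io.write_feature_table(
            table, out / f"features_{mode}.tsv", out / f"groups_{mode}.tsv"
        )
        truth_frames.append(truth.to_frame(list(table.features.index)))
        qc_cfg = feature_io.QcFilterConfig(**config["qc"])
        filtered = feature_io.qc_filter(table, qc_cfg)
        cleaned = feature_io.normalize(feature_io.impute_missing(filtered))
        tables[mode] = cleaned
        report["stages"][f"simulate_{mode}"] = {
            "n_features": len(table.features),
            "n_after_qc": len(filtered.features),
        }
    pd.concat(truth_frames).to_csv(out / "truth_set.tsv", sep="\t", index=False)

    screen_cfg = screening.ScreenConfig(**config["screen"])
    candidates = screening.run_cascade(tables, config=screen_cfg)
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    report["stages"]["screen"] = {"n_candidate_rows": len(candidates)}

    # --- annotate -------------------------------------------------------
    with _stage("annotation"):
        library = annotation.load_compound_library(config.get("library_path"))
        annotated = annotation.annotate_candidates(
            candidates, library, tol_ppm=float(config["annotate"]["tol_ppm"])
        )
        annotated.to_csv(out / "candidates_annotated.tsv", sep="\t", index=False)
        unique = annotation.finalize_candidates(annotated)
        unique.to_csv(out / "unique_compounds.tsv", sep="\t", index=False)
    report["stages"]["annotate"] = {
        "n_annotated_rows": int((annotated["cas"].astype(str).str.len() > 0).sum())
        if len(annotated) else 0,
        "n_unique_compounds": len(unique),
    }

    # --- quantify (synthetic pooled extracts from reference means) ------
    ref = pd.read_csv(
        Path(__file__).parent / "data" / "surface_concentrations.tsv", sep="\t"
    )
    true_conc = {}
    for metabolite, grp in ref.groupby("metabolite", sort=False):
        ax = grp.loc[grp["group"] == "axenic"]
        nx = grp.loc[grp["group"] == "nonaxenic"]
        if not int(ax["detected"].iloc[0]) or not int(nx["detected"].iloc[0]):
            continue
        true_conc[metabolite] = (
            float(ax["mean_mg_per_l"].iloc[0]), float(nx["mean_mg_per_l"].iloc[0])
        )
    qcfg = config["quantify"]
    quant = synthetic_data.simulate_quant_dataset(
        true_conc, cv=float(qcfg["cv"]), n_reps=int(qcfg["n_reps"]), seed=seed + 10,
        water_mass_mg=float(qcfg["water_mass_mg"]),
    )
    quantified = quantify.quantify_dataset(quant, float(qcfg["water_mass_mg"]))
    quantified.to_csv(out / "quantified.tsv", sep="\t", index=False)
    comparisons = quantify.compare_all(quantified)
    comparisons.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
    means = quantify.group_mean_concentrations(quantified)
    means.to_csv(out / "surface_concentration_means.tsv", sep="\t", index=False)
    report["stages"]["quantify"] = {"n_metabolites": len(true_conc)}

    # --- cocktail + bioassay --------------------------------------------
    ccfg = config["cocktail"]
    recipe = cocktail_bioassay.build_recipe(
        ref, source_group=ccfg["source_group"],
        inclusion_threshold=float(ccfg["inclusion_threshold"]),
    )
    doses = cocktail_bioassay.dose_series(recipe)
    doses.to_csv(out / "dose_series.tsv", sep="\t", index=False)
    report["stages"]["cocktail"] = {
        "components": recipe.components, "n_doses": len(doses),
    }

    def effect(dose):  # monotone saturating inhibition
        return 1.0 / (1.0 + 5.0 * dose)

    bioassays = {}
    for assay in ("germination", "growth"):
        data = synthetic_data.simulate_bioassay(
            list(cocktail_bioassay.DEFAULT_MULTIPLIERS), effect,
            n_reps=int(config["bioassay"]["n_reps"]), seed=seed + 20, assay=assay,
        )
        data.to_csv(out / f"bioassay_{assay}.tsv", sep="\t", index=False)
        rates = cocktail_bioassay.relative_rate(data)
        rates.to_csv(out / f"relative_rates_{assay}.tsv", sep="\t", index=False)
        summary = cocktail_bioassay.dose_response_summary(data)
        bioassays[assay] = {
            "omnibus_test": summary.omnibus_test,
            "p_value": summary.p_value,
            "rate_at_insitu_pct": float(
                rates.loc[rates["dose_level"] == 1.0, "relative_rate_pct"].iloc[0]
            ),
        }
    report["stages"]["bioassay"] = bioassays

    # --- survival --------------------------------------------------------
    scfg = config["survival"]
    surv = synthetic_data.simulate_survival(
        {"Bb": float(scfg["hazard_bb"]),
         "Bb+Cocktail": float(scfg["hazard_protected"])},
        n_per_group=int(scfg["n_per_group"]),
        horizon_days=int(scfg["horizon_days"]),
        obs_interval_days=int(scfg["obs_interval_days"]), seed=seed + 30,
    )
    surv.to_csv(out / "survival.tsv", sep="\t", index=False)
    curves = {
        g: survival_stats.km_estimate(surv, g) for g in ("Bb", "Bb+Cocktail")
    }
    for g, curve in curves.items():
        survival_stats.km_table(curve).to_csv(
            out / f"km_{g.replace('+', '_')}.tsv", sep="\t", index=False
        )
    lr = survival_stats.logrank_test(surv, "Bb", "Bb+Cocktail")
    report["stages"]["survival"] = {
        "final_survival": {g: c.final_survival for g, c in curves.items()},
        "logrank_chi_square": lr.chi_square,
        "logrank_p": lr.p_value,
    }

    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    report["manifest"] = manifest
    return report
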