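"""Compound annotation of screened features by accurate-mass matching.

A feature is annotated with a library compound when the observed m/z lies
within a ppm tolerance (default 10 ppm) of the compound's expected adduct
m/z: ``M + 1.007276`` for ``[M+H]+`` in positive mode, ``M - 1.007276`` for
``[M-H]-`` in negative mode.  Compounds flagged as common microbial
nutrients (amino acids, sugars) are excluded before bioassay follow-up, and
the remaining annotations are collapsed to a unique compound list by CAS
number across strains and ion modes.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass

import pandas as pd

from .errors import InputError
from .feature_io import FeatureMeta

logger = logging.getLogger(__name__)

#: Mass of a proton in Da, used for [M+H]+ / [M-H]- adducts.
PROTON_MASS = 1.007276

#: Monoisotopic atomic masses (Da) for formula arithmetic.
ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}


def mass_from_formula(formula: str) -> float:
    """Monoisotopic mass of a simple molecular formula like ``C10H7NO3``."""
    tokens = re.findall(r"([A-Z][a-z]?)(\d*)", formula)
    mass = 0.0
    seen = False
    for element, count in tokens:
        if not element:
            continue
        if element not in ATOMIC_MASS:
            raise InputError(f"unsupported element {element!r} in formula {formula!r}")
        mass += ATOMIC_MASS[element] * (int(count) if count else 1)
        seen = True
    if not seen or mass <= 0:
        raise InputError(f"cannot parse formula {formula!r}")
    return mass


@dataclass(frozen=True)
class Compound:
    name: str
    cas: str
    formula: str
    monoisotopic_mass: float
    is_nutrient: bool = False

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise InputError("monoisotopic_mass must be positive")

    def adduct_mz(self, ion_mode: str) -> float:
        """Expected m/z of the protonated/deprotonated molecule."""
        if ion_mode == "positive":
            return self.monoisotopic_mass + PROTON_MASS
        if ion_mode == "negative":
            return self.monoisotopic_mass - PROTON_MASS
        raise InputError(f"unknown ion mode {ion_mode!r}")


@dataclass(frozen=True)
class Annotation:
    feature_id: str
    compound: Compound
    adduct: str
    ppm_error: float


def load_compound_library(path=None) -> list[Compound]:
    """Load a compound library (packaged default: the 10 candidate
    metabolites plus 4 nutrient compounds).

    Format: delimited text with columns ``name, cas, formula,
    monoisotopic_mass, is_nutrient``.  Masses are recomputed from the
    formula; a stored mass deviating by more than 0.001 Da is rejected.
    """
    if path is None:
        path = importlib.resources.files("symbioscreen.data") / "compound_library.tsv"
    df = pd.read_csv(path, sep="\t")
    compounds = []
    seen_cas: set[str] = set()
    for row in df.itertuples(index=False):
        mass = mass_from_formula(row.formula)
        if abs(mass - float(row.monoisotopic_mass)) > 1e-3:
            raise InputError(
                f"library mass {row.monoisotopic_mass} for {row.name!r} "
                f"disagrees with formula {row.formula!r} ({mass:.5f})"
            )
        if row.cas in seen_cas:
            raise InputError(f"duplicate CAS {row.cas!r} in library")
        seen_cas.add(row.cas)
        compounds.append(
            Compound(row.name, row.cas, row.formula, mass, bool(row.is_nutrient))
        )
    return compounds


def ppm_match(
    feature: FeatureMeta, library: list[Compound], tol_ppm: float = 10.0
) -> list[Annotation]:
    """All library compounds whose adduct m/z is within ``tol_ppm`` of the
    feature's observed m/z, sorted by absolute ppm error.
    """
    if tol_ppm <= 0:
        raise InputError("tol_ppm must be positive")
    if not library:
        raise InputError("compound library is empty")
    adduct = "[M+H]+" if feature.ion_mode == "positive" else "[M-H]-"
    hits = []
    for compound in library:
        expected = compound.adduct_mz(feature.ion_mode)
        ppm = (feature.mz - expected) / expected * 1e6
        if abs(ppm) <= tol_ppm:
            hits.append(Annotation(feature.feature_id, compound, adduct, ppm))
    hits.sort(key=lambda a: abs(a.ppm_error))
    return hits


def exclude_nutrients(annotations: list[Annotation]) -> list[Annotation]:
    """Drop annotations to compounds used as common microbial nutrients."""
    kept = []
    for ann in annotations:
        if ann.compound.is_nutrient:
            logger.info(
                "excluding nutrient compound %s (%s) for feature %s",
                ann.compound.name, ann.compound.cas, ann.feature_id,
            )
        else:
            kept.append(ann)
    return kept


def annotate_candidates(
    candidate_table: pd.DataFrame,
    library: list[Compound],
    tol_ppm: float = 10.0,
    drop_nutrients: bool = True,
) -> pd.DataFrame:
    """Attach ``compound``/``cas``/``ppm_error`` columns to a candidate table
    by accurate-mass matching.  Rows without a match keep empty annotations;
    a row with several equally close matches is flagged ``ambiguous``.
    """
    rows = []
    for rec in candidate_table.itertuples(index=False):
        meta = FeatureMeta(rec.feature_id, float(rec.mz), float(rec.rt_seconds), rec.ion_mode)
        hits = ppm_match(meta, library, tol_ppm)
        if drop_nutrients:
            hits = exclude_nutrients(hits)
        base = rec._asdict()
        if not hits:
            rows.append({**base, "compound": "", "cas": "", "ppm_error": float("nan"),
                         "ambiguous": False})
            continue
        best = abs(hits[0].ppm_error)
        tied = [h for h in hits if abs(abs(h.ppm_error) - best) < 1e-12]
        for hit in tied:
            rows.append({**base, "compound": hit.compound.name, "cas": hit.compound.cas,
                         "ppm_error": hit.ppm_error, "ambiguous": len(tied) > 1})
    return pd.DataFrame(rows)


def finalize_candidates(candidate_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse an annotated candidate table to unique compounds.

    Rows sharing a CAS number (across strains and ion modes) become one
    compound with its supporting rows counted; unannotated rows are dropped.
    Returns a frame with columns ``compound, cas, n_supporting, strains,
    max_ratio_vs_b313, max_vip, min_p_value`` sorted by compound name.
    """
    if len(candidate_table) == 0 or "cas" not in candidate_table.columns:
        return pd.DataFrame(
            columns=["compound", "cas", "n_supporting", "strains",
                     "max_ratio_vs_b313", "max_vip", "min_p_value"]
        )
    annotated = candidate_table[
        candidate_table["cas"].astype(str).str.len() > 0
    ].copy()
    out = []
    for cas, grp in annotated.groupby("cas", sort=False):
        out.append(
            {
                "compound": grp["compound"].iloc[0],
                "cas": cas,
                "n_supporting": len(grp),
                "strains": ",".join(sorted(set(grp["strain"]))) if "strain" in grp else "",
                "max_ratio_vs_b313": grp["ratio_vs_b313"].max()
                if "ratio_vs_b313" in grp else float("nan"),
                "max_vip": grp["vip"].max() if "vip" in grp else float("nan"),
                "min_p_value": grp["p_value"].min() if "p_value" in grp else float("nan"),
            }
        )
    result = pd.DataFrame(out).sort_values("compound", kind="stable").reset_index(drop=True)
    return result


def load_candidate_fixture() -> pd.DataFrame:
    """The packaged 32-row candidate-metabolite table (screened features with
    strain, vs-control ratio, p value, VIP and compound assignment)."""
    path = importlib.resources.files("symbioscreen.data") / "candidate_metabolites.tsv"
    return pd.read_csv(path, sep="\t")
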