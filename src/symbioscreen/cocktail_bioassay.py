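"""Cocktail formulation, dose series and bioassay summarization.

The protective cocktail is reconstituted from the measured in-situ
body-surface concentrations: every candidate metabolite detected at a
group-mean concentration of at least ``inclusion_threshold`` mg/liter
(default 0.1) enters the recipe at that concentration.  Doses span a
twofold series (2^1 down to 2^-6 times the in-situ concentration) plus an
untreated control.  Germination and mycelial-growth measurements are
summarized as mean percent of control — net colony growth subtracts the
3-mm inoculation plug — and compared across doses with a test-selection
tree (one-way ANOVA + Tukey HSD, Welch's ANOVA + Dunnett T3, or
Kruskal-Wallis + Bonferroni-corrected Mann-Whitney) summarized as a
compact letter display.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .quantify import _normal_p

logger = logging.getLogger(__name__)

DEFAULT_INCLUSION_THRESHOLD = 0.1  # mg/liter
DEFAULT_PLUG_DIAMETER_MM = 3.0
DEFAULT_MULTIPLIERS = tuple(2.0**k for k in range(1, -7, -1))  # 2^1 .. 2^-6


@dataclass(frozen=True)
class CocktailRecipe:
    components: dict[str, float]  # metabolite -> mg/liter
    source_group: str
    inclusion_threshold: float = DEFAULT_INCLUSION_THRESHOLD

    def __post_init__(self) -> None:
        if not self.components:
            raise InputError("no components above threshold")
        if any(c < self.inclusion_threshold for c in self.components.values()):
            raise InputError("component below inclusion threshold")


def build_recipe(
    concentrations: pd.DataFrame,
    source_group: str = "nonaxenic",
    inclusion_threshold: float = DEFAULT_INCLUSION_THRESHOLD,
) -> CocktailRecipe:
    """Recipe from a per-metabolite, per-group mean concentration table.

    ``concentrations`` needs columns ``metabolite, group, mean_mg_per_l``
    and optionally ``detected`` (0 marks below-detection metabolites, which
    are excluded regardless of threshold).  Concentrations are copied
    verbatim; metabolites whose group mean is below ``inclusion_threshold``
    are left out.
    """
    sub = concentrations[concentrations["group"] == source_group]
    if sub.empty:
        raise InputError(f"no concentrations for group {source_group!r}")
    components = {}
    for row in sub.itertuples(index=False):
        detected = bool(getattr(row, "detected", 1))
        conc = float(row.mean_mg_per_l) if detected else float("nan")
        if not detected or np.isnan(conc):
            logger.info("cocktail: %s undetected, excluded", row.metabolite)
            continue
        if conc >= inclusion_threshold:
            components[row.metabolite] = conc
        else:
            logger.info("cocktail: %s at %.4g mg/liter below threshold %.4g",
                        row.metabolite, conc, inclusion_threshold)
    if not components:
        raise InputError("no components above threshold")
    return CocktailRecipe(components, source_group, inclusion_threshold)


def dose_series(
    recipe: CocktailRecipe, multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS
) -> pd.DataFrame:
    """Per-dose component concentrations; a control row (multiplier 0) is
    appended.  Rows are ordered by decreasing multiplier."""
    if any(m < 0 for m in multipliers):
        raise InputError("multipliers must be >= 0")
    mults = sorted({float(m) for m in multipliers if m > 0}, reverse=True) + [0.0]
    rows = [
        {"multiplier": m, **{k: m * v for k, v in recipe.components.items()}}
        for m in mults
    ]
    return pd.DataFrame(rows)


def relative_rate(
    dataset: pd.DataFrame, plug_diameter_mm: float = DEFAULT_PLUG_DIAMETER_MM
) -> pd.DataFrame:
    """Per-dose mean response as percent of the control dose.

    Germination uses the germinated fraction directly; growth first
    subtracts the inoculation plug from each colony diameter.  The control
    is the ``dose_level == 0`` group.
    """
    assay = dataset["assay"].iloc[0]
    if (dataset["assay"] != assay).any():
        raise InputError("mixed assays in one dataset")
    values = dataset["value"].astype(float)
    if assay == "growth":
        values = values - plug_diameter_mm
        if (values < -1e-9).any():
            raise InputError("colony diameter below plug diameter")
    df = dataset.assign(net=values)
    if not (df["dose_level"] == 0).any():
        raise InputError("control dose (0) missing")
    control_mean = df.loc[df["dose_level"] == 0, "net"].mean()
    if control_mean == 0:
        raise InputError("control mean response is zero")
    out = (
        df.groupby("dose_level", sort=False)["net"]
        .mean()
        .reset_index()
        .rename(columns={"net": "mean_response"})
    )
    out["relative_rate_pct"] = 100.0 * out["mean_response"] / control_mean
    return out


# ---------------------------------------------------------------------------
# Omnibus test selection and multiple comparisons
# ---------------------------------------------------------------------------

def welch_anova(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    Returns (F, df1, df2, p).
    """
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    if np.any(v == 0):
        v = np.maximum(v, 1e-300)
    w = n / v
    mw = float((w * m).sum() / w.sum())
    h = (1 - w / w.sum()) ** 2 / (n - 1)
    num = float((w * (m - mw) ** 2).sum()) / (k - 1)
    den = 1 + 2 * (k - 2) / (k**2 - 1) * float(h.sum())
    f = num / den
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * float(h.sum()))
    p = float(stats.f.sf(f, df1, df2))
    return f, float(df1), df2, p


def _dunnett_t3_pairs(groups, labels, alpha):
    """All-pairs Welch comparisons with a studentized-maximum-modulus style
    (Sidak) adjustment over the number of comparisons."""
    m = len(labels) * (len(labels) - 1) // 2
    sig = {}
    for (i, la), (j, lb) in itertools.combinations(enumerate(labels), 2):
        res = stats.ttest_ind(groups[i], groups[j], equal_var=False)
        p_adj = 1 - (1 - min(1.0, float(res.pvalue))) ** m
        sig[(la, lb)] = p_adj < alpha
    return sig


def _tukey_pairs(groups, labels, alpha):
    res = stats.tukey_hsd(*groups)
    sig = {}
    for (i, la), (j, lb) in itertools.combinations(enumerate(labels), 2):
        sig[(la, lb)] = float(res.pvalue[i, j]) < alpha
    return sig


def _mannwhitney_bonferroni_pairs(groups, labels, alpha):
    m = len(labels) * (len(labels) - 1) // 2
    sig = {}
    for (i, la), (j, lb) in itertools.combinations(enumerate(labels), 2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(
                stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided",
                                   method="asymptotic").pvalue
            )
        sig[(la, lb)] = min(1.0, p * m) < alpha
    return sig


def compact_letter_display(labels, means, significant) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant`` maps unordered label pairs to booleans.  Groups sharing
    a letter are not significantly different.  Letters are assigned in
    order of decreasing group mean.
    """
    order = [lab for _, lab in sorted(zip(means, labels), key=lambda t: -t[0])]
    sets: list[set[str]] = [set(order)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        for current in list(sets):
            if a in current and b in current:
                sets.remove(current)
                sets.extend([current - {a}, current - {b}])
        # absorb subsets
        sets = [s for s in sets if s and not any(s < t for t in sets if t is not s)]
    # deduplicate while keeping order by best member
    uniq = []
    for s in sets:
        if s not in uniq:
            uniq.append(s)
    uniq.sort(key=lambda s: min(order.index(x) for x in s))
    letters = {lab: "" for lab in labels}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", uniq):
        for lab in s:
            letters[lab] += letter
    return {lab: "".join(sorted(letters[lab])) for lab in labels}


@dataclass
class DoseResponseSummary:
    omnibus_test: str  # anova | welch_anova | kruskal_wallis
    statistic: float
    df: tuple[float, float] | float
    p_value: float
    posthoc_test: str
    letters: dict[float, str]
    group_means: dict[float, float]


def dose_response_summary(
    dataset: pd.DataFrame,
    alpha: float = 0.05,
    plug_diameter_mm: float = DEFAULT_PLUG_DIAMETER_MM,
) -> DoseResponseSummary:
    """Omnibus dose comparison with branch selection and letter display.

    All dose groups Lilliefors-normal: Levene homogeneous -> one-way ANOVA
    with Tukey HSD, else Welch's ANOVA with Dunnett-T3-style pairwise Welch
    comparisons; any normality failure -> Kruskal-Wallis with
    Bonferroni-corrected pairwise Mann-Whitney.
    """
    assay = dataset["assay"].iloc[0]
    values = dataset["value"].astype(float)
    if assay == "growth":
        values = values - plug_diameter_mm
    df = dataset.assign(net=values)
    doses = list(dict.fromkeys(df["dose_level"]))
    if len(doses) < 2:
        raise InputError("dose_response_summary needs >= 2 dose groups")
    groups = [df.loc[df["dose_level"] == d, "net"].to_numpy(dtype=float)
              for d in doses]
    if any(len(g) < 2 for g in groups):
        raise InputError("every dose needs >= 2 replicates")
    means = [float(g.mean()) for g in groups]

    normal = all(_normal_p(g) > alpha for g in groups)
    degenerate = any(np.ptp(g) == 0 for g in groups)
    if normal and not degenerate:
        if stats.levene(*groups, center="mean").pvalue > alpha:
            res = stats.f_oneway(*groups)
            k, n = len(groups), sum(len(g) for g in groups)
            sig = _tukey_pairs(groups, doses, alpha)
            summary = DoseResponseSummary(
                "anova", float(res.statistic), (float(k - 1), float(n - k)),
                float(res.pvalue), "tukey_hsd", {}, dict(zip(doses, means)),
            )
        else:
            f, df1, df2, p = welch_anova(groups)
            sig = _dunnett_t3_pairs(groups, doses, alpha)
            summary = DoseResponseSummary(
                "welch_anova", f, (df1, df2), p, "dunnett_t3", {},
                dict(zip(doses, means)),
            )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.kruskal(*groups)
        sig = _mannwhitney_bonferroni_pairs(groups, doses, alpha)
        summary = DoseResponseSummary(
            "kruskal_wallis", float(res.statistic), float(len(groups) - 1),
            float(res.pvalue), "mann_whitney_bonferroni", {},
            dict(zip(doses, means)),
        )
    summary.letters = compact_letter_display(doses, means, sig)
    return summary
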