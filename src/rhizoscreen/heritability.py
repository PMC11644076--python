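"""Factorial ANOVA, Tukey HSD letter groups, variance components and
broad-sense heritability.

The four treatment codes decompose into a 2 x 2 factorial of
phosphorus supply P (sufficient / low) and water status W (watered /
osmotic stress): C = +P+W, LP = -P+W, D = +P-W, DLP = -P-W. The
factorial ANOVA fits genotype (G), P, W, their interactions and an
additive block term with sequential (type I) sums of squares, which
coincide with all other SS types on balanced data.

Heritability uses the classical expected-mean-squares construction for
a genotype (random) x treatment (fixed) layout with r replicates and e
treatments:

    single treatment:  V_G = (MS_G - MS_E) / r,           V_e = MS_E
                       H = V_G / (V_G + V_e / r)
    combined:          V_GE = (MS_GE - MS_E) / r
                       V_G  = (MS_G - MS_GE) / (r e)
                       H_com = V_G / (V_G + V_GE / e + V_e / (r e))

Negative component estimates are truncated at zero (classical
convention), which keeps H and H_com inside [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnovaResult",
    "VarianceDecomposition",
    "factorial_anova",
    "tukey_letters",
    "variance_components",
    "estimate_heritability",
    "significance_stars",
    "TREATMENT_FACTORS",
]

#: treatment code -> (phosphorus level, water level)
TREATMENT_FACTORS = {
    "C": ("+P", "+W"),
    "LP": ("-P", "+W"),
    "D": ("+P", "-W"),
    "DLP": ("-P", "-W"),
}


def significance_stars(p: float) -> str:
    """Star classes at the conventional 0.05 / 0.01 / 0.001 thresholds."""
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaResult:
    """Fixed-effects ANOVA table (one row per term plus residual)."""

    table: pd.DataFrame  # term, ss, df, ms, F, p, stars

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def factorial_anova(
    trait_table: pd.DataFrame, trait: str, decompose_treatment: bool = True
) -> AnovaResult:
    """ANOVA of one trait over genotype, stress factors and block.

    With ``decompose_treatment=True`` (default) the treatment code is
    split into the P and W factors and the full G x P x W factorial is
    fitted; otherwise treatment enters as a single factor with the
    G x T interaction. Requires a balanced (or near-balanced) design
    with at least two levels per factor and positive residual degrees
    of freedom; missing design cells are an error.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = trait_table[trait_table["trait"] == trait].dropna(subset=["value"])
    if df.empty:
        raise ValueError(f"no data for trait {trait!r}")
    df = df.copy()
    if decompose_treatment:
        unknown = set(df["treatment"]) - set(TREATMENT_FACTORS)
        if unknown:
            raise ValueError(f"treatments without a P x W decomposition: {unknown}")
        df["P"] = df["treatment"].map(lambda t: TREATMENT_FACTORS[t][0])
        df["W"] = df["treatment"].map(lambda t: TREATMENT_FACTORS[t][1])
        formula = "value ~ C(block) + C(genotype) * C(P) * C(W)"
        rename = {
            "C(genotype)": "G",
            "C(P)": "P",
            "C(W)": "W",
            "C(genotype):C(P)": "G:P",
            "C(genotype):C(W)": "G:W",
            "C(P):C(W)": "P:W",
            "C(genotype):C(P):C(W)": "G:P:W",
            "C(block)": "block",
        }
        factor_cols = ["genotype", "P", "W"]
    else:
        formula = "value ~ C(block) + C(genotype) * C(treatment)"
        rename = {
            "C(genotype)": "G",
            "C(treatment)": "T",
            "C(genotype):C(treatment)": "G:T",
            "C(block)": "block",
        }
        factor_cols = ["genotype", "treatment"]

    for col in factor_cols:
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    counts = df.groupby(factor_cols, observed=True).size()
    full = np.prod([df[c].nunique() for c in factor_cols])
    if len(counts) < full:
        raise ValueError(
            f"missing design cells: expected {full}, found {len(counts)}"
        )
    if counts.nunique() > 1:
        warnings.warn(
            "unbalanced design: sequential (type I) sums of squares are "
            "order-dependent", stacklevel=2,
        )

    model = smf.ols(formula, data=df).fit()
    if model.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    aov = sm.stats.anova_lm(model, typ=1)
    aov = aov.rename(index=rename)
    table = pd.DataFrame(
        {
            "term": aov.index,
            "ss": aov["sum_sq"].to_numpy(),
            "df": aov["df"].to_numpy(),
            "ms": (aov["sum_sq"] / aov["df"]).to_numpy(),
            "F": aov["F"].to_numpy(),
            "p": aov["PR(>F)"].to_numpy(),
        }
    ).reset_index(drop=True)
    table.loc[table["term"] == "Residual", "term"] = "residual"
    table["stars"] = [
        significance_stars(p) if t != "residual" else ""
        for t, p in zip(table["term"], table["p"])
    ]
    return AnovaResult(table=table)


def tukey_letters(
    values: pd.Series | pd.DataFrame,
    groups: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD compact letter display over treatment groups.

    Accepts either a data frame with ``value``/``treatment`` columns or
    a value series plus a parallel group series. Groups that are not
    significantly different at ``alpha`` share a letter; letters are
    assigned in descending order of group mean, so the highest mean is
    (or shares) "a". Requires at least two groups with two values each
    and non-zero pooled within-group variance.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if isinstance(values, pd.DataFrame):
        groups = values["treatment"]
        values = values["value"]
    if groups is None:
        raise ValueError("group labels are required")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled_var = sum(
        np.var(values[groups == g], ddof=1) for g in labels
    )
    if pooled_var == 0:
        raise ValueError("zero within-group variance everywhere")

    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pairs = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    different = {
        frozenset((row["group1"], row["group2"]))
        for _, row in pairs.iterrows()
        if row["reject"]
    }

    means = {g: values[groups == g].mean() for g in labels}
    ordered = sorted(labels, key=lambda g: -means[g])

    # insert-and-absorb compact letter display
    letter_sets: list[set] = []
    for g in ordered:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in different for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # drop letter sets fully contained in another
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    letter_sets.sort(key=lambda s: -max(means[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = []
    for g in ordered:
        lets = "".join(
            alphabet[i] for i, s in enumerate(letter_sets) if g in s
        )
        out.append({"treatment": g, "mean": means[g], "letters": lets})
    return pd.DataFrame(out)


@dataclass
class VarianceDecomposition:
    """Variance components and broad-sense heritability."""

    v_g: float
    v_e: float
    r: int
    v_ge: float | None = None
    e: int | None = None
    truncated: bool = False

    @property
    def heritability(self) -> float:
        """Single-treatment broad-sense heritability H."""
        denom = self.v_g + self.v_e / self.r
        return self.v_g / denom if denom > 0 else 0.0

    @property
    def heritability_combined(self) -> float:
        """Across-treatment heritability discounting G x T variance."""
        if self.v_ge is None or self.e is None:
            raise ValueError("combined mode requires v_ge and e")
        denom = self.v_g + self.v_ge / self.e + self.v_e / (self.r * self.e)
        return self.v_g / denom if denom > 0 else 0.0


def variance_components(
    ms_g: float,
    ms_e: float,
    r: int,
    ms_ge: float | None = None,
    e: int | None = None,
) -> VarianceDecomposition:
    """Variance components from ANOVA mean squares.

    Single-treatment mode (``ms_ge`` omitted): V_G = (MS_G - MS_E)/r.
    Combined mode: V_GE = (MS_GE - MS_E)/r and V_G = (MS_G - MS_GE)/(r e).
    Negative estimates are truncated at zero.
    """
    if r < 2:
        raise ValueError("replication r must be >= 2")
    if ms_g < 0 or ms_e < 0 or (ms_ge is not None and ms_ge < 0):
        raise ValueError("mean squares must be >= 0")
    truncated = False
    if ms_ge is None:
        v_g = (ms_g - ms_e) / r
        if v_g < 0:
            v_g, truncated = 0.0, True
        return VarianceDecomposition(v_g=v_g, v_e=ms_e, r=r, truncated=truncated)
    if e is None or e < 1:
        raise ValueError("combined mode requires the number of treatments e >= 1")
    v_ge = (ms_ge - ms_e) / r
    v_g = (ms_g - ms_ge) / (r * e)
    if v_ge < 0:
        v_ge, truncated = 0.0, True
    if v_g < 0:
        v_g, truncated = 0.0, True
    return VarianceDecomposition(
        v_g=v_g, v_e=ms_e, r=r, v_ge=v_ge, e=e, truncated=truncated
    )


def _oneway_ms(values: np.ndarray, genotype: np.ndarray) -> tuple[float, float, int]:
    """One-way genotype ANOVA mean squares (MS_G, MS_E) and df check."""
    df = pd.DataFrame({"g": genotype, "y": values}).dropna()
    groups = df.groupby("g")["y"]
    n = len(df)
    k = groups.ngroups
    grand = df["y"].mean()
    ss_g = float((groups.mean().sub(grand) ** 2 * groups.size()).sum())
    ss_e = float(((df["y"] - groups.transform("mean")) ** 2).sum())
    ms_g = ss_g / (k - 1)
    ms_e = ss_e / (n - k)
    return ms_g, ms_e, k


def estimate_heritability(
    trait_table: pd.DataFrame,
    trait: str,
    treatment: str | None = None,
    log_scale: bool = False,
) -> VarianceDecomposition:
    """Estimate variance components and heritability for one trait.

    With ``treatment`` given, a one-way genotype ANOVA within that
    treatment yields Eq-5-style H. With ``treatment=None`` the
    genotype x treatment two-way ANOVA over all treatments yields the
    combined decomposition. ``log_scale=True`` log-transforms values
    first, matching the generative scale of the synthetic model (only
    valid for strictly positive traits).
    """
    df = trait_table[trait_table["trait"] == trait].dropna(subset=["value"]).copy()
    if treatment is not None:
        df = df[df["treatment"] == treatment]
    if df.empty:
        raise ValueError(f"no data for trait {trait!r}")
    if log_scale:
        if (df["value"] <= 0).any():
            raise ValueError("log_scale requires strictly positive values")
        df["value"] = np.log(df["value"])

    r = int(df.groupby(["genotype", "treatment"], observed=True).size().max())
    if r < 2:
        raise ValueError("need >= 2 replicates per genotype")

    if treatment is not None:
        ms_g, ms_e, _ = _oneway_ms(
            df["value"].to_numpy(), df["genotype"].to_numpy()
        )
        return variance_components(ms_g, ms_e, r=r)

    e = df["treatment"].nunique()
    cell = df.groupby(["genotype", "treatment"], observed=True)["value"]
    cell_mean = cell.mean()
    g_mean = df.groupby("genotype", observed=True)["value"].mean()
    t_mean = df.groupby("treatment", observed=True)["value"].mean()
    grand = df["value"].mean()
    n_g = g_mean.size

    ss_g = float(r * e * ((g_mean - grand) ** 2).sum())
    inter = (
        cell_mean
        - g_mean.reindex(cell_mean.index.get_level_values(0)).to_numpy()
        - t_mean.reindex(cell_mean.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ge = float(r * (inter**2).sum())
    within = df["value"] - cell.transform("mean")
    ss_e = float((within**2).sum())

    ms_g = ss_g / (n_g - 1)
    ms_ge = ss_ge / ((n_g - 1) * (e - 1)) if e > 1 else 0.0
    ms_e = ss_e / (n_g * e * (r - 1))
    return variance_components(ms_g, ms_e, r=r, ms_ge=ms_ge, e=e)
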