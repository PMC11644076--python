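"""Log-response-ratio effect sizes of stress treatments on traits.

For a trait with mean V_s under a stress treatment and V_c under
control (group standard deviations S, sizes n):

    LnR = ln(V_s / V_c)
    %D  = 100 (exp(LnR) - 1)
    v   = S_s^2 / (n_s V_s^2) + S_c^2 / (n_c V_c^2)

Per-effect 95% confidence intervals use the normal approximation
LnR +- 1.96 sqrt(v); overall effects pool records with fixed-effect
inverse-variance weights, the meta-analytic standard for the log
response ratio. An effect is called significant when its interval
excludes zero.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from rhizoscreen.simulate import STRESS_TREATMENTS
from rhizoscreen.traits import genotype_means

__all__ = [
    "Z_95",
    "log_response_ratio",
    "percent_change",
    "lnr_variance",
    "confidence_interval",
    "pool_effects",
    "effect_table",
]

#: normal quantile for a two-sided 95% interval
Z_95 = 1.959963984540054


def log_response_ratio(v_s, v_c):
    """ln(V_s / V_c); both group means must be strictly positive."""
    v_s = np.asarray(v_s, dtype=float)
    v_c = np.asarray(v_c, dtype=float)
    if np.any(v_s <= 0) or np.any(v_c <= 0):
        raise ValueError("group means must be > 0 for a log response ratio")
    out = np.log(v_s / v_c)
    return out if out.ndim else float(out)


def percent_change(lnr):
    """Percent-change transform 100 (exp(LnR) - 1); bounded below by -100."""
    lnr = np.asarray(lnr, dtype=float)
    out = 100.0 * (np.exp(lnr) - 1.0)
    return out if out.ndim else float(out)


def lnr_variance(s_s, n_s, v_s, s_c, n_c, v_c):
    """Sampling variance of LnR from group summaries."""
    s_s, s_c = np.asarray(s_s, float), np.asarray(s_c, float)
    v_s, v_c = np.asarray(v_s, float), np.asarray(v_c, float)
    n_s, n_c = np.asarray(n_s, float), np.asarray(n_c, float)
    if np.any(n_s < 1) or np.any(n_c < 1):
        raise ValueError("group sizes must be >= 1")
    if np.any(v_s <= 0) or np.any(v_c <= 0):
        raise ValueError("group means must be > 0")
    if np.any(s_s < 0) or np.any(s_c < 0):
        raise ValueError("standard deviations must be >= 0")
    out = s_s**2 / (n_s * v_s**2) + s_c**2 / (n_c * v_c**2)
    return out if out.ndim else float(out)


def confidence_interval(lnr, v, z: float = Z_95):
    """Normal-approximation interval LnR +- z sqrt(v)."""
    lnr = np.asarray(lnr, float)
    v = np.asarray(v, float)
    half = z * np.sqrt(v)
    return lnr - half, lnr + half


def pool_effects(lnr, v) -> dict:
    """Fixed-effect inverse-variance pooled LnR with 95% CI and %D.

    Records with zero sampling variance are excluded from the
    weighting (with a warning); pooling a single record returns that
    record with its own interval.
    """
    lnr = np.atleast_1d(np.asarray(lnr, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if lnr.size == 0:
        raise ValueError("cannot pool an empty set of effects")
    if lnr.shape != v.shape:
        raise ValueError("lnr and v must have matching shapes")
    keep = v > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance effect(s) from pooling",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("no effects with positive sampling variance")
    w = 1.0 / v[keep]
    pooled = float(np.sum(w * lnr[keep]) / np.sum(w))
    se = math.sqrt(1.0 / float(np.sum(w)))
    lo, hi = pooled - Z_95 * se, pooled + Z_95 * se
    return {
        "lnr": pooled,
        "se": se,
        "ci_low": lo,
        "ci_high": hi,
        "pct": percent_change(pooled),
        "significant": bool(lo > 0 or hi < 0),
        "n_effects": int(keep.sum()),
    }


def effect_table(
    trait_table: pd.DataFrame,
    stresses: tuple[str, ...] = STRESS_TREATMENTS,
    traits: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per trait × stress effect sizes over genotype-level values.

    Blocks are averaged within genotype first; group means and SDs are
    then taken across genotypes under stress versus control. Traits
    with non-positive group means (undefined on the log scale) are
    flagged missing. Returns the forest-table columns ``trait, stress,
    v_s, v_c, s_s, s_c, n_s, n_c, lnr, v, ci_low, ci_high, pct,
    significant``.
    """
    gm = genotype_means(trait_table)
    if traits is not None:
        gm = gm[gm["trait"].isin(traits)]
    rows = []
    for trait, sub in gm.groupby("trait", observed=True):
        wide = sub.pivot(index="genotype", columns="treatment", values="value")
        if "C" not in wide.columns:
            raise ValueError("control treatment 'C' missing")
        for stress in stresses:
            if stress not in wide.columns:
                continue
            pair = wide[["C", stress]].dropna()
            rec = {
                "trait": trait,
                "stress": stress,
                "v_s": pair[stress].mean(),
                "v_c": pair["C"].mean(),
                "s_s": pair[stress].std(ddof=1),
                "s_c": pair["C"].std(ddof=1),
                "n_s": len(pair),
                "n_c": len(pair),
            }
            if rec["v_s"] > 0 and rec["v_c"] > 0 and len(pair) >= 2:
                rec["lnr"] = log_response_ratio(rec["v_s"], rec["v_c"])
                rec["v"] = lnr_variance(
                    rec["s_s"], rec["n_s"], rec["v_s"],
                    rec["s_c"], rec["n_c"], rec["v_c"],
                )
                lo, hi = confidence_interval(rec["lnr"], rec["v"])
                rec["ci_low"], rec["ci_high"] = float(lo), float(hi)
                rec["pct"] = percent_change(rec["lnr"])
                rec["significant"] = bool(lo > 0 or hi < 0)
            else:
                rec.update(
                    lnr=np.nan, v=np.nan, ci_low=np.nan, ci_high=np.nan,
                    pct=np.nan, significant=False,
                )
            rows.append(rec)
    return pd.DataFrame(rows).sort_values(["trait", "stress"]).reset_index(drop=True)
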