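"""Stress-response metrics: relative trait change, phosphorus
acquisition efficiency, the seven biomass-based stress-tolerance
indices, the stress tolerance score (STS), and group-profile
normalization.

All indices are built from a genotype's dry weight under control
(DW_C) and under a stress treatment (DW_S), plus the population means
over all genotypes (DWbar_C, DWbar_S):

    SSI  = (1 - DW_S/DW_C) / (1 - DWbar_S/DWbar_C)   stress sensitivity
    TI   = DW_C - DW_S                                tolerance (loss)
    SI   = DW_S / DW_C                                stress index
    HMI  = 2 DW_C DW_S / (DW_C + DW_S)                harmonic mean
    MPI  = (DW_C + DW_S) / 2                          mean productivity
    GMPI = sqrt(DW_C DW_S)                            geometric mean
    STI  = DW_C DW_S / DWbar_C^2                      stress tolerance

    STS  = SSI + TI + SI + HMI + MPI + GMPI + STI
    STS_SUM = STS_D + STS_DLP + STS_LP

The dry-weight basis is total dry mass (root + shoot). STS is the
literal unweighted sum even though the seven indices carry mixed units
and directions; a z-standardized variant is available via
``standardize=True`` for users who prefer a unit-free score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rhizoscreen.simulate import STRESS_TREATMENTS
from rhizoscreen.traits import genotype_means

__all__ = [
    "PopulationDegenerateError",
    "relative_change",
    "pae",
    "stress_indices",
    "sts_sum",
    "normalize_profile",
    "stress_index_table",
    "stress_response_table",
]

INDEX_NAMES = ("ssi", "ti", "si", "hmi", "mpi", "gmpi", "sti")


class PopulationDegenerateError(ValueError):
    """Population stress and control means coincide; SSI is undefined."""


def relative_change(stress_value, control_value):
    """Relative change (stress - control) / control; NaN when control is 0."""
    stress_value = np.asarray(stress_value, dtype=float)
    control_value = np.asarray(control_value, dtype=float)
    out = np.full(np.broadcast(stress_value, control_value).shape, np.nan)
    np.divide(stress_value - control_value, control_value, out=out,
              where=control_value != 0)
    return out if out.ndim else float(out)


def pae(p_stress, p_control):
    """Phosphorus acquisition efficiency: stressed P content as a
    percentage of control P content. NaN when the control content is 0."""
    p_stress = np.asarray(p_stress, dtype=float)
    p_control = np.asarray(p_control, dtype=float)
    out = np.full(np.broadcast(p_stress, p_control).shape, np.nan)
    np.divide(p_stress, p_control, out=out, where=p_control != 0)
    out = out * 100.0
    return out if out.ndim else float(out)


def stress_indices(dw_c, dw_s, pop_mean_c: float, pop_mean_s: float) -> dict:
    """The seven stress indices and their sum (STS) for one or more genotypes.

    Parameters are the genotype's control and stressed dry weights and
    the population mean dry weights under control and stress. Raises
    :class:`PopulationDegenerateError` if the population means
    coincide (the SSI denominator vanishes) and ``ValueError`` for
    non-positive control weights or population means.
    """
    dw_c = np.asarray(dw_c, dtype=float)
    dw_s = np.asarray(dw_s, dtype=float)
    if not (pop_mean_c > 0):
        raise ValueError("population control mean dry weight must be > 0")
    if pop_mean_s < 0:
        raise ValueError("population stress mean dry weight must be >= 0")
    if pop_mean_s == pop_mean_c:
        raise PopulationDegenerateError(
            "population stress and control means are equal; SSI undefined"
        )
    if np.any(dw_c <= 0):
        raise ValueError("control dry weight must be > 0 for every genotype")
    if np.any(dw_s < 0):
        raise ValueError("stress dry weight must be >= 0")

    ratio = dw_s / dw_c
    out = {
        "ssi": (1.0 - ratio) / (1.0 - pop_mean_s / pop_mean_c),
        "ti": dw_c - dw_s,
        "si": ratio,
        "hmi": 2.0 * dw_c * dw_s / (dw_c + dw_s),
        "mpi": (dw_c + dw_s) / 2.0,
        "gmpi": np.sqrt(dw_c * dw_s),
        "sti": dw_c * dw_s / pop_mean_c**2,
    }
    out["sts"] = sum(out[k] for k in INDEX_NAMES)
    return out


def sts_sum(sts_by_stress: dict) -> float:
    """Sum of per-stress STS values over the three stresses (D, LP, DLP).

    Returns NaN if any stress is missing.
    """
    vals = [sts_by_stress.get(s, np.nan) for s in STRESS_TREATMENTS]
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        return float("nan")
    return float(sum(vals))


def normalize_profile(x):
    """Normalize group trait means to proportions: x'_i = x_i / sum(x).

    Raises ``ValueError`` on a zero sum.
    """
    x = np.asarray(x, dtype=float)
    total = x.sum()
    if total == 0:
        raise ValueError("cannot normalize a profile with zero sum")
    return x / total


def stress_index_table(
    trait_table: pd.DataFrame,
    dw_trait: str = "TDM",
    stresses: tuple[str, ...] = STRESS_TREATMENTS,
    standardize: bool = False,
) -> pd.DataFrame:
    """Per-genotype stress indices for each stress treatment.

    Blocks are averaged within genotype before index computation, and
    population mean dry weights are taken over the genotypes with
    complete control and stress data. With ``standardize=True`` the
    seven indices are z-scored across genotypes before summation into
    STS (unit-free variant); the default is the literal sum.

    Returns columns ``genotype, stress, ssi, ti, si, hmi, mpi, gmpi,
    sti, sts, sts_sum``.
    """
    gm = genotype_means(trait_table)
    dw = gm[gm["trait"] == dw_trait].pivot(
        index="genotype", columns="treatment", values="value"
    )
    if "C" not in dw.columns:
        raise ValueError("control treatment 'C' missing from trait table")
    frames = []
    for stress in stresses:
        if stress not in dw.columns:
            continue
        sub = dw[["C", stress]].dropna()
        res = stress_indices(
            sub["C"].to_numpy(),
            sub[stress].to_numpy(),
            float(sub["C"].mean()),
            float(sub[stress].mean()),
        )
        frame = pd.DataFrame({"genotype": sub.index, "stress": stress})
        for name in INDEX_NAMES:
            frame[name] = res[name]
        if standardize:
            z = frame[list(INDEX_NAMES)].apply(
                lambda s: (s - s.mean()) / s.std(ddof=1)
            )
            frame["sts"] = z.sum(axis=1)
        else:
            frame["sts"] = res["sts"]
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    totals = out.pivot(index="genotype", columns="stress", values="sts")
    have_all = totals.reindex(columns=list(stresses))
    out = out.merge(
        have_all.sum(axis=1, skipna=False).rename("sts_sum"),
        left_on="genotype", right_index=True, how="left",
    )
    return out


def stress_response_table(
    trait_table: pd.DataFrame,
    delta_traits: tuple[str, ...] = (
        "RL", "RL_s1", "RL_sub", "RD", "RD_s1", "RD_sub",
    ),
    p_trait: str = "TP",
    stresses: tuple[str, ...] = STRESS_TREATMENTS,
) -> pd.DataFrame:
    """Per-genotype relative trait changes and PAE for each stress.

    Returns columns ``genotype, stress, d_<trait>`` for each requested
    trait plus ``pae`` (from total phosphorus content).
    """
    gm = genotype_means(trait_table)
    wide = gm.pivot(index=["genotype", "treatment"], columns="trait",
                    values="value")
    frames = []
    for stress in stresses:
        try:
            ctrl = wide.xs("C", level="treatment")
            strs = wide.xs(stress, level="treatment")
        except KeyError:
            continue
        common = ctrl.index.intersection(strs.index)
        frame = pd.DataFrame({"genotype": common, "stress": stress})
        for t in delta_traits:
            if t in wide.columns:
                frame[f"d_{t}"] = relative_change(
                    strs.loc[common, t].to_numpy(),
                    ctrl.loc[common, t].to_numpy(),
                )
        frame["pae"] = pae(
            strs.loc[common, p_trait].to_numpy(),
            ctrl.loc[common, p_trait].to_numpy(),
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
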