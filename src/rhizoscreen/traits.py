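"""Derivation of global and depth-local root/shoot traits.

Input is the per-plant record table: one row per plant with the raw
primitives (maximum root depth, root number, per-layer root length and
mean diameter, dry weights, shoot height, leaf/tiller counts,
phosphorus concentrations, days after transplanting). Output is a long
trait table keyed by genotype × treatment × block × trait.

Depth convention: roots are measured in 20 cm layers down the growth
panel. Layer 1 (0-20 cm) is the top-root layer "s1"; everything below
20 cm down to the root tip is the sub-root layer "sub".

Per-layer surface area and volume follow cylinder geometry from length
and mean diameter (diameter in mm, lengths in cm):

    RA = pi * (RD/10) * RL        [cm^2]
    RV = (pi/4) * (RD/10)^2 * RL  [cm^3]

If the input table carries measured ``ra_s<k>_cm2`` / ``rv_s<k>_cm3``
columns (e.g. from image analysis), those override the geometric
formulas.

Undefined ratios (zero denominators) propagate as missing values
(NaN), never as zeros or exceptions; negative raw inputs are rejected.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

__all__ = [
    "KEY_COLUMNS",
    "layer_count",
    "derive_layer_traits",
    "derive_global_traits",
    "derive_traits",
    "summarize_by_treatment",
    "PANEL_AREA_CM2",
    "S1_AREA_CM2",
]

KEY_COLUMNS = ["genotype", "treatment", "block"]

#: growth-panel reference area for root length density (0-110 cm depth)
PANEL_AREA_CM2 = 1430.0
#: panel width implied by the reference area (1430 cm^2 / 110 cm)
PANEL_WIDTH_CM = PANEL_AREA_CM2 / 110.0
#: reference area of the 0-20 cm layer
S1_AREA_CM2 = 20.0 * PANEL_WIDTH_CM
#: reference area of the sub layer (below 20 cm)
SUB_AREA_CM2 = PANEL_AREA_CM2 - S1_AREA_CM2

_RL_RE = re.compile(r"^rl_s(\d+)_cm$")


def layer_count(plants: pd.DataFrame) -> int:
    """Number of 20 cm depth layers present in a plant-record table."""
    layers = sorted(int(m.group(1)) for c in plants.columns
                    if (m := _RL_RE.match(c)))
    if not layers:
        raise ValueError("no rl_s<k>_cm layer columns found")
    if layers != list(range(1, len(layers) + 1)):
        raise ValueError(f"non-contiguous layer columns: {layers}")
    return len(layers)


def _check_non_negative(plants: pd.DataFrame, columns: list[str]) -> None:
    for c in columns:
        bad = plants[c] < 0
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"negative value in column {c!r} (row {row})")


def _safe_div(num, den):
    """Element-wise ratio with NaN where the denominator is 0."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    np.divide(num, den, out=out, where=den != 0)
    return out


def _layer_arrays(plants: pd.DataFrame, n_layers: int):
    rl = plants[[f"rl_s{k}_cm" for k in range(1, n_layers + 1)]].to_numpy(float)
    rd = plants[[f"rd_s{k}_mm" for k in range(1, n_layers + 1)]].to_numpy(float)
    ra_cols = [f"ra_s{k}_cm2" for k in range(1, n_layers + 1)]
    rv_cols = [f"rv_s{k}_cm3" for k in range(1, n_layers + 1)]
    if all(c in plants.columns for c in ra_cols):
        ra = plants[ra_cols].to_numpy(float)
    else:
        ra = np.pi * (rd / 10.0) * rl
    if all(c in plants.columns for c in rv_cols):
        rv = plants[rv_cols].to_numpy(float)
    else:
        rv = (np.pi / 4.0) * (rd / 10.0) ** 2 * rl
    return rl, rd, ra, rv


def _weighted_diameter(rd: np.ndarray, rl: np.ndarray) -> np.ndarray:
    """Length-weighted mean diameter; NaN where total length is 0."""
    total = rl.sum(axis=1)
    return _safe_div((rd * rl).sum(axis=1), total)


def derive_layer_traits(plants: pd.DataFrame) -> pd.DataFrame:
    """Per-layer and s1/sub aggregate root traits, one row per plant.

    Columns: ``RL_s<k>``, ``RD_s<k>``, ``RA_s<k>``, ``RV_s<k>`` for
    each layer, the aggregates ``RL_s1``/``RL_sub`` (and RD/RA/RV
    analogues), layer length densities ``RLD_s1``/``RLD_sub`` and the
    top-to-sub length ratio ``RLR_s1_sub`` (NaN when no root grows
    below 20 cm).
    """
    n_layers = layer_count(plants)
    layer_cols = [f"rl_s{k}_cm" for k in range(1, n_layers + 1)]
    layer_cols += [f"rd_s{k}_mm" for k in range(1, n_layers + 1)]
    _check_non_negative(plants, layer_cols)
    rl, rd, ra, rv = _layer_arrays(plants, n_layers)

    out = plants[KEY_COLUMNS].copy()
    for k in range(n_layers):
        out[f"RL_s{k + 1}"] = rl[:, k]
        out[f"RD_s{k + 1}"] = np.where(rl[:, k] > 0, rd[:, k], np.nan)
        out[f"RA_s{k + 1}"] = ra[:, k]
        out[f"RV_s{k + 1}"] = rv[:, k]

    rl_s1, rl_sub = rl[:, 0], rl[:, 1:].sum(axis=1)
    out["RL_s1"] = rl_s1
    out["RL_sub"] = rl_sub
    out["RD_sub"] = _weighted_diameter(rd[:, 1:], rl[:, 1:])
    out["RA_sub"] = ra[:, 1:].sum(axis=1)
    out["RV_sub"] = rv[:, 1:].sum(axis=1)
    out["RLD_s1"] = rl_s1 / S1_AREA_CM2
    out["RLD_sub"] = rl_sub / SUB_AREA_CM2
    out["RLR_s1_sub"] = _safe_div(rl_s1, rl_sub)
    return out


def derive_global_traits(plants: pd.DataFrame) -> pd.DataFrame:
    """Whole-plant root and shoot traits, one row per plant.

    Root: RL (total length), RD (length-weighted mean diameter), RA,
    RV (layer sums), RLD = RL / panel area, SRL = RL/RDW (cm per g),
    RLI = RL/MRD, RTD = RDW/RV (g per cm^3), RGR = MRD/DAT, RP =
    RPC * RDW. Shoot: SGR = SH/DAT, SP = SPC * SDW, RSR = RDW/SDW,
    TDM = RDW + SDW, TP = RP + SP.
    """
    n_layers = layer_count(plants)
    scalar_cols = ["mrd_cm", "rn", "rdw_g", "sdw_g", "sh_cm", "ln", "tn",
                   "rpc_mg_g", "spc_mg_g", "dat"]
    _check_non_negative(plants, scalar_cols)
    rl, rd, ra, rv = _layer_arrays(plants, n_layers)

    out = plants[KEY_COLUMNS].copy()
    total_rl = rl.sum(axis=1)
    total_rv = rv.sum(axis=1)
    mrd = plants["mrd_cm"].to_numpy(float)
    rdw = plants["rdw_g"].to_numpy(float)
    sdw = plants["sdw_g"].to_numpy(float)
    dat = plants["dat"].to_numpy(float)

    out["MRD"] = mrd
    out["RN"] = plants["rn"].to_numpy(float)
    out["RL"] = total_rl
    out["RD"] = _weighted_diameter(rd, rl)
    out["RA"] = ra.sum(axis=1)
    out["RV"] = total_rv
    out["RLD"] = total_rl / PANEL_AREA_CM2
    out["SRL"] = _safe_div(total_rl, rdw)
    out["RLI"] = _safe_div(total_rl, mrd)
    out["RTD"] = _safe_div(rdw, total_rv)
    out["RGR"] = _safe_div(mrd, dat)
    out["RDW"] = rdw
    out["RPC"] = plants["rpc_mg_g"].to_numpy(float)
    out["RP"] = out["RPC"] * rdw
    out["SDW"] = sdw
    out["RSR"] = _safe_div(rdw, sdw)
    out["TDM"] = rdw + sdw
    out["SH"] = plants["sh_cm"].to_numpy(float)
    out["LN"] = plants["ln"].to_numpy(float)
    out["TN"] = plants["tn"].to_numpy(float)
    out["SGR"] = _safe_div(plants["sh_cm"].to_numpy(float), dat)
    out["SPC"] = plants["spc_mg_g"].to_numpy(float)
    out["SP"] = out["SPC"] * sdw
    out["TP"] = out["RP"] + out["SP"]
    return out


def derive_traits(plants: pd.DataFrame) -> pd.DataFrame:
    """All global and local traits in long format.

    Returns columns ``genotype, treatment, block, trait, value`` with
    one unique row per key. Wide tables are recovered with
    ``df.pivot_table(index=..., columns='trait', values='value')``.
    """
    wide = derive_global_traits(plants).merge(
        derive_layer_traits(plants), on=KEY_COLUMNS, validate="one_to_one"
    )
    long = wide.melt(id_vars=KEY_COLUMNS, var_name="trait", value_name="value")
    return long.sort_values(KEY_COLUMNS + ["trait"], kind="stable").reset_index(
        drop=True
    )


def genotype_means(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Block-averaged trait values per genotype × treatment × trait."""
    return (
        trait_table.groupby(["genotype", "treatment", "trait"], observed=True)[
            "value"
        ]
        .mean()
        .reset_index()
    )


def summarize_by_treatment(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Treatment-level mean and coefficient of variation per trait.

    Blocks are averaged within genotype first; the mean and CV
    (sample standard deviation over mean) are then taken across
    genotypes within each treatment. Requires at least two genotypes;
    a zero mean leaves the CV missing.
    """
    gm = genotype_means(trait_table)
    counts = gm.groupby(["treatment", "trait"], observed=True)["genotype"].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(
            f"need >= 2 genotypes per treatment x trait for a CV; got one for {bad[:3]}"
        )
    stats = (
        gm.groupby(["treatment", "trait"], observed=True)["value"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    stats["cv"] = _safe_div(stats["sd"], stats["mean"])
    return stats
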