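"""Synthetic replicated genotype × treatment trial generator.

Emulates a semi-hydroponic root-phenotyping screen: ``n_genotypes``
genotypes grown under a control (C) and three stress treatments — low
phosphorus (LP), osmotic drought (D) and their combination (DLP) — in
``n_blocks`` complete blocks, harvested at a fixed number of days after
transplanting (DAT).

Every positive-valued plant measurement ``y`` is generated on the log
scale as an additive decomposition

    ln y = ln mu + ln m_tj + g_i + (gt)_ij + b_k + eps

with genotype, genotype-by-treatment, block and residual effects drawn
independently from zero-mean Gaussians with configurable variances.
The log-normal model guarantees positivity of lengths and weights and
makes the log response ratio the natural effect scale downstream.
Counts are generated on the same scale and rounded.

Root geometry is kept self-consistent: total root length is split over
20 cm depth layers so that only layers reached by the maximum root
depth carry root, with a Dirichlet allocation biased toward shallow
layers under C/LP and toward deeper layers under D/DLP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "TraitSpec",
    "SimulationConfig",
    "generate_dataset",
    "simulate_trait_panel",
    "wheat_screen_preset",
    "null_screen_config",
    "planted_cluster_matrix",
    "LAYER_DEPTH_CM",
]

#: depth covered by one root layer (cm); panels are cut every 20 cm
LAYER_DEPTH_CM = 20.0

STRESS_TREATMENTS = ("LP", "D", "DLP")
DEFAULT_TREATMENTS = ("C", "LP", "D", "DLP")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class TraitSpec:
    """Generative parameters for one plant measurement.

    Parameters
    ----------
    mean
        Baseline (control) mean, in trait units; strictly positive.
    multipliers
        Treatment multiplier ``m_tj`` per treatment code. The control
        multiplier must be 1 (it is filled in if absent).
    var_g, var_gt, var_block, var_e
        Log-scale variances of the genotype, genotype × treatment,
        block and residual effects; all non-negative.
    integer
        Round generated values to the nearest non-negative integer
        (seminal root, leaf and tiller counts).
    """

    mean: float
    multipliers: dict[str, float] = field(default_factory=dict)
    var_g: float = 0.0
    var_gt: float = 0.0
    var_block: float = 0.0
    var_e: float = 0.0
    integer: bool = False

    def validate(self, name: str, treatments: tuple[str, ...]) -> None:
        if not (self.mean > 0):
            raise ConfigError(f"trait {name!r}: baseline mean must be > 0")
        for v, lab in [
            (self.var_g, "var_g"),
            (self.var_gt, "var_gt"),
            (self.var_block, "var_block"),
            (self.var_e, "var_e"),
        ]:
            if v < 0:
                raise ConfigError(f"trait {name!r}: {lab} must be >= 0")
        m = self.multipliers.get("C", 1.0)
        if m != 1.0:
            raise ConfigError(f"trait {name!r}: control multiplier must be 1")
        for t in treatments:
            if self.multipliers.get(t, 1.0) <= 0:
                raise ConfigError(f"trait {name!r}: multiplier for {t} must be > 0")


#: measurements generated directly (layer lengths/diameters are derived)
PRIMITIVE_TRAITS = (
    "mrd_cm",
    "rn",
    "rl_cm",
    "rd_mm",
    "rdw_g",
    "sdw_g",
    "sh_cm",
    "ln",
    "tn",
    "rpc_mg_g",
    "spc_mg_g",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated screening trial."""

    n_genotypes: int = 100
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    n_blocks: int = 4
    n_layers: int = 6
    dat: int = 65
    traits: dict[str, TraitSpec] = field(default_factory=dict)
    #: Dirichlet depth-decay rate per treatment; smaller = deeper roots
    layer_decay: dict[str, float] = field(
        default_factory=lambda: {"C": 0.9, "LP": 0.9, "D": 0.25, "DLP": 0.35}
    )
    #: Dirichlet concentration scale for the layer split (higher = less noisy)
    layer_concentration: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genotypes < 1:
            raise ConfigError("n_genotypes must be >= 1")
        if self.n_blocks < 2:
            raise ConfigError("n_blocks must be >= 2 (replication is required)")
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        if self.dat <= 0:
            raise ConfigError("dat must be > 0")
        if "C" not in self.treatments:
            raise ConfigError("treatments must include the control 'C'")
        if len(set(self.treatments)) != len(self.treatments):
            raise ConfigError("duplicate treatment codes")
        missing = [t for t in PRIMITIVE_TRAITS if t not in self.traits]
        if missing:
            raise ConfigError(f"missing trait specs: {missing}")
        for name, spec in self.traits.items():
            spec.validate(name, self.treatments)

    @property
    def max_depth_cm(self) -> float:
        return LAYER_DEPTH_CM * self.n_layers


def _effects(rng: np.random.Generator, var: float, shape) -> np.ndarray:
    if var == 0:
        return np.zeros(shape)
    return rng.normal(0.0, math.sqrt(var), size=shape)


def _simulate_values(
    spec: TraitSpec,
    n_genotypes: int,
    treatments: tuple[str, ...],
    n_blocks: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Values for one trait, shape (genotype, treatment, block)."""
    nt = len(treatments)
    g = _effects(rng, spec.var_g, (n_genotypes, 1, 1))
    gt = _effects(rng, spec.var_gt, (n_genotypes, nt, 1))
    b = _effects(rng, spec.var_block, (1, 1, n_blocks))
    eps = _effects(rng, spec.var_e, (n_genotypes, nt, n_blocks))
    m = np.array([spec.multipliers.get(t, 1.0) for t in treatments])
    ln_y = math.log(spec.mean) + np.log(m)[None, :, None] + g + gt + b + eps
    y = np.exp(ln_y)
    if spec.integer:
        y = np.maximum(np.rint(y), 0.0)
    return y


def _layer_split(
    rl: float,
    mrd: float,
    decay: float,
    n_layers: int,
    concentration: float,
    rng: np.random.Generator,
    stochastic: bool,
) -> np.ndarray:
    """Split total root length over the layers reached by ``mrd``."""
    n_occ = max(1, min(n_layers, math.ceil(mrd / LAYER_DEPTH_CM)))
    w = np.exp(-decay * np.arange(n_occ))
    w /= w.sum()
    if stochastic and n_occ > 1:
        w = rng.dirichlet(concentration * w)
    out = np.zeros(n_layers)
    out[:n_occ] = rl * w
    return out


def _layer_diameters(
    rd: float, rl_layers: np.ndarray, taper: float = 0.06
) -> np.ndarray:
    """Per-layer mean diameters whose length-weighted mean is exactly ``rd``.

    Roots thin slightly with depth (fixed relative taper per layer).
    """
    n = rl_layers.size
    profile = 1.0 - taper * np.arange(n)
    profile = np.clip(profile, 0.3, None)
    total = rl_layers.sum()
    if total <= 0:
        return np.full(n, rd)
    wmean = float(np.dot(profile, rl_layers) / total)
    return rd * profile / wmean


def generate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Generate one plant record per genotype × treatment × block.

    Returns a data frame in the plant-record schema: ``genotype``,
    ``treatment``, ``block``, ``mrd_cm``, ``rn``, ``rl_s<k>_cm`` and
    ``rd_s<k>_mm`` for each layer k, ``rdw_g``, ``sdw_g``, ``sh_cm``,
    ``ln``, ``tn``, ``rpc_mg_g``, ``spc_mg_g``, ``dat``. Identical
    configurations (including the seed) give identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_g, n_b = config.n_genotypes, config.n_blocks
    treatments = config.treatments

    values = {
        name: _simulate_values(config.traits[name], n_g, treatments, n_b, rng)
        for name in PRIMITIVE_TRAITS
    }
    # root tip must stay within the modelled depth window
    values["mrd_cm"] = np.clip(values["mrd_cm"], 1e-6, config.max_depth_cm)

    # allocation noise is residual noise: a zero-residual-variance root
    # length yields a deterministic split
    stochastic = config.traits["rl_cm"].var_e > 0

    rows = []
    for i in range(n_g):
        for j, trt in enumerate(treatments):
            decay = config.layer_decay.get(trt, 0.9)
            for k in range(n_b):
                rl = float(values["rl_cm"][i, j, k])
                mrd = float(values["mrd_cm"][i, j, k])
                rl_layers = _layer_split(
                    rl, mrd, decay, config.n_layers,
                    config.layer_concentration, rng, stochastic,
                )
                rd_layers = _layer_diameters(
                    float(values["rd_mm"][i, j, k]), rl_layers
                )
                row = {
                    "genotype": i + 1,
                    "treatment": trt,
                    "block": k + 1,
                    "mrd_cm": mrd,
                    "rn": float(values["rn"][i, j, k]),
                }
                for layer in range(config.n_layers):
                    row[f"rl_s{layer + 1}_cm"] = rl_layers[layer]
                for layer in range(config.n_layers):
                    row[f"rd_s{layer + 1}_mm"] = rd_layers[layer]
                for name in ("rdw_g", "sdw_g", "sh_cm", "ln", "tn",
                             "rpc_mg_g", "spc_mg_g"):
                    row[name] = float(values[name][i, j, k])
                row["dat"] = config.dat
                rows.append(row)
    return pd.DataFrame(rows)


def simulate_trait_panel(
    n_traits: int,
    n_genotypes: int,
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS,
    n_blocks: int = 4,
    mean: float = 1.0,
    multipliers: dict[str, dict[str, float]] | None = None,
    var_g: float = 0.0,
    var_gt: float = 0.0,
    var_block: float = 0.0,
    var_e: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a panel of generic traits under the trial design.

    Used by Monte-Carlo calibration suites (heritability recovery,
    null effect-size coverage) where many independent traits with the
    same variance structure are needed. Returns a long data frame with
    columns ``genotype, treatment, block, trait, value``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for t in range(n_traits):
        name = f"t{t + 1:04d}"
        mult = (multipliers or {}).get(name, {})
        spec = TraitSpec(
            mean=mean, multipliers=mult, var_g=var_g, var_gt=var_gt,
            var_block=var_block, var_e=var_e,
        )
        spec.validate(name, treatments)
        vals = _simulate_values(spec, n_genotypes, treatments, n_blocks, rng)
        idx = pd.MultiIndex.from_product(
            [range(1, n_genotypes + 1), treatments, range(1, n_blocks + 1)],
            names=["genotype", "treatment", "block"],
        )
        frames.append(
            pd.DataFrame({"trait": name, "value": vals.ravel()}, index=idx)
            .reset_index()
        )
    return pd.concat(frames, ignore_index=True)


def wheat_screen_preset(seed: int = 0) -> SimulationConfig:
    """Study-scale preset: 100 genotypes × (C, LP, D, DLP) × 4 blocks.

    Baseline means and treatment multipliers reproduce the qualitative
    treatment contrasts of a winter-wheat semi-hydroponic screen:
    drought increases root length, depth and diameter; low phosphorus
    and the combined stress depress biomass and phosphorus traits, the
    combination most strongly. Variances are chosen to give realistic
    genotypic coefficients of variation (roughly 0.3-0.6).
    """
    v = dict(var_g=0.15, var_gt=0.03, var_block=0.01, var_e=0.05)

    def spec(mean, lp, d, dlp, *, integer=False, **kw):
        params = {**v, **kw}
        return TraitSpec(
            mean=mean,
            multipliers={"C": 1.0, "LP": lp, "D": d, "DLP": dlp},
            integer=integer,
            **params,
        )

    traits = {
        "mrd_cm": spec(55.0, 1.45, 1.33, 1.36, var_g=0.08),
        "rn": spec(5.0, 1.0, 1.05, 0.95, integer=True, var_g=0.06),
        "rl_cm": spec(1290.0, 1.08, 1.43, 0.96, var_g=0.25),
        "rd_mm": spec(0.18, 1.33, 1.33, 1.28, var_g=0.18),
        "rdw_g": spec(0.12, 0.75, 1.17, 0.58, var_g=0.20),
        "sdw_g": spec(0.52, 0.23, 0.31, 0.21, var_g=0.18),
        "sh_cm": spec(45.0, 0.80, 0.72, 0.65, var_g=0.05),
        "ln": spec(6.0, 0.90, 0.85, 0.72, integer=True, var_g=0.05),
        "tn": spec(3.0, 0.70, 0.60, 0.50, integer=True, var_g=0.08),
        "rpc_mg_g": spec(3.0, 0.50, 0.90, 0.45, var_g=0.08),
        "spc_mg_g": spec(2.5, 0.40, 0.90, 0.35, var_g=0.08),
    }
    return SimulationConfig(traits=traits, seed=seed)


def null_screen_config(seed: int = 0) -> SimulationConfig:
    """Preset with every treatment multiplier set to 1 (no stress effect).

    Genotype main-effect and block variances are zero so that control
    and stress groups are statistically independent; this is the
    regime in which the independent-groups sampling variance of the
    log response ratio is exact, making the preset suitable for
    false-positive-rate calibration.
    """
    base = wheat_screen_preset(seed=seed)
    traits = {
        name: replace(
            s,
            multipliers={t: 1.0 for t in base.treatments},
            var_g=0.0,
            var_gt=0.08,
            var_block=0.0,
        )
        for name, s in base.traits.items()
    }
    return replace(base, traits=traits, seed=seed)


def planted_cluster_matrix(
    n_genotypes: int = 90,
    n_traits: int = 12,
    k: int = 3,
    separation: float = 4.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Genotype × trait matrix with a planted group structure.

    Genotypes are assigned round-robin to ``k`` groups with Gaussian
    cluster centres ``separation`` standard deviations apart; used to
    check that hierarchical clustering recovers known structure.
    Returns the matrix and the true labels.
    """
    rng = np.random.default_rng(seed)
    labels = np.arange(n_genotypes) % k
    centres = rng.normal(0.0, 1.0, size=(k, n_traits))
    centres *= separation / max(1e-12, np.std(centres))
    x = centres[labels] + rng.normal(0.0, noise_sd, size=(n_genotypes, n_traits))
    df = pd.DataFrame(
        x,
        index=pd.RangeIndex(1, n_genotypes + 1, name="genotype"),
        columns=[f"trait{j + 1}" for j in range(n_traits)],
    )
    return df, labels
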