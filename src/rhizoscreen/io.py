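"""CSV schema validation, configuration loading and the end-to-end
pipeline runner.

The pipeline orders the analyses as they are applied in a screening
study: simulate (or load) plant records -> derive traits -> treatment
summaries -> stress indices and responses -> ANOVA and heritability ->
effect sizes -> correlation / PCA / clustering / STS grouping. Every
stage writes a CSV into the output directory, plus a ``run.log``
recording the seed, package version and row counts. Reruns with an
identical configuration and seed are bit-identical (the log contains
no timestamps).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import rhizoscreen
from rhizoscreen import effects, heritability, multivariate, simulate, stress, traits

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "validate_schema",
    "read_plant_table",
    "run_pipeline",
]

log = logging.getLogger("rhizoscreen")

VALID_TREATMENTS = {"C", "LP", "D", "DLP"}

SCALAR_COLUMNS = [
    "genotype", "treatment", "block", "mrd_cm", "rn", "rdw_g", "sdw_g",
    "sh_cm", "ln", "tn", "rpc_mg_g", "spc_mg_g", "dat",
]

#: traits that are deterministic transforms of already-selected ones
DEFAULT_CV_DROP = ("RGR", "RLD")


class SchemaError(ValueError):
    """Plant-record table violates the expected schema."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid plant table:\n" + "\n".join(problems))


def validate_schema(plants: pd.DataFrame, n_layers: int | None = None) -> None:
    """Validate a plant-record table; raise ``SchemaError`` listing
    every problem found (missing columns, unknown treatment codes,
    negative measurements, inconsistent layer columns)."""
    problems: list[str] = []
    for c in SCALAR_COLUMNS:
        if c not in plants.columns:
            problems.append(f"missing required column {c!r}")
    try:
        found_layers = traits.layer_count(plants)
    except ValueError as exc:
        problems.append(str(exc))
        found_layers = 0
    if n_layers is not None and found_layers and found_layers != n_layers:
        problems.append(
            f"expected {n_layers} layers, found {found_layers}"
        )
    for k in range(1, found_layers + 1):
        if f"rd_s{k}_mm" not in plants.columns:
            problems.append(f"missing diameter column rd_s{k}_mm")
    if "treatment" in plants.columns:
        unknown = set(plants["treatment"].unique()) - VALID_TREATMENTS
        if unknown:
            problems.append(f"unknown treatment code(s): {sorted(unknown)}")
    numeric = [c for c in plants.columns
               if c not in ("genotype", "treatment", "block")
               and c in plants.columns]
    for c in numeric:
        col = pd.to_numeric(plants[c], errors="coerce")
        if col.isna().any() and plants[c].notna().any() and col.isna().sum() > plants[c].isna().sum():
            problems.append(f"non-numeric value(s) in column {c!r}")
        neg = col < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            problems.append(f"negative value in column {c!r} at row {row}")
    if problems:
        raise SchemaError(problems)


def read_plant_table(path: str | Path, n_layers: int | None = None) -> pd.DataFrame:
    """Read and validate a plant-record CSV."""
    plants = pd.read_csv(path)
    validate_schema(plants, n_layers=n_layers)
    return plants


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration."""

    input_path: str | None = None  # plant-record CSV; None = simulate preset
    out_dir: str = "results"
    seed: int = 0
    n_layers: int | None = None
    cv_threshold: float = 0.3
    cluster_k: int = 5
    cv_drop: tuple[str, ...] = DEFAULT_CV_DROP
    significance_thresholds: tuple[float, ...] = (0.05, 0.01, 0.001)
    anova_traits: tuple[str, ...] | None = None  # None = all traits

    def __post_init__(self):
        t = self.significance_thresholds
        if list(t) != sorted(t, reverse=True) or len(set(t)) != len(t):
            raise ValueError("significance thresholds must be strictly decreasing")
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        for key in ("cv_drop", "significance_thresholds", "anova_traits"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path, lines: list[str]) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    lines.append(f"{path.name}: {len(df)} rows")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write its outputs under ``config.out_dir``.

    Returns a dict of the in-memory stage results keyed by stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = [
        f"rhizoscreen {rhizoscreen.__version__}",
        f"seed: {config.seed}",
        f"input: {config.input_path or 'simulated preset'}",
    ]

    if config.input_path is None:
        sim = simulate.wheat_screen_preset(seed=config.seed)
        plants = simulate.generate_dataset(sim)
        log.info("simulated %d plant records", len(plants))
    else:
        plants = read_plant_table(config.input_path, n_layers=config.n_layers)
        log.info("loaded %d plant records from %s", len(plants), config.input_path)
    validate_schema(plants, n_layers=config.n_layers)
    _write(plants, out / "plants.csv", lines)

    trait_table = traits.derive_traits(plants)
    _write(trait_table, out / "traits_long.csv", lines)
    wide = trait_table.pivot_table(
        index=["genotype", "treatment", "block"], columns="trait",
        values="value", observed=True,
    ).reset_index()
    _write(wide, out / "traits_wide.csv", lines)

    summary = traits.summarize_by_treatment(trait_table)
    _write(summary, out / "treatment_summary.csv", lines)

    indices = stress.stress_index_table(trait_table)
    _write(indices, out / "stress_indices.csv", lines)
    responses = stress.stress_response_table(trait_table)
    _write(responses, out / "delta_pae.csv", lines)

    anova_traits = config.anova_traits or tuple(
        t for t in trait_table["trait"].unique()
        if not trait_table[trait_table["trait"] == t]["value"].isna().all()
    )
    anova_rows, herit_rows = [], []
    treatments = [t for t in ("C", "LP", "D", "DLP")
                  if t in set(plants["treatment"])]
    for t in anova_traits:
        sub = trait_table[trait_table["trait"] == t]
        if sub["value"].isna().any():
            continue  # factorial ANOVA requires complete cells
        try:
            res = heritability.factorial_anova(trait_table, t)
        except ValueError:
            continue
        tab = res.table.copy()
        tab.insert(0, "trait", t)
        anova_rows.append(tab)
        for trt in treatments:
            try:
                vd = heritability.estimate_heritability(trait_table, t, treatment=trt)
            except ValueError:
                continue
            herit_rows.append({
                "trait": t, "scope": trt, "v_g": vd.v_g, "v_ge": np.nan,
                "v_e": vd.v_e, "h": vd.heritability,
            })
        try:
            vd = heritability.estimate_heritability(trait_table, t)
            herit_rows.append({
                "trait": t, "scope": "combined", "v_g": vd.v_g,
                "v_ge": vd.v_ge, "v_e": vd.v_e,
                "h": vd.heritability_combined,
            })
        except ValueError:
            pass
    anova_table = (pd.concat(anova_rows, ignore_index=True)
                   if anova_rows else pd.DataFrame())
    _write(anova_table, out / "anova.csv", lines)
    _write(pd.DataFrame(herit_rows), out / "heritability.csv", lines)

    forest = effects.effect_table(trait_table)
    _write(forest, out / "effects.csv", lines)

    # multivariate screening within the control treatment
    ctrl = wide[wide["treatment"] == "C"]
    gmat = ctrl.groupby("genotype", observed=True).mean(numeric_only=True)
    gmat = gmat.drop(columns=[c for c in ("block",) if c in gmat.columns])
    cv_c = summary[summary["treatment"] == "C"].set_index("trait")["cv"]
    selected = multivariate.filter_by_cv(
        cv_c.dropna(), threshold=config.cv_threshold, drop=config.cv_drop
    )
    selected = [t for t in selected if t in gmat.columns
                and gmat[t].notna().all()]
    pd.DataFrame({"trait": selected}).to_csv(
        out / "selected_traits.csv", index=False
    )
    lines.append(f"selected_traits.csv: {len(selected)} rows")

    corr = multivariate.pearson_with_p(gmat[selected])
    _write(corr.to_long(), out / "correlation.csv", lines)

    pca = multivariate.pca_standardized(gmat[selected])
    eig = pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(len(pca.eigenvalues))],
        "eigenvalue": pca.eigenvalues,
        "explained_pct": pca.explained_pct,
        "retained": [i < pca.n_retained for i in range(len(pca.eigenvalues))],
    })
    _write(eig, out / "pca_eigenvalues.csv", lines)
    _write(pca.loadings.reset_index(names="trait"), out / "pca_loadings.csv", lines)

    clus = multivariate.ahc_cluster(gmat[selected], k=config.cluster_k)
    _write(clus.labels.reset_index(), out / "clusters.csv", lines)
    if clus.profiles is not None:
        _write(clus.profiles.reset_index(names="group"),
               out / "group_profiles.csv", lines)

    sts_by_g = indices.drop_duplicates("genotype").set_index("genotype")["sts_sum"]
    sts_groups = multivariate.sts_grouping(
        sts_by_g.dropna(), k=min(config.cluster_k, sts_by_g.dropna().nunique())
    )
    _write(sts_groups.reset_index(), out / "sts_groups.csv", lines)

    (out / "run.log").write_text("\n".join(lines) + "\n")
    return {
        "plants": plants,
        "traits": trait_table,
        "summary": summary,
        "indices": indices,
        "responses": responses,
        "anova": anova_table,
        "heritability": pd.DataFrame(herit_rows),
        "effects": forest,
        "selected_traits": selected,
        "correlation": corr,
        "pca": pca,
        "clusters": clus,
        "sts_groups": sts_groups,
    }
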