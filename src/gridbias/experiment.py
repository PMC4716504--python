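"""Pipeline head: run the six model variants per species, measure
parameter bias against the equal-area land-cover-weighted reference (ML),
compute range sizes and summarize across species.

The relative bias of a coefficient is its absolute difference from the
reference coefficient in units of the reference standard error; per
species these are averaged into one value per variant, weighting each
predictor's linear and quadratic term by that predictor's partial
explained deviance in the variant's own fit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from . import gridding, sdm
from .gridding import EQUALAREA, LONGLAT, GridAggregator, grid_for_world, land_cells
from .projection import ProjectionParams
from .sdm import REFERENCE_VARIANT, VARIANTS, FitResult
from .world import (
    PREDICTOR_NAMES,
    FineWorld,
    TrueNiche,
    WorldSpec,
    generate_species,
    make_world,
    species_metadata,
)

logger = logging.getLogger(__name__)

N_SLOPES = 8


class BiasError(ValueError):
    pass


def relative_bias(beta_d, beta_ref, se_ref):
    """|beta_D - beta_ref| / se_ref, elementwise."""
    se = np.asarray(se_ref, dtype=float)
    if np.any(se <= 0):
        raise BiasError("se_ref must be strictly positive")
    return np.abs(np.asarray(beta_d, dtype=float) - np.asarray(beta_ref, dtype=float)) / se


def mean_relative_bias(delta, w):
    """Weighted arithmetic mean of per-parameter biases.

    ``delta`` holds one value per slope (linear terms first, then the
    quadratic terms in the same predictor order); ``w`` holds one weight
    per predictor and is attached to both of that predictor's terms.  A
    weight vector already aligned with ``delta`` (one weight per
    parameter) is also accepted.  NaN-valued weights or deltas are
    excluded pairwise.
    """
    delta = np.asarray(delta, dtype=float)
    w = np.asarray(w, dtype=float)
    if delta.size == w.size:
        ww = w
    elif delta.size == 2 * w.size:
        ww = np.concatenate([w, w])
    else:
        raise BiasError(f"expected {2 * w.size} (or {w.size}) deltas for {w.size} weights")
    ok = ~(np.isnan(delta) | np.isnan(ww))
    total = np.sum(ww[ok])
    if not total > 0:
        raise BiasError("weights sum to zero; cannot form weighted mean")
    return float(np.sum(ww[ok] * delta[ok]) / total)


@dataclass
class BiasResult:
    """Per-parameter and mean relative bias of one variant vs the reference."""

    variant: str
    delta: np.ndarray       # 8 slopes
    weights: np.ndarray     # 4 predictors (variant's own partial deviances)
    mean_delta: float

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "delta": self.delta.tolist(),
            "weights": self.weights.tolist(),
            "mean_delta": self.mean_delta,
        }


def compare_to_reference(fit_d: FitResult, fit_ref: FitResult) -> BiasResult:
    """Relative bias of variant D against the reference fit.

    Uses raw (unstandardized) coefficients with the reference's raw
    standard errors; the statistic is invariant to any consistent
    rescaling of a design column, so standardized inputs give the same
    answer.  Weights are the partial explained deviances from D's own fit.
    """
    delta = relative_bias(fit_d.slopes, fit_ref.slopes, fit_ref.slope_standard_errors)
    w = np.asarray(fit_d.partial_deviance, dtype=float)
    return BiasResult(
        variant=fit_d.variant or "?",
        delta=delta,
        weights=w,
        mean_delta=mean_relative_bias(delta, w),
    )


def expected_range_area(p, area):
    """Sum of occurrence probability times cell area: the expectation of
    occupied area, no threshold involved."""
    p = np.asarray(p, dtype=float)
    area = np.asarray(area, dtype=float)
    if p.shape != area.shape:
        raise BiasError("probability and area vectors differ in length")
    return float(np.sum(p * area))


def thresholded_range_area(p, area, prevalence):
    """Total area of cells whose predicted probability exceeds prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise BiasError("prevalence must lie in (0, 1)")
    p = np.asarray(p, dtype=float)
    area = np.asarray(area, dtype=float)
    if p.shape != area.shape:
        raise BiasError("probability and area vectors differ in length")
    return float(np.sum(area[p > prevalence]))


# ---------------------------------------------------------------------------
# experiment orchestration

@dataclass
class ExperimentConfig:
    world: WorldSpec
    species: list[tuple[str, TrueNiche]]
    variants: tuple[str, ...] = ("L", "LA", "LL", "LLA", "M", "ML")
    longlat_cell_size: float = 1.0
    equalarea_cell_size: float = 100.0
    coverage_threshold: float = 0.10
    seed: int = 0
    outdir: Optional[Path] = None

    def __post_init__(self):
        for v in self.variants:
            if v not in VARIANTS:
                raise BiasError(f"unknown variant {v!r}")
        if REFERENCE_VARIANT not in self.variants:
            raise BiasError(f"reference variant {REFERENCE_VARIANT} must be included")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "world_seed": self.world.seed,
                "fine_resolution": self.world.fine_resolution,
                "lat_extent": list(self.world.lat_extent),
                "lon_extent": list(self.world.lon_extent),
                "land_fraction_target": self.world.land_fraction_target,
                "species": [[n, niche.to_dict()] for n, niche in self.species],
                "variants": list(self.variants),
                "cells": [self.longlat_cell_size, self.equalarea_cell_size],
                "coverage_threshold": self.coverage_threshold,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_niches(n_species: int = 12, seed: int = 0) -> list[tuple[str, TrueNiche]]:
    """A spread of high-latitude (cold-adapted) virtual species covering a
    range of range sizes and niche breadths.

    All niches carry a smooth nuisance component (unobserved, non-climatic
    range drivers); without it the thresholded range is an exact function
    of the fitted design and the GLMs separate.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_species):
        # every third species is continental (range kept away from coasts),
        # mirroring the mix of coastal and purely continental study species;
        # every fourth is temperate (narrow thermal band short of the pole)
        # so maximum range latitude varies across the set
        continental = i % 3 == 2
        temperate = i % 4 == 1
        if temperate:
            intercept = float(rng.uniform(1.5, 2.5))
            t_lin = float(rng.uniform(-0.5, -0.2))
            t_quad = float(rng.uniform(-3.5, -2.5))
        else:
            intercept = float(rng.uniform(0.0, 3.0))
            t_lin = float(rng.uniform(-4.5, -2.5))  # colder is better: northern species
            t_quad = float(rng.uniform(-0.6, -0.2))
        lin = (
            t_lin,
            float(rng.uniform(-0.3, 0.3)),
            float(rng.uniform(-0.4, 0.4)),
            float(rng.uniform(-0.3, 0.3)),
        )
        quad = (
            t_quad,
            float(rng.uniform(-0.1, 0.0)),
            float(rng.uniform(-0.2, 0.0)),
            float(rng.uniform(-0.1, 0.0)),
        )
        out.append(
            (
                f"species_{i:02d}",
                TrueNiche(
                    intercept,
                    lin,
                    quad,
                    nuisance_amplitude=float(rng.uniform(1.2, 2.0)),
                    nuisance_correlation_length=rng.uniform(12.0, 20.0),
                    interior_affinity=12.0 if continental else 0.0,
                    interior_scale=5.0,
                ),
            )
        )
    return out


def reference_species_niche() -> TrueNiche:
    """The default high-latitude continental virtual species used for the
    replicate-based bias-ordering and grid-agreement checks."""
    return TrueNiche(
        intercept=2.0,
        linear_coefs=(-4.0, 0.1, 0.2, -0.1),
        quadratic_coefs=(-0.5, -0.05, -0.1, -0.05),
        nuisance_amplitude=1.5,
        nuisance_correlation_length=20.0,
        interior_affinity=10.0,
        interior_scale=5.0,
    )


def true_cell_probability(table: pd.DataFrame, niche: TrueNiche, means, sds) -> np.ndarray:
    """True occurrence probability per coarse cell: the niche translated to
    raw predictor scale (via the fine-grid standardization moments) and
    evaluated on the cell's aggregated predictor means."""
    X, _, _ = sdm.design_matrix(table)
    return np.asarray(
        1.0 / (1.0 + np.exp(-X @ niche.raw_coefficients(means, sds)))
    )


def simulate_cell_presence(
    table: pd.DataFrame, niche: TrueNiche, means, sds, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli presence per coarse cell at the niche's true probability.

    This is the parameter-recovery oracle's data-generating process: the
    response follows the fitted model family exactly, so the reference
    variant must recover the raw-scale truth up to sampling error."""
    p = true_cell_probability(table, niche, means, sds)
    return (rng.random(len(p)) < p).astype(int)


def run_experiment(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Execute the full pipeline for every species in the config.

    Returns tidy tables: ``fits`` (one row per species x variant),
    ``bias`` (species x non-reference variant), ``ranges`` (species x
    grid / variant range sizes) and ``species`` (truth-derived metadata).
    If the config has an ``outdir`` the tables, per-grid cell tables and a
    manifest are written there.
    """
    t0 = time.time()
    params = ProjectionParams(earth_radius=config.world.earth_radius)
    world = make_world(config.world)
    grids = {
        LONGLAT: grid_for_world(config.world, LONGLAT, config.longlat_cell_size, params),
        EQUALAREA: grid_for_world(config.world, EQUALAREA, config.equalarea_cell_size, params),
    }
    aggregators = {k: GridAggregator(world, g, params) for k, g in grids.items()}
    logger.info("world and aggregators ready in %.1fs", time.time() - t0)

    fit_rows, bias_rows, range_rows, species_rows = [], [], [], []
    tables_by_species = {}
    for s_idx, (name, niche) in enumerate(config.species):
        # per-species presence on the shared world; seeding is positional
        sp_spec = replace(config.world, seed=config.world.seed + 100_003 * (s_idx + 1))
        sp_world = FineWorld(
            spec=sp_spec, land_mask=world.land_mask, predictors=world.predictors
        )
        prob, presence = generate_species(niche, sp_world)
        sp_world.true_probability, sp_world.presence, sp_world.niche = prob, presence, niche
        for agg in aggregators.values():
            agg.world = sp_world

        meta = species_metadata(sp_world)
        tables = {
            k: agg.aggregate(config.coverage_threshold) for k, agg in aggregators.items()
        }
        tables_by_species[name] = tables

        fits: dict[str, FitResult] = {}
        for vname in config.variants:
            variant = VARIANTS[vname]
            table = land_cells(tables[variant.projection])
            row = {"species": name, "variant": vname}
            try:
                fit = sdm.fit_variant(table, variant)
                fits[vname] = fit
                row.update(_fit_row(fit))
            except (sdm.FitError, sdm.SchemaError) as exc:
                row.update({"converged": False, "error": str(exc)})
                logger.warning("fit failed for %s/%s: %s", name, vname, exc)
            fit_rows.append(row)

        ref = fits.get(REFERENCE_VARIANT)
        for vname in config.variants:
            if vname == REFERENCE_VARIANT or vname not in fits or ref is None:
                continue
            try:
                b = compare_to_reference(fits[vname], ref)
            except BiasError as exc:
                logger.warning("bias failed for %s/%s: %s", name, vname, exc)
                continue
            bias_rows.append(
                {
                    "species": name,
                    "variant": vname,
                    "mean_delta": b.mean_delta,
                    **{f"delta_{c}": d for c, d in zip(sdm.DESIGN_COLUMNS[1:], b.delta)},
                    **{f"w_{p}": w for p, w in zip(PREDICTOR_NAMES, b.weights)},
                }
            )

        range_rows.extend(
            _range_rows(name, config, tables, fits, meta)
        )
        species_rows.append(
            {
                "species": name,
                "range_km2": meta["range_km2"],
                "log_range_km2": np.log(meta["range_km2"]) if meta["range_km2"] > 0 else np.nan,
                "max_latitude": meta["max_latitude"],
                "coast_share": meta["coast_share"],
                "coastal": meta["coastal"],
            }
        )

    results = {
        "fits": pd.DataFrame(fit_rows),
        "bias": pd.DataFrame(bias_rows),
        "ranges": pd.DataFrame(range_rows),
        "species": pd.DataFrame(species_rows),
    }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, df in results.items():
            df.to_csv(outdir / f"{key}.csv", index=False)
        first = next(iter(tables_by_species))
        for gname, table in tables_by_species[first].items():
            gridding.write_cell_table(table, outdir / f"cells_{gname}.csv", grids[gname])
        manifest = {
            "seed": config.seed,
            "world_seed": config.world.seed,
            "config_hash": config.config_hash(),
            "variants": list(config.variants),
            "n_species": len(config.species),
            "versions": _versions(),
            "runtime_s": round(time.time() - t0, 2),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _fit_row(fit: FitResult) -> dict:
    row = {
        "converged": fit.converged,
        "pseudo_r2": fit.pseudo_r2,
        "prevalence": fit.prevalence,
        "n_cells": fit.n_cells,
        "deviance": fit.deviance,
        "null_deviance": fit.null_deviance,
    }
    for c, b, se, in zip(fit.columns, fit.coefficients, fit.standard_errors):
        row[f"beta_{c}"] = b
        row[f"se_{c}"] = se
    for c, s in zip(fit.columns[1:], fit.standardized_coefficients):
        row[f"std_{c}"] = s
    for p, w in zip(PREDICTOR_NAMES, fit.partial_deviance):
        row[f"pdev_{p}"] = w
    return row


def _range_rows(name, config, tables, fits, meta):
    rows = []
    for gname, table in tables.items():
        original = float((table["area_km2"] * table["presence"]).sum())
        rows.append(
            {
                "species": name,
                "grid": gname,
                "variant": "original",
                "range_km2": original,
            }
        )
    for vname, fit in fits.items():
        if not fit.converged:
            continue
        variant = VARIANTS[vname]
        table = land_cells(tables[variant.projection])
        X, _, _ = sdm.design_matrix(table)
        p = sdm.predict_occurrence(fit, X)
        area = table["area_km2"].to_numpy()
        rows.append(
            {
                "species": name,
                "grid": variant.projection,
                "variant": vname,
                "range_km2": expected_range_area(p, area),
                "range_km2_thresholded": thresholded_range_area(p, area, fit.prevalence)
                if 0 < fit.prevalence < 1
                else np.nan,
            }
        )
    return rows


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


# ---------------------------------------------------------------------------
# cross-species summary

def summarize_bias(bias: pd.DataFrame, species: pd.DataFrame) -> dict:
    """Cross-species summary of mean relative bias.

    Returns per-variant mean/median bias, a fixed-effects two-way ANOVA
    (variant + species block) with Tukey-style pairwise variant contrasts,
    and the slopes of bias on log(range size) and on maximum latitude.
    With a single species the contrasts are omitted with a notice.
    """
    if bias.empty:
        raise BiasError("no bias rows to summarize")
    per_variant = (
        bias.groupby("variant")["mean_delta"].agg(["mean", "median", "count"]).reset_index()
    )
    out = {"variant_summary": per_variant, "notices": []}

    n_species = bias["species"].nunique()
    n_variants = bias["variant"].nunique()
    if n_species < 2 or n_variants < 2:
        out["notices"].append("fewer than 2 species or variants: contrasts omitted")
        out["tukey"] = None
        out["anova"] = None
    else:
        model = smf.ols("mean_delta ~ C(variant) + C(species)", data=bias).fit()
        out["anova"] = sm.stats.anova_lm(model, typ=2)
        out["tukey"] = _tukey_contrasts(bias, model)

    merged = bias.merge(species, on="species", how="left")
    drivers = []
    for col in ("log_range_km2", "max_latitude"):
        sub = merged.dropna(subset=[col, "mean_delta"])
        if sub[col].nunique() > 1:
            X = sm.add_constant(sub[col].to_numpy())
            res = sm.OLS(sub["mean_delta"].to_numpy(), X).fit()
            drivers.append(
                {"driver": col, "slope": res.params[1], "p_value": res.pvalues[1]}
            )
        else:
            out["notices"].append(f"driver {col} is constant: slope omitted")
    out["drivers"] = pd.DataFrame(drivers)
    return out


def _tukey_contrasts(bias: pd.DataFrame, block_model) -> pd.DataFrame:
    """Tukey HSD on variant means, using the residual MSE of the blocked
    fixed-effects model (balanced design assumed)."""
    variants = sorted(bias["variant"].unique())
    means = bias.groupby("variant")["mean_delta"].mean()
    counts = bias.groupby("variant")["mean_delta"].count()
    mse = block_model.mse_resid
    df_resid = block_model.df_resid
    k = len(variants)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = variants[i], variants[j]
            n_harm = 2.0 / (1.0 / counts[a] + 1.0 / counts[b])
            se = np.sqrt(mse / n_harm)
            diff = means[a] - means[b]
            q = np.abs(diff) / se
            p = stats.studentized_range.sf(q, k, df_resid)
            rows.append(
                {
                    "variant_a": a,
                    "variant_b": b,
                    "diff": diff,
                    "q": q,
                    "p_adj": min(float(p), 1.0),
                    "significant": bool(p < 0.05),
                }
            )
    return pd.DataFrame(rows)
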