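"""End-to-end orchestration: read and validate inputs, standardize traits,
compute per-plot metrics, run the stratified null models, summarize habitats
and fit the driver trees, writing deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import null_models, summary_stats, trait_drivers
from .metrics import FRACTION_LABELS, Fraction, plot_metrics
from .null_models import (
    FractionComposition,
    NullConfig,
    SpeciesPool,
    beals_index,
    simulate_plot,
)
from .trait_space import (
    DissimilarityMatrix,
    StandardizedTraits,
    TraitTable,
    gower_podani,
    pcoa,
    read_trait_table,
    standardize,
)

logger = logging.getLogger(__name__)

STATUSES = ("native", "naturalized", "invasive")
LIFE_FORMS = ("macrophanerophyte", "nanophanerophyte", "chamaephyte", "herb", "epiphyte")
HERB_LAYER_FORMS = ("herb", "chamaephyte")
PHANEROPHYTE_FORMS = ("nanophanerophyte", "macrophanerophyte")
DISTANCE_MODES = ("euclidean_traits", "gower_pcoa")


@dataclass(frozen=True)
class RunConfig:
    plots: str
    traits: str
    registry: str
    habitat_map: str | None = None
    out_dir: str = "traitedge_out"
    n_sim: int = 999
    weighting: str = "beals"
    seed: int = 0
    use_cover_weights: bool = False
    distance_mode: str = "euclidean_traits"
    layer_split: bool = False
    exclude_species: tuple[str, ...] = ()
    comparisons: tuple[str, ...] = ("vs_native", "naturalized_vs_invasive")
    tree_min_split: int = 20
    tree_min_leaf: int = 7
    tree_cv_folds: int = 10
    tree_life_forms: tuple[str, ...] | None = HERB_LAYER_FORMS

    def __post_init__(self) -> None:
        if self.distance_mode not in DISTANCE_MODES:
            raise ValueError(f"distance_mode must be one of {DISTANCE_MODES}")


@dataclass(frozen=True)
class LoadedInputs:
    plots: pd.DataFrame  # long: plot_id, habitat, species, cover
    trait_table: TraitTable
    registry: pd.DataFrame  # index species: status, life_form
    pools: dict[str, SpeciesPool]


def read_registry(path) -> pd.DataFrame:
    reg = pd.read_csv(path)
    if "species" not in reg.columns:
        raise ValueError("registry must contain a 'species' column")
    reg = reg.set_index("species")
    for col in ("status", "life_form"):
        if col not in reg.columns:
            raise ValueError(f"registry must contain a {col!r} column")
    bad = set(reg["status"]) - set(STATUSES)
    if bad:
        raise ValueError(f"unknown invasion statuses: {sorted(bad)}")
    return reg[["status", "life_form"]]


def read_plots(path, habitat_map: str | None = None) -> pd.DataFrame:
    """Read the long-format plot table; habitats from a column or a map file."""
    plots = pd.read_csv(path)
    required = {"plot_id", "species", "cover"}
    if required.issubset(plots.columns):
        long = plots
    else:
        # wide matrix: first column plot ids, remaining columns species covers
        wide = plots.set_index(plots.columns[0])
        long = (
            wide.stack()
            .rename("cover")
            .reset_index()
            .rename(columns={wide.index.name or "level_0": "plot_id", "level_1": "species"})
        )
        long = long[long["cover"] > 0]
    if habitat_map is not None:
        hmap = pd.read_csv(habitat_map)
        if not {"plot_id", "habitat"}.issubset(hmap.columns):
            raise ValueError("habitat map needs columns plot_id, habitat")
        long = long.drop(columns=["habitat"], errors="ignore").merge(
            hmap[["plot_id", "habitat"]], on="plot_id", how="left"
        )
    if "habitat" not in long.columns or long["habitat"].isna().any():
        raise ValueError("every plot needs a habitat (column or --habitat-map)")
    if (long["cover"] <= 0).any() or (long["cover"] > 100).any():
        raise ValueError("covers must lie in (0, 100]")
    return long[["plot_id", "habitat", "species", "cover"]]


def build_pools(plots: pd.DataFrame, registry: pd.DataFrame) -> dict[str, SpeciesPool]:
    """Habitat species pools with occurrence frequencies realized in plots."""
    pools = {}
    for habitat, grp in plots.groupby("habitat", sort=True):
        freq = grp.groupby("species")["plot_id"].nunique()
        table = registry.loc[freq.index].copy()
        table["frequency"] = freq
        pools[habitat] = SpeciesPool(habitat=habitat, table=table)
    return pools


def apply_layer_split(plots: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Split each plot into herb-layer and phanerophyte-layer pseudo-plots.

    Herb layer = herbs + chamaephytes; phanerophyte layer = nano- and
    macrophanerophytes; epiphytes are dropped with a warning.
    """
    lf = registry["life_form"]
    merged = plots.merge(lf.rename("life_form"), left_on="species", right_index=True)
    n_epi = int(merged["life_form"].eq("epiphyte").sum())
    if n_epi:
        logger.warning("layer split: dropping %d epiphyte occurrences", n_epi)
    herb = merged[merged["life_form"].isin(HERB_LAYER_FORMS)].copy()
    phan = merged[merged["life_form"].isin(PHANEROPHYTE_FORMS)].copy()
    herb["plot_id"] = herb["plot_id"].astype(str) + ":herb_layer"
    phan["plot_id"] = phan["plot_id"].astype(str) + ":phanerophyte_layer"
    out = pd.concat([herb, phan], ignore_index=True)
    return out[["plot_id", "habitat", "species", "cover"]]


def load_inputs(config: RunConfig) -> LoadedInputs:
    """Read, validate and cross-reference all inputs; build habitat pools."""
    trait_table = read_trait_table(config.traits)
    registry = read_registry(config.registry)
    plots = read_plots(config.plots, config.habitat_map)

    if config.exclude_species:
        excluded = set(config.exclude_species)
        plots = plots[~plots["species"].isin(excluded)].copy()
        registry = registry[~registry.index.isin(excluded)]

    unknown = sorted(set(plots["species"]) - set(registry.index))
    if unknown:
        raise ValueError(f"plot species missing from registry: {unknown[:10]}")
    untraited = sorted(set(plots["species"]) - set(trait_table.species))
    if untraited:
        raise ValueError(f"plot species missing from trait table: {untraited[:10]}")
    if plots.empty:
        raise ValueError("no plot records after filtering")

    if config.layer_split:
        plots = apply_layer_split(plots, registry)
        plots = plots[plots.groupby("plot_id")["species"].transform("size") >= 2]

    pools = build_pools(plots, registry)
    return LoadedInputs(plots=plots, trait_table=trait_table, registry=registry, pools=pools)


def _standardized_coords(inputs: LoadedInputs, config: RunConfig) -> StandardizedTraits:
    """Coordinates for all species, scaled once over the whole trait table.

    Scaling over the full table (rather than only species realized in plots)
    keeps the coordinate system fixed when plots or species are filtered, so
    sensitivity runs stay comparable.
    """
    if config.distance_mode == "euclidean_traits":
        return standardize(inputs.trait_table)
    return pcoa(gower_podani(inputs.trait_table))


def plot_fractions(
    plot_df: pd.DataFrame, registry: pd.DataFrame
) -> dict[str, FractionComposition]:
    """Observed fraction compositions (species, life forms, covers) of a plot."""
    merged = plot_df.merge(
        registry[["status", "life_form"]], left_on="species", right_index=True
    ).sort_values("species")
    fractions = {}
    for status, grp in merged.groupby("status"):
        fractions[status] = FractionComposition(
            label=status,
            species=tuple(grp["species"]),
            life_forms=tuple(grp["life_form"]),
            covers=grp["cover"].to_numpy(float),
        )
    return fractions


def compute_plot_metrics(
    inputs: LoadedInputs, std: StandardizedTraits
) -> pd.DataFrame:
    """Observed D/E per plot for all fractions present (needs natives)."""
    rows = []
    for (plot_id, habitat), grp in inputs.plots.groupby(["plot_id", "habitat"], sort=True):
        comps = plot_fractions(grp, inputs.registry)
        if "native" not in comps:
            continue
        fractions = {
            lab: Fraction(
                label=lab,
                species=comp.species,
                coords=std.matrix(list(comp.species)),
                covers=comp.covers,
            )
            for lab, comp in comps.items()
        }
        pm = plot_metrics(plot_id, fractions)
        for lab in pm.d:
            rows.append(
                {
                    "plot_id": plot_id,
                    "habitat": habitat,
                    "kind": "fraction",
                    "target": lab,
                    "n": pm.n[lab],
                    "d": pm.d[lab],
                    "d_weighted": pm.d_weighted[lab],
                    "e": np.nan,
                    "e_weighted": np.nan,
                }
            )
        for pair in pm.e:
            rows.append(
                {
                    "plot_id": plot_id,
                    "habitat": habitat,
                    "kind": "pair",
                    "target": f"{pair[0]}|{pair[1]}",
                    "n": pm.n[pair[0]] + pm.n[pair[1]],
                    "d": np.nan,
                    "d_weighted": np.nan,
                    "e": pm.e[pair],
                    "e_weighted": pm.e_weighted[pair],
                }
            )
    return pd.DataFrame(rows)


def run_null_models(
    inputs: LoadedInputs, std: StandardizedTraits, config: RunConfig
) -> pd.DataFrame:
    """Run every configured comparison for every eligible plot."""
    beals_by_habitat: dict[str, pd.DataFrame] = {}
    if config.weighting == "beals":
        for habitat, grp in inputs.plots.groupby("habitat", sort=True):
            presence = (
                grp.assign(present=1)
                .pivot_table(index="plot_id", columns="species", values="present", fill_value=0)
            )
            beals_by_habitat[habitat] = beals_index(presence)

    results: list[null_models.NullResult] = []
    habitats: dict[str, str] = {}
    skipped: dict[str, int] = {c: 0 for c in config.comparisons}
    for (plot_id, habitat), grp in inputs.plots.groupby(["plot_id", "habitat"], sort=True):
        comps = plot_fractions(grp, inputs.registry)
        pool = inputs.pools[habitat]
        beals_row = None
        if config.weighting == "beals":
            beals_row = beals_by_habitat[habitat].loc[plot_id]
        for comparison in config.comparisons:
            if comparison == "vs_native":
                eligible = "native" in comps and len(comps) > 1
            else:
                eligible = "naturalized" in comps and "invasive" in comps
            if not eligible:
                skipped[comparison] += 1
                continue
            null_config = NullConfig(
                n_sim=config.n_sim,
                weighting=config.weighting,
                seed=config.seed,
                comparison=comparison,
                use_cover_weights=config.use_cover_weights,
            )
            try:
                res = simulate_plot(
                    plot_id, comps, pool, std.coords, null_config, beals_row=beals_row
                )
            except null_models.StratumExhaustedError as err:
                logger.warning("skipping plot %s (%s): %s", plot_id, comparison, err)
                skipped[comparison] += 1
                continue
            results.append(res)
            habitats[plot_id] = habitat
    for comparison, count in skipped.items():
        logger.info("%s: skipped %d plots without the required fractions", comparison, count)
    frame = null_models.null_results_frame(results)
    if len(frame):
        frame["habitat"] = frame["plot_id"].map(habitats)
    else:
        frame["habitat"] = pd.Series(dtype=object)
    return frame


def fit_driver_trees(
    inputs: LoadedInputs,
    std: StandardizedTraits,
    null_frame: pd.DataFrame,
    config: RunConfig,
) -> dict[str, trait_drivers.TreeModel]:
    """Driver trees: naturalized delta-D (native-pool null) and invasive
    delta-D (naturalized-pool null), herbs + dwarf shrubs by default."""
    memberships = inputs.plots.merge(
        inputs.registry[["status", "life_form"]], left_on="species", right_index=True
    )[["plot_id", "species", "status", "life_form"]]
    delta = null_frame[null_frame["kind"] == "fraction"]
    trees = {}
    specs = {
        "naturalized": ("vs_native", "naturalized"),
        "invasive": ("naturalized_vs_invasive", "invasive"),
    }
    for name, (comparison, fraction) in specs.items():
        dataset = trait_drivers.build_driver_dataset(
            delta, memberships, std.coords, fraction, comparison, config.tree_life_forms
        )
        if len(dataset) < config.tree_min_split:
            logger.warning("tree %s: only %d rows, skipping", name, len(dataset))
            continue
        trees[name] = trait_drivers.fit_tree(
            dataset,
            min_split=config.tree_min_split,
            min_leaf=config.tree_min_leaf,
            cv_folds=config.tree_cv_folds,
            seed=config.seed,
        )
    return trees


@dataclass(frozen=True)
class AnalysisBundle:
    plot_metrics: pd.DataFrame
    null_results: pd.DataFrame
    habitat_summary: pd.DataFrame
    trees: dict[str, trait_drivers.TreeModel]
    manifest: dict


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_analysis(config: RunConfig, write: bool = True) -> AnalysisBundle:
    """Run the full pipeline; optionally write the output bundle."""
    inputs = load_inputs(config)
    std = _standardized_coords(inputs, config)
    metrics_frame = compute_plot_metrics(inputs, std)
    null_frame = run_null_models(inputs, std, config)
    delta = null_frame[null_frame["kind"] == "fraction"]
    summary = summary_stats.summarize_habitats(delta)
    trees = fit_driver_trees(inputs, std, null_frame, config)
    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_plots": int(inputs.plots["plot_id"].nunique()),
        "n_species": int(inputs.plots["species"].nunique()),
        "n_sim": config.n_sim,
        "weighting": config.weighting,
        "distance_mode": config.distance_mode,
        "comparisons": list(config.comparisons),
        "version": _package_version(),
    }
    bundle = AnalysisBundle(
        plot_metrics=metrics_frame,
        null_results=null_frame,
        habitat_summary=summary,
        trees=trees,
        manifest=manifest,
    )
    if write:
        write_bundle(bundle, config.out_dir)
    return bundle


def _package_version() -> str:
    from . import __version__

    return __version__


def write_bundle(bundle: AnalysisBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fail_marker = out / "FAILED"
    try:
        bundle.plot_metrics.to_csv(out / "plot_metrics.csv", index=False)
        bundle.null_results.to_csv(out / "null_results.csv", index=False)
        bundle.habitat_summary.to_csv(out / "habitat_summary.csv", index=False)
        for name, tree in bundle.trees.items():
            with open(out / f"tree_{name}.json", "w") as fh:
                json.dump(tree.to_dict(), fh, indent=1)
        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
    except Exception:
        fail_marker.touch()
        raise
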