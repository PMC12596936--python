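"""Synthetic vegetation-plot generator.

Builds habitat species pools (traits, invasion status, life form) and
invaded plots (every plot holds at least one native together with at least
one alien species) under named assembly scenarios:

``neutral``
    native, naturalized and invasive traits identically distributed;
``filtering``
    alien trait means coincide with the native centroid;
``eots``
    naturalized means at the centroid (with a mild variance contraction,
    i.e., environmental filtering), invasive means displaced from the native
    centroid by a configurable distance along random unit directions.

Traits are generated on the standardized scale and back-transformed
(10^x for log-scale traits, a clipped integer month for the flowering
midpoint) so the preprocessing stage is exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trait_space import TRAIT_META, TRAIT_NAMES, TraitTable

SCENARIOS = ("neutral", "filtering", "eots")

DEFAULT_LIFEFORM_MIX = {
    "herb": 0.7,
    "chamaephyte": 0.1,
    "nanophanerophyte": 0.1,
    "macrophanerophyte": 0.1,
}

#: SD multiplier for naturalized traits under the eots scenario; < 1 encodes
#: filtering-induced clustering so the naturalized fraction sits at or inside
#: the native cloud rather than straddling zero.
EOTS_NATURALIZED_SCALE = 0.8


@dataclass(frozen=True)
class CoverModel:
    """Log-normal percentage covers truncated to (0, 100]."""

    log_mean: float = 1.0
    log_sd: float = 1.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        covers = np.exp(rng.normal(self.log_mean, self.log_sd, size=size))
        return np.minimum(covers, 100.0)


@dataclass(frozen=True)
class ScenarioConfig:
    n_native: int = 200
    n_naturalized: int = 60
    n_invasive: int = 25
    n_plots: int = 100
    richness_mean: float = 12.0
    lifeform_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LIFEFORM_MIX))
    alien_displacement: float = 0.0
    scenario: str = "neutral"
    cover_model: CoverModel = field(default_factory=CoverModel)
    seed: int = 0
    habitat: str = "synthetic"
    # expected fraction of a plot's richness that is naturalized / invasive
    alien_mix: tuple[float, float] = (0.15, 0.10)

    def __post_init__(self) -> None:
        for name in ("n_native", "n_naturalized", "n_invasive", "n_plots"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.richness_mean <= 0:
            raise ValueError("richness_mean must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not np.isfinite(self.alien_displacement) or self.alien_displacement < 0:
            raise ValueError("alien_displacement must be finite and >= 0")
        total = sum(self.lifeform_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"lifeform_mix must sum to 1, got {total}")
        if any(p < 0 for p in self.lifeform_mix.values()):
            raise ValueError("lifeform_mix proportions must be nonnegative")


@dataclass(frozen=True)
class SyntheticDataset:
    trait_table: TraitTable
    registry: pd.DataFrame  # index species; columns status, life_form
    plots: pd.DataFrame  # long format: plot_id, habitat, species, cover
    truth: dict  # per-species generated displacement from the native centroid


def _back_transform(z: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Map standardized-scale draws to plausible raw trait values."""
    raw = {}
    for k, trait in enumerate(TRAIT_NAMES):
        log_flag, ordinal_flag = TRAIT_META[trait]
        col = z[:, k]
        if ordinal_flag:  # flowering midpoint: integer month 1..12
            raw[trait] = np.clip(np.rint(6.5 + 2.0 * col), 1, 12).astype(int)
        elif log_flag:
            raw[trait] = 10.0**col
        else:
            raw[trait] = col
    return pd.DataFrame(raw)


def generate_pool(config: ScenarioConfig) -> tuple[TraitTable, pd.DataFrame, dict]:
    """Generate the species pool: traits, registry and the truth record.

    Returns ``(trait_table, registry, truth)`` where ``truth`` maps each
    species to its generated displacement (vector and norm) from the native
    centroid on the standardized scale.
    """
    rng = np.random.default_rng(config.seed)
    k = len(TRAIT_NAMES)
    counts = {
        "native": config.n_native,
        "naturalized": config.n_naturalized,
        "invasive": config.n_invasive,
    }
    species_ids: list[str] = []
    statuses: list[str] = []
    z_rows: list[np.ndarray] = []
    truth: dict[str, dict] = {}
    for status, n in counts.items():
        means = np.zeros((n, k))
        scale = 1.0
        if status == "invasive" and config.scenario == "eots" and config.alien_displacement > 0:
            directions = rng.normal(size=(n, k))
            directions /= np.linalg.norm(directions, axis=1, keepdims=True)
            means = config.alien_displacement * directions
        if status == "naturalized" and config.scenario == "eots":
            scale = EOTS_NATURALIZED_SCALE
        z = means + scale * rng.normal(size=(n, k))
        for i in range(n):
            sid = f"{status[:4]}_{i + 1:04d}"
            species_ids.append(sid)
            statuses.append(status)
            truth[sid] = {
                "status": status,
                "mean_displacement": means[i].tolist(),
                "displacement_norm": float(np.linalg.norm(means[i])),
            }
        z_rows.append(z)
    z_all = np.vstack(z_rows)
    raw = _back_transform(z_all, rng)
    raw.index = pd.Index(species_ids, name="species")

    forms = list(config.lifeform_mix)
    probs = np.array([config.lifeform_mix[f] for f in forms], float)
    life_forms = rng.choice(forms, size=len(species_ids), p=probs)
    # guarantee every status stratum holds each requested life form at least
    # once so plot assembly and null draws cannot dead-end on tiny pools
    registry = pd.DataFrame(
        {"status": statuses, "life_form": life_forms}, index=raw.index
    )
    for status, n in counts.items():
        idx = registry.index[registry["status"] == status]
        present = set(registry.loc[idx, "life_form"])
        needed = [f for f, p in config.lifeform_mix.items() if p > 0 and f not in present]
        if len(needed) > len(idx):
            raise ValueError(f"stratum {status!r} too small for the life-form mix")
        for f, sid in zip(needed, idx):
            registry.loc[sid, "life_form"] = f
    for sid in truth:
        truth[sid]["life_form"] = str(registry.loc[sid, "life_form"])
    return TraitTable(data=raw), registry, truth


def _plot_fraction_sizes(
    richness: int, alien_mix: tuple[float, float], rng: np.random.Generator
) -> dict[str, int]:
    n_natz = max(1, int(np.rint(alien_mix[0] * richness)))
    n_inv = max(1, int(np.rint(alien_mix[1] * richness)))
    n_natv = richness - n_natz - n_inv
    if n_natv < 1:
        n_natv, n_natz, n_inv = 1, max(1, richness - 2), 1
    return {"native": n_natv, "naturalized": n_natz, "invasive": n_inv}


def generate_plots(
    trait_table: TraitTable,
    registry: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assemble invaded plots (long format: plot_id, habitat, species, cover).

    Each plot draws a richness from a Poisson truncated at >= 3, splits it
    into native / naturalized / invasive counts (each >= 1), fills every slot
    with a life form drawn from the configured mix and a uniformly chosen
    pool species of that status and life form (without replacement within
    the plot), then assigns log-normal covers.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    strata: dict[tuple[str, str], np.ndarray] = {}
    for (status, life_form), grp in registry.groupby(["status", "life_form"], sort=True):
        strata[(status, life_form)] = grp.index.to_numpy()
    forms = list(config.lifeform_mix)
    probs = np.array([config.lifeform_mix[f] for f in forms], float)
    records = []
    width = len(str(config.n_plots))
    for p in range(config.n_plots):
        plot_id = f"plot_{p + 1:0{width}d}"
        richness = max(3, int(rng.poisson(config.richness_mean)))
        sizes = _plot_fraction_sizes(richness, config.alien_mix, rng)
        chosen: list[tuple[str, str]] = []
        used: set[str] = set()
        for status, n_frac in sizes.items():
            for _ in range(n_frac):
                # draw a life form, fall back to any stratum with room
                lf_order = list(rng.permutation(forms[:]))
                lf_first = rng.choice(forms, p=probs)
                lf_order.remove(lf_first)
                picked = None
                for lf in [lf_first] + lf_order:
                    pool = strata.get((status, lf))
                    if pool is None:
                        continue
                    avail = [s for s in pool if s not in used]
                    if avail:
                        picked = avail[rng.integers(len(avail))]
                        break
                if picked is None:
                    raise ValueError(
                        f"pool exhausted for status {status!r} in plot {plot_id}"
                    )
                used.add(picked)
                chosen.append((status, picked))
        covers = config.cover_model.sample(rng, len(chosen))
        for (status, sid), cover in zip(chosen, covers):
            records.append(
                {
                    "plot_id": plot_id,
                    "habitat": config.habitat,
                    "species": sid,
                    "cover": float(cover),
                }
            )
    return pd.DataFrame(records)


def generate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset; byte-identical for one seed."""
    trait_table, registry, truth = generate_pool(config)
    plots = generate_plots(trait_table, registry, config)
    return SyntheticDataset(trait_table=trait_table, registry=registry, plots=plots, truth=truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write traits TSV, registry CSV, plots long CSV and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traits": outdir / "traits.tsv",
        "registry": outdir / "registry.csv",
        "plots": outdir / "plots.csv",
        "truth": outdir / "truth.json",
    }
    dataset.trait_table.data.to_csv(paths["traits"], sep="\t", index_label="species")
    dataset.registry.to_csv(paths["registry"], index_label="species")
    dataset.plots.to_csv(paths["plots"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
    return paths
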