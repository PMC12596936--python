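"""Stratified null models: simulate community fractions by random draws from
habitat species pools and reduce observed-vs-simulated statistics to
deviations (delta D) and empirical overlap probabilities.

Three pool-weighting schemes are supported: ``uniform`` (completely random),
``frequency`` (proportional to habitat occurrence frequency) and ``beals``
(proportional to the plot's Beals co-occurrence probability). Every simulated
fraction preserves the observed fraction's size, per-life-form counts and
cover multiset; the compared fractions of one replicate are drawn jointly and
disjointly.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

WEIGHTING_SCHEMES = ("uniform", "frequency", "beals")
COMPARISONS = ("vs_native", "naturalized_vs_invasive")

#: Floor applied to zero Beals probabilities so draws stay feasible in sparse
#: data; applied before normalization and logged when triggered.
BEALS_FLOOR = 1e-6


@dataclass(frozen=True)
class SpeciesPool:
    """Habitat species pool: status, life form and occurrence frequency."""

    habitat: str
    table: pd.DataFrame  # index: species; columns: status, life_form, frequency

    def __post_init__(self) -> None:
        required = {"status", "life_form", "frequency"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"pool table needs columns {sorted(required)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate species in pool")
        if (self.table["frequency"] < 1).any():
            raise ValueError("pool frequencies must be >= 1")

    def subset(self, status: str) -> pd.DataFrame:
        return self.table[self.table["status"] == status]


@dataclass(frozen=True)
class NullConfig:
    n_sim: int = 999
    weighting: str = "beals"
    seed: int = 0
    comparison: str = "vs_native"
    use_cover_weights: bool = False

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.weighting not in WEIGHTING_SCHEMES:
            raise ValueError(f"weighting must be one of {WEIGHTING_SCHEMES}")
        if self.comparison not in COMPARISONS:
            raise ValueError(f"comparison must be one of {COMPARISONS}")


@dataclass(frozen=True)
class FractionComposition:
    """Observed composition of one community fraction in one plot."""

    label: str
    species: tuple
    life_forms: tuple
    covers: np.ndarray

    def __post_init__(self) -> None:
        if len(self.species) == 0:
            raise ValueError(f"fraction {self.label!r} is empty")
        if not (len(self.species) == len(self.life_forms) == len(self.covers)):
            raise ValueError("composition fields not aligned")

    @property
    def n(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class NullResult:
    """Per-plot null-model reduction for one comparison."""

    plot_id: str
    comparison: str
    weighting: str
    n_sim: int
    seed: int
    observed_d: dict[str, float]
    mean_sim_d: dict[str, float]
    delta_d: dict[str, float]
    observed_e: dict[tuple[str, str], float]
    p_e: dict[tuple[str, str], float]
    use_cover_weights: bool = False


class StratumExhaustedError(RuntimeError):
    """Raised when a pool stratum cannot supply the required draw."""


def beals_index(occurrence: pd.DataFrame) -> pd.DataFrame:
    """Beals smoothing: probability of each species occurring in each plot.

    For plot i and species j:

        b_ij = (1 / S_ij) * sum_{k in plot i, k != j} M_jk / N_k

    where M_jk counts plots containing both j and k, N_k counts plots
    containing k, and S_ij is the number of species in plot i excluding j.
    The target species is excluded from its own prediction.
    """
    x = (occurrence.to_numpy(float) > 0).astype(float)
    n_k = x.sum(axis=0)
    if (n_k == 0).any():
        bad = occurrence.columns[n_k == 0].tolist()
        raise ValueError(f"species with zero occurrences: {bad[:5]}")
    m = x.T @ x
    q = m / n_k[None, :]  # q[j, k] = M_jk / N_k
    richness = x.sum(axis=1)
    numerator = x @ q.T - x  # subtract the k == j term (q[j, j] == 1)
    s = richness[:, None] - x
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(s > 0, numerator / np.where(s > 0, s, 1.0), 0.0)
    return pd.DataFrame(b, index=occurrence.index, columns=occurrence.columns)


def _weighted_sample_without_replacement(
    rng: np.random.Generator, n_candidates: int, k: int, weights: np.ndarray | None
) -> np.ndarray:
    """Draw ``k`` distinct indices from ``range(n_candidates)``.

    Weighted draws use the Gumbel top-k trick, which is distributionally
    identical to sequential weighted draws with renormalization after each
    removal (Efraimidis & Spirakis 2006).
    """
    if k > n_candidates:
        raise StratumExhaustedError(f"need {k} species from a stratum of {n_candidates}")
    if weights is None:
        return rng.choice(n_candidates, size=k, replace=False)
    keys = np.log(weights) + rng.gumbel(size=n_candidates)
    top = np.argpartition(-keys, k - 1)[:k]
    # descending key order == sequential draw order, so callers may split the
    # result into consecutive chunks (first fraction drawn first)
    return top[np.argsort(-keys[top])]


def _candidate_weights(
    candidates: pd.DataFrame, weighting: str, beals_row: pd.Series | None
) -> np.ndarray | None:
    if weighting == "uniform":
        return None
    if weighting == "frequency":
        w = candidates["frequency"].to_numpy(float)
    elif weighting == "beals":
        if beals_row is None:
            raise ValueError("beals weighting requires a beals_row")
        w = beals_row.reindex(candidates.index).fillna(0.0).to_numpy(float)
        n_floored = int((w <= 0).sum())
        if n_floored:
            logger.debug("flooring %d zero Beals probabilities", n_floored)
        w = np.maximum(w, BEALS_FLOOR)
    else:  # pragma: no cover
        raise ValueError(weighting)
    if not (w > 0).any():
        raise ValueError("all candidate probabilities are zero")
    return w


def draw_fraction(
    observed: FractionComposition,
    pool: SpeciesPool,
    weighting: str = "uniform",
    beals_row: pd.Series | None = None,
    rng: np.random.Generator | None = None,
    pool_status: str = "native",
    taken: set | None = None,
) -> FractionComposition:
    """Draw one simulated counterpart of ``observed`` from ``pool``.

    For each observed member a replacement of the same life form is drawn
    without replacement from the pool's ``pool_status`` stratum; the observed
    member's cover is inherited by its replacement. Species listed in
    ``taken`` are excluded (and the drawn species are added to it), which
    lets callers keep several fractions of one replicate disjoint.
    """
    rng = np.random.default_rng() if rng is None else rng
    taken = set() if taken is None else taken
    stratum_table = pool.subset(pool_status)
    new_species: list = [None] * observed.n
    order = np.arange(observed.n)
    for life_form in sorted(set(observed.life_forms)):
        slots = order[[lf == life_form for lf in observed.life_forms]]
        candidates = stratum_table[
            (stratum_table["life_form"] == life_form) & ~stratum_table.index.isin(taken)
        ]
        if len(candidates) < len(slots):
            raise StratumExhaustedError(
                f"habitat {pool.habitat!r}: stratum ({pool_status}, {life_form}) has "
                f"{len(candidates)} available species, {len(slots)} required"
            )
        weights = _candidate_weights(candidates, weighting, beals_row)
        idx = _weighted_sample_without_replacement(rng, len(candidates), len(slots), weights)
        chosen = candidates.index.to_numpy()[idx]
        for slot, sp in zip(slots, chosen):
            new_species[slot] = sp
        taken.update(chosen)
    return FractionComposition(
        label=observed.label,
        species=tuple(new_species),
        life_forms=observed.life_forms,
        covers=observed.covers,
    )


def plot_rng(master_seed: int, plot_id: str, comparison: str) -> np.random.Generator:
    """Deterministic per-plot generator independent of processing order."""
    key = (zlib.crc32(plot_id.encode()), zlib.crc32(comparison.encode()))
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


@dataclass
class _StratumSampler:
    """Pre-resolved candidates for one life-form stratum of a plot."""

    coords_idx: np.ndarray  # indices into the pool coordinate matrix
    weights: np.ndarray | None
    slots: list[tuple[int, np.ndarray]]  # (fraction position, member slots)


def _prepare_samplers(
    fractions: list[FractionComposition],
    stratum_table: pd.DataFrame,
    pool_index: pd.Index,
    weighting: str,
    beals_row: pd.Series | None,
) -> list[_StratumSampler]:
    samplers = []
    life_forms = sorted({lf for f in fractions for lf in f.life_forms})
    for life_form in life_forms:
        candidates = stratum_table[stratum_table["life_form"] == life_form]
        slots = []
        needed = 0
        for pos, frac in enumerate(fractions):
            member_slots = np.array(
                [i for i, lf in enumerate(frac.life_forms) if lf == life_form], dtype=int
            )
            if member_slots.size:
                slots.append((pos, member_slots))
                needed += member_slots.size
        if not slots:
            continue
        if len(candidates) < needed:
            raise StratumExhaustedError(
                f"stratum life form {life_form!r}: {len(candidates)} candidates, "
                f"{needed} required jointly"
            )
        weights = _candidate_weights(candidates, weighting, beals_row)
        coords_idx = pool_index.get_indexer(candidates.index)
        samplers.append(_StratumSampler(coords_idx=coords_idx, weights=weights, slots=slots))
    return samplers


def _fraction_weights(covers: np.ndarray, use_cover_weights: bool) -> np.ndarray:
    if use_cover_weights:
        w = np.sqrt(covers)
        return w / w.sum()
    return np.full(len(covers), 1.0 / len(covers))


def _d_statistic(coords: np.ndarray, center: np.ndarray, w: np.ndarray) -> float:
    return float(w @ np.linalg.norm(coords - center, axis=1))


def _e_statistic(cx: np.ndarray, cy: np.ndarray, wx: np.ndarray, wy: np.ndarray) -> float:
    e = (
        2.0 * (wx @ cdist(cx, cy) @ wy)
        - (wx @ cdist(cx, cx) @ wx)
        - (wy @ cdist(cy, cy) @ wy)
    )
    return float(max(e, 0.0))


def overlap_probability(observed_e: float, simulated_es: np.ndarray) -> float:
    """Empirical overlap probability: (#{sim >= observed} + 1) / (n_sim + 1)."""
    simulated_es = np.asarray(simulated_es, float)
    if simulated_es.size == 0:
        raise ValueError("no simulated values")
    return float((np.sum(simulated_es >= observed_e) + 1) / (simulated_es.size + 1))


def simulate_plot(
    plot_id: str,
    fractions: dict[str, FractionComposition],
    pool: SpeciesPool,
    coords: pd.DataFrame,
    config: NullConfig,
    beals_row: pd.Series | None = None,
) -> NullResult:
    """Run the stratified null model for one plot and one comparison.

    ``coords`` maps species to standardized trait-space coordinates (rows
    indexed by species). For ``vs_native`` all fractions present are redrawn
    from the habitat's native pool; for ``naturalized_vs_invasive`` the
    naturalized and invasive fractions are redrawn from the naturalized pool.
    Within a replicate the fractions are drawn jointly and disjointly, and D
    is referenced to the centroid of the simulated first (reference)
    fraction. Observed D uses the observed reference fraction's centroid.
    """
    if config.comparison == "vs_native":
        pool_status = "native"
        labels = [lab for lab in ("native", "naturalized", "invasive") if lab in fractions]
        if "native" not in fractions:
            raise ValueError(f"plot {plot_id!r}: vs_native requires a native fraction")
        pairs = [("native", lab) for lab in labels if lab != "native"]
    else:
        pool_status = "naturalized"
        labels = ["naturalized", "invasive"]
        if not all(lab in fractions for lab in labels):
            raise ValueError(
                f"plot {plot_id!r}: naturalized_vs_invasive requires both fractions"
            )
        pairs = [("naturalized", "invasive")]
    fracs = [fractions[lab] for lab in labels]
    reference = labels[0]

    pool_coords = coords.to_numpy(float)
    pool_index = coords.index
    obs_coords = {lab: coords.loc[list(fractions[lab].species)].to_numpy(float) for lab in labels}
    frac_w = {
        lab: _fraction_weights(fractions[lab].covers, config.use_cover_weights) for lab in labels
    }

    mu_obs = frac_w[reference] @ obs_coords[reference]
    observed_d = {lab: _d_statistic(obs_coords[lab], mu_obs, frac_w[lab]) for lab in labels}
    observed_e = {
        pair: _e_statistic(obs_coords[pair[0]], obs_coords[pair[1]], frac_w[pair[0]], frac_w[pair[1]])
        for pair in pairs
    }

    stratum_table = pool.subset(pool_status)
    samplers = _prepare_samplers(fracs, stratum_table, pool_index, config.weighting, beals_row)
    rng = plot_rng(config.seed, plot_id, config.comparison)

    sim_d = {lab: np.empty(config.n_sim) for lab in labels}
    sim_e = {pair: np.empty(config.n_sim) for pair in pairs}
    sim_idx = [np.empty(f.n, dtype=int) for f in fracs]
    for rep in range(config.n_sim):
        for sampler in samplers:
            chosen = _weighted_sample_without_replacement(
                rng, len(sampler.coords_idx), sum(s.size for _, s in sampler.slots), sampler.weights
            )
            offset = 0
            for pos, member_slots in sampler.slots:
                sim_idx[pos][member_slots] = sampler.coords_idx[
                    chosen[offset : offset + member_slots.size]
                ]
                offset += member_slots.size
        sim_coords = [pool_coords[idx] for idx in sim_idx]
        mu_sim = frac_w[reference] @ sim_coords[labels.index(reference)]
        for pos, lab in enumerate(labels):
            sim_d[lab][rep] = _d_statistic(sim_coords[pos], mu_sim, frac_w[lab])
        for pair in pairs:
            ia, ib = labels.index(pair[0]), labels.index(pair[1])
            sim_e[pair][rep] = _e_statistic(
                sim_coords[ia], sim_coords[ib], frac_w[pair[0]], frac_w[pair[1]]
            )

    mean_sim_d = {lab: float(sim_d[lab].mean()) for lab in labels}
    delta_d = {lab: observed_d[lab] - mean_sim_d[lab] for lab in labels}
    p_e = {pair: overlap_probability(observed_e[pair], sim_e[pair]) for pair in pairs}
    return NullResult(
        plot_id=plot_id,
        comparison=config.comparison,
        weighting=config.weighting,
        n_sim=config.n_sim,
        seed=config.seed,
        observed_d=observed_d,
        mean_sim_d=mean_sim_d,
        delta_d=delta_d,
        observed_e=observed_e,
        p_e=p_e,
        use_cover_weights=config.use_cover_weights,
    )


def null_results_frame(results: list[NullResult]) -> pd.DataFrame:
    """Tidy per-plot rows: one row per fraction plus one per fraction pair."""
    rows = []
    for res in results:
        for lab in res.observed_d:
            rows.append(
                {
                    "plot_id": res.plot_id,
                    "comparison": res.comparison,
                    "kind": "fraction",
                    "target": lab,
                    "observed": res.observed_d[lab],
                    "mean_sim": res.mean_sim_d[lab],
                    "delta_d": res.delta_d[lab],
                    "p_e": np.nan,
                    "n_sim": res.n_sim,
                    "weighting": res.weighting,
                    "cover_weighted": res.use_cover_weights,
                }
            )
        for pair, e_obs in res.observed_e.items():
            rows.append(
                {
                    "plot_id": res.plot_id,
                    "comparison": res.comparison,
                    "kind": "pair",
                    "target": f"{pair[0]}|{pair[1]}",
                    "observed": e_obs,
                    "mean_sim": np.nan,
                    "delta_d": np.nan,
                    "p_e": res.p_e[pair],
                    "n_sim": res.n_sim,
                    "weighting": res.weighting,
                    "cover_weighted": res.use_cover_weights,
                }
            )
    return pd.DataFrame(rows)
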