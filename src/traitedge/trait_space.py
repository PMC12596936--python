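"""Trait table handling: transformation, standardization, Gower/Podani
dissimilarity and principal coordinate analysis.

All downstream distance statistics operate on the coordinate system produced
here: traits are log10-transformed where flagged, then z-scored once over a
global scaling population so that plot-level centroids remain comparable
across plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Canonical trait columns with (log10-transform flag, ordinal flag).
#: Every trait except the flowering midpoint is log10-transformed; the
#: flowering midpoint (month, 1-12) is treated as ordinal for Gower/Podani.
TRAIT_META: dict[str, tuple[bool, bool]] = {
    "height": (True, False),
    "seed_mass": (True, False),
    "leaf_area": (True, False),
    "sla": (True, False),
    "ldmc": (True, False),
    "flowering_midpoint": (False, True),
    "flowering_length": (True, False),
    "genome_size": (True, False),
}

TRAIT_NAMES: tuple[str, ...] = tuple(TRAIT_META)


@dataclass(frozen=True)
class TraitTable:
    """Species-by-trait table of raw values with per-trait metadata.

    Parameters
    ----------
    data:
        Frame indexed by species id; one column per trait.
    log_flags, ordinal_flags:
        Per-trait metadata; default to :data:`TRAIT_META` for the canonical
        trait names.
    """

    data: pd.DataFrame
    log_flags: dict[str, bool] = field(default_factory=dict)
    ordinal_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.empty:
            raise ValueError("trait table is empty")
        if not self.log_flags:
            object.__setattr__(
                self,
                "log_flags",
                {t: TRAIT_META.get(t, (False, False))[0] for t in self.data.columns},
            )
        if not self.ordinal_flags:
            object.__setattr__(
                self,
                "ordinal_flags",
                {t: TRAIT_META.get(t, (False, False))[1] for t in self.data.columns},
            )
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(
                f"missing trait values in columns {bad}; impute traits externally "
                "before analysis (imputation is out of scope)"
            )
        for trait, flag in self.log_flags.items():
            if flag and (self.data[trait] <= 0).any():
                raise ValueError(f"log-transformed trait {trait!r} must be strictly positive")

    @property
    def species(self) -> pd.Index:
        return self.data.index

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def transformed(self) -> pd.DataFrame:
        """Raw values with log10 applied to log-flagged traits (no scaling)."""
        out = self.data.astype(float).copy()
        for trait, flag in self.log_flags.items():
            if flag:
                out[trait] = np.log10(out[trait])
        return out


@dataclass(frozen=True)
class ScalingRecord:
    """Per-trait mean and sample SD (ddof=1) used for z-scoring."""

    mean: pd.Series
    sd: pd.Series
    population_size: int


@dataclass(frozen=True)
class StandardizedTraits:
    """Species coordinates in the standardized trait space."""

    coords: pd.DataFrame
    scaling: ScalingRecord

    @property
    def species(self) -> pd.Index:
        return self.coords.index

    def matrix(self, species: list | pd.Index | None = None) -> np.ndarray:
        """Coordinate matrix (n_species x n_traits) for the given species."""
        if species is None:
            return self.coords.to_numpy(float)
        missing = [s for s in species if s not in self.coords.index]
        if missing:
            raise KeyError(f"species without standardized traits: {missing[:5]}")
        return self.coords.loc[list(species)].to_numpy(float)


def standardize(raw: TraitTable, scaling_population=None) -> StandardizedTraits:
    """Log10-transform flagged traits, then z-score over ``scaling_population``.

    The scaling population defaults to all species in ``raw``; its per-trait
    mean and sample SD are retained so plot-level computations reuse one
    global scaling.
    """
    transformed = raw.transformed()
    if scaling_population is None:
        pop = transformed
    else:
        scaling_population = list(scaling_population)
        if not scaling_population:
            raise ValueError("empty scaling population")
        missing = [s for s in scaling_population if s not in transformed.index]
        if missing:
            raise KeyError(f"scaling population species missing from traits: {missing[:5]}")
        pop = transformed.loc[scaling_population]
    mean = pop.mean()
    sd = pop.std(ddof=1)
    if (sd <= 0).any() or sd.isna().any():
        bad = sd.index[(sd <= 0) | sd.isna()].tolist()
        raise ValueError(f"zero or undefined SD for traits {bad}; cannot z-score")
    coords = (transformed - mean) / sd
    return StandardizedTraits(
        coords=coords, scaling=ScalingRecord(mean=mean, sd=sd, population_size=len(pop))
    )


@dataclass(frozen=True)
class DissimilarityMatrix:
    species: pd.Index
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.species):
            raise ValueError("dissimilarity matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValueError("dissimilarity matrix must be nonnegative")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix diagonal must be zero")


def _podani_ordinal_dissimilarity(values: np.ndarray) -> np.ndarray:
    """Podani (1999) tie-corrected rank dissimilarity for an ordinal trait.

    d_ij = (|r_i - r_j| - (T_i - 1)/2 - (T_j - 1)/2)
           / (r_max - r_min - (T_max - 1)/2 - (T_min - 1)/2)

    where r are average ranks and T_i is the number of objects tied with
    object i (itself included). Fully tied columns yield all-zero
    dissimilarities.
    """
    ranks = rankdata(values, method="average")
    # tie counts per object
    _, inverse, counts = np.unique(values, return_inverse=True, return_counts=True)
    ties = counts[inverse].astype(float)
    r_min, r_max = ranks.min(), ranks.max()
    t_min = ties[np.argmin(ranks)]
    t_max = ties[np.argmax(ranks)]
    denom = (r_max - r_min) - (t_max - 1) / 2.0 - (t_min - 1) / 2.0
    if denom <= 0:  # constant column
        return np.zeros((len(values), len(values)))
    num = np.abs(ranks[:, None] - ranks[None, :]) - (ties[:, None] - 1) / 2.0 - (ties[None, :] - 1) / 2.0
    d = np.maximum(num, 0.0) / denom
    np.fill_diagonal(d, 0.0)
    return d


def gower_podani(raw: TraitTable, apply_log: bool = True) -> DissimilarityMatrix:
    """Gower dissimilarity with the Podani extension for ordinal traits.

    Quantitative traits contribute range-normalized absolute differences;
    the ordinal flowering midpoint contributes the tie-corrected rank
    dissimilarity. Per-trait values lie in [0, 1] and are averaged with
    equal weights. Constant traits contribute 0 (with a logged warning).

    When ``apply_log`` is true, log-flagged traits enter on the log10 scale,
    matching the transformation used for the Euclidean coordinates.
    """
    table = raw.transformed() if apply_log else raw.data.astype(float)
    n = len(table)
    total = np.zeros((n, n))
    for trait in table.columns:
        col = table[trait].to_numpy(float)
        if raw.ordinal_flags.get(trait, False):
            d = _podani_ordinal_dissimilarity(col)
        else:
            rng_ = col.max() - col.min()
            if rng_ <= 0:
                logger.warning("constant trait %r contributes 0 to Gower dissimilarity", trait)
                d = np.zeros((n, n))
            else:
                d = np.abs(col[:, None] - col[None, :]) / rng_
        total += d
    total /= len(table.columns)
    np.fill_diagonal(total, 0.0)
    return DissimilarityMatrix(species=table.index, values=total)


def pcoa(d: DissimilarityMatrix, eig_rtol: float = 1e-10) -> StandardizedTraits:
    """Principal coordinate analysis of a dissimilarity matrix.

    Eigendecomposition of the double-centered matrix of squared
    dissimilarities; axes with eigenvalue <= ``eig_rtol`` times the largest
    eigenvalue are dropped (no Cailliez/Lingoes correction). For
    Euclidean-embeddable input the retained axes reproduce the pairwise
    distances exactly.
    """
    n = len(d.species)
    if n == 1:
        coords = pd.DataFrame(np.zeros((1, 1)), index=d.species, columns=["pcoa_1"])
        return StandardizedTraits(
            coords=coords,
            scaling=ScalingRecord(
                mean=pd.Series(0.0, index=["pcoa_1"]),
                sd=pd.Series(1.0, index=["pcoa_1"]),
                population_size=1,
            ),
        )
    a = -0.5 * d.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[0] <= 0:
        raise ValueError("no positive eigenvalue: dissimilarities carry no structure")
    keep = eigval > eig_rtol * eigval[0]
    if not keep.any():
        raise ValueError("all eigenvalues below tolerance")
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    frame = pd.DataFrame(
        coords, index=d.species, columns=[f"pcoa_{i + 1}" for i in range(coords.shape[1])]
    )
    return StandardizedTraits(
        coords=frame,
        scaling=ScalingRecord(
            mean=pd.Series(0.0, index=frame.columns),
            sd=pd.Series(1.0, index=frame.columns),
            population_size=n,
        ),
    )


def read_trait_table(path, sep: str | None = None) -> TraitTable:
    """Read a traits TSV/CSV with a ``species`` column plus trait columns."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep)
    if "species" not in frame.columns:
        raise ValueError("trait table must contain a 'species' column")
    frame = frame.set_index("species")
    return TraitTable(data=frame)


def write_standardized(std: StandardizedTraits, path) -> None:
    """Write standardized coordinates as TSV with the scaling record header."""
    with open(path, "w") as fh:
        means = ",".join(f"{t}={m:.10g}" for t, m in std.scaling.mean.items())
        sds = ",".join(f"{t}={s:.10g}" for t, s in std.scaling.sd.items())
        fh.write(f"# scaling_population_n={std.scaling.population_size}\n")
        fh.write(f"# mean: {means}\n")
        fh.write(f"# sd: {sds}\n")
        std.coords.to_csv(fh, sep="\t", index_label="species")
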