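"""Core per-plot statistics: mean distance from the native centroid (D)
and the two-sample energy distance (E), unweighted and cover-weighted.

The weighted forms use square-root-transformed percentage covers as weights,
normalized within each fraction; with equal covers they reduce exactly to the
unweighted forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

FRACTION_LABELS = ("native", "naturalized", "invasive")


@dataclass(frozen=True)
class Fraction:
    """One community fraction of a plot: species points in trait space.

    ``covers`` are percentage covers in (0, 100]; the statistical weights are
    their square roots.
    """

    label: str
    species: tuple = ()
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    covers: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, float))
        object.__setattr__(self, "coords", coords)
        if coords.shape[0] == 0:
            raise ValueError(f"fraction {self.label!r} is empty")
        if self.covers is not None:
            covers = np.asarray(self.covers, float)
            if covers.shape != (coords.shape[0],):
                raise ValueError("covers not aligned with members")
            if (covers <= 0).any():
                raise ValueError("covers must be strictly positive")
            object.__setattr__(self, "covers", covers)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def weights(self, use_weights: bool) -> np.ndarray:
        """Normalized sqrt-cover weights (uniform when unweighted)."""
        if not use_weights:
            return np.full(self.n, 1.0 / self.n)
        if self.covers is None:
            raise ValueError(f"fraction {self.label!r} has no covers for weighting")
        w = np.sqrt(self.covers)
        return w / w.sum()


def native_centroid(native: Fraction, use_weights: bool = False) -> np.ndarray:
    """Mean vector of the native fraction (sqrt-cover-weighted when asked)."""
    w = native.weights(use_weights)
    return w @ native.coords


def mean_distance_from_center(
    fraction: Fraction, center: np.ndarray, use_weights: bool = False
) -> float:
    """D: (weighted) mean Euclidean distance of members from ``center``."""
    center = np.asarray(center, float)
    if center.shape != (fraction.coords.shape[1],):
        raise ValueError("center dimensionality does not match fraction")
    dists = np.linalg.norm(fraction.coords - center, axis=1)
    return float(fraction.weights(use_weights) @ dists)


def e_distance(x: Fraction, y: Fraction, use_weights: bool = False) -> float:
    """Two-sample energy distance between fractions X and Y.

    E = 2 * mean ||x_i - y_j|| - mean ||x_i - x_j|| - mean ||y_i - y_j||,
    with the self-term diagonals zero. Weighted averages replace uniform
    means when ``use_weights``; E >= 0 and symmetric in its arguments.
    """
    if x.coords.shape[1] != y.coords.shape[1]:
        raise ValueError("fractions have different dimensionality")
    wx = x.weights(use_weights)
    wy = y.weights(use_weights)
    dxy = cdist(x.coords, y.coords)
    dxx = cdist(x.coords, x.coords)
    dyy = cdist(y.coords, y.coords)
    e = 2.0 * (wx @ dxy @ wy) - (wx @ dxx @ wx) - (wy @ dyy @ wy)
    # clamp tiny negative round-off; the statistic is nonnegative
    return float(max(e, 0.0))


@dataclass(frozen=True)
class FractionMetrics:
    """Per-plot D and E statistics for every fraction / fraction pair."""

    plot_id: str
    centroid: np.ndarray
    n: dict[str, int]
    d: dict[str, float]
    d_weighted: dict[str, float]
    e: dict[tuple[str, str], float]
    e_weighted: dict[tuple[str, str], float]


def plot_metrics(plot_id: str, fractions: dict[str, Fraction]) -> FractionMetrics:
    """Compute D for every fraction (from the native centroid) and E for
    every unordered fraction pair, in unweighted and cover-weighted forms.
    """
    if "native" not in fractions:
        raise ValueError(f"plot {plot_id!r} has no native fraction")
    mu = native_centroid(fractions["native"], use_weights=False)
    mu_w = native_centroid(fractions["native"], use_weights=True)
    labels = [lab for lab in FRACTION_LABELS if lab in fractions]
    n = {lab: fractions[lab].n for lab in labels}
    d = {lab: mean_distance_from_center(fractions[lab], mu) for lab in labels}
    d_w = {
        lab: mean_distance_from_center(fractions[lab], mu_w, use_weights=True) for lab in labels
    }
    e: dict[tuple[str, str], float] = {}
    e_w: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            e[(a, b)] = e_distance(fractions[a], fractions[b])
            e_w[(a, b)] = e_distance(fractions[a], fractions[b], use_weights=True)
    return FractionMetrics(
        plot_id=plot_id, centroid=mu, n=n, d=d, d_weighted=d_w, e=e, e_weighted=e_w
    )
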