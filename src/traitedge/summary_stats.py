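"""Habitat-level inference: paired Wilcoxon signed-rank tests on delta-D,
Benjamini-Hochberg adjustment across the whole test family, and effect sizes
r = z / sqrt(N) with the small/medium/large classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class WilcoxonResult:
    z: float
    p: float
    r: float
    n: int  # pairs retained after dropping zero differences


def wilcoxon_paired(x, y) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test with normal approximation.

    Zero differences are dropped before ranking (Wilcoxon's convention) and
    ``n`` counts the retained pairs. The variance is tie-corrected and no
    continuity correction is applied, so z is exactly recoverable and
    r = z / sqrt(n). Positive z means x tends to exceed y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    diff = diff[diff != 0]
    n = diff.size
    if n < 2:
        raise ValueError("fewer than 2 nonzero differences; test undefined")
    if n < 6:
        raise ValueError("normal approximation requires >= 6 nonzero differences")
    if n < 20:
        warnings.warn(
            f"only {n} informative pairs; normal approximation is rough", stacklevel=2
        )
    ranks = rankdata(np.abs(diff))
    w_plus = ranks[diff > 0].sum()
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the no-tie variance
    _, counts = np.unique(np.abs(diff), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    if sigma2 <= 0:
        raise ValueError("degenerate variance (all differences tied to one magnitude?)")
    z = (w_plus - mu) / np.sqrt(sigma2)
    p = 2.0 * norm.sf(abs(z))
    return WilcoxonResult(z=float(z), p=float(min(p, 1.0)), r=float(z / np.sqrt(n)), n=n)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_effect(r: float) -> str:
    """Classify |r|: small < 0.3 <= medium < 0.5 <= large."""
    if not np.isfinite(r):
        raise ValueError("effect size must be finite")
    r = abs(r)
    if r < 0.3:
        return "small"
    if r < 0.5:
        return "medium"
    return "large"


def summarize_habitats(delta_d: pd.DataFrame) -> pd.DataFrame:
    """Paired habitat-level comparisons of delta-D between fractions.

    ``delta_d`` needs columns ``plot_id``, ``habitat``, ``comparison``,
    ``target`` (fraction label) and ``delta_d``; rows come from the
    null-model stage. For every habitat the three fraction contrasts are
    tested on plots where both fractions are present; the difference is
    second fraction minus first (positive z: second fraction farther from
    the center). BH adjustment treats all tests of one call as one family.
    """
    contrasts = [
        ("native", "naturalized", "vs_native"),
        ("native", "invasive", "vs_native"),
        ("naturalized", "invasive", "naturalized_vs_invasive"),
    ]
    rows = []
    for habitat, hab_df in delta_d.groupby("habitat", sort=True):
        for first, second, comparison in contrasts:
            sub = hab_df[hab_df["comparison"] == comparison]
            wide = sub.pivot_table(
                index="plot_id", columns="target", values="delta_d", aggfunc="first"
            )
            if first not in wide.columns or second not in wide.columns:
                continue
            paired = wide[[first, second]].dropna()
            if len(paired) < 6:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = wilcoxon_paired(paired[second], paired[first])
                except ValueError:
                    continue
            rows.append(
                {
                    "habitat": habitat,
                    "comparison": f"{first}_vs_{second}",
                    "n": res.n,
                    "z": res.z,
                    "p": res.p,
                    "r": res.r,
                    "direction": int(np.sign(res.z)),
                    "effect_class": classify_effect(res.r),
                }
            )
    summary = pd.DataFrame(
        rows,
        columns=["habitat", "comparison", "n", "z", "p", "r", "direction", "effect_class"],
    )
    if len(summary):
        summary["p_adj"] = bh_adjust(summary["p"].to_numpy())
    else:
        summary["p_adj"] = pd.Series(dtype=float)
    return summary[
        ["habitat", "comparison", "n", "z", "p", "p_adj", "r", "direction", "effect_class"]
    ]
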