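import itertools

import numpy as np
import pandas as pd
import pytest

from traitedge.null_models import (
    FractionComposition,
    NullConfig,
    SpeciesPool,
    StratumExhaustedError,
    beals_index,
    draw_fraction,
    overlap_probability,
    plot_rng,
    simulate_plot,
)


def beals_oracle(x: np.ndarray) -> np.ndarray:
    """Nested-loop evaluation of the Beals formula."""
    n_plots, n_species = x.shape
    m = np.zeros((n_species, n_species))
    for j in range(n_species):
        for k in range(n_species):
            m[j, k] = np.sum(x[:, j] * x[:, k])
    n = x.sum(axis=0)
    b = np.zeros_like(x, dtype=float)
    for i in range(n_plots):
        for j in range(n_species):
            s = x[i].sum() - x[i, j]
            if s == 0:
                continue
            acc = 0.0
            for k in range(n_species):
                if k != j and x[i, k]:
                    acc += m[j, k] / n[k]
            b[i, j] = acc / s
    return b


class TestBeals:
    def test_perfect_cooccurrence_gives_one(self):
        # species 0 occurs in every plot, so M_jk / N_k = 1 for every k
        x = pd.DataFrame(
            [[1, 1, 1], [1, 1, 0], [1, 0, 1]],
            index=["p1", "p2", "p3"],
            columns=["sp0", "sp1", "sp2"],
        )
        b = beals_index(x)
        assert b.loc["p2", "sp0"] == pytest.approx(1.0)

    def test_never_cooccurring_gives_zero(self):
        x = pd.DataFrame(
            [[1, 1, 0], [0, 0, 1], [1, 1, 0], [0, 0, 1]],
            index=["p1", "p2", "p3", "p4"],
            columns=["sp0", "sp1", "sp2"],
        )
        b = beals_index(x)
        assert b.loc["p1", "sp2"] == pytest.approx(0.0)

    def test_matches_nested_loop_oracle(self, rng):
        x = (rng.uniform(size=(6, 5)) < 0.6).astype(int)
        x[:, x.sum(axis=0) == 0] = 1  # every species occurs somewhere
        x[x.sum(axis=1) == 0, 0] = 1
        frame = pd.DataFrame(x, columns=[f"sp{j}" for j in range(5)])
        np.testing.assert_allclose(beals_index(frame).to_numpy(), beals_oracle(x), atol=1e-12)

    def test_values_in_unit_interval(self, rng):
        x = (rng.uniform(size=(12, 8)) < 0.5).astype(int)
        x[:, x.sum(axis=0) == 0] = 1
        x[x.sum(axis=1) == 0, 0] = 1
        b = beals_index(pd.DataFrame(x)).to_numpy()
        assert (b >= 0).all() and (b <= 1 + 1e-12).all()

    def test_zero_occurrence_species_rejected(self):
        x = pd.DataFrame([[1, 0], [1, 0]], columns=["sp0", "sp1"])
        with pytest.raises(ValueError, match="zero occurrences"):
            beals_index(x)


def make_pool(n_per_stratum=10, statuses=("native",), life_forms=("herb", "chamaephyte")):
    rows = []
    for status in statuses:
        for lf in life_forms:
            for i in range(n_per_stratum):
                rows.append(
                    {
                        "species": f"{status[:4]}_{lf[:4]}_{i}",
                        "status": status,
                        "life_form": lf,
                        "frequency": i + 1,
                    }
                )
    table = pd.DataFrame(rows).set_index("species")
    return SpeciesPool(habitat="h", table=table)


def observed(label="naturalized", life_forms=("herb", "herb", "herb", "chamaephyte")):
    n = len(life_forms)
    return FractionComposition(
        label=label,
        species=tuple(f"obs_{i}" for i in range(n)),
        life_forms=tuple(life_forms),
        covers=np.linspace(5, 50, n),
    )


class TestDrawFraction:
    def test_life_form_counts_preserved(self, rng):
        pool = make_pool()
        obs = observed()
        for _ in range(50):
            sim = draw_fraction(obs, pool, rng=rng)
            assert sorted(sim.life_forms) == sorted(obs.life_forms)
            assert sim.n == obs.n
            np.testing.assert_array_equal(np.sort(sim.covers), np.sort(obs.covers))

    def test_forced_draw_when_stratum_equals_requirement(self, rng):
        pool = make_pool(n_per_stratum=3)
        obs = observed(life_forms=("herb", "herb", "herb"))
        sim = draw_fraction(obs, pool, rng=rng)
        assert set(sim.species) == set(pool.subset("native").query("life_form=='herb'").index)

    def test_stratum_exhaustion_raises(self, rng):
        pool = make_pool(n_per_stratum=2)
        obs = observed(life_forms=("herb",) * 5)
        with pytest.raises(StratumExhaustedError):
            draw_fraction(obs, pool, rng=rng)

    def test_covers_inherited_in_order(self, rng):
        pool = make_pool()
        obs = observed()
        sim = draw_fraction(obs, pool, rng=rng)
        np.testing.assert_array_equal(sim.covers, obs.covers)

    def test_taken_species_excluded(self, rng):
        pool = make_pool(n_per_stratum=4)
        obs = observed(life_forms=("herb", "herb"))
        taken: set = set()
        sim1 = draw_fraction(obs, pool, rng=rng, taken=taken)
        sim2 = draw_fraction(obs, pool, rng=rng, taken=taken)
        assert not set(sim1.species) & set(sim2.species)

    def test_frequency_weighting_matches_enumerated_inclusion(self, rng):
        """MC inclusion frequencies vs exact sequential-draw enumeration on a
        5-species stratum, drawing 2 without replacement."""
        weights = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        rows = [
            {"species": f"sp{i}", "status": "native", "life_form": "herb", "frequency": w}
            for i, w in enumerate(weights)
        ]
        pool = SpeciesPool(habitat="h", table=pd.DataFrame(rows).set_index("species"))
        obs = observed(life_forms=("herb", "herb"))

        # exact inclusion probabilities by enumerating ordered draws
        inclusion = np.zeros(5)
        total = weights.sum()
        for i, j in itertools.permutations(range(5), 2):
            p = (weights[i] / total) * (weights[j] / (total - weights[i]))
            inclusion[i] += p
            inclusion[j] += p

        n_draws = 10_000
        counts = np.zeros(5)
        for _ in range(n_draws):
            sim = draw_fraction(obs, pool, weighting="frequency", rng=rng)
            for sp in sim.species:
                counts[int(sp[2:])] += 1
        freq = counts / n_draws
        se = np.sqrt(inclusion * (1 - inclusion) / n_draws)
        assert (np.abs(freq - inclusion) <= 3 * se + 1e-9).all()

    def test_beals_weighting_requires_row(self, rng):
        pool = make_pool()
        with pytest.raises(ValueError, match="beals_row"):
            draw_fraction(observed(), pool, weighting="beals", rng=rng)

    def test_beals_zero_probabilities_floored(self, rng):
        pool = make_pool()
        row = pd.Series(0.0, index=pool.table.index)  # all zero -> floor applies
        sim = draw_fraction(observed(), pool, weighting="beals", beals_row=row, rng=rng)
        assert sim.n == 4


class TestOverlapProbability:
    def test_observed_exceeds_all(self):
        sims = np.linspace(0, 1, 999)
        assert overlap_probability(2.0, sims) == pytest.approx(1 / 1000)

    def test_exactly_49_of_999_greater_equal(self):
        sims = np.concatenate([np.full(950, 1.0), np.full(49, 3.0)])
        assert overlap_probability(2.0, sims) == pytest.approx(0.05)

    def test_observed_below_all(self):
        sims = np.linspace(1, 2, 999)
        assert overlap_probability(0.5, sims) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_probability(1.0, np.array([]))


def _plot_setup(rng, n_pool=30):
    rows = []
    for status in ("native", "naturalized"):
        for lf in ("herb", "chamaephyte"):
            for i in range(n_pool):
                rows.append(
                    {
                        "species": f"{status[:4]}_{lf[:4]}_{i}",
                        "status": status,
                        "life_form": lf,
                        "frequency": rng.integers(1, 20),
                    }
                )
    table = pd.DataFrame(rows).set_index("species")
    pool = SpeciesPool(habitat="h", table=table)
    coords = pd.DataFrame(
        rng.normal(size=(len(table), 3)), index=table.index, columns=list("abc")
    )
    native = FractionComposition(
        "native",
        tuple(f"nati_herb_{i}" for i in range(5)),
        ("herb",) * 5,
        np.full(5, 10.0),
    )
    natz = FractionComposition(
        "naturalized",
        ("natu_herb_0", "natu_cham_0"),
        ("herb", "chamaephyte"),
        np.array([20.0, 5.0]),
    )
    return pool, coords, {"native": native, "naturalized": natz}


class TestSimulatePlot:
    def test_delta_d_definition_and_determinism(self, rng):
        pool, coords, fractions = _plot_setup(rng)
        config = NullConfig(n_sim=37, weighting="uniform", seed=5, comparison="vs_native")
        res1 = simulate_plot("p1", fractions, pool, coords, config)
        res2 = simulate_plot("p1", fractions, pool, coords, config)
        assert res1.delta_d == res2.delta_d
        assert res1.p_e == res2.p_e
        for lab in res1.delta_d:
            assert res1.delta_d[lab] == pytest.approx(
                res1.observed_d[lab] - res1.mean_sim_d[lab]
            )
        assert ("native", "naturalized") in res1.p_e
        assert 0 < res1.p_e[("native", "naturalized")] <= 1

    def test_different_seeds_differ(self, rng):
        pool, coords, fractions = _plot_setup(rng)
        a = simulate_plot(
            "p1", fractions, pool, coords, NullConfig(n_sim=19, weighting="uniform", seed=1)
        )
        b = simulate_plot(
            "p1", fractions, pool, coords, NullConfig(n_sim=19, weighting="uniform", seed=2)
        )
        assert a.mean_sim_d != b.mean_sim_d

    def test_requires_fractions_for_comparison(self, rng):
        pool, coords, fractions = _plot_setup(rng)
        config = NullConfig(n_sim=5, comparison="naturalized_vs_invasive", weighting="uniform")
        with pytest.raises(ValueError, match="requires both"):
            simulate_plot("p1", fractions, pool, coords, config)

    def test_plot_rng_is_order_independent(self):
        a = plot_rng(7, "plot_1", "vs_native").integers(0, 10**9)
        _ = plot_rng(7, "plot_2", "vs_native").integers(0, 10**9)
        a_again = plot_rng(7, "plot_1", "vs_native").integers(0, 10**9)
        assert a == a_again

    def test_mean_sim_d_se_shrinks_with_n_sim(self, rng):
        """SE of the mean simulated D shrinks roughly as 1/sqrt(n_sim)."""
        pool, coords, fractions = _plot_setup(rng)

        def spread(n_sim):
            means = [
                simulate_plot(
                    "p1",
                    fractions,
                    pool,
                    coords,
                    NullConfig(n_sim=n_sim, weighting="uniform", seed=seed),
                ).mean_sim_d["naturalized"]
                for seed in range(30)
            ]
            return np.std(means)

        s_small, s_large = spread(10), spread(160)
        assert s_large < s_small / 2.0  # expect ~1/4

    def test_weighted_version_runs(self, rng):
        pool, coords, fractions = _plot_setup(rng)
        config = NullConfig(n_sim=9, weighting="uniform", use_cover_weights=True)
        res = simulate_plot("p1", fractions, pool, coords, config)
        assert all(np.isfinite(v) for v in res.delta_d.values())


class TestNullConfigValidation:
    def test_bad_n_sim(self):
        with pytest.raises(ValueError):
            NullConfig(n_sim=0)

    def test_bad_weighting(self):
        with pytest.raises(ValueError):
            NullConfig(weighting="magic")

    def test_bad_comparison(self):
        with pytest.raises(ValueError):
            NullConfig(comparison="nope")
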