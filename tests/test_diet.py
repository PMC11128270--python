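import numpy as np
import pandas as pd
import pytest

from divekit.diet import (foo_across_years, foo_table, numerical_abundance,
                          prey_length_summary)
from divekit.simulate import (PreySpecies, SimulationConfig,
                              simulate_diet_samples)


def toy_samples():
    """Five samples, one unidentifiable; hand-checkable by eye."""
    rows = [
        # sample s1 (M): 2 gobies, 1 wrasse
        ("s1", "M", 2021, "goby", 2, 7.0, True),
        ("s1", "M", 2021, "wrasse", 1, np.nan, True),
        # sample s2 (M): 1 goby
        ("s2", "M", 2021, "goby", 1, 8.0, True),
        # sample s3 (F): 3 wrasse
        ("s3", "F", 2021, "wrasse", 3, 9.0, True),
        # sample s4 (F): unidentifiable
        ("s4", "F", 2021, np.nan, 0, np.nan, False),
        # sample s5 (F): 1 goby, 1 flathead
        ("s5", "F", 2021, "goby", 1, np.nan, True),
        ("s5", "F", 2021, "flathead", 1, 14.0, True),
    ]
    return pd.DataFrame([{"sample_id": s, "individual_id": s.replace("s", "i"),
                          "sex": sex, "year": y, "species": sp, "count": c,
                          "length_cm": ln, "identifiable": ident}
                         for s, sex, y, sp, c, ln, ident in rows])


class TestFoo:
    def test_hand_computed(self):
        foo = foo_table(toy_samples(), group_by=())
        # 4 identifiable samples; goby in 3, wrasse in 2, flathead in 1
        by = foo.set_index("species")["foo"]
        assert by["goby"] == pytest.approx(3 / 4)
        assert by["wrasse"] == pytest.approx(2 / 4)
        assert by["flathead"] == pytest.approx(1 / 4)
        assert (foo["n_samples"] == 4).all()

    def test_grouped_by_sex(self):
        foo = foo_table(toy_samples(), group_by=("sex",))
        m = foo[(foo["sex"] == "M") & (foo["species"] == "goby")]
        f = foo[(foo["sex"] == "F") & (foo["species"] == "goby")]
        assert m["foo"].iloc[0] == pytest.approx(1.0)   # both M samples
        assert f["foo"].iloc[0] == pytest.approx(1 / 2)  # 1 of 2 identifiable F

    def test_absent_species_zero(self):
        df = toy_samples()
        df.loc[len(df)] = {"sample_id": "s6", "individual_id": "i6",
                           "sex": "M", "year": 2022, "species": "redbait",
                           "count": 1, "length_cm": np.nan, "identifiable": True}
        foo = foo_table(df, group_by=())
        by = foo.set_index("species")["foo"]
        assert by["redbait"] == pytest.approx(1 / 5)

    def test_duplicate_item_invariant(self):
        df = toy_samples()
        dup = df.iloc[[0]].copy()
        df2 = pd.concat([df, dup], ignore_index=True)
        foo1 = foo_table(df, group_by=())
        foo2 = foo_table(df2, group_by=())
        pd.testing.assert_frame_equal(foo1, foo2)

    def test_foo_times_n_is_integer(self):
        foo = foo_table(toy_samples(), group_by=("sex",))
        prod = foo["foo"] * foo["n_samples"]
        assert np.allclose(prod, np.round(prod))

    def test_across_years_mean_se(self):
        df = toy_samples()
        df2 = df.copy()
        df2["year"] = 2022
        df2["sample_id"] = df2["sample_id"] + "b"
        both = pd.concat([df, df2], ignore_index=True)
        out = foo_across_years(both, group_by=())
        goby = out[out["species"] == "goby"]
        assert goby["n_years"].iloc[0] == 2
        assert goby["foo_mean"].iloc[0] == pytest.approx(3 / 4)


class TestNumericalAbundance:
    def test_hand_computed(self):
        ab = numerical_abundance(toy_samples(), group_by=())
        by = ab.set_index("species")["mean_count"]
        # goby counts per identifiable sample: 2, 1, 0, 1 -> mean 1.0
        assert by["goby"] == pytest.approx(1.0)
        assert by["wrasse"] == pytest.approx(1.0)
        assert by["flathead"] == pytest.approx(0.25)

    def test_occurrences_only_mode(self):
        ab = numerical_abundance(toy_samples(), group_by=(),
                                 occurrences_only=True)
        by = ab.set_index("species")["mean_count"]
        assert by["goby"] == pytest.approx(4 / 3)
        assert by["flathead"] == pytest.approx(1.0)

    def test_additive_over_species(self):
        ab = numerical_abundance(toy_samples(), group_by=())
        total_items = toy_samples().loc[lambda d: d["identifiable"], "count"].sum()
        assert ab["mean_count"].sum() * 4 == pytest.approx(total_items)

    def test_poisson_recovery(self):
        cfg = SimulationConfig(seed=5)
        species = (PreySpecies("only", 1.0, 1.0, mean_count=3.0),)
        samples = simulate_diet_samples(cfg, seed=5, n_samples=400,
                                        species=species,
                                        identifiable_fraction=1.0)
        ab = numerical_abundance(samples, group_by=())
        mean = ab["mean_count"].iloc[0]
        se = np.sqrt(2.0) / np.sqrt(400)  # Var(1 + Pois(2)) = 2
        assert abs(mean - 3.0) < 2 * se + 0.05


class TestPreyLengths:
    def test_hand_computed(self):
        out = prey_length_summary(toy_samples(), group_by=())
        assert out["n_items"].iloc[0] == 4
        lengths = [7.0, 8.0, 9.0, 14.0]
        assert out["mean_length_cm"].iloc[0] == pytest.approx(np.mean(lengths))
        assert out["se_length_cm"].iloc[0] == pytest.approx(
            np.std(lengths, ddof=1) / 2.0)

    def test_simple_se(self):
        df = pd.DataFrame({
            "sample_id": ["a", "b", "c"], "individual_id": ["a", "b", "c"],
            "sex": ["M"] * 3, "year": [2021] * 3,
            "species": ["goby"] * 3, "count": [1] * 3,
            "length_cm": [10.0, 12.0, 14.0], "identifiable": [True] * 3})
        out = prey_length_summary(df, group_by=())
        assert out["mean_length_cm"].iloc[0] == pytest.approx(12.0)
        assert out["se_length_cm"].iloc[0] == pytest.approx(2 / np.sqrt(3))

    def test_single_item_flagged(self):
        df = toy_samples().iloc[[0]]
        out = prey_length_summary(df, group_by=())
        assert not out["se_defined"].iloc[0]
        assert np.isnan(out["se_length_cm"].iloc[0])

    def test_sex_difference_recovered(self):
        cfg = SimulationConfig(seed=9)
        samples = simulate_diet_samples(cfg, seed=9, n_samples=300,
                                        identifiable_fraction=1.0,
                                        male_length_bonus_cm=2.8)
        out = prey_length_summary(samples, group_by=("sex",))
        m = out[out["sex"] == "M"]["mean_length_cm"].iloc[0]
        f = out[out["sex"] == "F"]["mean_length_cm"].iloc[0]
        assert m > f


class TestSimulatedDiet:
    def test_zero_probability_never_occurs(self):
        cfg = SimulationConfig(seed=3)
        species = (PreySpecies("common", 0.9, 0.9),
                   PreySpecies("never", 0.0, 0.0))
        samples = simulate_diet_samples(cfg, seed=3, n_samples=200,
                                        species=species)
        assert (samples["species"] != "never").all()
        foo = foo_table(samples, group_by=())
        assert "never" not in set(foo["species"])

    def test_identifiable_fraction_binomial(self):
        cfg = SimulationConfig(seed=6)
        samples = simulate_diet_samples(cfg, seed=6, n_samples=790,
                                        identifiable_fraction=0.86)
        n_ident = samples.groupby("sample_id")["identifiable"].first().sum()
        # exact binomial 99% interval around 0.86 * 790
        from scipy import stats
        lo, hi = stats.binom.ppf([0.005, 0.995], 790, 0.86)
        assert lo <= n_ident <= hi

    def test_deterministic(self):
        cfg = SimulationConfig(seed=8)
        s1 = simulate_diet_samples(cfg, seed=8, n_samples=50)
        s2 = simulate_diet_samples(cfg, seed=8, n_samples=50)
        pd.testing.assert_frame_equal(s1, s2)

    def test_invalid_probability(self):
        from divekit.errors import ValidationError
        with pytest.raises(ValidationError):
            PreySpecies("bad", 1.2, 0.5)
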