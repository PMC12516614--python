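import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lifegain as lg
from lifegain.lifetable import build_life_table, e50, life_gain, life_table_arrays, partition_rates
from conftest import make_prevalence


def hr_frame(hrs, cause="all", se=0.05):
    return pd.DataFrame(
        [
            {"group": g, "cause": cause, "beta": np.log(h), "hr": h,
             "se": 0.0 if g == "none" else se}
            for g, h in zip(lg.GROUP_LABELS, hrs)
        ]
    )


def random_inputs(seed):
    """Random (rates, HRs, prevalence) triple for property checks."""
    rng = np.random.default_rng(seed)
    rt = lg.generate_rate_table(
        (rng.uniform(0.002, 0.01), rng.uniform(0.0, 0.12)),
        np.array([0.31, 0.23, 0.46]),
    )
    hrs = hr_frame(rng.uniform(0.5, 2.0, 5))
    p = rng.dirichlet(np.ones(5) * 2.0, size=17)
    prev = pd.DataFrame(p, columns=list(lg.GROUP_LABELS))
    prev.insert(0, "band_lower", np.arange(20, 105, 5))
    prev["carried"] = False
    return rt, hrs, prev.set_index("band_lower")


class TestPartition:
    def test_unit_hazard_ratios_are_degenerate_partition(self, gompertz_rates, uniform_prevalence):
        sch = partition_rates(gompertz_rates, hr_frame([1.0] * 5), uniform_prevalence)
        m_all, _, _ = gompertz_rates.arrays(50, 100)
        for g in lg.GROUP_LABELS:
            assert np.allclose(sch[g]["m"], m_all, rtol=1e-14)

    def test_two_group_hand_arithmetic(self):
        # p = (0.5, 0.5) on none/moderate, HR = (1, 3), m_total = 0.02
        rt = lg.generate_rate_table((0.02, 0.0), (0.31, 0.23, 0.46))
        prev = make_prevalence((0.5, 0.0, 0.5, 0.0, 0.0))
        sch = partition_rates(rt, hr_frame([1, 1, 3, 1, 1]), prev)
        assert np.allclose(sch["none"]["m"], 0.01)
        assert np.allclose(sch["moderate"]["m"], 0.03)
        assert np.allclose(0.5 * sch["none"]["m"] + 0.5 * sch["moderate"]["m"], 0.02)

    def test_concentrated_prevalence_recovers_total(self, gompertz_rates):
        prev = make_prevalence((0.0, 0.0, 1.0, 0.0, 0.0))
        sch = partition_rates(gompertz_rates, hr_frame([1, 1, 0.8, 1, 1]), prev)
        m_all, _, _ = gompertz_rates.arrays(50, 100)
        assert np.allclose(sch["moderate"]["m"], m_all, rtol=1e-14)

    @given(st.integers(0, 2**31 - 1))
    def test_partition_identity_property(self, seed):
        rt, hrs, prev = random_inputs(seed)
        sch = partition_rates(rt, hrs, prev)
        m_all, _, _ = rt.arrays(50, 100)
        ages = np.arange(50, 101)
        P = lg.lifetable.expand_prevalence(prev, ages)
        total = sum(
            P[:, gi] * sch[g]["m"].to_numpy() for gi, g in enumerate(lg.GROUP_LABELS)
        )
        assert np.allclose(total, m_all, rtol=1e-12, atol=0)

    def test_cause_hazards_sum_to_total(self, gompertz_rates, reference_hazards, uniform_prevalence):
        sch = partition_rates(gompertz_rates, reference_hazards, uniform_prevalence)
        for g, s in sch.items():
            tot = s["m_cvd"] + s["m_cancer"] + s["m_other"]
            assert np.allclose(tot, s["m"], atol=1e-15)

    def test_zero_denominator_rejected(self, gompertz_rates, uniform_prevalence):
        bad = hr_frame([1.0] * 5)
        bad.loc[bad["group"] != "none", "hr"] = np.nan
        with pytest.raises(ValueError):
            partition_rates(gompertz_rates, bad, uniform_prevalence)


class TestLifeTableConstruction:
    def test_log2_hazard_gives_half_survival(self):
        m = np.full(51, np.log(2.0))
        t = build_life_table(m)
        assert np.allclose(t["q"].iloc[:-1], 0.5)
        assert t["l"].iloc[1] == pytest.approx(50_000)

    def test_constant_hazard_matches_numerical_integration(self):
        """e50 for m = 0.02 vs an independent fine-grid integration of the
        constant-hazard survival function (with the same terminal closure)."""
        mu = 0.02
        t = build_life_table(np.full(51, mu))
        dt = 1e-4
        grid = np.arange(0.0, 50.0, dt)
        oracle = np.sum(np.exp(-mu * (grid + dt / 2))) * dt + np.exp(-50 * mu) / mu
        assert abs(e50(t) - oracle) < 0.02

    def test_certain_death_at_first_age(self):
        m = np.full(51, 0.01)
        m[0] = 1e4  # q_50 -> 1
        t = build_life_table(m)
        assert t["q"].iloc[0] == pytest.approx(1.0)
        assert e50(t) == pytest.approx(0.5, abs=1e-3)

    @given(st.integers(0, 2**31 - 1))
    def test_life_table_invariants(self, seed):
        rng = np.random.default_rng(seed)
        m = np.exp(rng.uniform(np.log(1e-4), np.log(0.3), 51))
        t = build_life_table(m)
        assert ((t["q"] >= 0) & (t["q"] <= 1)).all()
        assert (np.diff(t["l"]) <= 1e-9).all()
        assert np.allclose(t["T"], t["L"][::-1].cumsum()[::-1])
        assert np.allclose(t["e"], t["T"] / t["l"])

    def test_nonpositive_hazard_rejected(self):
        with pytest.raises(ValueError):
            build_life_table(np.zeros(51))

    def test_radix_and_ages(self):
        t = build_life_table(np.full(51, 0.01), radix=1000.0)
        assert t["l"].iloc[0] == 1000.0
        assert t["age"].iloc[0] == 50 and t["age"].iloc[-1] == 100


class TestLifeGain:
    def build_tables(self, hrs, rates, prev):
        sch = partition_rates(rates, hrs, prev)
        return {g: build_life_table(s) for g, s in sch.items()}

    def test_identical_tables_zero_gain(self, gompertz_rates, uniform_prevalence):
        tables = self.build_tables(hr_frame([1.0] * 5), gompertz_rates, uniform_prevalence)
        gains = life_gain(tables)
        assert (gains["gain_years"] == 0).all()

    def test_missing_reference_rejected(self, gompertz_rates, uniform_prevalence):
        tables = self.build_tables(hr_frame([1.0] * 5), gompertz_rates, uniform_prevalence)
        del tables["none"]
        with pytest.raises(ValueError):
            life_gain(tables)

    def test_gain_is_e50_difference(self, gompertz_rates, reference_hazards, uniform_prevalence):
        tables = self.build_tables(reference_hazards, gompertz_rates, uniform_prevalence)
        gains = life_gain(tables).set_index("group")
        ref = e50(tables["none"])
        for g in lg.GROUP_LABELS:
            assert gains.loc[g, "gain_years"] == pytest.approx(e50(tables[g]) - ref)

    @given(hr_mod=st.floats(0.5, 0.99))
    def test_lower_hazard_ratio_weakly_increases_e50(self, gompertz_rates, uniform_prevalence, hr_mod):
        base = self.build_tables(
            hr_frame([1, 0.93, 0.9, 0.87, 0.87]), gompertz_rates, uniform_prevalence
        )
        lowered = self.build_tables(
            hr_frame([1, 0.93, 0.9 * hr_mod, 0.87, 0.87]),
            gompertz_rates,
            uniform_prevalence,
        )
        assert e50(lowered["moderate"]) >= e50(base["moderate"])

    def test_population_consistency(self, gompertz_rates, reference_hazards, uniform_prevalence):
        """Prevalence-weighted mixture of group survival reproduces the
        population life table's e50 within 0.1 year."""
        sch = partition_rates(gompertz_rates, reference_hazards, uniform_prevalence)
        tables = {g: build_life_table(s) for g, s in sch.items()}
        p = uniform_prevalence[list(lg.GROUP_LABELS)].iloc[-1].to_numpy()
        L_mix = sum(p[i] * tables[g]["L"].to_numpy() for i, g in enumerate(lg.GROUP_LABELS))
        l50_mix = sum(p[i] * tables[g]["l"].iloc[0] for i, g in enumerate(lg.GROUP_LABELS))
        e_mix = L_mix.sum() / l50_mix
        m_all, _, _ = gompertz_rates.arrays(50, 100)
        e_pop = e50(build_life_table(m_all))
        assert abs(e_mix - e_pop) < 0.1


class TestVectorizedCore:
    def test_batched_matches_single(self):
        rng = np.random.default_rng(0)
        M = np.exp(rng.uniform(np.log(1e-3), np.log(0.2), (4, 51)))
        batch = life_table_arrays(M)
        for i in range(4):
            single = life_table_arrays(M[i])
            for k in batch:
                assert np.allclose(batch[k][i], single[k])
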