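"""Dilution-curve construction and NNI computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricenni import agronomy as agro


def day_frame(agb_by_gradient, n_by_gradient=None, day=1):
    rows = []
    for g, agbs in agb_by_gradient.items():
        ns = (n_by_gradient or {}).get(g, [2.0] * len(agbs))
        for agb, n in zip(agbs, ns):
            rows.append([f"{g}-{len(rows)}", "exp1", g, 0, day, 0.0, agb, n])
    return pd.DataFrame(rows, columns=["sample_id", "experiment", "gradient",
                                       "plot", "day", "n_rate_kg_hm2",
                                       "agb_t_hm2", "n_conc_pct"])


class TestKjeldahl:
    def test_zero_titration_gives_zero_concentration(self):
        assert agro.kjeldahl_n_concentration(agro.KjeldahlSample(0.0, 1.0)) == 0.0

    def test_known_titration(self):
        # 10 mL * 0.05 mol/L * 0.014 g/mmol / 0.7 g * 100 = 1.0 %
        got = agro.kjeldahl_n_concentration(agro.KjeldahlSample(10.0, 0.7))
        assert got == pytest.approx(1.0, rel=1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            agro.kjeldahl_n_concentration(agro.KjeldahlSample(5.0, 0.0))


class TestPartition:
    AGBS = {"N0": [1.0, 1.1, 0.9], "N1": [2.0, 2.1, 1.9], "N2": [3.0, 3.1, 2.9],
            "N3": [3.05, 3.0, 3.1], "N4": [3.0, 3.05, 3.1]}

    def test_low_gradients_limited_high_plateau_not(self):
        part = agro.partition_n_limited(day_frame(self.AGBS), alpha=0.05)
        assert part.limited == {"N0", "N1"}
        assert part.non_limited == {"N2", "N3", "N4"}

    def test_matches_statsmodels_tukey_oracle(self):
        # independent reference: statsmodels pairwise Tukey HSD vs top gradient
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        df = day_frame(self.AGBS)
        res = pairwise_tukeyhsd(df["agb_t_hm2"], df["gradient"], alpha=0.05)
        table = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        top = df.groupby("gradient")["agb_t_hm2"].mean().idxmax()
        expected_limited = set()
        for _, row in table.iterrows():
            pair = {row["group1"], row["group2"]}
            if top in pair and row["reject"]:
                expected_limited |= pair - {top}
        part = agro.partition_n_limited(df, alpha=0.05)
        assert part.limited == expected_limited

    def test_identical_gradients_all_non_limited(self):
        agbs = {g: [2.0, 2.0, 2.0] for g in ["N0", "N1", "N2"]}
        part = agro.partition_n_limited(day_frame(agbs))
        assert part.limited == frozenset()
        assert part.non_limited == {"N0", "N1", "N2"}

    def test_single_gradient_rejected(self):
        with pytest.raises(ValueError):
            agro.partition_n_limited(day_frame({"N0": [1.0, 1.1]}))

    def test_means_only_fallback_without_replicates(self):
        agbs = {"N0": [1.0], "N1": [2.0], "N2": [2.98], "N3": [3.0]}
        part = agro.partition_n_limited(day_frame(agbs))
        assert part.limited == {"N0", "N1"}
        assert part.non_limited == {"N2", "N3"}

    def test_invariants_hold_on_random_tables(self, rng):
        for _ in range(20):
            k = rng.integers(2, 6)
            agbs = {f"N{g}": list(rng.uniform(0.5, 5.0, size=3)) for g in range(k)}
            part = agro.partition_n_limited(day_frame(agbs))
            assert part.limited | part.non_limited == set(agbs)
            assert not part.limited & part.non_limited
            assert part.non_limited


class TestCriticalPoint:
    def test_two_point_line_evaluated_at_plateau(self):
        # N = 4.0 - 0.5*AGB through (1, 3.5) and (2, 3.0); plateau mean AGB = 3.0
        df = day_frame({"L": [1.0, 2.0], "H": [2.9, 3.1]},
                       {"L": [3.5, 3.0], "H": [2.0, 2.0]})
        part = agro.DayPartition(1, frozenset({"L"}), frozenset({"H"}))
        point = agro.critical_point_for_day(df, part)
        assert point.agb_max == pytest.approx(3.0)
        assert point.n_critical == pytest.approx(2.5)

    def test_zero_agb_spread_rejected(self):
        df = day_frame({"L": [2.0, 2.0], "H": [3.0]}, {"L": [3.5, 3.0], "H": [2.0]})
        part = agro.DayPartition(1, frozenset({"L"}), frozenset({"H"}))
        with pytest.raises(agro.DegenerateFitError):
            agro.critical_point_for_day(df, part)

    def test_flat_line_gives_constant_critical_value(self):
        df = day_frame({"L": [1.0, 3.0], "H": [5.0]}, {"L": [2.0, 2.0], "H": [2.0]})
        part = agro.DayPartition(1, frozenset({"L"}), frozenset({"H"}))
        assert agro.critical_point_for_day(df, part).n_critical == pytest.approx(2.0)


def make_points(a, b, agbs):
    return [agro.CriticalPoint(day=i, agb_max=x, n_critical=a * x ** (-b))
            for i, x in enumerate(agbs)]


class TestCurveFit:
    @pytest.mark.parametrize("a", [1.0, 2.03, 4.5])
    @pytest.mark.parametrize("b", [0.15, 0.46, 0.85])
    def test_noise_free_points_recover_generating_curve(self, a, b):
        curve = agro.fit_critical_curve(make_points(a, b, np.linspace(1.0, 12.0, 8)))
        assert curve.a == pytest.approx(a, rel=1e-6)
        assert curve.b == pytest.approx(b, rel=1e-6)
        assert curve.r2 == pytest.approx(1.0)
        assert curve.rmse == pytest.approx(0.0, abs=1e-9)

    def test_two_points_exactly_determined(self):
        pts = [agro.CriticalPoint(1, 1.0, 3.0),
               agro.CriticalPoint(2, 8.0, 3.0 * 8 ** (-0.3))]
        curve = agro.fit_critical_curve(pts)
        assert curve.a == pytest.approx(3.0, rel=1e-9)
        assert curve.b == pytest.approx(0.3, rel=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(agro.DegenerateFitError):
            agro.fit_critical_curve([agro.CriticalPoint(1, 1.0, 3.0)])

    def test_noisy_exponent_recovery_is_unbiased(self, rng):
        a, b = 2.03, 0.46
        errs = []
        for _ in range(100):
            pts = [agro.CriticalPoint(i, x, a * x ** (-b) * rng.lognormal(0, 0.05))
                   for i, x in enumerate(np.linspace(1.0, 12.0, 8))]
            errs.append(abs(agro.fit_critical_curve(pts).b - b))
        assert np.median(errs) < 0.05


class TestNni:
    CURVE = agro.CriticalCurve(a=2.03, b=0.46)

    def test_on_curve_sample_is_exactly_critical(self):
        for agb in (0.5, 1.0, 7.3):
            rec = agro.compute_nni(self.CURVE.critical_n(agb), agb, self.CURVE)
            assert rec.nni == pytest.approx(1.0)
            assert rec.group == "rich"  # boundary NNI >= 1

    def test_unit_biomass_normalizes_to_a(self):
        rec = agro.compute_nni(4.06, 1.0, self.CURVE)
        assert rec.nni == pytest.approx(2.0)

    def test_high_biomass_dilution(self):
        # oracle: 2.03 * 8**(-0.46) = 0.78066...
        rec = agro.compute_nni(0.78, 8.0, self.CURVE)
        assert rec.nni == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("nni,group", [(0.99, "deficit"), (1.0, "rich"),
                                           (1.31, "rich")])
    def test_group_rule(self, nni, group):
        assert agro.classify_nni(nni) == group

    def test_non_positive_nni_rejected(self):
        with pytest.raises(ValueError):
            agro.classify_nni(0.0)

    @given(st.floats(0.1, 3.0), st.floats(0.2, 12.0), st.floats(0.5, 2.0))
    @settings(deadline=None, max_examples=50)
    def test_scale_consistency(self, n_conc, agb, c):
        base = agro.compute_nni(n_conc, agb, self.CURVE).nni
        scaled = agro.compute_nni(c * n_conc, agb, self.CURVE).nni
        assert scaled == pytest.approx(c * base, rel=1e-12)
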