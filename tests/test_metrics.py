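"""Efficiency metrics, pre-incubation shift, correlation matrix, fold change."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moafit.metrics import (
    CompoundRecord,
    correlation_matrix,
    enthalpic_efficiency,
    fold_change,
    kinetic_efficiency,
    ligand_efficiency,
    max_preincubation_shift,
    radar_table,
)


def brute_force_spearman(x, y):
    """Independent oracle: average ranks by explicit tie groups, then Pearson."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    if sxx == 0 or syy == 0:
        return float("nan")
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    return sxy / (sxx * syy) ** 0.5


class TestEfficiencies:
    def test_ligand_efficiency_arithmetic(self):
        assert ligand_efficiency(9.0, 35) == pytest.approx(1.4 * 9 / 35)
        assert ligand_efficiency(9.0, 35) == pytest.approx(0.36)
        assert ligand_efficiency(7.0, 1) == pytest.approx(9.8)
        # doubling HA halves LE exactly
        assert ligand_efficiency(8.0, 60) == pytest.approx(ligand_efficiency(8.0, 30) / 2)

    def test_kinetic_and_enthalpic_quotients(self):
        assert kinetic_efficiency(3600.0, 36) == pytest.approx(100.0)
        assert enthalpic_efficiency(-42e3, 42) == pytest.approx(-1000.0)
        with pytest.raises(ValueError):
            kinetic_efficiency(100.0, 0)

    def test_missing_potency_propagates_as_gap(self):
        assert np.isnan(ligand_efficiency(float("nan"), 30))

    def test_ke_ordering_matches_rt_at_equal_ha(self):
        rts = [30.0, 3600.0, 600.0, 5.0]
        kes = [kinetic_efficiency(rt, 33) for rt in rts]
        assert np.argsort(kes).tolist() == np.argsort(rts).tolist()

    def test_radar_normalization_idempotent_max_one(self):
        df = pd.DataFrame({"le": [0.2, 0.4, 0.3], "ke": [10.0, 100.0, 50.0],
                           "ee": [-900.0, -300.0, -1200.0]})
        norm = radar_table(df)
        assert np.allclose(norm.max(axis=0), 1.0)
        pd.testing.assert_frame_equal(radar_table(norm), norm)

    def test_compound_record_validation(self):
        with pytest.raises(ValueError):
            CompoundRecord(compound_id="x", heavy_atoms=0)


class TestPreincubationShift:
    def test_max_shift_examples(self):
        assert max_preincubation_shift({0: 7.0, 15: 7.3, 60: 7.2}) == pytest.approx(0.3)
        assert max_preincubation_shift({0: 7.0, 15: 7.0, 60: 7.0}) == 0.0
        # negative shifts are reported as-is
        assert max_preincubation_shift({0: 7.5, 15: 7.1}) == pytest.approx(-0.4)

    def test_baseline_required_and_gap_handling(self):
        with pytest.raises(ValueError):
            max_preincubation_shift({15: 7.0})
        assert np.isnan(max_preincubation_shift({0: 7.0, 15: float("nan")}))

    def test_slow_binder_doubles_potency(self):
        """A residence time beyond 30 min doubles potency on pre-incubation.

        Without pre-incubation a slow binder's apparent inhibition reflects
        partial occupancy; after pre-incubating to equilibrium its IC50 drops
        at least twofold (shift >= 0.3 log units) under the designed kinetics.
        """
        from moafit.kinetics import motulsky_mahan_signal

        kon, koff = 1e5, 2.8e-4  # RT ~ 1 h
        L, kd_probe, k1, k2 = 1.5e-8, 1.1e-9, 1e6, 1.1e-3
        doses = np.sort(2.5e-6 / 3.0 ** np.arange(10))
        reaction_t = 600.0

        def pic50_at(preinc_s):
            # occupancy after preinc + reaction window vs equilibrium occupancy
            resp = []
            for d in doses:
                t_tot = preinc_s + reaction_t
                y = motulsky_mahan_signal(np.array([t_tot]), L, d, k1, k2, kon, koff, 1.0)[0]
                y0 = motulsky_mahan_signal(np.array([t_tot]), L, 0.0, k1, k2, 1e5, 1e-2, 1.0)[0]
                resp.append(100.0 * (1 - y / y0))
            from moafit.equilibrium import NormalizedCurve, fit_logistic4
            return fit_logistic4(
                NormalizedCurve(doses=doses, response=np.array(resp))).pic50

        shift = max_preincubation_shift(
            {0: pic50_at(0.0), 15: pic50_at(15 * 60.0), 60: pic50_at(60 * 60.0)})
        assert shift >= 0.3


class TestCorrelationMatrix:
    def test_perfect_monotone_and_reversed(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [10, 100, 1000, 1e4, 1e5],
                           "c": [5, 4, 3, 2, 1]})
        cm = correlation_matrix(df, method="spearman")
        assert cm.matrix.loc["a", "b"] == pytest.approx(1.0)
        assert cm.matrix.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(cm.matrix), 1.0)
        assert (cm.matrix.values == cm.matrix.values.T).all()

    def test_exhaustive_tie_patterns_match_oracle(self):
        """All {0,1,2}-valued pairs at n = 4..6 agree exactly with the oracle."""
        for n, alphabet in ((4, 3), (5, 2), (6, 2)):
            vectors = list(itertools.product(range(alphabet), repeat=n))
            for x in vectors:
                if len(set(x)) == 1:
                    continue
                for y in vectors[:: max(1, len(vectors) // 10)]:
                    if len(set(y)) == 1:
                        continue
                    df = pd.DataFrame({"x": x, "y": y})
                    got = correlation_matrix(df, min_pairs=2).matrix.loc["x", "y"]
                    assert got == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_matches_scipy_cross_check(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.integers(0, 5, size=(20, 3)), columns=list("abc"))
        cm = correlation_matrix(df)
        for a in "abc":
            for b in "abc":
                assert cm.matrix.loc[a, b] == pytest.approx(
                    spearmanr(df[a], df[b]).statistic, abs=1e-12)

    def test_pairwise_complete_and_constant_column(self):
        df = pd.DataFrame({
            "a": [1.0, 2, 3, 4, np.nan, 6],
            "b": [2.0, 4, 6, np.nan, 10, 12],
            "const": [5.0] * 6,
        })
        cm = correlation_matrix(df)
        assert cm.n.loc["a", "b"] == 4
        assert cm.matrix.loc["a", "b"] == pytest.approx(1.0)
        assert np.isnan(cm.matrix.loc["a", "const"])
        tiny = correlation_matrix(df.iloc[:2], min_pairs=3)
        assert np.isnan(tiny.matrix.loc["a", "b"])

    @given(st.lists(st.integers(1, 1000), min_size=5, max_size=10, unique=True))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, xs):
        xs = [float(v) for v in xs]
        ys = list(np.sin(xs))
        df1 = pd.DataFrame({"x": xs, "y": ys})
        df2 = pd.DataFrame({"x": np.log(xs), "y": ys})  # strictly monotone transform
        r1 = correlation_matrix(df1).matrix.loc["x", "y"]
        r2 = correlation_matrix(df2).matrix.loc["x", "y"]
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestFoldChange:
    def test_wild_type_vs_mutant_activator_affinity(self):
        """K_b 2.1 µM vs 0.5 µM rounds to the conventional 'fourfold'."""
        fc = fold_change(2.1e-6, 0.5e-6)
        assert fc.ratio == pytest.approx(4.2)
        assert fc.label == "fourfold"

    def test_identity_and_reciprocity(self):
        assert fold_change(3.0, 3.0).label == "onefold"
        assert fold_change(2.0, 1.0).ratio * fold_change(1.0, 2.0).ratio \
            == pytest.approx(1.0)
        with pytest.raises(ValueError):
            fold_change(-1.0, 2.0)
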