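"""Stop counting, the reactivity estimator and matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from cotshape.pipeline import (
    ReactivityProfile,
    StopCountTable,
    aligned_read_distribution,
    assemble_matrix,
    estimate_reactivity,
)
from cotshape.probing import stop_distribution


class TestEstimator:
    def test_hand_computed_toy_oracle(self):
        """Frozen hand evaluation of the log-survival closed form on a
        3-nt count table (computed independently of the implementation):
        beta = (1/6, 1/4, 1/5), gamma = (2/97, 2/99, 1/100)."""
        prof = estimate_reactivity(
            np.array([50, 10, 20, 20]), np.array([95, 2, 2, 1]), min_reads=1
        )
        assert prof.theta == pytest.approx(
            [0.25159537609738625, 0.41640816793120927, 0.3319964559714045]
        )
        assert prof.rho == pytest.approx(
            [0.7547861282921587, 1.2492245037936278, 0.9959893679142134]
        )
        assert not prof.low_signal

    def test_identical_channels_yield_low_signal_zero_profile(self):
        c = np.array([50, 10, 20, 20])
        prof = estimate_reactivity(c, c, min_reads=1)
        assert prof.low_signal
        assert np.all(prof.theta == 0)

    def test_normalisation_invariants(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            L = int(rng.integers(5, 40))
            cp = rng.integers(0, 50, size=L + 1) + 1
            cm = rng.integers(0, 5, size=L + 1) + 1
            prof = estimate_reactivity(cp, cm, min_reads=1)
            if not prof.low_signal:
                assert prof.theta.sum() == pytest.approx(1.0)
                assert prof.rho.mean() == pytest.approx(1.0)
                assert np.all(prof.theta >= 0)

    def test_invariance_under_per_length_reweighting(self):
        """Multiplying all reads at a length by a constant (ligation bias)
        leaves the profile unchanged."""
        cp = np.array([40, 5, 12, 9, 3])
        cm = np.array([80, 2, 1, 3, 1])
        a = estimate_reactivity(cp, cm, min_reads=1)
        b = estimate_reactivity(7 * cp, 3 * cm, min_reads=1)
        assert a.theta == pytest.approx(b.theta)

    def test_saturated_hazard_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="saturated"):
            prof = estimate_reactivity(
                np.array([0, 5, 10]), np.array([10, 1, 1]), min_reads=1
            )
        assert np.isfinite(prof.theta).all()

    def test_monotone_in_generative_rate(self):
        """Raising the true modification rate at one position does not
        decrease its estimated theta (expected-count oracle)."""
        L, bg, depth = 12, 0.01, 1.0
        base = np.full(L, 0.02)
        pos = 5  # 1-based position 6

        def expected_counts(rates):
            h = 1 - (1 - rates) * (1 - bg)
            return depth * stop_distribution(h)

        cm = depth * stop_distribution(np.full(L, bg))
        prev = -1.0
        for r in (0.02, 0.05, 0.1, 0.15):
            rates = base.copy()
            rates[pos] = r
            prof = estimate_reactivity(expected_counts(rates), cm, min_reads=0)
            assert prof.theta[pos] >= prev
            prev = prof.theta[pos]

    def test_recovers_rate_ratios_on_expected_counts(self):
        """On infinite-read (expected) counts the estimator recovers the
        generative rate ordering and ratios within 5% after normalisation."""
        rates = np.array([0.04, 0.004, 0.02, 0.04, 0.004, 0.02, 0.04, 0.004])
        bg = 0.002
        h = 1 - (1 - rates) * (1 - bg)
        cp = 1e6 * stop_distribution(h)
        cm = 1e6 * stop_distribution(np.full(len(rates), bg))
        prof = estimate_reactivity(cp, cm, min_reads=0)
        est = prof.theta
        truth = -np.log1p(-rates)
        truth = truth / truth.sum()
        assert np.all(np.abs(est / truth - 1) < 0.05)
        # class ordering: high > medium > low everywhere
        assert est[rates == 0.04].min() > est[rates == 0.02].max()
        assert est[rates == 0.02].min() > est[rates == 0.004].max()

    def test_simulated_single_hit_data_orders_classes(self, rng):
        """Monte-Carlo stop counts at desk depth still order the classes."""
        rates = np.concatenate([np.full(10, 0.04), np.full(10, 0.004)])
        bg = 0.002
        h = 1 - (1 - rates) * (1 - bg)
        cp = rng.multinomial(100_000, stop_distribution(h))
        cm = rng.multinomial(100_000, stop_distribution(np.full(20, bg)))
        prof = estimate_reactivity(cp, cm)
        assert prof.rho[:10].mean() > prof.rho[10:].mean()

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least one read"):
            estimate_reactivity(np.zeros(4), np.ones(4))
        with pytest.raises(ValueError, match="length"):
            estimate_reactivity(np.ones(4), np.ones(5))


class TestMatrix:
    def _profile(self, L, seed=0):
        rng = np.random.default_rng(seed + L)
        theta = rng.random(L)
        theta /= theta.sum()
        return ReactivityProfile(length=L, theta=theta)

    def test_single_profile_matrix(self):
        m = assemble_matrix([self._profile(10)])
        assert list(m.lengths) == [10]
        assert np.isfinite(m.rho(10)).all()

    def test_row_definition_and_na_above_diagonal(self):
        profiles = [self._profile(L) for L in range(20, 91)]
        m = assemble_matrix(profiles)
        assert len(m.lengths) == 71
        for L in (20, 55, 90):
            row = m.data.loc[L].to_numpy()
            assert np.isfinite(row[:L]).all()
            assert np.isnan(row[L:]).all()

    def test_duplicate_lengths_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assemble_matrix([self._profile(10), self._profile(10)])

    def test_low_signal_rows_kept_and_flagged_by_default(self):
        good = self._profile(10)
        bad = ReactivityProfile(length=12, theta=np.zeros(12), low_signal=True)
        m = assemble_matrix([good, bad])
        assert set(m.lengths) == {10, 12}
        assert m.good_lengths() == [10]
        m2 = assemble_matrix([good, bad], drop_low_signal=True)
        assert set(m2.lengths) == {10}

    def test_tsv_round_trip(self, tmp_path):
        m = assemble_matrix([self._profile(L) for L in (20, 21, 25)])
        m.to_tsv(tmp_path / "m.tsv")
        from cotshape.pipeline import ReactivityMatrix

        back = ReactivityMatrix.from_tsv(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(
            back.data, m.data, check_dtype=False, check_names=False, atol=1e-10
        )


class TestAlignedDistribution:
    def test_single_length_is_100_percent(self):
        t = StopCountTable(channel="minus")
        t.add(40, 0, 10)
        t.add(40, 3, 5)
        pct = aligned_read_distribution(t)
        assert pct[40] == pytest.approx(100.0)

    def test_percentages_sum_to_100_with_full_length_category(self):
        t = StopCountTable(channel="minus")
        for L, n in ((30, 10), (50, 30), (120, 60)):
            t.add(L, 0, n)
        pct = aligned_read_distribution(t, full_length=120)
        assert pct.sum() == pytest.approx(100.0)
        assert pct["full_length"] == pytest.approx(60.0)
        assert 120 not in pct.index

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="no aligned"):
            aligned_read_distribution(StopCountTable(channel="minus"))

    def test_higher_biotin_multiplicity_shifts_lengths_down(self, native):
        """More biotins per template proportionally shift the aligned-read
        distribution toward shorter transcripts."""
        from cotshape.probing import CHANNEL_MINUS
        from cotshape.workflow import simulate_sav_experiment

        means = {}
        for m in (1.0, 4.0):
            pop = simulate_sav_experiment(
                native, 30_000, m=m, fluoride_mM=10.0, seed=(21, 22)
            )
            t = StopCountTable(channel=CHANNEL_MINUS)
            internal = pop.L[pop.L < len(native)]
            for L, n in zip(*np.unique(internal, return_counts=True)):
                t.add(int(L), 0, int(n))
            pct = aligned_read_distribution(t)
            means[m] = float((pct.index.to_numpy() * pct.to_numpy()).sum() / 100.0)
        assert means[4.0] < means[1.0]
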