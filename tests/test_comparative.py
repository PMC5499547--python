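"""Efficiency, Delta-rho, footprint-shift and transition detection."""

import numpy as np
import pytest

from cotshape.compare import (
    delta_rho,
    detect_transition,
    estimate_footprint_shift,
    roadblock_efficiency,
)
from cotshape.pipeline import ReactivityProfile, assemble_matrix
from cotshape.tec import RoadblockModel, simulate_population


def make_matrix(rho_fn, lengths, n_pos, name="m"):
    """Matrix whose row L holds rho_fn(L, k) for 1-based position k."""
    profiles = []
    for L in lengths:
        rho = np.array([rho_fn(L, k) for k in range(1, L + 1)], dtype=float)
        theta = rho / rho.sum() if rho.sum() > 0 else np.zeros(L)
        profiles.append(ReactivityProfile(length=L, theta=theta))
    m = assemble_matrix(profiles, metadata={"name": name})
    return m


class TestEfficiency:
    def test_all_stalled(self, template_spec):
        rb = RoadblockModel.sav_template(55, stall_prob=1.0)
        pop = simulate_population(template_spec, [rb], 300, seed=1)
        assert roadblock_efficiency(pop) == 1.0

    def test_no_products_rejected(self, template_spec):
        pop = simulate_population(
            template_spec, [], 300, seed=2, fluoride_mM=0.0,
            terminator=__import__("cotshape").tec.TerminatorModel(p_term_no_fluoride=1.0),
        )
        with pytest.raises(ValueError, match="no roadblocked"):
            roadblock_efficiency(pop)

    def test_unbiased_over_replicates(self, template_spec):
        """Mean of 200 replicate estimates at p = 0.5 sits inside the
        binomial confidence band of 0.5."""
        rb = RoadblockModel.sav_template(55, stall_prob=0.5)
        n_rep, n_mol = 200, 400
        ests = [
            roadblock_efficiency(simulate_population(template_spec, [rb], n_mol, seed=s))
            for s in range(n_rep)
        ]
        se = np.sqrt(0.25 / (n_rep * n_mol))
        assert abs(np.mean(ests) - 0.5) < 4 * se


class TestDeltaRho:
    def test_identical_matrices_give_zero(self):
        m = make_matrix(lambda L, k: 1.0 + 0.1 * k, range(30, 50), 50)
        d = delta_rho(m, m)
        assert np.nanmax(np.abs(d.data.to_numpy())) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = make_matrix(lambda L, k: rng.random() + 0.2, range(30, 45), 45, "a")
        b = make_matrix(lambda L, k: rng.random() + 0.2, range(33, 50), 50, "b")
        dab = delta_rho(a, b)
        dba = delta_rho(b, a)
        assert np.allclose(
            dab.data.to_numpy(), -dba.data.to_numpy(), equal_nan=True
        )

    def test_disjoint_lengths_rejected(self):
        a = make_matrix(lambda L, k: 1.0, range(20, 25), 25)
        b = make_matrix(lambda L, k: 1.0, range(40, 45), 45)
        with pytest.raises(ValueError, match="no transcript lengths"):
            delta_rho(a, b)

    def test_low_reactivity_regions_have_near_zero_delta(self):
        """Where both ground truths are unreactive, |Delta-rho| stays
        near 0 even if reactive regions differ."""
        def rho_a(L, k):
            return 0.05 if k <= 10 else 1.5
        def rho_b(L, k):
            return 0.05 if k <= 10 else 1.0
        a = make_matrix(rho_a, range(30, 40), 40, "a")
        b = make_matrix(rho_b, range(30, 40), 40, "b")
        d = delta_rho(a, b)
        low_cols = [c for c in d.data.columns if c <= 10]
        assert d.data[low_cols].abs().max().max() < 0.2


class TestFootprintShift:
    @staticmethod
    def synthetic_pair(extra, lengths=range(40, 80)):
        """Reference protects the last 14 nt; the comparison matrix
        protects ``extra`` additional nt."""
        def ref(L, k):
            return 0.0 if k > L - 14 else 1.0
        def cmp_(L, k):
            return 0.0 if k > L - 14 - extra else 1.0
        a = make_matrix(cmp_, lengths, max(lengths), "sav")
        b = make_matrix(ref, lengths, max(lengths), "gln")
        return a, b

    def test_identical_matrices_give_zero_width(self):
        a, b = self.synthetic_pair(0)
        with pytest.warns(UserWarning, match="no qualifying"):
            mean_w, widths = estimate_footprint_shift(delta_rho(a, a), a)
        assert mean_w == 0.0

    @pytest.mark.parametrize("extra", [3, 5, 7])
    def test_recovers_known_protection_difference(self, extra):
        a, b = self.synthetic_pair(extra)
        mean_w, widths = estimate_footprint_shift(delta_rho(a, b), b)
        assert mean_w == pytest.approx(extra, abs=0.01)

    def test_infinite_threshold_degeneracy(self):
        a, b = self.synthetic_pair(4)
        with pytest.warns(UserWarning, match="no qualifying"):
            mean_w, _ = estimate_footprint_shift(delta_rho(a, b), b, tau=np.inf)
        assert mean_w == 0.0


class TestDetectTransition:
    @staticmethod
    def step_matrix(L_star, pre=2.0, post=0.2, lengths=range(40, 90), scale=1.0):
        def rho(L, k):
            if 11 <= k <= 16:
                return scale * (pre if L < L_star else post)
            return scale * 1.0
        return make_matrix(rho, lengths, max(lengths))

    def test_exact_step_onset_equals_completion(self):
        m = self.step_matrix(62)
        call = detect_transition(m, (11, 16), "decrease")
        assert call.onset == call.completion == 62

    def test_scale_invariance(self):
        a = self.step_matrix(62, scale=1.0)
        b = self.step_matrix(62, scale=3.7)
        ca = detect_transition(a, (11, 16), "decrease")
        cb = detect_transition(b, (11, 16), "decrease")
        assert (ca.onset, ca.completion) == (cb.onset, cb.completion)

    def test_wrong_direction_yields_no_call(self):
        m = self.step_matrix(62)
        call = detect_transition(m, (11, 16), "increase")
        assert not call.called

    def test_flat_trace_yields_no_call(self):
        m = self.step_matrix(200)  # never switches in range
        call = detect_transition(m, (11, 16), "decrease")
        assert not call.called

    def test_single_length_noise_does_not_trigger(self):
        """Persistence requirement: a one-length dip is not an onset."""
        def rho(L, k):
            if 11 <= k <= 16:
                if L == 55:
                    return 0.1  # spurious dip
                return 2.0 if L < 70 else 0.2
            return 1.0
        m = make_matrix(rho, range(40, 90), 90)
        call = detect_transition(m, (11, 16), "decrease")
        assert call.onset == 70

    def test_displacement_law_on_noise_free_profiles(self, pathway):
        """The detected onset for a roadblock with fixed backtrack b sits
        at E + f_rna + b (closed form from the folding ground truth)."""
        E_PK1 = 43
        for b in (0, 1, 4):
            protected = pathway.f_rna + b

            def rho(L, k, b=b, protected=protected):
                emerged = max(0, L - protected)
                if k > emerged:
                    return 1e-6
                rates = pathway.rate_vector(emerged, "+F")
                return float(rates[k - 1]) * 25.0

            m = make_matrix(rho, range(45, 95), 95)
            call = detect_transition(m, (11, 16), "decrease")
            assert call.onset == E_PK1 + pathway.f_rna + b

    def test_too_few_lengths_rejected(self):
        m = self.step_matrix(45, lengths=range(42, 49))
        with pytest.raises(ValueError, match="lengths"):
            detect_transition(m, (11, 16), "decrease")
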