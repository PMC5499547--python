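"""Roadblock stalling, backtracking, termination and partition."""

import pytest

from cotshape import defaults
from cotshape.tec import (
    FATE_RUNOFF,
    FATE_STALLED,
    FATE_TERMINATED,
    RoadblockModel,
    TECState,
    TerminatorModel,
    apply_backtracking,
    exo3_protection,
    greb_cleavage_register,
    pellet_partition,
    simulate_population,
    stall_outcome,
)


class TestStallOutcome:
    def test_gln111_defined_stop_14_upstream(self, rng):
        rb = RoadblockModel.gln111(59)
        outcomes = [stall_outcome(rb, rng) for _ in range(200)]
        lengths = {L for stalled, L, _ in outcomes if stalled}
        assert lengths == {45}

    def test_sav_template_cluster_7_to_13_upstream(self, rng):
        rb = RoadblockModel.sav_template(55)
        for _ in range(500):
            stalled, L, pushed = stall_outcome(rb, rng)
            if stalled:
                assert 55 - 13 <= L <= 55 - 7
                assert pushed == defaults.SAV_MODAL_OFFSET - (55 - L) or pushed == 0

    def test_certain_terminal_stall(self, rng):
        rb = RoadblockModel.terminal(120, stall_prob=1.0)
        for _ in range(50):
            stalled, L, _ = stall_outcome(rb, rng)
            assert stalled and L == 120

    def test_site_too_close_to_start(self, rng):
        with pytest.raises(ValueError, match="too close"):
            stall_outcome(RoadblockModel.sav_template(10), rng)

    def test_offsets_outside_printed_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            RoadblockModel.sav_template(55, offset_dist={5: 1.0})


class TestBacktracking:
    def test_gln111_never_beyond_1nt(self, rng):
        rb = RoadblockModel.gln111(59)
        tec = TECState(template_id=0, L=45)
        depths = {apply_backtracking(tec, rb, rng).b for _ in range(100_000)}
        assert max(depths) == 1

    def test_sav_primary_capped_at_4(self, rng):
        rb = RoadblockModel.sav_template(55)
        tec = TECState(template_id=0, L=45, pushed=0)
        depths = {apply_backtracking(tec, rb, rng).b for _ in range(20_000)}
        assert max(depths) == 4
        assert min(depths) >= 0

    def test_pushed_tec_reaches_7nt_floor(self, rng):
        # a TEC that advanced to +48 with a backtrack floor of +41
        rb = RoadblockModel.sav_template(55)
        tec = TECState(template_id=0, L=48, pushed=3)
        depths = [apply_backtracking(tec, rb, rng).b for _ in range(20_000)]
        assert max(depths) == 7
        assert min(48 - d for d in depths) == 41

    def test_structure_caps_backtracking_near_terminator(self, rng, pathway):
        rb = RoadblockModel.sav_template(90)
        tec = TECState(template_id=0, L=77)
        depths = {
            apply_backtracking(tec, rb, rng, pathway=pathway, condition="-F").b
            for _ in range(2000)
        }
        assert max(depths) <= 1
        # no cap with fluoride (terminator never winds)
        depths_f = {
            apply_backtracking(tec, rb, rng, pathway=pathway, condition="+F").b
            for _ in range(2000)
        }
        assert max(depths_f) == 4

    def test_clamp_to_length(self, rng):
        rb = RoadblockModel.sav_template(16, offset_dist={13: 1.0})
        tec = TECState(template_id=0, L=3)
        with pytest.warns(UserWarning, match="clamped"):
            out = apply_backtracking(tec, rb, rng)
        assert out.b <= 2


class TestRegisters:
    def test_greb_trims_to_active_site(self):
        assert greb_cleavage_register(TECState(0, L=45, b=0)) == 45
        assert greb_cleavage_register(TECState(0, L=45, b=4)) == 41

    def test_gln111_greb_products_at_least_44(self, rng):
        rb = RoadblockModel.gln111(59)
        tec = TECState(0, L=45)
        prods = {greb_cleavage_register(apply_backtracking(tec, rb, rng)) for _ in range(5000)}
        assert min(prods) == 44

    def test_exo3_base_footprint(self, rng):
        assert exo3_protection(TECState(0, L=45, b=0), rng, jitter=False) == 14

    def test_exo3_gln111_range(self, rng):
        rb = RoadblockModel.gln111(59)
        vals = {
            exo3_protection(apply_backtracking(TECState(0, L=45), rb, rng), rng, jitter=False)
            for _ in range(5000)
        }
        assert vals == {14, 15}

    def test_exo3_sav_range_spans_17_to_19(self, rng):
        dist = {3: 0.4, 4: 0.6}  # dominant depths of the default model
        rb = RoadblockModel.sav_template(55, backtrack_dist=dist)
        vals = {
            exo3_protection(apply_backtracking(TECState(0, L=45), rb, rng), rng)
            for _ in range(5000)
        }
        assert vals == {17, 18, 19}
        assert min(vals) >= 14


class TestPopulation:
    def test_all_runoff_without_roadblocks(self, template_spec):
        pop = simulate_population(template_spec, [], 500, seed=1)
        assert pop.fate_counts() == {FATE_RUNOFF: 500}

    def test_conservation_of_molecules(self, template_spec):
        rbs = [RoadblockModel.sav_template(40), RoadblockModel.gln111(70)]
        pop = simulate_population(
            template_spec, rbs, 5000, seed=2, fluoride_mM=0.0, terminator=TerminatorModel()
        )
        counts = pop.fate_counts()
        assert sum(counts.values()) == 5000
        assert set(counts) <= {FATE_STALLED, FATE_RUNOFF, FATE_TERMINATED}

    def test_stalls_explainable_by_configuration(self, template_spec):
        rbs = [RoadblockModel.sav_template(40), RoadblockModel.sav_template(70)]
        pop = simulate_population(template_spec, rbs, 5000, seed=3)
        allowed = {s - d for rb in rbs for s in [rb.site] for d in rb.offset_dist}
        assert set(pop.L[pop.stalled].tolist()) <= allowed

    def test_terminated_lengths_confined_to_window(self, template_spec):
        pop = simulate_population(
            template_spec, [], 5000, seed=4, fluoride_mM=0.0, terminator=TerminatorModel()
        )
        term = pop.L[pop.fate == FATE_TERMINATED]
        assert len(term) > 4800  # p_term = 0.99
        assert set(term.tolist()) <= {80, 81, 82}

    def test_fluoride_antitermination(self, template_spec):
        pop = simulate_population(
            template_spec, [], 5000, seed=5, fluoride_mM=10.0, terminator=TerminatorModel()
        )
        assert (pop.fate == FATE_TERMINATED).mean() < 0.03

    def test_runthrough_can_stall_downstream(self, template_spec):
        rbs = [
            RoadblockModel.sav_template(40, stall_prob=0.5),
            RoadblockModel.sav_template(80, stall_prob=1.0),
        ]
        pop = simulate_population(template_spec, rbs, 4000, seed=6)
        stalls = set(pop.L[pop.stalled].tolist())
        assert stalls & {80 - d for d in defaults.SAV_TEMPLATE_OFFSETS}
        assert pop.fate_counts().get(FATE_RUNOFF, 0) == 0  # second roadblock is certain


class TestPelletPartition:
    def test_all_runoff_population_has_empty_pellet(self, template_spec, rng):
        pop = simulate_population(template_spec, [], 200, seed=7)
        pellet, sup = pellet_partition(pop, rng)
        assert len(pellet) == 0 and len(sup) == 200

    def test_default_binding_fraction(self, template_spec, rng):
        rb = RoadblockModel.sav_template(55, stall_prob=1.0)
        pop = simulate_population(template_spec, [rb], 100_000, seed=8)
        pellet, sup = pellet_partition(pop, rng)
        frac = len(pellet) / len(pop)
        assert 0.95 <= frac <= 0.98

    def test_perfect_binding(self, template_spec, rng):
        rb = RoadblockModel.sav_template(55, stall_prob=1.0)
        pop = simulate_population(template_spec, [rb], 2000, seed=9)
        pellet, _ = pellet_partition(pop, rng, p_bound=1.0)
        assert len(pellet) == 2000
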