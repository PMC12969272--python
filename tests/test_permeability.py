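import numpy as np
import pytest

from bilayerlab.core import AnalysisConfig, assign_leaflets
from bilayerlab.permeability import (
    CrossingEvent,
    bulk_concentration,
    detect_crossings,
    estimate_permeability,
    permeability_coefficient,
)
from bilayerlab.synthetic import PMFSpec, SyntheticSpec, generate_solute_tracks


def brute_force_crossings(z_track, upper, lower):
    """Exhaustive three-state scan for a non-wrapping track: count complete
    transitions between the two bulk regions (up: z > upper, low: z < lower)."""
    events = []
    last_bulk = None
    for z in z_track:
        state = "up" if z > upper else ("low" if z < lower else None)
        if state is None:
            continue
        if last_bulk is not None and state != last_bulk:
            events.append("down" if state == "low" else "up")
        last_bulk = state
    return events


@pytest.fixture
def bounds_cfg():
    # phosphate planes at +-20, margin 5 -> boundaries at +-25
    return AnalysisConfig(equilibration_fraction=0.0, crossing_margin=5.0)


class TestDetectCrossings:
    def test_monotone_downward_track(self, make_bilayer, bounds_cfg):
        z = np.linspace(40, -40, 30)[:, None]
        t = make_bilayer(n_frames=30, solute_z=z)
        events = detect_crossings(t, assign_leaflets(t), bounds_cfg)
        assert len(events) == 1
        assert events[0].direction == "down"

    def test_rejected_recrossing(self, make_bilayer, bounds_cfg):
        z = np.concatenate([np.linspace(40, -10, 15), np.linspace(-10, 40, 15)])[:, None]
        t = make_bilayer(n_frames=30, solute_z=z)
        assert detect_crossings(t, assign_leaflets(t), bounds_cfg) == []

    def test_periodic_wrap_through_water_not_a_crossing(self, make_bilayer, bounds_cfg):
        # climb from upper bulk out of the top of the box (z wraps to the
        # lower bulk through water): must count zero crossings
        z = np.mod(np.linspace(30, 75, 40) + 50, 100)[:, None] - 50
        t = make_bilayer(n_frames=40, solute_z=z)
        assert detect_crossings(t, assign_leaflets(t), bounds_cfg) == []

    def test_wrap_then_real_crossing(self, make_bilayer, bounds_cfg):
        # wrap through water into the lower bulk, then cross upward
        seg1 = np.linspace(30, 70, 20)     # wraps at 50 into [-50, -30)
        seg2 = np.linspace(-30, 40, 30)    # genuine upward crossing
        z = np.concatenate([np.mod(seg1 + 50, 100) - 50, seg2])[:, None]
        t = make_bilayer(n_frames=50, solute_z=z)
        events = detect_crossings(t, assign_leaflets(t), bounds_cfg)
        assert [e.direction for e in events] == ["up"]

    def test_twenty_constructed_tracks_match_oracle(self, make_bilayer, bounds_cfg):
        rng = np.random.default_rng(99)
        n_frames = 400
        tracks = []
        for i in range(20):
            kind = i % 5
            if kind == 0:       # strong noise, multiple crossings
                z = np.cumsum(rng.normal(0, 6, n_frames))
                z = 40 * np.tanh(z / 60)
            elif kind == 1:     # stays in upper bulk
                z = 35 + rng.normal(0, 3, n_frames)
            elif kind == 2:     # dips into the membrane, returns
                z = 30 - 25 * np.exp(-((np.arange(n_frames) - 200) / 60.0) ** 2)
            elif kind == 3:     # single clean crossing with dwell
                z = np.concatenate([
                    np.full(100, 35.0), np.linspace(35, -35, 200), np.full(100, -35.0)
                ]) + rng.normal(0, 1, n_frames)
            else:               # oscillates between bulks
                z = 32 * np.sin(np.arange(n_frames) / 25.0) + rng.normal(0, 2, n_frames)
            tracks.append(np.clip(z, -48, 48))
        z_all = np.stack(tracks, axis=1)
        t = make_bilayer(n_frames=n_frames, solute_z=z_all)
        events = detect_crossings(t, assign_leaflets(t), bounds_cfg)

        expected = []
        for j in range(20):
            expected.extend(brute_force_crossings(z_all[:, j], 25.0, -25.0))
        got = [e.direction for e in sorted(events, key=lambda e: (e.solute_id, e.exit_frame))]
        assert len(events) == len(expected)
        assert sorted(got) == sorted(expected)

    def test_time_reversal_invariance(self, make_bilayer, bounds_cfg):
        rng = np.random.default_rng(17)
        z = np.cumsum(rng.normal(0, 5, size=(300, 10)), axis=0)
        z = 40 * np.tanh(z / 50)
        t = make_bilayer(n_frames=300, solute_z=z)
        fwd = detect_crossings(t, assign_leaflets(t), bounds_cfg)
        t_rev = make_bilayer(n_frames=300, solute_z=z[::-1])
        rev = detect_crossings(t_rev, assign_leaflets(t_rev), bounds_cfg)
        assert len(fwd) == len(rev)
        assert sorted(e.direction for e in fwd) == sorted(
            {"up": "down", "down": "up"}[e.direction] for e in rev
        )

    def test_margin_too_large(self, make_bilayer):
        cfg = AnalysisConfig(crossing_margin=40.0)
        z = np.zeros((5, 1))
        t = make_bilayer(solute_z=z)
        with pytest.raises(ValueError, match="margin"):
            detect_crossings(t, assign_leaflets(t), cfg)


class TestBulkConcentration:
    def test_arithmetic(self, make_bilayer):
        # box 100x100x100, planes +-20, margin 20 -> bulk = 20 A total height
        cfg = AnalysisConfig(crossing_margin=20.0)
        z = np.tile(np.full(10, 45.0), (5, 1))
        t = make_bilayer(n_frames=5, box=(100.0, 100.0, 100.0), solute_z=z)
        conc = bulk_concentration(t, assign_leaflets(t), cfg)
        assert conc == pytest.approx(5e19, rel=1e-9)

    def test_no_solute_in_bulk_gives_zero(self, make_bilayer):
        cfg = AnalysisConfig(crossing_margin=5.0)
        z = np.zeros((5, 3))
        t = make_bilayer(solute_z=z)
        assert bulk_concentration(t, assign_leaflets(t), cfg) == 0.0


class TestPermeabilityCoefficient:
    def test_formula_arithmetic(self):
        est = permeability_coefficient(100, 8e-13, 3e-6, 1.67e20)
        assert est.pm_cm_s == pytest.approx(0.1248, abs=2e-4)

    def test_zero_crossings_reports_bound(self):
        est = permeability_coefficient(0, 8e-13, 3e-6, 1.67e20)
        assert est.pm_cm_s == 0.0
        assert est.pm_upper_bound_cm_s == pytest.approx(0.001248, rel=1e-3)
        assert np.isnan(est.log10_pm)

    @pytest.mark.parametrize("bad", [(0.0, 1.0, 1.0), (1.0, 0.0, 1.0), (1.0, 1.0, -2.0)])
    def test_nonpositive_inputs(self, bad):
        with pytest.raises(ValueError):
            permeability_coefficient(3, *bad)


class TestCountingVsISD:
    def test_counting_pm_within_factor_two_of_isd(self, make_bilayer):
        spec = SyntheticSpec(
            n_solutes=60, solute_D_z=50.0,
            pmf=PMFSpec(form="single_gaussian_barrier", barrier_height=2.0, width=3.0),
            dt=0.05, substeps=15, n_frames=8000, box0=(40, 40, 80),
            membrane_halfwidth=17.0, seed=41,
        )
        tracks = generate_solute_tracks(spec)
        t = make_bilayer(
            n_frames=8000, box=(40, 40, 80), z_p=12.0,
            solute_z=tracks.z_wrapped, dt=0.05,
        )
        cfg = AnalysisConfig(equilibration_fraction=0.0, crossing_margin=5.0)
        lf = assign_leaflets(t)
        est, events = estimate_permeability(t, lf, cfg)
        pm_isd_cm_s = tracks.pm_isd * 10.0
        assert est.n_crossings >= 20
        assert 0.5 < est.pm_cm_s / pm_isd_cm_s < 2.0

    def test_doubling_solutes_leaves_pm_invariant(self, make_bilayer):
        def run(n_solutes, seed):
            spec = SyntheticSpec(
                n_solutes=n_solutes, solute_D_z=50.0,
                pmf=PMFSpec(form="single_gaussian_barrier", barrier_height=1.0, width=3.0),
                dt=0.05, substeps=15, n_frames=4000, box0=(40, 40, 80),
                membrane_halfwidth=17.0, seed=seed,
            )
            tracks = generate_solute_tracks(spec)
            t = make_bilayer(n_frames=4000, box=(40, 40, 80), z_p=12.0,
                             solute_z=tracks.z_wrapped, dt=0.05)
            cfg = AnalysisConfig(equilibration_fraction=0.0, crossing_margin=5.0)
            est, _ = estimate_permeability(t, assign_leaflets(t), cfg)
            return est

        a = run(20, 51)
        b = run(40, 52)
        assert b.n_crossings > a.n_crossings  # more solutes, more events
        assert 0.5 < b.pm_cm_s / a.pm_cm_s < 2.0


class TestCrossingEvent:
    def test_validation(self):
        with pytest.raises(ValueError):
            CrossingEvent(0, 5, 5, "up")
        with pytest.raises(ValueError):
            CrossingEvent(0, 1, 5, "sideways")
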