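"""Leaf morphogenesis and nutritive-value model."""

import numpy as np
import pytest

from pasture import (
    apparent_dmd_from_invitro,
    derive_ryegrass,
    generate_weather,
    init_tiller,
    nutritive_value,
    simulate_mdp,
    step_tiller,
)
from pasture.mdp import MDPParameters


class TestSpeciesParameters:
    def test_ryegrass_satisfies_all_four_derivations(self, fescue, ryegrass):
        """Lifespan 630->330 degC d, two-fold rates, NDF -5, NDFD +20."""
        assert fescue.leaf_lifespan == 630.0
        assert ryegrass.leaf_lifespan == 330.0
        assert ryegrass.phyllochron == pytest.approx(fescue.phyllochron / 2.0)
        assert ryegrass.leaf_elongation_rate == pytest.approx(2.0 * fescue.leaf_elongation_rate)
        assert ryegrass.ndf_min == pytest.approx(fescue.ndf_min - 5.0)
        assert ryegrass.ndfd_max == pytest.approx(fescue.ndfd_max + 20.0)
        derived = derive_ryegrass(fescue)
        for attr in ("leaf_lifespan", "phyllochron", "leaf_elongation_rate", "ndf_min", "ndfd_max"):
            assert getattr(derived, attr) == getattr(ryegrass, attr)

    def test_metabolic_factor_is_printed_constant(self, fescue, ryegrass):
        assert fescue.metabolic_factor == 119.0
        assert ryegrass.metabolic_factor == 119.0

    def test_invalid_parameter_combinations_rejected(self, fescue):
        with pytest.raises(ValueError, match="lifespan"):
            MDPParameters(
                species="x",
                phyllochron=300.0,
                leaf_elongation_rate=0.1,
                leaf_lifespan=200.0,
                ndf_min=45.0,
                ndf_max=65.0,
                ndfd_max=70.0,
                ndfd_min=35.0,
            )


class TestStepTiller:
    def test_zero_delta_is_identity(self, fescue):
        t = init_tiller(fescue)
        t2 = step_tiller(t, 0.0, fescue)
        assert t2.thermal_time == t.thermal_time
        assert len(t2.leaves) == len(t.leaves)
        assert t2.leaf_stage(fescue) == t.leaf_stage(fescue)

    def test_negative_delta_rejected(self, fescue):
        with pytest.raises(ValueError, match="non-negative"):
            step_tiller(init_tiller(fescue), -1.0, fescue)

    def test_second_leaf_initiated_at_one_phyllochron(self, fescue):
        t = init_tiller(fescue)
        before = step_tiller(t, fescue.phyllochron - 1e-6, fescue)
        after = step_tiller(t, fescue.phyllochron, fescue)
        assert len(before.live_leaves(fescue)) == 1
        assert len(after.live_leaves(fescue)) == 2

    def test_elongation_stops_at_duration(self, fescue):
        duration = fescue.elongation_duration()
        t = step_tiller(init_tiller(fescue), duration + 50.0, fescue)
        first = min(t.leaves, key=lambda lf: lf.appeared_tt)
        assert first.length == pytest.approx(fescue.leaf_elongation_rate * duration)

    def test_ryegrass_produces_twice_the_leaves(self, fescue, ryegrass):
        tf = step_tiller(init_tiller(fescue), 600.0, fescue)
        tr = step_tiller(init_tiller(ryegrass), 600.0, ryegrass)
        assert len(tr.leaves) == 2 * len(tf.leaves)

    def test_no_senescence_within_short_grazing_interval(self, ryegrass):
        """A grazing interval shorter than the lifespan loses no leaf."""
        t = init_tiller(ryegrass)
        t = step_tiller(t, ryegrass.leaf_lifespan - 5.0, ryegrass)
        statuses = [
            lf.status(t.thermal_time, ryegrass.leaf_lifespan, t.elongation_duration)
            for lf in t.leaves
            if not lf.cut
        ]
        assert "senescent" not in statuses

    def test_leaf_stage_monotone_then_plateau(self, ryegrass, constant_weather):
        weather = generate_weather(60, "constant", seed=0)
        traj = simulate_mdp(6.0, weather, ryegrass)
        stage = traj["leaf_stage"].to_numpy()
        tt = traj["thermal_time"].to_numpy()
        pre = stage[tt <= ryegrass.leaf_lifespan]
        assert np.all(np.diff(pre) >= -1e-9)
        cap = ryegrass.live_leaf_cap
        assert np.all(stage[tt > ryegrass.leaf_lifespan] >= cap - 1.1)
        assert np.all(stage <= np.ceil(cap) + 1.0)


class TestNutritiveValue:
    def test_young_sward_at_quality_bounds(self, fescue):
        t = init_tiller(fescue)  # one just-initiated leaf, age 0
        nv = nutritive_value(t, fescue)
        assert nv.ndf == pytest.approx(fescue.ndf_min)
        assert nv.ndfd == pytest.approx(fescue.ndfd_max)

    def test_aged_sward_at_opposite_bounds(self, fescue):
        from pasture.mdp import Leaf, TillerState

        old = TillerState(
            thermal_time=fescue.leaf_lifespan,
            leaves=[Leaf(appeared_tt=0.0, length=40.0)],
            next_appearance_tt=1e9,
            elongation_duration=fescue.elongation_duration(),
        )
        nv = nutritive_value(old, fescue)
        assert nv.ndf == pytest.approx(fescue.ndf_max)
        assert nv.ndfd == pytest.approx(fescue.ndfd_min)

    def test_dmd_combination_rule(self, fescue):
        t = step_tiller(init_tiller(fescue), 150.0, fescue)
        nv = nutritive_value(t, fescue)
        expected = (100.0 - nv.ndf) + nv.ndf * nv.ndfd / 100.0 - fescue.metabolic_factor / 10.0
        assert nv.dmd == pytest.approx(np.clip(expected, 0, 100))

    def test_values_always_within_bounds(self, ryegrass):
        weather = generate_weather(80, "summer", seed=3)
        traj = simulate_mdp(6.0, weather, ryegrass)
        for col in ("ndf", "ndfd", "dmd"):
            assert traj[col].between(0.0, 100.0).all()
        assert traj["ndf"].between(ryegrass.ndf_min, ryegrass.ndf_max).all()


class TestSimulateMdp:
    def test_zero_thermal_time_no_change(self, fescue):
        from pasture import WeatherSeries

        frozen = generate_weather(10, "constant", seed=0).frame.assign(tmin=-2.0, tmax=6.0)
        traj = simulate_mdp(6.0, WeatherSeries(frozen), fescue)  # tmean 2 < t_base 4
        assert traj["thermal_time"].nunique() == 1
        assert traj["leaf_stage"].nunique() == 1
        assert traj["dmd"].nunique() == 1

    def test_lower_residual_shorter_leaves_higher_dmd(self, fescue, constant_weather):
        trajs = {h: simulate_mdp(h, constant_weather, fescue) for h in (3.0, 6.0, 12.0)}
        l3, l6, l12 = (trajs[h]["leaf_length_cm"].to_numpy() for h in (3.0, 6.0, 12.0))
        d3, d6, d12 = (trajs[h]["dmd"].to_numpy() for h in (3.0, 6.0, 12.0))
        assert np.all(l3 <= l6) and np.all(l6 <= l12)
        assert np.all(d3 >= d6) and np.all(d6 >= d12)
        assert d3.mean() > d6.mean() > d12.mean()

    def test_dmd_declines_after_canopy_establishment(self, fescue, constant_weather):
        traj = simulate_mdp(6.0, constant_weather, fescue)
        dmd = traj["dmd"].to_numpy()
        peak = int(np.argmax(dmd))
        assert peak < len(dmd) - 5
        assert np.all(np.diff(dmd[peak:]) <= 1e-9)

    def test_rejects_bad_inputs(self, fescue, constant_weather):
        with pytest.raises(ValueError, match="residual height"):
            simulate_mdp(0.0, constant_weather, fescue)


class TestInVitroDigestibility:
    @pytest.mark.parametrize(
        "dm, ndf_inc, ndf_res, ndfd, true_dmd",
        [
            (1.0, 0.5, 0.2, 60.0, 80.0),
            (1.0, 0.5, 0.0, 100.0, 100.0),
            (1.0, 0.5, 0.5, 0.0, 50.0),
        ],
    )
    def test_printed_formulas(self, dm, ndf_inc, ndf_res, ndfd, true_dmd):
        out = apparent_dmd_from_invitro(dm, ndf_inc, ndf_res)
        assert out["ndfd"] == pytest.approx(ndfd)
        assert out["true_dmd"] == pytest.approx(true_dmd)
        assert out["apparent_dmd"] == pytest.approx(true_dmd - 11.9)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError, match="NDF"):
            apparent_dmd_from_invitro(1.0, 0.5, 0.6)
        with pytest.raises(ValueError, match="NDF"):
            apparent_dmd_from_invitro(0.4, 0.5, 0.2)
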