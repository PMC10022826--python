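import math

import pytest
from hypothesis import given, strategies as st

from formuqbd import sedem


def uniform_profile(radius: float) -> sedem.SedemProfile:
    """Profile whose 12 radii all equal ``radius`` (Ie/Ic/IH are coupled to
    the densities in a real record, so uniform profiles are built from
    radii directly)."""
    return sedem.profile_from_radii("uniform", {p: radius for p in sedem.PARAMETERS})


def make_consistent_record() -> sedem.PowderRecord:
    """A physically consistent, fully valid record."""
    return sedem.PowderRecord.from_measurements(
        "demo",
        bulk_density=0.55,
        tapped_density=0.72,
        cohesion_index=120.0,
        angle_of_repose=28.0,
        powder_flow_time=6.0,
        loss_on_drying=2.5,
        hygroscopicity=3.0,
        fines_fraction=12.0,
        homogeneity_index=0.012,
    )


class TestComputeRadius:
    def test_carr_index_midpoint(self):
        assert sedem.compute_radius("carr_index", 25.0) == pytest.approx(5.0)

    def test_hausner_ratio_ideal(self):
        assert sedem.compute_radius("hausner_ratio", 1.0) == pytest.approx(10.0)

    def test_cohesion_index_deficient(self):
        # 28.4 N / 20 = 1.42
        assert sedem.compute_radius("cohesion_index", 28.4) == pytest.approx(1.42)

    def test_angle_of_repose_deficient(self):
        # 10 - 39.9/5 = 2.02
        assert sedem.compute_radius("angle_of_repose", 39.9) == pytest.approx(2.02)

    def test_symbol_aliases(self):
        assert sedem.compute_radius("Icd", 28.4) == pytest.approx(1.42)

    def test_unknown_parameter(self):
        with pytest.raises(KeyError):
            sedem.compute_radius("not_a_parameter", 1.0)

    def test_non_finite_value(self):
        with pytest.raises(ValueError):
            sedem.compute_radius("carr_index", float("nan"))

    def test_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert sedem.compute_radius("carr_index", 80.0) == 10.0
        with pytest.warns(UserWarning):
            assert sedem.compute_radius("loss_on_drying", 50.0) == 0.0


INCREASING = [
    "bulk_density", "tapped_density", "interparticle_porosity",
    "carr_index", "cohesion_index", "homogeneity_index",
]
DECREASING = [
    "hausner_ratio", "angle_of_repose", "powder_flow_time",
    "loss_on_drying", "hygroscopicity", "fines_fraction",
]


@given(
    v1=st.floats(0.001, 50.0),
    v2=st.floats(0.001, 50.0),
)
def test_monotone_directions(v1, v2):
    lo, hi = sorted((v1, v2))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid in INCREASING:
            assert sedem.compute_radius(pid, lo) <= sedem.compute_radius(pid, hi)
        for pid in DECREASING:
            assert sedem.compute_radius(pid, lo) >= sedem.compute_radius(pid, hi)


@given(v=st.floats(-100.0, 100.0), pid=st.sampled_from(sedem.PARAMETERS))
def test_clamping_always_in_range(v, pid):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = sedem.compute_radius(pid, v)
    assert 0.0 <= r <= 10.0


@given(r=st.floats(0.01, 9.99), pid=st.sampled_from(sedem.PARAMETERS))
def test_round_trip_inverse(r, pid):
    v = sedem.invert_radius(pid, r)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert sedem.compute_radius(pid, v) == pytest.approx(r, abs=1e-9)


class TestBuildProfile:
    @pytest.mark.parametrize(
        "radius, ipp, ip, igc",
        [
            (10.0, 10.0, 1.0, 9.52),
            (5.0, 5.0, 1.0, 4.76),
            (0.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_uniform_profiles(self, radius, ipp, ip, igc):
        prof = uniform_profile(radius)
        assert prof.parameter_profile_index == pytest.approx(ipp, abs=1e-9)
        assert prof.parameter_index == pytest.approx(ip)
        assert prof.good_compression_index == pytest.approx(igc, abs=1e-9)

    def test_igc_equals_ipp_times_f(self):
        prof = sedem.build_profile(make_consistent_record())
        assert prof.good_compression_index <= prof.parameter_profile_index
        assert prof.good_compression_index == pytest.approx(
            prof.parameter_profile_index * prof.reliability_factor
        )

    def test_all_fives_fails_criterion(self):
        # IGC of the uniform-5 profile is below 5, which is what motivates
        # the reliability factor
        prof = uniform_profile(5.0)
        assert prof.good_compression_index < 5.0
        assert not prof.suitable_for_direct_compression

    def test_incidence_grouping(self):
        prof = uniform_profile(6.0)
        assert set(prof.incidence_means) == {
            "dimensions", "compressibility", "flowability",
            "lubricity_stability", "lubricity_dosage",
        }
        for mean in prof.incidence_means.values():
            assert mean == pytest.approx(6.0, abs=1e-9)

    def test_record_radii_match_direct_computation(self):
        record = make_consistent_record()
        prof = sedem.build_profile(record)
        for pid in sedem.PARAMETERS:
            assert prof.radii[pid] == pytest.approx(
                sedem.compute_radius(pid, getattr(record, pid))
            )

    def test_record_invariant_validation(self):
        with pytest.raises(ValueError, match="tapped"):
            sedem.PowderRecord(
                "bad", bulk_density=0.8, tapped_density=0.5,
                interparticle_porosity=0.1, carr_index=10, cohesion_index=100,
                hausner_ratio=1.1, angle_of_repose=30, powder_flow_time=5,
                loss_on_drying=2, hygroscopicity=2, fines_fraction=10,
                homogeneity_index=0.01,
            )
        with pytest.raises(ValueError, match="inconsistent"):
            sedem.PowderRecord(
                "bad", bulk_density=0.5, tapped_density=0.8,
                interparticle_porosity=0.9, carr_index=37.5, cohesion_index=100,
                hausner_ratio=1.6, angle_of_repose=30, powder_flow_time=5,
                loss_on_drying=2, hygroscopicity=2, fines_fraction=10,
                homogeneity_index=0.01,
            )


class TestCorrectionPercentage:
    def test_already_at_target(self):
        q = sedem.CorrectionQuery(RE=10.0, RP=5.0, R=5.0)
        assert sedem.correction_percentage(q) == pytest.approx(0.0)

    def test_deficient_cohesion(self):
        q = sedem.CorrectionQuery(RE=10.0, RP=1.42, R=5.0)
        # 100 - (5 / 8.58) * 100
        assert sedem.correction_percentage(q) == pytest.approx(41.72, abs=0.005)

    def test_midpoint(self):
        q = sedem.CorrectionQuery(RE=6.0, RP=4.0, R=5.0)
        assert sedem.correction_percentage(q) == pytest.approx(50.0)

    def test_infeasible(self):
        with pytest.raises(sedem.InfeasibleCorrectionError):
            sedem.CorrectionQuery(RE=3.0, RP=4.0, R=5.0)

    def test_target_unreachable_warns(self):
        q = sedem.CorrectionQuery(RE=5.0, RP=2.0, R=5.0)
        with pytest.warns(UserWarning):
            assert sedem.correction_percentage(q) == 100.0


class TestRadarPolygon:
    def test_structure(self):
        prof = uniform_profile(10.0)
        verts = sedem.radar_polygon(prof)
        assert len(verts) == 12
        angles = [a for a, _ in verts]
        assert len(set(angles)) == 12
        assert all(r == pytest.approx(10.0) for _, r in verts)
        # equal 30-degree spacing
        diffs = {round((angles[i] - angles[i + 1]) % 360, 6) for i in range(11)}
        assert diffs == {30.0}

    def test_order_preserved(self):
        prof = sedem.build_profile(make_consistent_record())
        verts = sedem.radar_polygon(prof)
        assert [r for _, r in verts] == [prof.radii[p] for p in sedem.PARAMETERS]
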