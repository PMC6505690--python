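"""Rib metrics: inflection counting, ICM, census, cohort summaries."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad

from spinemorph.geometry import GeometryError, Polyline3
from spinemorph.ribs import (
    Rib,
    cohort_rib_summary,
    count_inflections,
    rib_census,
    rib_metrics,
)
from spinemorph.simulate import RibSpec, default_config, generate_specimen
from spinemorph.specimen import Specimen
from tests.conftest import make_straight_spine


def sine_polyline(periods=2.0, n=500, amplitude=1.0):
    x = np.linspace(0, 2 * np.pi * periods, n)
    return Polyline3(np.column_stack([x, amplitude * np.sin(x), np.zeros_like(x)]))


def straight_rib(length=2.7, side="left", index=5):
    pts = np.column_stack([np.zeros(10), np.zeros(10), np.linspace(0, length, 10)])
    return Rib(side=side, index=index, centerline=Polyline3(pts))


def _signed_curvature_sign_changes(poly):
    """Independent planar oracle: sign changes of x'y'' - y'x''."""
    p = poly.points
    d1 = (p[2:] - p[:-2]) / 2
    d2 = p[2:] - 2 * p[1:-1] + p[:-2]
    s = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    s = s[np.abs(s) > 1e-8 * np.max(np.abs(s))]
    return int(np.count_nonzero(np.diff(np.sign(s)) != 0))


class TestInflectionCount:
    def test_straight_segment_has_none(self):
        assert count_inflections(straight_rib().centerline) == 0

    def test_two_period_sine_has_three(self):
        poly = sine_polyline(periods=2.0)
        assert count_inflections(poly) == 3
        assert _signed_curvature_sign_changes(poly) == 3

    def test_matches_signed_curvature_oracle_on_planar_waves(self):
        for periods in (1.0, 1.5, 3.0):
            poly = sine_polyline(periods=periods)
            assert count_inflections(poly) == _signed_curvature_sign_changes(poly)

    def test_helix_normal_rotates_without_flipping(self):
        t = np.linspace(0, 4 * np.pi, 400)
        poly = Polyline3(np.column_stack([np.cos(t), np.sin(t), 0.3 * t]))
        assert count_inflections(poly) == 0

    def test_semicircle_single_smooth_curve(self):
        t = np.linspace(0, np.pi, 300)
        poly = Polyline3(np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)]))
        assert count_inflections(poly) == 0


class TestRibMetrics:
    def test_straight_rib(self):
        m = rib_metrics(straight_rib(length=2.7))
        assert m.L_C == pytest.approx(2.7)
        assert m.L_S == pytest.approx(2.7)
        assert m.N == 0
        assert m.ICM == 0.0

    def test_sine_icm_matches_quadrature_oracle(self):
        arc, _ = quad(lambda x: np.sqrt(1 + np.cos(x) ** 2), 0, 4 * np.pi)
        expected = 3 * arc / (4 * np.pi)  # ~3.648
        rib = Rib("left", 5, centerline=sine_polyline(periods=2.0))
        m = rib_metrics(rib)
        assert m.N == 3
        assert m.ICM == pytest.approx(expected, rel=0.01)

    def test_semicircle_ratio_without_inflection(self):
        t = np.linspace(0, np.pi, 400)
        rib = Rib("left", 5, centerline=Polyline3(
            np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])))
        m = rib_metrics(rib)
        assert m.N == 0 and m.ICM == 0.0
        assert m.L_C / m.L_S == pytest.approx(np.pi / 2, rel=1e-4)

    def test_icm_scale_invariance(self):
        rib = Rib("left", 5, centerline=sine_polyline(periods=2.0))
        m1 = rib_metrics(rib)
        scaled = Rib("left", 5, centerline=Polyline3(rib.centerline.points * 37.0))
        m2 = rib_metrics(scaled)
        assert m2.ICM == pytest.approx(m1.ICM, rel=1e-6)
        assert m2.L_C == pytest.approx(37.0 * m1.L_C, rel=1e-9)

    def test_resolution_robustness_on_generator_ribs(self):
        # smooth wavy ribs with all inflection crossings well interior
        # (wavelength 0.9 mm on a 2.7 mm rib: zeros at <= 83 % arc fraction)
        base = dataclasses.replace(default_config(9, "control"), noise_sd_mm=0.0)
        for amp in (0.05, 0.1, 0.15):
            plan = tuple(
                dataclasses.replace(r, waviness_amplitude_mm=amp,
                                    waviness_wavelength_mm=0.9)
                for r in base.rib_plan
                if (r.side, r.index) == ("left", 5)
            )
            spec = generate_specimen(dataclasses.replace(base, rib_plan=plan), seed=2)
            rib = spec.ribs[0]
            m100 = rib_metrics(rib, n_resample=100)
            m400 = rib_metrics(rib, n_resample=400)
            assert m100.N == m400.N > 0
            assert m400.ICM == pytest.approx(m100.ICM, rel=0.02)

    def test_absent_rib_rejected(self):
        with pytest.raises(ValueError, match="rib absent"):
            rib_metrics(Rib("left", 5, centerline=None))

    def test_degenerate_chord_rejected(self):
        t = np.linspace(0, 2 * np.pi, 100)
        loop = Polyline3(np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)]))
        with pytest.raises(GeometryError, match="degenerate chord"):
            rib_metrics(Rib("left", 5, centerline=loop))


class TestCensus:
    def _specimen(self, missing=(), sid="s"):
        ribs = []
        for side in ("left", "right"):
            for i in range(1, 8):
                if (side, i) in missing:
                    continue
                rib = straight_rib(side=side, index=i)
                shifted = rib.centerline.points + [0.0, -0.5 * i, 0.0]
                rib.centerline = Polyline3(shifted)
                ribs.append(rib)
        return Specimen(spine=make_straight_spine(specimen_id=sid), ribs=ribs)

    def test_full_rib_cage(self):
        census = rib_census(self._specimen())
        assert not census.has_absent
        assert not census.has_fused

    def test_missing_rib_flags_specimen(self):
        census = rib_census(self._specimen(missing=[("left", 3)]))
        assert census.has_absent
        assert not census.presence[("left", 3)]

    def test_sustained_contact_called_fused(self):
        spec = self._specimen()
        # drop rib (left, 4) onto (left, 3): identical centerlines touch everywhere
        for rib in spec.ribs:
            if (rib.side, rib.index) == ("left", 4):
                donor = next(r for r in spec.ribs if (r.side, r.index) == ("left", 3))
                rib.centerline = Polyline3(donor.centerline.points + 1e-4)
        census = rib_census(spec)
        assert (("left", 3), ("left", 4)) in census.fused_pairs

    def test_separated_ribs_not_fused(self):
        spec = self._specimen()
        census = rib_census(spec)  # straight ribs share geometry but same origin...
        # move each rib to its own y offset to guarantee > threshold separation
        for k, rib in enumerate(spec.ribs):
            rib.centerline = Polyline3(rib.centerline.points + [0.0, 0.4 * k, 0.0])
        census = rib_census(spec)
        assert not census.has_fused


class TestCohortSummary:
    def test_identical_straight_ribs(self):
        specs = [
            Specimen(spine=make_straight_spine(specimen_id=f"s{i}", group="Im5"),
                     ribs=[straight_rib(length=1.7)])
            for i in range(4)
        ]
        out = cohort_rib_summary(specs)
        row = out.iloc[0]
        assert row["L_C_mean_mm"] == pytest.approx(1.7)
        assert row["L_C_sd_mm"] == pytest.approx(0.0, abs=1e-12)

    def test_single_specimen_sd_missing(self):
        specs = [Specimen(spine=make_straight_spine(specimen_id="solo"),
                          ribs=[straight_rib()])]
        out = cohort_rib_summary(specs)
        assert np.isnan(out.iloc[0]["L_C_sd_mm"])

    def test_absent_reference_rib_excluded_from_means(self):
        present = Specimen(spine=make_straight_spine(specimen_id="a"),
                           ribs=[straight_rib(length=2.0)])
        absent = Specimen(spine=make_straight_spine(specimen_id="b"),
                          ribs=[straight_rib(length=9.9, index=4)])
        with pytest.warns(UserWarning, match="reference rib"):
            out = cohort_rib_summary([present, absent])
        row = out.iloc[0]
        assert row["L_C_mean_mm"] == pytest.approx(2.0)
        assert row["prop_absent"] == pytest.approx(1.0)  # both lack some slot

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_rib_summary([])
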