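import numpy as np
import pytest

from potmorph.errors import (DegenerateInputError, DomainError, ValidationError)
from potmorph.profile_io import (CalibratedProfile, RawProfile, TrialRecord,
                                 calibrate, close_outline, percent_time,
                                 read_trials, resample_profile, smooth_profile,
                                 vessel_dimensions, write_trials)
from potmorph.synthetic_data import GeneratorConfig, generate_study


def make_profile(x, y):
    return CalibratedProfile(points=np.column_stack([np.asarray(x, float),
                                                     np.asarray(y, float)]))


def make_outline_trial(times, **kw):
    prof = resample_profile(make_profile([0, 3, 3, 0], [10, 7, 2, 0]), 64)
    outs = [close_outline(prof, gesture_index=i, elapsed_time=t)
            for i, t in enumerate(times)]
    defaults = dict(potter_id="PR1", community="PR", vessel_type="vase",
                    clay_mass_kg=2.25, trial_number=1)
    defaults.update(kw)
    return TrialRecord(outlines=outs, **defaults)


class TestCalibrate:
    def test_scales_coordinates(self):
        raw = RawProfile(points=[[100, 200], [50, 100], [0, 0]],
                         gesture_index=0, elapsed_time=0.0)
        cal = calibrate(raw, 0.05)
        assert np.allclose(cal.points[0], [5.0, 10.0])
        ident = calibrate(raw, 1.0)
        assert np.array_equal(ident.points, raw.points)

    @pytest.mark.parametrize("factor", [-1.0, 0.0])
    def test_nonpositive_factor_rejected(self, factor):
        raw = RawProfile(points=[[1, 1], [1, 2], [0, 3]], gesture_index=0,
                         elapsed_time=0.0)
        with pytest.raises(DomainError):
            calibrate(raw, factor)


class TestResample:
    def test_vertical_line(self):
        out = resample_profile(make_profile([3, 3], [0, 10]), 5)
        assert np.allclose(out.points[:, 0], 3.0)
        assert np.allclose(out.points[:, 1], [0, 2.5, 5, 7.5, 10])

    def test_default_length_is_256(self):
        out = resample_profile(make_profile([0, 1, 2, 1, 0.5],
                                            [0, 2, 5, 8, 10]))
        assert out.n_points == 256

    def test_semicircular_bowl_against_closed_form(self):
        # dome of radius R sampled densely along the arc, resampled onto the
        # regular vertical grid; compare against the circle equation
        R = 7.0
        th = np.linspace(0.0, np.pi / 2, 1000)
        prof = make_profile(R * np.cos(th), R * np.sin(th))
        res = resample_profile(prof, 256)
        x_true = np.sqrt(np.maximum(R**2 - res.points[:, 1] ** 2, 0.0))
        assert np.max(np.abs(res.points[:, 0] - x_true)) < 1e-3 * R

    def test_idempotent(self, rng):
        y = np.sort(rng.uniform(0, 10, 40))
        y[0], y[-1] = 0.0, 10.0
        prof = make_profile(rng.uniform(0, 5, 40), y)
        once = resample_profile(prof, 128)
        twice = resample_profile(once, 128)
        assert np.max(np.abs(once.points - twice.points)) < 1e-12

    def test_overhanging_profile_uses_arclength(self):
        # necked shape: y not monotone along the digitized wall
        prof = make_profile([1, 3, 2.5, 1.5], [0, 4, 3.5, 8])
        res = resample_profile(prof, 64)
        assert res.parameterization == "arclength"
        assert res.n_points == 64

    def test_zero_height_rejected(self):
        with pytest.raises(DegenerateInputError):
            resample_profile(make_profile([0, 1, 2], [5, 5, 5]))


class TestSmooth:
    def test_constant_series_unchanged(self):
        prof = make_profile(np.full(100, 2.0), np.linspace(0, 10, 100))
        sm = smooth_profile(prof, 0.1)
        assert np.allclose(sm.points[:, 0], 2.0, atol=1e-9)
        assert np.array_equal(sm.points[:, 1], prof.points[:, 1])

    def test_high_frequency_attenuated(self):
        n = 512
        y = np.linspace(0, 10, n)
        base = 3 + 0.5 * np.sin(2 * np.pi * y / 10)
        hf = 0.2 * np.sin(2 * np.pi * 0.3 * np.arange(n))  # above cutoff 0.1
        sm = smooth_profile(make_profile(base + hf, y), 0.1)
        residual = sm.points[:, 0] - base
        # interior only: reflective padding keeps endpoints but edge effects
        # are not part of the attenuation claim
        core = slice(32, -32)
        assert np.abs(residual[core]).max() < 0.1 * 0.2

    @pytest.mark.parametrize("cutoff", [0.0, 0.5, 0.6, -0.1])
    def test_cutoff_domain(self, cutoff):
        prof = make_profile(np.ones(20), np.linspace(0, 1, 20))
        with pytest.raises(DomainError):
            smooth_profile(prof, cutoff)


class TestCloseOutline:
    def test_point_count_after_merge(self):
        prof = resample_profile(make_profile([0, 2, 3, 2, 0],
                                             [0, 2, 5, 8, 10]), 256)
        pts = prof.points.copy()
        pts[0, 0] = pts[-1, 0] = 0.0
        out = close_outline(CalibratedProfile(points=pts))
        assert out.n_distinct == 2 * 256 - 2
        assert np.allclose(out.points[0], out.points[-1])

    def test_mirror_symmetry_and_area(self):
        y = np.linspace(0, 10, 200)
        x = 2 + np.sin(y / 3)
        x[0] = x[-1] = 0.0
        out = close_outline(make_profile(x, y))
        # reflection about x = 0 maps the contour onto itself
        reflected = out.points[:-1] * np.array([-1.0, 1.0])
        dists = [np.min(np.hypot(*(out.points[:-1] - p).T)) for p in reflected]
        assert max(dists) < 1e-9
        # signed shoelace area = 2 x area between the half-profile and axis
        p = out.points
        area = 0.5 * abs(np.sum(p[:-1, 0] * p[1:, 1] - p[1:, 0] * p[:-1, 1]))
        half_area = abs(np.trapezoid(x, y))
        assert area == pytest.approx(2 * half_area, rel=1e-9)

    def test_negative_x_rejected(self):
        with pytest.raises(ValidationError):
            close_outline(make_profile([0, -1, 2], [0, 5, 10]))


class TestVesselDimensions:
    def test_rectangle_and_dome(self):
        assert vessel_dimensions(make_profile([5, 5], [0, 10])) == (10.0, 10.0)
        th = np.linspace(0, np.pi / 2, 500)
        dome = make_profile(7 * np.cos(th), 7 * np.sin(th))
        h, md = vessel_dimensions(dome)
        assert h == pytest.approx(7.0, abs=1e-9)
        assert md == pytest.approx(14.0, abs=1e-9)

    def test_generator_nominal_dimensions(self):
        from potmorph.synthetic_data import template_from_latent
        tmpl = template_from_latent([np.log(0.65), -0.15, 0.7, 0.25], 20.0)
        h_nom, md_nom = tmpl.nominal_dimensions()
        hh = np.linspace(0, 1, 256)
        prof = make_profile(tmpl.radius_at(hh), hh * tmpl.height_scale)
        h, md = vessel_dimensions(resample_profile(prof, 256))
        assert h == pytest.approx(h_nom, abs=0.05)
        assert md == pytest.approx(md_nom, abs=0.05)

    def test_invariant_under_smoothing(self):
        y = np.linspace(0, 12, 256)
        x = 4 + np.cos(y / 4)  # band-limited
        prof = make_profile(x, y)
        h0, md0 = vessel_dimensions(prof)
        h1, md1 = vessel_dimensions(smooth_profile(prof, 0.1))
        assert h1 == h0
        assert abs(md1 - md0) < 0.005 * h0


class TestPercentTime:
    @pytest.mark.parametrize("times,expected", [
        ((0, 5, 10), (0, 50, 100)),
        ((0, 100), (0, 100)),
        ((2, 4, 8), (0, 100 / 3, 100)),
    ])
    def test_linear_map(self, times, expected):
        trial = make_outline_trial(times)
        assert np.allclose(percent_time(trial), expected)

    def test_zero_duration_impossible_by_invariant(self):
        with pytest.raises(ValidationError):
            make_outline_trial((5, 5))


class TestTrialIO:
    @pytest.fixture(scope="class")
    def tiny_trials(self):
        cfg = GeneratorConfig(potters_per_community=(2, 2, 2),
                              trials_per_potter=2, gestures_range=(2, 3),
                              vessel_types=(("bowl", 0.75),),
                              n_profile_points=48, seed=7)
        return generate_study(cfg)

    def test_fixture_trial_count(self, tiny_trials):
        assert len(tiny_trials) == 3 * 2 * 2

    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_roundtrip_identity(self, tiny_trials, tmp_path, fmt):
        path = tmp_path / f"trials.{fmt}"
        write_trials(tiny_trials, path)
        back = read_trials(path, resample_n=None)
        assert len(back) == len(tiny_trials)
        orig = {t.key: t for t in tiny_trials}
        for t in back:
            o = orig[t.key]
            assert t.n_outlines == o.n_outlines
            for a, b in zip(t.outlines, o.outlines):
                assert np.allclose(a.points, b.points, atol=1e-9)
                assert a.elapsed_time == pytest.approx(b.elapsed_time)

    def test_decreasing_time_rejected(self, tiny_trials, tmp_path):
        import pandas as pd
        path = tmp_path / "bad.csv"
        write_trials(tiny_trials[:1], path)
        df = pd.read_csv(path)
        df.loc[df.gesture_index == df.gesture_index.max(), "elapsed_time_s"] = -1.0
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="strictly increasing"):
            read_trials(path)

    def test_missing_column_rejected(self, tiny_trials, tmp_path):
        import pandas as pd
        path = tmp_path / "bad.csv"
        write_trials(tiny_trials[:1], path)
        pd.read_csv(path).drop(columns=["community"]).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="community"):
            read_trials(path)

    def test_frozen_fixtures_load(self):
        from pathlib import Path
        data = Path(__file__).parent / "data"
        for name in ("fixture_null.csv", "fixture_community.csv",
                     "fixture_full.csv"):
            trials = read_trials(data / name)
            assert len(trials) == 12
            assert all(t.n_outlines >= 2 for t in trials)
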