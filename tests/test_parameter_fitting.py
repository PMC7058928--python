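"""Parameter recovery: exact at zero noise, bounded error under
flow-cytometry-like multiplicative noise."""

import numpy as np
import pytest

from norcad import (DoseResponsePoint, QuadrantData, fit_hill,
                    fit_interference, fit_timescales, generate_quadrants,
                    generate_sweep, generate_timecourse)
from norcad.errors import DataError
from norcad.gate_library import ReporterRecord, SensorRecord


def _levels(library):
    up = library.sensor("P_Tet")
    down = library.sensor("P_Tac")
    return {"upstream": (up.off_rpu, up.on_rpu),
            "downstream": (down.off_rpu, down.on_rpu)}


def _points(ds):
    return [DoseResponsePoint(r.x_rpu, r.y_rpu)
            for r in ds.observations.itertuples()]


def _quadrants(ds):
    return QuadrantData({(bool(r.upstream_on), bool(r.downstream_on)):
                         r.y_rpu for r in ds.observations.itertuples()})


class TestHillFit:
    def test_noise_free_recovery_within_1_percent(self, library):
        g = library.gate("P2-PhlF")
        res = fit_hill(_points(generate_sweep(g, noise_cv=0)))
        assert res.converged
        for name, truth in (("y_min", g.y_min), ("y_max", g.y_max),
                            ("K", g.K), ("n", g.n)):
            assert res.estimates[name] == pytest.approx(truth, rel=0.01)

    def test_constant_output_flagged_non_identifiable(self):
        pts = [DoseResponsePoint(x, 1.0) for x in (0.01, 0.1, 1, 2, 5)]
        assert not fit_hill(pts).converged

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            fit_hill([DoseResponsePoint(0.1, 1.0)] * 4)

    def test_equivariant_under_point_reordering(self, library):
        g = library.gate("S2-SrpR")
        pts = _points(generate_sweep(g, noise_cv=0.05, seed=3))
        a = fit_hill(pts)
        b = fit_hill(list(reversed(pts)))
        for k in a.estimates:
            assert a.estimates[k] == pytest.approx(b.estimates[k],
                                                   rel=1e-6)

    def test_median_K_error_under_noise(self, library):
        """5% CV, 18 points, 50 seeds: median relative K error < 15%."""
        g = library.gate("P2-PhlF")
        errs = []
        for seed in range(50):
            ds = generate_sweep(g, noise_cv=0.05, seed=seed)
            res = fit_hill(_points(ds), n_starts=4, seed=seed)
            errs.append(abs(res.estimates["K"] - g.K) / g.K)
        assert np.median(errs) < 0.15


class TestInterferenceFit:
    def test_noise_free_recovery(self, library):
        g = library.gate("P1-PhlF")
        lv = _levels(library)
        ds = generate_quadrants(None, g, 0.22, 0.06, lv)
        res = fit_interference(_quadrants(ds), None, g, lv)
        assert res.estimates["alpha"] == pytest.approx(0.22, abs=1e-6)
        assert res.estimates["beta"] == pytest.approx(0.06, abs=1e-6)

    def test_additive_data_pins_estimates_at_unity(self, library):
        g = library.gate("P1-PhlF")
        lv = _levels(library)
        ds = generate_quadrants(None, g, 1.0, 1.0, lv)
        res = fit_interference(_quadrants(ds), None, g, lv)
        assert res.estimates["alpha"] == pytest.approx(1.0, abs=1e-6)
        assert res.constraint_active["alpha"]
        assert res.constraint_active["beta"]

    def test_estimates_never_exceed_one(self, library):
        """Adversarial data favoring amplification still respects the cap."""
        g = library.gate("P1-PhlF")
        lv = _levels(library)
        ds = generate_quadrants(None, g, 1.0, 1.0, lv)
        boosted = QuadrantData({k: 3.0 * v
                                for k, v in _quadrants(ds).observations
                                .items()})
        res = fit_interference(boosted, None, g, lv)
        assert res.estimates["alpha"] <= 1.0
        assert res.estimates["beta"] <= 1.0

    def test_median_alpha_error_under_noise_informative_design(self,
                                                               library):
        """5% CV quadrants, 50 seeds, on a low-background gate (small
        y_max), where the upstream term is not swamped in the
        upstream-ON/downstream-OFF observation: median |alpha error|
        stays below 0.1."""
        g = library.gate("B1-BM3R1")
        lv = _levels(library)
        errs = []
        for seed in range(50):
            ds = generate_quadrants(None, g, g.alpha, g.beta, lv,
                                    noise_cv=0.05, seed=seed)
            res = fit_interference(_quadrants(ds), None, g, lv)
            errs.append(abs(res.estimates["alpha"] - g.alpha))
        assert np.median(errs) < 0.1

    def test_missing_quadrant_rejected(self):
        with pytest.raises(DataError):
            QuadrantData({(False, False): 1.0, (True, True): 2.0})


class TestTimescaleFit:
    def _context(self, library, gate):
        return {"gate": gate,
                "sensor": SensorRecord("P_in", "P_in", 0.02, 2.0,
                                       tau_induction=1.0),
                "reporter": library.reporter}

    def test_noise_free_recovery_within_1_percent(self, library):
        g = library.gate("P1-PhlF")
        ds = generate_timecourse(g, "on_to_off", noise_cv=0)
        pts = list(zip(ds.observations.time_h, ds.observations.y))
        res = fit_timescales(pts, "on_to_off", self._context(library, g))
        assert res.estimates["tau_off"] == pytest.approx(4.0, rel=0.01)

    def test_off_to_on_direction(self, library):
        g = library.gate("P1-PhlF")
        ds = generate_timecourse(g, "off_to_on", noise_cv=0)
        pts = list(zip(ds.observations.time_h, ds.observations.y))
        res = fit_timescales(pts, "off_to_on", self._context(library, g))
        assert res.estimates["tau_on"] == pytest.approx(0.30, rel=0.01)

    def test_flat_trace_flagged(self, library):
        g = library.gate("P1-PhlF")
        pts = [(t, 1.0) for t in np.linspace(0, 8, 9)]
        res = fit_timescales(pts, "on_to_off", self._context(library, g))
        assert not res.converged

    def test_scale_invariance(self, library):
        g = library.gate("V1-VanR")
        ds = generate_timecourse(g, "on_to_off", noise_cv=0.02, seed=9)
        pts = list(zip(ds.observations.time_h, ds.observations.y))
        scaled = [(t, 100.0 * y) for t, y in pts]
        a = fit_timescales(pts, "on_to_off", self._context(library, g))
        b = fit_timescales(scaled, "on_to_off", self._context(library, g))
        assert a.estimates["tau_off"] == pytest.approx(
            b.estimates["tau_off"], rel=1e-5)


class TestGenerators:
    def test_zero_noise_sweep_lies_on_hill_curve(self, library):
        from norcad import hill_response
        g = library.gate("B1-BM3R1")
        ds = generate_sweep(g, noise_cv=0)
        for r in ds.observations.itertuples():
            assert r.y_rpu == pytest.approx(hill_response(g, r.x_rpu),
                                            rel=1e-12)

    def test_default_sweep_has_18_points(self, library):
        assert len(generate_sweep(library.gates[0]).observations) == 18

    def test_seed_reproducibility_is_byte_exact(self, library):
        g = library.gate("C1-CymR")
        a = generate_sweep(g, noise_cv=0.1, seed=7).to_tsv()
        b = generate_sweep(g, noise_cv=0.1, seed=7).to_tsv()
        c = generate_sweep(g, noise_cv=0.1, seed=8).to_tsv()
        assert a == b
        assert a != c
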