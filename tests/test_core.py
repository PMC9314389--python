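import math

import numpy as np
import pytest

import quollscr as q
from quollscr.exceptions import MaskError, ParameterError

from brute_scr import brute_loglik

ALL_CODES = ["0", "b", "bk", "B", "Bk", "T"]


class TestHalfNormal:
    def test_zero_distance_returns_g0(self):
        assert q.halfnormal_p(0.0, 0.1, 300.0) == pytest.approx(0.1)

    def test_at_one_sigma(self):
        assert q.halfnormal_p(300.0, 0.1, 300.0) == pytest.approx(
            0.1 * math.exp(-0.5), rel=1e-12
        )

    def test_far_tail_vanishes(self):
        assert q.halfnormal_p(3000.0, 0.1, 300.0) < 1e-21 * 0.1

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ParameterError):
            q.halfnormal_p(100.0, 0.1, 0.0)

    def test_monotone_decreasing_in_distance(self):
        d = np.linspace(0, 5000, 200)
        p = q.halfnormal_p(d, 0.2, 400.0)
        assert np.all(np.diff(p) < 0)


class TestMask:
    def test_single_detector_disc(self):
        det = q.DetectorArray(["o"], [(0.0, 0.0)])
        mask = q.build_mask(det, buffer=100.0, spacing=50.0)
        # brute-force check: every grid point of the covering lattice is
        # included iff within the disc
        xs = np.arange(-100 + 25, 100, 50.0)
        expected = {
            (x, y) for x in xs for y in xs if math.hypot(x, y) <= 100.0
        }
        got = {(round(x, 6), round(y, 6)) for x, y in mask.points}
        assert got == expected

    def test_point_beyond_buffer_excluded(self, pair_detectors):
        mask = q.build_mask(pair_detectors, buffer=400.0, spacing=100.0)
        d = mask.distances_to(pair_detectors.xy).min(axis=0)
        assert d.max() <= 400.0 + 1e-9

    def test_every_detector_covered_by_mask(self, grid25):
        mask = q.build_mask(grid25, buffer=2000.0)
        d = mask.distances_to(grid25.xy).min(axis=1)
        assert d.max() <= mask.spacing  # a cell centre is always nearby

    def test_cell_area(self):
        det = q.DetectorArray(["o"], [(0.0, 0.0)])
        mask = q.build_mask(det, buffer=200.0, spacing=50.0)
        assert mask.cell_area_km2 == pytest.approx(0.0025)

    def test_spacing_coarser_than_buffer_rejected(self, pair_detectors):
        with pytest.raises(MaskError):
            q.build_mask(pair_detectors, buffer=100.0, spacing=150.0)


class TestBehaviourCovariate:
    @staticmethod
    def _single_detection_capthist(T=4, K=2):
        inc = np.zeros((1, T, K), dtype=int)
        inc[0, 0, 0] = 1  # one detection at occasion 1, detector 0
        return q.CaptHist(["q1"], [f"d{k}" for k in range(K)], inc)

    def test_site_specific_learned_response(self):
        ch = self._single_detection_capthist()
        cov = q.behaviour_covariate(ch, "bk")
        assert cov.z[0, 0, :].sum() == 0          # nothing before occasion 1
        assert np.all(cov.z[0, 1:, 0] == 1)       # detector of detection
        assert np.all(cov.z[0, 1:, 1] == 0)       # other detector unaffected

    def test_transient_response_only_previous_occasion(self):
        ch = self._single_detection_capthist()
        cov = q.behaviour_covariate(ch, "B")
        assert np.all(cov.z[0, 1, :] == 1)
        assert np.all(cov.z[0, 2:, :] == 0)

    def test_global_learned_response_persists(self):
        ch = self._single_detection_capthist()
        cov = q.behaviour_covariate(ch, "b")
        assert np.all(cov.z[0, 1:, :] == 1)

    def test_time_covariate_centred(self):
        ch = self._single_detection_capthist(T=5)
        cov = q.behaviour_covariate(ch, "T")
        assert cov.u.sum() == pytest.approx(0.0)
        assert cov.u[0] == pytest.approx((1 - 3.0) / 5)

    @pytest.mark.parametrize("code", ALL_CODES)
    def test_empty_capthist_all_zero(self, code):
        ch = q.CaptHist([], ["d0"], np.zeros((0, 3, 1), dtype=int))
        assert q.behaviour_covariate(ch, code).z.size == 0

    def test_unknown_code_rejected(self):
        with pytest.raises(ParameterError):
            q.behaviour_covariate(self._single_detection_capthist(), "h2")


def _tiny_instances():
    """Small instances (<= 2 individuals, <= 2 occasions, <= 3 detectors,
    <= 9 mask cells) for enumeration cross-checks."""
    det2 = q.DetectorArray(["a", "b"], [(0.0, 0.0), (300.0, 0.0)])
    det3 = q.DetectorArray(["a", "b", "c"], [(0.0, 0.0), (300.0, 0.0), (150.0, 250.0)])
    out = []
    inc = np.zeros((1, 2, 2), dtype=int); inc[0, 0, 0] = 1; inc[0, 1, 1] = 1
    out.append((q.CaptHist(["x"], ["a", "b"], inc), det2))
    inc = np.zeros((2, 2, 2), dtype=int)
    inc[0, 0, 0] = 1; inc[0, 1, 0] = 1; inc[1, 1, 1] = 1
    out.append((q.CaptHist(["x", "y"], ["a", "b"], inc), det2))
    inc = np.zeros((2, 2, 3), dtype=int)
    inc[0, 0, 0] = 1; inc[0, 0, 2] = 1; inc[1, 0, 1] = 1; inc[1, 1, 1] = 1
    out.append((q.CaptHist(["x", "y"], ["a", "b", "c"], inc), det3))
    out.append((q.CaptHist([], ["a", "b"], np.zeros((0, 2, 2), dtype=int)), det2))
    return out


class TestLikelihood:
    @pytest.mark.parametrize("code", ALL_CODES)
    @pytest.mark.parametrize("instance", range(4))
    def test_matches_enumeration_oracle(self, code, instance):
        ch, det = _tiny_instances()[instance]
        mask = q.build_mask(det, buffer=400.0, spacing=300.0)
        assert mask.n_points <= 9
        model = q.ScrModel(code=code, D=0.5, g0=0.12, sigma=250.0,
                           beta1=None if code == "0" else 0.9)
        got = q.scr_loglik(ch, det, mask, model)
        want = brute_loglik(ch, det, mask, model)
        assert got == pytest.approx(want, rel=1e-10)

    def test_empty_data_closed_form(self, pair_detectors, tiny_mask):
        ch = q.CaptHist([], ["a", "b"], np.zeros((0, 3, 2), dtype=int))
        model = q.ScrModel("0", D=0.5, g0=0.1, sigma=250.0)
        ll = q.scr_loglik(ch, pair_detectors, tiny_mask, model)
        # closed form: -Lambda with pdot over 3 occasions
        d = tiny_mask.distances_to(pair_detectors.xy)
        p = 0.1 * np.exp(-d ** 2 / (2 * 250.0 ** 2))
        pdot = 1 - np.prod((1 - p) ** 3, axis=0)
        lam = 0.5 * tiny_mask.cell_area_km2 * pdot.sum()
        assert ll == pytest.approx(-lam, rel=1e-12)

    def test_doubling_density_with_empty_data_costs_lambda(self, pair_detectors, tiny_mask):
        ch = q.CaptHist([], ["a", "b"], np.zeros((0, 3, 2), dtype=int))
        l1 = q.scr_loglik(ch, pair_detectors, tiny_mask, q.ScrModel("0", 0.5, 0.1, 250.0))
        l2 = q.scr_loglik(ch, pair_detectors, tiny_mask, q.ScrModel("0", 1.0, 0.1, 250.0))
        assert l2 - l1 == pytest.approx(l1, rel=1e-10)  # l2 = 2*l1 = l1 - lam

    @pytest.mark.parametrize("code", [c for c in ALL_CODES if c != "0"])
    def test_nesting_identity_at_beta1_zero(self, code, pair_detectors, tiny_mask):
        ch, det = _tiny_instances()[1]
        null = q.ScrModel("0", D=0.5, g0=0.12, sigma=250.0)
        nested = q.ScrModel(code, D=0.5, g0=0.12, sigma=250.0, beta1=0.0)
        mask = q.build_mask(det, buffer=400.0, spacing=300.0)
        assert q.scr_loglik(ch, det, mask, nested) == pytest.approx(
            q.scr_loglik(ch, det, mask, null), rel=1e-12
        )

    @pytest.mark.parametrize("which", ["g0", "sigma"])
    def test_pdot_monotone(self, which, pair_detectors, tiny_mask):
        # Lambda = -loglik(empty data) is D * a * sum pdot; monotone in g0 and sigma
        ch = q.CaptHist([], ["a", "b"], np.zeros((0, 3, 2), dtype=int))
        vals = np.linspace(0.02, 0.4, 8) if which == "g0" else np.linspace(100, 800, 8)
        lams = []
        for v in vals:
            m = q.ScrModel("0", 0.5, v if which == "g0" else 0.1,
                           v if which == "sigma" else 250.0)
            lams.append(-q.scr_loglik(ch, pair_detectors, tiny_mask, m))
        assert np.all(np.diff(lams) > 0)

    def test_invariance_under_translation_and_relabelling(self):
        ch, det = _tiny_instances()[1]
        mask = q.build_mask(det, buffer=400.0, spacing=120.0)
        model = q.ScrModel("bk", D=0.5, g0=0.12, sigma=250.0, beta1=0.7)
        base = q.scr_loglik(ch, det, mask, model)
        # rigid translation of detectors and mask
        shift = np.array([12345.0, -6789.0])
        det2 = q.DetectorArray(det.station_ids, det.xy + shift)
        mask2 = q.HabitatMask(points=mask.points + shift, spacing=mask.spacing,
                              buffer=mask.buffer)
        assert q.scr_loglik(ch, det2, mask2, model) == pytest.approx(base, rel=1e-12)
        # relabelling (reordering) of individuals
        ch2 = q.CaptHist(("y", "x"), ch.detector_ids, ch.incidence[::-1])
        assert q.scr_loglik(ch2, det, mask, model) == pytest.approx(base, rel=1e-12)

    def test_impossible_detection_gives_neg_inf(self, pair_detectors, tiny_mask):
        ch, det = _tiny_instances()[0]
        # smallest positive float: logit-scale baseline underflows to p = 0
        model = q.ScrModel("0", D=0.5, g0=5e-324, sigma=250.0)
        assert q.scr_loglik(ch, det, tiny_mask, model) == -np.inf

    def test_randomised_instances_match_oracle(self):
        rng = np.random.default_rng(42)
        det = q.DetectorArray(["a", "b", "c"],
                              [(0.0, 0.0), (350.0, 0.0), (175.0, 300.0)])
        mask = q.build_mask(det, buffer=350.0, spacing=300.0)
        assert mask.n_points <= 9
        for trial in range(10):
            code = ALL_CODES[trial % 6]
            n = int(rng.integers(1, 3))
            inc = (rng.random((n, 2, 3)) < 0.4).astype(int)
            inc[inc.reshape(n, -1).sum(axis=1) == 0, 0, 0] = 1
            ch = q.CaptHist([f"i{j}" for j in range(n)], det.station_ids, inc)
            model = q.ScrModel(code, D=float(rng.uniform(0.1, 2.0)),
                               g0=float(rng.uniform(0.02, 0.5)),
                               sigma=float(rng.uniform(120, 500)),
                               beta1=None if code == "0" else float(rng.normal(0, 1)))
            assert q.scr_loglik(ch, det, mask, model) == pytest.approx(
                brute_loglik(ch, det, mask, model), rel=1e-10
            )
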