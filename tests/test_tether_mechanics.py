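"""Worm-like-chain mechanics: inversions, force balance, conversions."""

import numpy as np
import pytest

from ribotrace.tether_mechanics import (DEFAULT_MODEL, WLCParams,
                                        aa_to_contour, contour_to_aa,
                                        detection_resolution,
                                        equilibrium_force, ewlc_extension,
                                        force_trace_to_aa, series_compliance,
                                        total_extension, wlc_extension,
                                        wlc_force)
from ribotrace.trace import ForceTrace

PROTEIN = WLCParams(persistence_length=0.6, contour_length=100.0)
KBT = 4.11


class TestWLCForce:
    def test_zero_extension_is_zero_force(self):
        assert wlc_force(0.0, PROTEIN, KBT) == 0.0

    def test_half_extension_marko_siggia_value(self):
        # (kBT/P) * [1/(4*(1-0.5)^2) - 1/4 + 0.5] = (4.11/0.6) * 1.25
        assert wlc_force(0.5, PROTEIN, KBT) == pytest.approx(8.5625, rel=1e-12)

    @pytest.mark.parametrize("bad", [1.0, 1.5, -0.1])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            wlc_force(bad, PROTEIN, KBT)

    def test_strictly_increasing_and_diverging(self):
        z = np.linspace(0.0, 0.999, 400)
        f = wlc_force(z, PROTEIN, KBT)
        assert np.all(np.diff(f) > 0)
        assert wlc_force(0.9999, PROTEIN, KBT) > 1e5 * wlc_force(0.5, PROTEIN, KBT) / 1e3

    def test_inversion_roundtrip_bijection(self):
        forces = np.linspace(0.1, 30.0, 60)
        for f in forces:
            x = wlc_extension(f, PROTEIN, KBT)
            back = wlc_force(x / PROTEIN.contour_length, PROTEIN, KBT)
            assert back == pytest.approx(f, rel=1e-9)


class TestEWLC:
    DNA = WLCParams(35.0, 1352.0, 1200.0)

    def test_zero_force_limit(self):
        assert ewlc_extension(1e-9, self.DNA, KBT) < 1e-3

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            ewlc_extension(-1.0, self.DNA, KBT)

    def test_infinite_stretch_modulus_matches_inextensible(self):
        stiff = WLCParams(35.0, 1352.0, 1e15)
        for f in (0.5, 2.0, 10.0, 25.0):
            assert ewlc_extension(f, stiff, KBT) == pytest.approx(
                wlc_extension(f, self.DNA, KBT), rel=1e-6)

    def test_dna_extension_at_10pN(self):
        # enthalpic eWLC with P=35 nm, S=1200 pN, L=1352 nm
        assert ewlc_extension(10.0, self.DNA, KBT) == pytest.approx(1290, abs=2)

    def test_can_exceed_contour_at_high_force(self):
        assert ewlc_extension(400.0, self.DNA, KBT) > self.DNA.contour_length


class TestContourConversion:
    def test_zero(self):
        assert aa_to_contour(0) == 0.0

    def test_one_aa(self):
        assert aa_to_contour(1) == pytest.approx(0.365)

    def test_full_unfolding_transition_size(self):
        # 177 aa unfold as a 65 +/- 2 nm contour change
        assert aa_to_contour(177) == pytest.approx(65.0, abs=2.0)

    def test_roundtrip_exact(self):
        assert contour_to_aa(aa_to_contour(10)) == 10.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            aa_to_contour(-1)
        with pytest.raises(ValueError):
            contour_to_aa(-0.5)


class TestEquilibriumForce:
    def test_zero_delta_is_identity(self, model):
        assert equilibrium_force(model, 4.5, 20.0, 0.0) == 4.5

    def test_adding_contour_decreases_force(self, model):
        ref = 4.0
        contours = aa_to_contour(np.arange(10, 200, 20).astype(float))
        forces = [equilibrium_force(model, ref, 40.0, dc) for dc in contours]
        assert all(f < ref for f in forces)
        assert np.all(np.diff(forces) < 0)

    def test_removing_contour_increases_force(self, model):
        f = equilibrium_force(model, 4.0, aa_to_contour(164),
                              -aa_to_contour(75))
        assert f > 4.0

    def test_one_aa_step_at_restart_stall(self, model):
        """+1 aa to the linker-only chain at 4.5 pN drops ~0.006 pN."""
        step = equilibrium_force(model, 4.5, aa_to_contour(37), 0.365) - 4.5
        assert step == pytest.approx(-0.006, abs=5e-4)

    def test_one_aa_step_late_in_translation(self, model):
        """+1 aa to a 224-aa chain at 3.5 pN drops ~0.003 pN."""
        step = equilibrium_force(model, 3.5, aa_to_contour(224), 0.365) - 3.5
        assert step == pytest.approx(-0.003, abs=5e-4)

    def test_compliance_additivity(self, model):
        """System stiffness equals the series combination (finite diff)."""
        contour = aa_to_contour(100)
        for f in (3.0, 4.5, 8.0):
            dF = 1e-5
            num = (total_extension(model, f + dF, contour)
                   - total_extension(model, f - dF, contour)) / (2 * dF)
            assert num == pytest.approx(series_compliance(model, f, contour),
                                        rel=1e-6)


class TestForceTraceToAA:
    def test_constant_force_maps_to_constant_aa(self, model):
        t = np.arange(2000) / 100.0
        trace = ForceTrace(t, np.full_like(t, 4.0), 100.0)
        aa = force_trace_to_aa(trace, model, endpoint_codon=200)
        assert np.nanstd(aa) < 1e-9
        # tabulated inversion matches the direct solve to well under 0.01 aa
        assert np.nanmax(aa) == pytest.approx(200, abs=1e-2)

    def test_nonpositive_forces_flagged_not_dropped(self, model):
        t = np.arange(2000) / 100.0
        f = np.full_like(t, 4.0)
        f[5] = -0.2
        aa = force_trace_to_aa(ForceTrace(t, f, 100.0), model, 200)
        assert aa.size == t.size
        assert np.isnan(aa[5]) and np.isfinite(aa[6])

    def test_monotone_force_drop_maps_to_monotone_aa_growth(self, model):
        t = np.arange(4000) / 100.0
        f = np.linspace(4.5, 4.0, t.size)
        aa = force_trace_to_aa(ForceTrace(t, f, 100.0), model, 200)
        assert np.all(np.diff(aa) >= 0)

    def test_folding_step_size_roundtrip(self, model):
        """A 75-aa sequestration at ~4 pN converts back to 75 +/- 5 aa."""
        f_unfolded = 4.0
        f_folded = equilibrium_force(model, f_unfolded, aa_to_contour(219),
                                     -aa_to_contour(75))
        t = np.arange(4000) / 100.0
        f = np.where(t < 20, f_folded, f_unfolded)
        aa = force_trace_to_aa(ForceTrace(t, f, 100.0), model, 259)
        step = np.nanmedian(aa[t >= 20]) - np.nanmedian(aa[t < 20])
        assert step == pytest.approx(75, abs=5)


class TestDetectionResolution:
    def test_white_noise_scaling(self):
        steps, dwell = detection_resolution(0.25, 1333.0, 13.33, 0.006, 2.4)
        assert 0.25 * np.sqrt(13.33 / 1333.0) == pytest.approx(0.025, rel=1e-3)

    def test_ten_steps_at_target_snr(self):
        steps, _ = detection_resolution(0.25, 1333.0, 13.33, 0.006, 2.4)
        assert steps == 10

    def test_min_dwell_after_tenfold_downsampling(self):
        _, dwell = detection_resolution(0.25, 1333.0, 133.3, 0.006, 2.4)
        assert dwell == pytest.approx(0.0075, rel=1e-2)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            detection_resolution(0.25, 1333.0, 2000.0, 0.006, 2.4)
        with pytest.raises(ValueError):
            detection_resolution(-1.0, 1333.0, 13.33, 0.006, 2.4)
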