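"""Bartlett PSD, band aggregation, Box-Cox and within-subject ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal.windows import blackmanharris

from medisig import bartlett_psd, boxcox_normalize, rm_anova
from medisig.core import Recording
from medisig.spectral import PSDEstimate, band_power_anova, band_region_power

from .oracles import bartlett_psd_direct, rm_anova_hand


def _mono(x, fs=64.0, label="Cz"):
    return Recording(np.atleast_2d(x), fs, (label,), {label: "central"})


class TestBartlettPSD:
    def test_zero_signal_zero_psd(self):
        psd = bartlett_psd(_mono(np.zeros(2048)), 256)
        np.testing.assert_allclose(psd.power, 0.0)

    def test_bin_centred_tone_peaks_with_low_sidelobes(self):
        fs, n = 64.0, 256
        k = 40  # exact bin: 40 * fs/n = 10 Hz
        t = np.arange(8 * n)
        x = np.sin(2 * np.pi * k / n * t)
        psd = bartlett_psd(_mono(x, fs), n)
        p = psd.power[0]
        assert np.argmax(p) == k
        # 4-term Blackman-Harris sidelobes are ~92 dB down; allow leakage
        # into the +/-3-bin main lobe only
        far = np.delete(p, range(k - 3, k + 4))
        assert far.max() < p[k] * 10 ** (-60 / 10)

    def test_matches_direct_summation(self, rng):
        fs, n = 64.0, 64
        x = rng.standard_normal(4 * n)
        psd = bartlett_psd(_mono(x, fs), n)
        freqs, direct = bartlett_psd_direct(x, fs, n,
                                            blackmanharris(n, sym=False))
        np.testing.assert_allclose(psd.frequencies, freqs)
        np.testing.assert_allclose(psd.power[0], direct, atol=1e-9)

    def test_white_noise_flat_in_band(self):
        acc = None
        fs, n = 64.0, 256
        for seed in range(40):
            x = np.random.default_rng(seed).standard_normal(20 * n)
            p = bartlett_psd(_mono(x, fs), n).power[0]
            acc = p if acc is None else acc + p
        freqs = np.fft.rfftfreq(n, 1 / fs)
        band = acc[(freqs >= 4) & (freqs < 30)]
        mean = band.mean()
        assert band.max() / mean < 1.10
        assert band.min() / mean > 0.90

    def test_sign_flip_invariance_and_amplitude_scaling(self, rng):
        x = rng.standard_normal(2048)
        p1 = bartlett_psd(_mono(x), 256).power
        p2 = bartlett_psd(_mono(-x), 256).power
        p3 = bartlett_psd(_mono(3.0 * x), 256).power
        np.testing.assert_allclose(p1, p2)
        np.testing.assert_allclose(p3, 9.0 * p1, rtol=1e-12)

    def test_segment_length_larger_than_data_rejected(self):
        with pytest.raises(ValueError):
            bartlett_psd(_mono(np.zeros(100)), 256)


class TestBandRegionPower:
    def _psd(self, power, labels):
        freqs = np.arange(0.0, 32.25, 0.25)
        return PSDEstimate(
            frequencies=freqs,
            power=np.asarray(power, dtype=float),
            segment_length=256,
            n_segments=np.ones(len(labels), dtype=int),
            channel_labels=tuple(labels),
            fs=64.0,
        )

    def test_constant_band_returns_constant(self):
        freqs = np.arange(0.0, 32.25, 0.25)
        p = np.where((freqs >= 4) & (freqs < 8), 5.0, 1.0)[None, :]
        psd = self._psd(p, ["Cz"])
        table = band_region_power(psd, {"Cz": "central"})
        theta = table[(table.band == "theta")].power.item()
        assert theta == pytest.approx(5.0)

    def test_region_averages_channels(self):
        freqs = np.arange(0.0, 32.25, 0.25)
        pa = np.where((freqs >= 8) & (freqs < 12), 2.0, 0.5)
        pb = np.where((freqs >= 8) & (freqs < 12), 6.0, 0.5)
        psd = self._psd(np.vstack([pa, pb]), ["C3", "C4"])
        table = band_region_power(psd, {"C3": "central", "C4": "central"})
        alpha = table[table.band == "alpha"].power.item()
        assert alpha == pytest.approx(4.0)

    def test_band_intervals_left_closed_right_open(self):
        freqs = np.arange(0.0, 32.25, 0.25)
        p = np.zeros_like(freqs)
        p[freqs == 8.0] = 1.0  # 8 Hz belongs to alpha, not theta
        psd = self._psd(p[None, :], ["Cz"])
        table = band_region_power(psd, {"Cz": "central"})
        assert table[table.band == "theta"].power.item() == 0.0
        assert table[table.band == "alpha"].power.item() > 0.0


class TestBoxCox:
    def test_lognormal_lambda_near_zero(self, rng):
        x = np.exp(rng.normal(0.0, 1.0, 500))
        _, lam, _ = boxcox_normalize(x)
        assert lam is not None and -0.2 <= lam <= 0.2

    def test_normal_sample_untransformed_or_identity_lambda(self, rng):
        x = rng.normal(50.0, 2.0, 500)
        y, lam, p = boxcox_normalize(x)
        if lam is None:  # normality not rejected: no transform applied
            np.testing.assert_array_equal(y, x)
        else:
            assert 0.7 <= lam <= 1.3

    def test_lambda_one_is_shift(self):
        from medisig.spectral import boxcox_transform

        x = np.array([1.0, 2.5, 7.0])
        np.testing.assert_allclose(boxcox_transform(x, 1.0), x - 1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            boxcox_normalize(np.array([1.0, 0.0, 2.0]))


def _toy_table():
    y = np.array([
        [[10.0, 12.0], [8.0, 9.0]],
        [[11.0, 14.0], [9.0, 10.0]],
        [[9.0, 13.0], [7.0, 11.0]],
    ])
    rows = []
    for s in range(3):
        for i, cond in enumerate(["meditation", "control"]):
            for j, loc in enumerate(["L1", "L2"]):
                rows.append({"subject": s, "condition": cond,
                             "region": loc, "power": y[s, i, j]})
    return y, pd.DataFrame(rows)


class TestRmAnova:
    def test_identical_cells_give_zero_f(self):
        rows = [{"subject": s, "condition": c, "region": r, "power": 4.2}
                for s in range(3) for c in "mc" for r in "LR"]
        res = rm_anova(pd.DataFrame(rows), within=("condition", "region"))
        assert all(r.F == 0.0 for r in res)

    def test_toy_table_matches_hand_oracle(self):
        """Frozen sums-of-squares values for a 3x2x2 design."""
        y, df = _toy_table()
        res = {r.effect: r for r in
               rm_anova(df, within=("condition", "region"))}
        assert res["condition"].F == pytest.approx(75.0, abs=1e-10)
        assert res["region"].F == pytest.approx(10.714285714285714, abs=1e-10)
        assert res["condition x region"].F == pytest.approx(3.0, abs=1e-10)
        assert res["condition"].df == (1, 2)
        # and against the loop-based oracle, for any table
        hand = rm_anova_hand(y)
        assert res["condition"].F == pytest.approx(hand["A"][0], abs=1e-10)
        assert res["region"].F == pytest.approx(hand["B"][0], abs=1e-10)

    def test_matches_pingouin(self, rng):
        rows = [{"subject": s, "condition": c, "region": r,
                 "power": rng.normal(10, 2)}
                for s in range(6) for c in "mc" for r in "LRX"]
        df = pd.DataFrame(rows)
        res = {r.effect: r for r in
               rm_anova(df, within=("condition", "region"))}
        import pingouin as pg

        ref = pg.rm_anova(dv="power", within=["condition", "region"],
                          subject="subject", data=df)
        ref = dict(zip(ref["Source"], ref["F"]))
        assert res["condition"].F == pytest.approx(ref["condition"])
        assert res["region"].F == pytest.approx(ref["region"])
        assert res["condition x region"].F == pytest.approx(
            ref["condition * region"])

    def test_shift_and_scale_invariance(self):
        _, df = _toy_table()
        base = rm_anova(df, within=("condition", "region"))
        shifted = df.assign(power=df.power + 100.0)
        scaled = df.assign(power=df.power * 7.5)
        for other in (shifted, scaled):
            res = rm_anova(other, within=("condition", "region"))
            for a, b in zip(base, res):
                assert a.F == pytest.approx(b.F, rel=1e-9)

    def test_missing_cell_rejected(self):
        _, df = _toy_table()
        with pytest.raises(ValueError, match="missing"):
            rm_anova(df.iloc[:-1], within=("condition", "region"))

    def test_single_subject_rejected(self):
        _, df = _toy_table()
        with pytest.raises(ValueError, match="subjects"):
            rm_anova(df[df.subject == 0], within=("condition", "region"))

    def test_one_way_condition_effect(self):
        rows = []
        for s in range(8):
            base = 10 + s
            rows.append({"subject": s, "condition": "meditation",
                         "power": base + 2.0})
            rows.append({"subject": s, "condition": "control",
                         "power": base})
        (res,) = rm_anova(pd.DataFrame(rows), within=("condition",))
        assert res.df == (1, 7)
        assert res.F > 100
        assert res.p < 1e-4

    def test_injected_condition_main_effect_recovered(self, rng):
        """A pure condition shift yields condition F >> interaction F."""
        rows = []
        for s in range(10):
            subj = rng.normal(0, 1)
            for cond, shift in (("meditation", 1.0), ("control", 0.0)):
                for reg in ("A", "B", "C"):
                    rows.append({
                        "subject": s, "condition": cond, "region": reg,
                        "power": 10 + subj + shift + rng.normal(0, 0.3),
                    })
        res = {r.effect: r for r in
               rm_anova(pd.DataFrame(rows), within=("condition", "region"))}
        assert res["condition"].F > 10 * res["condition x region"].F
        assert res["condition"].cell_means[("meditation", "A")] > \
            res["condition"].cell_means[("control", "A")]


class TestBandPowerAnova:
    def test_boxcox_lambda_reported(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(8):
            for cond in ("meditation", "control"):
                for reg in ("A", "B"):
                    rows.append({"subject": s, "condition": cond,
                                 "band": "theta", "region": reg,
                                 "power": float(np.exp(rng.normal(2, 0.8)))})
        res = band_power_anova(pd.DataFrame(rows), "theta")
        assert res[0].boxcox_lambda is None or isinstance(
            res[0].boxcox_lambda, float)

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError):
            band_power_anova(pd.DataFrame({"band": ["theta"], "power": [1.0],
                                           "subject": [0],
                                           "condition": ["m"],
                                           "region": ["A"]}), "gamma")
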