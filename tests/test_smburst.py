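"""Burst pipeline tests: stream I/O, burst search, observables, FCS."""

import numpy as np
import pytest

from foxptools import fluortime, smburst, synthgen
from foxptools.photons import CHANNEL_CODE, PhotonStream, StreamSchemaError
from foxptools.synthgen import GeneratorConfig, PhotonStreamSpec, SpeciesSpec


def _make_stream(macro, micro=None, channel=None, **meta):
    macro = np.asarray(macro, dtype=float)
    n = macro.size
    defaults = {"excitation_period_ns": 50.0, "g_factor": 1.0}
    defaults.update(meta)
    return PhotonStream(
        macrotime_ns=macro,
        microtime_ns=np.full(n, 5.0) if micro is None else np.asarray(micro),
        channel=np.zeros(n, dtype=np.int8) if channel is None else
        np.asarray(channel, dtype=np.int8),
        meta=defaults,
    )


class TestStreamIO:
    def test_tsv_round_trip_identity(self, bursty_stream, tmp_path):
        path = tmp_path / "s.tsv"
        smburst.write_stream(bursty_stream, path)
        back = smburst.read_stream(path)
        np.testing.assert_array_equal(back.macrotime_ns,
                                      bursty_stream.macrotime_ns)
        np.testing.assert_array_equal(back.microtime_ns,
                                      bursty_stream.microtime_ns)
        np.testing.assert_array_equal(back.channel, bursty_stream.channel)

    def test_hdf5_and_tsv_agree(self, bursty_stream, tmp_path):
        smburst.write_stream(bursty_stream, tmp_path / "s.tsv")
        smburst.write_stream(bursty_stream, tmp_path / "s.h5")
        a = smburst.read_stream(tmp_path / "s.tsv")
        b = smburst.read_stream(tmp_path / "s.h5")
        np.testing.assert_array_equal(a.macrotime_ns, b.macrotime_ns)
        np.testing.assert_array_equal(a.microtime_ns, b.microtime_ns)
        np.testing.assert_array_equal(a.channel, b.channel)
        assert a.meta["seed"] == b.meta["seed"]

    def test_out_of_order_macrotimes_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "macrotime_ns\tmicrotime_ns\tchannel\n"
            "100.0\t1.0\tDp\n50.0\t2.0\tDs\n"
        )
        with pytest.raises(StreamSchemaError, match="out of order"):
            smburst.read_stream(path)

    def test_unknown_channel_reported_with_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "macrotime_ns\tmicrotime_ns\tchannel\n1.0\t1.0\tXX\n"
        )
        with pytest.raises(StreamSchemaError, match="channel"):
            smburst.read_stream(path)

    def test_missing_column_diagnosed(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("macrotime_ns\tchannel\n1.0\tDp\n")
        with pytest.raises(StreamSchemaError, match="missing columns"):
            smburst.read_stream(path)


class TestDetectBursts:
    def test_pure_background_yields_no_bursts(self):
        rng = np.random.default_rng(0)
        # 1 kHz over 10 s
        t = np.sort(rng.uniform(0, 10e9, size=10_000))
        stream = _make_stream(t)
        assert smburst.detect_bursts(stream) == []

    def test_planted_bursts_recovered(self):
        rng = np.random.default_rng(1)
        duration = 10e9
        bg = rng.uniform(0, duration, size=10_000)  # 1 kHz background
        parts = [bg]
        starts = np.linspace(0.2, 0.9, 20) * duration
        for s in starts:  # 100 photons at 50 kHz within 2 ms
            parts.append(s + np.sort(rng.uniform(0, 2e6, size=100)))
        t = np.sort(np.concatenate(parts))
        stream = _make_stream(t)
        bursts = smburst.detect_bursts(stream, 10, 500_000.0, 50)
        assert len(bursts) == 20

    def test_threshold_above_largest_burst_dominates(self, bursty_stream):
        assert smburst.detect_bursts(bursty_stream, min_photons=10**7) == []

    def test_invariance_to_offset_and_trailing_background(self):
        rng = np.random.default_rng(2)
        burst = 1e9 + np.sort(rng.uniform(0, 1e6, size=200))
        t = np.sort(np.concatenate([rng.uniform(0, 5e9, 2000), burst]))
        stream = _make_stream(t)
        found = smburst.detect_bursts(stream)
        shifted = _make_stream(t + 7.7e9)
        assert len(smburst.detect_bursts(shifted)) == len(found)
        extended = _make_stream(
            np.concatenate([t, np.sort(rng.uniform(5e9, 12e9, 2000))])
        )
        found_ext = smburst.detect_bursts(extended)
        assert [b.n_photons for b in found_ext][: len(found)] == [
            b.n_photons for b in found
        ]


class TestBurstObservables:
    def test_e_half_for_equal_donor_acceptor(self):
        n = 200
        channel = np.array([0, 2] * (n // 2), dtype=np.int8)  # Dp / Ap
        stream = _make_stream(np.arange(n) * 1e3, channel=channel)
        burst = smburst.Burst(0, n, 0.0, n * 1e3)
        out = smburst.burst_observables(burst, stream)
        assert out.e_fret == pytest.approx(0.5)

    def test_stoichiometry_limits(self):
        # ALEX stream: donor-only burst then acceptor-only burst
        period = 50.0
        n = 300
        donor = _make_stream(
            np.arange(n) * 1e3,
            micro=np.full(n, 5.0),
            channel=np.zeros(n, dtype=np.int8),
            alex=True,
        )
        b = smburst.burst_observables(
            smburst.Burst(0, n, 0.0, n * 1e3), donor
        )
        assert b.stoichiometry == pytest.approx(1.0)
        acceptor = _make_stream(
            np.arange(n) * 1e3,
            micro=np.concatenate([np.full(30, 5.0),
                                  np.full(n - 30, period / 2 + 5.0)]),
            channel=np.full(n, 2, dtype=np.int8),
            alex=True,
        )
        b2 = smburst.burst_observables(
            smburst.Burst(0, n, 0.0, n * 1e3), acceptor
        )
        assert b2.stoichiometry < 0.15

    def test_stoichiometry_undefined_without_alex(self):
        n = 100
        stream = _make_stream(np.arange(n) * 1e3)
        b = smburst.burst_observables(
            smburst.Burst(0, n, 0.0, n * 1e3), stream
        )
        assert np.isnan(b.stoichiometry)

    def test_e_s_invariant_under_count_scaling(self):
        period = 50.0

        def build(scale):
            blocks = []
            for code, micro in ((0, 5.0), (2, 5.0), (2, period / 2 + 5.0)):
                blocks.append((code, micro, 40 * scale))
            n = sum(b[2] for b in blocks)
            channel = np.concatenate(
                [np.full(c, code, np.int8) for code, _, c in blocks]
            )
            micro = np.concatenate(
                [np.full(c, m) for _, m, c in blocks]
            )
            stream = _make_stream(
                np.arange(n) * 1e3, micro=micro, channel=channel, alex=True
            )
            return smburst.burst_observables(
                smburst.Burst(0, n, 0.0, n * 1e3), stream
            )

        one, three = build(1), build(3)
        assert one.e_fret == pytest.approx(three.e_fret)
        assert one.stoichiometry == pytest.approx(three.stoichiometry)

    def test_planted_burst_rg_matches_perrin(self):
        """A large burst of a single species converges to the analytic
        steady-state anisotropy of that species."""
        species = SpeciesSpec(fraction=1.0)  # rho=60 ns, tau=4.35, r0=0.38
        spec = PhotonStreamSpec(
            duration_s=2.0, background_rate_hz=0.0, burst_rate_hz=2.0,
            molecular_brightness_hz=5e5, t_diff_ms=20.0, species=(species,),
        )
        stream = synthgen.gen_photon_stream(spec, GeneratorConfig(seed=6))
        bursts = smburst.detect_bursts(stream, min_photons=2000)
        assert bursts
        big = max(bursts, key=lambda b: b.n_photons)
        out = smburst.burst_observables(big, stream)
        expected = 0.38 / (1.0 + 4.35 / 60.0)
        assert out.r_g == pytest.approx(
            expected, abs=4.0 / np.sqrt(big.n_photons)
        )

    def test_two_rho_mixture_shows_two_rg_populations(self):
        """Species at rho=180 ns and rho=0.3 ns separate into r_G peaks
        near ~0.35 and ~0.04."""
        slow = SpeciesSpec(fraction=0.5, rotations=((1.0, 180.0),))
        fast = SpeciesSpec(fraction=0.5, rotations=((1.0, 0.3),))
        spec = PhotonStreamSpec(
            duration_s=30.0, background_rate_hz=0.0, burst_rate_hz=30.0,
            molecular_brightness_hz=2e5, t_diff_ms=2.0, species=(slow, fast),
        )
        stream = synthgen.gen_photon_stream(spec, GeneratorConfig(seed=8))
        bursts = [
            smburst.burst_observables(b, stream)
            for b in smburst.detect_bursts(stream, min_photons=100)
        ]
        rg = np.array([b.r_g for b in bursts])
        assert (np.abs(rg - 0.355) < 0.08).sum() > 10
        assert (np.abs(rg - 0.025) < 0.08).sum() > 10


class TestHist2D:
    def test_single_burst_single_bin_and_marginals(self):
        b = smburst.Burst(0, 10, 0.0, 1e6, r_g=0.2, mean_tau_ns=4.0)
        counts, xe, ye, mx, my = smburst.hist2d([b], "mean_tau", "r_g", bins=5)
        assert counts.sum() == 1
        assert (counts > 0).sum() == 1
        assert mx.sum() == 1 and my.sum() == 1

    def test_marginals_sum_to_burst_count(self, bursty_stream):
        bursts = smburst.analyze_bursts(bursty_stream)
        counts, _, _, mx, my = smburst.hist2d(bursts, "mean_tau", "r_g")
        n_finite = sum(
            1 for b in bursts
            if np.isfinite(b.r_g) and np.isfinite(b.mean_tau_ns)
        )
        assert mx.sum() == n_finite
        assert my.sum() == n_finite

    def test_unknown_field_rejected(self):
        b = smburst.Burst(0, 10, 0.0, 1e6)
        with pytest.raises(KeyError):
            smburst.hist2d([b], "nope", "r_g")

    def test_empty_burst_list_rejected(self):
        with pytest.raises(ValueError):
            smburst.hist2d([], "mean_tau", "r_g")


def _direct_multitau(trace, bin_ns, n_base=16, ppo=8, max_lag_ns=None):
    """O(N^2)-style reference correlator mirroring the multi-tau ladder,
    computed with explicit per-lag loops."""
    lags_out, g_out = [], []
    current = trace.astype(float)
    width = bin_ns
    level = 0
    while True:
        lags = (
            np.arange(1, n_base + 1) if level == 0
            else np.arange(ppo + 1, 2 * ppo + 1)
        )
        lags = lags[lags < current.size // 2]
        if lags.size == 0:
            break
        stop = False
        for k in lags:
            lag_ns = k * width
            if max_lag_ns is not None and lag_ns > max_lag_ns:
                stop = True
                break
            n = current.size
            acc = 0.0
            for i in range(n - k):
                acc += current[i] * current[i + k]
            ma = current[: n - k].mean()
            mb = current[k:].mean()
            g = acc / (n - k) / (ma * mb) - 1.0 if ma > 0 and mb > 0 else 0.0
            lags_out.append(lag_ns)
            g_out.append(g)
        if stop:
            break
        current = current[: 2 * (current.size // 2)].reshape(-1, 2).sum(1)
        width *= 2
        level += 1
        if current.size < 4 * ppo:
            break
    return np.array(lags_out) / 1e9, np.array(g_out)


class TestAutocorrelate:
    def test_constant_intensity_gives_zero(self):
        # one photon per bin, exactly periodic
        t = np.arange(0, 10_000) * 1000.0 + 500.0
        stream = _make_stream(t, duration_ns=1e7)
        curve = smburst.autocorrelate(stream, bin_ns=1000.0,
                                      max_lag_s=1e-3)
        np.testing.assert_allclose(curve.g, 0.0, atol=1e-12)

    def test_poisson_stream_shows_no_excess_correlation(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 20e9, size=100_000))  # 5 kHz Poisson
        stream = _make_stream(t, duration_ns=20e9)
        curve = smburst.autocorrelate(stream, bin_ns=10_000.0,
                                      max_lag_s=0.05)
        counts_per_bin = 100_000 / (20e9 / 1e4)
        n_pairs = 20e9 / 1e4
        sigma = 1.0 / (counts_per_bin * np.sqrt(n_pairs))
        assert np.all(np.abs(curve.g) < 4 * sigma)

    def test_agrees_with_direct_oracle(self):
        rng = np.random.default_rng(4)
        spec = PhotonStreamSpec(
            duration_s=2.0, background_rate_hz=100.0, burst_rate_hz=50.0,
            molecular_brightness_hz=1e5, t_diff_ms=0.5,
            species=(SpeciesSpec(fraction=1.0),),
        )
        stream = synthgen.gen_photon_stream(spec, GeneratorConfig(seed=13))
        assert len(stream) <= 3e4
        curve = smburst.autocorrelate(stream, bin_ns=10_000.0,
                                      max_lag_s=0.05)
        n_bins = int(np.ceil(stream.duration_ns() / 1e4))
        mask = stream.channel_mask(("Dp", "Ds"))
        trace = np.bincount(
            np.minimum(
                (stream.macrotime_ns[mask] / 1e4).astype(np.int64),
                n_bins - 1,
            ),
            minlength=n_bins,
        )
        lag_ref, g_ref = _direct_multitau(
            trace, 1e4, max_lag_ns=0.05 * 1e9
        )
        ref = dict(zip(np.round(lag_ref, 12), g_ref))
        matched = 0
        for lag, g in zip(np.round(curve.lag_s, 12), curve.g):
            if lag in ref:
                assert abs(g - ref[lag]) < 1e-10
                matched += 1
        assert matched >= 20

    def test_insufficient_duration_rejected(self):
        stream = _make_stream([1.0], duration_ns=10.0)
        with pytest.raises(ValueError):
            smburst.autocorrelate(stream)


class TestFitFCS:
    def test_model_anchor_values(self):
        # t -> 0 gives 1/N + B; 2D limit halves at t = t_diff
        g0 = smburst.fcs_model(1e-9, 2.0, 1e-3, 0.0, 0.0, 1e-6, 0.01)
        assert g0 == pytest.approx(0.5 + 0.01, rel=1e-4)
        g_half = smburst.fcs_model(1e-3, 2.0, 1e-3, 0.0, 0.0, 1e-6, 0.0)
        assert g_half == pytest.approx(0.25)

    def test_round_trip_t_diff(self):
        spec = PhotonStreamSpec(
            duration_s=120.0, background_rate_hz=0.0, burst_rate_hz=20.0,
            molecular_brightness_hz=1e5, t_diff_ms=1.0,
            species=(SpeciesSpec(fraction=1.0),),
        )
        stream = synthgen.gen_photon_stream(spec, GeneratorConfig(seed=1))
        curve = smburst.autocorrelate(stream, bin_ns=5000.0, max_lag_s=0.1)
        fit = smburst.fit_fcs(curve, fix_aspect=0.2, fit_photophysics=False)
        assert fit["params"]["t_diff"] == pytest.approx(1e-3, rel=0.2)

    def test_bound_species_diffuses_slower(self):
        """Free vs DNA-bound synthetic streams order their fitted
        diffusion times correctly."""
        fits = {}
        for label, td in (("free", 0.6), ("bound", 1.8)):
            spec = PhotonStreamSpec(
                duration_s=120.0, background_rate_hz=0.0, burst_rate_hz=20.0,
                molecular_brightness_hz=1e5, t_diff_ms=td,
                species=(SpeciesSpec(fraction=1.0),),
            )
            stream = synthgen.gen_photon_stream(
                spec, GeneratorConfig(seed=2)
            )
            curve = smburst.autocorrelate(
                stream, bin_ns=5000.0, max_lag_s=0.1
            )
            fits[label] = smburst.fit_fcs(
                curve, fix_aspect=0.2, fit_photophysics=False
            )["params"]["t_diff"]
        assert fits["bound"] > fits["free"]

    def test_too_few_lags_rejected(self):
        curve = smburst.CorrelationCurve(
            lag_s=np.geomspace(1e-5, 1e-3, 10), g=np.ones(10)
        )
        with pytest.raises(ValueError):
            smburst.fit_fcs(curve)
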