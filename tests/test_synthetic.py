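import numpy as np
import pytest
from scipy.stats import chisquare, poisson

from hfopipe.detect import bandpass
from hfopipe.rates import hfo_area
from hfopipe.synthetic import (
    GroundTruthEvent,
    SimChannelSpec,
    SimPatientSpec,
    generate_background,
    generate_cohort,
    generate_patient,
    generate_truth,
    ground_truth_rates,
    inject_burst,
)
from hfopipe.validation import classify_patient


class TestBackground:
    def test_seed_determinism(self):
        a = generate_background(6000, 2000, 10.0, 42)
        b = generate_background(6000, 2000, 10.0, 42)
        np.testing.assert_array_equal(a, b)

    def test_rms_matches_request(self):
        x = generate_background(6000, 2000, 10.0, 42)
        assert abs(np.sqrt(np.mean(x**2)) - 10.0) < 0.5

    @pytest.mark.parametrize("n,rms", [(0, 10.0), (6000, 0.0), (-5, 1.0)])
    def test_invalid_arguments(self, n, rms):
        with pytest.raises(ValueError):
            generate_background(n, 2000, rms, 0)

    def test_pink_spectral_slope(self):
        """Power should fall roughly as 1/f across two well-separated decades."""
        x = generate_background(2**18, 2000, 5.0, 3)
        f, p = np.fft.rfftfreq(len(x), 1 / 2000), np.abs(np.fft.rfft(x)) ** 2
        lo = p[(f > 1) & (f < 10)].mean()
        hi = p[(f > 100) & (f < 1000)].mean()
        ratio = np.log10(lo / hi) / 2  # decades of power per decade of frequency
        assert 0.7 < ratio < 1.3


class TestInjectBurst:
    def test_peak_amplitude_exact(self):
        sig = np.zeros(4000)
        out, ev = inject_burst(sig, 2000, 0.5, 140, 15.0, 80)
        assert np.abs(out).max() == pytest.approx(15.0, rel=0.02)
        assert ev.kind == "ripple"

    def test_locality(self):
        sig = np.zeros(8000)
        out, _ = inject_burst(sig, 2000, 0.5, 140, 15.0, 80)
        out, _ = inject_burst(out, 2000, 2.5, 350, 10.0, 30)
        delta = out - sig
        assert np.all(delta[: int(0.49 * 2000)] == 0)
        assert np.all(delta[int(1.2 * 2000) : int(2.45 * 2000)] == 0)

    def test_out_of_band_burst_removed_by_ripple_filter(self):
        sig = np.zeros(40000)
        out, _ = inject_burst(sig, 2000, 5.0, 300, 15.0, 40)
        residual = bandpass(out, 2000, (80, 250))
        assert np.abs(residual).max() < 1.0

    def test_burst_outside_bounds(self):
        with pytest.raises(ValueError):
            inject_burst(np.zeros(100), 2000, 0.04, 140, 10, 80)


class TestGeneratePatient:
    @staticmethod
    def _single(rate, seed, n_intervals=6, interval_len_s=300.0):
        ch = SimChannelSpec("A1-A2", "A", hfo_rate=rate)
        return SimPatientSpec(
            "p", (ch,), n_intervals=n_intervals, interval_len_s=interval_len_s, seed=seed
        )

    def test_pair_count_poisson_consistent(self):
        """3 pairs/min over 30 min: count inside the central 99% of Poisson(90)."""
        truth = generate_truth(self._single(3.0, seed=21))
        n = sum(1 for e in truth if e.kind == "HFO-pair")
        lo, hi = poisson.ppf([0.005, 0.995], 90)
        assert lo <= n <= hi

    def test_zero_rates_empty_truth(self):
        spec = self._single(0.0, seed=1, n_intervals=4, interval_len_s=60.0)
        data, truth, _ = generate_patient(spec)
        assert truth == []

    def test_seed_determinism(self):
        spec = self._single(1.0, seed=9, n_intervals=4, interval_len_s=60.0)
        _, t1, _ = generate_patient(spec)
        _, t2, _ = generate_patient(spec)
        assert t1 == t2

    def test_truth_only_path_matches_full_synthesis(self):
        spec = self._single(1.5, seed=13, n_intervals=4, interval_len_s=60.0)
        assert generate_truth(spec) == generate_patient(spec)[1]

    def test_pairs_share_at_least_half_overlap(self):
        truth = generate_truth(self._single(2.0, seed=2, n_intervals=4, interval_len_s=60.0))
        rip = [e for e in truth if e.kind == "ripple"]
        frs = [e for e in truth if e.kind == "FR"]
        for f in frs:
            ov = max(
                min(f.offset_s, r.offset_s) - max(f.onset_s, r.onset_s) for r in rip
            )
            assert ov >= 0.5 * (f.offset_s - f.onset_s)

    def test_poisson_goodness_of_fit_across_channels(self):
        """Per-channel pair counts over 50 channels match Poisson dispersion."""
        chs = tuple(
            SimChannelSpec(f"C{i}-C{i + 1}", f"E{i // 9}", hfo_rate=2.0) for i in range(50)
        )
        spec = SimPatientSpec("p", chs, n_intervals=4, interval_len_s=300.0, seed=77)
        truth = generate_truth(spec)
        counts = {c.channel_id: 0 for c in chs}
        for e in truth:
            if e.kind == "HFO-pair":
                counts[e.channel_id] += 1
        observed = np.array(list(counts.values()))
        mu = observed.mean()
        # bin into quartile-ish cells of the fitted Poisson and chi-square test
        edges = poisson.ppf([0.25, 0.5, 0.75], mu)
        binned = np.searchsorted(edges, observed)
        obs = np.bincount(binned, minlength=4)
        probs = np.diff([0, *poisson.cdf(edges, mu), 1.0])
        _, p = chisquare(obs, probs * len(observed), ddof=1)
        assert p > 0.001


class TestSpecValidation:
    def test_frequency_bands_enforced(self):
        with pytest.raises(ValueError):
            SimChannelSpec("A1-A2", "A", freq_ripple_hz=60)
        with pytest.raises(ValueError):
            SimChannelSpec("A1-A2", "A", freq_fr_hz=600)

    def test_interval_count_bounds(self):
        ch = SimChannelSpec("A1-A2", "A")
        with pytest.raises(ValueError):
            SimPatientSpec("p", (ch,), n_intervals=3)
        with pytest.raises(ValueError):
            SimPatientSpec("p", (ch,), n_intervals=15)

    def test_truth_event_ordering_invariant(self):
        with pytest.raises(ValueError):
            GroundTruthEvent("c", "ripple", 1.0, 0.5, 10, 140)


class TestGenerateCohort:
    @staticmethod
    def _statuses(cohort):
        out = []
        for spec, expected in cohort:
            rates = ground_truth_rates(spec)
            area = hfo_area(rates)
            resected = {c.channel_id for c in spec.channel_specs if c.resected}
            v = classify_patient(area, resected, spec.ilae, spec.patient_id)
            out.append((v.status, expected))
        return out

    def test_requested_confusion_table_realized(self):
        cohort = generate_cohort(20, {"TP": 6, "TN": 11, "FP": 3, "FN": 0}, seed=4)
        statuses = self._statuses(cohort)
        assert all(got == expected for got, expected in statuses)
        counts = [s for s, _ in statuses]
        assert (counts.count("TN"), counts.count("TP"), counts.count("FP"), counts.count("FN")) == (11, 6, 3, 0)

    def test_single_tn_patient(self):
        cohort = generate_cohort(1, {"TN": 1}, seed=0)
        spec, _ = cohort[0]
        assert spec.ilae == 1
        (status, expected), = self._statuses(cohort)
        assert status == expected == "TN"

    def test_single_fn_patient(self):
        cohort = generate_cohort(1, {"FN": 1}, seed=0)
        spec, _ = cohort[0]
        assert spec.ilae > 1
        (status, expected), = self._statuses(cohort)
        assert status == expected == "FN"

    def test_infeasible_counts(self):
        with pytest.raises(ValueError):
            generate_cohort(3, {"TP": 1, "TN": 1}, seed=0)
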