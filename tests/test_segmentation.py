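"""Segmenter correctness: forced-likelihood reads, oracle equivalence,
quantization bounds, detection behaviour."""

import numpy as np
import pytest
from dataclasses import replace

from tailbench.errors import SignalTooShortError
from tailbench.segmentation import (
    AnchorParams,
    HmmParams,
    WindowParams,
    anchor_params_from_config,
    anchor_segment,
    hmm_params_from_config,
    hmm_segment,
    oracle_segment,
    standardize,
    window_params_from_config,
    window_segment,
)
from tailbench.simulate import Squiggle, simulate_dataset


def _plateau_read(levels, widths, noise_sd=0.0, seed=0):
    """Piecewise-constant squiggle plus params whose state means are the
    exact standardized plateau levels (likelihood-forced segmentation)."""
    rng = np.random.default_rng(seed)
    x = np.repeat(np.asarray(levels, float), widths)
    if noise_sd:
        x = x + rng.normal(0, noise_sd, x.size)
    z = standardize(x)
    edges = np.cumsum([0, *widths])
    means = [z[edges[i]:edges[i + 1]].mean() for i in range(4)]
    return Squiggle("plateau", x, 3012, 1, 0.0), np.array(means), edges


class TestHmm:
    def test_zero_noise_plateaus_split_exactly_at_joins(self):
        sq, means, edges = _plateau_read(
            [70, 88, 108, 97], [300, 200, 400, 500])
        params = HmmParams(means=means, sds=np.full(4, 0.1),
                           adapter_anchor_n=0)
        seg = hmm_segment(sq, params)
        assert seg.regions == {
            "adapter": (0, 300), "rta": (300, 500), "polya": (500, 900),
            "transcript": (900, 1400)}
        assert seg.boundaries.detected and seg.boundaries.method == "hmm"

    def test_too_short_read_raises(self):
        sq = Squiggle("s", np.zeros(3) + [1, 2, 3], 3012, 1, 0.0)
        params = HmmParams(means=np.arange(4.0), sds=np.full(4, 1.0),
                           min_dur=np.full(4, 10))
        with pytest.raises(SignalTooShortError, match="too short"):
            hmm_segment(sq, params)

    def test_viterbi_matches_exhaustive_oracle(self, tiny_config):
        """Viterbi log-probability equals brute-force enumeration over all
        boundary triples on seeded small reads."""
        ds = simulate_dataset(tiny_config, 40, seed=11)
        params = replace(hmm_params_from_config(tiny_config),
                         min_dur=np.array([8, 4, 4, 8]))
        for sq in ds.squiggles:
            vit = hmm_segment(sq, params)
            orc = oracle_segment(sq, params)
            assert vit.log_prob == pytest.approx(orc.log_prob, rel=1e-9)

    def test_oracle_refuses_long_reads(self, rna002):
        sq = Squiggle("long", np.random.default_rng(0).normal(size=500),
                      3012, 1, 0.0)
        with pytest.raises(ValueError, match="refuses"):
            oracle_segment(sq, hmm_params_from_config(rna002))

    def test_oracle_minimum_duration_read_has_unique_tiling(self):
        sq, means, edges = _plateau_read([70, 88, 108, 97], [8, 4, 4, 8])
        params = HmmParams(means=means, sds=np.full(4, 0.5),
                           min_dur=np.array([8, 4, 4, 8]),
                           adapter_anchor_n=0)
        orc = oracle_segment(sq, params)
        assert orc.regions["polya"] == (12, 16)


class TestWindow:
    def test_plateau_recovered_within_one_bin(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([
            rng.normal(100, 15, 1500),
            np.full(2500, 108.0) + rng.normal(0, 1, 2500),
            rng.normal(95, 15, 1500)])
        sq = Squiggle("p", x, 3012, 1, 0.0)
        level = float(np.median(standardize(x)[1500:4000]))
        b = window_segment(sq, WindowParams(polya_level=level))
        assert b.detected
        assert abs(b.polya_start - 1500) <= 25
        assert abs(b.polya_end - 4000) <= 25

    def test_seeded_tail_span_within_two_bins(self, rna002):
        cfg = replace(rna002, rate_mean=30.0, rate_sd=0.0,
                      tail_population=[(60.0, 1.0)])
        ds = simulate_dataset(cfg, 1, seed=7)
        b = window_segment(ds.squiggles[0], window_params_from_config(cfg))
        assert b.detected
        assert abs(b.span - 1800) <= 50

    def test_structureless_noise_is_undetected(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1, 4000) * rng.uniform(0.5, 2.0, 4000)
        b = window_segment(Squiggle("n", noise * 10 + 100, 3012, 1, 0.0),
                           WindowParams(polya_level=0.0))
        assert not b.detected
        assert b.span == 0


class TestAnchor:
    def test_zero_noise_read_recovered_exactly(self):
        sq, means, edges = _plateau_read(
            [70, 88, 108, 97], [300, 200, 400, 500])
        z = standardize(sq.samples)
        params = AnchorParams(polya_level=float(z[600]),
                              adapter_level=float(z[0]), anchor_n=100)
        b = anchor_segment(sq, params)
        assert (b.polya_start, b.polya_end) == (500, 900)

    def test_region_shorter_than_minimum_is_undetected(self, rna002):
        cfg = replace(rna002, tail_population=[(3.0, 1.0)])
        ds = simulate_dataset(cfg, 10, seed=3)
        params = anchor_params_from_config(cfg)
        detected = [anchor_segment(sq, params).detected
                    for sq in ds.squiggles]
        assert sum(detected) <= 2  # 3 nt x ~43 samples/nt << min length

    def test_anchor_detects_subset_of_hmm_detections(self, rna002):
        """The conservative anchor method discards reads the HMM keeps."""
        cfg = replace(rna002, tail_population=[
            (5.0, 0.3), (10.0, 0.2), (60.0, 0.5)])
        ds = simulate_dataset(cfg, 150, seed=9)
        hp = hmm_params_from_config(cfg)
        ap = anchor_params_from_config(cfg)
        n_hmm = sum(hmm_segment(sq, hp).boundaries.detected
                    for sq in ds.squiggles)
        n_anchor = sum(anchor_segment(sq, ap).detected
                       for sq in ds.squiggles)
        assert n_anchor < n_hmm


class TestSharedProperties:
    def test_scale_equivariance_of_all_methods(self, rna002):
        cfg = replace(rna002, tail_population=[(60.0, 1.0)])
        ds = simulate_dataset(cfg, 5, seed=21)
        hp = hmm_params_from_config(cfg)
        wp = window_params_from_config(cfg)
        ap = anchor_params_from_config(cfg)
        for sq in ds.squiggles:
            scaled = Squiggle(sq.read_id, sq.samples * 7.3,
                              sq.sampling_rate, sq.channel, sq.start_time)
            for fn, p in [(window_segment, wp), (anchor_segment, ap)]:
                a, b = fn(sq, p), fn(scaled, p)
                assert (a.polya_start, a.polya_end, a.detected) == \
                    (b.polya_start, b.polya_end, b.detected)
            ha, hb = hmm_segment(sq, hp), hmm_segment(scaled, hp)
            assert ha.regions == hb.regions

    def test_boundary_error_grows_with_emission_noise(self, rna002):
        """Mean boundary error is non-decreasing along a noise ladder."""
        base = replace(rna002, transcript_len_nt=60, transcript_mean=92.0,
                       transcript_level_sd=10.0,
                       tail_population=[(40.0, 1.0)])
        mean_errs = []
        for mult in (2.0, 3.0, 4.0, 6.0, 8.0):
            cfg = replace(base, adapter_sd=4 * mult, rta_sd=3.5 * mult,
                          polya_sd=2.2 * mult, transcript_sd=2.5 * mult)
            ds = simulate_dataset(cfg, 100, seed=77)
            hp = hmm_params_from_config(cfg)
            errs = []
            for sq, ann in zip(ds.squiggles, ds.annotations):
                seg = hmm_segment(sq, hp)
                errs.append(abs(seg.boundaries.polya_start - ann.polya[0])
                            + abs(seg.boundaries.polya_end - ann.polya[1]))
            mean_errs.append(np.mean(errs))
        assert all(a <= b * 1.05 for a, b in zip(mean_errs, mean_errs[1:]))

    def test_zero_noise_recovery_of_all_methods_on_simulator(self, rna002):
        """On noise-free simulated reads every method lands within one
        nucleotide-level dwell of the annotation."""
        cfg = replace(rna002, adapter_sd=0, rta_sd=0, polya_sd=0,
                      transcript_sd=0, adapter_samples_sd=0, rate_sd=0)
        ds = simulate_dataset(cfg, 5, seed=42)
        hp = hmm_params_from_config(cfg)
        wp = window_params_from_config(cfg)
        ap = anchor_params_from_config(cfg)
        dwell = int(np.ceil(cfg.rate_mean)) + 1
        for sq, ann in zip(ds.squiggles, ds.annotations):
            for fn, p in [(window_segment, wp), (anchor_segment, ap)]:
                b = fn(sq, p)
                assert b.detected
                assert abs(b.polya_start - ann.polya[0]) <= 25
                assert abs(b.polya_end - ann.polya[1]) <= 3 * dwell
            seg = hmm_segment(sq, hp)
            assert abs(seg.boundaries.polya_start - ann.polya[0]) <= 2
            assert abs(seg.boundaries.polya_end - ann.polya[1]) <= 3 * dwell
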