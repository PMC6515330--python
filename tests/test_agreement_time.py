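"""Continuous-time confusion measures and pseudo-kappa.

Exact interval-sweep results are cross-checked against an independent
1 ms dense-grid oracle on randomized fixtures.
"""

import math

import numpy as np
import pytest

from lungphase import (
    AnnotationSet,
    AnnotatorNoise,
    BreathingProfile,
    IntervalSet,
    PhaseInterval,
    confusion_for_pair,
    corpus_summary,
    corrupt_annotations,
    generate_schedule,
    interpret_kappa,
    phase_region,
    pseudo_kappa,
    sensitivity,
    specificity,
    time_confusion,
)
from lungphase.agreement_time import TimeConfusion
from lungphase.annotations import EXPIRATION, INSPIRATION


GRID = 1e-3


def grid_confusion(a: IntervalSet, b: IntervalSet, total: float):
    """Independent oracle: rasterize regions on a 1 ms grid and count."""
    n = int(round(total / GRID))
    xa = np.zeros(n, dtype=bool)
    xb = np.zeros(n, dtype=bool)
    for spans, x in ((a.spans, xa), (b.spans, xb)):
        for s, e in spans:
            x[int(round(s / GRID)) : int(round(e / GRID))] = True
    return {
        "tp": np.sum(xa & xb) * GRID,
        "fp": np.sum(xa & ~xb) * GRID,
        "tn": np.sum(~xa & ~xb) * GRID,
        "fn": np.sum(~xa & xb) * GRID,
    }


def random_region(rng, total, n_max=6):
    spans = []
    for _ in range(int(rng.integers(0, n_max + 1))):
        s = rng.uniform(0, total)
        spans.append((s, min(s + rng.uniform(0.05, total / 2), total)))
    return IntervalSet(spans)


class TestPhaseRegion:
    def test_both_scope_merges_abutting(self):
        ann = AnnotationSet(
            "r", 5.0, "s",
            (PhaseInterval(0, 1, INSPIRATION), PhaseInterval(1, 2, EXPIRATION)),
        )
        region = phase_region(ann, "both")
        assert region.spans.tolist() == [[0.0, 2.0]]

    def test_single_scope_excludes_other_phase(self):
        ann = AnnotationSet(
            "r", 5.0, "s", (PhaseInterval(1, 2, EXPIRATION),)
        )
        assert not phase_region(ann, "inspiration")
        assert phase_region(ann, "expiration").measure == pytest.approx(1.0)

    def test_merged_measure_matches_grid(self, rng):
        for _ in range(30):
            region = random_region(rng, 15.0)
            n = int(round(15.0 / GRID))
            x = np.zeros(n, dtype=bool)
            for s, e in region.spans:
                x[int(round(s / GRID)) : int(round(e / GRID))] = True
            n_bounds = 2 * len(region.spans)
            assert region.measure == pytest.approx(
                x.sum() * GRID, abs=GRID * (n_bounds + 1)
            )
            # disjointness after merging
            assert np.all(region.spans[1:, 0] >= region.spans[:-1, 1])


class TestTimeConfusion:
    def test_worked_example(self):
        tc = time_confusion(
            IntervalSet([(0, 4)]), IntervalSet([(2, 6)]), total=10.0
        )
        assert (tc.tp, tc.fp, tc.fn, tc.tn) == (2.0, 2.0, 2.0, 4.0)

    def test_identical_regions(self):
        a = IntervalSet([(1, 3), (5, 6)])
        tc = time_confusion(a, a, total=10.0)
        assert tc.fp == tc.fn == 0.0
        assert tc.tp == pytest.approx(3.0)
        assert tc.tn == pytest.approx(7.0)

    def test_region_outside_total_rejected(self):
        with pytest.raises(ValueError):
            time_confusion(IntervalSet([(0, 12)]), IntervalSet(), total=10.0)

    def test_matches_grid_oracle_and_conserves(self, rng):
        total = 15.0
        for _ in range(100):
            a = random_region(rng, total)
            b = random_region(rng, total)
            tc = time_confusion(a, b, total)
            assert tc.tp + tc.fp + tc.tn + tc.fn == pytest.approx(
                total, abs=1e-9
            )
            oracle = grid_confusion(a, b, total)
            tol = GRID * (2 * (len(a.spans) + len(b.spans)) + 2)
            for key in ("tp", "fp", "tn", "fn"):
                assert getattr(tc, key) == pytest.approx(
                    oracle[key], abs=tol
                ), key


class TestSensitivitySpecificity:
    def test_direct_ratios(self):
        tc = TimeConfusion(2, 2, 4, 2, 10)
        assert sensitivity(tc) == pytest.approx(0.5)
        assert specificity(tc) == pytest.approx(4 / 6)

    def test_perfect_agreement(self):
        tc = TimeConfusion(4, 0, 6, 0, 10)
        assert sensitivity(tc) == 1.0
        assert specificity(tc) == 1.0

    def test_zero_denominator_is_nan(self):
        assert math.isnan(sensitivity(TimeConfusion(0, 4, 6, 0, 10)))
        assert math.isnan(specificity(TimeConfusion(4, 0, 0, 6, 10)))

    def test_orientation_switch_swaps_roles(self):
        a = AnnotationSet("r", 10.0, "a", (PhaseInterval(0, 4, INSPIRATION),))
        b = AnnotationSet("r", 10.0, "b", (PhaseInterval(0, 6, INSPIRATION),))
        paper = confusion_for_pair(a, b, "both", "paper")
        conv = confusion_for_pair(a, b, "both", "conventional")
        assert paper.fp == conv.fn
        assert paper.fn == conv.fp


class TestCorpusSummary:
    def test_unweighted_mean_excludes_undefined(self):
        def one(rec, cover_all):
            ivs = (
                (PhaseInterval(0, 10, INSPIRATION),)
                if cover_all
                else (PhaseInterval(0, 5, INSPIRATION),)
            )
            a = AnnotationSet(rec, 10.0, "a", ivs)
            b = AnnotationSet(rec, 10.0, "b", ivs)
            return a, b

        pairs = [one("r1", False), one("r2", True)]
        s = corpus_summary(pairs, "both")
        # r2's specificity is 0/0 -> excluded; r1 is perfect
        assert s["mean_specificity"] == pytest.approx(1.0)
        assert s["mean_sensitivity"] == pytest.approx(1.0)

    def test_zero_noise_gives_perfect_scores(self):
        pairs = []
        for k in range(5):
            truth = generate_schedule(
                BreathingProfile(seed=k), recording_id=f"r{k}"
            )
            pairs.append((truth, truth))
        for scope in ("inspiration", "expiration", "both"):
            s = corpus_summary(pairs, scope)
            assert s["mean_sensitivity"] == pytest.approx(1.0)
            assert s["mean_specificity"] == pytest.approx(1.0)

    def test_unpaired_recordings_rejected(self):
        a = AnnotationSet("r1", 10.0, "a", ())
        b = AnnotationSet("r2", 10.0, "b", ())
        with pytest.raises(ValueError, match="unpaired"):
            corpus_summary([(a, b)])


class TestPseudoKappa:
    def test_identical_corpora_kappa_one(self):
        pairs = []
        for k in range(6):
            truth = generate_schedule(
                BreathingProfile(seed=k), recording_id=f"r{k}"
            )
            pairs.append((truth, truth))
        pk = pseudo_kappa(pairs, "both", n_shuffles=20, n_bootstrap=50, seed=0)
        assert pk.po == pytest.approx(1.0)
        assert pk.pe < 1.0
        assert pk.kappa == pytest.approx(1.0)
        assert pk.ci_low == pytest.approx(1.0)
        assert pk.interpretation == "almost perfect agreement"

    def test_independent_corpora_kappa_near_zero(self):
        pairs = []
        for k in range(50):
            a = generate_schedule(
                BreathingProfile(seed=k), recording_id=f"r{k}", source_id="a"
            )
            b = generate_schedule(
                BreathingProfile(seed=10_000 + k),
                recording_id=f"r{k}",
                source_id="b",
            )
            pairs.append((a, b))
        pk = pseudo_kappa(pairs, "both", n_shuffles=200, n_bootstrap=50, seed=42)
        assert abs(pk.kappa) < 0.05

    def test_reproducible_and_order_invariant(self):
        pairs = []
        for k in range(8):
            truth = generate_schedule(
                BreathingProfile(seed=k), recording_id=f"r{k}"
            )
            noisy = corrupt_annotations(
                truth, AnnotatorNoise(boundary_jitter_sd=0.2, seed=k)
            )
            pairs.append((truth, noisy))
        kw = dict(n_shuffles=30, n_bootstrap=100, seed=5)
        pk1 = pseudo_kappa(pairs, "both", **kw)
        pk2 = pseudo_kappa(pairs, "both", **kw)
        pk3 = pseudo_kappa(list(reversed(pairs)), "both", **kw)
        assert pk1 == pk2
        assert pk3.po == pytest.approx(pk1.po)
        assert pk3.kappa == pytest.approx(pk1.kappa, abs=0.02)

    def test_ci_brackets_kappa(self):
        pairs = []
        for k in range(12):
            truth = generate_schedule(
                BreathingProfile(seed=k), recording_id=f"r{k}"
            )
            noisy = corrupt_annotations(
                truth, AnnotatorNoise(boundary_jitter_sd=0.3, seed=k)
            )
            pairs.append((truth, noisy))
        pk = pseudo_kappa(pairs, "both", n_shuffles=30, n_bootstrap=300, seed=9)
        assert pk.ci_low - 0.05 <= pk.kappa <= pk.ci_high + 0.05

    def test_ci_narrows_with_more_files(self):
        def width(n_files):
            pairs = []
            for k in range(n_files):
                truth = generate_schedule(
                    BreathingProfile(seed=k), recording_id=f"r{k}"
                )
                noisy = corrupt_annotations(
                    truth, AnnotatorNoise(boundary_jitter_sd=0.3, seed=k)
                )
                pairs.append((truth, noisy))
            pk = pseudo_kappa(
                pairs, "both", n_shuffles=20, n_bootstrap=200, seed=3
            )
            return pk.ci_high - pk.ci_low

        assert width(80) < width(20)

    def test_fewer_than_two_pairs_rejected(self):
        truth = generate_schedule(BreathingProfile(seed=0))
        with pytest.raises(ValueError, match="at least 2"):
            pseudo_kappa([(truth, truth)], "both", seed=0)


class TestInterpretation:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (-0.2, "no agreement"),
            (0.0, "no agreement"),
            (0.10, "slight agreement"),
            (0.20, "slight agreement"),
            (0.35, "fair agreement"),
            (0.40, "fair agreement"),
            (0.55, "moderate agreement"),
            (0.60, "moderate agreement"),
            (0.75, "substantial agreement"),
            (0.80, "substantial agreement"),
            (0.81, "almost perfect agreement"),
            (1.0, "almost perfect agreement"),
        ],
    )
    def test_scale_bins(self, kappa, label):
        assert interpret_kappa(kappa) == label


class TestMonotoneDegradation:
    def test_error_time_increases_with_jitter(self):
        sigmas = [0.05, 0.3, 0.6]
        mean_err = []
        for sigma in sigmas:
            errs = []
            for rep in range(20):
                truth = generate_schedule(
                    BreathingProfile(seed=rep), recording_id=f"r{rep}"
                )
                noisy = corrupt_annotations(
                    truth,
                    AnnotatorNoise(boundary_jitter_sd=sigma, seed=1000 + rep),
                )
                tc = confusion_for_pair(truth, noisy, "both")
                errs.append(tc.fp + tc.fn)
            mean_err.append(np.mean(errs))
        assert mean_err[0] < mean_err[1] < mean_err[2]
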