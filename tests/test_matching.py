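"""Cross-correlation alignment, classification and the paired CC test."""

import math

import numpy as np
import pytest
from scipy import stats

from ambarcode import (
    AMProfile,
    Assignment,
    DegenerateProfileError,
    MatchConfig,
    MatchResult,
    NoValidAlignmentError,
    UNCLASSIFIED,
    classification_report,
    classify,
    cross_correlate,
    paired_cc_test,
    znormalize,
)
from ambarcode.matching import _resample


def profile(values, bpp=225.0, genome_id="ref", normalized=False):
    return AMProfile(
        np.asarray(values, dtype=float), bpp, genome_id=genome_id, normalized=normalized
    )


def random_profile(rng, n, genome_id="ref"):
    return profile(rng.random(n) + 0.1, genome_id=genome_id)


def brute_force_cc(query, reference, cfg):
    """Explicit loop over every stretch/orientation/shift with scipy Pearson."""
    q = query.values
    min_len = math.ceil(cfg.min_overlap_frac * q.size)
    best = None
    for stretch in cfg.stretch_grid:
        r = _resample(reference.values, float(stretch))
        for orientation in ("+", "-") if cfg.try_both_orientations else ("+",):
            qv = q if orientation == "+" else q[::-1]
            for t in range(-(len(qv) - 1), len(r)):
                i0, i1 = max(0, -t), min(len(qv), len(r) - t)
                n = i1 - i0
                if n < max(min_len, 2):
                    continue
                a, b = qv[i0:i1], r[t + i0 : t + i1]
                if a.std() == 0 or b.std() == 0:
                    continue
                cc = float(stats.pearsonr(a, b).statistic)
                key = (cc, -abs(t), orientation == "+", -abs(float(stretch) - 1.0))
                if best is None or key > best[0]:
                    best = (key, MatchResult("ref", cc, t, orientation, float(stretch)))
    return best[1] if best else None


class TestZnormalize:
    def test_basic_and_idempotent(self):
        z = znormalize(profile([1.0, 2.0, 3.0]))
        assert z.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.values.std() == pytest.approx(1.0, abs=1e-12)
        z2 = znormalize(z)
        np.testing.assert_allclose(z2.values, z.values, atol=1e-12)
        assert z.normalized

    def test_constant_profile_degenerate(self):
        with pytest.raises(DegenerateProfileError):
            znormalize(profile([5.0, 5.0, 5.0]))


class TestCrossCorrelate:
    def test_self_correlation(self, rng):
        p = random_profile(rng, 120)
        res = cross_correlate(p, p)
        assert res.cc == pytest.approx(1.0, abs=1e-9)
        assert res.shift_px == 0
        assert res.orientation == "+"
        assert res.stretch == pytest.approx(1.0, abs=1e-9)

    def test_reversed_query_matches_with_flip(self, rng):
        p = random_profile(rng, 120)
        rev = p.copy_with(p.values[::-1].copy())
        res = cross_correlate(rev, p)
        assert res.cc == pytest.approx(1.0, abs=1e-9)
        assert res.orientation == "-"

    def test_affine_invariance(self, rng):
        p = random_profile(rng, 120)
        scaled = p.copy_with(3.7 * p.values + 11.0)
        res = cross_correlate(scaled, p)
        assert res.cc == pytest.approx(1.0, abs=1e-9)
        assert res.shift_px == 0

    def test_scale_mismatch_rejected(self, rng):
        p = random_profile(rng, 50)
        q = profile(rng.random(50) + 0.1, bpp=100.0)
        with pytest.raises(ValueError):
            cross_correlate(p, q)

    def test_unsatisfiable_overlap_raises(self, rng):
        long_query = random_profile(rng, 200)
        short_ref = random_profile(rng, 40)
        with pytest.raises(NoValidAlignmentError):
            cross_correlate(long_query, short_ref, MatchConfig())

    def test_shifted_window_recovers_shift(self, rng):
        r = random_profile(rng, 150)
        cfg = MatchConfig(stretch_min=1.0, stretch_max=1.0, stretch_step=0.01,
                          try_both_orientations=False)
        q = profile(r.values[30:110].copy())
        res = cross_correlate(q, r, cfg)
        assert res.shift_px == 30
        assert res.cc == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cfg = MatchConfig(stretch_min=0.9, stretch_max=1.1, stretch_step=0.05)
        ref = random_profile(rng, 80)
        noisy = np.clip(
            _resample(ref.values, 0.95) + 0.1 * rng.standard_normal(76), 0, None
        )
        query = profile(noisy[5:70])
        fast = cross_correlate(query, ref, cfg)
        slow = brute_force_cc(query, ref, cfg)
        assert fast.cc == pytest.approx(slow.cc, abs=1e-9)
        assert (fast.shift_px, fast.orientation) == (slow.shift_px, slow.orientation)
        assert fast.stretch == pytest.approx(slow.stretch)


class TestClassify:
    def test_query_equal_to_one_reference(self, rng):
        refs = [random_profile(rng, 100, genome_id=f"ref{i}") for i in range(3)]
        a = classify(refs[1], refs)
        assert a.reference_id == "ref1"
        assert a.best.cc == pytest.approx(1.0, abs=1e-9)
        assert set(a.cc_by_reference) == {"ref0", "ref1", "ref2"}

    def test_low_cc_is_unclassified(self, rng):
        # uncorrelated noise profiles: best CC stays below the 0.85 bar
        q = random_profile(rng, 150, genome_id="q")
        refs = [random_profile(rng, 150, genome_id=f"ref{i}") for i in range(3)]
        a = classify(q, refs, MatchConfig(cc_threshold=0.85))
        assert max(a.cc_by_reference.values()) <= 0.85
        assert a.reference_id == UNCLASSIFIED

    def test_exact_tie_flags_ambiguous_first_reference_wins(self, rng):
        p = random_profile(rng, 100, genome_id="A")
        dup = AMProfile(p.values.copy(), p.bp_per_pixel, genome_id="B")
        a = classify(p, [p, dup], MatchConfig(cc_threshold=0.5))
        assert a.ambiguous
        assert a.reference_id == "A"

    def test_empty_reference_list_rejected(self, rng):
        with pytest.raises(ValueError):
            classify(random_profile(rng, 50), [])


def _assignment(ref_id, cc=0.95):
    return Assignment(
        reference_id=ref_id,
        best=MatchResult(ref_id if ref_id != UNCLASSIFIED else "r0", cc, 0, "+", 1.0),
        cc_by_reference={},
    )


class TestClassificationReport:
    def test_histogram_mean_sd_significance(self):
        # counts [8, 1, 1, 0] over four references
        assignments = {}
        for i in range(8):
            assignments[f"m{i}"] = _assignment("r0")
        assignments["m8"] = _assignment("r1")
        assignments["m9"] = _assignment("r2")
        report = classification_report(assignments, ["r0", "r1", "r2", "r3"])
        assert report.hist_mean == pytest.approx(2.5)
        assert report.hist_sd == pytest.approx(3.696846, abs=1e-5)
        assert report.significant_refs == ("r0",)
        assert sum(report.histogram.values()) == report.n_classified == 10

    def test_equal_counts_nothing_significant(self):
        assignments = {f"m{i}": _assignment(f"r{i % 2}") for i in range(4)}
        report = classification_report(assignments, ["r0", "r1"])
        assert report.hist_sd == 0.0
        assert report.significant_refs == ()

    def test_single_molecule_many_refs(self):
        report = classification_report(
            {"m0": _assignment("r7")}, [f"r{i}" for i in range(20)]
        )
        assert report.histogram["r7"] == 1
        assert sum(report.histogram.values()) == 1

    def test_unclassified_excluded_from_histogram(self):
        assignments = {"m0": _assignment("r0"), "m1": _assignment(UNCLASSIFIED)}
        report = classification_report(assignments, ["r0", "r1"])
        assert report.n_classified == 1
        assert report.n_unclassified == 1


class TestPairedCCTest:
    def test_hand_computed_example(self):
        # d = [1, 2, 3]: mean 2, sd 1, t = 2 / (1/sqrt(3))
        res = paired_cc_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * math.sqrt(3), abs=1e-6)
        assert res.n == 3
        ref = stats.ttest_rel([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(float(ref.pvalue))

    def test_constant_positive_difference_floors_p(self):
        res = paired_cc_test([0.9] * 4, [0.8] * 4)
        assert math.isinf(res.t) and res.t > 0
        assert res.p == 0.0
        assert not res.degenerate

    def test_identical_inputs_degenerate_not_nan_propagation(self):
        res = paired_cc_test([0.5, 0.6], [0.5, 0.6])
        assert res.degenerate

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_cc_test([0.5], [0.4])
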