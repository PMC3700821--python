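"""Linear occupancy scoring, profiles, and Peak/Background decomposition."""

import numpy as np
import pytest

from nucbind import nucleosome_scoring as ns
from nucbind import sequence_core as sc
from nucbind.synthetic_data import make_nucleosome_model
from tests.conftest import random_seq


def naive_score(model, window):
    """Brute-force re-count of canonical k-mer features."""
    total = model.intercept
    for s in range(len(window) - model.k + 1):
        kmer = window[s : s + model.k]
        total += model.weights.get(sc.canonical_kmer(kmer), 0.0)
    return total


class TestModelIO:
    def test_intercept_only(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("#k=2\t#intercept=0.5\n")
        model = ns.load_model(path)
        assert ns.score_window(model, "C" * 147) == 0.5

    def test_gc_dimer_model(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("#k=2\t#intercept=0.0\nGC\t1.0\n")
        model = ns.load_model(path)
        assert ns.score_window(model, "GC" * 73 + "G") == 73.0

    def test_round_trip_preserves_scores(self, tmp_path, rng):
        model = make_nucleosome_model(seed=3)
        path = tmp_path / "m.tsv"
        ns.save_model(model, path)
        back = ns.load_model(path)
        for _ in range(10):
            w = random_seq(rng, 147)
            assert ns.score_window(back, w) == pytest.approx(
                ns.score_window(model, w), abs=0
            )

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("#k=2\t#intercept=0.0\nGC\n")
        with pytest.raises(ValueError, match="line 2"):
            ns.load_model(path)

    def test_duplicate_canonical_keys_summed_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            m = ns.NucleosomeModel(k=2, weights={"GA": 1.0, "TC": 0.5})
        assert m.weights == {"GA": 1.5}


class TestScoreWindow:
    def test_intercept_only_model(self):
        m = ns.NucleosomeModel(k=3, weights={}, intercept=0.7)
        assert ns.score_window(m, "ACG" * 49) == 0.7

    def test_poly_a_mononucleotide(self):
        m = ns.NucleosomeModel(k=1, weights={"A": 1.0}, intercept=0.0)
        assert ns.score_window(m, "A" * 147) == 147.0

    def test_masked_window_undefined(self):
        m = ns.NucleosomeModel(k=1, weights={"A": 1.0})
        assert np.isnan(ns.score_window(m, "a" * 147))
        assert np.isnan(ns.score_window(m, "A" * 146 + "N"))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            ns.score_window(ns.NucleosomeModel(k=1, weights={}), "ACGT")

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_naive_feature_counter(self, rng, k):
        kmers = list(sc.enumerate_kmer_space(sc.MotifPattern(tuple(range(k)), k)))
        weights = {km: float(w) for km, w in zip(kmers, rng.normal(size=len(kmers)))}
        model = ns.NucleosomeModel(k=k, weights=weights, intercept=0.3)
        for _ in range(5):
            w = random_seq(rng, 147)
            assert ns.score_window(model, w) == pytest.approx(naive_score(model, w))

    def test_weight_shift_linearity(self, rng):
        k = 2
        kmers = sc.enumerate_kmer_space(sc.MotifPattern((0, 1), 2))
        w0 = {km: float(x) for km, x in zip(sorted(kmers), rng.normal(size=len(kmers)))}
        delta = 0.25
        m0 = ns.NucleosomeModel(k=k, weights=dict(w0))
        m1 = ns.NucleosomeModel(k=k, weights={km: w + delta for km, w in w0.items()})
        win = random_seq(rng, 147)
        assert ns.score_window(m1, win) - ns.score_window(m0, win) == pytest.approx(
            delta * (147 - k + 1)
        )


class TestProfile:
    def test_length_and_flat_model(self):
        m = ns.NucleosomeModel(k=2, weights={}, intercept=1.5)
        p = ns.profile(m, "C" * 1500)
        assert len(p.scores) == 1354
        assert p.offsets[0] == -677 and p.offsets[-1] == 676
        assert np.allclose(p.scores, 1.5)

    def test_elementwise_equals_score_window(self, rng):
        model = make_nucleosome_model(seed=1)
        flank = random_seq(rng, 1500)
        p = ns.profile(model, flank)
        for s in [0, 100, 677, 1353]:
            assert p.scores[s] == pytest.approx(
                ns.score_window(model, flank[s : s + 147])
            )

    def test_masked_windows_flagged(self, rng):
        model = make_nucleosome_model(seed=1)
        flank = list(random_seq(rng, 1500))
        flank[300] = "n"
        p = ns.profile(model, "".join(flank))
        # every window covering position 300 is undefined
        covered = (p.offsets + 750 - 73 <= 300) & (300 < p.offsets + 750 - 73 + 147)
        assert np.isnan(p.scores[covered]).all()
        assert np.isfinite(p.scores[~covered]).all()


class TestDecompose:
    def test_flat_profile(self):
        p = ns.InosProfile(ns.PROFILE_OFFSETS.copy(), np.full(1354, 2.0))
        d = ns.decompose(p)
        assert (d.peak_value, d.background_value, d.relative_value) == (2.0, 2.0, 0.0)

    def test_anchor_bump(self):
        scores = np.full(1354, 1.0)
        scores[677] = 2.0
        d = ns.decompose(ns.InosProfile(ns.PROFILE_OFFSETS.copy(), scores))
        assert d.relative_value == pytest.approx(1.0)

    def test_triangular_profile_hand_computed(self):
        offsets = ns.PROFILE_OFFSETS
        scores = 1.0 - np.abs(offsets) / 677.0
        d = ns.decompose(ns.InosProfile(offsets.copy(), scores))
        bg = scores[np.abs(offsets) >= 150].mean()
        assert d.peak_value == pytest.approx(1.0)
        assert d.background_value == pytest.approx(bg)
        assert d.relative_value == d.peak_value - d.background_value

    def test_all_background_undefined(self):
        scores = np.full(1354, np.nan)
        scores[677] = 1.0
        d = ns.decompose(ns.InosProfile(ns.PROFILE_OFFSETS.copy(), scores))
        assert np.isnan(d.background_value) and np.isnan(d.relative_value)

    def test_batch_matches_scalar_path(self, rng):
        model = make_nucleosome_model(seed=2)
        flanks = [random_seq(rng, 1500) for _ in range(8)]
        batch = ns.decompose_flanks(model, flanks)
        for i, f in enumerate(flanks):
            d = ns.decompose(ns.profile(model, f))
            assert batch[i, 0] == pytest.approx(d.peak_value)
            assert batch[i, 1] == pytest.approx(d.background_value)
            assert batch[i, 2] == pytest.approx(d.relative_value)


class TestMotifExcludedInos:
    def test_zero_weight_model_unchanged(self, rng):
        m = ns.NucleosomeModel(k=2, weights={}, intercept=0.4)
        flank = random_seq(rng, 1500)
        out = ns.motif_excluded_inos(m, flank, (746, 754), replicates=20, seed=0)
        assert out == pytest.approx(0.4)

    def test_gc_resampling_raises_at_rich_span(self, rng):
        m = ns.NucleosomeModel(k=1, weights={"C": 1.0})  # rewards G/C
        flank = "A" * 1500
        original = ns.score_window(m, flank[677:824])
        out = ns.motif_excluded_inos(m, flank, (746, 754), gc=1.0, replicates=200, seed=1)
        assert out >= original

    def test_seeded_determinism(self, rng):
        model = make_nucleosome_model(seed=5)
        flank = random_seq(rng, 1500)
        a = ns.motif_excluded_inos(model, flank, (700, 713), replicates=50, seed=11)
        b = ns.motif_excluded_inos(model, flank, (700, 713), replicates=50, seed=11)
        assert a == b

    def test_span_outside_central_window_rejected(self):
        m = ns.NucleosomeModel(k=1, weights={})
        with pytest.raises(ValueError):
            ns.motif_excluded_inos(m, "A" * 1500, (100, 110))


class TestAverageProfile:
    def test_mean_of_flats(self):
        p0 = ns.InosProfile(ns.PROFILE_OFFSETS.copy(), np.zeros(1354))
        p2 = ns.InosProfile(ns.PROFILE_OFFSETS.copy(), np.full(1354, 2.0))
        mean, counts = ns.average_profile([p0, p2])
        assert np.allclose(mean.scores, 1.0)
        assert (counts == 2).all()

    def test_single_profile_identity(self, rng):
        p = ns.InosProfile(ns.PROFILE_OFFSETS.copy(), rng.normal(size=1354))
        mean, counts = ns.average_profile([p])
        assert np.array_equal(mean.scores, p.scores)

    def test_nan_entries_excluded(self, rng):
        a = rng.normal(size=1354)
        b = rng.normal(size=1354)
        b[10] = np.nan
        mean, counts = ns.average_profile(
            [
                ns.InosProfile(ns.PROFILE_OFFSETS.copy(), a),
                ns.InosProfile(ns.PROFILE_OFFSETS.copy(), b),
            ]
        )
        assert counts[10] == 1 and mean.scores[10] == a[10]
        assert mean.scores[0] == pytest.approx((a[0] + b[0]) / 2)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ns.average_profile([])


class TestSyntheticModelCalibration:
    def test_standardized_scores(self, rng):
        model = make_nucleosome_model(seed=7)
        wins = [random_seq(rng, 147) for _ in range(2000)]
        scores = np.array([ns.score_window(model, w) for w in wins])
        assert abs(scores.mean()) < 0.1
        assert 0.8 < scores.std() < 1.2

    def test_gc_rich_scores_above_at_rich(self):
        model = make_nucleosome_model(seed=7)
        assert ns.score_window(model, "CG" * 73 + "C") > ns.score_window(
            model, "AT" * 73 + "A"
        )
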