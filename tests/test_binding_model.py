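"""Feature table construction and the logistic binding model."""

import numpy as np
import pandas as pd
import pytest

from nucbind import binding_model as bm
from nucbind import sequence_core as sc
from nucbind.kmer_enrichment import PeakSet


def occ(chrom, center, span=13):
    start = center - span // 2
    return sc.MotifOccurrence(chrom, start, start + span, "+", "GACATGTC", "GACATGTC")


def make_table(rng, n, beta, predictors=("INOS_p", "INOS_b", "CGI", "CLT", "CO", "DHS")):
    """Synthetic feature table drawn straight from the logistic model."""
    tbl = pd.DataFrame(
        {
            "INOS_p": rng.normal(0, 1, n),
            "INOS_b": rng.normal(0, 0.5, n),
            "CGI": (rng.random(n) < 0.05).astype(float),
            "CLT": (rng.random(n) < 0.3).astype(float),
            "CO": (rng.random(n) < 0.2).astype(float),
            "DHS": (rng.random(n) < 0.15).astype(float),
        }
    )
    tbl["INOS_rp"] = tbl.INOS_p - tbl.INOS_b
    eta = beta[0] + tbl[list(predictors)].to_numpy() @ np.asarray(beta[1:])
    tbl["BV"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return tbl


class TestLabelBound:
    def test_center_on_peak_center(self):
        peaks = PeakSet([("c1", 900, 1100, 1000)])
        assert bm.label_bound([occ("c1", 1000)], peaks)[0] == 1

    def test_just_outside_window(self):
        peaks = PeakSet([("c1", 900, 1100, 1000)])
        assert bm.label_bound([occ("c1", 1151)], peaks)[0] == 0

    def test_matches_all_pairs_oracle(self, rng):
        peaks = PeakSet(
            [("c1", int(c) - 50, int(c) + 50, int(c)) for c in rng.integers(100, 50_000, 40)]
        )
        occs = [occ("c1", int(c)) for c in rng.integers(0, 50_000, 200)]
        got = bm.label_bound(occs, peaks)
        pc = [c for _, _, _, c in peaks.intervals]
        expected = [
            int(any(abs(o.center - c) <= 150 for c in pc)) for o in occs
        ]
        assert list(got) == expected


class TestBuildFeatures:
    def test_binary_covariates(self):
        occs = [occ("c1", 1000), occ("c1", 1100), occ("c1", 5000)]
        decomp = np.tile([1.0, 0.5, 0.5], (3, 1))
        table, n_excl = bm.build_features(
            occs,
            decomp,
            cgi_intervals=[("c1", 950, 1050)],
            second_occurrences=[occ("c1", 1120, span=7)],
            dhs_intervals=[("c1", 4000, 6000)],
        )
        assert n_excl == 0
        assert list(table.CGI) == [1, 0, 0]
        assert list(table.CLT) == [1, 1, 0]  # neighbors 100 bp apart
        assert list(table.CO) == [1, 1, 0]
        assert list(table.DHS) == [0, 0, 1]
        assert np.allclose(table.INOS_rp, table.INOS_p - table.INOS_b)

    def test_undefined_rows_excluded_and_counted(self):
        occs = [occ("c1", 1000), occ("c1", 2000)]
        decomp = np.array([[1.0, 0.5, 0.5], [np.nan, np.nan, np.nan]])
        table, n_excl = bm.build_features(occs, decomp, [], [], [])
        assert len(table) == 1 and n_excl == 1

    def test_matches_brute_force_interval_checks(self, rng):
        occs = [occ("c1", int(c)) for c in rng.integers(500, 20_000, 100)]
        decomp = np.column_stack(
            [rng.normal(size=100), rng.normal(size=100), np.zeros(100)]
        )
        decomp[:, 2] = decomp[:, 0] - decomp[:, 1]
        cgi = [("c1", int(s), int(s) + 300) for s in rng.integers(0, 20_000, 10)]
        dhs = [("c1", int(s), int(s) + 500) for s in rng.integers(0, 20_000, 8)]
        second = [occ("c1", int(c), span=7) for c in rng.integers(0, 20_000, 50)]
        table, _ = bm.build_features(occs, decomp, cgi, second, dhs)
        for i, o in enumerate(occs):
            assert table.CGI[i] == int(any(s <= o.center < e for _, s, e in cgi))
            assert table.DHS[i] == int(any(s <= o.center < e for _, s, e in dhs))
            others = [p.center for p in occs if p is not o]
            assert table.CLT[i] == int(
                any(abs(o.center - c) <= 150 for c in others)
            )
            assert table.CO[i] == int(
                any(abs(o.center - s.center) <= 150 for s in second)
            )


class TestPve:
    @pytest.mark.parametrize("d,nd,expected", [(7.0, 7.0, 0.0), (0.0, 9.0, 100.0), (4.5, 9.0, 50.0)])
    def test_formula(self, d, nd, expected):
        assert bm.pve(d, nd) == expected

    def test_zero_null_deviance_undefined(self):
        assert np.isnan(bm.pve(0.0, 0.0))


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        tbl = pd.DataFrame(
            {
                "x": np.r_[np.zeros(40), np.ones(60)],
                "BV": np.r_[np.zeros(30), np.ones(10), np.zeros(20), np.ones(40)].astype(int),
            }
        )
        res = bm.fit_logistic(tbl, ("x",))
        log_or = np.log((40 * 30) / (20 * 10))
        assert res.coefficients["x"] == pytest.approx(log_or, abs=1e-6)
        assert res.coefficients["const"] == pytest.approx(np.log(10 / 30), abs=1e-6)
        assert res.converged

    def test_permuted_labels_give_near_zero_pve(self, rng):
        tbl = make_table(rng, 5000, [-2.5, 1.0, 0.5, 0.8, 0.7, 1.2, 1.5])
        tbl["BV"] = rng.permutation(tbl["BV"].to_numpy())
        res = bm.fit_logistic(tbl, ("INOS_p", "INOS_b", "CGI", "CLT", "CO", "DHS"))
        assert res.pve < 0.5

    def test_perfect_separation_flags_and_saturates(self):
        tbl = pd.DataFrame(
            {"x": np.r_[np.zeros(50), np.ones(50)], "BV": np.r_[np.zeros(50), np.ones(50)].astype(int)}
        )
        res = bm.fit_logistic(tbl, ("x",))
        assert not res.converged
        assert res.pve > 99.5

    def test_single_class_rejected(self):
        tbl = pd.DataFrame({"x": [0.0, 1.0], "BV": [1, 1]})
        with pytest.raises(ValueError):
            bm.fit_logistic(tbl, ("x",))

    def test_collinear_inos_terms_still_fit(self, rng):
        tbl = make_table(rng, 3000, [-2.0, 1.0, 0.5, 0.8, 0.7, 1.2, 1.5])
        res = bm.fit_logistic(tbl, ("INOS_p", "INOS_b", "INOS_rp"))
        assert np.isfinite(res.pve) and 0 < res.pve < 100

    def test_nested_pve_monotone(self, rng):
        tbl = make_table(rng, 8000, [-2.5, 1.0, 0.5, 0.8, 0.7, 1.2, 1.5])
        sets = [
            ("INOS_p", "INOS_b", "INOS_rp"),
            ("INOS_p", "INOS_b", "INOS_rp", "CGI"),
            ("INOS_p", "INOS_b", "INOS_rp", "CGI", "CLT"),
            ("INOS_p", "INOS_b", "INOS_rp", "CGI", "CLT", "CO"),
            ("INOS_p", "INOS_b", "INOS_rp", "CGI", "CLT", "CO", "DHS"),
        ]
        pves = [bm.fit_logistic(tbl, s).pve for s in sets]
        assert all(b >= a - 1e-8 for a, b in zip(pves, pves[1:]))


class TestCvAuc:
    def test_constant_scores_give_half(self):
        tbl = pd.DataFrame(
            {"x": np.ones(200), "BV": np.r_[np.zeros(150), np.ones(50)].astype(int)}
        )
        assert bm.cv_auc(tbl, ("x",), folds=5, seed=0) == 0.5

    def test_perfect_separation_gives_one(self):
        tbl = pd.DataFrame(
            {"x": np.r_[np.zeros(100), np.ones(100)], "BV": np.r_[np.zeros(100), np.ones(100)].astype(int)}
        )
        assert bm.cv_auc(tbl, ("x",), folds=5, seed=0) == 1.0

    def test_invariant_under_monotone_transform(self, rng):
        tbl = make_table(rng, 2000, [-2.0, 1.0, 0.5, 0.8, 0.7, 1.2, 1.5])
        a = bm.cv_auc(tbl, ("INOS_p",), seed=4)
        tbl2 = tbl.copy()
        tbl2["INOS_p"] = np.exp(tbl2["INOS_p"] / 2)  # strictly increasing map
        b = bm.cv_auc(tbl2, ("INOS_p",), seed=4)
        # the monotone map changes fitted scores only monotonically per fold
        assert b == pytest.approx(a, abs=0.01)

    def test_cv_error_bounded_by_base_rate(self, rng):
        tbl = make_table(rng, 3000, [-2.5, 1.5, 0.5, 0.8, 0.7, 1.2, 1.5])
        err = bm.cv_error(tbl, ("INOS_p", "INOS_b"), seed=1)
        assert 0 <= err <= tbl.BV.mean() + 0.02


class TestPercentBoundByInos:
    def test_all_bound(self, rng):
        tbl = pd.DataFrame({"INOS_p": rng.normal(size=100), "BV": np.ones(100, dtype=int)})
        h = bm.percent_bound_by_inos(tbl)
        assert (h.loc[h.n_total > 0, "percent"] == 100.0).all()

    def test_none_bound(self, rng):
        tbl = pd.DataFrame({"INOS_p": rng.normal(size=100), "BV": np.zeros(100, dtype=int)})
        h = bm.percent_bound_by_inos(tbl)
        assert (h.loc[h.n_total > 0, "percent"] == 0.0).all()

    def test_totals_conserved(self, rng):
        tbl = pd.DataFrame(
            {"INOS_p": rng.normal(size=500), "BV": (rng.random(500) < 0.2).astype(int)}
        )
        h = bm.percent_bound_by_inos(tbl)
        assert h.n_total.sum() == 500
        assert h.n_bound.sum() == tbl.BV.sum()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            bm.percent_bound_by_inos(pd.DataFrame({"INOS_p": [], "BV": []}))


def test_parameter_recovery_single_replicate(rng):
    beta = [-3.5, 1.0, 0.5, 0.8, 0.7, 1.2, 1.5]
    preds = ("INOS_p", "INOS_b", "CGI", "CLT", "CO", "DHS")
    tbl = make_table(rng, 20_000, beta, preds)
    res = bm.fit_logistic(tbl, preds)
    truth = dict(zip(("const",) + preds, beta))
    for name, b in res.coefficients.items():
        se = res.std_errors[name]
        assert abs(b - truth[name]) < 3.5 * se
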