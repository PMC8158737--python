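"""Evaluation statistics against published values and independent oracles."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from conftest import TABLE1_COUNTS
from spinegrader.datamodel import PATHOLOGIES, SEGMENTS, ReferenceReading, ValidationError
from spinegrader.diagstats import (
    ConfusionCounts,
    accuracy_ci,
    confusion,
    evaluate_table,
    mcnemar,
    metrics,
    pooled_confusion,
)


def _random_readings(rng, n_studies, p_truth=0.15, p_flip=0.2):
    truth, pred = {}, {}
    for i in range(n_studies):
        sid = f"s{i}"
        t = ReferenceReading(study_id=sid)
        p = ReferenceReading(study_id=sid)
        for seg in SEGMENTS:
            for path in PATHOLOGIES:
                tv = rng.random() < p_truth
                pv = tv ^ (rng.random() < p_flip)
                t.set(seg, path, tv)
                p.set(seg, path, pv)
        truth[sid], pred[sid] = t, p
    return pred, truth


class TestConfusion:
    def test_identity_prediction(self):
        rng = np.random.default_rng(0)
        _, truth = _random_readings(rng, 10)
        c = pooled_confusion(truth, truth, "herniation")
        assert c.fp == 0 and c.fn == 0 and c.total == 60

    def test_all_negative_prediction(self):
        truth = {"s": ReferenceReading(study_id="s")}
        truth["s"].set("L1/L2", "stenosis", True)
        pred = {"s": ReferenceReading(study_id="s")}
        c = pooled_confusion(pred, truth, "stenosis")
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 5, 0, 1)

    def test_segment_universe_mismatch_rejected(self):
        a = ReferenceReading(study_id="s")
        b = ReferenceReading(study_id="s", segments=("L4/L5",))
        with pytest.raises(ValidationError):
            confusion(a, b, "herniation")

    def test_matches_brute_force_recount_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            pred, truth = _random_readings(rng, 5)
            for path in PATHOLOGIES:
                c = pooled_confusion(pred, truth, path)
                tp = tn = fp = fn = 0
                for sid in truth:
                    for seg in SEGMENTS:
                        t = truth[sid].get(seg, path)
                        p = pred[sid].get(seg, path)
                        tp += t and p
                        tn += (not t) and (not p)
                        fp += (not t) and p
                        fn += t and (not p)
                assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
                s = metrics(c)
                if tp + fn:
                    assert s.sensitivity == pytest.approx(100 * tp / (tp + fn), abs=0.005)
                assert s.accuracy == pytest.approx(100 * (tp + tn) / c.total, abs=0.005)

    def test_swapping_pred_and_truth_transposes_discordants(self):
        rng = np.random.default_rng(1)
        pred, truth = _random_readings(rng, 8)
        for path in PATHOLOGIES:
            c = pooled_confusion(pred, truth, path)
            cs = pooled_confusion(truth, pred, path)
            assert (cs.fp, cs.fn) == (c.fn, c.fp)
            assert metrics(cs).accuracy == metrics(c).accuracy
            assert mcnemar(cs) == mcnemar(c)


class TestPublishedTable:
    """The published diagnostic-performance table, cell by cell."""

    EXPECTED = {
        # pathology: (sens, spec, acc, ppv, npv) in percent
        "herniation": (75.32, 87.92, 86.82, 37.18, 97.40),
        "extrusion": (89.13, 86.34, 86.49, 26.28, 99.32),
        "stenosis": (77.14, 98.94, 98.09, 75.00, 99.06),
        "bulging": (51.88, 79.74, 75.56, 31.08, 90.39),
        "nerve_root_compression": (71.19, 91.71, 90.54, 34.15, 98.14),
        "spondylolisthesis": (80.00, 87.79, 87.61, 13.11, 99.48),
    }

    @pytest.mark.parametrize("pathology", list(TABLE1_COUNTS))
    def test_metric_cells(self, pathology):
        c = ConfusionCounts(*TABLE1_COUNTS[pathology])
        s = metrics(c)
        sens, spec, acc, ppv, npv = self.EXPECTED[pathology]
        assert s.sensitivity == pytest.approx(sens, abs=0.005)
        assert s.specificity == pytest.approx(spec, abs=0.005)
        assert s.accuracy == pytest.approx(acc, abs=0.005)
        assert s.ppv == pytest.approx(ppv, abs=0.005)
        assert s.npv == pytest.approx(npv, abs=0.005)

    def test_herniation_accuracy_ci(self):
        c = ConfusionCounts(*TABLE1_COUNTS["herniation"])
        low, high = accuracy_ci(c)
        assert low <= (c.tp + c.tn) / c.total <= high
        assert round(low, 2) == 0.84 and round(high, 2) == 0.89


class TestMcNemar:
    def test_stenosis_counts_give_p_exactly_one(self):
        assert mcnemar(ConfusionCounts(*TABLE1_COUNTS["stenosis"])) == 1.0

    def test_herniation_counts_give_p_below_point001(self):
        assert mcnemar(ConfusionCounts(*TABLE1_COUNTS["herniation"])) < 0.001

    def test_symmetric_discordants_give_p_one(self):
        c = ConfusionCounts(10, 10, 5, 5)
        assert mcnemar(c, "cc_chi2") == pytest.approx(1.0, abs=1e-9)
        assert mcnemar(c, "exact") == pytest.approx(1.0)

    def test_no_discordants_give_p_one(self):
        assert mcnemar(ConfusionCounts(5, 5, 0, 0)) == 1.0

    @pytest.mark.parametrize("fp,fn", [(9, 8), (98, 19), (20, 5), (3, 0)])
    def test_agrees_with_statsmodels(self, fp, fn):
        c = ConfusionCounts(10, 10, fp, fn)
        table = [[c.tp, c.fp], [c.fn, c.tn]]
        ours = mcnemar(c, "cc_chi2")
        ref = sm_mcnemar(table, exact=False, correction=True).pvalue
        # statsmodels clips chi2 at 0 the same way only for |fp-fn|<=1
        if abs(fp - fn) > 1:
            assert ours == pytest.approx(float(ref))
        exact_ours = mcnemar(c, "exact")
        exact_ref = sm_mcnemar(table, exact=True).pvalue
        assert exact_ours == pytest.approx(float(exact_ref))


class TestAccuracyCI:
    def test_perfect_score_upper_bound_is_one(self):
        low, high = accuracy_ci(ConfusionCounts(10, 0, 0, 0))
        assert high == 1.0 and low < 1.0

    def test_exact_interval_wider_than_normal_approximation(self):
        from statsmodels.stats.proportion import proportion_confint

        c = ConfusionCounts(8, 5, 1, 1)
        lo_e, hi_e = accuracy_ci(c)
        lo_n, hi_n = proportion_confint(13, 15, method="normal")
        assert hi_e - lo_e > hi_n - lo_n

    def test_coverage_near_nominal(self):
        # 10 000 binomial draws at n=888, p=0.87: Clopper-Pearson interval
        # must cover p in ~95% of draws (conservative, so >= 95 - MC error)
        rng = np.random.default_rng(7)
        n, p, reps = 888, 0.87, 10_000
        k = rng.binomial(n, p, size=reps)
        low = stats.beta.ppf(0.025, k, n - k + 1)
        low = np.where(k == 0, 0.0, low)
        high = stats.beta.ppf(0.975, k + 1, n - k)
        high = np.where(k == n, 1.0, high)
        coverage = np.mean((low <= p) & (p <= high))
        assert 0.944 <= coverage <= 0.985
        # the vectorized formula matches the implementation
        c = ConfusionCounts(int(k[0]), 0, 0, n - int(k[0]))
        assert accuracy_ci(c) == pytest.approx((low[0], high[0]))


class TestEvaluateTable:
    def test_identical_readings_give_perfect_row(self):
        rng = np.random.default_rng(2)
        _, truth = _random_readings(rng, 6)
        df = evaluate_table(truth, truth)
        assert set(df["pathology"]) == set(PATHOLOGIES)
        assert (df["accuracy"] == 100.0).all()
        assert (df["mcnemar_p"] == 1.0).all()

    def test_undefined_rates_render_na(self):
        truth = {"s": ReferenceReading(study_id="s")}
        pred = {"s": ReferenceReading(study_id="s")}
        df = evaluate_table(pred, truth)
        row = df[df["pathology"] == "herniation"].iloc[0]
        assert row["sensitivity"] == "NA" and row["ppv"] == "NA"
        assert row["specificity"] == 100.0
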