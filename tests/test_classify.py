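import numpy as np
import pandas as pd
import pytest

import cortexfate as cf
from cortexfate.classify import (
    MARKER_GENES, OUTCOME_LABELS, ThresholdSet, classify, fit_thresholds,
    genotype_frequencies, line_bias_interval, line_frequencies,
    training_agreement, wilson_interval,
)
from cortexfate.io import SampleMetadata

TH = ThresholdSet(foxg1_low=8.4, dlx5_low=5.8, nkx21_high=6.5, pax6_low=7.0,
                  foxg1_verylow=7.8, dlx5_verylow=4.6)


def _expr(rows: np.ndarray, ids=None) -> cf.ExpressionMatrix:
    return cf.ExpressionMatrix(
        pd.DataFrame(rows, columns=list(MARKER_GENES),
                     index=ids or [f"s{i}" for i in range(len(rows))]),
        scale="log2",
    )


def truth_table_label(f, d, n, p, th: ThresholdSet) -> str:
    """Independent enumeration of the five disjoint regions of marker space."""
    hc = f < th.foxg1_verylow and d < th.dlx5_verylow
    caudal = f < th.foxg1_low and d < th.dlx5_low
    regions = {
        "highly_caudalized": hc,
        "partially_caudalized": caudal and not hc,
        "highly_ventralized": (not caudal) and n >= th.nkx21_high
        and p < th.pax6_low,
        "partially_ventralized": (not caudal) and n >= th.nkx21_high
        and p >= th.pax6_low,
        "dorsalized": (not caudal) and n < th.nkx21_high,
    }
    assert sum(regions.values()) == 1
    return next(lab for lab, hit in regions.items() if hit)


class TestClassify:
    def test_matches_truth_table_on_random_marker_vectors(self):
        rng = np.random.default_rng(20)
        X = rng.uniform(3, 11, size=(1000, 4))
        labels = classify(_expr(X), TH)
        expected = [truth_table_label(*row, TH) for row in X]
        assert labels.tolist() == expected

    def test_high_pax6_high_nkx21_is_partially_ventralized(self):
        X = np.array([[9.5, 7.0, 8.0, 8.5]])  # FOXG1, DLX5, NKX2-1, PAX6
        assert classify(_expr(X), TH).iloc[0] == "partially_ventralized"

    def test_fall_through_is_dorsalized(self):
        X = np.array([[9.5, 7.0, 5.0, 9.0]])
        assert classify(_expr(X), TH).iloc[0] == "dorsalized"

    def test_caudal_call_takes_precedence_over_ventral(self):
        # FOXG1/DLX5 low AND NKX2-1 high: still caudal
        X = np.array([[7.0, 4.0, 9.0, 4.0]])
        assert classify(_expr(X), TH).iloc[0] == "highly_caudalized"

    def test_raising_nkx21_never_unventralizes(self):
        rng = np.random.default_rng(21)
        X = rng.uniform(3, 11, size=(300, 4))
        before = classify(_expr(X), TH)
        X2 = X.copy()
        X2[:, 2] += rng.uniform(0, 3, size=300)
        after = classify(_expr(X2), TH)
        ventral = {"highly_ventralized", "partially_ventralized"}
        for b, a in zip(before, after):
            if b in ventral:
                assert a != "dorsalized"

    def test_lowering_foxg1_dlx5_keeps_caudal_calls(self):
        rng = np.random.default_rng(22)
        X = rng.uniform(3, 11, size=(300, 4))
        before = classify(_expr(X), TH)
        X2 = X.copy()
        X2[:, 0] -= rng.uniform(0, 3, size=300)
        X2[:, 1] -= rng.uniform(0, 3, size=300)
        after = classify(_expr(X2), TH)
        caudal = {"highly_caudalized", "partially_caudalized"}
        for b, a in zip(before, after):
            if b in caudal:
                assert a in caudal

    def test_missing_marker_raises_by_name(self):
        expr = cf.ExpressionMatrix(
            pd.DataFrame({"FOXG1": [9.0], "DLX5": [5.0], "PAX6": [8.0]}),
            scale="log2")
        with pytest.raises(KeyError, match="NKX2-1"):
            classify(expr, TH)

    def test_linear_scale_rejected(self):
        expr = cf.ExpressionMatrix(
            pd.DataFrame(np.full((1, 4), 100.0), columns=list(MARKER_GENES)))
        with pytest.raises(ValueError):
            classify(expr, TH)


# ---------------------------------------------------------------------------
# threshold fitting and its brute-force oracle
# ---------------------------------------------------------------------------

CLASS_BOXES = {
    # FOXG1, DLX5, NKX2-1, PAX6 sampling boxes per late outcome
    "dorsalized": [(9.0, 10.0), (4.0, 5.5), (4.0, 5.2), (8.0, 9.5)],
    "highly_ventralized": [(9.0, 10.0), (6.5, 8.0), (7.5, 9.0), (4.0, 6.2)],
    "partially_ventralized": [(9.0, 10.0), (6.5, 8.0), (7.5, 9.0), (7.2, 9.5)],
    "partially_caudalized": [(7.4, 8.2), (4.0, 5.5), (4.0, 5.2), (7.0, 8.5)],
    "highly_caudalized": [(5.0, 6.6), (2.5, 3.6), (4.0, 5.2), (6.0, 7.5)],
}


def make_training_set(seed: int, with_hc: bool = True, n_per_class: int = 5):
    rng = np.random.default_rng(seed)
    classes = list(CLASS_BOXES)
    if not with_hc:
        classes.remove("highly_caudalized")
    rows, labels = [], []
    for lab in classes:
        for _ in range(n_per_class):
            rows.append([rng.uniform(lo, hi) for lo, hi in CLASS_BOXES[lab]])
            labels.append(lab)
    ids = [f"t{i}" for i in range(len(rows))]
    expr = _expr(np.array(rows), ids=ids)
    pairs = [(i, i) for i in ids]
    late = dict(zip(ids, labels))
    return expr, late, pairs


def _oracle_candidates(values):
    v = sorted(set(values))
    mids = [(a + b) / 2 for a, b in zip(v, v[1:])]
    return [v[0] - 1.0] + mids + [v[-1] + 1.0]


def _oracle_margin(cut, values):
    return min(abs(x - cut) for x in values)


def oracle_fit(expr, late, pairs, verylow_offset=2.0) -> ThresholdSet:
    """Plain-loop exhaustive grid search mirroring the fitting procedure."""
    ids = [p[0] for p in pairs]
    M = expr.values.loc[ids]
    fox, dlx = M["FOXG1"].tolist(), M["DLX5"].tolist()
    nkx, pax = M["NKX2-1"].tolist(), M["PAX6"].tolist()
    y = [late[p[1]] for p in pairs]

    def search(xs, ys, score):
        best = None
        for cx in _oracle_candidates(xs):
            for cy in _oracle_candidates(ys):
                key = (score(cx, cy),
                       min(_oracle_margin(cx, xs), _oracle_margin(cy, ys)),
                       -cx, -cy)
                if best is None or key > best[0]:
                    best = (key, cx, cy)
        return best[1], best[2]

    caudal = {"partially_caudalized", "highly_caudalized"}

    def caudal_score(cx, cy):
        return sum((f < cx and d < cy) == (lab in caudal)
                   for f, d, lab in zip(fox, dlx, y))

    fl, dl = search(fox, dlx, caudal_score)

    rest = [i for i in range(len(ids)) if not (fox[i] < fl and dlx[i] < dl)]

    def ventral_score(cn, cp):
        agree = 0
        for i in rest:
            if nkx[i] >= cn and pax[i] < cp:
                pred = "highly_ventralized"
            elif nkx[i] >= cn:
                pred = "partially_ventralized"
            else:
                pred = "dorsalized"
            agree += pred == y[i]
        return agree

    nh, pl = search([nkx[i] for i in rest], [pax[i] for i in rest],
                    ventral_score)

    pred_caud = [i for i in range(len(ids)) if fox[i] < fl and dlx[i] < dl]
    if any(lab == "highly_caudalized" for lab in y) and pred_caud:
        def vl_score(cx, cy):
            return sum((fox[i] < cx and dlx[i] < cy)
                       == (y[i] == "highly_caudalized") for i in pred_caud)
        fvl, dvl = search([fox[i] for i in pred_caud],
                          [dlx[i] for i in pred_caud], vl_score)
        fvl, dvl = min(fvl, fl), min(dvl, dl)
    else:
        fvl, dvl = fl - verylow_offset, dl - verylow_offset
    return ThresholdSet(foxg1_low=fl, dlx5_low=dl, nkx21_high=nh, pax6_low=pl,
                        foxg1_verylow=fvl, dlx5_verylow=dvl,
                        provenance="fitted")


class TestFitThresholds:
    def test_separable_training_gives_full_agreement_and_interior_cutoffs(self):
        expr, late, pairs = make_training_set(seed=30)
        th = fit_thresholds(expr, late, pairs)
        assert training_agreement(expr, late, pairs, th) == 1.0
        vals = expr.values
        # caudal cutoffs sit strictly between caudal and rostral FOXG1 ranges
        caudal_ids = [i for i, l in late.items()
                      if l.endswith("caudalized")]
        rostral_ids = [i for i in late if i not in caudal_ids]
        assert vals.loc[caudal_ids, "FOXG1"].max() < th.foxg1_low
        assert th.foxg1_low < vals.loc[rostral_ids, "FOXG1"].min()
        hv_pv = [i for i, l in late.items() if l.endswith("ventralized")]
        dorsal = [i for i, l in late.items() if l == "dorsalized"]
        assert vals.loc[dorsal, "NKX2-1"].max() < th.nkx21_high
        assert th.nkx21_high < vals.loc[hv_pv, "NKX2-1"].min()

    @pytest.mark.parametrize("seed,with_hc", [(40, True), (41, False),
                                              (42, True), (43, False)])
    def test_matches_exhaustive_grid_oracle(self, seed, with_hc):
        expr, late, pairs = make_training_set(seed=seed, with_hc=with_hc)
        th = fit_thresholds(expr, late, pairs)
        want = oracle_fit(expr, late, pairs)
        for name in ("foxg1_low", "dlx5_low", "nkx21_high", "pax6_low",
                     "foxg1_verylow", "dlx5_verylow"):
            assert getattr(th, name) == pytest.approx(getattr(want, name),
                                                      abs=1e-12), name

    def test_stable_under_small_jitter(self):
        expr, late, pairs = make_training_set(seed=44)
        th = fit_thresholds(expr, late, pairs)
        rng = np.random.default_rng(45)
        jittered = cf.ExpressionMatrix(
            expr.values + rng.uniform(-0.01, 0.01, expr.values.shape),
            scale="log2")
        th2 = fit_thresholds(jittered, late, pairs)
        l1 = classify(expr, th)
        l2 = classify(expr, th2)
        assert l1.tolist() == l2.tolist()

    def test_nonseparable_data_warns_and_returns_best_effort(self):
        expr, late, pairs = make_training_set(seed=46, n_per_class=4)
        # relabel one dorsalized sample as highly ventralized: inseparable
        dorsal_id = next(i for i, l in late.items() if l == "dorsalized")
        late = dict(late)
        late[dorsal_id] = "highly_ventralized"
        with pytest.warns(UserWarning, match="not separable"):
            th = fit_thresholds(expr, late, pairs)
        assert training_agreement(expr, late, pairs, th) < 1.0

    def test_verylow_defaults_from_offset_without_hc_examples(self):
        expr, late, pairs = make_training_set(seed=47, with_hc=False)
        th = fit_thresholds(expr, late, pairs, verylow_offset=2.0)
        assert th.foxg1_verylow == pytest.approx(th.foxg1_low - 2.0)
        assert th.dlx5_verylow == pytest.approx(th.dlx5_low - 2.0)


# ---------------------------------------------------------------------------
# line and genotype summaries
# ---------------------------------------------------------------------------

def _meta(lines: dict[str, str]) -> SampleMetadata:
    return SampleMetadata(pd.DataFrame({
        "sample_id": list(lines), "uin": list(lines),
        "line": list(lines.values()),
        "genotype": ["control"] * len(lines),
    }))


class TestLineFrequencies:
    def test_simple_frequencies(self):
        labels = pd.Series(
            {"s1": "dorsalized", "s2": "dorsalized", "s3": "highly_ventralized",
             "s4": "dorsalized", "s5": "dorsalized"})
        meta = _meta({"s1": "A", "s2": "A", "s3": "A", "s4": "B", "s5": "B"})
        tab = line_frequencies(labels, meta, min_n=2)
        assert tab.loc["A", "freq_dorsalized"] == pytest.approx(2 / 3)
        freq_cols = [f"freq_{l}" for l in OUTCOME_LABELS]
        np.testing.assert_allclose(tab[freq_cols].sum(axis=1), 1.0)

    def test_single_differentiation_line_excluded(self):
        labels = pd.Series({"s1": "dorsalized", "s2": "dorsalized",
                            "s3": "dorsalized"})
        meta = _meta({"s1": "A", "s2": "A", "s3": "B"})
        tab = line_frequencies(labels, meta, min_n=2)
        assert list(tab.index) == ["A"]

    def test_line_frequencies_match_generator_probabilities(self, sim149):
        from cortexfate.simulate import line_outcome_probabilities
        labels = sim149.truth.labels()
        tab = line_frequencies(labels, sim149.metadata, min_n=2)
        for line in tab.index:
            n = tab.loc[line, "n_differentiations"]
            probs = line_outcome_probabilities(line, n_mc=2000, seed=7)
            for lab in OUTCOME_LABELS:
                p = probs[lab]
                se = np.sqrt(p * (1 - p) / n) + 0.02  # + MC error allowance
                assert abs(tab.loc[line, f"freq_{lab}"] - p) <= 4 * se + 1e-9


class TestLineBiasInterval:
    def test_equal_proportions_interval_contains_zero(self):
        lo, hi = line_bias_interval((5, 10), (5, 10))
        assert lo < 0 < hi

    def test_published_worked_example(self):
        # 56/70 vs 48/80: difference 0.2, 95% interval (0.0524, 0.3339)
        lo, hi = line_bias_interval((56, 70), (48, 80))
        assert lo == pytest.approx(0.0524, abs=5e-4)
        assert hi == pytest.approx(0.3339, abs=5e-4)

    def test_consistently_nondorsal_line_flagged(self):
        lo, hi = line_bias_interval((0, 26), (86, 123))
        assert hi < 0

    def test_empty_comparison_group_raises(self):
        with pytest.raises(ValueError):
            line_bias_interval((1, 2), (0, 0))

    def test_wilson_interval_brackets_proportion(self):
        lo, hi = wilson_interval(8, 10)
        assert lo < 0.8 < hi


class TestGenotypeFrequencies:
    @staticmethod
    def _line_table(freqs: dict[str, float], ns: dict[str, int]):
        rows = []
        for line, f in freqs.items():
            row = {f"freq_{l}": 0.0 for l in OUTCOME_LABELS}
            row["freq_dorsalized"] = f
            row["freq_highly_ventralized"] = 1 - f
            row["n_differentiations"] = ns[line]
            rows.append(pd.Series(row, name=line))
        return pd.DataFrame(rows)

    def test_lines_weighted_equally_regardless_of_n(self):
        tab = self._line_table({"A": 1.0, "B": 0.5, "C": 0.0},
                               {"A": 20, "B": 2, "C": 5})
        out = genotype_frequencies(tab, {"A": "g1", "B": "g1", "C": "g1"},
                                   min_lines=3)
        assert out.loc["g1", "freq_dorsalized"] == pytest.approx(0.5)
        assert out.loc["g1", "freq_partly_cortical"] == pytest.approx(0.5)

    def test_two_line_genotype_excluded(self):
        tab = self._line_table({"A": 1.0, "B": 0.5, "C": 0.0, "D": 0.4,
                                "E": 0.6},
                               dict.fromkeys("ABCDE", 3))
        out = genotype_frequencies(
            tab, {"A": "g1", "B": "g1", "C": "g1", "D": "g2", "E": "g2"})
        assert list(out.index) == ["g1"]

    def test_missing_line_in_map_raises(self):
        tab = self._line_table({"A": 1.0}, {"A": 2})
        with pytest.raises(KeyError):
            genotype_frequencies(tab, {})
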