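import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chemoscreen.datatypes import ChemoscreenError, PredictionMatrix
from chemoscreen.screen import (
    NON_RESPONDER,
    RESPONDER,
    compute_soc_score,
    correlate_with_soc,
    differential_screen,
    intersect_candidates,
    pooled_t_test,
    screen_records_to_frame,
    stratify,
)


def _pred(values, samples=None, drugs=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    drugs = drugs or [f"d{i}" for i in range(values.shape[1])]
    return PredictionMatrix(pd.DataFrame(values, index=samples, columns=drugs))


def textbook_pooled_t(a, b):
    """Independent oracle: the textbook pooled-variance two-sample t."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


# ---------------------------------------------------------------------------
# SOC score and stratification


def test_compute_soc_score_is_columnwise_mean():
    pred = _pred([[3.0, 5.0, 9.0], [1.0, 2.0, 9.0]], drugs=["cisplatin", "docetaxel", "other"])
    score = compute_soc_score(pred, ["cisplatin", "docetaxel"])
    np.testing.assert_allclose(score.to_numpy(), [4.0, 1.5])
    # both columns equal -> score equals either column
    pred2 = _pred([[2.0, 2.0], [7.0, 7.0]], drugs=["cisplatin", "docetaxel"])
    score2 = compute_soc_score(pred2, ["cisplatin", "docetaxel"])
    np.testing.assert_allclose(score2.to_numpy(), pred2.data["cisplatin"].to_numpy())
    with pytest.raises(ChemoscreenError, match="absent"):
        compute_soc_score(pred, ["cisplatin", "paclitaxel"])


def test_stratify_top_quantile_counts_and_identity():
    score = pd.Series(np.arange(1.0, 11.0), index=[f"s{i}" for i in range(10)])
    strat = stratify(score, 0.20)
    assert sorted(strat.non_responders) == ["s8", "s9"]  # scores 9 and 10
    assert strat.labels.value_counts()[NON_RESPONDER] == 2
    assert min(score[strat.non_responders]) >= max(score[strat.responders])


def test_stratify_mean_split():
    score = pd.Series([1.0, 2.0, 3.0, 10.0], index=list("abcd"))
    strat = stratify(score, rule="mean_split")
    assert strat.non_responders == ["d"]


def test_stratify_tie_at_cut_lexicographic():
    score = pd.Series([5.0, 5.0, 5.0, 1.0, 0.0], index=["zz", "aa", "mm", "x", "y"])
    strat = stratify(score, 0.40)  # k = 2, three tied at the top
    assert sorted(strat.non_responders) == ["aa", "mm"]


def test_stratify_degenerate_inputs():
    with pytest.raises(ChemoscreenError, match="n >= 5"):
        stratify(pd.Series([1.0, 2.0], index=["a", "b"]), 0.2)
    flat = pd.Series(np.ones(8), index=[f"s{i}" for i in range(8)])
    with pytest.raises(ChemoscreenError, match="identical"):
        stratify(flat, 0.2)
    with pytest.raises(ChemoscreenError, match="rule"):
        stratify(pd.Series(np.arange(6.0)), rule="median")


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_stratify_invariant_to_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    score = pd.Series(rng.normal(size=20), index=[f"s{i:02d}" for i in range(20)])
    base = stratify(score, 0.25)
    for transform in (lambda x: 3 * x + 1, np.exp, lambda x: x**3):
        other = stratify(pd.Series(transform(score.to_numpy()), index=score.index), 0.25)
        pd.testing.assert_series_equal(base.labels, other.labels)


# ---------------------------------------------------------------------------
# pooled t


def test_pooled_t_textbook_fixture():
    t, p = pooled_t_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    t_oracle, df, p_oracle = textbook_pooled_t([1, 2, 3], [4, 5, 6])
    assert df == 4
    assert t == pytest.approx(t_oracle, abs=1e-12)
    assert abs(t) == pytest.approx(3.674, abs=5e-4)
    assert p == pytest.approx(p_oracle, abs=1e-12)
    assert p == pytest.approx(0.0213, abs=5e-4)


def test_pooled_t_label_swap_antisymmetry(rng):
    a, b = rng.normal(size=6), rng.normal(size=9)
    t1, p1 = pooled_t_test(a, b)
    t2, p2 = pooled_t_test(b, a)
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)


def test_pooled_t_degenerate_conventions():
    assert pooled_t_test([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)
    t, p = pooled_t_test([0.0, 0.0], [1.0, 1.0])
    assert np.isinf(t) and t < 0 and p == 0.0
    t, p = pooled_t_test([0.0, 0.0], [1.0, 1.0], tail="one_sided")
    assert p == 0.0
    t, p = pooled_t_test([1.0, 1.0], [0.0, 0.0], tail="one_sided")
    assert p == 1.0
    assert pooled_t_test([2.0, 2.0], [2.0, 2.0], tail="one_sided")[1] == 0.5
    with pytest.raises(ChemoscreenError, match=">= 2"):
        pooled_t_test([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# differential screen


def _screen_fixture():
    # 6 samples; SOC drugs define the score; d_hit lower in non-responders,
    # d_null flat, d_wrongdir higher in non-responders
    samples = [f"s{i}" for i in range(6)]
    data = pd.DataFrame(
        {
            "cisplatin": [1.0, 2.0, 3.0, 4.0, 9.0, 10.0],
            "docetaxel": [1.0, 2.0, 3.0, 4.0, 9.0, 10.0],
            "d_hit": [4.0, 5.0, 6.0, 4.5, 1.5, 2.2],
            "d_null": [5.0, 5.1, 4.9, 5.0, 5.05, 4.95],
            "d_wrongdir": [1.0, 1.5, 1.2, 1.1, 9.0, 9.5],
        },
        index=samples,
    )
    return PredictionMatrix(data)


def test_differential_screen_direction_and_alpha():
    pred = _screen_fixture()
    soc = compute_soc_score(pred, ["cisplatin", "docetaxel"])
    strat = stratify(soc, 1 / 3)
    records = differential_screen(pred, strat, alpha=0.05,
                                  soc_drugs=["cisplatin", "docetaxel"])
    by_drug = {r.drug_id: r for r in records}
    assert set(by_drug) == {"d_hit", "d_null", "d_wrongdir"}  # SOC excluded
    assert by_drug["d_hit"].candidate
    assert by_drug["d_hit"].mean_non_responder < by_drug["d_hit"].mean_responder
    assert not by_drug["d_null"].candidate
    # significant in the wrong direction is never a candidate
    assert by_drug["d_wrongdir"].p_value < 0.05
    assert not by_drug["d_wrongdir"].candidate
    # every record honours the candidate invariant
    for r in records:
        assert r.candidate == (
            r.mean_non_responder < r.mean_responder and r.p_value < 0.05
        )
    frame = screen_records_to_frame(records)
    assert {"mean_responder", "mean_non_responder", "t_statistic", "p_value",
            "fdr_q", "candidate"} <= set(frame.columns)


def test_differential_screen_identical_groups():
    samples = [f"s{i}" for i in range(6)]
    data = pd.DataFrame(
        {"cisplatin": np.arange(6.0), "docetaxel": np.arange(6.0),
         "flat": np.ones(6)},
        index=samples,
    )
    pred = PredictionMatrix(data)
    strat = stratify(compute_soc_score(pred, ["cisplatin", "docetaxel"]), 1 / 3)
    (rec,) = differential_screen(pred, strat, soc_drugs=["cisplatin", "docetaxel"])
    assert rec.t_statistic == 0.0 and rec.p_value == 1.0 and not rec.candidate


def test_differential_screen_calibrated_on_iid_predictions(null_predictions):
    """With predictions iid across samples the joint direction+p<alpha rule
    flags about alpha/2 of null drugs."""
    soc = compute_soc_score(null_predictions, ["cisplatin", "docetaxel"])
    strat = stratify(soc, 0.20)
    records = differential_screen(
        null_predictions, strat, alpha=0.05, soc_drugs=["cisplatin", "docetaxel"]
    )
    rate = np.mean([r.candidate for r in records])
    n = len(records)
    band = 1.96 * np.sqrt(0.025 * 0.975 / n)
    assert abs(rate - 0.025) < band + 0.01  # small cushion at n=200


# ---------------------------------------------------------------------------
# intersection


def test_intersect_candidates():
    cs = intersect_candidates(
        {"P1": ["A", "B"], "P2": ["A", "C"], "P3": ["A"], "P4": ["A", "D"]}
    )
    assert cs.final == ["A"]
    single = intersect_candidates({"P1": ["B", "A"]})
    assert single.final == ["A", "B"]  # lexicographic
    sizes = {"P1": 13, "P2": 17, "P3": 18, "P4": 12}
    lists = {k: [f"d{i}" for i in range(n)] for k, n in sizes.items()}
    assert len(intersect_candidates(lists).final) <= min(sizes.values())
    with pytest.raises(ChemoscreenError):
        intersect_candidates({})


# ---------------------------------------------------------------------------
# correlations


def test_correlate_perfect_and_textbook():
    soc = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    pred = _pred(
        np.column_stack([-soc.to_numpy(), soc.to_numpy(), [2.0, 1.0, 4.0, 3.0]]),
        samples=list("abcd"),
        drugs=["anti", "with", "textbook"],
    )
    recs = {r.drug_id: r for r in correlate_with_soc(pred, soc)}
    assert recs["anti"].r == pytest.approx(-1.0)
    assert recs["with"].r == pytest.approx(1.0)
    # hand covariance oracle: x=(1,2,3,4), y=(2,1,4,3) -> r = 3/5
    assert recs["textbook"].r == pytest.approx(0.6, abs=1e-12)


def test_spearman_on_values_equals_pearson_on_ranks(rng):
    soc = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
    pred = _pred(rng.normal(size=(30, 4)), samples=soc.index.tolist())
    spear = correlate_with_soc(pred, soc, method="spearman", on="values")
    ranks = correlate_with_soc(pred, soc, method="pearson", on="ranks")
    for a, b in zip(spear, ranks):
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)


def test_correlate_constant_column_excluded():
    soc = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
    pred = _pred([[1.0], [1.0], [1.0]], samples=list("abc"), drugs=["flat"])
    (rec,) = correlate_with_soc(pred, soc)
    assert rec.excluded and np.isnan(rec.r)
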