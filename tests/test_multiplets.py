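"""Multiplet-fraction estimator: printed-formula oracles and invariants."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cardioforest as cf
from cardioforest.errors import EstimationError


def test_two_equal_samples_hand_values():
    est = cf.estimate_multiplet_fractions(cf.MultiplexSummary({"a": 50, "b": 50}, 10))
    assert est.pi_within == pytest.approx(2 / 3)
    assert est.pi_between == pytest.approx(1 / 3)
    assert est.p_multiplet == pytest.approx(0.3)
    assert est.n_within == 20


def test_three_sample_hand_values():
    est = cf.estimate_multiplet_fractions(cf.MultiplexSummary({"a": 10, "b": 20, "c": 30}, 11))
    assert est.pi_within == pytest.approx(0.56)
    assert est.pi_between == pytest.approx(0.44)
    assert est.p_multiplet == pytest.approx(11 / 26.4, abs=1e-9)
    assert est.n_within == 14


def test_single_sample_unidentifiable():
    with pytest.raises(EstimationError, match="unidentifiable"):
        cf.estimate_multiplet_fractions(cf.MultiplexSummary({"a": 100}, 5))


def test_pi_fractions_sum_to_one_and_lower_bound():
    rng = np.random.default_rng(0)
    for _ in range(200):
        k = rng.integers(2, 9)
        counts = {f"s{i}": int(rng.integers(1, 10_000)) for i in range(k)}
        n = sum(counts.values())
        d_b = int(rng.integers(0, max(1, n // 5)))
        est = cf.estimate_multiplet_fractions(cf.MultiplexSummary(counts, d_b))
        assert est.pi_within + est.pi_between == 1.0
        assert est.p_multiplet >= d_b / n - 1e-12


def test_exact_agreement_with_brute_force_oracle():
    """pi_w equals a literal double loop over sample pairs, exactly, for 1000
    random configurations of 2-8 samples with counts up to 10^4."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        k = rng.integers(2, 9)
        counts = {f"s{i}": int(rng.integers(1, 10_001)) for i in range(k)}
        vals = list(counts.values())
        within = sum(n * n for n in vals)
        between = 0
        for i in range(len(vals)):
            for j in range(len(vals)):
                if i > j:
                    between += vals[i] * vals[j]
        expected = Fraction(within, within + between)
        est = cf.estimate_multiplet_fractions(cf.MultiplexSummary(counts, 1))
        assert est.pi_within == float(expected)


@settings(derandomize=True, max_examples=200)
@given(
    counts=st.lists(st.integers(1, 10_000), min_size=2, max_size=8),
    d_b=st.integers(0, 5_000),
)
def test_estimate_invariants_property(counts, d_b):
    """For any sample configuration: exact unit sum of the fractions, the
    D_b/N lower bound on the estimated rate, and a non-negative within count."""
    import warnings

    summary = cf.MultiplexSummary({f"s{i}": c for i, c in enumerate(counts)}, d_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # p_m > 1 warns for extreme d_b
        est = cf.estimate_multiplet_fractions(summary)
    assert est.pi_within + est.pi_between == 1.0
    assert 0.0 <= est.pi_within <= 1.0
    assert est.p_multiplet >= d_b / summary.n_cells - 1e-12
    assert est.n_within >= 0


def test_scale_invariance():
    base = {"a": 50, "b": 50}
    e1 = cf.estimate_multiplet_fractions(cf.MultiplexSummary(base, 10))
    scaled = {k: v * 10 for k, v in base.items()}
    e2 = cf.estimate_multiplet_fractions(cf.MultiplexSummary(scaled, 100))
    assert e1.pi_within == e2.pi_within
    assert e1.p_multiplet == pytest.approx(e2.p_multiplet, abs=1e-12)
    assert e2.n_within == 10 * e1.n_within  # exact here (no rounding residue)

    # with rounding, the scaled count can differ from 10x by at most the
    # rounding slack of the unscaled estimate
    f1 = cf.estimate_multiplet_fractions(cf.MultiplexSummary({"a": 30, "b": 50, "c": 20}, 7))
    f2 = cf.estimate_multiplet_fractions(
        cf.MultiplexSummary({"a": 300, "b": 500, "c": 200}, 70)
    )
    assert f1.pi_within == f2.pi_within
    assert abs(f2.n_within - 10 * f1.n_within) <= 5


def test_combinatorial_variant_uses_unordered_self_pairs():
    est = cf.estimate_multiplet_fractions(
        cf.MultiplexSummary({"a": 50, "b": 50}, 10), combinatorial=True
    )
    # C(50,2)*2 = 2450 within vs 2500 between
    assert est.pi_within == pytest.approx(2450 / 4950)


def test_p_m_above_one_warns_but_reports():
    with pytest.warns(UserWarning, match="exceeds 1"):
        est = cf.estimate_multiplet_fractions(cf.MultiplexSummary({"a": 5, "b": 5}, 10))
    assert est.p_multiplet > 1


# -- call summarization -----------------------------------------------------


def test_summarize_calls_tally():
    calls = pd.Series(["a", "a", "b", "doublet", "negative"], index=list("vwxyz"))
    s = cf.summarize_sample_calls(calls)
    assert s.sample_counts == {"a": 2, "b": 1}
    assert s.d_between == 1 and s.n_negative == 1 and s.n_cells == 3


def test_summarize_no_doublets():
    s = cf.summarize_sample_calls(pd.Series(["a", "b"], index=["c1", "c2"]))
    assert s.d_between == 0


def test_summarize_empty_errors():
    with pytest.raises(EstimationError):
        cf.summarize_sample_calls(pd.Series(dtype=object))


def test_summarize_matches_simulator_ground_truth():
    mc = cf.MultiplexConfig(
        seed=9, sample_sizes={"a": 4000, "b": 6000}, doublet_rate=0.1, negative_rate=0.03
    )
    calls, truth = cf.simulate_multiseq_experiment(mc)
    s = cf.summarize_sample_calls(pd.Series(calls["call"].values, index=calls["cell_id"]))
    assert s.d_between == ((truth["kind"] == "doublet") & ~truth["within_sample"]).sum()
    assert s.n_negative == (truth["kind"] == "negative").sum()
    assert s.n_cells == (calls["call"].isin(["a", "b"])).sum()


# -- flagging ---------------------------------------------------------------


def test_flag_zero_is_empty():
    est = cf.MultipletEstimate(0.5, 0.5, 0.0, 0)
    assert cf.flag_within_sample_doublets({"c1": 0.3}, est) == set()


def test_flag_tie_break_on_cell_id():
    est = cf.MultipletEstimate(0.5, 0.5, 0.1, 2)
    flagged = cf.flag_within_sample_doublets({"c1": 0.9, "c2": 0.1, "c3": 0.9}, est)
    assert flagged == {"c1", "c3"}


def test_flag_more_than_available_warns():
    est = cf.MultipletEstimate(0.5, 0.5, 0.9, 5)
    with pytest.warns(UserWarning, match="flagging all"):
        flagged = cf.flag_within_sample_doublets({"c1": 0.2, "c2": 0.4}, est)
    assert flagged == {"c1", "c2"}


def test_library_size_score_recovers_within_sample_doublets():
    """With summed doublet profiles and library size as the score, at least
    70% of flagged cells are true within-sample doublets (rate 0.2, seeded)."""
    mc = cf.MultiplexConfig(
        seed=3, sample_sizes={"a": 1000, "b": 1000}, doublet_rate=0.2, negative_rate=0.0
    )
    m, calls, truth = cf.simulate_multiseq_counts(mc)
    call_series = pd.Series(calls["call"].values, index=calls["cell_id"])
    est = cf.estimate_multiplet_fractions(cf.summarize_sample_calls(call_series))
    lib = pd.Series(m.library_sizes(), index=m.cell_ids)
    flagged = cf.flag_within_sample_doublets(lib[call_series != "doublet"], est)
    t = truth.set_index("cell_id")
    assert t.loc[sorted(flagged), "within_sample"].mean() >= 0.70
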