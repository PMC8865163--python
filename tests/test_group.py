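"""Binomial group-level inference: exact tail, Monte-Carlo null, summaries."""

import math

import numpy as np
import pytest

import tractnorm as tn
from tractnorm.evaluate import evaluate_subject
from tractnorm.group import (exact_binomial_tail, group_summary,
                             group_tract_test, mc_null)
from tractnorm.normative import NotEvaluable


def brute_force_tail(k, m, p0):
    """Independent oracle: direct log-space summation of the upper tail."""
    total = 0.0
    for j in range(k, m + 1):
        log_term = (math.lgamma(m + 1) - math.lgamma(j + 1)
                    - math.lgamma(m - j + 1)
                    + j * math.log(p0) + (m - j) * math.log1p(-p0))
        total += math.exp(log_term)
    return min(total, 1.0)


# -- exact tail ------------------------------------------------------------

def test_tail_at_zero_is_one():
    assert exact_binomial_tail(0, 20, 0.025) == 1.0


def test_single_bernoulli_tail():
    assert exact_binomial_tail(1, 1, 0.025) == pytest.approx(0.025)


def test_tail_m20_k4_matches_hand_summation():
    p = exact_binomial_tail(4, 20, 0.025)
    assert p == pytest.approx(0.0013, abs=1e-4)
    assert p == pytest.approx(brute_force_tail(4, 20, 0.025), rel=1e-12)


@pytest.mark.parametrize("m", [1, 3, 7, 21, 50])
def test_tail_matches_brute_force_and_is_monotone(m):
    prev = None
    for k in range(m + 1):
        p = exact_binomial_tail(k, m, 0.025)
        assert p == pytest.approx(brute_force_tail(k, m, 0.025), rel=1e-10)
        if prev is not None:
            assert p <= prev
        prev = p


def test_tail_argument_errors():
    with pytest.raises(ValueError):
        exact_binomial_tail(5, 4, 0.025)
    with pytest.raises(ValueError):
        exact_binomial_tail(1, 4, 0.0)


# -- Monte-Carlo null ------------------------------------------------------

def test_mc_null_deterministic_given_seed():
    a = mc_null(20, seed=11)
    b = mc_null(20, seed=11)
    np.testing.assert_array_equal(a.draws, b.draws)
    assert np.any(a.draws != mc_null(20, seed=12).draws)


def test_mc_null_mean_within_clt_bound():
    m, p0, iters = 20, 0.025, 100_000
    null = mc_null(m, p0, iters, seed=5)
    bound = 4.0 * math.sqrt(m * p0 * (1 - p0) / iters)
    assert abs(null.draws.mean() - m * p0) < bound


def test_mc_null_zero_trials_all_zero():
    assert np.all(mc_null(0, seed=1).draws == 0)


@pytest.mark.parametrize("m", [3, 7, 21])
def test_mc_tail_converges_to_exact(m):
    null = mc_null(m, iterations=100_000, seed=202)
    for k in range(0, 7):
        if k > m:
            continue
        exact = exact_binomial_tail(k, m, 0.025)
        mc = null.tail_p(k)
        tol = 3.0 * math.sqrt(exact * (1 - exact) / 100_000) + 1 / 100_000
        assert abs(mc - exact) < tol


def test_mc_tail_floor_never_zero():
    null = mc_null(3, iterations=1000, seed=0)
    assert null.tail_p(3) >= 1 / 1000


# -- group_tract_test over constructed reports -----------------------------

def _report(subject_id, flags):
    """Report with per-(tract, metric) significance set directly."""
    r = tn.SubjectReport(subject_id=subject_id, sex=tn.Sex.MALE, alpha=0.025)
    for (tract, metric), sig in flags.items():
        r.findings.append(tn.TractFinding(
            tract=tract, metric=metric, value=0.4, z=-1.0,
            p=0.0 if sig else 0.5, n_controls=50, significant=sig))
    return r


def test_group_zero_observed_is_p_one():
    reports = [_report(f"s{i}", {("Cingulum left", "fa"): False})
               for i in range(10)]
    res = group_tract_test(reports, "Cingulum left", "fa")
    assert res.p_group == 1.0 and not res.significant
    assert (res.m, res.k_observed) == (10, 0)


def test_group_m20_k4_significant():
    reports = [_report(f"s{i}", {("Cingulum left", "fa"): i < 4})
               for i in range(20)]
    res = group_tract_test(reports, "Cingulum left", "fa")
    assert res.p_group == pytest.approx(0.0013, abs=1e-4)
    assert res.significant


def test_single_subject_group_reduces_to_bernoulli():
    res = group_tract_test([_report("s0", {("Cingulum left", "rd"): True})],
                           "Cingulum left", "rd")
    assert res.p_group == pytest.approx(0.025)


def test_group_p_nonincreasing_in_k_both_modes():
    for mode in ("exact", "monte_carlo"):
        prev = None
        for k in range(0, 8):
            reports = [_report(f"s{i}", {("Cingulum left", "fa"): i < k})
                       for i in range(20)]
            res = group_tract_test(reports, "Cingulum left", "fa", mode=mode,
                                   seed=9, iterations=20_000)
            if prev is not None:
                assert res.p_group <= prev
            prev = res.p_group


def test_strict_exceedance_mode_is_smaller():
    reports = [_report(f"s{i}", {("Cingulum left", "fa"): i < 2})
               for i in range(20)]
    ge = group_tract_test(reports, "Cingulum left", "fa", exceedance=">=")
    gt = group_tract_test(reports, "Cingulum left", "fa", exceedance=">")
    assert gt.p_group < ge.p_group
    assert gt.p_group == pytest.approx(exact_binomial_tail(3, 20, 0.025))


def test_null_trials_tracts_mode_uses_tract_count():
    reports = [_report(f"s{i}",
                       {("Cingulum left", "fa"): i < 2,
                        ("Cingulum right", "fa"): False,
                        ("Corpus callosum: genu", "fa"): False})
               for i in range(5)]
    res = group_tract_test(reports, "Cingulum left", "fa",
                           null_trials="tracts")
    # 3 distinct evaluable tracts -> Binomial(3, .025) null
    assert res.p_group == pytest.approx(exact_binomial_tail(2, 3, 0.025))
    assert res.m == 5  # m still reports the patient count


def test_tract_evaluable_nowhere_signals():
    reports = [_report("s0", {("Cingulum left", "fa"): False})]
    with pytest.raises(NotEvaluable):
        group_tract_test(reports, "Uncinate fascicle left", "fa")


def test_monte_carlo_requires_seed():
    reports = [_report("s0", {("Cingulum left", "fa"): True})]
    with pytest.raises(ValueError, match="seed"):
        group_tract_test(reports, "Cingulum left", "fa", mode="monte_carlo")


# -- group_summary on the synthetic study ----------------------------------

def test_group_summary_sorted_and_complete(study, references, registry):
    _, _, patients = study
    reports = [evaluate_subject(p, references[p.sex])
               for p in patients if p.phenotype == "ALSFTD-C9+"]
    df = group_summary(reports, registry, "rd")
    assert list(df.columns) == ["tract", "metric", "m", "k_observed",
                                "p_group", "significant"]
    assert len(df) == 50
    assert (df.p_group.diff().dropna() >= 0).all()
    assert (df.m == 21).all()


def test_signature_tracts_rank_first(study, references, registry):
    """Injected signature tracts occupy the lowest group p-values."""
    _, _, patients = study
    sig = tn.builtin_signatures(registry)["ALSFTD-C9+"]
    reports = [evaluate_subject(p, references[p.sex])
               for p in patients if p.phenotype == "ALSFTD-C9+"]
    df = group_summary(reports, registry, "rd")
    top = set(df.head(len(sig.rd_tracts)).tract)
    overlap = len(top & set(sig.rd_tracts)) / len(sig.rd_tracts)
    assert overlap >= 0.9


def test_all_null_group_rarely_significant(study, references, registry):
    """Null group of 20: expected significant tracts ~ 50 * 0.0013 << 1."""
    params, _, _ = study
    null_sig = tn.PhenotypeSignature("null", ())
    reports = []
    for s in range(20):
        subj = tn.simulate_patient(null_sig, params, 900 + s, sex="male")
        reports.append(evaluate_subject(subj, references[tn.Sex.MALE]))
    for metric in ("fa", "rd"):
        df = group_summary(reports, registry, metric)
        assert df.significant.sum() <= 2


def test_render_group_table_lists_significant(study, references, registry):
    _, _, patients = study
    reports = [evaluate_subject(p, references[p.sex])
               for p in patients if p.phenotype == "svPPA"]
    df = group_summary(reports, registry, "rd")
    text = tn.group.render_group_table(df)
    assert "p_FWER" in text
    n_sig = int(df.significant.sum())
    assert len([l for l in text.splitlines() if l.startswith("  ")]) == n_sig
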