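"""Single-subject rank evaluation: p-value arithmetic, calibration, reports."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tractnorm as tn
from tractnorm.cohort import Role, Sex, SubjectRecord, TractMetrics
from tractnorm.evaluate import (empirical_p, evaluate_subject,
                                laterality_summary, leave_one_out_flags,
                                render_report, report_from_json)
from tractnorm.normative import NotEvaluable


# -- empirical_p -----------------------------------------------------------

CONTROLS4 = [0.40, 0.42, 0.44, 0.46]


@pytest.mark.parametrize("value, direction, expected", [
    (0.10, "lower", 0.0),          # below all controls
    (0.43, "lower", 2 / 4),        # two controls strictly below
    (0.42, "lower", 1 / 4),        # tie not counted as exceeding
    (0.42, "higher", 2 / 4),       # two strictly above, tie excluded
    (0.99, "higher", 0.0),
    (0.99, "lower", 1.0),
])
def test_empirical_p_direct_counts(value, direction, expected):
    assert empirical_p(value, CONTROLS4, direction) == expected


def test_empirical_p_requires_two_controls():
    with pytest.raises(NotEvaluable):
        empirical_p(0.5, [0.4], "lower")


@given(st.lists(st.floats(0.1, 0.9), min_size=2, max_size=60),
       st.floats(0.0, 1.0), st.floats(0.0, 1.0))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_empirical_p_monotone_and_discrete(controls, v1, v2):
    """Lower-tail p is monotone in the value and lies on the 1/n grid."""
    lo, hi = sorted((v1, v2))
    n = len(controls)
    p_lo = empirical_p(lo, controls, "lower")
    p_hi = empirical_p(hi, controls, "lower")
    assert p_lo <= p_hi
    for p in (p_lo, p_hi):
        assert 0.0 <= p <= 1.0
        assert round(p * n) == pytest.approx(p * n)
    # complementary direction is antitone
    assert empirical_p(lo, controls, "higher") >= \
        empirical_p(hi, controls, "higher")


@given(st.lists(st.floats(0.05, 0.95), min_size=3, max_size=40, unique=True),
       st.floats(0.05, 0.95))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_significance_invariant_under_monotone_transform(controls, value):
    """Rank tests only see order, so exp() applied to everyone changes nothing."""
    p_raw = empirical_p(value, controls, "lower")
    p_tr = empirical_p(np.exp(value), np.exp(controls), "lower")
    assert p_raw == p_tr


# -- evaluate_subject ------------------------------------------------------

def _subject_from_reference(ref, fa_z=0.0, rd_z=0.0, tracts=None,
                            subject_id="p1"):
    """Build a patient lying at given z-offsets from the reference."""
    values = {}
    for tract in ref.tracts:
        fa_mu = float(np.mean(ref.sample(tract, "fa")))
        fa_sd = float(np.std(ref.sample(tract, "fa"), ddof=1))
        rd_mu = float(np.mean(ref.sample(tract, "rd")))
        rd_sd = float(np.std(ref.sample(tract, "rd"), ddof=1))
        z_f = fa_z if (tracts is None or tract in tracts) else 0.0
        z_r = rd_z if (tracts is None or tract in tracts) else 0.0
        values[tract] = (np.clip(fa_mu + z_f * fa_sd, 0, 1),
                         max(rd_mu + z_r * rd_sd, 1e-12))
    return SubjectRecord(subject_id=subject_id, sex=ref.sex, age=61.0,
                         role=Role.PATIENT, metrics=TractMetrics(values))


def test_subject_at_the_mean_has_no_affected_tracts(references):
    ref = references[Sex.MALE]
    report = evaluate_subject(_subject_from_reference(ref), ref)
    assert report.affected == []
    assert len(report.findings) == 2 * 50


def test_depressed_fa_in_five_tracts_flags_exactly_those(references, registry):
    ref = references[Sex.MALE]
    targets = set(registry.names[:5])
    subject = _subject_from_reference(ref, fa_z=-4.0, tracts=targets)
    report = evaluate_subject(subject, ref)
    assert set(report.affected) == targets
    for f in report.significant_findings():
        assert f.metric == "fa" and f.p < 0.025 and f.z < -3


def test_sex_mismatch_rejected(references, study):
    _, _, patients = study
    male = next(p for p in patients if p.sex is Sex.MALE)
    with pytest.raises(ValueError, match="sex"):
        evaluate_subject(male, references[Sex.FEMALE])


def test_missing_tract_listed_not_evaluable(references):
    ref = references[Sex.MALE]
    subject = _subject_from_reference(ref)
    dropped = ref.tracts[0]
    del subject.metrics.values[dropped]
    report = evaluate_subject(subject, ref)
    assert dropped in report.not_evaluable
    assert len(report.evaluable_tracts) == 49


def test_leave_one_out_flag_rate_is_exact(study, references):
    """LOO calibration: each tract flags exactly #{k : k/49 < .025} = 2 of 50."""
    ref = references[Sex.MALE]
    for tract in ref.tracts[:10]:
        flags = leave_one_out_flags(ref.sample(tract, "fa"), "lower")
        assert flags == 2
        flags = leave_one_out_flags(ref.sample(tract, "rd"), "higher")
        assert flags == 2


# -- laterality ------------------------------------------------------------

def test_laterality_empty(references, registry):
    ref = references[Sex.MALE]
    report = evaluate_subject(_subject_from_reference(ref), ref)
    assert laterality_summary(report, registry) == \
        tn.evaluate.LateralitySummary(0, 0, 0)


def test_laterality_counts_by_hemisphere(references, registry):
    ref = references[Sex.MALE]
    report = evaluate_subject(_subject_from_reference(ref), ref)
    report.affected = ["Arcuate fascicle left", "Cingulum left",
                       "Corpus callosum: genu"]
    lat = laterality_summary(report, registry)
    assert (lat.n_left, lat.n_right, lat.n_commissural) == (2, 0, 1)


# -- rendering -------------------------------------------------------------

def test_text_report_no_findings(references):
    ref = references[Sex.MALE]
    report = evaluate_subject(_subject_from_reference(ref), ref)
    text = render_report(report, "text")
    assert "no tracts significant at alpha = 0.025" in text


def test_text_report_sorted_by_p_then_name(references, registry):
    ref = references[Sex.MALE]
    targets = set(registry.names[:3])
    subject = _subject_from_reference(ref, fa_z=-5.0, tracts=targets)
    report = evaluate_subject(subject, ref)
    text = render_report(report, "text")
    body = [l for l in text.splitlines() if l.startswith("  ")]
    assert len(body) == 3
    ps = []
    for line in body:
        assert "[FA]" in line and "z = " in line
        ps.append(line)
    # all at p=0 here, so ordering is lexicographic by tract name
    names = [l.strip().split(" [")[0] for l in body]
    assert names == sorted(names)
    assert "p < 0.0200" in body[0]  # p=0 rendered as < 1/n


def test_json_report_round_trips(references, registry):
    ref = references[Sex.FEMALE]
    subject = _subject_from_reference(ref, fa_z=-3.0, rd_z=3.0,
                                      tracts=set(registry.names[:4]))
    report = evaluate_subject(subject, ref)
    payload = render_report(report, "json")
    assert json.loads(payload)["schema_version"] == 1
    back = report_from_json(payload)
    assert back == report
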