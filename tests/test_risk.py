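"""Combined risk metrics: HI, mRPI, TRV-ratio and RPF scaling, tier flow."""

import numpy as np
import pytest

from conftest import make_exposure
from mixtox.exposure import percentile_with_uncertainty
from mixtox.risk import (
    CombinedRiskMetric,
    RelativePotencyFactorSet,
    RiskQuotient,
    combine_with_rpf,
    cumulative_exposure_trv_scaling,
    hazard_index,
    mrpi_sum,
    risk_characterisation,
    tiered_assessment,
)


def rq(compound, q, p=95, flavor="RPQ"):
    return RiskQuotient(compound=compound, group="g", scenario="UB",
                        percentile=p, quotient=q, flavor=flavor)


def test_hazard_index_sums():
    assert hazard_index([rq("a", 0.2, flavor="HQ"), rq("b", 0.3, flavor="HQ")]
                        ).value == pytest.approx(0.5)
    assert hazard_index([rq("a", 1.0, flavor="HQ")]).value == pytest.approx(1.0)
    assert hazard_index([rq(c, 0.0, flavor="HQ") for c in "abc"]).value == 0.0


def test_mixed_percentiles_rejected():
    with pytest.raises(ValueError, match="mixed percentiles"):
        hazard_index([rq("a", 0.2, p=50), rq("b", 0.3, p=95)])


def test_mrpi_sum_printed_haematological_row():
    """Per-compound P95 UB RPQs for the toddler haematological group sum to ~17."""
    quotients = [0.004, 0.020, 0.71, 9.6, 6.9]  # DAS, NIV, MON, T2, HT2
    metric = mrpi_sum([rq(c, q) for c, q in
                       zip(["DAS", "NIV", "MON", "T2", "HT2"], quotients)])
    assert metric.value == pytest.approx(17.234)
    assert metric.reported == pytest.approx(17.0)


def test_mrpi_sum_printed_nephrotoxicity_row():
    """Toddler kidney-group P95 UB RPQs sum to 2.486, reported as 2.5."""
    quotients = [1.0, 0.088, 0.084, 0.084, 0.005, 1.2, 0.025]
    metric = mrpi_sum([rq(c, q) for c, q in
                       zip(["CIT", "FB1", "FB2", "FB3", "NIV", "OTA", "PAT"], quotients)])
    assert metric.value == pytest.approx(2.486)
    assert metric.reported == pytest.approx(2.5)


def test_mrpi_reports_missing_members():
    metric = mrpi_sum([rq("a", 0.1)], expected_compounds=["a", "b"])
    assert metric.missing_compounds == ("b",)


def test_trv_scaling_single_compound_identity():
    e = make_exposure([0.1, 0.4, 0.9])
    out = cumulative_exposure_trv_scaling({"a": e}, {"a": 2.0}, "a")
    assert out.values == pytest.approx(e.values)


def test_trv_scaling_equal_trvs_is_plain_sum():
    a = make_exposure([1.0, 2.0])
    b = make_exposure([0.5, 0.5])
    out = cumulative_exposure_trv_scaling({"a": a, "b": b}, {"a": 3.0, "b": 3.0}, "a")
    assert out.values == pytest.approx([1.5, 2.5])


def test_reference_compound_invariance_trv_scaling():
    """The TRV-ratio risk quotient is independent of the reference compound."""
    rng = np.random.default_rng(10)
    exposures = {c: make_exposure(rng.lognormal(-2, 1, size=200)) for c in "abcd"}
    trvs = {"a": 0.02, "b": 1.75, "c": 0.65, "d": 6.6}
    quotients = {}
    for ref in trvs:
        combined = cumulative_exposure_trv_scaling(exposures, trvs, ref)
        quotients[ref] = np.percentile(combined.values, 95) / trvs[ref]
    base = quotients["a"]
    for ref, q in quotients.items():
        assert q == pytest.approx(base, rel=1e-12)


def test_rpf_combination_worked_example():
    """1 NIV + 0.01 T2/HT2 at RPF 140 gives 2.4 NIV-equivalents."""
    exposures = {"NIV": make_exposure([1.0]), "T2HT2": make_exposure([0.01])}
    rpfs = RelativePotencyFactorSet(reference="NIV", rpfs={"NIV": 1.0, "T2HT2": 140.0})
    out = combine_with_rpf(exposures, rpfs)
    assert out.values == pytest.approx([2.4])


def test_rpf_reference_self_map_identity():
    e = make_exposure([0.3, 0.6])
    rpfs = RelativePotencyFactorSet(reference="NIV", rpfs={"NIV": 1.0})
    assert combine_with_rpf({"NIV": e}, rpfs).values == pytest.approx(e.values)


def test_rpf_reference_must_be_one():
    with pytest.raises(ValueError, match="must equal 1"):
        RelativePotencyFactorSet(reference="NIV", rpfs={"NIV": 2.0})
    with pytest.raises(ValueError, match="positive"):
        RelativePotencyFactorSet(reference="NIV", rpfs={"NIV": 1.0, "T2HT2": -3.0})


def test_rpf_reference_choice_ratio_identity():
    """Metrics under two references differ by exactly RPF x TRV_alt / TRV_ref.

    This fixed factor (140 x 0.02 / 1.75 = 1.6 for the WBC pair) is the
    mechanism behind reference-compound dependence of RPF-based risk.
    """
    rng = np.random.default_rng(4)
    exposures = {"NIV": make_exposure(rng.lognormal(-1, 0.8, 300)),
                 "T2HT2": make_exposure(rng.lognormal(-4, 1.0, 300))}
    trvs = {"NIV": 1.75, "T2HT2": 0.02}
    rpf = 140.0
    set_niv = RelativePotencyFactorSet("NIV", {"NIV": 1.0, "T2HT2": rpf})
    set_t2 = set_niv.rebased("T2HT2")
    assert set_t2.rpf("NIV") == pytest.approx(1 / rpf)
    expected_ratio = rpf * trvs["T2HT2"] / trvs["NIV"]
    assert expected_ratio == pytest.approx(1.6)
    for p in (50, 95):
        m_niv = np.percentile(combine_with_rpf(exposures, set_niv).values, p) / trvs["NIV"]
        m_t2 = np.percentile(combine_with_rpf(exposures, set_t2).values, p) / trvs["T2HT2"]
        assert m_niv / m_t2 == pytest.approx(expected_ratio, rel=1e-12)


def test_comonotonic_equality_of_sum_and_individual():
    """For identically-ranked exposures the sum of percentiles equals the
    percentile of the sum, so mRPI_sum == mRPI_individual."""
    base = np.sort(np.random.default_rng(2).lognormal(0, 1, 500))
    exposures = {"a": make_exposure(2.0 * base), "b": make_exposure(0.5 * base)}
    trvs = {"a": 1.0, "b": 1.0}
    for p in (10, 50, 95):
        combined = cumulative_exposure_trv_scaling(exposures, trvs, "a")
        individual = np.percentile(combined.values, p) / trvs["a"]
        summed = sum(np.percentile(e.values, p) / trvs[c] for c, e in exposures.items())
        assert individual == pytest.approx(summed, rel=1e-12)


def test_single_compound_degeneracy():
    """Every combined method collapses to the single compound's RPQ."""
    e = make_exposure(np.linspace(0.1, 2.0, 50))
    trv = 0.5
    p = 95
    rpq = np.percentile(e.values, p) / trv
    combined_trv = cumulative_exposure_trv_scaling({"x": e}, {"x": trv}, "x")
    combined_rpf = combine_with_rpf({"x": e}, RelativePotencyFactorSet("x", {"x": 1.0}))
    assert np.percentile(combined_trv.values, p) / trv == pytest.approx(rpq)
    assert np.percentile(combined_rpf.values, p) / trv == pytest.approx(rpq)
    assert mrpi_sum([rq("x", rpq)]).value == pytest.approx(rpq)


def test_risk_characterisation_scales_with_trv():
    e = make_exposure(np.linspace(0, 1, 40))
    m1 = risk_characterisation(e, 0.5, percentiles=[95], B=50, seed=3)[0]
    m2 = risk_characterisation(e, 1.0, percentiles=[95], B=50, seed=3)[0]
    assert m1.value == pytest.approx(2 * m2.value, rel=1e-12)


def test_risk_characterisation_unit_metric():
    e = make_exposure([1.0] * 10)
    m = risk_characterisation(e, 1.0, percentiles=[50], B=20, seed=1)[0]
    assert m.value == pytest.approx(1.0)
    assert not m.exceeds_one  # threshold is strict


def test_sum_tends_to_exceed_individual_at_p95():
    """With independently drawn exposures, summing P95 RPQs overstates the
    individually-combined P95 in the large majority of replicates."""
    rng_master = np.random.default_rng(2024)
    seeds = rng_master.integers(0, 2**31 - 1, size=200)
    trvs = {"a": 1.0, "b": 0.5, "c": 2.0}
    wins = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        exposures = {c: make_exposure(rng.lognormal(-1, 1, 300)) for c in trvs}
        summed = sum(np.percentile(e.values, 95) / trvs[c]
                     for c, e in exposures.items())
        combined = cumulative_exposure_trv_scaling(exposures, trvs, "a")
        individual = np.percentile(combined.values, 95) / trvs["a"]
        wins += summed >= individual
    assert wins / len(seeds) >= 0.90


def _exposure_maps(values_by_compound, scenario="UB"):
    n = len(next(iter(values_by_compound.values())))
    ids = [f"i{k}" for k in range(n)]
    return {c: make_exposure(v, compound=c, scenario=scenario, ids=ids)
            for c, v in values_by_compound.items()}


def test_tiered_flow_stops_and_refines():
    """A low-exposure group stops at the organ tier; a T2-driven group refines
    through the phenomenon tier into the RPF tier."""
    rng = np.random.default_rng(8)
    low = {s: _exposure_maps({"FB1": rng.lognormal(-5, 0.5, 100) * 0 + 0.01,
                              "ZEN": np.full(100, 0.02)}, s) for s in ("LB", "UB")}
    hot_vals = {"NIV": rng.lognormal(-3, 1, 100), "T2HT2": rng.lognormal(-3, 1, 100)}
    hot = {s: _exposure_maps(hot_vals, s) for s in ("LB", "UB")}
    trail = tiered_assessment(
        organ_groups={"liver": low, "haematological": hot},
        organ_trvs={"liver": {"FB1": 1.0, "ZEN": 3.33},
                    "haematological": {"NIV": 1.75, "T2HT2": 0.02}},
        phenomenon_groups={"wbc": "haematological"},
        phenomenon_exposures={"wbc": hot},
        phenomenon_trvs={"wbc": {"NIV": 1.75, "T2HT2": 0.02}},
        rpf_sets={"wbc": RelativePotencyFactorSet("NIV", {"NIV": 1.0, "T2HT2": 140.0})},
        B=30, seed=5,
    )
    by_key = {(t.group, t.tier): t for t in trail}
    assert not by_key[("liver", "organ")].proceed
    assert ("wbc", "phenomenon") in by_key  # refinement happened
    assert by_key[("haematological", "organ")].proceed
    assert ("wbc", "rpf") in by_key


def test_tiered_flow_reports_missing_refinement():
    """A concerning organ group without a phenomenon subgroup is flagged
    'refinement not possible' (the nephrotoxicity situation)."""
    rng = np.random.default_rng(9)
    hot = {s: _exposure_maps({"CIT": rng.lognormal(0, 0.5, 50)}, s) for s in ("UB",)}
    trail = tiered_assessment(
        organ_groups={"kidney": hot},
        organ_trvs={"kidney": {"CIT": 0.1}},
        B=20, seed=2,
    )
    assert trail[0].proceed
    assert trail[1].tier == "phenomenon" and not trail[1].proceed
    assert "refinement not possible" in trail[1].note
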