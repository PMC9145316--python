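"""Benchmark-dose engine: likelihoods, BMD inversion, averaging, joint fits."""

import math

import numpy as np
import pytest

from mixtox.doseresponse import (
    DoseResponseDataset,
    aic_weights,
    bmd_from_model,
    fit_model,
    model_average_bmd,
    sd_to_sem,
    select_reference_compound,
    simultaneous_fit,
    BmdResult,
)
from mixtox.simulate import DoseResponseDesign, generate_dose_response


def exp_dataset(a=10.0, b=0.05, c=0.6, doses=(0, 1, 4, 16, 64), sd_frac=0.0, n=10):
    doses = np.asarray(doses, float)
    mean = a * (c - (c - 1) * np.exp(-b * doses))
    sd = sd_frac * mean
    return DoseResponseDataset("X", "wbc", doses, mean, sd, np.full(len(doses), n))


@pytest.mark.parametrize("sd,n,expected", [(4, 16, 1.0), (3.0, 1, 3.0),
                                           (3.5, 10, 3.5 / math.sqrt(10))])
def test_sd_to_sem(sd, n, expected):
    assert sd_to_sem(sd, n) == pytest.approx(expected)
    assert sd_to_sem(expected * math.sqrt(n), n) * math.sqrt(n) == pytest.approx(
        expected * math.sqrt(n))  # sem*sqrt(n) = sd round trip


def test_sd_to_sem_rejects_bad_n():
    with pytest.raises(ValueError):
        sd_to_sem(1.0, 0)


def test_from_rows_sem_conversion():
    ds = DoseResponseDataset.from_rows("X", "wbc", [
        (0, 10.0, 0.5, "SEM", 16), (1, 9.0, 2.0, "SD", 16), (4, 8.0, 0.4, "SEM", 16)])
    assert ds.sd == pytest.approx([2.0, 2.0, 1.6])


def test_dataset_requires_control_and_positive_means():
    with pytest.raises(ValueError, match="control"):
        DoseResponseDataset("X", "e", [1, 2, 4], [3, 2, 1], [0.1] * 3, [5] * 3)
    with pytest.raises(ValueError, match="positive"):
        DoseResponseDataset("X", "e", [0, 1], [3, -2], [0.1] * 2, [5] * 2)


def test_noise_free_recovery():
    """Fitting noiseless exponential data recovers the generating curve."""
    ds = exp_dataset(a=10, b=0.05, c=0.6, sd_frac=0.0)
    m = fit_model(ds, "exponential")
    assert m.a == pytest.approx(10, rel=1e-5)
    assert m.b == pytest.approx(0.05, rel=1e-4)
    assert m.c == pytest.approx(0.6, rel=1e-4)


def test_flat_data_degenerate():
    """On flat data the exponential fit collapses onto the null model and the
    BMD is unbounded."""
    ds = DoseResponseDataset("X", "e", [0, 1, 4, 16], [5.0] * 4, [0.5] * 4, [10] * 4)
    null = fit_model(ds, "null")
    expo = fit_model(ds, "exponential")
    assert expo.loglik == pytest.approx(null.loglik, abs=1e-3)
    assert math.isinf(bmd_from_model(expo, 0.10))


def test_likelihood_nesting():
    rng = np.random.default_rng(3)
    ds = exp_dataset(sd_frac=0.1)
    noisy = DoseResponseDataset("X", "e", ds.dose,
                                ds.mean * np.exp(rng.normal(0, 0.05, len(ds.dose))),
                                ds.sd, ds.n)
    lnull = fit_model(noisy, "null").loglik
    lexp = fit_model(noisy, "exponential").loglik
    lfull = fit_model(noisy, "full").loglik
    assert lfull >= lexp >= lnull - 1e-6


def test_bmd_closed_form_pure_exponential():
    """For the pure decay a*exp(-b d) (c=0), BMD = -ln(1-BMR)/b."""
    a, b = 12.0, 0.03
    doses = np.array([0, 5, 20, 80, 240.0])
    ds = DoseResponseDataset("X", "e", doses, a * np.exp(-b * doses),
                             np.zeros(5), np.full(5, 10))
    m = fit_model(ds, "exponential")
    for bmr in (0.05, 0.10, 0.20):
        assert bmd_from_model(m, bmr) == pytest.approx(-math.log(1 - bmr) / b, rel=1e-3)


def test_bmd_monotone_in_bmr_and_scale_equivariant():
    ds = exp_dataset(sd_frac=0.0)
    m = fit_model(ds, "exponential")
    bmds = [bmd_from_model(m, bmr) for bmr in (0.01, 0.05, 0.10, 0.20)]
    assert all(x < y for x, y in zip(bmds, bmds[1:]))
    # doubling potency halves the BMD
    ds2 = exp_dataset(b=0.10, sd_frac=0.0)
    m2 = fit_model(ds2, "exponential")
    assert bmd_from_model(m2, 0.10) == pytest.approx(bmd_from_model(m, 0.10) / 2, rel=1e-4)


def test_bmd_rejects_bad_bmr():
    m = fit_model(exp_dataset(), "exponential")
    with pytest.raises(ValueError):
        bmd_from_model(m, 0.0)
    with pytest.raises(ValueError):
        bmd_from_model(m, 1.0)


def test_aic_weights_normalised():
    ds = exp_dataset(sd_frac=0.1)
    models = [fit_model(ds, f) for f in ("exponential", "hill")]
    w = aic_weights(models)
    assert w.sum() == pytest.approx(1.0)
    assert np.all(w > 0)


def test_model_average_ordering_and_reproducibility():
    design = DoseResponseDesign(true_rpf={}, reference="A")
    (ds,) = generate_dose_response(design, 5)
    res = model_average_bmd(ds, families=("exponential", "hill"), bmr=0.10,
                            B=100, seed=9)
    assert res.bmdl <= res.bmd <= res.bmdu
    res2 = model_average_bmd(ds, families=("exponential", "hill"), bmr=0.10,
                             B=100, seed=9)
    assert (res.bmd, res.bmdl, res.bmdu) == (res2.bmd, res2.bmdl, res2.bmdu)
    assert sum(res.weights.values()) == pytest.approx(1.0)


def test_model_average_single_family_degenerates():
    design = DoseResponseDesign(true_rpf={}, reference="A")
    (ds,) = generate_dose_response(design, 6)
    res = model_average_bmd(ds, families=("exponential",), bmr=0.10, B=50, seed=2)
    assert res.method == "single_model"
    assert res.weights == {"exponential": pytest.approx(1.0)}


def test_simultaneous_identical_datasets_rpf_one():
    ds = exp_dataset(sd_frac=0.1)
    ds2 = DoseResponseDataset("Y", "wbc", ds.dose, ds.mean, ds.sd, ds.n)
    fit = simultaneous_fit([ds, ds2], "X", families=("exponential",))
    assert fit.rpfs()["Y"] == pytest.approx(1.0, rel=1e-6)


def test_simultaneous_dose_scaling_recovery():
    """A dataset built from another's curve with doses divided by k yields
    RPF = k."""
    k = 50.0
    design = DoseResponseDesign(true_rpf={"B": k}, reference="A",
                                residual_sd_log=0.15, shared_noise=True)
    ds = generate_dose_response(design, 11)
    fit = simultaneous_fit(ds, "A")
    assert fit.rpfs()["B"] == pytest.approx(k, rel=0.05)


def test_rpf_invariant_to_bmr():
    niv, t2 = _wbc()
    fit = simultaneous_fit([niv, t2], "NIV", families=("exponential",))
    r1 = fit.bmd("NIV", 0.05) / fit.bmd("T2HT2", 0.05)
    r2 = fit.bmd("NIV", 0.10) / fit.bmd("T2HT2", 0.10)
    assert r1 == pytest.approx(r2, rel=1e-9)
    assert r1 == pytest.approx(fit.rpfs()["T2HT2"], rel=1e-9)


def test_dose_unit_equivariance():
    """Multiplying one compound's doses by k divides its BMD by k and
    multiplies its RPF by k."""
    niv, t2 = _wbc()
    fit = simultaneous_fit([niv, t2], "NIV", families=("exponential",))
    t2_scaled = DoseResponseDataset("T2HT2", t2.endpoint, t2.dose / 10.0,
                                    t2.mean, t2.sd, t2.n, t2.direction)
    fit2 = simultaneous_fit([niv, t2_scaled], "NIV", families=("exponential",))
    assert fit2.rpfs()["T2HT2"] == pytest.approx(10 * fit.rpfs()["T2HT2"], rel=1e-4)
    assert fit2.bmd("T2HT2", 0.10) == pytest.approx(fit.bmd("T2HT2", 0.10) / 10,
                                                    rel=1e-4)


def _wbc():
    from mixtox.simulate import synthetic_wbc_datasets
    return synthetic_wbc_datasets()


def test_select_reference_compound():
    def result(c, lo, hi):
        return BmdResult(compound=c, bmr=0.1, bmd=math.sqrt(lo * hi),
                         bmdl=lo, bmdu=hi, method="model_average")
    res = {"NIV": result("NIV", 750, 2625), "T2HT2": result("T2HT2", 4.7, 22.09)}
    assert res["NIV"].interval_ratio == pytest.approx(3.5)
    assert res["T2HT2"].interval_ratio == pytest.approx(4.7)
    assert select_reference_compound(res) == "NIV"
    assert select_reference_compound({"ONLY": result("ONLY", 1, 2)}) == "ONLY"
    tied = {"B": result("B", 1, 3), "A": result("A", 2, 6)}
    assert select_reference_compound(tied) == "A"  # equal ratios: lexicographic


def test_parameter_recovery_median_error():
    """Across seeded noisy datasets the median BMD error stays moderate.

    Group size 20 reflects a two-sex 90-day design with haematology on all
    animals (10 per sex per group)."""
    design = DoseResponseDesign(true_rpf={}, reference="A", residual_sd_log=0.15,
                                shared_noise=False, n_per_group=20)
    true_bmd = -math.log((0.65 - 1 + 0.10) / (0.65 - 1)) / 0.05
    errs = []
    for seed in range(50):
        (ds,) = generate_dose_response(design, seed)
        m = fit_model(ds, "exponential")
        bmd = bmd_from_model(m, 0.10)
        if math.isfinite(bmd):
            errs.append(abs(bmd / true_bmd - 1))
        else:
            errs.append(1.0)
    assert np.median(errs) < 0.15
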