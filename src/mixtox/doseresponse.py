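"""Continuous-endpoint benchmark-dose analysis from dose-group summaries.

Dose-response data arrive as group summaries (dose, arithmetic mean, SD or
SEM, group size) for a continuous endpoint such as white blood cell count.
Responses are assumed lognormal within groups, so arithmetic summaries are
converted to log-scale moments and the model describes the geometric-mean
(median) response:

    median(d) = a * h(b*d; c, g)

with background ``a``, potency ``b`` (per unit dose), asymptote fold-change
``c`` and optional steepness ``g``.  The model set follows the continuous
families in common regulatory benchmark-dose practice: exponential and Hill,
each in a 3- and 4-parameter form, plus the null (flat) and full (saturated)
models used for goodness of fit.

The benchmark dose (BMD) at benchmark response BMR is the dose where the
median response changes by the fraction BMR from background; because all
families act through the product ``b*d``, the BMD is ``u*(c, g, BMR)/b`` and
relative potencies from a shared-shape (parallel-curve) simultaneous fit are
exactly independent of the BMR.

BMD confidence bounds (BMDL, BMDU) come from a seeded parametric bootstrap;
model-averaged results sample the refitted family by AIC weight.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "FAMILIES",
    "DoseResponseDataset",
    "FittedModel",
    "BmdResult",
    "SimultaneousFit",
    "sd_to_sem",
    "fit_model",
    "bmd_from_model",
    "model_average_bmd",
    "simultaneous_fit",
    "select_reference_compound",
    "aic_weights",
]

FAMILIES = ("null", "exponential", "exponential4", "hill", "hill4", "full")
_SHAPE_DIM = {"exponential": 2, "exponential4": 3, "hill": 2, "hill4": 3}
_G_MAX = 8.0


def sd_to_sem(sd: float, n: int) -> float:
    """Standard deviation to standard error of the mean: sem = sd / sqrt(n)."""
    if n < 1:
        raise ValueError(f"group size must be >= 1, got {n}")
    if sd < 0:
        raise ValueError("standard deviation must be nonnegative")
    return sd / math.sqrt(n)


def sem_to_sd(sem: float, n: int) -> float:
    """Inverse of :func:`sd_to_sem`."""
    if n < 1:
        raise ValueError(f"group size must be >= 1, got {n}")
    return sem * math.sqrt(n)


@dataclass
class DoseResponseDataset:
    """Dose-group summary statistics for one compound and one endpoint.

    ``sd`` always stores standard deviations; use :meth:`from_rows` to build
    from mixed SD/SEM reporting.  ``direction`` states whether the adverse
    change is a decrease or an increase of the mean.
    """

    compound: str
    endpoint: str
    dose: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    direction: str = "decrease"

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.direction not in ("decrease", "increase"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not (len(self.dose) == len(self.mean) == len(self.sd) == len(self.n)):
            raise ValueError("dose, mean, sd and n must have equal length")
        if not np.any(self.dose == 0):
            raise ValueError("dataset must include a control group (dose 0)")
        if np.any(self.mean <= 0):
            raise ValueError("group means must be positive (lognormal response)")
        if np.any(self.n < 1):
            raise ValueError("group sizes must be >= 1")
        if np.any(self.sd < 0):
            raise ValueError("dispersions must be nonnegative")

    @classmethod
    def from_rows(
        cls,
        compound: str,
        endpoint: str,
        rows: Iterable[tuple],
        direction: str = "decrease",
    ) -> "DoseResponseDataset":
        """Build from (dose, mean, dispersion, dispersion_type, n) rows."""
        dose, mean, sd, n = [], [], [], []
        for d, m, disp, dtype, ng in rows:
            dose.append(d)
            mean.append(m)
            n.append(ng)
            if dtype.upper() == "SD":
                sd.append(disp)
            elif dtype.upper() == "SEM":
                sd.append(sem_to_sd(disp, ng))
            else:
                raise ValueError(f"dispersion type must be SD or SEM, got {dtype!r}")
        return cls(compound, endpoint, np.array(dose), np.array(mean),
                   np.array(sd), np.array(n), direction)

    def log_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-group log-scale (mean, variance) under the lognormal assumption."""
        cv2 = (self.sd / self.mean) ** 2
        logvar = np.log1p(cv2)
        logmean = np.log(self.mean) - logvar / 2.0
        return logmean, logvar

    @classmethod
    def from_log_moments(
        cls, compound: str, endpoint: str, dose: np.ndarray,
        logmean: np.ndarray, logvar: np.ndarray, n: np.ndarray,
        direction: str = "decrease",
    ) -> "DoseResponseDataset":
        """Exact inverse of :meth:`log_moments`."""
        logvar = np.maximum(np.asarray(logvar, float), 0.0)
        mean = np.exp(np.asarray(logmean, float) + logvar / 2.0)
        sd = mean * np.sqrt(np.expm1(logvar))
        return cls(compound, endpoint, dose, mean, sd, n, direction)

    @property
    def max_dose(self) -> float:
        return float(np.max(self.dose))


# ---------------------------------------------------------------------------
# Mean functions.  All families act through u = b*d so potency rescales dose.

def _h(family: str, u: np.ndarray, c: float, g: float) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if family == "exponential":
        return c - (c - 1.0) * np.exp(-u)
    if family == "exponential4":
        return c - (c - 1.0) * np.exp(-(u ** g))
    if family == "hill":
        return 1.0 + (c - 1.0) * u / (1.0 + u)
    if family == "hill4":
        ug = u ** g
        return 1.0 + (c - 1.0) * ug / (1.0 + ug)
    raise ValueError(f"unknown family {family!r}")


def _u_at_fold_change(family: str, c: float, g: float, m: float) -> float:
    """Solve h(u) = m for u; returns inf when the asymptote never reaches m."""
    if (m - 1.0) * (c - 1.0) <= 0:
        return math.inf  # response moves the wrong way
    if abs(m - 1.0) >= abs(c - 1.0):
        return math.inf  # asymptote closer to background than the BMR
    if family in ("exponential", "exponential4"):
        ug = math.log((c - 1.0) / (c - m))
        return ug ** (1.0 / g) if family == "exponential4" else ug
    if family in ("hill", "hill4"):
        frac = (m - 1.0) / (c - m)
        return frac ** (1.0 / g) if family == "hill4" else frac
    raise ValueError(f"unknown family {family!r}")


@dataclass
class FittedModel:
    """A maximum-likelihood fit of one family to one dataset."""

    family: str
    a: float  # background (median response at dose 0)
    b: float  # potency, 1/dose units (0 for null/full)
    c: float  # asymptote fold change (1 for null)
    g: float  # steepness (1 for 3-parameter forms)
    sigma2: float  # residual log-scale variance (ML)
    loglik: float
    k: int  # number of free parameters incl. sigma
    converged: bool = True
    max_dose: float = math.inf
    direction: str = "decrease"
    group_logmeans: np.ndarray | None = None  # only for the full model

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    def median_response(self, dose: np.ndarray) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        if self.family == "null":
            return np.full_like(dose, self.a)
        if self.family == "full":
            raise ValueError("the saturated model has no dose-response curve")
        return self.a * _h(self.family, self.b * dose, self.c, self.g)


def _profile_loglik(
    logmean: np.ndarray, logvar: np.ndarray, n: np.ndarray, log_h: np.ndarray
) -> tuple[float, float, float]:
    """Profile background and variance out of the lognormal likelihood.

    Given log h(b*d) per group, the ML background is the n-weighted mean of
    (ybar - log h) and the ML variance pools within- and between-group sums
    of squares.  Returns (loglik, log_a, sigma2).
    """
    N = int(np.sum(n))
    log_a = float(np.sum(n * (logmean - log_h)) / N)
    resid = logmean - log_a - log_h
    ss = float(np.sum((n - 1) * logvar) + np.sum(n * resid ** 2))
    sigma2 = max(ss / N, 1e-300)
    loglik = -0.5 * N * (math.log(2 * math.pi * sigma2) + 1.0)
    return loglik, log_a, sigma2


def _fit_null(data: DoseResponseDataset) -> FittedModel:
    logmean, logvar = data.log_moments()
    ll, log_a, s2 = _profile_loglik(logmean, logvar, data.n, np.zeros_like(logmean))
    return FittedModel("null", math.exp(log_a), 0.0, 1.0, 1.0, s2, ll, k=2,
                       max_dose=data.max_dose, direction=data.direction)


def _fit_full(data: DoseResponseDataset) -> FittedModel:
    logmean, logvar = data.log_moments()
    N = int(np.sum(data.n))
    ss = float(np.sum((data.n - 1) * logvar))
    sigma2 = max(ss / N, 1e-300)
    ll = -0.5 * N * (math.log(2 * math.pi * sigma2) + 1.0)
    return FittedModel("full", float(data.mean[data.dose == 0][0]), 0.0, 1.0, 1.0,
                       sigma2, ll, k=len(data.dose) + 1, max_dose=data.max_dose,
                       direction=data.direction, group_logmeans=logmean)


def _unpack_shape(family: str, theta: np.ndarray) -> tuple[float, float, float]:
    b = math.exp(theta[0])
    c = math.exp(theta[1])
    g = 1.0
    if family in ("exponential4", "hill4"):
        g = 1.0 + math.exp(theta[2])
        if g > _G_MAX:
            return b, c, math.nan
    return b, c, g


def _neg_profile(theta: np.ndarray, family: str, data_log: tuple) -> float:
    logmean, logvar, n, dose = data_log
    family_base = family
    b, c, g = _unpack_shape(family, theta)
    if not math.isfinite(b) or not math.isfinite(c) or math.isnan(g):
        return 1e12
    h = _h(family_base, b * dose, c, g)
    if np.any(h <= 0):
        return 1e12
    ll, _, _ = _profile_loglik(logmean, logvar, n, np.log(h))
    return -ll


def _start_grid(data: DoseResponseDataset, family: str, hints=None) -> list[np.ndarray]:
    logmean, _ = data.log_moments()
    y0 = logmean[data.dose == 0].mean()
    yend = logmean[np.argmax(data.dose)]
    c0 = float(np.clip(math.exp(yend - y0), 1e-3, 1e3))
    if abs(c0 - 1.0) < 1e-3:
        c0 = 0.9 if data.direction == "decrease" else 1.1
    dmax = max(data.max_dose, 1e-12)
    if hints is not None:
        b_hint, c_hint, g_hint = hints
        bs = [b_hint, b_hint * 3, b_hint / 3]
        starts = []
        for b in bs:
            t = [math.log(max(b, 1e-300)), math.log(max(c_hint, 1e-6))]
            if family in ("exponential4", "hill4"):
                t.append(math.log(max(g_hint - 1.0, 1e-3)))
            starts.append(np.array(t))
        return starts
    bs = np.geomspace(0.03 / dmax, 300.0 / dmax, 10)
    starts = []
    for b in bs:
        t = [math.log(b), math.log(c0)]
        if family in ("exponential4", "hill4"):
            t.append(math.log(1.0))  # g = 2 start
        starts.append(np.array(t))
    return starts


def fit_model(
    data: DoseResponseDataset,
    family: str,
    hints: tuple[float, float, float] | None = None,
) -> FittedModel:
    """Maximum-likelihood fit of one family, multi-start over potency.

    The background and residual variance are profiled out in closed form, so
    the numerical search runs over the 2-3 shape parameters only.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if family == "null":
        return _fit_null(data)
    if family == "full":
        return _fit_full(data)
    if len(data.dose) < 3:
        raise ValueError("non-null families need at least 3 dose groups")

    logmean, logvar = data.log_moments()
    data_log = (logmean, logvar, data.n, data.dose)
    best = None
    for theta0 in _start_grid(data, family, hints):
        res = minimize(
            _neg_profile, theta0, args=(family, data_log), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    b, c, g = _unpack_shape(family, best.x)
    if math.isnan(g):
        g = _G_MAX
    h = _h(family, b * data.dose, c, g)
    ll, log_a, s2 = _profile_loglik(logmean, logvar, data.n, np.log(h))
    k = 2 + _SHAPE_DIM[family]  # a, sigma + shape parameters
    converged = bool(best.success) and math.isfinite(ll)
    return FittedModel(family, math.exp(log_a), b, c, g, s2, ll, k,
                       converged=converged, max_dose=data.max_dose,
                       direction=data.direction)


def bmd_from_model(model: FittedModel, bmr: float, direction: str | None = None) -> float:
    """Benchmark dose: the dose where the median changes by the fraction BMR.

    Solves median(BMD) = median(0) * (1 - BMR) for a decrease (1 + BMR for an
    increase).  Returns ``inf`` (unbounded flag) when the fitted curve never
    reaches the BMR, or only beyond 10x the highest tested dose.
    """
    if not 0 < bmr < 1:
        raise ValueError(f"BMR must lie in (0, 1), got {bmr}")
    direction = direction or model.direction
    if model.family in ("null", "full"):
        return math.inf
    m = 1.0 - bmr if direction == "decrease" else 1.0 + bmr
    u = _u_at_fold_change(model.family, model.c, model.g, m)
    if not math.isfinite(u) or model.b <= 0:
        return math.inf
    bmd = u / model.b
    if math.isfinite(model.max_dose) and bmd > 10.0 * model.max_dose:
        return math.inf
    return bmd


def aic_weights(models: Sequence[FittedModel]) -> np.ndarray:
    """Akaike weights, normalised to sum to 1."""
    aics = np.array([m.aic for m in models])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class BmdResult:
    """A benchmark-dose estimate with bootstrap confidence bounds."""

    compound: str
    bmr: float
    bmd: float
    bmdl: float
    bmdu: float
    method: str  # "single_model" | "model_average"
    weights: dict[str, float] = field(default_factory=dict)
    B: int = 0
    seed: int | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.bmdl <= self.bmd <= self.bmdu):
            raise ValueError(
                f"BMD ordering violated: {self.bmdl} <= {self.bmd} <= {self.bmdu}")

    @property
    def interval_ratio(self) -> float:
        """BMDU/BMDL, the width criterion for reference-compound selection."""
        return self.bmdu / self.bmdl


def _simulate_dataset(
    data: DoseResponseDataset, model: FittedModel, rng: np.random.Generator
) -> DoseResponseDataset:
    """Parametric bootstrap draw of group summaries from a fitted curve."""
    mu = np.log(model.median_response(data.dose))
    s2 = model.sigma2
    n = data.n
    ybar = rng.normal(mu, np.sqrt(s2 / n))
    logvar = np.empty(len(n))
    for i, ng in enumerate(n):
        logvar[i] = s2 * rng.chisquare(ng - 1) / (ng - 1) if ng > 1 else 0.0
    return DoseResponseDataset.from_log_moments(
        data.compound, data.endpoint, data.dose, ybar, logvar, n, data.direction)


def model_average_bmd(
    data: DoseResponseDataset,
    families: Sequence[str] = ("exponential", "exponential4", "hill", "hill4"),
    bmr: float = 0.10,
    B: int = 1000,
    seed: int | None = None,
) -> BmdResult:
    """AIC-weighted model-averaged BMD with parametric-bootstrap bounds.

    Each replicate draws a family by Akaike weight, simulates group summaries
    from that family's fit, refits the same family and records its BMD.  The
    reported BMD is the bootstrap median and BMDL/BMDU are the 5th and 95th
    percentiles (a two-sided 90% interval).
    """
    if seed is None:
        raise ValueError("a bootstrap seed is required for reproducibility")
    fits = {}
    for fam in families:
        try:
            m = fit_model(data, fam)
        except ValueError:
            continue
        if m.converged and math.isfinite(bmd_from_model(m, bmr)):
            fits[fam] = m
    if not fits:
        raise RuntimeError("no family converged to a bounded BMD; no result")
    fams = list(fits)
    w = aic_weights([fits[f] for f in fams])
    rng = np.random.default_rng(seed)
    bmds = []
    flags = []
    for _ in range(B):
        fam = fams[rng.choice(len(fams), p=w)]
        parent = fits[fam]
        sim = _simulate_dataset(data, parent, rng)
        refit = fit_model(sim, fam, hints=(parent.b, parent.c, parent.g))
        bmds.append(bmd_from_model(refit, bmr))
    bmds = np.array(bmds)
    n_unbounded = int(np.sum(~np.isfinite(bmds)))
    if n_unbounded:
        flags.append(f"{n_unbounded}/{B} bootstrap replicates unbounded")
        bmds = np.where(np.isfinite(bmds), bmds, 10.0 * data.max_dose * 10.0)
    return BmdResult(
        compound=data.compound, bmr=bmr,
        bmd=float(np.median(bmds)),
        bmdl=float(np.percentile(bmds, 5)),
        bmdu=float(np.percentile(bmds, 95)),
        method="model_average" if len(fams) > 1 else "single_model",
        weights={f: float(x) for f, x in zip(fams, w)},
        B=B, seed=seed, flags=flags,
    )


@dataclass
class SimultaneousFit:
    """A joint parallel-curve fit across compounds with a shared shape.

    Per-compound backgrounds and potencies, shared asymptote/steepness and
    residual variance.  With curves parallel on log dose the relative potency
    RPF_i = BMD_ref / BMD_i = b_i / b_ref is the same at every BMR.
    """

    family: str
    compounds: list[str]
    reference: str
    a: dict[str, float]
    b: dict[str, float]
    c: float
    g: float
    sigma2: float
    loglik: float
    k: int
    direction: str = "decrease"
    parallel_ok: bool = True
    aic_margin: float = 0.0
    bmd_results: dict[str, BmdResult] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    def rpfs(self) -> dict[str, float]:
        bref = self.b[self.reference]
        return {cpd: self.b[cpd] / bref for cpd in self.compounds}

    def bmd(self, compound: str, bmr: float) -> float:
        m = 1.0 - bmr if self.direction == "decrease" else 1.0 + bmr
        u = _u_at_fold_change(self.family, self.c, self.g, m)
        return u / self.b[compound] if math.isfinite(u) else math.inf


def _joint_neg_profile(theta, family, data_logs):
    # theta = [log c, (log(g-1)), log b_1 ... log b_k]
    shape_dim = 2 if family in ("exponential4", "hill4") else 1
    c = math.exp(theta[0])
    g = 1.0 + math.exp(theta[1]) if shape_dim == 2 else 1.0
    if g > _G_MAX or not math.isfinite(c):
        return 1e12
    total_N = 0
    total_ss = 0.0
    for i, (logmean, logvar, n, dose) in enumerate(data_logs):
        b = math.exp(theta[shape_dim + i])
        h = _h(family, b * dose, c, g)
        if np.any(h <= 0):
            return 1e12
        log_h = np.log(h)
        N = int(np.sum(n))
        log_a = float(np.sum(n * (logmean - log_h)) / N)
        resid = logmean - log_a - log_h
        total_ss += float(np.sum((n - 1) * logvar) + np.sum(n * resid ** 2))
        total_N += N
    sigma2 = max(total_ss / total_N, 1e-300)
    return 0.5 * total_N * (math.log(2 * math.pi * sigma2) + 1.0)


def simultaneous_fit(
    datasets: Sequence[DoseResponseDataset],
    reference: str,
    bmr: float = 0.10,
    families: Sequence[str] = ("exponential", "exponential4", "hill", "hill4"),
    B: int = 200,
    seed: int | None = None,
    aic_margin_per_param: float = 2.0,
    _hints: "SimultaneousFit | None" = None,
) -> SimultaneousFit:
    """Joint parallel-curve fit across compounds, yielding BMR-free RPFs.

    All datasets must share the endpoint and direction and include controls.
    The best family by AIC is retained.  A parallelism check compares the
    joint fit against fully separate per-compound fits: if the joint model is
    worse by more than ``aic_margin_per_param`` AIC units per parameter saved,
    the fit is flagged (RPFs are still reported).  When ``seed`` is given,
    per-compound BMD confidence bounds at ``bmr`` are attached via parametric
    bootstrap of the joint fit.
    """
    if len(datasets) < 2:
        raise ValueError("a simultaneous fit needs at least two datasets")
    endpoints = {d.endpoint for d in datasets}
    directions = {d.direction for d in datasets}
    if len(endpoints) > 1 or len(directions) > 1:
        raise ValueError("datasets must share endpoint and direction")
    compounds = [d.compound for d in datasets]
    if reference not in compounds:
        raise ValueError(f"reference {reference!r} not among {compounds}")

    data_logs = [(d.log_moments()[0], d.log_moments()[1], d.n, d.dose) for d in datasets]

    best: SimultaneousFit | None = None
    for family in families:
        shape_dim = 2 if family in ("exponential4", "hill4") else 1
        if _hints is not None and _hints.family == family:
            bs0 = [max(_hints.b[c], 1e-12) for c in compounds]
            base = [math.log(max(_hints.c, 1e-6))]
            if shape_dim == 2:
                base.append(math.log(max(_hints.g - 1.0, 1e-3)))
            starts = [np.array(base + [math.log(b) for b in bs0])]
            separate = None
        else:
            separate = [fit_model(d, family) for d in datasets]
            starts = []
            c_start = float(np.mean([max(s.c, 1e-6) for s in separate]))
            base = [math.log(c_start)] + ([math.log(1.0)] if shape_dim == 2 else [])
            starts.append(np.array(base + [math.log(max(s.b, 1e-12)) for s in separate]))
            for mult in (0.3, 3.0):
                starts.append(np.array(
                    base + [math.log(max(s.b * mult, 1e-12)) for s in separate]))
        res_best = None
        for theta0 in starts:
            res = minimize(_joint_neg_profile, theta0, args=(family, data_logs),
                           method="Nelder-Mead",
                           options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 8000})
            if res_best is None or res.fun < res_best.fun:
                res_best = res
        assert res_best is not None
        c = math.exp(res_best.x[0])
        g = 1.0 + math.exp(res_best.x[1]) if shape_dim == 2 else 1.0
        bs = {cpd: math.exp(res_best.x[shape_dim + i]) for i, cpd in enumerate(compounds)}
        # recompute per-compound backgrounds and the pooled variance
        total_N, total_ss = 0, 0.0
        a = {}
        ll = -res_best.fun
        for (logmean, logvar, n, dose), cpd in zip(data_logs, compounds):
            h = _h(family, bs[cpd] * dose, c, g)
            log_h = np.log(h)
            N = int(np.sum(n))
            a[cpd] = math.exp(float(np.sum(n * (logmean - log_h)) / N))
            resid = logmean - math.log(a[cpd]) - log_h
            total_ss += float(np.sum((n - 1) * logvar) + np.sum(n * resid ** 2))
            total_N += N
        sigma2 = total_ss / total_N
        # k: per-compound a and b, shared c (+g), shared sigma
        k = 2 * len(compounds) + shape_dim + 1
        if separate is not None:
            sep_aic = sum(s.aic for s in separate)
            joint_aic = 2 * k - 2 * ll
            extra_params = sum(s.k for s in separate) - k
            margin = float(joint_aic - sep_aic)
            parallel_ok = bool(margin <= aic_margin_per_param * max(extra_params, 1))
        else:
            margin, parallel_ok = 0.0, True
        fit = SimultaneousFit(
            family=family, compounds=compounds, reference=reference,
            a=a, b=bs, c=c, g=g, sigma2=sigma2, loglik=ll, k=k,
            direction=datasets[0].direction,
            parallel_ok=parallel_ok, aic_margin=margin,
        )
        if best is None or fit.aic < best.aic:
            best = fit
    assert best is not None
    if not best.parallel_ok:
        warnings.warn(
            f"parallelism check failed (joint AIC worse by {best.aic_margin:.1f}); "
            "RPFs reported with a flag", stacklevel=2)
    if seed is not None:
        best.bmd_results = _joint_bootstrap(datasets, best, bmr, B, seed)
    return best


def _joint_bootstrap(
    datasets: Sequence[DoseResponseDataset],
    fit: SimultaneousFit,
    bmr: float,
    B: int,
    seed: int,
) -> dict[str, BmdResult]:
    """Per-compound BMD bounds from a parametric bootstrap of the joint fit."""
    rng = np.random.default_rng(seed)
    boot: dict[str, list[float]] = {c: [] for c in fit.compounds}
    for _ in range(B):
        sims = []
        for d, cpd in zip(datasets, fit.compounds):
            mu = np.log(fit.a[cpd] * _h(fit.family, fit.b[cpd] * d.dose, fit.c, fit.g))
            ybar = rng.normal(mu, np.sqrt(fit.sigma2 / d.n))
            logvar = np.array([
                fit.sigma2 * rng.chisquare(ng - 1) / (ng - 1) if ng > 1 else 0.0
                for ng in d.n])
            sims.append(DoseResponseDataset.from_log_moments(
                d.compound, d.endpoint, d.dose, ybar, logvar, d.n, d.direction))
        refit = simultaneous_fit(
            sims, fit.reference, bmr=bmr, families=(fit.family,), seed=None,
            _hints=fit)
        for cpd in fit.compounds:
            boot[cpd].append(refit.bmd(cpd, bmr))
    out = {}
    for cpd, vals in boot.items():
        arr = np.array(vals)
        arr = np.where(np.isfinite(arr), arr, np.nanmax(arr[np.isfinite(arr)]) * 100)
        out[cpd] = BmdResult(
            compound=cpd, bmr=bmr,
            bmd=float(np.median(arr)),
            bmdl=float(np.percentile(arr, 5)),
            bmdu=float(np.percentile(arr, 95)),
            method="single_model", B=B, seed=seed,
            weights={fit.family: 1.0},
        )
    return out


def select_reference_compound(results: Mapping[str, BmdResult]) -> str:
    """Pick the compound with the least uncertain BMD (smallest BMDU/BMDL).

    Ties break lexicographically by compound id.
    """
    if not results:
        raise ValueError("no BMD results to select from")
    return min(results, key=lambda c: (results[c].interval_ratio, c))
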