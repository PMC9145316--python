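"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generators emulate the shape of total-diet-study inputs: multi-day
consumption diaries with lognormal body weights and amounts, composite
samples contaminated at lognormal levels with heavy left-censoring at
realistic LOD/LOQ, and dose-group summary datasets drawn around known
parallel dose-response curves (so potency recovery can be tested against a
known truth).

All randomness flows from one root seed through named substreams, so each
component can be regenerated independently and byte-for-byte reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mixtox.doseresponse import DoseResponseDataset, _h
from mixtox.exposure import ConsumptionSurvey, FoodConversionTable
from mixtox.hazard import builtin_trvs
from mixtox.risk import RelativePotencyFactorSet

__all__ = [
    "SurveyDesign",
    "FoodDesign",
    "ContaminationDesign",
    "ContaminantDesign",
    "DoseResponseDesign",
    "generate_survey",
    "generate_concentrations",
    "generate_dose_response",
    "synthetic_wbc_datasets",
    "study_fixture",
    "FixtureBundle",
]

_STREAMS = {"survey": 1, "concentration": 2, "dose_response": 3, "fixture": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class FoodDesign:
    """Daily consumption behaviour for one diary food."""

    food_code: str
    probability: float  # chance of consumption on any survey day
    amount_median_g: float
    amount_sigma_log: float = 0.4

    def __post_init__(self) -> None:
        if not 0 <= self.probability <= 1:
            raise ValueError("consumption probability must lie in [0, 1]")
        if self.amount_median_g < 0:
            raise ValueError("amounts must be nonnegative")


@dataclass(frozen=True)
class SurveyDesign:
    """A diary design: individuals, days and food consumption behaviour."""

    n_individuals: int
    n_days: int = 2
    age_group: str = "1-2"
    bw_median_kg: float = 11.5
    bw_sigma_log: float = 0.13
    foods: tuple[FoodDesign, ...] = ()


@dataclass(frozen=True)
class ContaminantDesign:
    """Contamination of one composite sample by one compound."""

    sample_code: str
    compound: str
    occurrence: float  # probability a sample carries the compound at all
    conc_median_ug_per_kg: float
    conc_sigma_log: float = 0.8
    lod_ug_per_kg: float = 0.1
    loq_ug_per_kg: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.occurrence <= 1:
            raise ValueError("occurrence must lie in [0, 1]")
        if self.lod_ug_per_kg > self.loq_ug_per_kg:
            raise ValueError("LOD must not exceed LOQ")


@dataclass(frozen=True)
class ContaminationDesign:
    """Per sample x compound contamination with optional co-occurrence.

    ``rank_correlation`` > 0 couples the compounds within a sample through a
    shared latent normal (1.0 gives perfectly rank-correlated levels, the
    comonotonic fixture).
    """

    contaminants: tuple[ContaminantDesign, ...]
    n_samples_per_code: int = 1
    rank_correlation: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.rank_correlation <= 1:
            raise ValueError("rank correlation must lie in [0, 1]")


def generate_survey(design: SurveyDesign, seed: int) -> ConsumptionSurvey:
    """Draw a seeded consumption survey matching the design."""
    rng = _rng(seed, "survey")
    ids = [f"ind{i:04d}" for i in range(design.n_individuals)]
    bw = rng.lognormal(np.log(design.bw_median_kg), design.bw_sigma_log,
                       size=design.n_individuals)
    individuals = pd.DataFrame({
        "individual_id": ids,
        "body_weight_kg": bw,
        "age_group": design.age_group,
    })
    rows = []
    for iid in ids:
        for day in range(1, design.n_days + 1):
            for food in design.foods:
                if rng.random() < food.probability:
                    amount = rng.lognormal(np.log(max(food.amount_median_g, 1e-12)),
                                           food.amount_sigma_log)
                    rows.append((iid, day, food.food_code, amount))
    records = pd.DataFrame(rows, columns=["individual_id", "day", "food_code", "amount_g"])
    if records.empty:
        records = pd.DataFrame(columns=["individual_id", "day", "food_code", "amount_g"])
    return ConsumptionSurvey(individuals=individuals, records=records,
                             n_survey_days=design.n_days)


def generate_concentrations(design: ContaminationDesign, seed: int) -> pd.DataFrame:
    """Draw a seeded concentration table with left-censoring.

    Occurrence is drawn first; occurring values below the LOD are emitted as
    censored with only the LOD on record, values between LOD and LOQ as
    censored with both limits (detected but not quantified).
    """
    rng = _rng(seed, "concentration")
    by_sample: dict[str, list[ContaminantDesign]] = {}
    for c in design.contaminants:
        by_sample.setdefault(c.sample_code, []).append(c)

    rows = []
    for sample_code, contaminants in by_sample.items():
        for rep in range(design.n_samples_per_code):
            code = sample_code if design.n_samples_per_code == 1 else f"{sample_code}_{rep}"
            shared = rng.standard_normal()
            for c in contaminants:
                rho = design.rank_correlation
                z = rho * shared + np.sqrt(1 - rho ** 2) * rng.standard_normal()
                u = rng.random() if rho < 1 else _std_normal_cdf(shared)
                occurred = u < c.occurrence
                value = np.exp(np.log(c.conc_median_ug_per_kg) + c.conc_sigma_log * z) \
                    if occurred else 0.0
                if not occurred or value < c.lod_ug_per_kg:
                    rows.append((code, c.compound, np.nan, True, c.lod_ug_per_kg, np.nan))
                elif value < c.loq_ug_per_kg:
                    rows.append((code, c.compound, np.nan, True,
                                 c.lod_ug_per_kg, c.loq_ug_per_kg))
                else:
                    rows.append((code, c.compound, value, False,
                                 c.lod_ug_per_kg, c.loq_ug_per_kg))
    return pd.DataFrame(rows, columns=[
        "sample_code", "compound", "value_ug_per_kg", "censored",
        "lod_ug_per_kg", "loq_ug_per_kg"])


def _std_normal_cdf(z: float) -> float:
    from math import erf, sqrt
    return 0.5 * (1.0 + erf(z / sqrt(2.0)))


@dataclass(frozen=True)
class DoseResponseDesign:
    """True parallel curves for potency-recovery experiments.

    The reference compound follows median(d) = a * h(b*d; c, g); every other
    compound's curve is the reference curve with doses divided by its true
    RPF (parallel on log dose by construction).
    """

    family: str = "exponential"
    a: float = 100.0
    b_reference: float = 0.05  # potency of the reference compound, 1/dose
    c: float = 0.65
    g: float = 1.0
    true_rpf: Mapping[str, float] = field(default_factory=dict)  # compound -> RPF
    reference: str = "REF"
    dose_grids: Mapping[str, Sequence[float]] = field(default_factory=dict)
    n_per_group: int = 10
    residual_sd_log: float = 0.15
    shared_noise: bool = True
    reporting: Mapping[str, str] = field(default_factory=dict)  # compound -> SD|SEM
    endpoint: str = "white blood cell count"
    direction: str = "decrease"


def generate_dose_response(design: DoseResponseDesign, seed: int) -> list[DoseResponseDataset]:
    """Draw seeded dose-group summaries around the true curves.

    Non-reference compounds follow the reference curve with doses divided by
    their true RPF (parallel curves).  With ``shared_noise`` (the default)
    compounds whose grids have the same number of groups reuse the reference
    dataset's group-level deviations, i.e. a scaled compound's dataset is the
    reference dataset translated along log dose — the construction that makes
    potency-ratio recovery a sharp test.  With ``shared_noise=False`` every
    dataset gets independent deviations.
    """
    rng = _rng(seed, "dose_response")
    compounds = [design.reference] + [c for c in design.true_rpf if c != design.reference]
    default_grid = np.asarray(
        design.dose_grids.get(design.reference, (0, 1, 4, 16, 64)), dtype=float)
    s = design.residual_sd_log
    n_ref = design.n_per_group
    eps_ref = rng.standard_normal(len(default_grid))
    chi_ref = rng.chisquare(max(n_ref - 1, 1), size=len(default_grid))
    out = []
    for cpd in compounds:
        rpf = 1.0 if cpd == design.reference else float(design.true_rpf[cpd])
        b = design.b_reference * rpf
        if cpd in design.dose_grids:
            dose = np.asarray(design.dose_grids[cpd], dtype=float)
        else:
            dose = default_grid / rpf
        n = np.full(len(dose), design.n_per_group, dtype=int)
        mu = np.log(design.a * _h(design.family, b * dose, design.c, design.g))
        if s > 0:
            if design.shared_noise and len(dose) == len(default_grid):
                eps, chi = eps_ref, chi_ref
            else:
                eps = rng.standard_normal(len(dose))
                chi = rng.chisquare(max(design.n_per_group - 1, 1), size=len(dose))
            ybar = mu + eps * s / np.sqrt(n)
            logvar = np.where(n > 1, s ** 2 * chi / np.maximum(n - 1, 1), 0.0)
        else:
            ybar, logvar = mu, np.zeros(len(dose))
        ds = DoseResponseDataset.from_log_moments(
            cpd, design.endpoint, dose, ybar, logvar, n, design.direction)
        if design.reporting.get(cpd, "SD").upper() == "SEM":
            # round-trip through SEM reporting, as heterogeneous sources do
            ds = DoseResponseDataset.from_rows(
                cpd, design.endpoint,
                [(d, m, sd / np.sqrt(ng), "SEM", int(ng))
                 for d, m, sd, ng in zip(ds.dose, ds.mean, ds.sd, ds.n)],
                design.direction)
        out.append(ds)
    return out


def synthetic_wbc_datasets(seed: int = 42) -> tuple[DoseResponseDataset, DoseResponseDataset]:
    """SYNTHETIC stand-in for a pair of 90-day rat white-blood-cell datasets.

    Two parallel exponential curves with a true potency ratio of 140 (the
    less potent compound labelled NIV, the more potent T2HT2), group sizes of
    ten and a residual log-scale SD of 0.15 (a typical white-blood-cell
    coefficient of variation).  The NIV curve reaches a 10% median decrease
    near 1400 ug/kg bw/d and the T2HT2 curve near 10 ug/kg bw/d; the T2HT2
    grid is the NIV grid translated along log dose, so the pair is parallel
    in realisation as well as in truth.  NIV dispersion is reported as SD and
    T2HT2 as SEM, exercising the SD-to-SEM alignment step.  These are
    simulated data, not measurements from any study.
    """
    u10 = np.log((0.65 - 1.0) / (0.65 - 0.90))  # = ln 1.4
    design = DoseResponseDesign(
        family="exponential", a=9.0, b_reference=u10 / 1400.0, c=0.65,
        true_rpf={"T2HT2": 140.0}, reference="NIV",
        dose_grids={"NIV": (0, 100, 400, 1600, 6400)},
        n_per_group=10, residual_sd_log=0.15, shared_noise=True,
        reporting={"NIV": "SD", "T2HT2": "SEM"},
    )
    niv, t2 = generate_dose_response(design, seed)
    return niv, t2


@dataclass
class FixtureBundle:
    """A full synthetic study: survey, concentrations, groups and TRVs."""

    survey: ConsumptionSurvey
    conversion: FoodConversionTable
    concentrations: pd.DataFrame
    organ_groups: dict[str, list[str]]  # group id -> member compounds
    phenomenon_groups: dict[str, str]  # phenomenon id -> parent organ group
    phenomenon_members: dict[str, list[str]]
    trvs: dict[str, dict[str, float]]  # group id -> compound -> TRV
    rpf_sets: dict[str, RelativePotencyFactorSet]
    seed: int = 0

    def exposures(self, group: str, scenario: str):
        """Per-compound OIM exposure distributions for one group/scenario."""
        from mixtox.exposure import oim_exposure, sum_exposures

        members = self.phenomenon_members.get(group) or self.organ_groups[group]
        out = {}
        for compound in members:
            if compound == "T2HT2":
                parts = [oim_exposure(self.survey, self.concentrations,
                                      self.conversion, scenario, c)
                         for c in ("T2", "HT2")]
                out[compound] = sum_exposures(parts, "T2HT2")
            else:
                out[compound] = oim_exposure(self.survey, self.concentrations,
                                             self.conversion, scenario, compound)
        return out


def study_fixture(seed: int, comonotonic: bool = False) -> FixtureBundle:
    """A three-group study fixture driving the tiered flow end to end.

    Kidney-like, liver-like and haematological groups with TRVs from the
    packaged reference-point table; contamination levels are set so that the
    liver group raises no concern (all combined metrics below 1) while
    T2/HT2-driven haematological exposure exceeds its TRV, triggering
    refinement to the reduced-white-blood-cell phenomenon tier, where an RPF
    set (T2HT2 vs NIV, potency ratio 140) is available for the final tier.

    With ``comonotonic=True`` all compounds contaminate a single composite
    sample with perfectly rank-correlated levels, making per-compound
    exposures comonotonic across individuals.
    """
    foods = (
        FoodDesign("bread", 0.95, 80.0, 0.3),
        FoodDesign("milk", 0.85, 300.0, 0.4),
        FoodDesign("oat_porridge", 0.45, 150.0, 0.4),
        FoodDesign("maize_snack", 0.30, 30.0, 0.5),
        FoodDesign("fruit_puree", 0.50, 90.0, 0.4),
    )
    survey = generate_survey(SurveyDesign(n_individuals=150, foods=foods), seed)

    if comonotonic:
        conv_rows = pd.DataFrame(
            [(f.food_code, "composite_all", 1.0) for f in foods],
            columns=["food_code", "sample_code", "proportion"])
        contaminants = tuple(
            ContaminantDesign("composite_all", cpd, 1.0, median, 0.8, 0.01, 0.03)
            for cpd, median in [("CIT", 2.0), ("OTA", 0.2), ("PAT", 5.0),
                                ("FB1", 20.0), ("ZEN", 2.0), ("NIV", 20.0),
                                ("T2", 3.0), ("HT2", 2.0), ("DAS", 0.5)])
        contamination = ContaminationDesign(contaminants, rank_correlation=1.0)
    else:
        conv_rows = pd.DataFrame([
            ("bread", "wheat_composite", 1.0),
            ("milk", "dairy_composite", 1.0),
            ("oat_porridge", "oat_composite", 1.0),
            ("maize_snack", "maize_composite", 1.0),
            ("fruit_puree", "fruit_composite", 1.0),
        ], columns=["food_code", "sample_code", "proportion"])
        contaminants = (
            # kidney group: CIT and OTA in cereals, PAT in fruit
            ContaminantDesign("wheat_composite", "CIT", 0.35, 3.0, 0.8, 1.0, 2.0),
            ContaminantDesign("wheat_composite", "OTA", 0.40, 0.3, 0.8, 0.05, 0.15),
            ContaminantDesign("fruit_composite", "PAT", 0.30, 4.0, 0.8, 1.0, 3.0),
            # liver group: FB1 in maize, ZEN in wheat - low relative to TRVs
            ContaminantDesign("maize_composite", "FB1", 0.50, 15.0, 0.8, 2.0, 5.0),
            ContaminantDesign("wheat_composite", "ZEN", 0.40, 1.5, 0.8, 0.5, 1.0),
            # haematological group: T2/HT2 in oats drive the risk
            ContaminantDesign("oat_composite", "NIV", 0.50, 25.0, 0.8, 5.0, 10.0),
            ContaminantDesign("oat_composite", "T2", 0.70, 4.0, 0.8, 0.5, 1.0),
            ContaminantDesign("oat_composite", "HT2", 0.70, 3.0, 0.8, 0.5, 1.0),
            ContaminantDesign("dairy_composite", "DAS", 0.10, 0.3, 0.8, 0.1, 0.3),
        )
        contamination = ContaminationDesign(contaminants)
    concentrations = generate_concentrations(contamination, seed)

    trv = builtin_trvs()
    organ_groups = {
        "kidney": ["CIT", "OTA", "PAT"],
        "liver": ["FB1", "ZEN"],
        "haematological": ["DAS", "NIV", "T2HT2"],
    }
    phenomenon_groups = {"wbc": "haematological"}
    phenomenon_members = {"wbc": ["DAS", "NIV", "T2HT2"]}
    trvs = {
        "kidney": {c: trv[(c, "kidney")].value for c in organ_groups["kidney"]},
        "liver": {c: trv[(c, "liver")].value for c in organ_groups["liver"]},
        "haematological": {c: trv[(c, "haematological")].value
                           for c in organ_groups["haematological"]},
        "wbc": {c: trv[(c, "wbc")].value for c in phenomenon_members["wbc"]},
    }
    rpf_sets = {"wbc": RelativePotencyFactorSet(reference="NIV",
                                                rpfs={"NIV": 1.0, "T2HT2": 140.0})}
    return FixtureBundle(
        survey=survey,
        conversion=FoodConversionTable(rows=conv_rows),
        concentrations=concentrations,
        organ_groups=organ_groups,
        phenomenon_groups=phenomenon_groups,
        phenomenon_members=phenomenon_members,
        trvs=trvs,
        rpf_sets=rpf_sets,
        seed=seed,
    )
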