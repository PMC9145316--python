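"""Mixture risk characterisation under dose addition.

Two families of combined-risk metrics are implemented:

* *Percentile summation* — per-compound risk quotients (exposure percentile
  over TRV) are summed at a common percentile: the hazard index (HI, against
  HBGVs) and the modified reference point index (mRPI, against group-specific
  TRVs).  Summing high percentiles of individually-ranked distributions can
  overstate the combined risk when high exposures do not co-occur in the same
  individuals.
* *Individual-level combination* — per-compound exposures are first scaled to
  equivalents of a reference compound (by TRV ratios, or by relative potency
  factors from a simultaneous dose-response analysis), summed within each
  individual, and only then reduced to percentiles and divided by the
  reference compound's TRV.

The tiered flow evaluates organ-level groups first, refines to the
phenomenon level only where a combined metric exceeds 1, and refines further
to RPF-based combination only where suitable paired dose-response data exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from mixtox.exposure import ExposureDistribution, percentile_with_uncertainty
from mixtox.hazard import ToxicologicalReferenceValue, round_sig

__all__ = [
    "RiskQuotient",
    "CombinedRiskMetric",
    "RelativePotencyFactorSet",
    "TierDecision",
    "hazard_index",
    "mrpi_sum",
    "cumulative_exposure_trv_scaling",
    "combine_with_rpf",
    "risk_characterisation",
    "tiered_assessment",
]


@dataclass(frozen=True)
class RiskQuotient:
    """Exposure percentile over a reference value, for one compound.

    ``flavor`` distinguishes an HQ (exposure over HBGV) from an RPQ (exposure
    over a group-specific TRV, equivalently exposure x AF / RP).
    """

    compound: str
    group: str
    scenario: str
    percentile: float
    quotient: float
    flavor: str = "RPQ"  # "HQ" | "RPQ"

    def __post_init__(self) -> None:
        if self.quotient < 0:
            raise ValueError("risk quotient must be nonnegative")
        if self.flavor not in ("HQ", "RPQ"):
            raise ValueError(f"unknown quotient flavor {self.flavor!r}")


@dataclass(frozen=True)
class CombinedRiskMetric:
    """A combined risk value for one group/scenario/percentile."""

    group: str
    scenario: str
    percentile: float
    method: str  # "HI" | "mRPI_sum" | "mRPI_individual" | "RPF_individual"
    value: float
    reference_compound: str | None = None
    missing_compounds: tuple[str, ...] = ()

    @property
    def reported(self) -> float:
        return round_sig(self.value, 2)

    @property
    def exceeds_one(self) -> bool:
        # threshold applied to the unrounded value
        return self.value > 1.0


@dataclass(frozen=True)
class RelativePotencyFactorSet:
    """Relative potencies versus a reference compound (RPF_reference = 1)."""

    reference: str
    rpfs: Mapping[str, float]

    def __post_init__(self) -> None:
        for c, r in self.rpfs.items():
            if r <= 0:
                raise ValueError(f"RPF for {c} must be positive, got {r}")
        ref_rpf = self.rpfs.get(self.reference, 1.0)
        if abs(ref_rpf - 1.0) > 1e-12:
            raise ValueError("RPF of the reference compound must equal 1")

    def rpf(self, compound: str) -> float:
        if compound == self.reference:
            return 1.0
        return self.rpfs[compound]

    def rebased(self, new_reference: str) -> "RelativePotencyFactorSet":
        """Express the same potencies against a different reference compound."""
        scale = self.rpf(new_reference)
        return RelativePotencyFactorSet(
            reference=new_reference,
            rpfs={c: r / scale for c, r in {**self.rpfs, self.reference: 1.0}.items()},
        )


def _check_alignment(quotients: Sequence[RiskQuotient]) -> None:
    if not quotients:
        raise ValueError("no risk quotients supplied")
    percentiles = {q.percentile for q in quotients}
    scenarios = {q.scenario for q in quotients}
    if len(percentiles) > 1:
        raise ValueError(f"mixed percentiles {sorted(percentiles)} cannot be summed")
    if len(scenarios) > 1:
        raise ValueError(f"mixed scenarios {sorted(scenarios)} cannot be summed")


def hazard_index(hqs: Sequence[RiskQuotient]) -> CombinedRiskMetric:
    """Sum hazard quotients into a hazard index at one percentile/scenario."""
    _check_alignment(hqs)
    q = hqs[0]
    return CombinedRiskMetric(
        group=q.group, scenario=q.scenario, percentile=q.percentile,
        method="HI", value=float(sum(h.quotient for h in hqs)),
    )


def mrpi_sum(
    rpqs: Sequence[RiskQuotient],
    expected_compounds: Sequence[str] | None = None,
) -> CombinedRiskMetric:
    """Sum per-compound RPQs into the modified reference point index.

    ``expected_compounds`` lets the caller declare the group membership so
    compounds missing from the summation are reported rather than silently
    dropped.
    """
    _check_alignment(rpqs)
    q = rpqs[0]
    present = {r.compound for r in rpqs}
    missing = tuple(sorted(set(expected_compounds or ()) - present))
    return CombinedRiskMetric(
        group=q.group, scenario=q.scenario, percentile=q.percentile,
        method="mRPI_sum", value=float(sum(r.quotient for r in rpqs)),
        missing_compounds=missing,
    )


def _aligned_values(
    exposures: Mapping[str, ExposureDistribution]
) -> tuple[list, dict[str, np.ndarray], str]:
    ids = None
    scenario = None
    for dist in exposures.values():
        if ids is None:
            ids, scenario = dist.individual_ids, dist.scenario
        elif dist.individual_ids != ids:
            raise ValueError("exposure distributions cover different individuals")
        elif dist.scenario != scenario:
            raise ValueError("exposure distributions mix censoring scenarios")
    assert ids is not None
    return ids, {c: d.values for c, d in exposures.items()}, scenario


def cumulative_exposure_trv_scaling(
    exposures: Mapping[str, ExposureDistribution],
    trvs: Mapping[str, float | ToxicologicalReferenceValue],
    reference: str,
) -> ExposureDistribution:
    """Individual-level cumulative exposure in reference-compound equivalents.

    Each compound's per-individual exposure is multiplied by TRV_ref/TRV_i and
    the scaled exposures are summed within individuals.  The resulting risk
    quotient (percentile over TRV_ref) is invariant to the choice of
    reference, since it reduces to the sum of E_i/TRV_i.
    """
    ids, values, scenario = _aligned_values(exposures)

    def trv_of(c: str) -> float:
        try:
            trv = trvs[c]
        except KeyError:
            raise KeyError(f"no TRV configured for compound {c!r}") from None
        return trv.value if isinstance(trv, ToxicologicalReferenceValue) else float(trv)

    trv_ref = trv_of(reference)
    total = np.zeros(len(ids))
    for compound, e in values.items():
        total += e * (trv_ref / trv_of(compound))
    return ExposureDistribution(
        compound=f"{reference}-equivalents", scenario=scenario,
        individual_ids=ids, values=total,
    )


def combine_with_rpf(
    exposures: Mapping[str, ExposureDistribution],
    rpfs: RelativePotencyFactorSet,
) -> ExposureDistribution:
    """Individual-level cumulative exposure in RPF-scaled equivalents.

    Per individual: sum of E_i x RPF_i, with RPF of the reference equal to 1.
    Changing the reference rescales every RPF by the inverse of the new
    reference's RPF, so metrics under two reference choices differ by a fixed
    factor (RPF x TRV ratio), unlike TRV-ratio scaling.
    """
    ids, values, scenario = _aligned_values(exposures)
    total = np.zeros(len(ids))
    for compound, e in values.items():
        total += e * rpfs.rpf(compound)
    return ExposureDistribution(
        compound=f"{rpfs.reference}-equivalents", scenario=scenario,
        individual_ids=ids, values=total,
    )


def risk_characterisation(
    combined: ExposureDistribution,
    trv_ref: float | ToxicologicalReferenceValue,
    percentiles: Sequence[float] = (50, 95),
    B: int = 100,
    seed: int | None = None,
    group: str = "",
    method: str = "mRPI_individual",
    reference: str | None = None,
) -> list[CombinedRiskMetric]:
    """Divide combined-exposure percentiles by the reference TRV.

    Percentiles are the bootstrap medians from
    :func:`mixtox.exposure.percentile_with_uncertainty`.
    """
    trv = trv_ref.value if isinstance(trv_ref, ToxicologicalReferenceValue) else float(trv_ref)
    if trv <= 0:
        raise ValueError("reference TRV must be positive")
    out = []
    for p in percentiles:
        est = percentile_with_uncertainty(combined, p, B=B, seed=seed)
        out.append(CombinedRiskMetric(
            group=group or combined.compound, scenario=combined.scenario,
            percentile=p, method=method, value=est.median_of_bootstrap / trv,
            reference_compound=reference,
        ))
    return out


@dataclass
class TierDecision:
    """Outcome of one tier of the assessment for one group."""

    group: str
    tier: str  # "organ" | "phenomenon" | "rpf"
    proceed: bool
    trigger: float  # max combined metric observed at this tier
    metrics: list[CombinedRiskMetric] = field(default_factory=list)
    note: str = ""


def _tier_metrics(
    exposures_by_scenario: Mapping[str, Mapping[str, ExposureDistribution]],
    trvs: Mapping[str, float],
    percentiles: Sequence[float],
    B: int,
    seed: int,
    group: str,
    method: str = "mRPI_individual",
    rpfs: RelativePotencyFactorSet | None = None,
) -> list[CombinedRiskMetric]:
    metrics: list[CombinedRiskMetric] = []
    for scenario, exposures in exposures_by_scenario.items():
        members = list(exposures)
        reference = rpfs.reference if rpfs is not None else members[0]
        if rpfs is not None:
            combined = combine_with_rpf(exposures, rpfs)
        else:
            combined = cumulative_exposure_trv_scaling(exposures, trvs, reference)
        metrics.extend(risk_characterisation(
            combined, trvs[reference], percentiles, B=B, seed=seed,
            group=group, method=method, reference=reference,
        ))
        # percentile-summation companion (mRPI as sum of per-compound RPQs)
        for p in percentiles:
            rpqs = []
            for c in members:
                est = percentile_with_uncertainty(exposures[c], p, B=B, seed=seed)
                rpqs.append(RiskQuotient(
                    compound=c, group=group, scenario=scenario, percentile=p,
                    quotient=est.median_of_bootstrap / trvs[c],
                ))
            metrics.append(mrpi_sum(rpqs, expected_compounds=members))
    return metrics


def tiered_assessment(
    organ_groups: Mapping[str, Mapping[str, Mapping[str, ExposureDistribution]]],
    organ_trvs: Mapping[str, Mapping[str, float]],
    phenomenon_groups: Mapping[str, str] | None = None,
    phenomenon_exposures: Mapping[str, Mapping[str, Mapping[str, ExposureDistribution]]] | None = None,
    phenomenon_trvs: Mapping[str, Mapping[str, float]] | None = None,
    rpf_sets: Mapping[str, RelativePotencyFactorSet] | None = None,
    percentiles: Sequence[float] = (50, 95),
    B: int = 100,
    seed: int = 0,
) -> list[TierDecision]:
    """Run the tiered decision flow over assessment groups.

    ``organ_groups`` maps group id -> scenario -> compound -> exposure
    distribution.  The organ tier is always evaluated; a group proceeds to
    the phenomenon tier only if any combined metric exceeds 1 there, and to
    the RPF tier only if a phenomenon-level concern remains and an RPF set is
    available for that group.  The returned trail records every decision.
    """
    phenomenon_groups = phenomenon_groups or {}
    phenomenon_exposures = phenomenon_exposures or {}
    phenomenon_trvs = phenomenon_trvs or {}
    rpf_sets = rpf_sets or {}
    trail: list[TierDecision] = []

    for group, by_scenario in organ_groups.items():
        metrics = _tier_metrics(by_scenario, organ_trvs[group], percentiles, B, seed, group)
        trigger = max(m.value for m in metrics)
        proceed = trigger > 1.0
        trail.append(TierDecision(
            group=group, tier="organ", proceed=proceed, trigger=trigger,
            metrics=metrics,
            note="" if proceed else "no combined metric exceeds 1; no refinement needed",
        ))
        if not proceed:
            continue

        pheno = next((p for p, parent in phenomenon_groups.items() if parent == group), None)
        if pheno is None or pheno not in phenomenon_exposures:
            trail.append(TierDecision(
                group=group, tier="phenomenon", proceed=False, trigger=trigger,
                note="refinement not possible: no common phenomenological effect identified",
            ))
            continue
        pmetrics = _tier_metrics(
            phenomenon_exposures[pheno], phenomenon_trvs[pheno], percentiles, B, seed, pheno)
        ptrigger = max(m.value for m in pmetrics)
        pproceed = ptrigger > 1.0
        trail.append(TierDecision(
            group=pheno, tier="phenomenon", proceed=pproceed, trigger=ptrigger,
            metrics=pmetrics,
            note="" if pproceed else "no combined metric exceeds 1; no refinement needed",
        ))
        if not pproceed:
            continue

        if pheno not in rpf_sets:
            trail.append(TierDecision(
                group=pheno, tier="rpf", proceed=False, trigger=ptrigger,
                note="RPF tier skipped: no common-endpoint dose-response pair available",
            ))
            continue
        rpfs = rpf_sets[pheno]
        members_with_rpf = {
            scen: {c: d for c, d in exp.items() if c == rpfs.reference or c in rpfs.rpfs}
            for scen, exp in phenomenon_exposures[pheno].items()
        }
        rmetrics = _tier_metrics(
            members_with_rpf, phenomenon_trvs[pheno], percentiles, B, seed, pheno,
            method="RPF_individual", rpfs=rpfs,
        )
        rtrigger = max(m.value for m in rmetrics if m.method == "RPF_individual")
        trail.append(TierDecision(
            group=pheno, tier="rpf", proceed=rtrigger > 1.0, trigger=rtrigger,
            metrics=rmetrics,
        ))
    return trail
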