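"""Hazard characterisation: assessment groups and toxicological reference values.

A toxicological reference value (TRV) anchors the risk characterisation of one
compound for one assessment group (a set of compounds sharing a target organ,
e.g. kidney, or a phenomenological effect, e.g. reduced white blood cell
count).  The TRV either *is* an existing health-based guidance value (HBGV,
e.g. a tolerable daily intake) when the group corresponds to the compound's
critical effect, or it is derived as a reference point (NOAEL, LOEL or BMDL)
divided by the product of assessment factors:

    TRV = RP / (AF_interspecies x AF_intraspecies x AF_duration x AF_LOEL x ...)

The default factor scheme is the EFSA-convention one: 10 for interspecies
differences (omitted for human studies), 10 for interindividual variability,
2 for subchronic-to-chronic extrapolation, 10 for a non-chronic clinical
study, 3 for LOEL-to-NOAEL extrapolation, plus optional extra factors such as
a 1.5 data-limitation factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RP_TYPES",
    "SPECIES",
    "DURATION_CLASSES",
    "Compound",
    "ReferencePoint",
    "AssessmentFactorSet",
    "ToxicologicalReferenceValue",
    "AssessmentGroup",
    "VocabularyError",
    "compose_assessment_factors",
    "derive_trv",
    "build_assessment_group",
    "round_sig",
    "builtin_reference_points",
    "builtin_trvs",
    "trvs_from_table",
]

RP_TYPES = frozenset({"NOAEL", "LOEL", "BMDL05", "BMDL10"})
SPECIES = frozenset({"rat", "mouse", "pig", "human"})
DURATION_CLASSES = frozenset({"chronic", "subchronic", "clinical_nonchronic"})

#: default assessment factors (EFSA conventions)
AF_INTERSPECIES = 10.0
AF_INTRASPECIES = 10.0
AF_SUBCHRONIC = 2.0
AF_CLINICAL_NONCHRONIC = 10.0
AF_LOEL_TO_NOAEL = 3.0


class VocabularyError(ValueError):
    """A value falls outside one of the closed vocabularies."""


def round_sig(x: float, digits: int = 2) -> float:
    """Round ``x`` to ``digits`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class Compound:
    """A chemical under assessment, identified by a short code such as ``NIV``."""

    id: str
    name: str = ""
    genotoxic: bool = False


@dataclass(frozen=True)
class ReferencePoint:
    """A point of departure for one compound in one assessment group.

    ``value`` is a dose in ug/kg bw/d.  ``duration_class`` captures the study
    duration relative to chronic exposure and drives the duration factor.
    """

    compound: str
    group: str
    value: float
    rp_type: str
    species: str
    duration_class: str
    effect: str = ""
    is_critical_effect: bool = False

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"reference point must be positive, got {self.value}")
        if self.rp_type not in RP_TYPES:
            raise VocabularyError(f"unknown rp_type {self.rp_type!r}")
        if self.species not in SPECIES:
            raise VocabularyError(f"unknown species {self.species!r}")
        if self.duration_class not in DURATION_CLASSES:
            raise VocabularyError(f"unknown duration_class {self.duration_class!r}")


@dataclass(frozen=True)
class AssessmentFactorSet:
    """The labelled assessment factors applied to one reference point.

    ``factors`` maps a label (``interspecies``, ``intraspecies``, ``duration``,
    ``loel_to_noael``, ``extra_1`` ...) to the applied factor; ``composed`` is
    their exact product.
    """

    factors: Mapping[str, float]
    composed: float = field(init=False)

    def __post_init__(self) -> None:
        for label, f in self.factors.items():
            if f < 1:
                raise ValueError(f"assessment factor {label}={f} must be >= 1")
        object.__setattr__(self, "composed", math.prod(self.factors.values()))


def compose_assessment_factors(
    rp_type: str,
    species: str,
    duration_class: str,
    extra_factors: Sequence[float] = (),
) -> AssessmentFactorSet:
    """Compose the default assessment factors for a reference point.

    Rules: 10x10 inter/intraspecies (no interspecies factor for a human
    study); duration factor 2 for subchronic, 10 for a non-chronic clinical
    study, none for chronic; 3 for LOEL-to-NOAEL extrapolation; ``extra_factors``
    (each >= 1) are appended verbatim, e.g. a 1.5 data-limitation factor.
    """
    if rp_type not in RP_TYPES:
        raise VocabularyError(f"unknown rp_type {rp_type!r}")
    if species not in SPECIES:
        raise VocabularyError(f"unknown species {species!r}")
    if duration_class not in DURATION_CLASSES:
        raise VocabularyError(f"unknown duration_class {duration_class!r}")

    factors: dict[str, float] = {}
    if species != "human":
        factors["interspecies"] = AF_INTERSPECIES
    factors["intraspecies"] = AF_INTRASPECIES
    if duration_class == "subchronic":
        factors["duration"] = AF_SUBCHRONIC
    elif duration_class == "clinical_nonchronic":
        factors["duration"] = AF_CLINICAL_NONCHRONIC
    if rp_type == "LOEL":
        factors["loel_to_noael"] = AF_LOEL_TO_NOAEL
    for k, f in enumerate(extra_factors, start=1):
        if f < 1:
            raise ValueError(f"extra factor {f} must be >= 1")
        factors[f"extra_{k}"] = float(f)
    return AssessmentFactorSet(factors=factors)


@dataclass(frozen=True)
class ToxicologicalReferenceValue:
    """A TRV in ug/kg bw/d for one compound in one assessment group.

    ``source`` records whether the value is an adopted HBGV or was derived as
    RP over composed AFs.  ``value`` keeps full precision; ``reported`` is the
    2-significant-figure display value.
    """

    compound: str
    group: str
    value: float
    source: str  # "hbgv" | "rp_over_af"
    rp: ReferencePoint | None = None
    afs: AssessmentFactorSet | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("TRV must be positive")
        if self.source not in ("hbgv", "rp_over_af"):
            raise ValueError(f"unknown TRV source {self.source!r}")

    @property
    def reported(self) -> float:
        return round_sig(self.value, 2)


def derive_trv(rp: ReferencePoint, afs: AssessmentFactorSet) -> ToxicologicalReferenceValue:
    """Derive a TRV as reference point over composed assessment factors."""
    if rp.value <= 0:
        raise ValueError("reference point must be positive")
    return ToxicologicalReferenceValue(
        compound=rp.compound,
        group=rp.group,
        value=rp.value / afs.composed,
        source="rp_over_af",
        rp=rp,
        afs=afs,
    )


@dataclass
class AssessmentGroup:
    """Compounds combined by common target organ or phenomenological effect.

    A phenomenon-level group refines an organ-level group and must be a
    subset of it; pass the parent group to validate the containment.
    """

    id: str
    level: str  # "organ" | "phenomenon"
    target: str
    members: frozenset[str]
    parent: str | None = None
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("organ", "phenomenon"):
            raise ValueError(f"unknown group level {self.level!r}")
        if not self.members:
            raise ValueError(f"assessment group {self.id!r} has no members: no assessment possible")
        self.members = frozenset(self.members)

    def validate_parent(self, parent: "AssessmentGroup") -> None:
        if not self.members <= parent.members:
            extra = sorted(self.members - parent.members)
            raise ValueError(
                f"phenomenon group {self.id!r} members {extra} not in parent {parent.id!r}"
            )


@dataclass(frozen=True)
class EvidenceRow:
    """One line of grouping evidence for a compound."""

    compound: str
    group: str
    has_effect_evidence: bool
    genotoxic: bool = False
    has_reference_point: bool = True


def build_assessment_group(
    evidence: Iterable[EvidenceRow | tuple],
    group_id: str | None = None,
    level: str = "organ",
    target: str = "",
    parent: str | None = None,
) -> AssessmentGroup:
    """Build an assessment group from effect-evidence rows.

    Members are the compounds with effect evidence, excluding genotoxic or
    carcinogenic compounds and compounds lacking any usable reference point;
    exclusions are recorded with a reason.  An empty resulting group raises,
    signalling that no assessment is possible.
    """
    rows = [r if isinstance(r, EvidenceRow) else EvidenceRow(*r) for r in evidence]
    if group_id is None:
        groups = {r.group for r in rows}
        if len(groups) != 1:
            raise ValueError(f"evidence spans several groups {sorted(groups)}; pass group_id")
        group_id = groups.pop()

    members: set[str] = set()
    excluded: dict[str, str] = {}
    for r in rows:
        if r.group != group_id:
            continue
        if not r.has_effect_evidence:
            continue
        if r.genotoxic:
            excluded[r.compound] = "carcinogenic/mutagenic"
        elif not r.has_reference_point:
            excluded[r.compound] = "no reference point available"
        else:
            members.add(r.compound)
    return AssessmentGroup(
        id=group_id, level=level, target=target or group_id,
        members=frozenset(members), parent=parent, excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Packaged reference-point table

_REQUIRED_COLUMNS = [
    "compound", "group", "rp_value_ug_per_kg_bw_d", "rp_type", "species",
    "duration_class", "extra_af", "is_critical", "hbgv_ug_per_kg_bw_d",
]


def builtin_reference_points() -> pd.DataFrame:
    """The packaged per-compound, per-group reference-point table."""
    with resources.files("mixtox.data").joinpath("reference_points.csv").open("r") as fh:
        df = pd.read_csv(fh)
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reference point table missing columns {sorted(missing)}")
    return df


def trvs_from_table(df: pd.DataFrame) -> dict[tuple[str, str], ToxicologicalReferenceValue]:
    """Derive a TRV for every (compound, group) row of a reference-point table.

    Precedence: if the row carries an HBGV and the group matches the
    compound's critical effect, the HBGV is adopted verbatim; otherwise the
    TRV is derived as RP over the composed assessment factors (with any extra
    factor the row opts into).
    """
    out: dict[tuple[str, str], ToxicologicalReferenceValue] = {}
    for _, row in df.iterrows():
        key = (row["compound"], row["group"])
        rp = ReferencePoint(
            compound=row["compound"],
            group=row["group"],
            value=float(row["rp_value_ug_per_kg_bw_d"]),
            rp_type=row["rp_type"],
            species=row["species"],
            duration_class=row["duration_class"],
            effect=str(row.get("effect", "")),
            is_critical_effect=bool(row["is_critical"]),
        )
        hbgv = row["hbgv_ug_per_kg_bw_d"]
        if pd.notna(hbgv) and bool(row["is_critical"]):
            out[key] = ToxicologicalReferenceValue(
                compound=rp.compound, group=rp.group, value=float(hbgv),
                source="hbgv", rp=rp,
            )
        else:
            extra = [] if pd.isna(row["extra_af"]) else [float(row["extra_af"])]
            afs = compose_assessment_factors(rp.rp_type, rp.species, rp.duration_class, extra)
            out[key] = derive_trv(rp, afs)
    return out


#: structural read-across: one TRV record stands for several congeners
#: (fumonisins B1-3 share a group guidance value; T2 and HT2 are assessed as
#: one compound record whose exposure columns are summed before risk)
READ_ACROSS: dict[str, tuple[str, ...]] = {"FB1": ("FB2", "FB3")}


def expand_read_across(
    trvs: Mapping[tuple[str, str], ToxicologicalReferenceValue],
    mapping: Mapping[str, tuple[str, ...]] | None = None,
) -> dict[tuple[str, str], ToxicologicalReferenceValue]:
    """Duplicate each TRV record onto its read-across congeners."""
    mapping = READ_ACROSS if mapping is None else mapping
    out = dict(trvs)
    for (compound, group), trv in list(trvs.items()):
        for target in mapping.get(compound, ()):
            out[(target, group)] = ToxicologicalReferenceValue(
                compound=target, group=group, value=trv.value,
                source=trv.source, rp=trv.rp, afs=trv.afs,
            )
    return out


def builtin_trvs(expand: bool = True) -> dict[tuple[str, str], ToxicologicalReferenceValue]:
    """TRVs for every (compound, group) in the packaged reference-point table.

    With ``expand=True`` (default) read-across congeners (FB2, FB3) receive
    copies of their source record's TRV.
    """
    trvs = trvs_from_table(builtin_reference_points())
    return expand_read_across(trvs) if expand else trvs
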