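"""Data model and I/O for a multi-institution snake neoplasia registry.

The registry joins two tables: a species census (the prevalence
denominator: every individual of a species housed at the participating
institutions, affected or not) and a case table (one row per snake with a
histologically confirmed neoplasm, carrying its tumors, treatment,
survival time and cause of death). Scientific names are the join key;
common names are display-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger("snakeonc")

FAMILIES = ("Boidae", "Colubridae", "Elapidae", "Pythonidae", "Viperidae")
SEXES = ("female", "male", "unknown")
MATURITIES = ("adult", "juvenile", "unknown")
BEHAVIORS = ("benign", "malignant", "unspecified")
METASTASIS = ("yes", "no", "unknown")
TREATMENTS = (
    "surgery_only",
    "chemotherapy",
    "surgery_and_chemotherapy",
    "supportive_care",
    "unknown",
    "none",
)
OUTCOMES = ("died_of_tumor", "died_other_cause", "unknown", "lost_to_followup")

#: outcomes that admit a case into the cause-of-death model
MODELABLE_OUTCOMES = ("died_of_tumor", "died_other_cause")


class SchemaError(ValueError):
    """A file does not match the documented column schema."""


class ValidationError(ValueError):
    """A record violates a registry invariant."""


# Grouping of free-text histologic diagnoses into the coarser controlled
# vocabulary used as the "tumor type" predictor. Keys are matched on the
# lower-cased diagnosis after stripping any parenthetical qualifier.
_TUMOR_TYPE_GROUPS = {
    "soft tissue sarcoma": "soft_tissue_sarcoma",
    "lymphoma/leukemia": "lymphoma_leukemia",
    "lymphoma": "lymphoma_leukemia",
    "leukemia": "lymphoma_leukemia",
    "chromatophoroma": "chromatophoroma",
    "malignant chromatophoroma": "chromatophoroma",
    "hepatocellular carcinoma": "hepatobiliary_tumor",
    "hepatobiliary carcinoma": "hepatobiliary_tumor",
    "hepatic adenocarcinoma": "hepatobiliary_tumor",
    "hepatic adenoma": "hepatobiliary_tumor",
    "hepatocellular adenoma": "hepatobiliary_tumor",
    "hepatic cystadenocarcinoma": "hepatobiliary_tumor",
    "cholangiocellular carcinoma": "hepatobiliary_tumor",
    "biliary adenocarcinoma": "hepatobiliary_tumor",
    "biliary cystadenoma": "hepatobiliary_tumor",
    "renal adenocarcinoma": "renal_tumor",
    "renal carcinoma": "renal_tumor",
    "renal adenoma": "renal_tumor",
    "renal cystadenoma": "renal_tumor",
    "squamous cell carcinoma": "squamous_cell_carcinoma",
    "gastrointestinal adenocarcinoma": "alimentary_tumor",
    "esophageal carcinoma": "alimentary_tumor",
    "colonic adenocarcinoma": "alimentary_tumor",
    "granulosa cell tumor": "gonadal_tumor",
    "sertoli cell tumor": "gonadal_tumor",
    "ovarian carcinoma": "gonadal_tumor",
    "oviduct adenocarcinoma": "gonadal_tumor",
    "pancreatic adenoma": "pancreatic_tumor",
    "pancreatic carcinoma": "pancreatic_tumor",
    "pancreatic adenocarcinoma": "pancreatic_tumor",
    "osteosarcoma": "bone_cartilage_tumor",
    "chondrosarcoma": "bone_cartilage_tumor",
    "hemangiosarcoma": "vascular_tumor",
    "neuroendocrine tumor": "neuroendocrine_tumor",
    "thyroid carcinoma": "endocrine_tumor",
    "histiocytic sarcoma": "hemolymphatic_tumor",
    "undifferentiated carcinoma": "undifferentiated_tumor",
    "undifferentiated adenocarcinoma": "undifferentiated_tumor",
    "lipoma": "lipoma",
}


def normalize_diagnosis(diagnosis: str) -> str:
    """Strip parenthetical qualifiers and case, e.g.
    ``"Malignant Chromatophoroma (Melanoma)"`` -> ``"malignant chromatophoroma"``."""
    base = diagnosis.split("(")[0].strip().lower()
    return base


def group_tumor_type(diagnosis: str) -> str:
    """Map a histologic diagnosis to its controlled tumor-type group."""
    base = normalize_diagnosis(diagnosis)
    try:
        return _TUMOR_TYPE_GROUPS[base]
    except KeyError:
        raise ValidationError(f"no tumor-type group for diagnosis {diagnosis!r}")


@dataclass(frozen=True)
class TumorEntry:
    diagnosis: str
    tumor_type: str
    behavior: str  # benign | malignant | unspecified

    @classmethod
    def from_diagnosis(cls, diagnosis: str, behavior: str) -> "TumorEntry":
        """Build an entry, grouping the diagnosis and enforcing that
        lymphomas/leukemias are malignant (multicentric by nature)."""
        if behavior not in BEHAVIORS:
            raise ValidationError(f"unknown behavior {behavior!r}")
        ttype = group_tumor_type(diagnosis)
        if ttype == "lymphoma_leukemia" and behavior != "malignant":
            log.info("coercing %r behavior %r -> malignant", diagnosis, behavior)
            behavior = "malignant"
        return cls(diagnosis=diagnosis, tumor_type=ttype, behavior=behavior)


@dataclass(frozen=True)
class SpeciesCensus:
    species: str
    common_name: str
    family: str
    total_individuals: int
    institution: str | None = None

    def __post_init__(self):
        if self.total_individuals < 0:
            raise ValidationError(
                f"{self.species}: total_individuals must be >= 0, "
                f"got {self.total_individuals}"
            )


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    species: str
    family: str
    sex: str = "unknown"
    age_months: int | None = None
    maturity: str = "unknown"
    tumors: tuple[TumorEntry, ...] = ()
    metastasis: str = "unknown"
    treatment: str = "unknown"
    radiation: bool = False
    supportive_care_adjunct: bool = False
    nsaid_short: bool = False
    survival_months: float | None = None
    outcome: str = "unknown"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"{self.case_id}: unknown sex {self.sex!r}")
        if self.maturity not in MATURITIES:
            raise ValidationError(f"{self.case_id}: unknown maturity {self.maturity!r}")
        if self.metastasis not in METASTASIS:
            raise ValidationError(
                f"{self.case_id}: unknown metastasis {self.metastasis!r}"
            )
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"{self.case_id}: unknown treatment {self.treatment!r}; "
                f"allowed: {', '.join(TREATMENTS)}"
            )
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"{self.case_id}: unknown outcome {self.outcome!r}")
        if not self.tumors:
            raise ValidationError(f"{self.case_id}: case must carry >= 1 tumor")
        if len(self.tumors) > 2:
            log.warning("%s: %d tumors (more than 2)", self.case_id, len(self.tumors))
        if self.survival_months is not None and self.survival_months <= 0:
            raise ValidationError(
                f"{self.case_id}: survival_months must be > 0, "
                f"got {self.survival_months}"
            )

    @property
    def n_tumor_types(self) -> int:
        """Number of observed tumor types, capped at 2 for modelling."""
        return min(len(self.tumors), 2)

    @property
    def eligible_for_outcome_model(self) -> bool:
        """Snakes without a known cause of death (or lost to follow-up)
        are excluded from outcome modelling."""
        return self.outcome in MODELABLE_OUTCOMES


@dataclass
class RegistryBundle:
    census: list[SpeciesCensus]
    cases: list[CaseRecord]
    provenance: str = "user"  # fixture | synthetic | user

    def census_by_species(self) -> dict[str, SpeciesCensus]:
        return {c.species: c for c in self.census}


# ---------------------------------------------------------------------------
# CSV I/O

_CENSUS_COLUMNS = ["species", "common_name", "family", "total_individuals"]
_CASE_COLUMNS = [
    "case_id", "species", "family", "sex", "age_months", "maturity",
    "metastasis", "treatment", "radiation", "supportive_adjunct",
    "nsaid_short", "survival_months", "outcome",
    "tumor1_diagnosis", "tumor1_type", "tumor1_behavior",
    "tumor2_diagnosis", "tumor2_type", "tumor2_behavior",
]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")


def load_census(path) -> list[SpeciesCensus]:
    """Read a census CSV (species, common_name, family, total_individuals
    [, institution]); duplicate species are rejected."""
    df = pd.read_csv(path)
    _require_columns(df, _CENSUS_COLUMNS, path)
    out: list[SpeciesCensus] = []
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        inst = row.get("institution")
        inst = None if pd.isna(inst) else str(inst)
        n = int(row["total_individuals"])
        if n < 0:
            raise ValidationError(
                f"{path} row {i + 2}: negative total_individuals ({n})"
            )
        key = (row["species"], inst)
        if key in seen:
            raise ValidationError(f"{path} row {i + 2}: duplicate species {key}")
        seen.add(key)
        out.append(
            SpeciesCensus(
                species=str(row["species"]),
                common_name=str(row["common_name"]),
                family=str(row["family"]),
                total_individuals=n,
                institution=inst,
            )
        )
    return out


def write_census(census: list[SpeciesCensus], path) -> None:
    rows = [
        {
            "species": c.species,
            "common_name": c.common_name,
            "family": c.family,
            "total_individuals": c.total_individuals,
            "institution": c.institution,
        }
        for c in census
    ]
    pd.DataFrame(rows, columns=_CENSUS_COLUMNS + ["institution"]).to_csv(
        path, index=False
    )


def _opt_float(v):
    return None if pd.isna(v) else float(v)


def _opt_int(v):
    return None if pd.isna(v) else int(v)


def load_cases(path) -> list[CaseRecord]:
    """Read a case CSV in the documented schema (up to two tumors wide)."""
    df = pd.read_csv(path)
    _require_columns(df, _CASE_COLUMNS[:13] + _CASE_COLUMNS[13:16], path)
    out: list[CaseRecord] = []
    for i, row in df.iterrows():
        tumors = []
        for k in (1, 2):
            diag = row.get(f"tumor{k}_diagnosis")
            if diag is None or pd.isna(diag):
                continue
            tumors.append(
                TumorEntry.from_diagnosis(str(diag), str(row[f"tumor{k}_behavior"]))
            )
        try:
            rec = CaseRecord(
                case_id=str(row["case_id"]),
                species=str(row["species"]),
                family=str(row["family"]),
                sex=str(row["sex"]),
                age_months=_opt_int(row["age_months"]),
                maturity=str(row["maturity"]),
                tumors=tuple(tumors),
                metastasis=str(row["metastasis"]),
                treatment=str(row["treatment"]),
                radiation=bool(row["radiation"]),
                supportive_care_adjunct=bool(row["supportive_adjunct"]),
                nsaid_short=bool(row["nsaid_short"]),
                survival_months=_opt_float(row["survival_months"]),
                outcome=str(row["outcome"]),
            )
        except ValidationError as err:
            raise ValidationError(f"{path} row {i + 2}: {err}") from err
        out.append(rec)
    return out


def write_cases(cases: list[CaseRecord], path) -> None:
    rows = []
    for c in cases:
        row = {
            "case_id": c.case_id,
            "species": c.species,
            "family": c.family,
            "sex": c.sex,
            "age_months": c.age_months,
            "maturity": c.maturity,
            "metastasis": c.metastasis,
            "treatment": c.treatment,
            "radiation": int(c.radiation),
            "supportive_adjunct": int(c.supportive_care_adjunct),
            "nsaid_short": int(c.nsaid_short),
            "survival_months": c.survival_months,
            "outcome": c.outcome,
        }
        for k, t in enumerate(c.tumors[:2], start=1):
            row[f"tumor{k}_diagnosis"] = t.diagnosis
            row[f"tumor{k}_type"] = t.tumor_type
            row[f"tumor{k}_behavior"] = t.behavior
        rows.append(row)
    pd.DataFrame(rows, columns=_CASE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation

def validate(bundle: RegistryBundle) -> list[str]:
    """Cross-check cases against the census; returns a list of violation
    messages (empty when the bundle is internally consistent)."""
    violations: list[str] = []
    census = bundle.census_by_species()
    counts: dict[str, int] = {}
    for case in bundle.cases:
        counts[case.species] = counts.get(case.species, 0) + 1
        sc = census.get(case.species)
        if sc is None:
            violations.append(f"{case.case_id}: species {case.species!r} not in census")
        elif sc.family != case.family:
            violations.append(
                f"{case.case_id}: family {case.family!r} does not match census "
                f"({sc.family!r})"
            )
    for species, n_cases in counts.items():
        sc = census.get(species)
        if sc is not None and n_cases > sc.total_individuals:
            violations.append(
                f"{species}: {n_cases} cases exceed census total "
                f"{sc.total_individuals}"
            )
    return violations


__all__ = [
    "SpeciesCensus", "TumorEntry", "CaseRecord", "RegistryBundle",
    "SchemaError", "ValidationError",
    "load_census", "load_cases", "write_census", "write_cases", "validate",
    "group_tumor_type", "normalize_diagnosis",
    "FAMILIES", "SEXES", "BEHAVIORS", "METASTASIS", "TREATMENTS", "OUTCOMES",
    "MODELABLE_OUTCOMES",
]
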