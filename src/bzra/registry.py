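"""Drug metadata registry: potency conversion, DDD values and approved indications.

Every benzodiazepine-receptor agonist (BZRA) handled by the pipeline is
described by a :class:`DrugSpec` carrying its ATC code, drug class
(benzodiazepine vs Z-drug), its conversion factor to diazepam milligram
equivalents (DME) and its WHO defined daily dose (DDD).  A companion
:class:`IndicationMap` lists, per drug, the ICD-10 stems of the approved
indications, used by the over-indication classifier.

The packaged default registry covers the twelve BZRAs dispensed in Chinese
psychiatric out-patient settings (eight benzodiazepines, four Z-drugs).  All
values are configuration, not logic: :func:`load_registry` merges a user YAML
file over the defaults and validates the result.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "DrugClass",
    "DrugSpec",
    "DMETable",
    "IndicationMap",
    "RegistryError",
    "load_registry",
    "save_registry",
]

#: syntactic shape of an ICD-10 stem: letter, digits, optional dot-suffix
_ICD10_STEM = re.compile(r"^[A-Z][0-9]{1,2}(\.[0-9A-Z]{1,4})?$")


class RegistryError(ValueError):
    """Raised for malformed or inconsistent registry configuration."""


class DrugClass(str, Enum):
    BZD = "BZD"
    Z_DRUG = "Z_DRUG"


@dataclass(frozen=True)
class DrugSpec:
    """Per-drug metadata.

    Parameters
    ----------
    drug_id : canonical lowercase generic name.
    atc_code : WHO ATC classification code.
    drug_class : benzodiazepine or Z-drug.
    dme_per_mg : diazepam milligram equivalents per mg of drug (> 0).
    ddd_mg : WHO defined daily dose in mg (> 0).
    """

    drug_id: str
    atc_code: str
    drug_class: DrugClass
    dme_per_mg: float
    ddd_mg: float

    def __post_init__(self) -> None:
        if not self.drug_id or self.drug_id != self.drug_id.lower():
            raise RegistryError(f"drug_id must be lowercase: {self.drug_id!r}")
        if not (isinstance(self.dme_per_mg, (int, float)) and math.isfinite(self.dme_per_mg) and self.dme_per_mg > 0):
            raise RegistryError(f"{self.drug_id}: dme_per_mg must be positive, got {self.dme_per_mg!r}")
        if not (isinstance(self.ddd_mg, (int, float)) and math.isfinite(self.ddd_mg) and self.ddd_mg > 0):
            raise RegistryError(f"{self.drug_id}: ddd_mg must be positive, got {self.ddd_mg!r}")


@dataclass
class DMETable:
    """Mapping drug → :class:`DrugSpec`, with a provenance note for the factors."""

    specs: dict[str, DrugSpec]
    provenance: str = ""

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.specs

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.specs)

    def spec(self, drug_id: str) -> DrugSpec:
        try:
            return self.specs[drug_id]
        except KeyError:
            raise RegistryError(
                f"unknown drug {drug_id!r}; known drugs: {', '.join(self.drug_ids)}"
            ) from None

    def drug_class(self, drug_id: str) -> DrugClass:
        return self.spec(drug_id).drug_class

    def to_dme(self, drug_id: str, dose_mg: float) -> float:
        """Convert a dose in mg of `drug_id` to diazepam milligram equivalents.

        Linear in dose: ``dose_mg * dme_per_mg``.
        """
        if dose_mg < 0:
            raise ValueError(f"dose_mg must be non-negative, got {dose_mg}")
        return dose_mg * self.spec(drug_id).dme_per_mg

    def to_ddd(self, drug_id: str, total_mg: float) -> float:
        """Express a cumulative amount in mg as a number of WHO defined daily doses."""
        if total_mg < 0:
            raise ValueError(f"total_mg must be non-negative, got {total_mg}")
        return total_mg / self.spec(drug_id).ddd_mg


@dataclass
class IndicationMap:
    """Per-drug approved-indication stems (ICD-10 prefixes).

    A diagnosis code *matches* a drug when it starts with any stem in the
    drug's entry (prefix semantics; stems are coarse blocks such as ``G47``).
    """

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.entries

    def stems(self, drug_id: str) -> frozenset[str]:
        try:
            return self.entries[drug_id]
        except KeyError:
            raise RegistryError(
                f"drug {drug_id!r} has no entry in the indication map"
            ) from None

    def matches(self, drug_id: str, diagnosis_code: str) -> bool:
        """True when `diagnosis_code` prefix-matches any approved stem of the drug."""
        code = diagnosis_code.strip().upper()
        return any(code.startswith(stem) for stem in self.stems(drug_id))


def _parse_drug(drug_id: str, entry: Mapping) -> DrugSpec:
    allowed = {"atc_code", "drug_class", "dme_per_mg", "ddd_mg"}
    unknown = set(entry) - allowed
    if unknown:
        raise RegistryError(f"{drug_id}: unknown field(s) {sorted(unknown)}")
    try:
        drug_class = DrugClass(entry["drug_class"])
    except (KeyError, ValueError):
        raise RegistryError(
            f"{drug_id}: drug_class must be one of {[c.value for c in DrugClass]}"
        ) from None
    return DrugSpec(
        drug_id=drug_id,
        atc_code=str(entry.get("atc_code", "")),
        drug_class=drug_class,
        dme_per_mg=float(entry["dme_per_mg"]),
        ddd_mg=float(entry["ddd_mg"]),
    )


def _validate_indications(raw: Mapping, table: DMETable) -> IndicationMap:
    entries: dict[str, frozenset[str]] = {}
    for drug_id, stems in raw.items():
        if drug_id not in table:
            raise RegistryError(f"indication entry for unknown drug {drug_id!r}")
        cleaned = []
        for stem in stems:
            stem = str(stem).strip().upper()
            if not _ICD10_STEM.match(stem):
                raise RegistryError(
                    f"{drug_id}: malformed ICD-10 stem {stem!r}"
                )
            cleaned.append(stem)
        entries[drug_id] = frozenset(cleaned)
    return IndicationMap(entries)


def _read_yaml(path: Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise RegistryError(f"registry config {path} is not a mapping")
    return doc


def load_registry(config_path: str | Path | None = None) -> tuple[DMETable, IndicationMap]:
    """Load the packaged default registry, optionally merged with a user config.

    A user YAML file may override or extend individual drugs (section
    ``drugs:``) and indication lists (section ``indications:``); overriding a
    drug replaces only the fields given.  Entries violating the
    :class:`DrugSpec` invariants are rejected with a :class:`RegistryError`
    naming the offending drug.
    """
    default_path = resources.files("bzra.data").joinpath("default_registry.yaml")
    doc = _read_yaml(Path(str(default_path)))
    drugs_raw: dict[str, dict] = {k: dict(v) for k, v in doc.get("drugs", {}).items()}
    indications_raw: dict[str, list] = {k: list(v) for k, v in doc.get("indications", {}).items()}
    provenance = str(doc.get("provenance", "")).strip()

    if config_path is not None:
        user = _read_yaml(Path(config_path))
        extra = set(user) - {"drugs", "indications", "provenance"}
        if extra:
            raise RegistryError(f"unknown top-level section(s) {sorted(extra)}")
        for drug_id, entry in (user.get("drugs") or {}).items():
            drug_id = str(drug_id).lower()
            merged = dict(drugs_raw.get(drug_id, {}))
            merged.update(entry)
            drugs_raw[drug_id] = merged
        for drug_id, stems in (user.get("indications") or {}).items():
            indications_raw[str(drug_id).lower()] = list(stems)
        if "provenance" in user:
            provenance = str(user["provenance"]).strip()

    specs = {d: _parse_drug(d, entry) for d, entry in drugs_raw.items()}
    table = DMETable(specs=specs, provenance=provenance)
    indications = _validate_indications(indications_raw, table)
    return table, indications


def save_registry(table: DMETable, indications: IndicationMap, path: str | Path) -> None:
    """Serialise a registry to the YAML layout accepted by :func:`load_registry`."""
    doc = {
        "provenance": table.provenance,
        "drugs": {
            spec.drug_id: {
                "atc_code": spec.atc_code,
                "drug_class": spec.drug_class.value,
                "dme_per_mg": spec.dme_per_mg,
                "ddd_mg": spec.ddd_mg,
            }
            for spec in (table.specs[d] for d in table.drug_ids)
        },
        "indications": {d: sorted(indications.entries[d]) for d in sorted(indications.entries)},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
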