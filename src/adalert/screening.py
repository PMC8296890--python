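"""Drug standardization, alert matching, amine classification and the dose rule.

Screening is 2D substructure matching: structures are desalted (largest
covalent fragment kept), stereochemistry is dropped, and each drug is tested
against every SMARTS alert. Aromatic amines are further classified by the
hydrogen count on nitrogens bonded to a benzene-ring carbon — two N-H
(primary), one N-H (secondary), none (tertiary) — because those variants
carry different autoimmune-risk associations. The daily-dose rule flags
drugs dosed at or above a cutoff (100 mg/day by default), the co-factor
that sharpens alert specificity.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .alerts import AlertLibrary, AlertPattern
from .errors import ConfigError, DataError, FormatError, StructureError

logger = logging.getLogger(__name__)


class ADLabel(Enum):
    """Autoimmune-disease association status of a drug."""

    AD_POSITIVE = 1
    AD_NEGATIVE = 0

    @classmethod
    def parse(cls, value: object) -> "ADLabel":
        text = str(value).strip().lower()
        if text in {"1", "pos", "positive", "ad_positive", "true"}:
            return cls.AD_POSITIVE
        if text in {"0", "neg", "negative", "ad_negative", "false"}:
            return cls.AD_NEGATIVE
        raise FormatError(f"unrecognized AD label {value!r}")


@dataclass
class DrugRecord:
    """One drug: identity, structure, daily dose and AD label.

    ``daily_dose_mg`` is the labeled adult daily dose in mg/day and may be
    missing (``None``); when present it must be non-negative.
    """

    drug_id: str
    name: str
    smiles: str
    daily_dose_mg: float | None
    label: ADLabel

    def __post_init__(self) -> None:
        if self.daily_dose_mg is not None and self.daily_dose_mg < 0:
            raise FormatError(
                f"drug {self.drug_id!r}: daily_dose_mg must be >= 0, got {self.daily_dose_mg}"
            )


@dataclass(frozen=True)
class DoseRule:
    """Inclusive high-dose threshold in mg/day (default >= 100 mg)."""

    cutoff_mg: float = 100.0

    def __post_init__(self) -> None:
        if self.cutoff_mg <= 0:
            raise ConfigError(f"cutoff_mg must be positive, got {self.cutoff_mg}")


@dataclass
class AlertMatchMatrix:
    """Boolean drugs x alerts match matrix with exclusion report.

    ``matches[i, j]`` is True iff drug ``drug_ids[i]`` contains the
    substructure of alert ``alert_ids[j]``. Drugs whose SMILES failed to
    parse are listed in ``excluded`` as ``(drug_id, reason)`` pairs and do
    not appear in the matrix.
    """

    drug_ids: list[str]
    alert_ids: list[str]
    matches: np.ndarray
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matches = np.asarray(self.matches, dtype=bool)
        if self.matches.shape != (len(self.drug_ids), len(self.alert_ids)):
            raise DataError(
                f"match matrix shape {self.matches.shape} does not fit "
                f"{len(self.drug_ids)} drugs x {len(self.alert_ids)} alerts"
            )

    def column(self, alert_id: str) -> np.ndarray:
        return self.matches[:, self.alert_ids.index(alert_id)]

    def to_frame(self) -> pd.DataFrame:
        """Wide 0/1 DataFrame indexed by drug_id."""
        return pd.DataFrame(
            self.matches.astype(int), index=self.drug_ids, columns=self.alert_ids
        )


class AromaticAmineClass(Enum):
    """Substitution class of a nitrogen bonded to a benzene-ring carbon."""

    TWO_NH = "two N-H (primary)"
    ONE_NH = "one N-H (secondary)"
    NO_NH = "no N-H (tertiary)"
    NONE = "no aromatic amine"


@dataclass(frozen=True)
class AmineClassification:
    """Per-nitrogen classes plus per-molecule flags.

    ``per_nitrogen`` lists the class of each benzene-bonded nitrogen in
    atom-index order; ``classes`` is the set of classes present in the
    molecule ({NONE} when there is no such nitrogen). A molecule with both
    a secondary and a tertiary aromatic amine is flagged for both classes.
    """

    per_nitrogen: tuple[AromaticAmineClass, ...]

    @property
    def classes(self) -> frozenset[AromaticAmineClass]:
        if not self.per_nitrogen:
            return frozenset({AromaticAmineClass.NONE})
        return frozenset(self.per_nitrogen)

    def __contains__(self, cls: AromaticAmineClass) -> bool:
        return cls in self.classes


def _parse_mol(smiles: str, drug_id: str | None = None) -> Chem.Mol:
    if not smiles or not smiles.strip():
        raise StructureError("empty SMILES", drug_id)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES {smiles!r}", drug_id)
    return mol


def standardize_structure(smiles: str, drug_id: str | None = None) -> str:
    """Canonical SMILES of the largest covalent fragment, stereochemistry dropped.

    Salt and counter-ion components are stripped by keeping the fragment
    with the greatest molecular weight (ties broken by heavy-atom count).
    The operation is idempotent: standardizing the output returns it
    unchanged.
    """
    mol = _parse_mol(smiles, drug_id)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda f: (Descriptors.MolWt(f), f.GetNumHeavyAtoms()))
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def match_alert(smiles: str, alert: AlertPattern) -> bool:
    """True iff the (standardized) structure contains the alert substructure."""
    mol = _parse_mol(standardize_structure(smiles))
    return mol.HasSubstructMatch(alert.query)


def screen_library(
    drugs: Sequence[DrugRecord], library: AlertLibrary
) -> AlertMatchMatrix:
    """Match every drug against every alert in the library.

    Drugs whose SMILES cannot be parsed are excluded from the matrix and
    reported (logged and listed in ``AlertMatchMatrix.excluded``) so that a
    single bad record does not abort a batch screen.
    """
    if len(library) == 0:
        raise DataError("cannot screen against an empty alert library")
    kept_ids: list[str] = []
    rows: list[list[bool]] = []
    excluded: list[tuple[str, str]] = []
    queries = [(alert.alert_id, alert.query) for alert in library]
    for drug in drugs:
        try:
            mol = _parse_mol(standardize_structure(drug.smiles, drug.drug_id), drug.drug_id)
        except StructureError as err:
            logger.warning("excluding drug %s: %s", drug.drug_id, err)
            excluded.append((drug.drug_id, str(err)))
            continue
        rows.append([mol.HasSubstructMatch(q) for _, q in queries])
        kept_ids.append(drug.drug_id)
    matrix = np.array(rows, dtype=bool) if rows else np.zeros((0, len(queries)), dtype=bool)
    return AlertMatchMatrix(
        drug_ids=kept_ids,
        alert_ids=[aid for aid, _ in queries],
        matches=matrix,
        excluded=excluded,
    )


_BENZENE_QUERY = Chem.MolFromSmarts("c1ccccc1")


def classify_aromatic_amine(smiles: str) -> AmineClassification:
    """Classify each benzene-bonded nitrogen by its total hydrogen count.

    Hydrogens are counted as implicit + explicit on the nitrogen. Only
    nitrogens directly bonded to a carbon of a six-membered aromatic
    carbocycle (benzene ring) count; a molecule without one classifies as
    ``NONE``.
    """
    mol = _parse_mol(standardize_structure(smiles))
    benzene_carbons = {idx for match in mol.GetSubstructMatches(_BENZENE_QUERY) for idx in match}
    classes: list[AromaticAmineClass] = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 7:
            continue
        if not any(nb.GetIdx() in benzene_carbons for nb in atom.GetNeighbors()):
            continue
        h = atom.GetTotalNumHs()
        if h >= 2:
            classes.append(AromaticAmineClass.TWO_NH)
        elif h == 1:
            classes.append(AromaticAmineClass.ONE_NH)
        else:
            classes.append(AromaticAmineClass.NO_NH)
    return AmineClassification(per_nitrogen=tuple(classes))


def high_dose_flag(dose_mg: float, rule: DoseRule = DoseRule()) -> bool:
    """True iff the daily dose meets the cutoff (inclusive: 100 mg >= 100 mg)."""
    if dose_mg is None:
        raise DataError("dose is missing; use dose_flags() with a missing-dose policy")
    return dose_mg >= rule.cutoff_mg


def dose_flags(
    drugs: Sequence[DrugRecord],
    rule: DoseRule = DoseRule(),
    missing: str = "exclude",
) -> tuple[list[str], np.ndarray, list[str]]:
    """Vector of high-dose flags with a policy for missing doses.

    ``missing='exclude'`` (default) drops drugs without a dose and reports
    them; ``'false'`` treats a missing dose as below-cutoff; ``'error'``
    raises. Returns ``(drug_ids, flags, excluded_ids)``.
    """
    if missing not in {"exclude", "false", "error"}:
        raise ConfigError(f"unknown missing-dose policy {missing!r}")
    ids: list[str] = []
    flags: list[bool] = []
    dropped: list[str] = []
    for drug in drugs:
        if drug.daily_dose_mg is None:
            if missing == "error":
                raise DataError(f"drug {drug.drug_id!r} has no daily dose")
            if missing == "exclude":
                dropped.append(drug.drug_id)
                continue
            flags.append(False)
        else:
            flags.append(high_dose_flag(drug.daily_dose_mg, rule))
        ids.append(drug.drug_id)
    if dropped:
        logger.warning("%d drug(s) excluded for missing dose: %s", len(dropped), dropped)
    return ids, np.asarray(flags, dtype=bool), dropped


def load_drugs(path: str | Path) -> list[DrugRecord]:
    """Read drugs from CSV with columns drug_id,name,smiles,daily_dose_mg,label."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        required = ("drug_id", "smiles", "label")
        if reader.fieldnames is None or any(c not in reader.fieldnames for c in required):
            raise FormatError(f"{path}: drug CSV needs columns {required}")
        drugs: list[DrugRecord] = []
        for row in reader:
            dose_raw = (row.get("daily_dose_mg") or "").strip()
            drugs.append(
                DrugRecord(
                    drug_id=row["drug_id"],
                    name=row.get("name") or row["drug_id"],
                    smiles=row["smiles"],
                    daily_dose_mg=float(dose_raw) if dose_raw else None,
                    label=ADLabel.parse(row["label"]),
                )
            )
    return drugs


def load_drugs_sdf(path: str | Path, doses: dict[str, float] | None = None,
                   labels: dict[str, ADLabel] | None = None) -> list[DrugRecord]:
    """Read structures from an SDF file, mapping the molecule title to drug_id.

    Dose and label annotations, when not embedded as SD properties
    ``daily_dose_mg`` / ``label``, can be supplied via the mappings.
    """
    drugs: list[DrugRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("%s: skipping unreadable SDF record %d", path, i)
            continue
        drug_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_{i}"
        if mol.HasProp("daily_dose_mg"):
            dose: float | None = float(mol.GetProp("daily_dose_mg"))
        else:
            dose = (doses or {}).get(drug_id)
        if mol.HasProp("label"):
            label = ADLabel.parse(mol.GetProp("label"))
        elif labels and drug_id in labels:
            label = labels[drug_id]
        else:
            raise FormatError(f"{path}: no AD label for SDF record {drug_id!r}")
        drugs.append(
            DrugRecord(
                drug_id=drug_id,
                name=drug_id,
                smiles=Chem.MolToSmiles(mol),
                daily_dose_mg=dose,
                label=label,
            )
        )
    return drugs


def write_drugs(drugs: Iterable[DrugRecord], path: str | Path) -> None:
    """Write drugs to the CSV layout accepted by :func:`load_drugs`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["drug_id", "name", "smiles", "daily_dose_mg", "label"])
        for d in drugs:
            writer.writerow(
                [
                    d.drug_id,
                    d.name,
                    d.smiles,
                    "" if d.daily_dose_mg is None else f"{d.daily_dose_mg:g}",
                    d.label.name,
                ]
            )
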