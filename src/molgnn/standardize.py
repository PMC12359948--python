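"""SMILES screening and standardisation.

Every input compound is pushed through a fixed pipeline before any 3D or
graph work happens:

    parse -> element screen -> normalise -> parent fragment -> tautomer

The element screen keeps only molecules built from the ten elements common in
stable drug-like organic chemistry (H, C, N, O, F, P, S, Cl, Br, I).
Normalisation removes explicit hydrogens, disconnects covalent metal bonds and
neutralises ionic charges; the parent molecule is the largest fragment of a
multi-fragment (salt/solvate) record; tautomer canonicalisation maps every
tautomeric form of a compound onto one representative so that e.g. both
enol and keto inputs of the same drug yield one SMILES.

Failures never raise out of :func:`standardize_record`: each record yields a
:class:`StandardizationOutcome` carrying the stage that failed and a message,
so a whole dataset can be processed with full rejection accounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from molgnn.records import CompoundRecord, write_compound_csv

RDLogger.DisableLog("rdApp.*")

#: Elements retained by the screen (atomic symbols).
ALLOWED_ELEMENTS = frozenset({"H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"})

Stage = Literal["parse", "element_screen", "normalize", "parent", "tautomer", "none"]


@dataclass(frozen=True)
class StandardizationOutcome:
    record: CompoundRecord
    status: Literal["accepted", "rejected"]
    stage_failed: Stage
    message: str
    standardized_smiles: str | None

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def parse_smiles(smiles: str) -> Chem.Mol | None:
    """Parse a SMILES string; None on failure (invalid syntax or valence)."""
    return Chem.MolFromSmiles(smiles)


def screen_elements(mol: Chem.Mol) -> tuple[bool, frozenset[str]]:
    """Check that every atom is one of the ten allowed elements.

    Returns ``(accepted, offending)`` where ``offending`` is the set of
    disallowed element symbols found (empty when accepted). Rejection is a
    result, not an error.
    """
    offending = frozenset(
        a.GetSymbol() for a in mol.GetAtoms() if a.GetSymbol() not in ALLOWED_ELEMENTS
    )
    return (len(offending) == 0, offending)


_NORMALIZER = rdMolStandardize.Normalizer()
_METAL_DISCONNECTOR = rdMolStandardize.MetalDisconnector()
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()


def normalize_molecule(mol: Chem.Mol) -> Chem.Mol:
    """Normalise: drop explicit hydrogens, disconnect metals, neutralise charges.

    Idempotent; net-neutral charge-separated groups (e.g. nitro) are left
    intact by the neutraliser.
    """
    mol = Chem.RemoveHs(mol)
    mol = _NORMALIZER.normalize(mol)
    mol = _METAL_DISCONNECTOR.Disconnect(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.SanitizeMol(mol)
    return mol


def select_parent_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Return the largest fragment by heavy-atom count.

    Ties are broken by the lexicographically smallest canonical SMILES, which
    is deterministic and invariant to input atom ordering.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 0:
        raise ValueError("empty molecule has no fragments")
    return min(frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def canonicalize_tautomer(mol: Chem.Mol) -> Chem.Mol:
    """Map a molecule to its canonical tautomeric form (deterministic)."""
    return _TAUTOMER_ENUMERATOR.Canonicalize(mol)


def standardize_record(
    record: CompoundRecord, *, screen_after_parent: bool = False
) -> StandardizationOutcome:
    """Run the full standardisation pipeline on one record.

    Stages run in order parse -> element_screen -> normalize -> parent ->
    tautomer; the first failing stage is recorded and later stages are
    skipped. With ``screen_after_parent`` the element screen moves after
    parent-fragment selection, so metal counterions of salts are stripped
    rather than causing whole-record rejection (off by default: the default
    ordering screens the record as submitted).
    """

    def reject(stage: Stage, message: str) -> StandardizationOutcome:
        return StandardizationOutcome(record, "rejected", stage, message, None)

    mol = parse_smiles(record.smiles)
    if mol is None:
        return reject("parse", f"could not parse SMILES {record.smiles!r}")

    def screen(m: Chem.Mol) -> StandardizationOutcome | None:
        ok, offending = screen_elements(m)
        if not ok:
            return reject(
                "element_screen",
                "disallowed elements: " + ", ".join(sorted(offending)),
            )
        return None

    if not screen_after_parent:
        failure = screen(mol)
        if failure is not None:
            return failure

    try:
        mol = normalize_molecule(mol)
    except Exception as exc:  # RDKit raises a zoo of exception types
        return reject("normalize", f"normalisation failed: {exc}")

    try:
        mol = select_parent_fragment(mol)
        # a parent split off from a salt may carry the charge its counterion
        # balanced; neutralise again on the isolated fragment
        mol = _UNCHARGER.uncharge(mol)
    except Exception as exc:
        return reject("parent", f"parent selection failed: {exc}")

    if screen_after_parent:
        failure = screen(mol)
        if failure is not None:
            return failure

    try:
        mol = canonicalize_tautomer(mol)
    except Exception as exc:
        return reject("tautomer", f"tautomer canonicalisation failed: {exc}")

    return StandardizationOutcome(
        record, "accepted", "none", "", Chem.MolToSmiles(mol)
    )


def standardize_dataset(
    records: Iterable[CompoundRecord], *, screen_after_parent: bool = False
) -> list[StandardizationOutcome]:
    """Standardise every record, preserving order; nothing raises per record."""
    return [
        standardize_record(r, screen_after_parent=screen_after_parent)
        for r in records
    ]


def write_standardization_outputs(
    outcomes: Sequence[StandardizationOutcome],
    accepted_path: str | Path,
    rejects_path: str | Path,
) -> None:
    """Write the accepted table (with standardized_smiles) and the rejects sidecar."""
    accepted = [o for o in outcomes if o.accepted]
    rejected = [o for o in outcomes if not o.accepted]
    write_compound_csv(
        [o.record for o in accepted],
        accepted_path,
        extra_columns={"standardized_smiles": [o.standardized_smiles for o in accepted]},
    )
    import pandas as pd

    pd.DataFrame(
        {
            "name": [o.record.name for o in rejected],
            "smiles": [o.record.smiles for o in rejected],
            "stage_failed": [o.stage_failed for o in rejected],
            "message": [o.message for o in rejected],
        }
    ).to_csv(rejects_path, index=False, encoding="utf-8")
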