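"""Bundled toy molecules and synthetic labelled-dataset generators.

Two generators make every stage of the pipeline testable without external
downloads:

* ``substructure`` — drug-like molecules assembled from fragment templates
  over the ten allowed elements; the positive class carries a planted
  substructure (a nitro group by default). Composition from templates, not
  random SMILES mutation, guarantees chemical validity.
* ``charge`` — molecules drawn from template pairs that share one heavy-atom
  skeleton and differ only in the order of a single carbon-oxygen bond
  (ketone C=O versus secondary alcohol C-OH); the label is whether the
  molecule's maximum Gasteiger partial charge exceeds a threshold tau, which
  cleanly separates the two groups. Within a pair the atomic numbers and the
  adjacency structure are identical, and the basic-schema convolutions --
  whose update equations consume node features and connectivity but no edge
  features -- cannot tell the classes apart, while the custom schema carries
  the charge (and hydrogen-count/valence) node features that make the task
  immediate. This builds the custom-versus-basic feature contrast into the
  data itself.

Labels are the planted signal XOR an optional noise flip; everything is
reproducible from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from typing import Literal

import numpy as np
from rdkit import Chem

from molgnn.featurize import compute_gasteiger_charges
from molgnn.records import CompoundRecord

#: Default planted substructure: the nitro group.
NITRO_SMARTS = "[N+](=O)[O-]"

#: Default charge threshold between carbonyl carbons (max Gasteiger charge
#: about 0.126-0.136 over alkyl skeletons) and alcohol carbons (0.048-0.057).
DEFAULT_CHARGE_TAU = 0.09


@dataclass(frozen=True)
class SyntheticSpec:
    n_molecules: int
    signal: Literal["substructure", "charge"] = "substructure"
    pattern: str = NITRO_SMARTS
    tau: float = DEFAULT_CHARGE_TAU
    label_noise: float = 0.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 20:
            raise ValueError("n_molecules must be >= 20")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must be in (0, 1)")

    def to_json(self) -> str:
        from dataclasses import asdict

        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        return cls(**json.loads(text))


def toy_library() -> list[CompoundRecord]:
    """A fixed curated library exercising every standardisation branch.

    Contains common drugs, simple organics, a zwitterion, hydrochloride
    salts, one unparseable string and one arsenic- plus one boron-containing
    record (both rejected by the element screen); the rest pass the full
    pipeline. Labels are arbitrary but balanced.
    """
    entries = [
        ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
        ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
        ("warfarin_enol_tautomer", "CC(=O)CC(c1ccccc1)C1=C(O)c2ccccc2OC1=O"),
        ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
        ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
        ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
        ("nicotine", "CN1CCC[C@H]1c1cccnc1"),
        ("benzoic_acid", "OC(=O)c1ccccc1"),
        ("salicylic_acid", "OC(=O)c1ccccc1O"),
        ("benzene", "c1ccccc1"),
        ("toluene", "Cc1ccccc1"),
        ("ethanol", "CCO"),
        ("acetone", "CC(C)=O"),
        ("propen-2-ol", "CC(O)=C"),
        ("acetic_acid", "CC(=O)O"),
        ("glycine_zwitterion", "[NH3+]CC(=O)[O-]"),
        ("alanine_zwitterion", "C[C@@H]([NH3+])C(=O)[O-]"),
        ("ethylamine_hydrochloride", "CCN.Cl"),
        ("aniline_hydrochloride", "Nc1ccccc1.Cl"),
        ("acetic_acid_hydrate", "CC(=O)O.O"),
        ("nitrobenzene", "O=[N+]([O-])c1ccccc1"),
        ("chlorobenzene", "Clc1ccccc1"),
        ("bromoethane", "CCBr"),
        ("iodomethane", "CI"),
        ("dimethyl_sulfoxide", "CS(=O)C"),
        ("trimethyl_phosphate", "COP(=O)(OC)OC"),
        ("pyridine", "c1ccncc1"),
        ("furan", "c1ccoc1"),
        ("acetarsol_like_arsenical", "Oc1ccc(cc1)[As](=O)(O)O"),
        ("phenylboronic_acid", "OB(O)c1ccccc1"),
        ("unclosed_ring", "C1CC"),
    ]
    return [
        CompoundRecord(compound_id=f"toy{i:02d}", name=name, smiles=smi, label=i % 2)
        for i, (name, smi) in enumerate(entries)
    ]


# --- substructure generator -------------------------------------------------

_SCAFFOLDS = (
    "c1ccc({0})cc1",
    "c1ccc({0})c({1})c1",
    "c1cc({0})ccc1{1}",
    "c1cc({0})cnc1",
    "C1CCC({0})CC1",
    "CC({0})CC{1}",
    "CCC({0})C",
)

_SUBSTITUENTS = (
    "C",
    "CC",
    "CCC",
    "O",
    "OC",
    "F",
    "Cl",
    "Br",
    "N",
    "NC",
    "C#N",
    "C(=O)C",
    "C(=O)OC",
    "SC",
    "CO",
)


def _assemble_substructure_molecule(
    rng: np.random.Generator, positive: bool, pattern: str
) -> str:
    """One valid SMILES from a scaffold template; positives carry the pattern."""
    query = Chem.MolFromSmarts(pattern)
    for _ in range(100):
        scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
        n_slots = scaffold.count("{")
        subs = [str(_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]) for _ in range(n_slots)]
        if positive:
            subs[rng.integers(n_slots)] = "[N+](=O)[O-]"
        smiles = scaffold.format(*subs)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        if mol.HasSubstructMatch(query) != positive:
            continue
        return Chem.MolToSmiles(mol)
    raise RuntimeError("could not assemble a valid molecule after bounded retries")


# --- charge-threshold generator ---------------------------------------------

# Skeleton-sharing pairs: each entry is ("{a}C(=O){b}", "{a}C(O){b}") for one
# pair of alkyl flanks, i.e. a ketone and the secondary alcohol on the same
# heavy-atom skeleton. Ring skeletons are included.
_CHARGE_ALKYLS = ("C", "CC", "CCC", "CC(C)", "CCCC", "CC(C)C", "CCC(C)")
_CHARGE_PAIRS = tuple(
    (f"{a}C(=O){b}", f"{a}C(O){b}")
    for a in _CHARGE_ALKYLS
    for b in _CHARGE_ALKYLS
) + (("O=C1CCCCC1", "OC1CCCCC1"), ("O=C1CCCC1", "OC1CCCC1"))


def charge_pair_templates() -> tuple[tuple[str, str], ...]:
    """The (high-charge, low-charge) skeleton-sharing template pairs."""
    return _CHARGE_PAIRS


def max_gasteiger_charge(smiles: str) -> float:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"bad SMILES {smiles!r}")
    return float(np.max(compute_gasteiger_charges(mol)))


def generate_synthetic_dataset(spec: SyntheticSpec) -> list[CompoundRecord]:
    """Generate a labelled synthetic dataset per the spec.

    The intended class of each molecule is drawn to match ``class_balance``;
    the pre-noise label is the *actual* planted signal evaluated on the
    assembled molecule (substructure match, or max Gasteiger charge > tau),
    then flipped with probability ``label_noise``. Raises if the realised
    class balance drifts more than 10 percentage points from the target
    after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_molecules * spec.class_balance))
    want_positive = np.zeros(spec.n_molecules, dtype=bool)
    want_positive[:n_pos] = True
    rng.shuffle(want_positive)

    records = []
    n_signal_pos = 0
    for k in range(spec.n_molecules):
        if spec.signal == "substructure":
            smiles = _assemble_substructure_molecule(
                rng, bool(want_positive[k]), spec.pattern
            )
            signal = Chem.MolFromSmiles(smiles).HasSubstructMatch(
                Chem.MolFromSmarts(spec.pattern)
            )
        else:
            pair = _CHARGE_PAIRS[rng.integers(len(_CHARGE_PAIRS))]
            smiles = pair[0] if want_positive[k] else pair[1]
            signal = max_gasteiger_charge(smiles) > spec.tau
        label = int(signal)
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            label = 1 - label
        n_signal_pos += int(signal)
        records.append(
            CompoundRecord(
                compound_id=f"syn{k:04d}",
                name=f"synthetic_{spec.signal}_{k}",
                smiles=smiles,
                label=label,
            )
        )
    realized = n_signal_pos / spec.n_molecules
    if abs(realized - spec.class_balance) > 0.10:
        raise RuntimeError(
            f"class balance {realized:.2f} drifted from target {spec.class_balance:.2f}"
        )
    return records
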