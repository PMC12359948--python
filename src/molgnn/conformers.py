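"""3D conformer generation, force-field optimisation and bond-length analysis.

A standardised molecule gets explicit hydrogens, a distance-geometry embedding
from random coordinates (up to a configurable attempt budget, 5000 by
default) and an MMFF94 relaxation that minimises the molecular energy. Bond
lengths measured on the embedded and on the relaxed geometry feed the
percent-change statistics used to audit how much the force field moves the
initial geometry; a paired t-test compares matched samples of such changes.

Embedding and minimisation are delegated to RDKit; what this module owns is
the retry/seed policy, failure logging, measurement and statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy import stats as _sstats


@dataclass
class Conformer3D:
    """An embedded (not yet optimised) conformation with explicit hydrogens."""

    atom_elements: list[str]
    coords: np.ndarray  # (n, 3), Angstrom
    attempts_used: int
    embedded: bool
    seed: int


@dataclass
class OptimizedConformer:
    coords: np.ndarray  # (n, 3), Angstrom
    converged: bool
    energy_before: float  # kcal/mol
    energy_after: float


@dataclass
class BondChangeStats:
    """Summary of absolute percent bond-length changes for one sample of bonds."""

    per_bond_change: np.ndarray  # percent, >= 0
    mean: float
    median: float
    std: float
    min: float
    max: float


@dataclass
class PairedTTestResult:
    t_stat: float
    p_value: float
    n_pairs: int


def add_hydrogens(mol: Chem.Mol) -> Chem.Mol:
    """Explicit-hydrogen copy; heavy-atom indices are preserved (Hs appended)."""
    return Chem.AddHs(mol)


def embed_conformer(
    mol: Chem.Mol, max_attempts: int = 5000, seed: int = 0
) -> Conformer3D:
    """Embed one 3D conformer by distance geometry from random coordinates.

    ``mol`` must already carry explicit hydrogens (see :func:`add_hydrogens`).
    Attempts are issued one at a time with per-attempt seeds derived from
    ``seed`` so the number actually consumed is observable; exhaustion yields
    ``embedded=False`` rather than an exception, so failures can be logged
    alongside the successes.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    work = Chem.Mol(mol)
    if work.GetNumAtoms() == 0:
        return Conformer3D(elements, np.zeros((0, 3)), 1, False, seed)
    for attempt in range(1, max_attempts + 1):
        # keep derived seeds in int32 range; 0 would mean "nondeterministic"
        attempt_seed = (seed * 7919 + attempt) % (2**31 - 1) + 1
        try:
            cid = AllChem.EmbedMolecule(work, maxAttempts=1, randomSeed=attempt_seed)
        except ValueError:
            return Conformer3D(elements, np.zeros((len(elements), 3)), attempt, False, seed)
        if cid >= 0:
            coords = np.array(work.GetConformer(cid).GetPositions(), dtype=float)
            return Conformer3D(elements, coords, attempt, True, seed)
    return Conformer3D(elements, np.zeros((len(elements), 3)), max_attempts, False, seed)


def mmff_optimize(
    mol: Chem.Mol, conformer: Conformer3D, max_iterations: int = 2000
) -> OptimizedConformer:
    """Relax an embedded conformer with MMFF94, returning energies before/after.

    Raises ``ValueError`` if the conformer is not embedded or MMFF parameters
    cannot be assigned (e.g. unusual valence states).
    """
    if not conformer.embedded:
        raise ValueError("cannot optimise a conformer that failed to embed")
    work = Chem.Mol(mol)
    conf = Chem.Conformer(work.GetNumAtoms())
    for i, xyz in enumerate(conformer.coords):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    work.RemoveAllConformers()
    cid = work.AddConformer(conf, assignId=True)
    props = AllChem.MMFFGetMoleculeProperties(work)
    if props is None:
        raise ValueError("MMFF parameters unavailable for molecule")
    ff = AllChem.MMFFGetMoleculeForceField(work, props, confId=cid)
    if ff is None:
        raise ValueError("MMFF force field setup failed")
    energy_before = float(ff.CalcEnergy())
    status = ff.Minimize(maxIts=max_iterations)
    energy_after = float(ff.CalcEnergy())
    coords = np.array(work.GetConformer(cid).GetPositions(), dtype=float)
    return OptimizedConformer(coords, status == 0, energy_before, energy_after)


def measure_bond_lengths(
    coords: np.ndarray, bonds: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Euclidean distances (Angstrom) between bonded atom pairs."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    for i, j in bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"bond ({i}, {j}) out of range for {n} atoms")
    if len(bonds) == 0:
        return np.zeros(0)
    idx = np.asarray(bonds, dtype=int)
    return np.linalg.norm(coords[idx[:, 0]] - coords[idx[:, 1]], axis=1)


def heavy_atom_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    """Index pairs of bonds between two heavy atoms, in RDKit bond order."""
    return [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        for b in mol.GetBonds()
        if b.GetBeginAtom().GetAtomicNum() > 1 and b.GetEndAtom().GetAtomicNum() > 1
    ]


def bond_change_statistics(
    before: Sequence[float], after: Sequence[float]
) -> BondChangeStats:
    """Absolute percent change per bond, 100*|after-before|/before, with summary.

    Signed changes can be recovered by the caller; only magnitudes are
    summarised here. Sample standard deviation (ddof=1) is used, 0.0 for a
    single bond.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must be positionally matched")
    if np.any(before <= 0):
        raise ValueError("bond lengths must be positive")
    change = 100.0 * np.abs(after - before) / before
    std = float(np.std(change, ddof=1)) if change.size > 1 else 0.0
    return BondChangeStats(
        per_bond_change=change,
        mean=float(np.mean(change)),
        median=float(np.median(change)),
        std=std,
        min=float(np.min(change)),
        max=float(np.max(change)),
    )


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> PairedTTestResult:
    """Two-sided paired t-test on matched samples.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y, p from Student-t with n-1
    degrees of freedom. Zero-variance differences make the statistic
    undefined and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two matched 1-d samples of size >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance differences: t statistic undefined")
    res = _sstats.ttest_rel(x, y)
    return PairedTTestResult(
        t_stat=float(res.statistic), p_value=float(res.pvalue), n_pairs=int(x.size)
    )


@dataclass
class ConformerResult:
    """Full geometry pipeline output for one molecule."""

    mol_h: Chem.Mol  # explicit-hydrogen molecule
    conformer: Conformer3D
    optimized: OptimizedConformer | None
    bonds: list[tuple[int, int]]  # heavy-atom bonds, molH indices
    lengths_before: np.ndarray
    lengths_after: np.ndarray


def conformer_pipeline(
    mol: Chem.Mol, *, seed: int = 0, max_attempts: int = 5000
) -> ConformerResult:
    """Hydrogenate, embed, MMFF-optimise and measure heavy-atom bond lengths.

    ``mol`` is the (hydrogen-suppressed) standardised molecule. Returns a
    result with ``optimized=None`` when embedding fails.
    """
    mol_h = add_hydrogens(mol)
    conf = embed_conformer(mol_h, max_attempts=max_attempts, seed=seed)
    bonds = heavy_atom_bonds(mol_h)
    if not conf.embedded:
        empty = np.zeros(len(bonds))
        return ConformerResult(mol_h, conf, None, bonds, empty, empty)
    opt = mmff_optimize(mol_h, conf)
    return ConformerResult(
        mol_h,
        conf,
        opt,
        bonds,
        measure_bond_lengths(conf.coords, bonds),
        measure_bond_lengths(opt.coords, bonds),
    )


def write_sdf(
    results: Sequence[tuple[str, ConformerResult]], path
) -> None:
    """Write optimised conformers as an SDF block per molecule."""
    writer = Chem.SDWriter(str(path))
    for mol_id, res in results:
        if res.optimized is None:
            continue
        work = Chem.Mol(res.mol_h)
        conf = Chem.Conformer(work.GetNumAtoms())
        for i, xyz in enumerate(res.optimized.coords):
            conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        work.RemoveAllConformers()
        work.AddConformer(conf, assignId=True)
        work.SetProp("_Name", mol_id)
        writer.write(work)
    writer.close()
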