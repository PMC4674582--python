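"""Structure and archive I/O.

Receptors come from PDB files read with :mod:`gemmi`; only ``ATOM`` records
survive — HETATM entries (waters, ions, cofactors, the ligand itself) are
stripped on read, so the receptor is the bare protein.  Ligands come from
SDF/MOL2/PDB read with RDKit and must carry explicit hydrogens.

Minima archives are multi-record SDF files (one record per stored minimum,
with ``energy_kcal_mol`` / ``rank`` properties) plus an optional CSV index.
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Geometry import Point3D

from .structures import (
    AtomRecord,
    Conformation,
    FlexibleLigand,
    RigidReceptor,
    TorsionDef,
    mass_for_element,
    vdw_for_element,
)

__all__ = [
    "read_receptor",
    "write_receptor",
    "read_ligand",
    "ligand_from_rdkit",
    "detect_torsions",
    "write_minima_archive",
    "read_minima_archive",
]


def read_receptor(path: str | os.PathLike) -> RigidReceptor:
    """Load a receptor from PDB, keeping ATOM records only.

    Raises ``ValueError`` if no ATOM records survive, ``IOError``/parse
    errors from gemmi propagate for unreadable files.
    """
    structure = gemmi.read_pdb(str(path))
    atoms: list[AtomRecord] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                if residue.het_flag == "H":  # HETATM: waters, ions, ligands
                    continue
                for at in residue:
                    element = at.element.name if at.element.name else at.name[0]
                    atoms.append(
                        AtomRecord(
                            element=element,
                            position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            partial_charge=0.0,
                            mass=mass_for_element(element),
                            vdw_params=vdw_for_element(element),
                        )
                    )
        break  # first model only
    if not atoms:
        raise ValueError(f"{path}: no ATOM records — empty structure")
    return RigidReceptor(atoms=atoms, source_id=Path(path).stem)


def write_receptor(receptor: RigidReceptor, path: str | os.PathLike) -> None:
    """Write a receptor as a minimal single-chain PDB."""
    with open(path, "w") as fh:
        for k, atom in enumerate(receptor.atoms, start=1):
            x, y, z = atom.position
            name = atom.element[:2].upper().rjust(2)
            fh.write(
                f"ATOM  {k:5d} {name:<4s} UNK A{1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element.upper():>2s}\n"
            )
        fh.write("END\n")


def apply_vdw_params(receptor: RigidReceptor, path: str | os.PathLike) -> RigidReceptor:
    """Overwrite per-atom (sigma, epsilon) from a JSON sidecar file.

    PDB carries no force-field parameters, so synthetic pockets whose
    sites use non-default Lennard-Jones values ship a ``[[sigma, eps],
    ...]`` sidecar alongside the structure.
    """
    import json

    pairs = json.loads(Path(path).read_text())
    if len(pairs) != len(receptor.atoms):
        raise ValueError(
            f"{path}: {len(pairs)} parameter pairs for {len(receptor.atoms)} atoms"
        )
    for atom, (sigma, eps) in zip(receptor.atoms, pairs):
        atom.vdw_params = (float(sigma), float(eps))
    return receptor


def _mol_from_path(path: str | os.PathLike) -> Chem.Mol:
    p = str(path)
    ext = Path(p).suffix.lower()
    if ext in (".sdf", ".mol", ".sd"):
        supplier = Chem.SDMolSupplier(p, removeHs=False, sanitize=True)
        mols = [m for m in supplier if m is not None]
        if len(mols) > 1:
            raise ValueError(f"{path}: contains {len(mols)} molecules, expected one")
        if not mols:
            raise ValueError(f"{path}: no parsable molecule")
        return mols[0]
    if ext == ".mol2":
        mol = Chem.MolFromMol2File(p, removeHs=False, sanitize=True)
    elif ext == ".pdb":
        mol = Chem.MolFromPDBFile(p, removeHs=False, sanitize=True)
    else:
        raise ValueError(f"{path}: unsupported ligand format {ext!r}")
    if mol is None:
        raise ValueError(f"{path}: RDKit could not parse the molecule")
    return mol


def ligand_from_rdkit(mol: Chem.Mol, source_id: str = "") -> FlexibleLigand:
    """Convert an RDKit molecule (with a 3D conformer) to a ligand."""
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ValueError("input contains multiple disconnected molecules")
    if mol.GetNumConformers() == 0:
        raise ValueError("ligand molecule has no 3D coordinates")
    conf = mol.GetConformer()
    atoms = []
    for at in mol.GetAtoms():
        element = at.GetSymbol()
        pos = conf.GetAtomPosition(at.GetIdx())
        atoms.append(
            AtomRecord(
                element=element,
                position=np.array([pos.x, pos.y, pos.z]),
                partial_charge=0.0,
                mass=at.GetMass(),
                vdw_params=vdw_for_element(element),
            )
        )
    bonds = [
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            int(round(b.GetBondTypeAsDouble())),
            b.IsInRing(),
        )
        for b in mol.GetBonds()
    ]
    ligand = FlexibleLigand(
        atoms=atoms,
        bonds=bonds,
        formal_charge=Chem.GetFormalCharge(mol),
        source_id=source_id,
    )
    ligand.torsions = detect_torsions(ligand)
    return ligand


def read_ligand(path: str | os.PathLike) -> FlexibleLigand:
    """Load a single ligand (SDF/MOL2/PDB, explicit hydrogens expected)."""
    mol = _mol_from_path(path)
    return ligand_from_rdkit(mol, source_id=Path(path).stem)


def detect_torsions(ligand: FlexibleLigand) -> list[TorsionDef]:
    """Find the rotatable torsions of a ligand.

    A torsion is a single (order-1) acyclic bond whose rotation moves heavy
    atoms on both sides: each axis atom must have at least one non-hydrogen
    neighbour besides its axis partner, so hydrogen-only rotors (methyl,
    hydroxyl) are not counted.  The rotating set is the smaller of the two
    components obtained by deleting the axis bond; on a tie, the component
    containing the higher-indexed axis atom.
    """
    adj = ligand.adjacency()
    heavy = {k for k, a in enumerate(ligand.atoms) if a.is_heavy}
    torsions: list[TorsionDef] = []
    for i, j, order, in_ring in ligand.bonds:
        if order != 1 or in_ring:
            continue
        if not any(k in heavy for k in adj[i] - {j}):
            continue
        if not any(k in heavy for k in adj[j] - {i}):
            continue
        side_j = _component(adj, start=j, blocked_edge=(i, j))
        side_i = set(range(len(ligand.atoms))) - side_j
        if len(side_j) < len(side_i):
            axis, rotating = (i, j), side_j
        elif len(side_i) < len(side_j):
            axis, rotating = (j, i), side_i
        else:  # tie: rotate the side holding the higher-indexed axis atom
            axis, rotating = ((i, j), side_j) if j > i else ((j, i), side_i)
        torsions.append(TorsionDef(axis=axis, rotating_set=frozenset(rotating)))
    return torsions


def _component(adj: list[set[int]], start: int, blocked_edge: tuple[int, int]) -> set[int]:
    a, b = blocked_edge
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if {u, v} == {a, b}:
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


# ---------------------------------------------------------------------------
# minima archives


def _ligand_to_rwmol(ligand: FlexibleLigand) -> Chem.RWMol:
    rw = Chem.RWMol()
    for atom in ligand.atoms:
        a = Chem.Atom(atom.element.capitalize())
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for i, j, order, _ in ligand.bonds:
        rw.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
    return rw


def write_minima_archive(
    sdf_path: str | os.PathLike,
    ligand: FlexibleLigand,
    minima,
    csv_path: str | os.PathLike | None = None,
    rmsds_to_native=None,
    cluster_ids=None,
    rescored_energies=None,
) -> None:
    """Write a minima set as a multi-record SDF plus an optional CSV index.

    ``minima`` is any iterable of objects with ``conf`` and ``energy``
    attributes, assumed already sorted ascending by energy.
    """
    template = _ligand_to_rwmol(ligand)
    writer = Chem.SDWriter(str(sdf_path))
    writer.SetKekulize(False)
    rows = []
    minima = list(minima)
    for rank, m in enumerate(minima, start=1):
        mol = Chem.RWMol(template)
        conf = Chem.Conformer(mol.GetNumAtoms())
        for k, (x, y, z) in enumerate(m.conf.coords):
            conf.SetAtomPosition(k, Point3D(float(x), float(y), float(z)))
        mol.AddConformer(conf, assignId=True)
        mol.SetProp("_Name", f"{ligand.source_id or 'ligand'}_min{rank}")
        mol.SetProp("energy_kcal_mol", f"{m.energy:.10f}")
        mol.SetProp("rank", str(rank))
        if rescored_energies is not None:
            mol.SetProp("rescored_energy_kcal_mol", f"{rescored_energies[rank - 1]:.10f}")
        writer.write(mol)
        row = {"rank": rank, "energy": m.energy}
        if rmsds_to_native is not None:
            row["rmsd_to_native"] = rmsds_to_native[rank - 1]
        if cluster_ids is not None:
            row["cluster_id"] = cluster_ids[rank - 1]
        rows.append(row)
    writer.close()
    if csv_path is not None:
        pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_minima_archive(sdf_path: str | os.PathLike) -> list[tuple[Conformation, float]]:
    """Read back an archive as ``[(conformation, energy), ...]`` in rank order."""
    supplier = Chem.SDMolSupplier(str(sdf_path), removeHs=False, sanitize=False)
    out = []
    for mol in supplier:
        if mol is None:
            continue
        conf = mol.GetConformer()
        coords = np.array(
            [[conf.GetAtomPosition(k).x, conf.GetAtomPosition(k).y, conf.GetAtomPosition(k).z]
             for k in range(mol.GetNumAtoms())]
        )
        energy = float(mol.GetProp("energy_kcal_mol"))
        out.append((Conformation(coords), energy))
    return out
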