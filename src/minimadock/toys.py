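"""Deterministic synthetic systems with analytically known minima.

Real docking runs need a receptor structure, a protonated ligand and a
production energy model; none of that is required to test the search, the
metrics or the thermodynamics.  This module builds tiny rigid "pockets"
out of fixed Lennard-Jones sites whose interior minimum count is known by
construction, plus small chain ligands with a requested number of
rotatable torsions:

* ``double-well`` — two LJ sites on the x axis.  The single-atom probe
  potential is axisymmetric and has exactly two point minima, one just
  inside each site, at slightly different depths (the two sites have
  different well depths).  Everything else on the axis is a saddle.
* ``spherical-cavity`` — a Fibonacci-sphere shell of LJ sites at the pair
  equilibrium distance; by symmetry the interior minimum is the center.

It also loads the packaged benchmark-table transcriptions (16 complexes:
binding-energy decompositions and per-target-function energies with
experimental values), checksummed against accidental edits.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import ToyFieldParams, ToyForceField
from .stats import ComplexRecord
from .structures import AtomRecord, Conformation, FlexibleLigand, RigidReceptor
from .thermo import BindingBreakdown

__all__ = [
    "ToySystemSpec",
    "make_toy_pocket",
    "make_toy_ligand",
    "grid_scan_minima",
    "load_paper_tables",
    "write_fixture",
]

_TABLE_SHA256 = {
    "table4.csv": "807fde3617b0aff254b6add92babbceb76a03296f6fda048008a4293012a04c4",
    "table5.csv": "cbef67837d87f7c64c93c8c43772c7584a6852a118a0d04d0555b54e186acfb3",
}

# pocket-site LJ parameters; combined with the carbon probe
# (sigma 3.4, eps 0.1) by Lorentz-Berthelot these give pair parameters
# sigma_ij = 2.0 Å and eps_ij = 0.40 / 0.25 kcal/mol for the two wells.
# With the sites 6.4 Å apart each site's spherical sticking shell is
# tilted toward the other site, leaving exactly two point minima, one
# just inside each site on the axis; the only other stationary points
# are saddles: the midpoint, rings around each site, and two very flat
# axial points outside the pair at |x| ~ 5.4.  The search sphere that
# belongs to this fixture (DOUBLE_WELL_SEARCH_RADIUS) stops short of
# those outer flats, so the sphere holds exactly the two minima.
_SITE_SIGMA = 0.6
_SITE_EPS_A = 1.6  # sqrt(1.6 * 0.1) = 0.4
_SITE_EPS_B = 0.625  # sqrt(0.625 * 0.1) = 0.25
_SITE_SEPARATION = 3.2  # sites at x = -3.2 and +3.2
_PAIR_SIGMA = 2.0
_PAIR_RSTAR = 2.0 * 2.0 ** (1.0 / 6.0)

#: search-sphere radius matched to the double-well construction (Å)
DOUBLE_WELL_SEARCH_RADIUS = 5.0


@dataclass(frozen=True)
class ToySystemSpec:
    """Everything needed to rebuild a toy system bit-for-bit."""

    pocket_kind: str = "double-well"  # "double-well" | "spherical-cavity" | "none"
    ligand_size: int = 1
    n_torsions: int = 0
    seed: int = 0
    field_params: ToyFieldParams = field(default_factory=ToyFieldParams)


def make_toy_pocket(spec: ToySystemSpec) -> RigidReceptor:
    """Build the rigid pocket for a spec; deterministic given the spec."""
    if spec.pocket_kind == "none":
        return RigidReceptor(atoms=[], source_id="none")
    if spec.pocket_kind == "double-well":
        atoms = [
            AtomRecord("C", np.array([-_SITE_SEPARATION, 0.0, 0.0]),
                       mass=12.011, vdw_params=(_SITE_SIGMA, _SITE_EPS_A)),
            AtomRecord("C", np.array([+_SITE_SEPARATION, 0.0, 0.0]),
                       mass=12.011, vdw_params=(_SITE_SIGMA, _SITE_EPS_B)),
        ]
        return RigidReceptor(atoms=atoms, source_id="double-well")
    if spec.pocket_kind == "spherical-cavity":
        n_sites = 30
        pts = _fibonacci_sphere(n_sites) * _PAIR_RSTAR
        atoms = [
            AtomRecord("C", p, mass=12.011, vdw_params=(_SITE_SIGMA, _SITE_EPS_A))
            for p in pts
        ]
        return RigidReceptor(atoms=atoms, source_id="spherical-cavity")
    raise ValueError(f"unknown pocket kind {spec.pocket_kind!r}")


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def make_toy_ligand(spec: ToySystemSpec) -> tuple[FlexibleLigand, Conformation]:
    """Build a chain ligand with ``spec.n_torsions`` rotatable torsions.

    A chain of n heavy atoms has n-3 internal rotatable bonds, so the
    requested torsion count fixes the minimum size; sizes below
    ``n_torsions + 3`` (or below 1) are infeasible.
    """
    size = spec.ligand_size
    if size < 1:
        raise ValueError("ligand_size must be at least 1")
    max_torsions = max(0, size - 3)
    if spec.n_torsions > max_torsions:
        raise ValueError(
            f"a {size}-atom chain supports at most {max_torsions} torsions, "
            f"not {spec.n_torsions}"
        )
    # zig-zag carbon chain: bond 1.54 Å, tetrahedral angles, all-trans
    bond = 1.54
    half = math.radians(109.47) / 2.0
    coords = np.zeros((size, 3))
    for i in range(1, size):
        coords[i, 0] = coords[i - 1, 0] + bond * math.sin(half)
        coords[i, 1] = bond * math.cos(half) * (i % 2)
    atoms = [AtomRecord("C", coords[i].copy()) for i in range(size)]
    bonds = [(i, i + 1, 1, False) for i in range(size - 1)]
    ligand = FlexibleLigand(atoms=atoms, bonds=bonds, source_id="toy-chain")
    from .io import detect_torsions

    ligand.torsions = detect_torsions(ligand)
    assert len(ligand.torsions) == max_torsions
    return ligand, ligand.reference_conformation()


# ---------------------------------------------------------------------------
# the grid-scan oracle


def grid_scan_minima(
    receptor: RigidReceptor,
    ligand: FlexibleLigand,
    model: ToyForceField | None = None,
    axis: np.ndarray = np.array([1.0, 0.0, 0.0]),
    lo: float = -DOUBLE_WELL_SEARCH_RADIUS,
    hi: float = DOUBLE_WELL_SEARCH_RADIUS,
    step: float = 1e-3,
) -> list[tuple[np.ndarray, float]]:
    """Independent enumeration of single-atom-probe minima by grid scan.

    The toy pockets are built symmetric about an axis, so every point
    minimum lies on it.  The probe energy is evaluated on a 1-D lattice
    along the axis at ``step`` Å; interior lattice minima are kept only
    if the full 3-D Hessian there is positive definite, which rejects
    axial points that are transverse saddles.  The default scan range is
    the search sphere that belongs to the double-well fixture — minima
    are enumerated over the same region the search itself retains poses
    from.  Returns ``[(position, energy), ...]`` sorted by energy.
    """
    if model is None:
        model = ToyForceField()
    if len(ligand) != 1:
        raise ValueError("the grid-scan oracle supports single-atom probes only")
    axis = axis / np.linalg.norm(axis)
    from .energy import SingularGeometryError

    ts = np.arange(lo, hi + step / 2, step)
    energies = np.empty(len(ts))
    for k, t in enumerate(ts):
        try:
            e, _ = model.evaluate(receptor, ligand, Conformation((t * axis)[None, :]))
        except SingularGeometryError:
            e = np.inf  # lattice point on top of a receptor site
        energies[k] = e
    from .thermo import _numerical_hessian

    found: list[tuple[np.ndarray, float]] = []
    for k in range(1, len(ts) - 1):
        if energies[k] < energies[k - 1] and energies[k] < energies[k + 1]:
            pos = ts[k] * axis
            H = _numerical_hessian(model, receptor, ligand, Conformation(pos[None, :]))
            if np.all(np.linalg.eigvalsh(H) > 0):
                found.append((pos, float(energies[k])))
    found.sort(key=lambda pe: pe[1])
    return found


# ---------------------------------------------------------------------------
# packaged benchmark tables


def _load_checked_csv(name: str) -> pd.DataFrame:
    ref = resources.files("minimadock.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE_SHA256[name]:
        raise ValueError(f"fixture {name} is corrupted (sha256 mismatch)")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_paper_tables() -> tuple[list[BindingBreakdown], list[ComplexRecord]]:
    """Load the packaged 16-complex benchmark transcriptions.

    Returns the binding-energy decompositions (dE, dG_v, dG_t, dG_r,
    dG_all, dG_bind, dG_exp per complex) and the per-target-function
    binding energies with experimental values.
    """
    t4 = _load_checked_csv("table4.csv")
    breakdowns = [
        BindingBreakdown(
            dE=row.dE, dG_v=row.dG_v, dG_t=row.dG_t, dG_r=row.dG_r,
            dG_all=row.dG_all, dG_bind=row.dG_bind, dG_exp=row.dG_exp,
            pdb_id=row.pdb_id,
        )
        for row in t4.itertuples()
    ]
    t5 = _load_checked_csv("table5.csv")
    label_cols = [c for c in t5.columns if c not in ("pdb_id", "dG_exp")]
    records = [
        ComplexRecord(
            pdb_id=row["pdb_id"],
            dG_exp=row["dG_exp"],
            per_function_energies={c: row[c] for c in label_cols},
        )
        for _, row in t5.iterrows()
    ]
    return breakdowns, records


def write_fixture(kind: str, seed: int, out_dir: str | os.PathLike) -> dict:
    """Emit a toy system to disk: receptor PDB, probe/ligand SDF and an
    expected-minima JSON computed with the grid-scan oracle."""
    from .io import write_minima_archive, write_receptor
    from .search import LocalMinimum

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = ToySystemSpec(pocket_kind=kind, ligand_size=1, n_torsions=0, seed=seed)
    receptor = make_toy_pocket(spec)
    ligand, conf = make_toy_ligand(spec)
    write_receptor(receptor, out / "receptor.pdb")
    # PDB cannot carry the sites' LJ parameters; ship them alongside
    (out / "receptor_params.json").write_text(
        json.dumps([list(a.vdw_params) for a in receptor.atoms])
    )
    write_minima_archive(
        out / "ligand.sdf", ligand, [LocalMinimum(conf=conf, energy=0.0)]
    )
    minima = grid_scan_minima(receptor, ligand)
    payload = {
        "kind": kind,
        "seed": seed,
        "search_radius": DOUBLE_WELL_SEARCH_RADIUS,
        "minima": [
            {"position": [float(v) for v in pos], "energy": e} for pos, e in minima
        ],
    }
    (out / "expected_minima.json").write_text(json.dumps(payload, indent=2))
    return payload
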