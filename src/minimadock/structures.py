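"""Molecular structure containers: rigid receptor, flexible ligand, poses.

The receptor is a fixed set of atoms that only contributes an external
field; its coordinates never move after loading.  The ligand carries the
bond graph, the rotatable torsions derived from it, and per-atom force
field parameters.  A :class:`Conformation` is just a Cartesian snapshot of
the ligand, ordered exactly like ``FlexibleLigand.atoms``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "RigidReceptor",
    "TorsionDef",
    "FlexibleLigand",
    "Conformation",
    "geometric_center",
    "DEFAULT_VDW",
    "ELEMENT_MASSES",
]

#: default per-element Lennard-Jones parameters (sigma Å, epsilon kcal/mol)
#: used by the built-in toy force field; values are generic, not MMFF94.
DEFAULT_VDW: dict[str, tuple[float, float]] = {
    "H": (1.20, 0.02),
    "C": (3.40, 0.10),
    "N": (3.25, 0.17),
    "O": (3.00, 0.21),
    "S": (3.60, 0.25),
    "P": (3.70, 0.20),
    "F": (2.95, 0.06),
    "CL": (3.45, 0.27),
    "BR": (3.60, 0.30),
    "I": (3.80, 0.32),
}
_VDW_FALLBACK = (3.50, 0.15)

ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "SE": 78.971, "B": 10.81,
}


def vdw_for_element(element: str) -> tuple[float, float]:
    return DEFAULT_VDW.get(element.upper(), _VDW_FALLBACK)


def mass_for_element(element: str) -> float:
    try:
        return ELEMENT_MASSES[element.upper()]
    except KeyError:
        raise ValueError(f"unknown element {element!r}: cannot assign a mass")


@dataclass
class AtomRecord:
    """One atom: element, position (Å), charge (e), mass (amu), vdW pair."""

    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    mass: float = 0.0
    vdw_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        if self.mass == 0.0:
            self.mass = mass_for_element(self.element)
        if self.mass <= 0:
            raise ValueError("atom mass must be positive")
        if self.vdw_params is None:
            self.vdw_params = vdw_for_element(self.element)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class RigidReceptor:
    """Fixed protein atoms; coordinates are frozen after load."""

    atoms: list[AtomRecord]
    source_id: str = ""

    def __post_init__(self) -> None:
        coords = np.array([a.position for a in self.atoms], dtype=float)
        coords.setflags(write=False)
        self._coords = coords

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class TorsionDef:
    """A rotatable bond: the ordered axis pair and the atoms it moves.

    ``rotating_set`` is the connected component obtained by deleting the
    axis bond that contains ``axis[1]``; rotating it about the axis leaves
    every bond length and bond angle unchanged.
    """

    axis: tuple[int, int]
    rotating_set: frozenset[int]

    def __post_init__(self) -> None:
        if self.axis[0] in self.rotating_set or self.axis[1] not in self.rotating_set:
            raise ValueError("rotating_set must contain axis[1] but not axis[0]")


@dataclass
class FlexibleLigand:
    """Ligand topology: atoms, bonds, torsions, and derived bulk data.

    ``bonds`` entries are ``(i, j, order, in_ring)``.  ``torsions`` is
    derived with :func:`minimadock.io.detect_torsions` at load time but may
    be supplied directly for synthetic systems.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, int, bool]]
    torsions: list[TorsionDef] = field(default_factory=list)
    formal_charge: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("bond index out of range")
        if n > 1 and not self._connected():
            raise ValueError("ligand bond graph must be connected")

    def _connected(self) -> bool:
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for k in adj[stack.pop()]:
                if k not in seen:
                    seen.add(k)
                    stack.append(k)
        return len(seen) == len(self.atoms)

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.atoms]
        for i, j, _, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([k for k, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    @property
    def total_mass(self) -> float:
        return float(sum(a.mass for a in self.atoms))

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def reference_conformation(self) -> "Conformation":
        return Conformation(np.array([a.position for a in self.atoms], dtype=float))

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Conformation:
    """Cartesian coordinates (Å) in the ligand's atom order."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    def copy(self) -> "Conformation":
        return Conformation(self.coords.copy())

    def __len__(self) -> int:
        return len(self.coords)


def geometric_center(conf: Conformation) -> np.ndarray:
    """Unit-mass center of a pose: the plain mean over all atoms,
    hydrogens included."""
    if len(conf) == 0:
        raise ValueError("cannot take the center of an empty conformation")
    return conf.coords.mean(axis=0)
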