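"""Energy models: the evaluation contract, a built-in toy force field, and
rescoring / reoptimization of minima sets under alternate models.

The package deliberately does not ship a production force field; search and
thermodynamics are exercised against a small, smooth, analytic toy field
(harmonic bonds and angles, a cosine torsion series, Lennard-Jones plus
screened Coulomb nonbonded terms).  Production models — force fields,
semiempirical methods, implicit-solvent rescoring — plug in through the
same contract: a callable mapping ``(receptor, ligand, conformation)`` to
``(energy kcal/mol, gradient kcal/mol/Å per ligand atom)``.  Gradients are
over ligand Cartesian coordinates only; the receptor never moves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Protocol, runtime_checkable

import numpy as np

from .structures import Conformation, FlexibleLigand, RigidReceptor

__all__ = [
    "EnergyModel",
    "ToyFieldParams",
    "ToyForceField",
    "register_model",
    "get_model",
    "rescore_set",
    "reoptimize_set",
]


@runtime_checkable
class EnergyModel(Protocol):
    """The pluggable energy-model contract.

    Implementations must be pure: identical inputs give identical outputs,
    in kcal/mol and kcal/mol/Å.
    """

    name: str

    def evaluate(
        self,
        receptor: RigidReceptor | None,
        ligand: FlexibleLigand,
        conf: Conformation,
    ) -> tuple[float, np.ndarray]: ...


@dataclass(frozen=True)
class ToyFieldParams:
    """Parameters of the built-in toy field.

    Bond and angle reference values are taken from the ligand's reference
    geometry, so a freshly loaded ligand starts near its bonded-term
    minimum.  ``torsion_series`` entries are ``(n, k, phase)`` giving a
    term ``k * (1 + cos(n*phi - phase))`` applied to every rotatable
    torsion.
    """

    dielectric: float = 1.0
    bond_k: float = 300.0  # kcal/mol/Å^2
    angle_k: float = 50.0  # kcal/mol/rad^2
    torsion_series: tuple[tuple[int, float, float], ...] = ((3, 1.0, 0.0),)
    cutoff: float | None = None  # optional nonbonded distance cutoff, Å

    def __post_init__(self) -> None:
        if self.bond_k <= 0 or self.angle_k <= 0 or self.dielectric <= 0:
            raise ValueError("force constants and dielectric must be positive")


_MIN_SEPARATION = 1e-6  # Å; closer pairs are a singular geometry


class SingularGeometryError(ValueError):
    """Raised when two atoms (nearly) coincide and the field diverges."""


class ToyForceField:
    """Smooth analytic test field honouring the :class:`EnergyModel` contract."""

    def __init__(self, params: ToyFieldParams | None = None, name: str = "toy"):
        self.params = params or ToyFieldParams()
        self.name = name
        self._topo_cache: dict[int, dict] = {}

    # -- topology ---------------------------------------------------------

    def _topology(self, ligand: FlexibleLigand) -> dict:
        key = id(ligand)
        topo = self._topo_cache.get(key)
        if topo is not None:
            return topo
        ref = ligand.reference_conformation().coords
        n = len(ligand)
        bonds = [(i, j) for i, j, _, _ in ligand.bonds]
        bond_r0 = np.array([np.linalg.norm(ref[i] - ref[j]) for i, j in bonds])
        adj = ligand.adjacency()
        angles = []
        for j in range(n):
            nbrs = sorted(adj[j])
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    angles.append((nbrs[a], j, nbrs[b]))
        angle_t0 = np.array([_angle(ref[i], ref[j], ref[k]) for i, j, k in angles])
        # dihedral quadruples: one per rotatable torsion, heavy-preferring
        # reference neighbours on each side of the axis
        dihedrals = []
        for tor in ligand.torsions:
            a, b = tor.axis
            i = _pick_neighbor(adj, ligand, a, exclude=b)
            l = _pick_neighbor(adj, ligand, b, exclude=a)
            if i is not None and l is not None:
                dihedrals.append((i, a, b, l))
        # intramolecular nonbonded pairs: graph distance >= 3 (1-4 and up)
        dist = _graph_distances(adj, n)
        nb_pairs = [
            (i, j) for i in range(n) for j in range(i + 1, n) if dist[i][j] >= 3
        ]
        sigma = np.array([at.vdw_params[0] for at in ligand.atoms])
        eps = np.array([at.vdw_params[1] for at in ligand.atoms])
        charge = np.array([at.partial_charge for at in ligand.atoms])
        topo = {
            "bonds": np.array(bonds, dtype=int).reshape(-1, 2),
            "bond_r0": bond_r0,
            "angles": np.array(angles, dtype=int).reshape(-1, 3),
            "angle_t0": angle_t0,
            "dihedrals": np.array(dihedrals, dtype=int).reshape(-1, 4),
            "nb_pairs": np.array(nb_pairs, dtype=int).reshape(-1, 2),
            "sigma": sigma,
            "eps": eps,
            "charge": charge,
        }
        self._topo_cache[key] = topo
        return topo

    # -- evaluation -------------------------------------------------------

    def evaluate(
        self,
        receptor: RigidReceptor | None,
        ligand: FlexibleLigand,
        conf: Conformation,
    ) -> tuple[float, np.ndarray]:
        p = self.params
        topo = self._topology(ligand)
        x = conf.coords
        n = len(x)
        energy = 0.0
        grad = np.zeros((n, 3))

        # bonds: k (r - r0)^2
        B = topo["bonds"]
        if len(B):
            d = x[B[:, 0]] - x[B[:, 1]]
            r = np.linalg.norm(d, axis=1)
            _check_separation(r)
            dr = r - topo["bond_r0"]
            energy += float(p.bond_k * np.sum(dr**2))
            g = (2.0 * p.bond_k * dr / r)[:, None] * d
            np.add.at(grad, B[:, 0], g)
            np.add.at(grad, B[:, 1], -g)

        # angles: k (theta - theta0)^2
        for (i, j, k), t0 in zip(topo["angles"], topo["angle_t0"]):
            theta, gi, gj, gk = _angle_grad(x[i], x[j], x[k])
            dt = theta - t0
            energy += float(p.angle_k * dt**2)
            c = 2.0 * p.angle_k * dt
            grad[i] += c * gi
            grad[j] += c * gj
            grad[k] += c * gk

        # torsion cosine series on rotatable torsions
        for i, j, k, l in topo["dihedrals"]:
            phi, gi, gj, gk, gl = _dihedral_grad(x[i], x[j], x[k], x[l])
            for order, kphi, phase in p.torsion_series:
                energy += float(kphi * (1.0 + np.cos(order * phi - phase)))
                dEdphi = -kphi * order * np.sin(order * phi - phase)
                grad[i] += dEdphi * gi
                grad[j] += dEdphi * gj
                grad[k] += dEdphi * gk
                grad[l] += dEdphi * gl

        # intramolecular nonbonded (1-4 and beyond)
        NB = topo["nb_pairs"]
        if len(NB):
            d = x[NB[:, 0]] - x[NB[:, 1]]
            r = np.linalg.norm(d, axis=1)
            _check_separation(r)
            sig = 0.5 * (topo["sigma"][NB[:, 0]] + topo["sigma"][NB[:, 1]])
            epsp = np.sqrt(topo["eps"][NB[:, 0]] * topo["eps"][NB[:, 1]])
            qq = topo["charge"][NB[:, 0]] * topo["charge"][NB[:, 1]]
            e_pair, dEdr = _lj_coulomb(r, sig, epsp, qq, p.dielectric, p.cutoff)
            energy += float(np.sum(e_pair))
            g = (dEdr / r)[:, None] * d
            np.add.at(grad, NB[:, 0], g)
            np.add.at(grad, NB[:, 1], -g)

        # receptor-ligand nonbonded
        if receptor is not None and len(receptor) > 0:
            rc = receptor.coords
            rsig = np.array([a.vdw_params[0] for a in receptor.atoms])
            reps = np.array([a.vdw_params[1] for a in receptor.atoms])
            rq = np.array([a.partial_charge for a in receptor.atoms])
            d = x[:, None, :] - rc[None, :, :]  # (n, N, 3)
            r = np.linalg.norm(d, axis=2)
            _check_separation(r)
            sig = 0.5 * (topo["sigma"][:, None] + rsig[None, :])
            epsp = np.sqrt(topo["eps"][:, None] * reps[None, :])
            qq = topo["charge"][:, None] * rq[None, :]
            e_pair, dEdr = _lj_coulomb(r, sig, epsp, qq, p.dielectric, p.cutoff)
            energy += float(np.sum(e_pair))
            grad += np.sum((dEdr / r)[:, :, None] * d, axis=1)

        return energy, grad


def _check_separation(r: np.ndarray) -> None:
    if np.any(r < _MIN_SEPARATION):
        raise SingularGeometryError("coincident atoms: interatomic distance below 1e-6 Å")


def _lj_coulomb(r, sigma, eps, qq, dielectric, cutoff):
    from .constants import CONSTANTS

    sr6 = (sigma / r) ** 6
    e = 4.0 * eps * (sr6**2 - sr6) + CONSTANTS.coulomb_kcal * qq / (dielectric * r)
    dEdr = (
        4.0 * eps * (-12.0 * sr6**2 + 6.0 * sr6) / r
        - CONSTANTS.coulomb_kcal * qq / (dielectric * r**2)
    )
    if cutoff is not None:
        mask = r <= cutoff
        e = np.where(mask, e, 0.0)
        dEdr = np.where(mask, dEdr, 0.0)
    return e, dEdr


def _angle(a, b, c):
    u, v = a - b, c - b
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def _angle_grad(a, b, c):
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    cos = np.clip(np.dot(uh, vh), -1.0, 1.0)
    sin = np.sqrt(max(1.0 - cos * cos, 1e-12))
    theta = float(np.arccos(cos))
    ga = (cos * uh - vh) / (nu * sin)
    gc = (cos * vh - uh) / (nv * sin)
    gb = -(ga + gc)
    return theta, ga, gb, gc


def _dihedral_grad(ri, rj, rk, rl):
    b1, b2, b3 = rj - ri, rk - rj, rl - rk
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    phi = float(np.arctan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2)))
    sq1 = max(np.dot(n1, n1), 1e-12)
    sq2 = max(np.dot(n2, n2), 1e-12)
    gi = -nb2 / sq1 * n1
    gl = nb2 / sq2 * n2
    p = np.dot(b1, b2) / nb2**2
    q = np.dot(b3, b2) / nb2**2
    gj = -(1.0 + p) * gi + q * gl
    gk = p * gi - (1.0 + q) * gl
    return phi, gi, gj, gk, gl


def _graph_distances(adj, n):
    # BFS up to depth 2 is enough to tell 1-2/1-3 from the rest
    dist = [dict() for _ in range(n)]
    for s in range(n):
        dist[s][s] = 0
        frontier = [s]
        for depth in (1, 2):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist[s]:
                        dist[s][v] = depth
                        nxt.append(v)
            frontier = nxt
    full = [[dist[i].get(j, 3) for j in range(n)] for i in range(n)]
    return full


def _pick_neighbor(adj, ligand, atom, exclude):
    heavy = [k for k in sorted(adj[atom]) if k != exclude and ligand.atoms[k].is_heavy]
    others = [k for k in sorted(adj[atom]) if k != exclude]
    if heavy:
        return heavy[0]
    return others[0] if others else None


# ---------------------------------------------------------------------------
# model registry

_REGISTRY: dict[str, EnergyModel] = {}


def register_model(model: EnergyModel, name: str | None = None) -> None:
    _REGISTRY[name or model.name] = model


def get_model(name: str) -> EnergyModel:
    if name not in _REGISTRY:
        raise KeyError(f"no energy model registered under {name!r}; "
                       f"known: {sorted(_REGISTRY)}")
    return _REGISTRY[name]


register_model(ToyForceField())


# ---------------------------------------------------------------------------
# rescoring / reoptimization of minima sets


def rescore_set(mset, receptor, ligand, model: EnergyModel, tag: str | None = None):
    """Re-evaluate every stored minimum's energy under another model.

    Geometries are untouched; the set is re-sorted by the new energies and
    tagged with the (search model, rescore model) provenance.  Members the
    model fails on are dropped from the ranking; their count is available
    as ``result.n_failed``.
    """
    from .search import MinimaSet

    rescored = []
    n_failed = 0
    for m in mset.members:
        try:
            e, _ = model.evaluate(receptor, ligand, m.conf)
        except Exception:
            n_failed += 1
            continue
        rescored.append(replace(m, energy=float(e)))
    rescored.sort(key=lambda m: m.energy)
    out = MinimaSet(
        capacity=mset.capacity,
        dedup_rmsd=mset.dedup_rmsd,
        heavy_indices=mset.heavy_indices,
        model_tag=tag or f"{mset.model_tag}+{model.name}",
    )
    out.members = rescored
    out.n_failed = n_failed
    return out


def reoptimize_set(
    mset,
    receptor,
    ligand,
    model: EnergyModel,
    grad_tol: float = 1e-5,
    tag: str | None = None,
):
    """Locally re-minimize every stored minimum under another model.

    Each member is optimized from its current geometry; the pairwise-RMSD
    deduplication rule is then re-applied, since distinct wells of the old
    model may share a basin of the new one.  Optimizer failures keep the
    unoptimized member and emit a warning.  Per-member displacements (Å,
    heavy-atom RMSD old vs new) are available as ``result.displacements``.
    """
    from .metrics import heavy_atom_rmsd
    from .search import MinimaSet, SearchConfig, local_minimize

    cfg = SearchConfig(grad_tol=grad_tol)
    optimized = []
    displacements = []
    n_failed = 0
    for m in mset.members:
        res = local_minimize(model, receptor, ligand, m.conf, cfg)
        if res is None:
            warnings.warn("reoptimization failed for a member; kept unoptimized")
            n_failed += 1
            new = m
        else:
            new = replace(m, conf=res.conf, energy=res.energy,
                          n_optimizer_steps=res.n_optimizer_steps)
        displacements.append(heavy_atom_rmsd(m.conf, new.conf, mset.heavy_indices))
        optimized.append(new)
    out = MinimaSet(
        capacity=mset.capacity,
        dedup_rmsd=mset.dedup_rmsd,
        heavy_indices=mset.heavy_indices,
        model_tag=tag or f"{mset.model_tag}->{model.name}",
    )
    for m in sorted(optimized, key=lambda m: m.energy):
        out.try_insert(m)
    out.n_failed = n_failed
    out.displacements = displacements
    return out
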