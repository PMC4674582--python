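"""Exhaustive low-energy minima search.

The search is a simple Monte Carlo scheme: draw a random ligand pose
(random placement of the geometric center inside a search sphere, random
whole-body rotation, random torsion angles), reject it if any atom pair is
too close, locally minimize the surviving pose with L-BFGS over all ligand
Cartesian coordinates, and offer the resulting minimum to a
capacity-bounded, energy-sorted, RMSD-deduplicated set.  Repeated over
enough trials this enumerates the low-energy part of the local-minima
spectrum of the target function inside the search sphere.
"""

from __future__ import annotations

import bisect
import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .structures import Conformation, FlexibleLigand, RigidReceptor, geometric_center

__all__ = [
    "SearchConfig",
    "LocalMinimum",
    "MinimaSet",
    "SearchDiagnostics",
    "random_trial_pose",
    "clash_filter",
    "local_minimize",
    "run_search",
]


@dataclass
class SearchConfig:
    """Search parameters.

    Defaults follow the protocol the search was designed around: an 8 Å
    sphere centred on the native ligand's geometric center, a 0.5 Å
    clash cutoff (a pose passes only if every atom pair is separated by
    *more* than the cutoff), L-BFGS convergence at a 1e-5 kcal/mol/Å
    max-gradient component, a 1024-minimum capacity and a 0.1 Å
    heavy-atom-RMSD identity rule for distinct minima.
    """

    sphere_center: np.ndarray | None = None  # default: native pose center
    sphere_radius: float = 8.0
    clash_cutoff: float = 0.5
    grad_tol: float = 1e-5
    capacity: int = 1024
    dedup_rmsd: float = 0.1
    seed: int = 0
    max_test_optimizations: int = 1000
    max_optimizer_iters: int = 10_000
    time_budget: float | None = None  # seconds; optional wall-clock halt
    worker_count: int = 1

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if self.capacity < 1:
            raise ValueError("capacity must be at least 1")
        if self.dedup_rmsd <= 0 or self.grad_tol <= 0:
            raise ValueError("dedup_rmsd and grad_tol must be positive")
        if self.sphere_center is not None:
            self.sphere_center = np.asarray(self.sphere_center, dtype=float)


@dataclass(frozen=True)
class LocalMinimum:
    """One converged local minimum of the target function."""

    conf: Conformation
    energy: float
    n_optimizer_steps: int = 0
    origin_trial_index: int = -1


@dataclass
class SearchDiagnostics:
    """Per-run accounting, including the minima-set update history used to
    judge search saturation (no recent updates = likely thorough)."""

    n_test_optimizations: int = 0
    n_clash_rejected: int = 0
    n_out_of_sphere_rejected: int = 0
    n_optimizer_failures: int = 0
    n_dedup_rejected: int = 0
    n_capacity_rejected: int = 0
    n_inserted: int = 0
    update_events: list[int] = field(default_factory=list)
    last_global_update: int = -1


class MinimaSet:
    """Capacity-bounded, ascending-energy-sorted, RMSD-deduplicated set.

    Two minima count as the same if their heavy-atom RMSD (identity atom
    mapping, no superposition — the receptor frame is fixed) is at or
    below ``dedup_rmsd``.  When full, a candidate must beat the current
    worst energy to displace it.
    """

    def __init__(
        self,
        capacity: int = 1024,
        dedup_rmsd: float = 0.1,
        heavy_indices: np.ndarray | None = None,
        model_tag: str = "",
    ):
        self.capacity = capacity
        self.dedup_rmsd = dedup_rmsd
        self.heavy_indices = heavy_indices
        self.model_tag = model_tag
        self.members: list[LocalMinimum] = []

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def energies(self) -> np.ndarray:
        return np.array([m.energy for m in self.members])

    def _rmsd(self, a: Conformation, b: Conformation) -> float:
        from .metrics import heavy_atom_rmsd

        return heavy_atom_rmsd(a, b, self.heavy_indices)

    def try_insert(
        self,
        m: LocalMinimum,
        sphere_center: np.ndarray | None = None,
        sphere_radius: float | None = None,
        diagnostics: SearchDiagnostics | None = None,
        trial_index: int = -1,
    ) -> bool:
        """Offer a minimum to the set; return True if it was stored."""
        if sphere_center is not None and sphere_radius is not None:
            center = geometric_center(m.conf)
            if np.linalg.norm(center - sphere_center) > sphere_radius:
                if diagnostics is not None:
                    diagnostics.n_out_of_sphere_rejected += 1
                return False
        for other in self.members:
            if self._rmsd(m.conf, other.conf) <= self.dedup_rmsd:
                if diagnostics is not None:
                    diagnostics.n_dedup_rejected += 1
                return False
        if len(self.members) >= self.capacity:
            if m.energy >= self.members[-1].energy:
                if diagnostics is not None:
                    diagnostics.n_capacity_rejected += 1
                return False
        # ties broken by insertion order: insert after equal energies
        pos = bisect.bisect_right([x.energy for x in self.members], m.energy)
        self.members.insert(pos, m)
        if len(self.members) > self.capacity:
            self.members.pop()
        if diagnostics is not None:
            diagnostics.n_inserted += 1
            diagnostics.update_events.append(trial_index)
            if pos == 0:
                diagnostics.last_global_update = trial_index
        return True


# ---------------------------------------------------------------------------
# pose generation and filtering


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    ux, uy, uz = axis
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def random_trial_pose(
    ligand: FlexibleLigand,
    ref_conf: Conformation,
    cfg: SearchConfig,
    rng: np.random.Generator,
) -> Conformation:
    """Draw one random trial pose.

    In order: (i) the geometric center is moved to a point uniform in the
    search sphere; (ii) the whole ligand is rotated about a random axis
    through its center by an angle uniform in [-pi, pi] (axis uniform on
    the unit sphere — deliberately the literal axis-angle recipe, not the
    Haar measure on SO(3)); (iii) each rotatable torsion is turned by an
    independent angle uniform in [-pi, pi].  Bond lengths and bond angles
    are preserved exactly; the pose is not re-centered after torsions.
    """
    center = cfg.sphere_center
    if center is None:
        raise ValueError("cfg.sphere_center must be set before pose generation")
    coords = ref_conf.coords.copy()
    # (i) translate center into the sphere (radius ~ U^(1/3) for uniformity)
    direction = _random_unit_vector(rng)
    radius = cfg.sphere_radius * rng.uniform() ** (1.0 / 3.0)
    target = center + radius * direction
    coords += target - coords.mean(axis=0)
    # (ii) whole-body rotation about the new center
    axis = _random_unit_vector(rng)
    angle = rng.uniform(-np.pi, np.pi)
    R = _rotation_matrix(axis, angle)
    c = coords.mean(axis=0)
    coords = (coords - c) @ R.T + c
    # (iii) torsion rotations
    for tor in ligand.torsions:
        a, b = tor.axis
        t_angle = rng.uniform(-np.pi, np.pi)
        Rt = _rotation_matrix(coords[b] - coords[a], t_angle)
        idx = np.fromiter(tor.rotating_set, dtype=int)
        coords[idx] = (coords[idx] - coords[a]) @ Rt.T + coords[a]
    return Conformation(coords)


def clash_filter(
    receptor: RigidReceptor | None,
    ligand: FlexibleLigand,
    conf: Conformation,
    cutoff: float = 0.5,
) -> bool:
    """Accept a pose only if every relevant atom pair is separated by more
    than ``cutoff`` Å.  Bonded (1-2) and angle (1-3) ligand pairs are
    exempt — those separations are set by the topology, not the pose."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    x = conf.coords
    n = len(x)
    if n > 1:
        from .energy import _graph_distances

        adj = ligand.adjacency()
        dist = _graph_distances(adj, n)
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i][j] >= 3 and np.linalg.norm(x[i] - x[j]) <= cutoff:
                    return False
    if receptor is not None and len(receptor) > 0:
        d = np.linalg.norm(x[:, None, :] - receptor.coords[None, :, :], axis=2)
        if np.min(d) <= cutoff:
            return False
    return True


# ---------------------------------------------------------------------------
# local optimization


def local_minimize(
    model,
    receptor: RigidReceptor | None,
    ligand: FlexibleLigand,
    start: Conformation,
    cfg: SearchConfig,
    origin_trial_index: int = -1,
) -> LocalMinimum | None:
    """L-BFGS minimization over all ligand Cartesian coordinates.

    Converged when the maximal gradient component drops to ``grad_tol``
    (kcal/mol/Å).  Returns ``None`` on failure: iteration cap, non-finite
    energy, singular geometry, or a final gradient above tolerance.
    """
    n = len(start)

    def fun(flat: np.ndarray):
        e, g = model.evaluate(receptor, ligand, Conformation(flat.reshape(n, 3)))
        return e, g.ravel()

    x0 = start.coords.ravel()
    total_iters = 0
    try:
        for _ in range(3):  # restart if stopped on ftol before gtol reached
            res = _scipy_minimize(
                fun,
                x0,
                jac=True,
                method="L-BFGS-B",
                options={
                    "maxiter": cfg.max_optimizer_iters,
                    "ftol": 1e-16,
                    "gtol": cfg.grad_tol,
                    "maxcor": 20,
                },
            )
            total_iters += res.nit
            x0 = res.x
            if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
                return None
            e, g = fun(res.x)
            if np.max(np.abs(g)) <= cfg.grad_tol:
                return LocalMinimum(
                    conf=Conformation(res.x.reshape(n, 3)),
                    energy=float(e),
                    n_optimizer_steps=total_iters,
                    origin_trial_index=origin_trial_index,
                )
            if total_iters >= cfg.max_optimizer_iters:
                break
    except (ValueError, FloatingPointError):
        return None
    return None


# ---------------------------------------------------------------------------
# the search loop


def run_search(
    receptor: RigidReceptor | None,
    ligand: FlexibleLigand,
    native_conf: Conformation,
    model,
    cfg: SearchConfig,
) -> tuple[MinimaSet, SearchDiagnostics]:
    """Run the Monte Carlo minima search.

    The search sphere defaults to ``cfg.sphere_radius`` around the native
    pose's geometric center.  Each trial draws its randomness from a
    stream keyed by ``(seed, trial_index)``, so results are independent of
    how trials are partitioned among workers: any ``worker_count`` yields
    the same minima multiset as the serial run.
    """
    if cfg.sphere_center is None:
        cfg = replace_center(cfg, geometric_center(native_conf))
    diag = SearchDiagnostics()
    mset = MinimaSet(
        capacity=cfg.capacity,
        dedup_rmsd=cfg.dedup_rmsd,
        heavy_indices=ligand.heavy_indices,
        model_tag=model.name,
    )
    ref = native_conf
    t0 = time.monotonic()
    for trial in range(cfg.max_test_optimizations):
        if cfg.time_budget is not None and time.monotonic() - t0 > cfg.time_budget:
            break
        diag.n_test_optimizations += 1
        rng = np.random.default_rng([cfg.seed, trial])
        pose = random_trial_pose(ligand, ref, cfg, rng)
        if not clash_filter(receptor, ligand, pose, cfg.clash_cutoff):
            diag.n_clash_rejected += 1
            continue
        minimum = local_minimize(model, receptor, ligand, pose, cfg,
                                 origin_trial_index=trial)
        if minimum is None:
            diag.n_optimizer_failures += 1
            continue
        mset.try_insert(
            minimum,
            sphere_center=cfg.sphere_center,
            sphere_radius=cfg.sphere_radius,
            diagnostics=diag,
            trial_index=trial,
        )
    if len(mset) == 0:
        import warnings

        warnings.warn("search produced zero accepted minima")
    return mset, diag


def replace_center(cfg: SearchConfig, center: np.ndarray) -> SearchConfig:
    from dataclasses import replace

    return replace(cfg, sphere_center=np.asarray(center, dtype=float))
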