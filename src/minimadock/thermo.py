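"""Multiwell-approximation binding free energy.

The configuration integral of a species (ligand or protein-ligand complex)
is approximated as a sum over its distinct low-energy wells, each treated
as an independent harmonic oscillator:

    Z = sum_i exp(-E0_i / kT) * Zv_i * Zt_i * Zr_i,      G = -kT ln Z

with the quantum harmonic vibrational factor per mode
``exp(-hw/2kT) / (1 - exp(-hw/kT))``, the translational factor
``Zt = e (2 pi M k T)^{3/2} / (h^3 rho)`` at standard concentration
``rho = 1 mol/L``, and the rigid-rotor factor
``Zr = (8 pi^2 k T)^{3/2} / h^3 * sqrt(pi I_A I_B I_C)``.

Binding is then ``dG_bind = G(PL) - G(P) - G(L)`` with the protein rigid:
it contributes potential energy and whole-body translation/rotation but no
vibrational modes.  The decomposition reported alongside splits dG_bind
into the global-minima potential-energy gap dE, vibrational, translational
and rotational corrections at the global minima, and dG_all — the residual
from counting every well rather than only the global minima.

All partition-function work is done in log space and in SI units;
interfaces use kcal/mol, Å, amu and K.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import CONSTANTS
from .structures import Conformation, FlexibleLigand, RigidReceptor

__all__ = [
    "WellDescriptor",
    "SpeciesThermo",
    "BindingBreakdown",
    "normal_mode_frequencies",
    "vibrational_partition",
    "translational_partition",
    "rotational_partition",
    "principal_moments",
    "multiwell_free_energy",
    "binding_breakdown",
    "dG_from_Ki",
]

#: eigenvalue tolerance: modes softer than 1 cm^-1 are treated as numerical
#: zeros of the Hessian (s^-2)
_OMEGA_1CM = 2 * math.pi * 2.99792458e10  # rad/s for 1 cm^-1
_LAMBDA_TOL_SI = _OMEGA_1CM**2


class SaddlePointError(ValueError):
    """The supplied geometry has a substantial negative curvature."""


@dataclass
class WellDescriptor:
    """One harmonic well: bottom energy and its normal-mode frequencies.

    ``frequencies`` are angular frequencies (rad/s) of the retained modes:
    all 3n for a complex (the rigid receptor's field breaks translational
    and rotational invariance), 3n-6 for a nonlinear free ligand (3n-5
    linear, 0 for a single atom) after removing the rigid-body modes.
    """

    E0: float  # kcal/mol
    frequencies: np.ndarray  # rad/s
    n_vibrating_atoms: int
    species: str = "complex"  # "complex" | "free-ligand"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(self.frequencies <= 0):
            raise ValueError("well frequencies must all be positive")


@dataclass
class SpeciesThermo:
    """Whole-body data for translation/rotation of one species."""

    total_mass: float  # amu
    moments: tuple[float, float, float] | None = None  # amu*Å^2, ascending
    temperature: float = 310.0
    density: float = field(default=CONSTANTS.standard_density)  # molecules/m^3

    def __post_init__(self) -> None:
        if self.total_mass <= 0 or self.temperature <= 0 or self.density <= 0:
            raise ValueError("mass, temperature and density must be positive")
        if self.moments is not None:
            m = tuple(sorted(float(v) for v in self.moments))
            if m[0] < 0:
                raise ValueError("principal moments must be non-negative")
            self.moments = m


@dataclass
class BindingBreakdown:
    """dG_bind and its additive components, all kcal/mol.

    The identity dG_bind = dE + dG_v + dG_t + dG_r + dG_all holds exactly
    by construction.
    """

    dE: float
    dG_v: float
    dG_t: float
    dG_r: float
    dG_all: float
    dG_bind: float
    dG_exp: float | None = None
    pdb_id: str = ""


# ---------------------------------------------------------------------------
# Hessian / normal modes


def _numerical_hessian(model, receptor, ligand, conf: Conformation, step: float = 1e-4):
    """Central-difference Hessian of the model energy from its analytic
    gradient; symmetrized."""
    n = len(conf)
    x0 = conf.coords.copy()
    H = np.zeros((3 * n, 3 * n))
    for d in range(3 * n):
        i, c = divmod(d, 3)
        xp = x0.copy()
        xp[i, c] += step
        _, gp = model.evaluate(receptor, ligand, Conformation(xp))
        xm = x0.copy()
        xm[i, c] -= step
        _, gm = model.evaluate(receptor, ligand, Conformation(xm))
        H[:, d] = (gp.ravel() - gm.ravel()) / (2 * step)
    return 0.5 * (H + H.T)


def normal_mode_frequencies(
    model,
    receptor: RigidReceptor | None,
    ligand: FlexibleLigand,
    minimum: Conformation,
    species: str = "complex",
    E0: float | None = None,
    fd_step: float = 1e-4,
) -> WellDescriptor:
    """Mass-weighted normal-mode analysis of one well.

    The Hessian over the ligand's Cartesian coordinates is built by
    central finite differences of the analytic gradient (step ``fd_step``
    Å), mass-weighted, and diagonalized; frequencies are ``sqrt`` of the
    eigenvalues in SI.  For ``species="free-ligand"`` the rigid-body modes
    (6 for a nonlinear molecule, 5 linear, 3 for a single atom) are
    removed as the smallest-magnitude eigenvalues.  Remaining eigenvalues
    more negative than a 1 cm^-1 tolerance raise
    :class:`SaddlePointError`; tiny negatives are clamped out with a
    warning.
    """
    if species not in ("complex", "free-ligand"):
        raise ValueError("species must be 'complex' or 'free-ligand'")
    n = len(minimum)
    if E0 is None:
        E0, _ = model.evaluate(receptor, ligand, minimum)
    H = _numerical_hessian(model, receptor, ligand, minimum, step=fd_step)
    masses = np.repeat(ligand.masses, 3)
    Hmw = H / np.sqrt(np.outer(masses, masses))
    eigvals = np.linalg.eigvalsh(Hmw) * CONSTANTS.hessian_to_si  # s^-2
    if species == "free-ligand":
        n_rigid = 3 if n == 1 else (5 if n == 2 else 6)
        keep = np.argsort(np.abs(eigvals))[n_rigid:]
        eigvals = np.sort(eigvals[keep])
    if np.any(eigvals < -_LAMBDA_TOL_SI):
        raise SaddlePointError(
            "negative curvature beyond tolerance: geometry is not a minimum"
        )
    clamped = eigvals <= 0
    if np.any(clamped):
        warnings.warn(f"clamped out {int(np.sum(clamped))} near-zero mode(s)")
        eigvals = eigvals[~clamped]
    return WellDescriptor(
        E0=float(E0),
        frequencies=np.sqrt(eigvals),
        n_vibrating_atoms=n,
        species=species,
    )


# ---------------------------------------------------------------------------
# partition-function components (log-space internals)


def log_vibrational_partition(well: WellDescriptor, T: float) -> float:
    if T <= 0:
        raise ValueError("temperature must be positive")
    x = CONSTANTS.hbar * well.frequencies / (CONSTANTS.k_J * T)
    return float(np.sum(-x / 2 - np.log1p(-np.exp(-x))))


def vibrational_partition(well: WellDescriptor, T: float) -> float:
    """Quantum harmonic vibrational factor; 1 for an empty mode list."""
    return math.exp(log_vibrational_partition(well, T))


def log_translational_partition(sp: SpeciesThermo) -> float:
    M = sp.total_mass * CONSTANTS.amu_to_kg
    kT = CONSTANTS.k_J * sp.temperature
    return float(
        1.0  # the prefactor e
        + 1.5 * math.log(2 * math.pi * M * kT)
        - 3.0 * math.log(CONSTANTS.h)
        - math.log(sp.density)
    )


def translational_partition(sp: SpeciesThermo) -> float:
    """``Zt = e (2 pi M k T)^{3/2} / (h^3 rho)`` — dimensionless at the
    species' concentration (1 mol/L unless overridden)."""
    return math.exp(log_translational_partition(sp))


def principal_moments(conf: Conformation, masses: np.ndarray) -> tuple[float, float, float]:
    """Principal moments of inertia about the center of mass, amu*Å^2."""
    m = np.asarray(masses, dtype=float)
    x = conf.coords - np.average(conf.coords, axis=0, weights=m)
    r2 = np.sum(x**2, axis=1)
    I = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            I[a, b] = np.sum(m * ((r2 if a == b else 0.0) - x[:, a] * x[:, b]))
    vals = np.sort(np.linalg.eigvalsh(I))
    return (float(vals[0]), float(vals[1]), float(vals[2]))


def log_rotational_partition(sp: SpeciesThermo) -> float:
    if sp.moments is None:
        return 0.0  # point species: no rotational factor
    conv = CONSTANTS.amu_to_kg * CONSTANTS.angstrom_to_m**2
    IA, IB, IC = (v * conv for v in sp.moments)
    if IA <= 0:
        raise ValueError("collinear geometry: rigid-rotor factor undefined")
    kT = CONSTANTS.k_J * sp.temperature
    return float(
        1.5 * math.log(8 * math.pi**2 * kT)
        - 3.0 * math.log(CONSTANTS.h)
        + 0.5 * math.log(math.pi * IA * IB * IC)
    )


def rotational_partition(conf: Conformation, masses, T: float, density=None) -> float:
    """Classical rigid-rotor factor from a geometry; errors on collinear
    (including diatomic) geometries, which have a vanishing moment."""
    moments = principal_moments(conf, np.asarray(masses, dtype=float))
    if moments[0] < 1e-8:
        raise ValueError("collinear geometry: rigid-rotor factor undefined")
    sp = SpeciesThermo(total_mass=float(np.sum(masses)), moments=moments, temperature=T)
    return math.exp(log_rotational_partition(sp))


# ---------------------------------------------------------------------------
# the multiwell sum


def _log_Z(wells: list[WellDescriptor], sp: SpeciesThermo) -> float:
    if not wells:
        raise ValueError("at least one well is required")
    kT = CONSTANTS.kT(sp.temperature)
    logzt = log_translational_partition(sp)
    logzr = log_rotational_partition(sp)
    terms = [
        -w.E0 / kT + log_vibrational_partition(w, sp.temperature) + logzt + logzr
        for w in wells
    ]
    return float(logsumexp(terms))


def multiwell_free_energy(wells: list[WellDescriptor], sp: SpeciesThermo) -> float:
    """``G = -kT ln sum_i exp(-E0_i/kT) Zv_i Zt Zr`` in kcal/mol.

    The whole-body translational and rotational factors are evaluated once
    per species from ``sp`` (global-minimum mass and inertia); per-well
    inertia variation is neglected.
    """
    return -CONSTANTS.kT(sp.temperature) * _log_Z(wells, sp)


def binding_breakdown(
    complex_wells: list[WellDescriptor],
    ligand_wells: list[WellDescriptor],
    protein_energy: float,
    sp_complex: SpeciesThermo,
    sp_ligand: SpeciesThermo,
    sp_protein: SpeciesThermo | None = None,
    dG_exp: float | None = None,
    pdb_id: str = "",
    include_protein_tr: bool = True,
) -> BindingBreakdown:
    """Assemble dG_bind = G(PL) - G(P) - G(L) and its decomposition.

    The protein is rigid: a single conformation with potential energy
    ``protein_energy``, no vibrations, and (by default) its own
    translational and rotational factors.  ``include_protein_tr=False``
    switches to a ligand-only convention where the protein contributes
    energy alone.  Components are evaluated at the global minima; dG_all
    is the multiwell-vs-global-minima residual and the returned fields
    satisfy dG_bind = dE + dG_v + dG_t + dG_r + dG_all exactly.
    """
    temps = {sp_complex.temperature, sp_ligand.temperature}
    if sp_protein is not None:
        temps.add(sp_protein.temperature)
    if len(temps) != 1:
        raise ValueError("all species must share one temperature")
    T = sp_complex.temperature
    kT = CONSTANTS.kT(T)
    if include_protein_tr and sp_protein is None:
        raise ValueError("sp_protein is required unless include_protein_tr=False")

    cw = sorted(complex_wells, key=lambda w: w.E0)
    lw = sorted(ligand_wells, key=lambda w: w.E0)
    dE = cw[0].E0 - protein_energy - lw[0].E0
    dG_v = -kT * (
        log_vibrational_partition(cw[0], T) - log_vibrational_partition(lw[0], T)
    )
    log_t = log_translational_partition(sp_complex) - log_translational_partition(sp_ligand)
    log_r = log_rotational_partition(sp_complex) - log_rotational_partition(sp_ligand)
    G_protein = protein_energy
    if include_protein_tr:
        log_t -= log_translational_partition(sp_protein)
        log_r -= log_rotational_partition(sp_protein)
        G_protein -= kT * (
            log_translational_partition(sp_protein) + log_rotational_partition(sp_protein)
        )
    dG_t = -kT * log_t
    dG_r = -kT * log_r

    G_complex = multiwell_free_energy(cw, sp_complex)
    G_ligand = multiwell_free_energy(lw, sp_ligand)
    dG_multi = G_complex - G_protein - G_ligand
    dG_global = dE + dG_v + dG_t + dG_r
    dG_all = dG_multi - dG_global
    return BindingBreakdown(
        dE=dE, dG_v=dG_v, dG_t=dG_t, dG_r=dG_r, dG_all=dG_all,
        dG_bind=dG_global + dG_all, dG_exp=dG_exp, pdb_id=pdb_id,
    )


def dG_from_Ki(Ki: float, T: float = 310.0) -> float:
    """Experimental binding free energy ``kT ln(Ki)`` (Ki in mol/L)."""
    if Ki <= 0:
        raise ValueError("Ki must be positive")
    return CONSTANTS.kT(T) * math.log(Ki)
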