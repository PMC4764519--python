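"""Energies and forces of the one-bead-per-amino-acid implicit-solvent model.

Interaction terms:

* harmonic bonds at 0.38 nm,
* tabulated bending (3-bead angle) and torsion (4-bead dihedral) backbone
  stiffness, interpolated with cubic splines,
* a hydrophobic pair potential: a fixed short-range repulsion plus an
  attractive well whose depth scales with the product of the two beads'
  hydrophobicities, normalised so the Phe-Phe (and binding-spot-Phe) well
  depth equals ``eps_max`` = 5.2 kJ/mol,
* Debye-Hueckel screened electrostatics, energy-shifted at 5.0 nm,
* a purely repulsive (WCA-style) excluded-volume term with exact contact at
  ``sigma_c``, used for scaffold beads and inert cargo surfaces.

All pair terms are energy-shifted so they are exactly zero at and beyond
their cutoff.  Scalar functions here are the reference implementation; the
simulation engine evaluates the same expressions in compiled kernels
(:mod:`fgpore._kernels`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .units import COULOMB

__all__ = [
    "ResidueParams",
    "ForceFieldParams",
    "TabulatedPotential",
    "load_residue_table",
    "load_tabulated",
    "default_force_field",
    "bond_energy",
    "backbone_stiffness_energy",
    "hydrophobic_pair_energy",
    "electrostatic_pair_energy",
    "excluded_volume_energy",
    "TopologyError",
    "AMINO_ACIDS",
    "BINDING_SPOT_CODE",
]

#: the 20 canonical one-letter codes accepted in input sequences
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: pseudo-residue code for cargo-surface binding spots (F-like)
BINDING_SPOT_CODE = "X"

_TWO_POW_SIXTH = 2.0 ** (1.0 / 6.0)


class TopologyError(ValueError):
    """Raised for invalid bead/bond/chain indexing."""


@dataclass(frozen=True)
class ResidueParams:
    """Coarse-grained parameters of one residue type."""

    code: str
    hydrophobicity: float
    charge: float
    bead_radius: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.hydrophobicity <= 1.0:
            raise ValueError(f"hydrophobicity outside [0,1] for {self.code!r}")
        if self.bead_radius <= 0:
            raise ValueError(f"bead_radius must be positive for {self.code!r}")


def _data_path(name: str) -> Path:
    return Path(resources.files("fgpore.data").joinpath(name))  # type: ignore[arg-type]


def load_residue_table(path: str | Path | None = None) -> dict[str, ResidueParams]:
    """Load the per-residue parameter table (delimited text).

    The default packaged table covers the 20 amino acids plus the
    binding-spot pseudo-residue ``X``; F carries the maximum hydrophobicity
    of 1.0 by construction.
    """
    path = _data_path("residues.tsv") if path is None else Path(path)
    table: dict[str, ResidueParams] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("code"):
            continue
        code, h, q, r = line.split("\t")
        table[code] = ResidueParams(code, float(h), float(q), float(r))
    missing = set(AMINO_ACIDS) - set(table)
    if missing:
        raise ValueError(f"residue table missing amino acids: {sorted(missing)}")
    if BINDING_SPOT_CODE not in table:
        raise ValueError("residue table missing the binding-spot pseudo-residue")
    hmax = max(p.hydrophobicity for p in table.values())
    if table["F"].hydrophobicity != hmax:
        raise ValueError("F must carry the maximum hydrophobicity of the scale")
    return table


class TabulatedPotential:
    """Cubic-spline interpolant of a two-column (x, energy) table.

    Non-periodic tables are clamped outside their domain (constant energy,
    zero force); the clamp count is reported so callers can warn.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, periodic: bool = False):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.size < 4:
            raise ValueError("need at least 4 table points")
        dx = np.diff(x)
        if not np.allclose(dx, dx[0], rtol=1e-8):
            raise ValueError("table grid must be uniform")
        if periodic and not np.isclose(y[0], y[-1]):
            raise ValueError("periodic table must close on itself")
        self.x = x
        self.y = y
        self.periodic = periodic
        self._spline = CubicSpline(x, y, bc_type="periodic" if periodic else "natural")
        # piecewise coefficients for the compiled kernels
        self.x0 = float(x[0])
        self.dx = float(dx[0])
        self.coeffs = np.ascontiguousarray(self._spline.c)
        self.span = float(x[-1] - x[0])

    def energy_force(self, x: np.ndarray | float) -> tuple[np.ndarray, np.ndarray, int]:
        """Return (energy, dE/dx, number of clamped evaluations)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.periodic:
            xw = self.x0 + np.mod(x - self.x0, self.span)
            return self._spline(xw), self._spline(xw, 1), 0
        n_clamp = int(np.sum((x < self.x[0]) | (x > self.x[-1])))
        xc = np.clip(x, self.x[0], self.x[-1])
        e = self._spline(xc)
        de = self._spline(xc, 1)
        de[(x < self.x[0]) | (x > self.x[-1])] = 0.0
        return e, de, n_clamp


def load_tabulated(path: str | Path, periodic: bool = False) -> TabulatedPotential:
    """Read a two-column (angle [rad], energy [kJ/mol]) delimited table."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line[0].isalpha():
            continue
        a, e = line.split()
        rows.append((float(a), float(e)))
    arr = np.array(rows)
    return TabulatedPotential(arr[:, 0], arr[:, 1], periodic=periodic)


@dataclass
class ForceFieldParams:
    """Global force-field parameters (nm, kJ/mol, Da)."""

    bond_length: float = 0.38
    bond_stiffness: float = 8000.0
    eps_max: float = 5.2
    vdw_cutoff: float = 2.5
    coulomb_cutoff: float = 5.0
    debye_length: float = 0.8
    dielectric: float = 80.0
    bead_mass: float = 120.0
    #: strength of the fixed short-range repulsion (kJ/mol), shared by the
    #: hydrophobic repulsive branch and the excluded-volume term
    rep_strength: float = 5.2
    bending_potential: TabulatedPotential = field(default=None)  # type: ignore[assignment]
    torsion_potential: TabulatedPotential = field(default=None)  # type: ignore[assignment]
    residues: dict[str, ResidueParams] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.vdw_cutoff <= 0 or self.coulomb_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.coulomb_cutoff < self.vdw_cutoff:
            raise ValueError("coulomb_cutoff must be >= vdw_cutoff")
        if self.eps_max <= 0:
            raise ValueError("eps_max must be positive")
        if self.bending_potential is None:
            self.bending_potential = load_tabulated(_data_path("bending.tsv"))
        if self.torsion_potential is None:
            self.torsion_potential = load_tabulated(_data_path("torsion.tsv"), periodic=True)
        if self.residues is None:
            self.residues = load_residue_table()


def default_force_field() -> ForceFieldParams:
    return ForceFieldParams()


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def bond_energy(
    positions: np.ndarray, bonds: np.ndarray, params: ForceFieldParams
) -> tuple[float, np.ndarray]:
    """Harmonic bond energy E = sum 1/2 k (r - r0)^2 and exact forces."""
    positions = np.asarray(positions, dtype=float)
    bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
    n = positions.shape[0]
    forces = np.zeros_like(positions)
    if bonds.size == 0:
        return 0.0, forces
    if bonds.min() < 0 or bonds.max() >= n:
        raise TopologyError("bond index out of range")
    d = positions[bonds[:, 1]] - positions[bonds[:, 0]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise TopologyError("coincident bonded beads")
    dr = r - params.bond_length
    e = 0.5 * params.bond_stiffness * np.sum(dr**2)
    # dE/dr_j = k (r - r0) * d/r  (force is the negative gradient)
    fpair = (params.bond_stiffness * dr / r)[:, None] * d
    np.add.at(forces, bonds[:, 0], fpair)
    np.add.at(forces, bonds[:, 1], -fpair)
    return float(e), forces


def backbone_stiffness_energy(
    positions: np.ndarray,
    angles: np.ndarray,
    dihedrals: np.ndarray,
    params: ForceFieldParams,
) -> tuple[float, np.ndarray]:
    """Tabulated bending + torsion energy of chain backbones with forces.

    ``angles`` is an (n, 3) index array of consecutive triples, ``dihedrals``
    an (m, 4) array of consecutive quadruples.  Angles falling outside a
    non-periodic table's domain are clamped with a warning.
    """
    from ._kernels import bend_forces, dihedral_forces

    positions = np.ascontiguousarray(positions, dtype=float)
    forces = np.zeros_like(positions)
    e = 0.0
    angles = np.asarray(angles, dtype=np.int64).reshape(-1, 3)
    dihedrals = np.asarray(dihedrals, dtype=np.int64).reshape(-1, 4)
    if angles.size:
        if angles.max() >= positions.shape[0] or angles.min() < 0:
            raise TopologyError("angle index out of range")
        bp = params.bending_potential
        eb, n_clamp = bend_forces(positions, angles, bp.x0, bp.dx, bp.coeffs, forces)
        e += eb
        if n_clamp:
            warnings.warn(f"{n_clamp} bending angle(s) clamped to table domain")
    if dihedrals.size:
        if dihedrals.max() >= positions.shape[0] or dihedrals.min() < 0:
            raise TopologyError("dihedral index out of range")
        tp = params.torsion_potential
        e += dihedral_forces(positions, dihedrals, tp.x0, tp.dx, tp.coeffs, tp.span, forces)
    return float(e), forces


# ---------------------------------------------------------------------------
# nonbonded pair terms (scalar/array reference implementations)
# ---------------------------------------------------------------------------

def _lj_raw(r: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """4[(s/r)^12 - (s/r)^6] and its r-derivative."""
    sr6 = (sigma / r) ** 6
    e = 4.0 * (sr6**2 - sr6)
    de = (24.0 * sr6 - 48.0 * sr6**2) / r
    return e, de


def hydrophobic_pair_energy(
    r: np.ndarray | float,
    eps_ij: float,
    sigma_ij: float,
    cutoff: float = 2.5,
    rep_strength: float = 5.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Hydrophobic pair potential: fixed repulsion + scaled attraction.

    The repulsive branch is a WCA core of strength ``rep_strength`` (active
    for r below the LJ minimum); the attractive branch is the LJ tail scaled
    so that after energy-shifting at the cutoff the well depth is exactly
    ``eps_ij``.  ``eps_ij = 0`` leaves a purely repulsive interaction.
    Returns (energy, radial force) with force = -dU/dr (positive = repulsive).
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    e = np.zeros_like(r)
    f = np.zeros_like(r)
    rmin = _TWO_POW_SIXTH * sigma_ij
    inside = r < cutoff
    if np.any(inside):
        ri = r[inside]
        lj, dlj = _lj_raw(ri, sigma_ij)
        core = ri < rmin
        erep = np.where(core, rep_strength * (lj + 1.0), 0.0)
        derep = np.where(core, rep_strength * dlj, 0.0)
        # normalised attractive branch: -1 inside the core, LJ tail outside
        att = np.where(core, -1.0, lj)
        datt = np.where(core, 0.0, dlj)
        shift = 4.0 * ((sigma_ij / cutoff) ** 12 - (sigma_ij / cutoff) ** 6)
        scale = eps_ij / (1.0 + shift)  # exact well depth after shifting
        e[inside] = erep + scale * (att - shift)
        f[inside] = -(derep + scale * datt)
    return e, f


def electrostatic_pair_energy(
    r: np.ndarray | float,
    q_i: float,
    q_j: float,
    params: ForceFieldParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Debye-Hueckel screened Coulomb, energy-shifted to zero at the cutoff.

    U(r) = (C q_i q_j / eps_r) exp(-r/lambda)/r - U(r_cut) for r < r_cut.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    pref = COULOMB * q_i * q_j / params.dielectric
    e = np.zeros_like(r)
    f = np.zeros_like(r)
    if pref == 0.0:
        return e, f
    lam = params.debye_length
    rc = params.coulomb_cutoff
    inside = r < rc
    ri = r[inside]
    shift = np.exp(-rc / lam) / rc
    e[inside] = pref * (np.exp(-ri / lam) / ri - shift)
    # -dU/dr
    f[inside] = pref * np.exp(-ri / lam) * (1.0 / ri**2 + 1.0 / (ri * lam))
    return e, f


def excluded_volume_energy(
    r: np.ndarray | float,
    sigma_c: float,
    strength: float = 5.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Purely repulsive WCA-form potential with exact contact at sigma_c.

    Zero energy and force for r >= sigma_c; steep continuous repulsion below.
    """
    if sigma_c <= 0:
        raise ValueError("sigma_c must be positive")
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    e = np.zeros_like(r)
    f = np.zeros_like(r)
    inside = r < sigma_c
    if np.any(inside):
        sw = sigma_c / _TWO_POW_SIXTH  # LJ sigma with minimum at sigma_c
        lj, dlj = _lj_raw(r[inside], sw)
        e[inside] = strength * (lj + 1.0)
        f[inside] = -strength * dlj
    return e, f
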