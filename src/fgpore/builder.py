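"""Construction of the simulated system.

Builds the eightfold-symmetric rigid scaffold, grafts disordered FG chains
at anchor rings, realises inert / composite / binding-spot cargoes as rigid
bodies, produces the minimal-variant anchor set, and generates deterministic
scaled-down synthetic fixtures for desk-scale testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from .forcefield import (
    AMINO_ACIDS,
    BINDING_SPOT_CODE,
    ForceFieldParams,
    ResidueParams,
    TopologyError,
    load_residue_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScaffoldGeometry",
    "NupAnchor",
    "CargoSpec",
    "CargoBody",
    "SystemTopology",
    "MINIMAL_VARIANT_REMOVED",
    "build_scaffold",
    "make_inert_cargo",
    "make_kap_complex",
    "realize_cargo",
    "graft_nups",
    "build_system",
    "make_minimal_variant",
    "generate_synthetic_fixture",
]

#: Nup types absent from the minimal viable pore variant
MINIMAL_VARIANT_REMOVED = (
    "Nup42",
    "Nup159",
    "Nup1",
    "Nup60",
    "Nup100",
    "Nsp1",
    "Nup145",
)

_SCAFFOLD_CODE = "SCA"
_CARGO_CODE = "CGO"
_ANCHOR_CODE = "ANC"
_FG_BEAD_RADIUS = 0.3


@dataclass(frozen=True)
class ScaffoldGeometry:
    """Rigid pore-wall geometry (nm)."""

    pore_diameter: float = 60.0
    pore_half_height: float = 15.4
    scaffold_bead_diameter: float = 5.0
    symmetry_order: int = 8
    #: fractional widening of the wall radius at |z| = half height (hourglass)
    flare: float = 0.25

    def __post_init__(self) -> None:
        if self.symmetry_order < 1:
            raise ValueError("symmetry_order must be >= 1")
        if self.pore_diameter <= self.scaffold_bead_diameter:
            raise ValueError("pore_diameter must exceed the scaffold bead diameter")

    def wall_radius(self, z: np.ndarray | float) -> np.ndarray | float:
        """Inner wall radius at height z (waist at z = 0)."""
        zz = np.asarray(z) / self.pore_half_height
        return 0.5 * self.pore_diameter * (1.0 + self.flare * zz**2)


@dataclass(frozen=True)
class NupAnchor:
    """One ring of grafting sites for a Nup type."""

    nup_name: str
    ring_z: float
    ring_radius: float
    copies: int
    sequence_id: str


@dataclass(frozen=True)
class CargoSpec:
    """Geometric/energetic description of a rigid model cargo."""

    D: float
    kind: str  # "single" | "composite" | "kap"
    sigma_c: float
    r_c: float = 0.0
    n_spots: int = 0
    spot_spacing: float = 0.0
    spot_diameter: float = 0.6


@dataclass
class CargoBody:
    """A realised rigid cargo: body-frame bead layout plus dynamic frame."""

    spec: CargoSpec
    local: np.ndarray  # (m, 3) body-frame coordinates
    contact: np.ndarray  # per-bead excluded-volume contact radius
    hydrophobicity: np.ndarray
    codes: list[str]
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quat: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    index: np.ndarray | None = None  # bead indices within the topology

    @property
    def n_beads(self) -> int:
        return self.local.shape[0]

    def mass(self, bead_mass: float = 120.0) -> float:
        return self.n_beads * bead_mass

    def inertia(self, bead_mass: float = 120.0) -> float:
        # uniform sphere of the nominal diameter
        return 0.4 * self.mass(bead_mass) * (0.5 * self.spec.D) ** 2

    def world_coords(self) -> np.ndarray:
        return self.center + self.local @ _quat_to_matrix(self.quat).T


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass
class SystemTopology:
    """Bead-level description of the full simulated system.

    Bead groups: 0 = flexible mobile bead, 1 = static bead (scaffold and
    chain anchors), 2 = rigid-cargo member bead.
    """

    positions: np.ndarray
    codes: list[str]
    hydrophobicity: np.ndarray
    charge: np.ndarray
    radius: np.ndarray
    contact: np.ndarray
    mass: np.ndarray
    group: np.ndarray
    bonds: np.ndarray
    angles: np.ndarray
    dihedrals: np.ndarray
    chains: list[tuple[str, int, int]]  # (name, start, stop) bead ranges
    scaffold_index: np.ndarray
    cargo: CargoBody | None = None

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def flexible(self) -> np.ndarray:
        return self.group == 0

    def fg_bead_mask(self, mobile_only: bool = True) -> np.ndarray:
        is_fg = np.array([c in AMINO_ACIDS for c in self.codes])
        if mobile_only:
            is_fg &= self.flexible
        return is_fg

    def exclusion_keys(self) -> np.ndarray:
        """Sorted unique i*N+j keys (i<j) of nonbonded-excluded pairs."""
        n = self.n_beads
        keys = []
        for arr, cols in ((self.bonds, [(0, 1)]), (self.angles, [(0, 2)])):
            if arr.size:
                for a, b in cols:
                    i = np.minimum(arr[:, a], arr[:, b])
                    j = np.maximum(arr[:, a], arr[:, b])
                    keys.append(i.astype(np.int64) * n + j)
        if self.cargo is not None and self.cargo.index is not None:
            idx = np.sort(self.cargo.index)
            ii, jj = np.triu_indices(len(idx), k=1)
            keys.append(idx[ii].astype(np.int64) * n + idx[jj])
        if not keys:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(keys))

    def sync_cargo_positions(self) -> None:
        if self.cargo is not None and self.cargo.index is not None:
            self.positions[self.cargo.index] = self.cargo.world_coords()


# ---------------------------------------------------------------------------
# scaffold
# ---------------------------------------------------------------------------

def build_scaffold(geom: ScaffoldGeometry) -> np.ndarray:
    """Tile the pore wall with rigid beads, exactly symmetric under rotation
    by 2*pi/symmetry_order about z.  Returns (n, 3) bead centers."""
    d = geom.scaffold_bead_diameter
    n_rings = max(2, int(np.floor(2.0 * geom.pore_half_height / d)) + 1)
    zs = np.linspace(-geom.pore_half_height, geom.pore_half_height, n_rings)
    beads = []
    for ring, z in enumerate(zs):
        r_center = float(geom.wall_radius(z)) + 0.5 * d
        n_sector = max(1, int(np.floor(2.0 * np.pi * r_center / (geom.symmetry_order * d))))
        n_beads = geom.symmetry_order * n_sector
        offset = (np.pi / n_beads) * (ring % 2)  # stagger preserves symmetry
        ang = offset + 2.0 * np.pi * np.arange(n_beads) / n_beads
        beads.append(
            np.column_stack([r_center * np.cos(ang), r_center * np.sin(ang), np.full(n_beads, z)])
        )
    return np.vstack(beads)


# ---------------------------------------------------------------------------
# cargoes
# ---------------------------------------------------------------------------

def _sphere_directions(n: int) -> np.ndarray:
    """n near-uniform unit vectors (spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _effective_contact_deviation(dirs: np.ndarray, r_c: float, reach: float) -> float:
    """Worst relative deviation of the composite contact surface from the
    ideal sphere of radius r_c + reach, probed over 1000 directions."""
    probes = _sphere_directions(1000)
    centers = r_c * dirs
    proj = probes @ centers.T
    perp2 = np.sum(centers**2, axis=1)[None, :] - proj**2
    disc = reach**2 - perp2
    rho = np.where(disc > 0, proj + np.sqrt(np.maximum(disc, 0.0)), -np.inf)
    eff = rho.max(axis=1)
    ideal = r_c + reach
    return float(np.abs(eff - ideal).max() / ideal)


def _composite_directions(r_c: float, reach: float) -> np.ndarray:
    """Smallest direction set whose effective repulsive surface deviates
    from the ideal sphere by < 4.5% (margin under the 5% contract)."""
    for n in (62, 92, 132, 192, 272, 392):
        dirs = _sphere_directions(n)
        if _effective_contact_deviation(dirs, r_c, reach) < 0.045:
            return dirs
    raise ValueError(f"cannot tile composite cargo with r_c = {r_c} nm")


_COMPOSITE_SIGMA_C = 2.5  # repulsion distance of composite sub-beads, nm


def make_inert_cargo(D: float) -> CargoSpec:
    """Inert cargo of diameter D: single bead for D <= 5 nm, composite above.

    Single bead: sigma_c = D/2 + r_b.  Composite: sub-beads with
    sigma_c = 2.5 nm centered at r_c = D/2 - (sigma_c - r_b) from the center.
    """
    if D <= 0:
        raise ValueError("cargo diameter must be positive")
    if D <= 5.0:
        return CargoSpec(D=D, kind="single", sigma_c=D / 2.0 + _FG_BEAD_RADIUS)
    r_c = D / 2.0 - (_COMPOSITE_SIGMA_C - _FG_BEAD_RADIUS)
    return CargoSpec(D=D, kind="composite", sigma_c=_COMPOSITE_SIGMA_C, r_c=r_c)


def make_kap_complex(D: float, n_spots: int, d: float) -> CargoSpec:
    """Rigid Kap-cargo complex: inert body of diameter D plus ``n_spots``
    F-like binding spots on its surface along a great-circle stripe at arc
    spacing ``d``."""
    if n_spots < 0:
        raise ValueError("n_spots must be >= 0")
    if d <= 0:
        raise ValueError("spot spacing must be positive")
    if n_spots * d > np.pi * D:
        raise TopologyError(
            f"stripe cannot hold {n_spots} spots at spacing {d} nm on a "
            f"sphere of diameter {D} nm (circumference {np.pi * D:.2f} nm)"
        )
    base = make_inert_cargo(D)
    return replace(base, kind="kap", n_spots=n_spots, spot_spacing=d)


def realize_cargo(spec: CargoSpec, residues: dict[str, ResidueParams] | None = None) -> CargoBody:
    """Realise a cargo spec as a rigid body with body-frame bead layout."""
    residues = residues or load_residue_table()
    spot = residues[BINDING_SPOT_CODE]
    if spec.kind == "single":
        local = np.zeros((1, 3))
        contact = np.array([spec.D / 2.0])
        hydro = np.array([0.0])
        codes = [_CARGO_CODE]
    else:
        dirs = _composite_directions(spec.r_c, spec.sigma_c)
        local = spec.r_c * dirs
        contact = np.full(len(dirs), spec.sigma_c - _FG_BEAD_RADIUS)
        hydro = np.zeros(len(dirs))
        codes = [_CARGO_CODE] * len(dirs)
        if spec.kind == "kap" and spec.n_spots > 0:
            # spots on the equatorial great circle, centered, at arc spacing d
            dalpha = 2.0 * spec.spot_spacing / spec.D
            alphas = (np.arange(spec.n_spots) - (spec.n_spots - 1) / 2.0) * dalpha
            r_surf = spec.D / 2.0
            spots = np.column_stack(
                [r_surf * np.cos(alphas), r_surf * np.sin(alphas), np.zeros_like(alphas)]
            )
            local = np.vstack([local, spots])
            contact = np.concatenate([contact, np.full(spec.n_spots, spot.bead_radius)])
            hydro = np.concatenate([hydro, np.full(spec.n_spots, spot.hydrophobicity)])
            codes += ["SPT"] * spec.n_spots
    return CargoBody(spec=spec, local=local, contact=contact, hydrophobicity=hydro, codes=codes)


# ---------------------------------------------------------------------------
# grafting and assembly
# ---------------------------------------------------------------------------

def _anchor_sites(anchor: NupAnchor, symmetry_order: int, phase: float) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(anchor.copies) / anchor.copies
    return np.column_stack(
        [
            anchor.ring_radius * np.cos(ang),
            anchor.ring_radius * np.sin(ang),
            np.full(anchor.copies, anchor.ring_z),
        ]
    )


def _grow_chain(
    start: np.ndarray,
    n_res: int,
    bond: float,
    rng: np.random.Generator,
    obstacles: np.ndarray,
    obstacle_r: np.ndarray,
) -> np.ndarray:
    """Self-avoiding random walk from the anchor, biased toward the axis."""
    pos = np.empty((n_res, 3))
    pos[0] = start
    inward = -start.copy()
    inward[2] = 0.0
    nrm = np.linalg.norm(inward)
    inward = inward / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
    prev = inward.copy()
    for i in range(1, n_res):
        for attempt in range(40):
            step = 0.6 * prev + 0.25 * inward + rng.normal(scale=0.6, size=3)
            step /= np.linalg.norm(step)
            cand = pos[i - 1] + bond * step
            if obstacles.size:
                d = np.linalg.norm(obstacles - cand, axis=1)
                if np.any(d < obstacle_r):
                    continue
            d_self = np.linalg.norm(pos[: max(0, i - 1)] - cand, axis=1) if i > 1 else np.empty(0)
            if d_self.size and d_self.min() < 0.35:
                continue
            break
        pos[i] = cand
        prev = step
    return pos


def graft_nups(
    scaffold: np.ndarray | ScaffoldGeometry,
    anchors: list[NupAnchor],
    sequences: dict[str, str],
    seed: int,
    cargo: CargoBody | None = None,
    cargo_center: np.ndarray | None = None,
    residues: dict[str, ResidueParams] | None = None,
    params: ForceFieldParams | None = None,
) -> SystemTopology:
    """Assemble the full system topology.

    One chain per anchor copy; the anchored (first) bead is fixed at the
    anchor site and the rest of the chain is grown as a self-avoiding random
    walk away from the wall.  Deterministic for a given seed.
    """
    params = params or ForceFieldParams()
    residues = residues or params.residues
    if isinstance(scaffold, ScaffoldGeometry):
        geom = scaffold
        scaffold_pos = build_scaffold(geom)
        sym = geom.symmetry_order
        scaffold_contact = 0.5 * geom.scaffold_bead_diameter
    else:
        scaffold_pos = np.asarray(scaffold, dtype=float)
        sym = 8
        scaffold_contact = 2.5

    for a in anchors:
        if a.sequence_id not in sequences:
            raise TopologyError(f"anchor {a.nup_name}: unknown sequence {a.sequence_id!r}")

    rng = np.random.default_rng(seed)

    # realise the cargo first so chains can avoid it
    cargo_world = np.empty((0, 3))
    cargo_avoid_r = np.empty(0)
    if cargo is not None:
        if cargo_center is not None:
            cargo.center = np.asarray(cargo_center, dtype=float)
        cargo_world = cargo.world_coords()
        cargo_avoid_r = cargo.contact + _FG_BEAD_RADIUS

    sites: list[tuple[NupAnchor, np.ndarray]] = []
    all_sites = []
    for k, a in enumerate(anchors):
        phase = 2.0 * np.pi * (k / max(1, len(anchors))) / max(1, sym)
        s = _anchor_sites(a, sym, phase)
        sites.append((a, s))
        all_sites.append(s)
    if all_sites:
        flat = np.vstack(all_sites)
        from scipy.spatial.distance import pdist

        if len(flat) > 1 and pdist(flat).min() < 0.1:
            raise TopologyError("overlapping anchor positions")

    positions = [scaffold_pos]
    codes: list[str] = [_SCAFFOLD_CODE] * len(scaffold_pos)
    group = [np.ones(len(scaffold_pos), dtype=np.int8)]
    contact = [np.full(len(scaffold_pos), scaffold_contact)]
    hydro = [np.zeros(len(scaffold_pos))]
    charge = [np.zeros(len(scaffold_pos))]
    radius = [np.full(len(scaffold_pos), scaffold_contact)]
    mass = [np.full(len(scaffold_pos), params.bead_mass)]
    bonds = []
    angles = []
    dihedrals = []
    chains = []
    n = len(scaffold_pos)

    obstacles = np.vstack([scaffold_pos, cargo_world]) if len(cargo_world) else scaffold_pos
    obstacle_r = np.concatenate(
        [np.full(len(scaffold_pos), scaffold_contact + _FG_BEAD_RADIUS), cargo_avoid_r]
    ) if len(cargo_world) else np.full(len(scaffold_pos), scaffold_contact + _FG_BEAD_RADIUS)

    for a, site_set in sites:
        seq = sequences[a.sequence_id].upper()
        n_res = len(seq)
        for c, site in enumerate(site_set):
            # bead 0 is the fixed anchor (grafting) bead; the n_res residue
            # beads that follow are all mobile
            chain_pos = _grow_chain(
                site, n_res + 1, params.bond_length, rng, obstacles, obstacle_r
            )
            idx0 = n
            positions.append(chain_pos)
            codes.append(_ANCHOR_CODE)
            codes.extend(list(seq))
            g = np.zeros(n_res + 1, dtype=np.int8)
            g[0] = 1
            group.append(g)
            rp = [residues[r] for r in seq]
            hydro.append(np.concatenate([[0.0], [p.hydrophobicity for p in rp]]))
            charge.append(np.concatenate([[0.0], [p.charge for p in rp]]))
            radius.append(np.concatenate([[0.3], [p.bead_radius for p in rp]]))
            contact.append(np.concatenate([[0.3], [p.bead_radius for p in rp]]))
            mass.append(np.full(n_res + 1, params.bead_mass))
            ii = idx0 + np.arange(n_res)
            bonds.append(np.column_stack([ii, ii + 1]))
            # backbone stiffness acts on the residue beads only
            if n_res >= 3:
                ii = idx0 + 1 + np.arange(n_res - 2)
                angles.append(np.column_stack([ii, ii + 1, ii + 2]))
            if n_res >= 4:
                ii = idx0 + 1 + np.arange(n_res - 3)
                dihedrals.append(np.column_stack([ii, ii + 1, ii + 2, ii + 3]))
            chains.append((f"{a.nup_name}:{c}", idx0, idx0 + n_res + 1))
            n += n_res + 1

    cargo_index = None
    if cargo is not None:
        m = cargo.n_beads
        cargo_index = np.arange(n, n + m)
        cargo.index = cargo_index
        positions.append(cargo_world)
        codes.extend(cargo.codes)
        group.append(np.full(m, 2, dtype=np.int8))
        hydro.append(cargo.hydrophobicity)
        charge.append(np.zeros(m))
        radius.append(np.full(m, _FG_BEAD_RADIUS))
        contact.append(cargo.contact)
        mass.append(np.full(m, params.bead_mass))
        n += m

    topo = SystemTopology(
        positions=np.ascontiguousarray(np.vstack(positions)),
        codes=codes,
        hydrophobicity=np.concatenate(hydro),
        charge=np.concatenate(charge),
        radius=np.concatenate(radius),
        contact=np.concatenate(contact),
        mass=np.concatenate(mass),
        group=np.concatenate(group),
        bonds=np.vstack(bonds).astype(np.int64) if bonds else np.empty((0, 2), dtype=np.int64),
        angles=np.vstack(angles).astype(np.int64) if angles else np.empty((0, 3), dtype=np.int64),
        dihedrals=np.vstack(dihedrals).astype(np.int64)
        if dihedrals
        else np.empty((0, 4), dtype=np.int64),
        chains=chains,
        scaffold_index=np.arange(len(scaffold_pos)),
        cargo=cargo,
    )
    return topo


def build_system(
    geom: ScaffoldGeometry,
    anchors: list[NupAnchor],
    sequences: dict[str, str],
    seed: int,
    cargo_spec: CargoSpec | None = None,
    cargo_center: np.ndarray | None = None,
    params: ForceFieldParams | None = None,
) -> SystemTopology:
    """Convenience wrapper: scaffold + grafted chains + optional cargo."""
    cargo = realize_cargo(cargo_spec) if cargo_spec is not None else None
    return graft_nups(
        geom, anchors, sequences, seed, cargo=cargo, cargo_center=cargo_center, params=params
    )


def make_free_cargo_system(
    cargo_spec: CargoSpec,
    center: np.ndarray | tuple = (0.0, 0.0, 0.0),
    params: ForceFieldParams | None = None,
) -> SystemTopology:
    """A system containing only a rigid cargo (no scaffold, no chains).

    Used for single-particle reference simulations (thermostat checks,
    analytic umbrella oracles)."""
    cargo = realize_cargo(cargo_spec)
    return graft_nups(
        np.empty((0, 3)),
        [],
        {},
        seed=0,
        cargo=cargo,
        cargo_center=np.asarray(center, dtype=float),
        params=params,
    )


def make_free_bead_system(
    n: int,
    spacing: float = 10.0,
    code: str = "G",
    params: ForceFieldParams | None = None,
) -> SystemTopology:
    """``n`` unbonded flexible beads spread along x, one per ``spacing`` nm.

    With spacing beyond the interaction cutoffs the beads are independent;
    used for thermostat checks and batched single-particle umbrella runs."""
    params = params or ForceFieldParams()
    rp = params.residues[code]
    pos = np.zeros((n, 3))
    pos[:, 0] = spacing * np.arange(n)
    return SystemTopology(
        positions=pos,
        codes=[code] * n,
        hydrophobicity=np.full(n, rp.hydrophobicity),
        charge=np.full(n, rp.charge),
        radius=np.full(n, rp.bead_radius),
        contact=np.full(n, rp.bead_radius),
        mass=np.full(n, params.bead_mass),
        group=np.zeros(n, dtype=np.int8),
        bonds=np.empty((0, 2), dtype=np.int64),
        angles=np.empty((0, 3), dtype=np.int64),
        dihedrals=np.empty((0, 4), dtype=np.int64),
        chains=[],
        scaffold_index=np.empty(0, dtype=np.int64),
    )


def make_minimal_variant(anchors: list[NupAnchor]) -> list[NupAnchor]:
    """Remove all copies of the seven deleted Nup types; others untouched."""
    removed_lc = {n.lower() for n in MINIMAL_VARIANT_REMOVED}
    present = {a.nup_name.lower() for a in anchors}
    absent = removed_lc - present
    if absent:
        warnings.warn(f"minimal-variant names not present: {sorted(absent)}")
    return [a for a in anchors if a.nup_name.lower() not in removed_lc]


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

_SPACER_POOL = list("STNQGAP")
_SPACER_WEIGHTS = np.array([0.22, 0.18, 0.14, 0.14, 0.16, 0.10, 0.06])


def _synthetic_sequence(n_units: int, rng: np.random.Generator, spacer_len: int = 10) -> str:
    """FSFG motifs separated by hydrophilic spacers with near-zero net charge."""
    parts = []
    for _ in range(n_units):
        parts.append("FSFG")
        spacer = list(rng.choice(_SPACER_POOL, size=spacer_len, p=_SPACER_WEIGHTS))
        if spacer_len >= 4 and rng.random() < 0.5:
            # charge-balanced pair keeps net charge at zero
            i, j = rng.choice(spacer_len, size=2, replace=False)
            spacer[i] = "K"
            spacer[j] = "E"
        parts.append("".join(spacer))
    return "".join(parts)


def generate_synthetic_fixture(
    scale: float,
    seed: int,
    n_chains: int = 16,
    units_per_chain: int | None = None,
) -> tuple[ScaffoldGeometry, list[NupAnchor], dict[str, str]]:
    """Deterministic scaled-down pore with FG-like synthetic sequences.

    ``scale`` scales the pore diameter (60 nm) and half height (15.4 nm) and
    the chain lengths; the generated sequences carry FG motifs at roughly
    10-15% of residues with near-zero net charge.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    if n_chains % 8 != 0:
        raise ValueError("n_chains must be a multiple of the symmetry order (8)")
    rng = np.random.default_rng(seed)
    geom = ScaffoldGeometry(
        pore_diameter=60.0 * scale,
        pore_half_height=15.4 * scale,
    )
    n_rings = n_chains // 8
    ring_zs = (
        np.linspace(-0.45, 0.45, n_rings) * 2.0 * geom.pore_half_height
        if n_rings > 1
        else np.array([0.0])
    )
    n_units = units_per_chain if units_per_chain is not None else max(2, int(round(12 * scale)))
    anchors = []
    sequences: dict[str, str] = {}
    for k, z in enumerate(ring_zs):
        sid = f"synfg{k + 1}"
        sequences[sid] = _synthetic_sequence(n_units, rng)
        anchors.append(
            NupAnchor(
                nup_name=f"SynNup{k + 1}",
                ring_z=float(z),
                ring_radius=float(geom.wall_radius(z)),
                copies=8,
                sequence_id=sid,
            )
        )
    for sid, seq in sequences.items():
        n_fg = seq.count("FG")
        net_q = seq.count("K") + seq.count("R") - seq.count("E") - seq.count("D")
        logger.info(
            "fixture sequence %s: length %d, FG motifs %d (%.1f%% of residues), net charge %+d",
            sid, len(seq), n_fg, 200.0 * n_fg / len(seq), net_q,
        )
    return geom, anchors, sequences
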