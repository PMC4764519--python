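"""Derived quantities: energy barriers, density maps, PMF campaigns.

The energy barrier is the difference between the mean PMF over the pore
core interval (default -5 < z < 5 nm) and over the cytoplasmic reference
interval (default 20 < z < 27 nm), with a dispersion given by the pooled
standard deviation of the PMF values over the two intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .builder import (
    CargoSpec,
    NupAnchor,
    ScaffoldGeometry,
    SystemTopology,
    build_system,
)
from .dynamics import LangevinParams
from .forcefield import ForceFieldParams
from .umbrella import PMFProfile, UmbrellaWindow, WindowSamples, run_window, wham
from .units import KBT_300

__all__ = [
    "BarrierEstimate",
    "DensityMap",
    "energy_barrier",
    "density_map",
    "make_system_factory",
    "axial_pmf_campaign",
    "radial_pmf_campaign",
    "barrier_curve",
    "CoverageError",
]

CORE_INTERVAL = (-5.0, 5.0)
REFERENCE_INTERVAL = (20.0, 27.0)


class CoverageError(ValueError):
    """PMF does not cover a requested averaging interval."""


@dataclass(frozen=True)
class BarrierEstimate:
    """Scalar energy barrier with its dispersion (kJ/mol)."""

    G: float
    dispersion: float
    core: tuple[float, float] = CORE_INTERVAL
    reference: tuple[float, float] = REFERENCE_INTERVAL


@dataclass
class DensityMap:
    """Circumferentially averaged (r, z) mass density of the FG beads."""

    r_edges: np.ndarray
    z_edges: np.ndarray
    density: np.ndarray  # (n_r, n_z), Da nm^-3, frame-averaged
    frame_count: int
    overflow_mass: float  # Da per frame falling outside the grid

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    def voxel_volumes(self) -> np.ndarray:
        dr = np.diff(self.r_edges)
        dz = np.diff(self.z_edges)
        return 2.0 * np.pi * self.r_centers[:, None] * dr[:, None] * dz[None, :]

    def total_mass(self) -> float:
        """Integrated mass per frame, including overflow (Da)."""
        return float(np.sum(self.density * self.voxel_volumes())) + self.overflow_mass


def energy_barrier(
    pmf: PMFProfile,
    core: tuple[float, float] = CORE_INTERVAL,
    reference: tuple[float, float] = REFERENCE_INTERVAL,
) -> BarrierEstimate:
    """Interval-difference barrier statistic with pooled dispersion."""
    ok = np.isfinite(pmf.G)
    out = []
    means = []
    sds = []
    for name, (lo, hi) in (("core", core), ("reference", reference)):
        sel = ok & (pmf.z >= lo) & (pmf.z <= hi)
        if not np.any(sel):
            out.append(name)
            continue
        means.append(float(np.mean(pmf.G[sel])))
        sds.append(float(np.std(pmf.G[sel])))
    if out:
        raise CoverageError(f"PMF does not cover interval(s): {', '.join(out)}")
    g = means[0] - means[1]
    dispersion = float(np.sqrt(0.5 * (sds[0] ** 2 + sds[1] ** 2)))
    return BarrierEstimate(G=g, dispersion=dispersion, core=core, reference=reference)


def density_map(
    frames: list[np.ndarray],
    topology: SystemTopology,
    r_max: float,
    z_min: float,
    z_max: float,
    dr: float = 0.5,
    dz: float = 0.5,
) -> DensityMap:
    """Bin mobile FG-bead mass into annular (r, z) voxels, frame-averaged."""
    if not frames:
        raise ValueError("empty trajectory")
    mask = topology.fg_bead_mask(mobile_only=True)
    masses = topology.mass[mask]
    r_edges = np.arange(0.0, r_max + dr * 0.5, dr)
    z_edges = np.arange(z_min, z_max + dz * 0.5, dz)
    acc = np.zeros((len(r_edges) - 1, len(z_edges) - 1))
    overflow = 0.0
    for pos in frames:
        p = pos[mask]
        r = np.hypot(p[:, 0], p[:, 1])
        z = p[:, 2]
        inside = (r < r_edges[-1]) & (z >= z_edges[0]) & (z < z_edges[-1])
        h, _, _ = np.histogram2d(
            r[inside], z[inside], bins=(r_edges, z_edges), weights=masses[inside]
        )
        acc += h
        overflow += masses[~inside].sum()
    n = len(frames)
    dm = DensityMap(
        r_edges=r_edges,
        z_edges=z_edges,
        density=acc / n,
        frame_count=n,
        overflow_mass=overflow / n,
    )
    dm.density /= dm.voxel_volumes()
    return dm


# ---------------------------------------------------------------------------
# campaigns
# ---------------------------------------------------------------------------

def make_system_factory(
    geom: ScaffoldGeometry,
    anchors: list[NupAnchor],
    sequences: dict[str, str],
    cargo_spec: CargoSpec | None,
    params: ForceFieldParams | None = None,
    base_seed: int = 0,
):
    """A callable (cargo_center, seed) -> fresh SystemTopology.

    Each umbrella window starts from an independently grown configuration
    with the cargo already placed at the window center, so chains never
    start inside the cargo.
    """

    def factory(cargo_center, seed: int) -> SystemTopology:
        return build_system(
            geom,
            anchors,
            sequences,
            seed=base_seed + seed,
            cargo_spec=cargo_spec,
            cargo_center=np.asarray(cargo_center, dtype=float),
            params=params,
        )

    return factory


def axial_pmf_campaign(
    factory,
    windows: list[UmbrellaWindow],
    ff_params: ForceFieldParams,
    lang: LangevinParams,
    bin_width: float = 0.25,
    reference: tuple[float, float] | None = None,
    coord_every: int = 10,
    sequential: bool = True,
    window_kw: dict | None = None,
    **wham_kw,
) -> tuple[PMFProfile, list[WindowSamples]]:
    """Umbrella campaign along the pore axis (r = 0) and its WHAM profile.

    In sequential mode (default) one system is built with the cargo at the
    outermost window and dragged inward window by window, so every window
    samples the same chain realisation; in independent mode each window gets
    a freshly grown system (cheap, but window histograms then come from
    different quenched conformations and may not stitch).
    """
    samples = []
    if sequential:
        ordered = sorted(windows, key=lambda w: -abs(w.center))
        topo = factory((0.0, 0.0, ordered[0].center), ordered[0].seed)
        evaluator = None
        for w in ordered:
            s = run_window(
                topo, w, ff_params, lang, coord="z", coord_every=coord_every,
                evaluator=evaluator, **(window_kw or {}),
            )
            evaluator = s.evaluator
            samples.append(s)
    else:
        for w in windows:
            topo = factory((0.0, 0.0, w.center), w.seed)
            samples.append(
                run_window(
                    topo, w, ff_params, lang, coord="z", coord_every=coord_every,
                    **(window_kw or {}),
                )
            )
    prof = wham(samples, bin_width=bin_width, reference=reference, **wham_kw)
    return prof, samples


def radial_pmf_campaign(
    factory,
    windows: list[UmbrellaWindow],
    ff_params: ForceFieldParams,
    lang: LangevinParams,
    z_plane: float = -2.5,
    angles: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0),
    bin_width: float = 0.25,
    coord_every: int = 10,
    window_kw: dict | None = None,
    **wham_kw,
) -> dict[float, PMFProfile]:
    """Radial umbrella campaigns at fixed z, one per direction angle.

    Profiles are zero-referenced at r = 0.
    """
    out: dict[float, PMFProfile] = {}
    for theta in angles:
        th = np.deg2rad(theta)
        samples = []
        for w in windows:
            center = (w.center * np.cos(th), w.center * np.sin(th), z_plane)
            topo = factory(center, w.seed + int(theta) * 1009)
            samples.append(
                run_window(
                    topo, w, ff_params, lang, coord="r", theta=theta,
                    z_plane=z_plane, coord_every=coord_every,
                    **(window_kw or {}),
                )
            )
        prof = wham(samples, bin_width=bin_width, **wham_kw)
        # zero at the axis
        i0 = np.nanargmin(np.abs(prof.z))
        prof = PMFProfile(prof.z, prof.G - prof.G[i0], prof.sigma, prof.kBT, prof.bin_width)
        out[theta] = prof
    return out


def barrier_curve(
    barriers: dict[float, BarrierEstimate],
    kBT: float = KBT_300,
) -> pd.DataFrame:
    """Tabulate (D, G, dispersion) and locate the size-selectivity threshold.

    The threshold D* is where the linearly interpolated G(D) crosses kBT;
    all crossings are reported if the curve is non-monotonic, and D* is None
    when G never reaches kBT.  Crossings are stored in ``df.attrs``.
    """
    if len(barriers) < 2:
        raise ValueError("need barriers for at least two diameters")
    ds = np.array(sorted(barriers))
    gs = np.array([barriers[d].G for d in ds])
    disp = np.array([barriers[d].dispersion for d in ds])
    df = pd.DataFrame({"D": ds, "G": gs, "dispersion": disp})
    crossings = []
    h = gs - kBT
    for i in range(len(ds) - 1):
        if h[i] == 0.0:
            crossings.append(float(ds[i]))
        elif h[i] * h[i + 1] < 0:
            t = h[i] / (h[i] - h[i + 1])
            crossings.append(float(ds[i] + t * (ds[i + 1] - ds[i])))
    if h[-1] == 0.0:
        crossings.append(float(ds[-1]))
    df.attrs["kBT"] = kBT
    df.attrs["crossings"] = crossings
    df.attrs["D_star"] = crossings[0] if crossings else None
    return df
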