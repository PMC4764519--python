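"""Canned reference campaigns for validating the pipeline end to end.

These wire together builder, dynamics, umbrella sampling and analysis into
reproducible campaigns with analytic or qualitative expectations:

* a Langevin umbrella campaign in an analytic double well (estimator plus
  sampler),
* a Boltzmann-resampled campaign (estimator only),
* desk-scale barrier campaigns in the synthetic pore fixture,
* the full-scale campaign driver used for cluster-tier reproduction runs.

Used by the acceptance test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import (
    BarrierEstimate,
    axial_pmf_campaign,
    energy_barrier,
    make_system_factory,
)
from .builder import (
    CargoSpec,
    generate_synthetic_fixture,
    make_free_bead_system,
    make_inert_cargo,
    make_kap_complex,
    make_minimal_variant,
)
from .dynamics import ArrayPotential, LangevinParams, run
from .forcefield import ForceFieldParams, default_force_field
from .umbrella import PMFProfile, WindowSamples, plan_windows, synthetic_window_samples, wham
from .units import KBT_300

__all__ = [
    "DoubleWell",
    "double_well_md_campaign",
    "boltzmann_estimator_campaign",
    "FIXTURE_SCALE",
    "fixture_campaign_settings",
    "fixture_barrier_campaign",
    "wildtype_campaign",
    "cluster_targets",
]


@dataclass(frozen=True)
class DoubleWell:
    """U(z) = h (z^2 - 1)^2, the analytic oracle potential."""

    h: float = 5.0

    def energy(self, z):
        z = np.asarray(z, dtype=float)
        return self.h * (z * z - 1.0) ** 2

    def energy_deriv(self, z):
        z = np.asarray(z, dtype=float)
        return 4.0 * self.h * z * (z * z - 1.0)

    def bin_averaged(self, z, bin_width, kBT=KBT_300):
        """-kT ln <exp(-U/kT)> over each bin — what a histogram estimator
        of the bin probability actually converges to."""
        gx, gw = np.polynomial.legendre.leggauss(9)
        zz = np.asarray(z)[:, None] + 0.5 * bin_width * gx[None, :]
        return -kBT * np.log(0.5 * np.exp(-self.energy(zz) / kBT) @ gw)

    @property
    def barrier(self) -> float:
        return self.h


_DW_WINDOW_KW = dict(z_start=-1.4, z_end=1.4, dz=0.35)
_DW_REFERENCE = (-1.2, -0.8)


def double_well_md_campaign(
    seed: int,
    n_steps: int = 200000,
    equilibration: int = 10000,
    stride: int = 5,
    bin_width: float = 0.1,
    n_bootstrap: int = 40,
    well: DoubleWell = DoubleWell(),
) -> PMFProfile:
    """Langevin umbrella campaign of independent single particles in the
    analytic double well; all windows propagate in one integrator pass.

    Friction and particle mass are sampling-efficiency knobs (they do not
    enter the equilibrium distribution) and are chosen so the windows
    decorrelate within a few steps.
    """
    windows = plan_windows(n_steps=n_steps, seed=seed, **_DW_WINDOW_KW)
    centers = np.array([w.center for w in windows])
    ks = np.array([w.bias_stiffness for w in windows])
    ff = ForceFieldParams(bead_mass=1.0)
    lang = LangevinParams(temperature=300.0, timestep=0.02, friction=5.0, seed=seed)
    topo = make_free_bead_system(len(windows), spacing=10.0, params=ff)
    topo.positions[:, 2] = centers

    def field(pos):
        z = pos[:, 2]
        e = well.energy(z) + 0.5 * ks * (z - centers) ** 2
        F = np.zeros_like(pos)
        F[:, 2] = -well.energy_deriv(z) - ks * (z - centers)
        return float(e.sum()), F

    pot = ArrayPotential(field)
    rng = np.random.default_rng(seed)
    res = run(topo, ff, lang, restraints=(pot,), n_steps=equilibration,
              coord_every=equilibration, rng=rng)
    res = run(topo, ff, lang, restraints=(pot,), n_steps=n_steps,
              coord_every=n_steps + 1, frame_every=stride,
              state=res.state, evaluator=res.evaluator, rng=rng)
    zs = np.array([f[:, 2] for f in res.frames])
    samples = [
        WindowSamples(window=w, values=zs[:, i]) for i, w in enumerate(windows)
    ]
    return wham(
        samples, bin_width=bin_width, n_bootstrap=n_bootstrap,
        reference=_DW_REFERENCE, min_counts=100,
        rng=np.random.default_rng(seed + 1),
    )


def boltzmann_estimator_campaign(
    seed: int,
    n_samples: int = 8000,
    bin_width: float = 0.1,
    n_bootstrap: int = 80,
    well: DoubleWell = DoubleWell(),
) -> PMFProfile:
    """WHAM on samples drawn directly from the biased Boltzmann law (no
    dynamics) — isolates the estimator from the sampler."""
    rng = np.random.default_rng(seed)
    windows = plan_windows(n_steps=0, seed=seed, **_DW_WINDOW_KW)
    samples = [
        synthetic_window_samples(well.energy, w, n_samples, rng, -2.0, 2.0)
        for w in windows
    ]
    return wham(
        samples, bin_width=bin_width, n_bootstrap=n_bootstrap,
        reference=_DW_REFERENCE, min_counts=100,
        rng=np.random.default_rng(seed + 100),
    )


# ---------------------------------------------------------------------------
# desk-scale fixture campaigns
# ---------------------------------------------------------------------------

FIXTURE_SCALE = 1.0 / 3.0  # L = 20 nm


def fixture_campaign_settings(scale: float = FIXTURE_SCALE) -> dict:
    """Validated desk-scale campaign settings for the synthetic fixture.

    The cargo mass/friction overrides minimise the cargo-coordinate
    decorrelation time (kinetics only); the bias is stiffer than the
    plan_windows default so windows stay on station against the brush.
    """
    return dict(
        core=(0.0, 5.0 * scale),
        reference=(20.0 * scale, 27.0 * scale),
        z_top=9.0 * (scale / FIXTURE_SCALE),
        dz=0.75,
        bias_stiffness=20.0,
        n_steps=8000,
        equilibration_fraction=0.3,
        bin_width=0.25,
        chain_friction=1.0,
        # heavy enough that stiff multi-contact collisions stay stable at
        # dt = 0.02 ps (lighter cargoes blow up inside the brush), light
        # enough that windows decorrelate within ~100 steps
        window_kw=dict(cargo_mass=96.0, cargo_friction=0.2),
    )


def fixture_barrier_campaign(
    cargo_spec: CargoSpec,
    seed: int,
    scale: float = FIXTURE_SCALE,
    units_per_chain: int = 4,
    n_bootstrap: int = 12,
) -> tuple[BarrierEstimate, PMFProfile]:
    """Axial umbrella campaign for one cargo in the synthetic fixture,
    reduced to the interval-difference barrier with scaled intervals.

    By the fixture's top-bottom symmetry only z >= 0 is sampled and the core
    interval is its upper half.
    """
    cfg = fixture_campaign_settings(scale)
    geom, anchors, seqs = generate_synthetic_fixture(
        scale, seed=seed, units_per_chain=units_per_chain
    )
    ff = default_force_field()
    lang = LangevinParams(seed=seed, friction=cfg["chain_friction"])
    windows = plan_windows(
        0.0, cfg["z_top"], cfg["dz"], bias_stiffness=cfg["bias_stiffness"],
        n_steps=cfg["n_steps"], equilibration_fraction=cfg["equilibration_fraction"],
        seed=seed + 100,
    )
    factory = make_system_factory(
        geom, anchors, seqs, cargo_spec, params=ff, base_seed=seed + 7
    )
    prof, _ = axial_pmf_campaign(
        factory, windows, ff, lang, bin_width=cfg["bin_width"],
        reference=cfg["reference"], n_bootstrap=n_bootstrap,
        window_kw=cfg["window_kw"],
    )
    est = energy_barrier(prof, core=cfg["core"], reference=cfg["reference"])
    return est, prof


# ---------------------------------------------------------------------------
# cluster tier (full-scale wildtype reproduction; not desk-feasible)
# ---------------------------------------------------------------------------

def wildtype_campaign(
    cargo_spec: CargoSpec,
    seed: int,
    minimal: bool = False,
    dz: float = 1.5,
    n_steps: int = 200000,
    bin_width: float = 0.5,
) -> BarrierEstimate:
    """Full-scale axial campaign (L = 60 nm, 128 chains) with the shipped
    example anchor table and synthetic stand-in sequences.

    This is the faithful full pipeline for the paper-scale targets; it needs
    cluster-scale compute and, lacking the true yeast sequences and anchor
    coordinates, reproduces the published numbers only qualitatively.
    """
    from importlib import resources

    from . import io as fio
    from .builder import ScaffoldGeometry

    anchors = fio.read_anchor_table(
        str(resources.files("fgpore.data").joinpath("example_anchors.tsv"))
    )
    seqs = fio.read_fasta(
        str(resources.files("fgpore.data").joinpath("example_sequences.fasta"))
    )
    if minimal:
        anchors = make_minimal_variant(anchors)
    geom = ScaffoldGeometry()
    ff = default_force_field()
    lang = LangevinParams(seed=seed, friction=1.0)
    windows = plan_windows(
        -5.0, 27.0, dz, bias_stiffness=20.0, n_steps=n_steps, seed=seed + 100
    )
    factory = make_system_factory(
        geom, anchors, seqs, cargo_spec, params=ff, base_seed=seed + 7
    )
    prof, _ = axial_pmf_campaign(
        factory, windows, ff, lang, bin_width=bin_width,
        reference=(20.0, 27.0), n_bootstrap=12,
        window_kw=dict(cargo_mass=240.0, cargo_friction=0.5),
    )
    return energy_barrier(prof)


def cluster_targets(seed: int, n_steps: int = 200000) -> dict:
    """Compute the paper-scale targets t1-t5 (cluster-tier only)."""
    from .analysis import barrier_curve

    out: dict[str, dict] = {}
    g_wt = wildtype_campaign(make_inert_cargo(10.0), seed, n_steps=n_steps)
    out["t1"] = {"value": g_wt.G, "n": 128}
    g_kap7 = wildtype_campaign(
        make_kap_complex(10.0, 7, 4.94), seed, n_steps=n_steps
    )
    out["t2"] = {"value": g_kap7.G, "n": 128}
    g_kap3 = wildtype_campaign(
        make_kap_complex(10.0, 3, 1.3), seed, n_steps=n_steps
    )
    out["t3"] = {"value": g_kap3.G, "n": 128}
    g_min = wildtype_campaign(
        make_inert_cargo(10.0), seed, minimal=True, n_steps=n_steps
    )
    out["t4"] = {"value": 100.0 * (g_wt.G - g_min.G) / g_wt.G, "n": 128}
    barriers = {10.0: g_wt}
    for D in (2.0, 4.2, 6.0, 7.3):
        barriers[D] = wildtype_campaign(make_inert_cargo(D), seed, n_steps=n_steps)
    df = barrier_curve(barriers)
    out["t5"] = {"value": df.attrs["D_star"], "n": 128}
    return out
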