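"""Umbrella-sampling campaign management and WHAM unbiasing.

A campaign subdivides the reaction coordinate into overlapping harmonically
biased windows; :func:`wham` recombines the window histograms into a single
potential of mean force by self-consistent iteration, with per-bin
uncertainties from a block bootstrap over time-decorrelated blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .builder import SystemTopology
from .dynamics import ForceEvaluator, LangevinParams, Restraint, run
from .forcefield import ForceFieldParams
from .units import KBT_300

__all__ = [
    "UmbrellaWindow",
    "WindowSamples",
    "PMFProfile",
    "WhamError",
    "plan_windows",
    "run_window",
    "wham",
    "convergence_report",
    "synthetic_window_samples",
]


class WhamError(RuntimeError):
    """Raised on non-overlapping histograms or failed convergence."""


@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased window along the reaction coordinate."""

    center: float
    bias_stiffness: float
    lateral_stiffness: float = 100.0
    n_steps: int = 20000
    equilibration_steps: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias_stiffness <= 0:
            raise ValueError("bias stiffness must be positive")

    def bias_energy(self, z: np.ndarray) -> np.ndarray:
        return 0.5 * self.bias_stiffness * (np.asarray(z) - self.center) ** 2


@dataclass
class WindowSamples:
    """Reaction-coordinate time series of one window (post-equilibration)."""

    window: UmbrellaWindow
    values: np.ndarray
    drift_flag: bool = False
    #: force evaluator of the producing run (reusable by sequential campaigns)
    evaluator: object | None = None

    def histogram(self, edges: np.ndarray) -> np.ndarray:
        h, _ = np.histogram(self.values, bins=edges)
        return h


@dataclass
class PMFProfile:
    """Free energy vs reaction coordinate (kJ/mol vs nm)."""

    z: np.ndarray
    G: np.ndarray
    sigma: np.ndarray
    kBT: float = KBT_300
    bin_width: float = 0.0

    def shifted(self, region: tuple[float, float] | None = None) -> "PMFProfile":
        """Return a copy re-referenced to zero mean over ``region``.

        With no region the profile is zeroed over the top 10% of the covered
        coordinate range (the 'cytoplasmic end' convention).
        """
        ok = np.isfinite(self.G)
        if region is None:
            zs = self.z[ok]
            lo = zs.max() - 0.1 * (zs.max() - zs.min())
            sel = ok & (self.z >= lo)
        else:
            sel = ok & (self.z >= region[0]) & (self.z <= region[1])
            if not np.any(sel):
                raise ValueError(f"no populated bins inside reference region {region}")
        return PMFProfile(
            self.z.copy(), self.G - np.nanmean(self.G[sel]), self.sigma.copy(),
            self.kBT, self.bin_width,
        )

    def interp(self, z: np.ndarray) -> np.ndarray:
        ok = np.isfinite(self.G)
        return np.interp(z, self.z[ok], self.G[ok])


def plan_windows(
    z_start: float,
    z_end: float,
    dz: float,
    bias_stiffness: float | None = None,
    lateral_stiffness: float = 100.0,
    n_steps: int = 20000,
    equilibration_fraction: float = 0.2,
    kBT: float = KBT_300,
    seed: int = 0,
) -> list[UmbrellaWindow]:
    """Window centers from z_start to z_end inclusive at spacing dz.

    The default bias stiffness makes the ideal-spring positional SD equal to
    about dz/2: k = 4 kBT / dz^2.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    lo, hi = sorted((float(z_start), float(z_end)))
    n = int(np.floor((hi - lo) / dz + 1e-9)) + 1
    centers = lo + dz * np.arange(n)
    if not centers.size:
        centers = np.array([lo])
    k = bias_stiffness if bias_stiffness is not None else 4.0 * kBT / dz**2
    n_equil = int(round(equilibration_fraction * n_steps))
    return [
        UmbrellaWindow(
            center=float(c),
            bias_stiffness=float(k),
            lateral_stiffness=lateral_stiffness,
            n_steps=n_steps,
            equilibration_steps=n_equil,
            seed=seed + i,
        )
        for i, c in enumerate(centers)
    ]


def run_window(
    topology: SystemTopology,
    window: UmbrellaWindow,
    ff_params: ForceFieldParams,
    lang: LangevinParams,
    coord: str = "z",
    theta: float = 0.0,
    z_plane: float = 0.0,
    coord_every: int = 10,
    extra_potentials: tuple = (),
    force_cap: float = 1.0e4,
    evaluator: ForceEvaluator | None = None,
    cargo_mass: float | None = None,
    cargo_friction: float | None = None,
    freeze_orientation: bool = False,
) -> WindowSamples:
    """Sample one umbrella window by Langevin dynamics.

    ``coord='z'`` biases the cargo-center z with a lateral restraint holding
    it on the axis; ``coord='r'`` biases the in-plane projection along the
    direction ``theta`` (degrees) at fixed z = ``z_plane``.  The
    equilibration segment is discarded.
    """
    lang = replace(lang, seed=window.seed)
    if coord == "z":
        bias = Restraint("z", window.bias_stiffness, window.center)
        laterals = [Restraint("r", window.lateral_stiffness, 0.0)]
        extract = lambda c: c[:, 2]  # noqa: E731
    elif coord == "r":
        th = np.deg2rad(theta)
        ax = (np.cos(th), np.sin(th))
        perp = (-np.sin(th), np.cos(th))
        bias = Restraint("dir", window.bias_stiffness, window.center, axis=ax)
        laterals = [
            Restraint("dir", window.lateral_stiffness, 0.0, axis=perp),
            Restraint("z", window.lateral_stiffness, z_plane),
        ]
        extract = lambda c: c[:, 0] * ax[0] + c[:, 1] * ax[1]  # noqa: E731
    else:
        raise ValueError(f"unknown umbrella coordinate {coord!r}")

    restraints = [bias, *laterals, *extra_potentials]
    rng = np.random.default_rng(lang.seed)
    kinetic_kw = dict(
        cargo_mass=cargo_mass,
        cargo_friction=cargo_friction,
        freeze_orientation=freeze_orientation,
    )
    res = run(
        topology,
        ff_params,
        lang,
        restraints=restraints,
        n_steps=window.equilibration_steps,
        coord_every=max(1, window.equilibration_steps),
        force_cap=force_cap,
        evaluator=evaluator,
        rng=rng,
        **kinetic_kw,
    )
    res = run(
        topology,
        ff_params,
        lang,
        restraints=restraints,
        n_steps=window.n_steps - window.equilibration_steps,
        coord_every=coord_every,
        state=res.state,
        evaluator=res.evaluator,
        rng=rng,
        **kinetic_kw,
    )
    values = extract(res.centers[1:])  # drop the carried-over initial sample
    sd = values.std()
    drift = bool(abs(values.mean() - window.center) > 3.0 * max(sd, 1e-12))
    if drift:
        warnings.warn(
            f"window at {window.center:g}: sample mean {values.mean():.3g} drifted "
            f"more than 3 SD from the bias center"
        )
    return WindowSamples(
        window=window, values=values, drift_flag=drift, evaluator=res.evaluator
    )


def wham(
    samples: list[WindowSamples],
    bin_width: float = 0.2,
    tol: float = 1.0e-5,
    max_iter: int = 100000,
    kBT: float = KBT_300,
    reference: tuple[float, float] | None = None,
    n_bootstrap: int = 30,
    n_blocks: int = 50,
    min_counts: int = 5,
    rng: np.random.Generator | None = None,
) -> PMFProfile:
    """Self-consistent WHAM solution over the shared histogram grid.

    Iteration stops when the maximum change of the window free-energy
    constants drops below ``tol`` (kJ/mol).  Per-bin uncertainties come from
    a block bootstrap over ``n_blocks`` contiguous blocks per window.
    """
    if not samples:
        raise ValueError("no window samples")
    samples = sorted(samples, key=lambda s: s.window.center)
    lo = min(s.values.min() for s in samples)
    hi = max(s.values.max() for s in samples)
    n_bins = max(2, int(np.ceil((hi - lo) / bin_width)))
    if n_bins > 100_000:
        raise WhamError(
            f"histogram grid of {n_bins} bins over [{lo:.3g}, {hi:.3g}] nm — "
            "window samples look divergent (unstable sampling run?)"
        )
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    hists = np.array([s.histogram(edges) for s in samples])  # (W, B)
    for a, b in zip(samples[:-1], samples[1:]):
        ha, _ = np.histogram(a.values, bins=edges)
        hb, _ = np.histogram(b.values, bins=edges)
        if not np.any((ha > 0) & (hb > 0)):
            raise WhamError(
                f"no histogram overlap between windows at {a.window.center:g} "
                f"and {b.window.center:g} nm"
            )

    beta = 1.0 / kBT
    # bin-averaged Boltzmann factor of each bias (5-point Gauss-Legendre per
    # bin); evaluating at bin centers alone biases the profile for stiff
    # springs or wide bins
    gx, gw = np.polynomial.legendre.leggauss(5)
    zq = centers[None, :] + 0.5 * bin_width * gx[:, None]  # (Q, B)
    log_eb = np.empty((len(samples), len(centers)))  # (W, B)
    for i, s in enumerate(samples):
        log_eb[i] = np.log(0.5 * gw @ np.exp(-beta * s.window.bias_energy(zq)))

    def solve(counts: np.ndarray) -> np.ndarray:
        # fully log-space self-consistent iteration (robust to steep PMFs)
        N = counts.sum(axis=1)  # (W,)
        M = counts.sum(axis=0).astype(float)  # (B,)
        with np.errstate(divide="ignore"):
            logN = np.log(N)
            logM = np.log(M)
        bf = np.zeros(len(samples))  # beta * f_i
        for _ in range(max_iter):
            log_denom = logsumexp(
                logN[:, None] + bf[:, None] + log_eb, axis=0
            )  # (B,)
            log_p = logM - log_denom
            bf_new = -logsumexp(log_eb + log_p[None, :], axis=1)
            bf_new -= bf_new[0]
            delta = kBT * np.max(np.abs(bf_new - bf))
            bf = bf_new
            if not np.isfinite(delta):
                raise WhamError("WHAM iteration diverged (histograms too sparse?)")
            if delta < tol:
                break
        else:
            raise WhamError(f"WHAM failed to converge: residual {delta:.3g} kJ/mol")
        log_denom = logsumexp(logN[:, None] + bf[:, None] + log_eb, axis=0)
        with np.errstate(invalid="ignore"):
            g = -kBT * (logM - log_denom)
        g[M <= 0] = np.nan
        return g

    G = solve(hists)
    # bins with almost no support carry meaningless WHAM values
    G[hists.sum(axis=0) < min_counts] = np.nan

    # reference convention: zero mean over the reference region (default:
    # the top 10% of the covered coordinate range)
    ok = np.isfinite(G)
    if reference is None:
        zs = centers[ok]
        ref_sel = ok & (centers >= zs.max() - 0.1 * (zs.max() - zs.min()))
    else:
        ref_sel = ok & (centers >= reference[0]) & (centers <= reference[1])
        if not np.any(ref_sel):
            raise ValueError(f"no populated bins inside reference region {reference}")
    G = G - np.nanmean(G[ref_sel])

    # block bootstrap: every replicate is re-referenced with the same
    # convention, so sigma includes the uncertainty of the reference shift
    sigma = np.zeros_like(G)
    if n_bootstrap > 0:
        rng = rng or np.random.default_rng(0)
        reps = []
        blocks = [np.array_split(s.values, min(n_blocks, max(1, len(s.values)))) for s in samples]
        for _ in range(n_bootstrap):
            counts = np.empty_like(hists)
            for w, blks in enumerate(blocks):
                pick = rng.integers(0, len(blks), size=len(blks))
                vals = np.concatenate([blks[p] for p in pick])
                counts[w], _ = np.histogram(vals, bins=edges)
            try:
                g = solve(counts)
            except WhamError:
                continue
            reps.append(g - np.nanmean(g[ref_sel]))
        if len(reps) >= 2:
            sigma = np.nanstd(np.array(reps), axis=0)

    return PMFProfile(centers, G, sigma, kBT=kBT, bin_width=bin_width)


def convergence_report(variants: dict[str, PMFProfile]) -> pd.DataFrame:
    """Pairwise per-bin and max |delta PMF| between campaign variants.

    Profiles on mismatched grids are regridded (linear) with a warning.
    """
    if len(variants) < 2:
        raise ValueError("need at least two campaign variants")
    names = list(variants)
    ref = variants[names[0]]
    rows = []
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = variants[names[a_i]], variants[names[b_i]]
            if len(a.z) != len(b.z) or not np.allclose(a.z, b.z):
                warnings.warn(
                    f"profiles {names[a_i]!r} and {names[b_i]!r} are on different "
                    "grids; regridding"
                )
            zlo = max(a.z[np.isfinite(a.G)].min(), b.z[np.isfinite(b.G)].min())
            zhi = min(a.z[np.isfinite(a.G)].max(), b.z[np.isfinite(b.G)].max())
            grid = ref.z[(ref.z >= zlo) & (ref.z <= zhi)]
            da = a.interp(grid)
            db = b.interp(grid)
            diff = np.abs((da - da.mean()) - (db - db.mean()))
            rows.append(
                {
                    "variant_a": names[a_i],
                    "variant_b": names[b_i],
                    "max_abs_diff": diff.max(),
                    "mean_abs_diff": diff.mean(),
                    "n_bins": len(grid),
                }
            )
    return pd.DataFrame(rows)


def synthetic_window_samples(
    potential_fn,
    window: UmbrellaWindow,
    n_samples: int,
    rng: np.random.Generator,
    lo: float,
    hi: float,
    kBT: float = KBT_300,
    grid_points: int = 4001,
) -> WindowSamples:
    """Draw independent samples from the biased Boltzmann law (no dynamics).

    Inverse-CDF sampling of p(z) proportional to exp(-(U(z) + bias)/kBT) on a
    fine grid; used to test the WHAM estimator in isolation.
    """
    z = np.linspace(lo, hi, grid_points)
    u = np.asarray(potential_fn(z)) + window.bias_energy(z)
    w = np.exp(-(u - u.min()) / kBT)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    vals = np.interp(rng.random(n_samples), cdf, z)
    return WindowSamples(window=window, values=vals)
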