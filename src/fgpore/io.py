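"""File formats: FASTA sequences, PDB structures, XYZ trajectories,
delimited tables (anchors, window samples, PMFs, barriers, density maps),
and key-value parameter/config files.

Internal units are nm/ps/kJ/mol everywhere; the PDB boundary converts to
Angstrom, and that is the only unit conversion layer in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .builder import NupAnchor, SystemTopology
from .forcefield import AMINO_ACIDS
from .transport import TransportModelParams
from .umbrella import PMFProfile, UmbrellaWindow, WindowSamples
from .units import NM_TO_ANGSTROM

__all__ = [
    "FastaError",
    "read_fasta",
    "write_fasta",
    "read_anchor_table",
    "write_anchor_table",
    "write_structure",
    "read_structure",
    "write_xyz",
    "read_xyz",
    "write_bead_table",
    "write_pmf",
    "read_pmf",
    "write_window_samples",
    "read_window_samples",
    "write_campaign_manifest",
    "read_campaign_manifest",
    "write_model_params",
    "read_model_params",
    "RunConfig",
]


class FastaError(ValueError):
    pass


_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "SPT", "SCA": "SCA", "CGO": "CGO", "SPT": "SPT", "ANC": "ANC",
}

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences, validated against the 20-letter amino-acid alphabet.

    Lowercase letters are uppercased with a warning; duplicate record IDs
    and invalid residues are errors (with record name and offset).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FastaError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"record {rec.id!r}: lowercase residues uppercased")
            seq = seq.upper()
        for i, c in enumerate(seq):
            if c not in AMINO_ACIDS:
                raise FastaError(
                    f"record {rec.id!r}: invalid residue {c!r} at position {i + 1}"
                )
        out[rec.id] = seq
    return out


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as f:
        for sid, seq in sequences.items():
            f.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                f.write(seq[i : i + width] + "\n")


def read_anchor_table(path: str | Path) -> list[NupAnchor]:
    """Delimited text: nup_name, ring_z, ring_radius, copies, sequence_id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"nup_name", "ring_z", "ring_radius", "copies", "sequence_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"anchor table missing columns: {sorted(missing)}")
    return [
        NupAnchor(
            nup_name=str(r.nup_name),
            ring_z=float(r.ring_z),
            ring_radius=float(r.ring_radius),
            copies=int(r.copies),
            sequence_id=str(r.sequence_id),
        )
        for r in df.itertuples()
    ]


def write_anchor_table(path: str | Path, anchors: list[NupAnchor]) -> None:
    df = pd.DataFrame([asdict(a) for a in anchors])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# structures and trajectories
# ---------------------------------------------------------------------------

def write_structure(topology: SystemTopology, path: str | Path) -> None:
    """Export one PDB record per bead (coordinates in Angstrom).

    Chain identifiers cycle per Nup copy; scaffold, cargo and binding-spot
    beads carry the residue names SCA, CGO and SPT.  Atom numbering wraps at
    99999 (PDB fixed-width limit).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = topology.n_beads
    if n == 0:
        Path(path).write_text("REMARK   generated by fgpore (empty topology)\nEND\n")
        return
    arr = struc.AtomArray(n)
    arr.coord = topology.positions * NM_TO_ANGSTROM
    chain_ids = np.empty(n, dtype="U4")
    res_ids = np.zeros(n, dtype=int)
    chain_ids[:] = _CHAIN_IDS[0]
    res_ids[topology.scaffold_index] = np.arange(len(topology.scaffold_index)) + 1
    for k, (_, start, stop) in enumerate(topology.chains):
        cid = _CHAIN_IDS[(k + 1) % len(_CHAIN_IDS)]
        chain_ids[start:stop] = cid
        res_ids[start:stop] = np.arange(stop - start) + 1
    if topology.cargo is not None and topology.cargo.index is not None:
        idx = topology.cargo.index
        chain_ids[idx] = "z"
        res_ids[idx] = np.arange(len(idx)) + 1
    arr.chain_id = chain_ids
    arr.res_id = res_ids
    arr.res_name = np.array([_THREE_LETTER.get(c, "UNK") for c in topology.codes])
    arr.atom_name = np.full(n, "CA", dtype="U4")
    arr.element = np.full(n, "C", dtype="U2")
    arr.hetero = np.array([c in ("SCA", "CGO", "SPT", "ANC") for c in topology.codes])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_structure(path: str | Path) -> np.ndarray:
    """Read bead coordinates back from PDB, in nm."""
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(model=1)
    return arr.coord / NM_TO_ANGSTROM


def write_xyz(path: str | Path, frames: list[np.ndarray], comment: str = "") -> None:
    """Plain multi-frame XYZ (nm), one pseudo-element per line."""
    with open(path, "w") as f:
        for k, pos in enumerate(frames):
            f.write(f"{len(pos)}\n")
            f.write(f"frame {k} {comment}\n")
            for p in pos:
                f.write(f"C {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_xyz(path: str | Path) -> list[np.ndarray]:
    frames = []
    with open(path) as f:
        while True:
            line = f.readline()
            if not line.strip():
                break
            n = int(line)
            f.readline()
            pos = np.empty((n, 3))
            for i in range(n):
                parts = f.readline().split()
                pos[i] = [float(x) for x in parts[1:4]]
            frames.append(pos)
    return frames


def write_bead_table(topology: SystemTopology, path: str | Path) -> None:
    """Sidecar per-bead table (code, group, mass) for trajectory analysis."""
    pd.DataFrame(
        {"code": topology.codes, "group": topology.group, "mass": topology.mass}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PMFs, samples, campaigns
# ---------------------------------------------------------------------------

def write_pmf(path: str | Path, pmf: PMFProfile, header: str = "") -> None:
    with open(path, "w") as f:
        if header:
            for line in header.splitlines():
                f.write(f"# {line}\n")
        f.write(f"# kBT={pmf.kBT:.6g} bin_width={pmf.bin_width:.6g}\n")
        f.write("z\tG\tsigma_G\n")
        for z, g, s in zip(pmf.z, pmf.G, pmf.sigma):
            f.write(f"{z:.6f}\t{g:.6f}\t{s:.6f}\n")


def read_pmf(path: str | Path) -> PMFProfile:
    kbt, bw = None, 0.0
    for line in Path(path).read_text().splitlines():
        if line.startswith("# kBT="):
            parts = dict(p.split("=") for p in line[2:].split())
            kbt = float(parts["kBT"])
            bw = float(parts["bin_width"])
    df = pd.read_csv(path, sep="\t", comment="#")
    return PMFProfile(
        df["z"].to_numpy(), df["G"].to_numpy(), df["sigma_G"].to_numpy(),
        kBT=kbt if kbt is not None else 2.494, bin_width=bw,
    )


def write_window_samples(path: str | Path, samples: WindowSamples, dt_sample: float = 1.0) -> None:
    """Two-column text: time (ps), reaction coordinate (nm)."""
    w = samples.window
    with open(path, "w") as f:
        f.write(
            f"# center={w.center:.6g} k={w.bias_stiffness:.6g} "
            f"lateral_k={w.lateral_stiffness:.6g} seed={w.seed}\n"
        )
        f.write("time\tvalue\n")
        for i, v in enumerate(samples.values):
            f.write(f"{i * dt_sample:.4f}\t{v:.6f}\n")


def read_window_samples(path: str | Path) -> WindowSamples:
    meta: dict[str, float] = {}
    first = Path(path).read_text().splitlines()[0]
    if first.startswith("#"):
        meta = {k: float(v) for k, v in (p.split("=") for p in first[1:].split())}
    df = pd.read_csv(path, sep="\t", comment="#")
    window = UmbrellaWindow(
        center=meta.get("center", 0.0),
        bias_stiffness=meta.get("k", 1.0),
        lateral_stiffness=meta.get("lateral_k", 100.0),
        seed=int(meta.get("seed", 0)),
    )
    return WindowSamples(window=window, values=df["value"].to_numpy())


def write_campaign_manifest(
    path: str | Path, entries: list[tuple[str, UmbrellaWindow]]
) -> None:
    """Delimited text listing window sample files, centers, stiffnesses, seeds."""
    df = pd.DataFrame(
        [
            {
                "file": fname,
                "center": w.center,
                "bias_stiffness": w.bias_stiffness,
                "lateral_stiffness": w.lateral_stiffness,
                "n_steps": w.n_steps,
                "equilibration_steps": w.equilibration_steps,
                "seed": w.seed,
            }
            for fname, w in entries
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_campaign_manifest(path: str | Path) -> list[WindowSamples]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        s = read_window_samples(path.parent / str(r.file))
        s.window = UmbrellaWindow(
            center=float(r.center),
            bias_stiffness=float(r.bias_stiffness),
            lateral_stiffness=float(r.lateral_stiffness),
            n_steps=int(r.n_steps),
            equilibration_steps=int(r.equilibration_steps),
            seed=int(r.seed),
        )
        out.append(s)
    return out


def write_model_params(
    path: str | Path, params: TransportModelParams, provenance: dict | None = None
) -> None:
    """Key-value text with a provenance header (fit inputs, seed, date)."""
    with open(path, "w") as f:
        for k, v in (provenance or {}).items():
            f.write(f"# {k}: {v}\n")
        for k in ("a1", "b0", "b1", "b2", "L", "a", "kBT"):
            f.write(f"{k} = {getattr(params, k):.8g}\n")


def read_model_params(path: str | Path) -> TransportModelParams:
    vals: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, v = (s.strip() for s in line.split("="))
        vals[k] = float(v)
    return TransportModelParams(**vals)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

def write_density_map(path: str | Path, dm) -> None:
    """Dense matrix file: one-line grid-spec header, rows = r bins."""
    with open(path, "w") as f:
        f.write(
            f"# r_min={dm.r_edges[0]:.6g} r_max={dm.r_edges[-1]:.6g} "
            f"z_min={dm.z_edges[0]:.6g} z_max={dm.z_edges[-1]:.6g} "
            f"n_r={len(dm.r_edges) - 1} n_z={len(dm.z_edges) - 1} "
            f"frames={dm.frame_count} overflow_mass={dm.overflow_mass:.6g}\n"
        )
        np.savetxt(f, dm.density, fmt="%.6e", delimiter="\t")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every tunable of the pipeline, with defaults at the published values.

    Unknown keys are rejected when loading; every run should write its fully
    resolved config next to its outputs (see :meth:`dump`).
    """

    seed: int = 0
    out_dir: str = "."
    # force field
    bond_length: float = 0.38
    bond_stiffness: float = 8000.0
    eps_max: float = 5.2
    vdw_cutoff: float = 2.5
    coulomb_cutoff: float = 5.0
    debye_length: float = 0.8
    dielectric: float = 80.0
    bead_mass: float = 120.0
    rep_strength: float = 5.2
    # geometry
    pore_diameter: float = 60.0
    pore_half_height: float = 15.4
    scaffold_bead_diameter: float = 5.0
    symmetry_order: int = 8
    # dynamics
    temperature: float = 300.0
    timestep: float = 0.02
    friction: float = 50.0
    freeze_orientation: bool = False
    # umbrella
    window_spacing: float = 2.0
    bias_stiffness: float = 0.0  # 0 -> auto (4 kBT / dz^2)
    lateral_stiffness: float = 100.0
    window_steps: int = 20000
    equilibration_fraction: float = 0.2
    bin_width: float = 0.25
    n_bootstrap: int = 30
    n_blocks: int = 50
    # analysis
    core_lo: float = -5.0
    core_hi: float = 5.0
    reference_lo: float = 20.0
    reference_hi: float = 27.0
    density_dr: float = 0.5
    density_dz: float = 0.5
    # transport model
    model_L: float = 60.0
    model_a: float = 0.6
    constrain_b0_zero: bool = False

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def forcefield_params(self):
        from .forcefield import ForceFieldParams

        return ForceFieldParams(
            bond_length=self.bond_length,
            bond_stiffness=self.bond_stiffness,
            eps_max=self.eps_max,
            vdw_cutoff=self.vdw_cutoff,
            coulomb_cutoff=self.coulomb_cutoff,
            debye_length=self.debye_length,
            dielectric=self.dielectric,
            bead_mass=self.bead_mass,
            rep_strength=self.rep_strength,
        )

    def langevin_params(self):
        from .dynamics import LangevinParams

        return LangevinParams(
            temperature=self.temperature,
            timestep=self.timestep,
            friction=self.friction,
            seed=self.seed,
        )
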