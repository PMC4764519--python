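# fgpore

Coarse-grained simulation and free-energy analysis of cargo transport
through an FG-Nup-lined nanopore (an NPC-like channel).

The package implements, end to end:

- **Force field** (`fgpore.forcefield`) — a one-bead-per-amino-acid
  implicit-solvent model: harmonic bonds (0.38 nm), tabulated bending and
  torsion backbone stiffness, a hydrophobic pair potential whose well depth
  scales with the residues' hydrophobicities (maximum −5.2 kJ/mol for
  Phe–Phe and binding-spot contacts), Debye–Hückel electrostatics (shifted
  at 5 nm), and purely repulsive excluded volume for scaffold and inert
  cargo surfaces. Parameter tables are plain text and user-replaceable.
- **System builder** (`fgpore.builder`) — an eightfold-symmetric rigid pore
  scaffold of 5 nm beads, FG chains grafted at anchor rings (one fixed
  anchor bead per chain), rigid cargoes: single-bead (D ≤ 5 nm), composite
  (σ_c = 2.5 nm sub-beads at r_c = D/2 − 2.2 nm), and Kap-cargo complexes
  with F-like binding spots along a great-circle stripe. Includes the
  minimal-variant anchor filter (removal of Nup42, Nup159, Nup1, Nup60,
  Nup100, Nsp1, Nup145) and a deterministic synthetic fixture generator
  (scaled pore + FG-like sequences).
- **Dynamics** (`fgpore.dynamics`) — BAOAB Langevin integration (300 K,
  dt = 0.02 ps, friction 50 ps⁻¹ by default) with rigid-body cargo
  propagation, Verlet neighbor lists, harmonic restraints and external
  potentials. Hot loops are numba kernels.
- **Umbrella sampling + WHAM** (`fgpore.umbrella`) — window planning,
  biased sampling, a log-space self-consistent WHAM estimator with
  bin-averaged bias factors, block-bootstrap uncertainties, and
  convergence reports.
- **Analysis** (`fgpore.analysis`) — the interval-difference energy barrier
  (mean PMF over −5 < z < 5 nm minus 20 < z < 27 nm), circumferentially
  averaged (r, z) density maps, radial PMF campaigns, and
  barrier-versus-diameter curves with the kBT size-selectivity threshold.
- **Transport model** (`fgpore.transport`) — the closed form
  G(D, n) = a₁(D/L)² − (b₂X² + b₁X + b₀) with X = na/(πD); fitting from
  barrier tables, prediction, expelled/transported/trapped classification,
  and (D, n) energy maps.

## CLI

The `fgpore` command exposes the pipeline:

```sh
fgpore fixture --scale 0.33 --seed 1 --out fixture/      # synthetic pore
fgpore build --anchors fixture/anchors.tsv --sequences fixture/sequences.fasta \
    --config fixture/config.yaml --cargo-d 8 --out system.pdb
fgpore plan --start 27 --end -5 --dz 2.0 --out windows.tsv
fgpore sample --anchors ... --sequences ... --windows windows.tsv \
    --cargo-d 10 --out campaign/
fgpore wham --manifest campaign/campaign.tsv --out pmf.tsv
fgpore barrier --pmf pmf.tsv
fgpore density --xyz traj.xyz --beads beads.tsv --r-max 30 --z-min -30 --z-max 30 --out density.tsv
fgpore radial --anchors ... --sequences ... --cargo-d 10 --r-max 6 --out radial/
fgpore fitmodel --f-table f.tsv --g-table g.tsv --out model.txt
fgpore predict --params model.txt --diameter 10 --spots 7
fgpore map --params model.txt --out map.tsv
```

A small analytic-well umbrella campaign ships in
`src/fgpore/data/examples/wham/` for trying the `wham` subcommand.

## Units

nm, ps, kJ/mol, K, Da and elementary charges everywhere internally; PDB
export converts to Ångström at the format boundary only.
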