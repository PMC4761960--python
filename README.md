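# cntkit

Analysis toolkit for carbon-nanotube / protein systems: armchair nanotube
model construction, interaction fingerprinting of tube–protein
trajectories, substrate-channel occlusion statistics, and pairwise
interaction-energy / RMSD series — validated end to end on synthetic
trajectories with exactly known ground truth.

## What it does

- **`cntkit.builder`** — generates armchair `(n,n)` single-walled nanotube
  coordinates (whole translational unit cells, atoms on a cylinder about
  the z axis), attaches edge carboxylates with formal charge −1 each,
  assigns nonbonded parameters (tube carbons: ε = 0.36 kJ/mol,
  σ = 0.34 nm, uncharged), and rigidly poses the tube against a protein
  channel mouth (sidewall / end-on / sidewall-and-edge modes).
- **`cntkit.fingerprints`** — per-frame detectors for heavy-atom contacts,
  hydrogen bonds (distance + D–H···A angle), salt bridges (cationic N to
  anionic O), and π–π stacking classified as *parallel* (face-to-face) or
  *T-shape* (edge-to-face) against the local curved tube surface; plus
  per-residue contact-ratio and stacking-formation-ratio tables with a 50%
  persistence flag.
- **`cntkit.occlusion`** — channel mouths defined by lining-residue Cα
  centroids; per-frame blocked flags, persistent blocking onsets per run,
  and the duration-weighted pooled blocked fraction across runs.
- **`cntkit.energetics`** — 12-6 Lennard-Jones + Coulomb cross-group
  energy series (vacuum, plain cutoff truncation, Lorentz–Berthelot
  combination; kJ/mol and kcal/mol) and Kabsch-superposed Cα RMSD series.
- **`cntkit.synthetic`** — seeded toy trajectories with scripted stacking,
  salt-bridge, hydrogen-bond and channel-blocking events; ground truth is
  exact by construction, so every detector is testable without external
  data.
- **`cntkit.io` / `cntkit.model` / `cntkit.selection`** — PDB/GRO readers
  and writers (nm internally, Å↔nm at the PDB boundary), multi-model PDB
  trajectories (XTC/DCD via MDAnalysis when available), and a small atom
  selection language.
- **`cntkit.pipeline` / `cntkit.cli`** — YAML-config-driven orchestration
  producing a deterministic JSON report plus TSV series.

## Command line

```bash
# build the default carboxylated (12,12) tube: 7 nm target, 11 carboxyls
cntkit build --n 12 --length 7.0 --carboxyls 11 --out tube_out/

# place it against a channel mouth of a protein structure
cntkit pose --protein protein.pdb \
    --channel-lining "residue_id == 100 or residue_id == 101 or residue_id == 102" \
    --mode sidewall_facing --gap 1.0 --out posed.pdb

# run the full analysis described by a config file
cntkit analyze --config config.yaml

# synthetic ground-truth validation of all detectors (exit 0 = recovered)
cntkit validate --seed 7

# render plots from a finished analysis directory
cntkit report --report-dir out/
```

A minimal `config.yaml`:

```yaml
topology: topology.pdb
runs:
  - id: run1
    trajectory: run1.pdb        # multi-model PDB (or .xtc/.dcd)
selections:
  tube: residue_name == CNT
  carboxyl: residue_name == CBX
  protein: chain == A
channels:
  - id: 2e
    lining: residue_id == 10 or residue_id == 11 or residue_id == 12
    block_distance: 0.7
criteria:
  contact: {cutoff: 0.5}
  hbond: {da_cutoff: 0.35, dha_angle_min: 150}
output_dir: out
```

All cutoffs default to common trajectory-analysis values and are echoed
into `out/report.json`, so any figure is regenerable from the report
alone.

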