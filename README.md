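# lipidff

Force-field parameter fitting and lipid-bilayer structural analysis.

`lipidff` implements the computational machinery around an AMBER-family
lipid force-field workflow, exercised end to end on synthetic ground-truth
fixtures (no quantum-chemistry or molecular-dynamics engine required):

- **`ff_energy`** — the cosine-series torsion potential, harmonic valence
  angle, SCNB-scaled 1–4 Lennard-Jones, and the QM-vs-MM least-squares
  fitness with optimal constant-offset alignment.
- **`param_fit`** — a deterministic real-coded genetic algorithm that fits
  torsion barrier heights and discrete phases (0/180° for hydrocarbon
  torsions, 60° increments for headgroups; periodicities n = 1–5 for 1D
  scans, n = 1–3 for conformer ensembles, or retained per label), a
  brute-force grid oracle for validation, harmonic-angle scan fitting, and
  train/test overfitting reports.
- **`charges`** — ensemble averaging of per-conformer partial-charge sets
  with exact integer-net-charge enforcement and modular head/tail assembly
  validation.
- **`membrane`** — area and volume per lipid, number/electron density
  profiles, head-to-head bilayer thickness (D_HH), C–H (NMR) order
  parameters |S_CD|, X-ray and neutron scattering form factors, sterol tilt
  histograms, midplane transit-event detection (flip-flop vs transient
  visit), and melting-point extraction from heating scans.
- **`fixtures`** — seeded generators for every input class above, each with
  a ground-truth sidecar: conformer energy datasets from known torsion
  series, angle scans, charge ensembles, idealized bead bilayers with
  prescribed S_CD / D_HH / tilt statistics, logistic heating scans, and
  scripted midplane-crossing z-paths.
- **`fileio` / `cli`** — CSV/JSON dataset schemas, AMBER frcmod DIHE/ANGLE
  records, multi-model PDB and AMBER NetCDF trajectories, two-column
  profile/form-factor text, JSONL event records; all writes are atomic and
  every command leaves a provenance JSON beside its outputs.

## CLI

One umbrella command (`lipidff`) plus direct aliases:

```sh
# generate a fixture with known ground truth
simulate-fixtures --kind fit --seed 7 --out fx/            # also: angle|charges|bilayer|heating|zpaths

# fit torsions / angles
fit-torsion --dataset fx/fit.csv --phase-policy binary --periodicity ensemble \
            --pop 200 --gens 500 --seed 7 --out fitted.frcmod --report report.json
fit-angle --scan fx/scan.csv --out fitted.frcmod

# charges
avg-charges --ensemble fx/charges.csv --target-net -1 --out charges.txt

# bilayer observables
analyze apl --traj fx/traj.pdb --meta fx/meta.csv --n-lipids 64 --out apl.csv
analyze dhh --traj fx/traj.pdb --meta fx/meta.csv --out dhh.json
analyze scd --traj fx/traj.pdb --meta fx/meta.csv --pairs fx/ch_pairs.json --out scd.csv
analyze formfactor --traj fx/traj.pdb --meta fx/meta.csv --out ff.txt
analyze tilt --traj fx/traj.pdb --meta fx/meta.csv --probes fx/probes.json --out tilt.json
analyze transit --series fx/zpaths.csv --out events.jsonl

# melting point from a heating scan
melt-scan --series fx/scan.csv --window-ns 1.0 --n-lipids 128
```

## Conventions

kcal/mol, Å, degrees at API surfaces (radians internally for harmonic
forms); dihedral angles wrap modulo 360°; bilayer normal along z with z = 0
at the lipid center of mass; frames/atoms 0-indexed.
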