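# foldsense

Analysis toolkit for studying **co-translational folding defects** with
spectral FRET, arrest-peptide force profiles, and conformational free-energy
analysis — built around the case of an epilepsy-associated Trp→Arg mutation
in the calmodulin-binding helix A of a Kv7 potassium channel's calcium
responsive domain (CRD), which folds correctly in vitro yet misfolds during
translation in cells.

It is aimed at researchers who quantify protein–protein interactions and
folding in cells and want the full computational chain — from raw 32-band
emission stacks to FRET efficiencies, from construct tables to force-profile
peak calls, from angle trajectories to potentials of mean force and ensemble
ΔΔG estimates — as tested, scriptable building blocks.  Every stage can be
exercised on synthetic data with known ground truth, generated in-package.

## What it computes

- **Spectral FRET** (`spectral_fret`): non-negative least-squares unmixing of
  32×5-nm emission stacks against donor/acceptor references, integral and
  peak-ratio FRET indices, a 20–170 a.u. expression-window gate, and
  efficiency via transfer functions *E = a + b·x/(x+c)*.  Two calibrated
  presets are built in: `hek_cfp_yfp` (0.001, 1.0022, 2.11) for living-cell
  mCFP/mCitrine work and `bact_tfp_venus` (−0.9279, 1.9335, 0.6821) for
  bacterial mTFP1/mcpVenus sensors.
- **Förster theory** (`forster`): overlap integral *J = ∫f_D ε_A λ⁴ dλ*,
  Förster radius *R₀ = 0.211·(κ²n⁻⁴Q_D J)^{1/6}* Å, the efficiency–distance
  law *E = 1/(1+(r/R₀)⁶)*, and derivation of new transfer functions by
  forward simulation + nonlinear fit (R² > 0.99).
- **Conformation** (`conformation`): helix-axis/side-chain inclination
  angles from coordinates, native (N) vs tilted (T) state classification and
  populations, potentials of mean force *F(θ) = −kT·ln p(θ)* by Boltzmann
  inversion and by WHAM over umbrella windows, pairwise LJ+Coulomb
  interaction energies (12 Å cutoff), and an ensemble Metropolis ΔΔG
  protocol (50 runs × 50,000 moves, kT_mc = 1.2, ΔΔG = ΔG_mut − ΔG_WT).
- **Force profiles** (`force_profile`): full-length fraction from
  acceptor/donor peak emission, replicate-averaged profiles over tether
  libraries (default 18–50 residues), a significance rule for peak vs
  no-resolvable-peak calls, and soluble-fraction densitometry.
- **Synthetic data** (`synthetic_data`): Gaussian fluorophore spectra,
  spectral stacks at known efficiency, overdamped Langevin sampling of
  double-well angle landscapes (WT-like and mutant-like presets), umbrella
  windows, toy helix+side-chain+partner PDB structures, and arrest-peptide
  tether libraries with known peaks.

See `docs/methods.md` for the models, conventions and their limitations.

## Worked example

Run the end-to-end demo (library call or `foldsense run --seed 1 --out out/`):

```python
from foldsense import pipeline

cfg = pipeline.RunConfig(seed=1, output_dir="out")
summary = pipeline.run_demo(cfg)
```

With seed 1 this writes CSV tables, a summary plot and `summary.json`
containing (abridged):

```json
{
  "fret": {
    "transfer_function": {"a": 0.0, "b": 1.0, "c": 2.02078, "r_squared": 1.0},
    "preset_efficiency_at_zero_index": {"hek_cfp_yfp": 0.001,
                                        "bact_tfp_venus": -0.9279},
    "max_abs_efficiency_error": 0.000696
  },
  "conformation": {
    "wt":    {"population_n": 1.0,    "n_transitions": 0},
    "w344r": {"population_t": 0.6728, "n_transitions": 266},
    "wham_w344r_well_depth_difference": -0.867
  },
  "fpa": {
    "wt_plus_cam":    {"peak_call": 22,   "true_peak": 22},
    "wt_no_cam":      {"peak_call": null, "true_peak": null},
    "w344r_plus_cam": {"peak_call": null, "true_peak": 27}
  },
  "ddg": {"ddg": -56.0, "wt_binds_stronger": false}
}
```

Reading these numbers: the freshly derived transfer function recovers
simulated FRET efficiencies to <0.001 despite noise; the WT-like angle
landscape stays locked in its native orientation (zero N→T transitions)
while the mutant-like landscape populates the tilted state (67%) with
frequent transitions and a WHAM free-energy difference of −0.87 kcal/mol in
favor of T; the WT tether library shows a sharp folding-force peak at a
22-residue tether that disappears without the folding partner, and the
mutant library yields no resolvable peak; and with the mutant's bound-state
interaction term more favorable, the ensemble ΔΔG is negative — under the
convention that positive ΔΔG means stronger wild-type binding.

The same run with the same seed reproduces `summary.json` byte-for-byte.

## Command-line interface

```
foldsense simulate {spectra|stack|traj|umbrella|complex|fpa}
foldsense fret {unmix|efficiency}   --transfer {hek_cfp_yfp|bact_tfp_venus|file:...}
foldsense forster {r0|transfer}
foldsense conf {angle|classify|pmf|wham|energy|ddg}
foldsense fpa {profile|peak|solubility}
foldsense run --config demo.yaml
```

All file interfaces are plain text: CSV for spectra, trajectories, PMFs,
construct tables and profiles; multi-page TIFF or long CSV for spectral
stacks; PDB for structures; YAML for run configuration; JSON for transfer
functions and summaries.
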