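# foxptools

Quantitative analysis of domain tethering in the human transcription factor
FoxP1, for biophysicists working with ensemble and single-molecule
fluorescence and with coarse simulation trajectories.  FoxP1 tethers two
dimerization-competent domains — a leucine-zipper (ZIP) coiled coil and a
Forkhead (FKH) DNA-binding domain — through a ~90-residue disordered
linker; the package implements the complete analysis chain used to ask how
that tethering shapes dimerization, stability, DNA binding and interdomain
dynamics:

* **`thermo`** — equilibrium binding (r_obs = r_max·[P]/(K_d+[P]) plus an
  exact monomer–dimer isotherm) and linear-extrapolation chemical unfolding
  (ΔG_U(D) = ΔG_H2O + m·D) for two- and three-state monomer and dimer
  mechanisms, with closed-form fraction solvers in total-monomer units
  (K_U = 2P_t f_U²/f_N for N₂⇌2U), multi-start fitting, standard errors,
  bootstrap, and a profile-likelihood estimator for weakly identified
  summed stabilities.
* **`fluortime`** — multi-exponential lifetime fitting with analytic
  Gaussian-IRF reconvolution, Poisson MLE, F-test model selection,
  steady-state anisotropy r = (F_p−F_s)/(F_p+2G·F_s), the Perrin relation
  r_S(τ) = r₀·Σ b_i/(1+τ/ρ_i), and joint polarized-decay fits with one or
  two rotational correlation times.
* **`smburst`** — photon-stream I/O (TSV and HDF5), sliding-window burst
  search, per-burst r_G / ⟨τ⟩_F / FRET efficiency / stoichiometry, 2D burst
  histograms with Perrin overlay lines, multi-tau autocorrelation and
  3D-Gaussian FCS fitting.
* **`landscape`** — radius of gyration, dihedral-based α-helical fraction,
  2D potential of mean force over (Rg, helicity), basin detection and
  representative-frame selection from multi-model PDB / XYZ / TSV input.
* **`synthgen`** — seeded generators for every input above (titrations,
  unfolding curves, time-tagged photon streams, reaction-coordinate
  series, ideal peptide backbones), parameterized at the published FoxP1
  values.
* **`pipeline` / CLI** — declarative multi-stage runs, a fixture suite
  with a manifest of generating truths, and `foxptools` subcommands
  (`simulate`, `fit-binding`, `fit-unfolding`, `fit-decay`,
  `fit-anisotropy`, `bursts`, `fcs`, `landscape`, `run`, `make-fixtures`).

See `docs/methods.md` for the models, estimator design and the limits of
the synthetic benchmarks.

## Worked example

Generate a dimerization titration at the ZIP-lin dissociation constant
(123 nM) and fit it back:

```python
import numpy as np
from foxptools import synthgen, thermo

cfg = synthgen.GeneratorConfig(seed=1, noise_sd=0.001,
                               construct_label="ZIP-lin")
curve = synthgen.gen_titration(kd_nm=123.0, r_mono=0.12, r_dimer=0.22,
                               cfg=cfg)
fit = thermo.fit_binding(curve)
print(fit.summary())
```

```
model: binding-hyperbolic
  kd = 124.281 +/- 2.92
  r_max = 0.100106 +/- 0.0005263
  offset = 0.120303 +/- 0.000407
  reduced chi-square = 4.446e-07
```

The fitted dissociation constant (124.3 ± 2.9 nM) recovers the generating
123 nM within one standard error; `r_max` is the anisotropy change on
dimerization and `offset` the monomer anisotropy.  The same pattern runs
through every stage — unfolding curves generated at ΔG_U = 10 kcal/mol for
the 200 nM ZIP-lin dimer fit back to a median of 10.00 over 20 seeds
(typical standard error 0.3), and 10⁶-photon streams generated with a 70%
fast-rotation fraction (ρ = 0.2 ns vs 60 ns) return fitted fractions of
0.695–0.703 across seeds.

A small end-to-end demonstration lives in `examples/demo.yaml`:

```bash
foxptools run examples/demo.yaml
```

which writes per-stage TSV data, fit reports, figures and a consolidated
`metrics.json` under `runs/demo/`.

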