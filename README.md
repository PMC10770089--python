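# geompot

An equivariant **vector–scalar message-passing potential** for molecules,
built around *runtime geometry calculation*: per-atom direction units (sums
of unit vectors toward within-cutoff neighbors) whose inner products — taken
directly, or after vector rejection off an edge axis — yield the sums of
angle, dihedral-torsion and improper-angle cosines in time linear in the
edge count. A spherical-harmonics expansion extends the same trick to higher
tensor orders via the addition theorem, without Clebsch–Gordan products.

The package contains:

- `geompot.structures_io` — configuration data model, extended-XYZ and
  NPZ-archive I/O (`z`/`R`/`E`/`F` keys), cutoff neighbor lists.
- `geompot.rgc` — direction units, rejections, angle/dihedral/improper
  scalars, real spherical harmonics (l ≤ 4), plus explicit trigonometric
  enumeration oracles used to cross-validate every scalar.
- `geompot.network` — the model: embedding block, stacked message-passing
  blocks (edge-fusion graph attention, scalar-gated vector updates,
  channelwise runtime angle/dihedral/improper terms), gated equivariant
  output blocks, and heads for energy/forces, dipole magnitude, electronic
  spatial extent and generic scalars. Forces are exact negative energy
  gradients (reverse-mode autodiff via `autograd`), so the potential is
  energy-conserving by construction.
- `geompot.training` — combined MSE loss (default weights 0.05 energy /
  0.95 force), AdamW with plateau-triggered LR decay (factor 0.8) and early
  stopping, MAE evaluation.
- `geompot.md_sim` — velocity-Verlet integrator, optional Berendsen
  thermostat (default τ = 0.5 fs), interatomic distance distribution h(r).
  Units: Å, fs, amu, kcal/mol.
- `geompot.synthetic` — random clusters, analytic bonded toy potentials
  with exact energy/force labels, random rigid transforms, and the frozen
  parameter-recovery fixture used by the acceptance suite.

Everything runs on NumPy/SciPy in float64; no GPU or external data needed.

## CLI

```bash
geompot selftest                      # geometry oracle/invariance checks
geompot synth --spec spec.yaml --frames 50 --seed 7 --out data.xyz
geompot train --config run.yaml --data data.xyz --out rundir/
geompot predict --checkpoint rundir/model.npz --input mol.xyz \
                --head energy_forces --output pred.xyz
geompot md --checkpoint rundir/model.npz --initial mol.xyz --steps 2000 \
           --thermostat berendsen --temperature 300 --traj traj.xyz
geompot analyze hr --traj traj.xyz --out hr.txt
```

`run.yaml` holds two mappings, `model:` (fields of `ModelConfig`: blocks,
hidden dim, l_max ∈ {1, 2}, cutoff, RBF count, heads, improper flag, head)
and `training:` (fields of `TrainConfig`: loss weights, lr, decay factor,
patiences, epochs, seed). A toy-potential `spec.yaml` lists `bonds`
(i, j, k, r0), `angles` (i, j, k, k_theta, theta0), `dihedrals`
(i, j, k, l, k_phi, n, phi0), `atomic_numbers` and
`equilibrium_coordinates`.

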