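# spiralsort

Design and analysis toolkit for size- and density-based particle separation
in spiral inertial-microfluidic channels with rectangular cross-sections.

What it does:

- **Flow numbers** — hydraulic diameter, cross-section mean velocity,
  Reynolds number, Dean number, and the empirical Dean (secondary-flow)
  velocity for a spiral channel (`spiralsort.geometry_flow`).
- **Forces** — inertial lift (∝ a⁴), Dean drag (∝ a), and the
  density-difference centrifugal force (∝ a³), plus the focusing ratio
  `R_f = F_L / F_D` and the dense-particle balance `F_L = F_D + F_c`
  (`spiralsort.forces`).
- **Focusing thresholds** — four threshold models built on the criterion
  `a/x ≥ 0.07`: TM1 (`x = D`), TM2 (`x = h`), TM3 (`x = (D+3h)/4`), and the
  density-aware TM4 (`a/D ≥ 0.07c` with `c = 0.127ρ + 0.867`, ρ in g/ml,
  valid 1.05–2.75 g/ml), with two-point/least-squares calibration of the
  coefficient line (`spiralsort.thresholds`).
- **Averaging test** — bisection refinement of a focusing threshold from
  replicate highest-recovery-rate (hPRR) measurements, using a one-sided
  Welch t-test as the narrowing decision (`spiralsort.averaging_test`).
- **Sorting surrogate + PRR** — a reduced-order outlet simulator (threshold
  decision plus a monotone placement map; no CFD) and particle-recovery-rate
  analytics over outlet count tables (`spiralsort.sorting_sim`).
- **Synthetic populations & I/O** — seeded generators for regular
  microspheres and irregular powders (±2 µm size bins, circularity uniform on
  [0.1, 1]), replicate hPRR generators, and strict CSV/YAML I/O
  (`spiralsort.synthetic_io`).

## CLI

All quantities carry inline units (`1.7ml/min`, `21um`, `2.75g/ml`). Without
`--config`, the built-in reference device (500 µm × 220 µm, 5 outlets, water)
is used; see `examples/device.yaml` for the config schema.

```bash
spiralsort flow --config examples/device.yaml --flow-rate 1.7ml/min --json
spiralsort forces --flow-rate 1.7ml/min --diameter 21um --density 1.05g/ml --radius 4mm
spiralsort threshold --model TM4 --density 2.75g/ml --json
spiralsort calibrate --anchors anchors.csv --out dcm.json
spiralsort avgtest --low 15um --high 21um --measurements prr.csv \
    --reference-diameter 21 --tol 0.5um
spiralsort generate --n 300 --diameter 21 --density 1.05 --shape regular \
    --distribution fixed --seed 1 --out pop.csv
spiralsort simulate --population pop.csv --flow-rate 1.7ml/min --seed 42 --out counts.csv
spiralsort prr --counts counts.csv
```

File formats (CSV, comma-delimited, headers required):
`outlet,count` for count tables; `diameter_um,density_g_per_ml,circularity`
for populations; `diameter_um,replicate,outlet,hprr_percent` for hPRR
replicate tables; `density_g_per_ml,c` for calibration anchors.

## Conventions

- Internal unit system is SI; config files and CLI flags declare units
  explicitly and are converted once, on load.
- Lateral positions are fractions of channel width, 0 at the outer wall and
  1 at the inner wall; outlet indices increase toward the inner wall; outlet
  bins are half-open `[k/n, (k+1)/n)` with the last bin closed.
- Every stochastic operation takes an explicit seed; there is no hidden
  global RNG state.
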