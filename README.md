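# tpmbend

Local DNA bend-angle measurement from tethered particle motion (TPM) data.

A bead tethered to a surface by a single DNA molecule explores an excursion
cloud whose in-plane amplitude reports the DNA's effective length.  A local
bend — intrinsic to the sequence (phased A-tracts) or induced by a bound
protein — shrinks that amplitude in a way a kinked worm-like-chain (WLC)
model predicts in closed form.  This package implements the full analysis
chain plus the simulation and synthetic-data machinery needed to validate
it end to end:

- **`tpmbend.wlc`** — kinked-WLC mean-squared end-to-end distance, the
  reduced fitting form `R(θ) = D·sqrt(1 + c·cosθ)` with the coefficient
  computed from geometry, the single-site angle inversion (with cosine
  clamping at saturation), a detection-floor calculator, and the
  heterogeneous (stiff-insert) WLC with its persistence-length solver.
- **`tpmbend.corrections`** — camera blur correction, the minimal bead
  correction `R_DNA = sqrt(1.5·R∥² − R_p²)`, the transcendental
  excursion-number (Segall) correction, and batch table correction with
  first-order uncertainty propagation.
- **`tpmbend.bendfit`** — multi-start nonlinear least squares of bend series
  (R_DNA vs number of phased inserts) for D, θ₁ and optionally an intrinsic
  offset θ₀; per-insert angles via the single-site inversion.
- **`tpmbend.simulate`** — equilibrium Metropolis Monte Carlo of a
  wall-tethered discrete semiflexible chain with an imposed local bend and a
  reporter bead (rigid or swivel mount), numba-accelerated, validated
  against freely-jointed and discrete-WLC closed forms.
- **`tpmbend.trajectory`** — reduction of raw 2D bead trajectories: anchor
  and drift estimation, windowed amplitude of motion, exposure-aware
  correlation-time fitting, blur correction, asymmetry-factor quality
  filtering.
- **`tpmbend.synthetic`** — exact-discretisation Ornstein–Uhlenbeck bead
  trajectories with camera blur and drift, and bend-series tables, all with
  ground-truth sidecars.
- **`tpmbend.datasets`** — the packaged published measurement table for the
  575 bp construct series (8 constructs, 0–7 phased inserts).

## Command line

```sh
tpmbend correct table.csv --method minimal --bead-radius 150
tpmbend fit-series series.csv --with-theta0
tpmbend invert-angle --r-bent 229 --r-straight 249 --contour-bp 1943 --bend-bp 301
tpmbend detection-floor --rel-change 0.02
tpmbend simulate --thetas 0,60,120,180 --sweeps 20000 --out sweep.csv
tpmbend process-traj trajectories.csv
tpmbend synth --kind trajectory --out traj.csv --truth-out truth.json
tpmbend benchmark          # recompute every published benchmark value
```

A flat YAML config (`--config file.yaml`) can supply defaults
(`contour_length_bp`, `bend_position_bp`, `persistence_length_bp`,
`rise_nm_per_bp`, `bead_radius_nm`, `exposure_ms`, `method`); flags
override config.

## Notes

- Lengths are nm internally; base-pair inputs convert at 0.34 nm/bp.
  The default persistence length is 150 bp (51.0 nm).
- Angles are degrees at every public interface.
- The Segall correction is implemented exactly as its printed equation;
  for these parameter ranges it returns smaller distances than the minimal
  correction, so the minimal method is the default.
- The simulator's bead mount is configurable: `rigid` (bead along the last
  bond, bead–wall overlap rejected; the default) or `swivel` (independent
  bead orientation).  The swivel mount without bead–wall coupling realises
  the statistical independence the minimal correction assumes and is used
  to validate the correction + fit protocol against simulation.
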