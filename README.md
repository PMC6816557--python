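# ecmflock

A two-layer, nematic Vicsek-type model of how migrating fibroblasts create —
and are guided by — the extracellular matrix (ECM), together with the image
metrics needed to quantify the tissue-scale patterns that emerge.

## The scientific problem

Fibroblasts deposit, degrade and rearrange collagen/fibronectin fibers, but
the fibers they lay down also steer their subsequent migration (contact
guidance). This two-way coupling makes it hard to reason experimentally
about how mesoscale matrix topologies — aligned tendon-like bundles, dermal
swirls, corralled high-density tracts, diffuse isotropic meshworks — arise
and interconvert. `ecmflock` is for computational biologists and tissue
modellers who want a minimal agent-based sandbox for that feedback loop.

## The model

Cells are self-propelled 4-bead rods (head *r*, two body beads 2*r*, tail
*r*; aspect ratio 3:1) on a continuous periodic domain. Cell *i* has heading
θᵢ(t), constant speed sᵢ, and updates synchronously:

- **Persistence / noise** — a unit vector along θᵢ + η with
  η ~ N(0, Var(η)), weight w_p = 1 − w_c − w_m.
- **Cell-cell guidance** — the mean heading of contacting cells, each folded
  nematically (θ or θ + π, whichever is within π/2 of θᵢ), weight w_c; zero
  with no contacts.
- **Matrix guidance** — beneath each cell's head lies a grid point holding
  fiber counts in 8 apolar orientation bins spanning [0, π). A bin is drawn
  with probability proportional to its count (Gillespie selection) and the
  cell flocks with the bin's left bound, nematically folded; weight w_m
  (zero over bare substrate, optionally scaled by a fiber-density ramp f(d)
  with f(5) = 0 and f(10) = 1).

The new heading is atan2 of the renormalized weighted sum. The cell then
deposits fibers into the bin of its new heading (deposition rate), depletes
all bins (degradation rate) and pulls fibers from the two neighbouring bins
into its own (rearrangement rate), and finally advances by sᵢ·v_e, where
v_e = 0.25 if its head bead overlaps another cell (inner 75% of combined
radii) and 1 otherwise.

Five metrics quantify a matrix: long- and short-range alignment **LRA** /
**SRA** (1 − D̄/(π/2), where D̄ is the mean over fibers of the weighted
median acute angle to fibers within 200 µm / 20 µm; 1 = aligned, 0.5 =
isotropic), **HDM** (% pixels above an intensity threshold), **Curv** (mean
absolute turning angle along skeletonized fiber paths, degrees per sampling
window), and **Frac** (box-counting fractal dimension of the fiber mask).

## Worked example

Four phenotypes, seven simulated days, 800 cells on 1 mm², deposition rate 1:

```python
from ecmflock import SimulationParams, initialize, compute_metric_set
from ecmflock.params import noise_variance_from_eta

for label, eta, wm in [("quiet cells, no feedback ", 0.0, 0.0),
                       ("quiet cells, feedback 0.2", 0.0, 0.2),
                       ("noisy cells, no feedback ", 0.14, 0.0),
                       ("noisy cells, feedback 0.2", 0.14, 0.2)]:
    params = SimulationParams(noise_variance=noise_variance_from_eta(eta),
                              w_c=0.03, w_m=wm, rng_seed=42)
    sim = initialize(params)
    sim.run()
    m = compute_metric_set(sim.grid)
    print(f"{label}  LRA={m.lra:.2f} SRA={m.sra:.2f} HDM={m.hdm:4.1f}% "
          f"Curv={m.curv:4.1f} deg Frac={m.frac:.2f}")
```

prints

```
quiet cells, no feedback   LRA=0.66 SRA=0.67 HDM=23.1% Curv= 9.3 deg Frac=1.70
quiet cells, feedback 0.2  LRA=0.62 SRA=0.85 HDM=27.0% Curv= 9.9 deg Frac=1.77
noisy cells, no feedback   LRA=0.50 SRA=0.51 HDM= 5.4% Curv=13.5 deg Frac=1.80
noisy cells, feedback 0.2  LRA=0.61 SRA=0.74 HDM=24.7% Curv= 9.7 deg Frac=1.71
```

Read: quiet cells align through cell-cell guidance alone (LRA ≈ SRA); adding
matrix feedback turns their pattern swirl-like (SRA stays high, LRA drops);
noisy cells deposit an isotropic mesh (everything near the 0.5 baseline,
high curvature), but matrix feedback corrals even them into locally aligned,
dense tracks — the feedback loop, not intrinsic persistence, generates the
short-range order.

A command-line surface wraps the same library (`ecmflock simulate`, `sweep`,
`metrics`, `remodel`, `calibrate`, `fixtures`); every run directory gets a
`manifest.json` and is bit-reproducible under `--seed`.

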