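# smlmdiff

Single-molecule diffusivity and membrane-lesion kinetics analysis for
SMLM/TIRF single-particle-tracking experiments — built around the question of
how caveolae (Caveolin/Cavin-scaffolded plasma-membrane invaginations)
respond to membrane wounding.

The package is aimed at biophysicists analyzing sparse-photoactivation
localization data (PALM-style movies, ~30 ms frames, ~30 nm localization
precision) together with confocal intensity time-lapse data of the lesion
site. It covers the full chain:

1. **Localization & filtering** — sub-pixel 2-D Gaussian spot fitting; quality
   rules reject spots with fitted SD < 109 nm (one camera pixel) or
   localization precision > 70 nm.
2. **Trajectory linking** — frame-to-frame optimal assignment within a 500 nm
   search radius, no gap closing, minimum 5 frames.
3. **Diffusion estimation** — per-trajectory mean square displacement

   MSD(t) = ⟨(x_{i+n} − x_i)²⟩ + ⟨(y_{i+n} − y_i)²⟩ = 4·D·t + 4·σ²_loc,
   t = n·Δt,

   fit by linear regression with offset over lags n = 1 … L−4 for
   trajectories of at least L = 9 frames; D = |slope|/4 (the modulus keeps
   near-immobile molecules whose noisy slope comes out negative), analyzed as
   D̃ = log₁₀(D / 1 µm²s⁻¹).
4. **Mixture decomposition** — area-normalized D̃ histograms (bin width 0.2)
   fit globally across conditions with sums of log-Gaussians,

   PDF(D̃) = Σⱼ fⱼ/(σ̃ⱼ√2π) · exp[−(D̃ − D̃ⱼ)²/(2σ̃ⱼ²)],

   sharing centers D̃ⱼ and the common width σ̃ between datasets so only the
   fractional populations fⱼ differ; plus peak-diffusivity (D_pk) extraction
   and population-shift bookkeeping.
5. **Spatial profiles** — trajectories grouped into 2 µm annuli around the
   lesion (outer radii 2–10 µm), geometric-mean D per annulus, exponential
   D(r) = D₀·e^(−r/r₀) + D∞ and linear distance fits.
6. **Intensity kinetics** — background subtraction and biexponential
   photobleaching correction, I(t) = (I_raw(t) − BG)/BL(t) with
   BL(t) = A·e^(−t/τ₁) + (1−A)·e^(−t/τ₂); trace normalization and
   Z-line/sarcolemma ratios.
7. **Statistics** — two-sided Fisher exact test for 2×2 survival tables,
   Welch t-tests with Holm step-down adjustment.
8. **Synthetic data** — a seeded generator for localization tables, rendered
   TIFF frame stacks and intensity traces (Brownian populations, localization
   noise, geometric photobleaching-limited track lengths, lesion-centered
   diffusivity gradients), so the entire pipeline is testable without
   microscope data.

## Worked example

Simulate a before/after-lesioning experiment in which a third of an immobile
population mobilizes, run the analysis chain, and decompose both diffusivity
distributions in one global fit:

```python
import numpy as np
from smlmdiff import (PopulationSpec, SimulationConfig, simulate_trajectories,
                      filter_localizations, link_trajectories, estimate_all,
                      build_pdf, fit_mixture_global, population_shift,
                      fisher_exact_2x2)

conditions = {"before": [0.85, 0.05, 0.10], "after": [0.55, 0.25, 0.20]}
D_true = [0.001, 0.02, 0.3]  # um^2/s
pdfs = []
for i, (label, fractions) in enumerate(conditions.items()):
    cfg = SimulationConfig(
        populations=[PopulationSpec(d, f) for d, f in zip(D_true, fractions)],
        sigma_loc=30.0, dt=0.03, mean_track_len=8.0,
        n_molecules=30_000, fov=(30.0, 30.0), n_frames=6_000, seed=10 + i)
    locs, _ = simulate_trajectories(cfg)
    trajs = link_trajectories(filter_localizations(locs), 500.0, min_len=5)
    est = estimate_all(trajs, dt=0.03)
    pdfs.append(build_pdf(est["D_log"].to_numpy(), label=label))
    print(f"{label}: {trajs.traj_id.nunique()} trajectories, "
          f"{len(est)} eligible for MSD analysis")

model = fit_mixture_global(pdfs, J=3, seed=0)
print("shared centers (log10 D):", np.round(model.centers[0], 2))
print("shared width:", round(model.widths[0, 0], 2))
for d, label in enumerate(model.labels):
    print(f"{label} fractions: {np.round(model.fractions[d], 2)}")
shift = population_shift(model.fractions[0], model.fractions[1])
print(f"population 1 lost {shift['loss_pop1_pct']:.0f}% of itself; "
      f"{shift['gain_pct'][2]:.0f}% went to population 2")
print(f"survival: Fisher exact p = {fisher_exact_2x2([[9, 0], [8, 9]]):.3f}")
```

Output:

```
before: 17914 trajectories, 9720 eligible for MSD analysis
after: 17922 trajectories, 9719 eligible for MSD analysis
shared centers (log10 D): [-2.86 -1.69 -0.6 ]
shared width: 0.49
before fractions: [0.88 0.01 0.12]
after fractions: [0.6  0.22 0.18]
population 1 lost 32% of itself; 24% went to population 2
survival: Fisher exact p = 0.009
```

Reading the numbers: the three log-Gaussian components sit where the
generator put its populations (apparent centers are shifted slightly left of
log₁₀ D_true — an intrinsic property of short-trajectory MSD estimates, see
`docs/methods.md`), the immobile fraction drops from 0.88 to 0.60 after
lesioning, and the population-shift summary expresses the change relative to
the pre-lesion immobile pool. The Fisher line is the survival comparison of
wounded wild-type (9 alive / 0 dead) versus mutant (8 alive / 9 dead) cells,
p = 0.009.

The same chain is available from a shell:

```sh
smlmdiff simulate --n-molecules 30000 --fov 30 --out locs.csv
smlmdiff filter   --in locs.csv --out locs.f.csv
smlmdiff link     --in locs.f.csv --radius 500 --min-len 5 --out trajs.csv
smlmdiff msd      --in trajs.csv --dt 0.03 --out D.csv
smlmdiff fitpdf   --in D.csv --j 3 --share centers,width --out model.txt
smlmdiff spatial  --in D.csv --center 15,15 --fit exp,linear --out profile.csv
smlmdiff survival --table 9,0,8,9
smlmdiff run      --config pipeline.cfg     # all stages, one seed, one run dir
```

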