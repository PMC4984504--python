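# divetrace

Analysis of deep-diving ("mesopelagic excursion") behaviour from archival-tag
depth/temperature time series — built for biologging researchers working with
pop-up satellite archival tag (PSAT) records of epipelagic predators such as
oceanic whitetip sharks.

Pelagic sharks carrying 2-min archival tags spend ~90% of their time in the
upper 100 m but occasionally dive far beyond the 200 m epipelagic boundary.
`divetrace` turns a raw depth/temperature record stream into an analysis of
those excursions:

- **Detection.** A mesopelagic excursion (ME) is a maximal run of ≥5
  consecutive records strictly below the 200 m isobath, bounded on both sides
  by a record above 200 m (the bounding records are the excursion's start and
  end, so every ME spans ≥7 records). Records at exactly 200.0 m neither
  extend nor bound a run.
- **Annotation.** Each ME gets a diel period (dawn/day/dusk/night from solar
  altitude), lunar-phase quarter, date, daily SST (per-date maximum recorded
  temperature), and an oxygen-minimum-zone class — `none`, `apex_within`
  (O₂ ≤ 3.5 mL/L at maximum depth), or `passed_through` (crossed the OMZ into
  oxygen-rich water).
- **Shape clustering.** Each ME splits at its apex into a descent and an
  ascent; profiles are standardized (time and depth each mapped to [0, 1],
  resampled to P = 20 points) and clustered by k-means with Euclidean
  distance, with an R²-versus-k table for choosing the cluster count.
- **Transition-point ascents.** A continuous two-segment piecewise-linear
  ("broken-stick") regression, `depth(t) = b₀ + b₁t + b₂(t − c)₊`, is profiled
  over the change point `c`; the transition point is the first record strictly
  after the estimate, and a 95% CI comes from inverting the Gaussian profile
  likelihood.
- **Statistics.** ME frequency is modelled with negative-binomial (NB2)
  regression with a log exposure offset and a per-individual Gaussian random
  intercept (maximum likelihood by Gauss–Hermite quadrature; analysis-of-
  deviance χ² for factors). Dive characteristics use Box–Cox transformed
  linear mixed models with Tukey-style single-step pairwise contrasts and
  compact letter displays; pre-ME temperature windows are compared against
  random non-ME windows that avoid every ME ± 1 h.
- **Synthetic tracks.** A simulator generates tag series with known
  ground-truth excursions (shape classes, change points, segment slopes),
  a thermocline temperature profile and an OMZ band, so every stage is
  testable without field data.

## Worked example

```python
import numpy as np
from divetrace import *

cfg = SimulationConfig(n_individuals=4, days=30, seed=42, me_rate_per_day=0.5)
series, truths = simulate_track(cfg)

excs = []
for s in series:
    excs.extend(detect_excursions(s))
annotate_excursions(excs, 24.12, -75.28, oxygen=EnvironmentModel())
print("excursions:", len(excs), "of", len(truths), "simulated")

e = excs[0]
print(f"first ME: {e.start_time:%Y-%m-%d %H:%M} UTC, max depth {e.max_depth:.1f} m, "
      f"min temp {e.min_temperature:.2f} C, duration {e.duration_min:.0f} min, "
      f"{e.diel_period}/{e.lunar_phase}, OMZ class {e.omz_class}")

descents, ascents = zip(*[split_phases(e) for e in excs])
Xa = np.array([standardize_profile(a) for a in ascents])
model = fit_kmeans(Xa, k=3, seed=0)
print("ascent clusters:", np.bincount(model.assignments), "R2=%.3f" % model.r_squared)

tpa = [a for a, lab in zip(ascents, model.assignments) if lab == 1 and len(a.depth) >= 5]
fit = fit_broken_stick(tpa[0])
idx, depth, temp, t = transition_point(fit, tpa[0])
```

prints

```
excursions: 63 of 63 simulated
first ME: 2012-05-01 02:02 UTC, max depth 436.5 m, min temp 11.10 C, duration 32 min, night/first_quarter, OMZ class none
ascent clusters: [33 19 11] R2=0.941
```

All 63 simulated excursions are recovered exactly (the detector's recall and
precision on simulator output are both 100% by construction). Three ascent
clusters explain 94% of standardized shape variation here; cluster sizes are
reported largest-first (cluster 1 is the most common shape). The broken-stick
fit on one transition-point ascent estimates the change point at 343 s after
the apex (95% CI 335–352 s) with segment velocities −0.50 and −0.09 m/s: a
fast initial climb that slows abruptly at the transition record (360 s,
263.1 m, 15.3 °C).

The same analysis runs end-to-end from a shell:

```sh
divetrace simulate --seed 42 --out tracks/
divetrace detect tracks/sim*.csv --out me_table.csv
divetrace run --out results/        # full pipeline with manifest + figures
```

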