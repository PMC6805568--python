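# pengmove

Movement, dive-mode, habitat and orientation analysis for satellite-tracked
penguins — with a synthetic Argos study generator so the whole pipeline is
testable offline.

The package re-implements the analysis chain used to study how juvenile
king penguins (*Aptenodytes patagonicus*), tracked from their natal colony
in the Crozet Archipelago alongside non-breeding adults, disperse, forage
and orient during their first year at sea. Tags deliver Argos locations
(~14.5/day, with occasional extreme errors) and dive summaries on a
1-day-ON / 2-days-OFF duty cycle (~55 dives per recording day). From these
the pipeline answers three questions: *where do the birds go* (track
filtering, movement phases, winter range), *what are they doing* (traveling
vs foraging dive modes), and *what drives those choices* (habitat models,
orientation relative to wind and current).

## The methods at its core

- **Speed filter.** Fixes implying travel above v_max = 14 km h⁻¹ are
  removed iteratively (McConnell-style RMS-over-neighbors scoring;
  endpoints exempt; deterministic tie-breaking).
- **NSD segmentation.** Daily net squared displacement
  NSD(d) = gc(x_d, x_0)², segmented by a 3-state Gaussian HMM on √NSD
  (EM + Viterbi): two low-variance encamped states (summer / winter
  residency) and a high-variance transit state. State-2 days binned on a
  1°×1° grid give the winter range; a PCA summarizes its environmental
  variability.
- **Dive modes.** Hourly means of (depth, duration, surface interval,
  travel speed), standardized, clustered with Manhattan distance + UPGMA
  linkage (with the HCPC-style k-means consolidation pass), cut at k = 3;
  the fastest cluster is the traveling mode, the rest foraging.
- **Habitat model.** logit P(foraging) = Σⱼ fⱼ(envⱼ) + f₂(x, y) +
  year + stage + season + b_individual, with cubic regression-spline
  smooths with shrinkage, a tensor smooth on Lambert-azimuthal-equal-area
  coordinates, and ridge-block random intercepts; penalized IRLS with
  Laplace-approximate-ML smoothing selection; exhaustive AIC dredge with
  the ΔAIC > 2 rule.
- **Orientation.** 12-h re-interpolated headings vs flow direction;
  angular differences binned into downstream [315°, 45°], upstream
  [135°, 225°] and cross (the rest); binomial random-intercept GLMMs
  (adaptive Gauss–Hermite) with Bonferroni pairwise letters; upstream
  choice modeled against CHLA at t and t+1.

## Worked example

```python
from pengmove.simulate import SimConfig, simulate_dataset
from pengmove.filtering import filter_dataset
from pengmove.nsd import daily_mean_locations, compute_nsd, fit_latent_states, decode_states

cfg = SimConfig(seed=1, n_juveniles=3, n_nonbreeders=1)
tracks, dives, env, manifest = simulate_dataset(cfg)
print(f"{len(tracks)} fixes, {len(dives)} dives from {tracks.id.nunique()} individuals")

filt, rep = filter_dataset(tracks, vmax=14.0)
print(f"speed filter removed {rep.n_removed}/{rep.n_input} fixes "
      f"({100 * rep.removed_fraction:.1f}%)")

series = compute_nsd(daily_mean_locations(filt[filt.id == "J01"]))
model = fit_latent_states(series, seed=1)
states = decode_states(model, series)
print("days per state:", states.state.value_counts().sort_index().to_dict())
```

prints

```
13305 fixes, 16919 dives from 4 individuals
speed filter removed 693/13305 fixes (5.2%)
days per state: {1: 88, 2: 83, 3: 39}
```

The 5.2% removal reflects the generator's 5% planted outlier rate (plus a
handful of jitter-induced removals); the decoded state sequence recovers
the planted itinerary of this bird — an ~88-day summer encampment near the
colony, a ~39-day directed transit, and an ~83-day winter residency far
away.

The same stages are available from the shell, each reading and writing
files so any stage can be rerun independently:

```
pengmove simulate --seed 1 --out study/
pengmove filter --vmax 14 --in study/tracks.csv --out study/tracks_filtered.csv --report study/report.json
pengmove segment --in study/tracks_filtered.csv --out study/nsd_states.csv --seed 1
pengmove modes --dives study/dives.csv --tracks study/tracks_filtered.csv --out study/hourly_modes.csv
pengmove run-all --seed 1 --out study/       # everything, end to end
```

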