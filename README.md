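# numaniso

Construction and analysis toolkit for radially vs. tangentially arranged
disc displays in numerosity-estimation experiments.

Peripheral vision interferes more strongly with items arranged along the
fixation axis (radially) than perpendicular to it (tangentially). This
package builds stimulus displays that manipulate that anisotropy and runs
the accompanying statistical pipeline, end to end and fully offline:

- **geometry** — eccentricity-scaled elliptical interference zones (one
  radial, one tangential per base disc), membership and overlap predicates
  backed by a 64-vertex polygon approximation.
- **generator** — packs base discs by rejection sampling under
  zone-non-overlap constraints, allocates single/pair/triplet
  configurations (`percent_pairs` ∈ {0, 25, 50, 75, 100} or all-triplet
  mode), samples flankers inside the designated zone (never in the central
  overlap lens), and assigns contrast polarity (uniform dark/light or
  mixed: dark bases, light flankers).
- **properties** — the five matching covariates: mean eccentricity, mean
  nearest-neighbor spacing, convex-hull area, occupancy area, density.
- **matcher** — generates radial/tangential display pools and greedily
  pairs them at equal numerosity in z-scored property space under a
  standardized-mean-difference cap.
- **observer** — synthetic participants: session designs (300 main + 30
  subitizing control trials for the single-range experiments; 6×80 and
  8×144 block designs for the others; reference numerosities at the block
  mean × {0.75, 0.875, 1, 1.125, 1.25}) and a generative response model
  with contrast-coded fixed effects, participant random intercepts and
  arrangement slopes, central-tendency pull, and invalid-response noise.
- **analysis** — participant screening (>5% invalid responses or <90%
  control accuracy excluded), deviation scores (response − true
  numerosity), ±0.5 simple contrast coding, linear mixed models
  (statsmodels MixedLM; REML for estimates, ML for likelihood-ratio
  tests), cross-experiment comparisons with simple or sum coding, and
  simulation-based power with exact binomial CIs.

## CLI

```bash
numaniso generate --arrangement radial --percent-pairs 50 --n 5 \
    --seed 1 --out pool.json --render imgs/
numaniso properties pool.json --out props.csv
numaniso match --percent-pairs 50 --n-per-arrangement 50 --seed 1 --out match.json
numaniso simulate --experiment 1a --participants 10 --seed 1 --out trials.csv
numaniso analyze trials.csv --outdir analysis/
numaniso power --experiment 1a --participants 15 --reps 200 --seed 1 --out power.json
numaniso run --config config.yaml --outdir run/   # full pipeline + manifest
```

Displays are JSON (degrees of visual angle, fixation at the origin), trial
tables are long-format CSV (empty response cells mark invalid responses),
and renderings use the experiment palette (#B6B6B6 background, #000000 /
#FFFFFF discs, 0.04°/pixel).

## Notes on calibration

Zone extents default to 0.25 × eccentricity radially and 0.1 ×
eccentricity tangentially on *each side* of a disc (full axes 0.5/0.2 ×
eccentricity); with the default small field (21.5° × 13.5°, 4° fixation
exclusion) base packing saturates at 17–22 discs. `GeneratorConfig`
exposes every constraint (zone factors, field size, containment flag,
failure budget) if you need a different regime.
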