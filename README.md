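# whalemove

Behavioural analysis of satellite-tracked whale migrations, built as a
reusable, tested pipeline. Given irregular Argos locations of migrating
whales, the package:

1. **regularizes** each track to 6-h location estimates with uncertainty,
   using a first-difference correlated random walk state-space model
   (x_t = x_{t-1} + γ(x_{t-1} − x_{t-2}) + η_t) fitted by exact
   linear-Gaussian maximum likelihood, with irregular fixes tied to the grid
   by interpolation weights and per-Argos-class error SDs;
2. **extracts** step speeds (km h⁻¹) and turning angles, restricted to the
   Southern Ocean (south of 36°S);
3. **fits** 2-state hidden Markov models — gamma step-speed and wrapped
   Cauchy turning-angle emissions for *transit* vs *resident* behaviour —
   in four configurations that let sex (female/male/unknown) enter the
   movement parameters and/or the transition probabilities, selecting among
   them by AIC;
4. **pools** estimates across m track realizations drawn from the
   state-space smoothing distribution (multiple imputation, Rubin's rules
   on the link scale) to propagate location uncertainty into 95% CIs;
5. **summarizes** spatial usage per whale: maximum displacement from the
   tagging site, total track distance, percent of locations decoded
   resident, counts per Southern Ocean management area (CCAMLR statistical
   areas, IWC areas, proposed MPA), arrival times; and grids historical
   catch records at 1×1°.

Because the original telemetry lives in a non-public database, the package
includes a first-class synthetic generator (Markov state switching, gamma /
wrapped-Cauchy movement on the sphere, Argos-class noise at irregular times
with dropout) whose defaults are the study conditions, so the whole chain is
testable against known ground truth. The published per-whale summary table
is packaged as a fixture. See `docs/methods.md` for the full model account.

Audience: movement ecologists and biologging analysts who want a
self-contained Python implementation of this analysis pattern
(state-space filtering → HMM with covariates → MI pooling → management-area
summaries).

## Worked example

Simulate twelve Argos-observed tracks and run the full pipeline with a
desk-scale configuration (m = 10 imputations, restricted restarts):

```sh
whalemove simulate --n-tracks 12 --n-steps 425 --seed 1 --out obs.csv
cat > cfg.yml <<EOF
m_realizations: 10
n_restarts: 2
seed: 1
EOF
whalemove -v run-all --obs obs.csv --config cfg.yml --outdir out/
```

which logs the per-configuration comparison (output of the command above):

```
INFO whalemove: config 1: loglik=-16046.07 aic=32112.14
INFO whalemove: config 2: loglik=-15963.31 aic=31954.62
INFO whalemove: config 3: loglik=-15304.32 aic=30660.64
INFO whalemove: config 4: loglik=-15303.36 aic=30666.71
best config 3; 5112 filtered locations
```

— the sex-on-movement configuration (3) wins the AIC comparison, as it
should when movement parameters genuinely differ between sexes, and the
~5100 filtered locations match the scale of the original dataset. `out/`
then contains the regularized tracks, the step/turn series, all four fits
(`hmm_fits.json`), the pooled parameter table with 95% CIs
(`pooled_parameters.csv` — this run's transit-to-resident switching row
reads `0.028 [0.021, 0.037]`, bracketing the generating value 0.035), the
per-whale summary table mirroring the management-area layout, and a
manifest recording the seed and config hash.

From Python, the same pieces are importable directly:

```python
from whalemove import (simulate_track, steps_and_turns, fit_hmm,
                       stationary_distribution, TransitionMatrix)
tm = TransitionMatrix.from_switch_probs(0.035, 0.017)
print(stationary_distribution(tm))   # [0.32692308 0.67307692] -> 67.3% resident
```

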