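# pbaekit

Chemometrics for combinatorial **poly-beta-amino-ester (PBAE)** drug-conjugate
libraries. PBAEs are cationic polymers (diacrylate × amine, optionally
end-capped) that carry drugs such as dexamethasone into cartilage by
electrostatic attraction to the tissue's negatively charged
glycosaminoglycans (GAGs). Screening such a library produces a polymer ×
descriptor table (computed monomer/repeat-unit properties plus measured
polymer properties), replicated drug-uptake measurements against the
clinical DEX-P reference, permeation traces for diffusion-coefficient
estimation, and GAG time courses from *ex vivo* efficacy experiments.
`pbaekit` implements the full analysis of that bundle for polymer chemists
and formulation scientists, together with synthetic-data generators so every
stage is testable with known ground truth.

What it computes:

* **Library handling** — descriptor-table I/O, validation (missing cells,
  constant columns, multicollinearity report), z-scoring.
* **Clustering** — Manhattan distance + complete linkage over standardized
  descriptors; Newick and merge-table export.
* **PLS regression (NIPALS, from scratch)** — components t = Xw chosen to
  maximize covariance with the (log) uptake ratios; per-component and
  cumulative X-R²/Y-R² tables; in-sample RMSE scree; component selection by
  the inflection of the cumulative X-R² curve with the ≥80%-variance rule
  and RMSE elbow reported alongside; circle-of-correlations loading maps and
  signed descriptor-importance profiles per end-cap.
* **Diffusion kinetics** — break-through (lag) time from receiver/donor
  fluorescence-ratio traces via R̂(t) = K·max(0, t − t_lag) with late-time
  asymptote refinement, and D = δ²/(6·t_lag).
* **Efficacy statistics** — uptake ratio vs DEX-P with delta-method CI and
  observed-direction one-tailed Welch t-test; cumulative GAG variation
  Δ%(t) = 100·(GAG(t) − GAG(0))/GAG(0); one-way ANOVA with Tukey HSD (the
  studentized range evaluated by fast in-package quadrature).

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from pbaekit import (LibrarySimConfig, generate_library, standardize,
                     fit_pls, rmse_scree, select_components, variance_tables)
from pbaekit.pls import variable_response_correlations

# a simulated 36-backbone library: 30 descriptors driven by 5 latent factors
table, responses, truth = generate_library(LibrarySimConfig(noise_seed=1))
X = standardize(table).to_frame()
model = fit_pls(X, np.log(responses), H=10)
sel = select_components(rmse_scree(model), model.r2x_cumulative)

print(variance_tables(model).round(2).head(6).to_string(index=False))
print(sel.rationale)
```

prints

```
 n_components  X_R2  X_R2_cum  Y_R2  Y_R2_cum
            1  0.38      0.38  0.85      0.85
            2  0.14      0.52  0.10      0.95
            3  0.12      0.63  0.03      0.98
            4  0.14      0.77  0.00      0.98
            5  0.13      0.90  0.00      0.99
            6  0.01      0.90  0.00      0.99
X-R2 inflection at h=5; RMSE elbow at h=3; cumulative X-R2 reaches 80% at h=5; selected by x_inflection
```

The X-R² column stops growing after five components — the five planted
latent factors — which is where the selection lands, while the two-response
Y block is already ~95% explained after two. The strongest signed
correlations with the e2 uptake ratio at the selected depth,

```python
vr = variable_response_correlations(model, sel.h_selected)
```

come out as `amine_complexity +0.77`, `amine_logP +0.74`,
`amine_steric_quadrupole_z −0.74` for this seed: descriptors loading on the
uptake-relevant latent factors, with the sign giving the direction of the
relationship (the real-data analogue is reading off which polymer
properties — zeta potential, pKa, diffusion coefficient — drive uptake).

The full pipeline (simulate → cluster → PLS → diffusion → uptake → GAG) runs
from one config and writes a manifest with per-stage seeds and file hashes:

```sh
pbae simulate --outdir bundle --seed 3     # emit a study bundle
pbae run config.yaml                       # or the whole pipeline
pbae diffusion traces.csv --out fits.csv
pbae uptake bundle/uptake_measurements.csv --out uptake.csv
pbae gag bundle/gag_timecourses.csv --outdir gag/
```

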