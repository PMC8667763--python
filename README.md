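# mhladr-endotypes

Trajectory endotyping of monocyte HLA-DR (mHLA-DR) in sepsis.

Sepsis leaves the immune system dysregulated for days to weeks, and the
surface expression of HLA-DR on monocytes — measured as antibodies bound
per cell (AB/C) by standardized flow cytometry — is the reference marker of
the immunosuppressive side of that dysregulation. Patients whose mHLA-DR
stays low or falls during the first ICU week are at elevated risk of
ICU-acquired infection (IAI) and death. This package implements the full
statistical pipeline for discovering and characterizing *trajectory
endotypes* — subgroups of patients sharing a common first-week mHLA-DR
trend — for biostatisticians and immunomonitoring researchers working with
sparse, irregularly sampled marker panels:

1. **Preprocessing** — Box-Cox normalization (profile-likelihood λ) and
   Tukey-fence outlier exclusion on the pooled transformed samples.
2. **Longitudinal k-means** — clustering of n×3 window trajectories with a
   missing-data-adjusted distance
   d(x,y) = √((T/|O|)·Σ_{t∈O}(x_t−y_t)²), copy-mean imputation,
   Calinski–Harabasz best-of-restarts selection, Gaussian-kernel assignment
   probabilities, and a deterministic naming rule for the four endotypes
   (Non-improvers, Decliners, Improvers, High expressors).
3. **Mixed-effects trends** — per-endotype quadratic fixed effects of time
   with patient-level random intercept and slope (REML), and 95%
   fixed-effects confidence bands back-transformed to AB/C.
4. **Competing risks** — Aalen–Johansen cumulative incidence of IAI, death
   and ICU discharge per endotype, and Fine–Gray subdistribution hazard
   regression (IPCW-weighted partial likelihood, sandwich variances):
   F(t|Z) = 1 − (1 − F₀(t))^exp(βZ).
5. **Cohort comparison** — partition concordance under the best label
   bijection, χ² proportion tests, and Table-1-style descriptive tests
   (Shapiro–Wilk-routed ANOVA/Kruskal–Wallis, Yates-corrected χ²/Fisher).

The original cohorts are not publicly deposited, so the package includes a
first-class **synthetic cohort generator** that reproduces the published
structure — four endotype mean trajectories anchored at the printed
day-1/day-6 means, lognormal patient-level noise, three sampling windows
with missingness, sporadic assay-floor readings, and 28-day competing
outcomes generated under proportional subdistribution hazards at the
printed incidence plateaus. Every stage is validated by recovering those
parameters.

## Worked example

```sh
mhladr-endotypes simulate --cohort aggregated --n 378 --seed 42 --out sim/
mhladr-endotypes run --traj sim/trajectories.csv --events sim/outcomes.csv \
    --out run/ --seed 42 --restarts 100
```

or equivalently in Python:

```python
import mhladr_endotypes as m

cfg = m.default_config("aggregated", seed=42)        # 378 patients
traj, labels = m.simulate_trajectories(cfg)
clean = m.clean_trajectories(traj)                   # Box-Cox + Tukey
cohort = m.TrajectoryCohort.from_long(clean.data)
part = m.kmeans_longitudinal(cohort, k=4, n_restarts=100, seed=43)
centers = clean.transform.inverse(part.centers)      # back to AB/C
part.names = m.name_endotypes(centers)
for c in range(4):
    print(f"{part.names[c]:16s} D1={centers[c,0]:7.0f}  D6={centers[c,2]:7.0f}  "
          f"n={(part.assignment==c).sum()}")
```

prints (seed 42):

```
High expressors  D1=   9260  D6=  28632  n=15
Decliners        D1=  30106  D6=  10173  n=25
Non-improvers    D1=   3222  D6=   3814  n=202
Improvers        D1=   6243  D6=   9633  n=136
```

The four back-transformed cluster centers land on the anchor means the
generator was configured with (3265/3865, 31774/10785, 6331/9787,
9681/28604 AB/C), the adverse endotypes (Non-improvers + Decliners)
comprise 60% of the cohort, and the mean posterior probability of each
patient's assigned cluster is 1.00 — i.e. the partition is crisp. The
`run` command additionally fits the mixed-effects trend bands and the
competing-risks models and writes a single `manifest.json` with every
estimate and seed.

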