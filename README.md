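# restconn

Resting-state EEG source power, coherence and directed connectivity for
two-group clinical cohorts, exercised end-to-end on synthetic data with
known ground truth.

## The problem

In mild cognitive impairment (MCI), resting-state EEG rhythms change in
three distinguishable ways: band-limited source *power* drops (notably alpha
and beta), *functional* coupling between cortical sources (coherence)
weakens, and the *directed* information flow between them becomes sparser
and more unidirectional. Relating these electrophysiological markers to
amyloid burden (PiB-PET SUVR) and ApoE &epsilon;4 genotype requires a long
chain of signal-processing and statistical machinery. This package
implements that chain as a tested library with an analysis layer on top:

1. **Preprocessing** — zero-phase 0.5–70 Hz bandpass (24 dB/oct) with 50 Hz
   notch, downsampling to 256 Hz, average reference, 2 s epochs.
2. **Spectra** — window-averaged tapered periodograms on a 0.25 Hz grid;
   band power for &delta; (1–3), &theta; (4–7), &alpha; (8–13), &beta;
   (14–30), &gamma; (30–49 Hz); individual alpha frequency (IAF) estimation
   and IAF-anchored band edges (each canonical edge *e* &rarr;
   (*e*/10)·IAF).
3. **Forward model** — five concentric spheres (white matter, gray matter,
   CSF, skull, skin) solved analytically by Legendre series; lead fields on
   a cubic source grid.
4. **DICS beamforming** — cross-spectral density matrices; unit-gain
   minimum-variance spatial filters; power and coherence tomography;
   iterative coherent-source identification with within-recording surrogate
   significance.
5. **Directed connectivity** — MVAR models at the AIC-minimizing order;
   renormalized partial directed coherence (RPDC)

   &nbsp;&nbsp;&lambda;<sub>j&rarr;i</sub>(f) = **X**&prime;
   **V**<sub>ij</sub>(f)<sup>&minus;1</sup> **X**, &nbsp; **X** = (Re
   &Amacr;<sub>ij</sub>(f), Im &Amacr;<sub>ij</sub>(f))

   with per-pair bootstrap significance and time-reversal testing (TRT)
   against volume-conduction artifacts.
6. **Statistics** — group *t*/&chi;&sup2;/Friedman tests, Spearman and
   age-partialled correlations with SUVR and ApoE risk, percentile-bootstrap
   CIs, Bonferroni correction, Lilliefors normality screening.
7. **Classification & Bayesian estimation** — SVM (linear kernel for
   clinical scalars, polynomial for EEG features) with repeated stratified
   75/25 validation, and a robust Bayesian two-group model (t-distributed
   groups, broad data-scaled priors) yielding posterior effect sizes and
   *credible separation*.

Because no subject-level recordings are distributed for cohorts of this
kind, the package ships a first-class synthetic-data module:
coupled MVAR dipole sources projected through the forward model, plus
clinical covariates with the published group distributions (SUVR: HC
1.24 ± 0.2, MCI 1.45 ± 0.2, positivity at ≥ 1.265; per-group ApoE genotype
frequencies) and a Gaussian-copula link that makes amyloid burden
rank-anticorrelated with connectivity in the impaired group.

## Worked example

```python
import restconn as rc
from restconn import synthetic

# a two-group cohort (17 + 17) with the default study conditions
table, _ = synthetic.simulate_cohort(synthetic.CohortSpec(seed=7))

# band-by-measure group battery, Bonferroni m = 15
battery = rc.group_comparison_battery(table)
print(battery[battery.significant][["measure", "band", "t", "p_adj"]])

# IAF-adjusted bands for an individual alpha frequency of 10.1 Hz
print(rc.iaf_adjusted_bands(10.1)["delta"])
```

The battery flags the alpha/beta cells that carry the generator's designed
group effects — for cohort seed 7 it prints `power alpha t=16.31` and
`power beta t=15.42` (both `p_adj < 1e-4`), `rpdc alpha t=4.11` and `rpdc
beta t=6.27`, plus two weaker incidental cells this cohort draws by chance
(`power delta t=-3.41`, `coherence theta t=-3.27`) — and the delta band
rescales to `FrequencyBand(name='delta', lo=1.01, hi=3.03)`: the
10%-of-edge scaling rule at IAF 10.1 Hz.

The numbered drivers under `analysis/` run the full chain on this synthetic
cohort and write their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py       # cohort table + example recordings
python analysis/02_source_localization.py   # DICS coherent-source networks
python analysis/03_directed_connectivity.py # RPDC + bootstrap + TRT edges
python analysis/04_group_statistics.py      # batteries and interactions
python analysis/05_classification.py        # SVM + Bayesian separation
```

For cohort seed 7 the classification driver prints, e.g., `beta_power
(poly): train 97.2%  test 97.8%  overall 97.4%` and `all_eeg (poly): train
100.0%  test 95.6%  overall 98.8%`, and the Bayesian stage reports full
credible separation (100%) for the alpha/beta power markers — EEG summaries
separate the synthetic groups essentially perfectly at their designed effect
sizes, while the clinical scalars alone do not (`apoe: overall 50.3%`).

## Layout

- `src/restconn/` — the library: `preprocess`, `spectral`, `forward`,
  `montage`, `dics`, `mvar`, `rpdc`, `synthetic`, `stats`, `classify`,
  `bayes`, `io`, `config`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — the methods note: models, assumptions, parameter
  choices, numerical details, limitations.
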