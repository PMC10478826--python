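# rmdose

Image-based red marrow dosimetry for [¹⁷⁷Lu]Lu-DOTATATE therapy.

Bone marrow suppression is a common toxicity of ¹⁷⁷Lu-DOTATATE treatment of
neuroendocrine neoplasms. Somatostatin receptor type 2 — the therapeutic
target — is also expressed on CD34⁺ hematopoietic progenitors, so part of
the activity seen in skeletal sites is *specific* (receptor-bound) marrow
uptake rather than circulating blood. Blood-based marrow dosimetry misses
that component. `rmdose` implements the image-based alternative for users
working from SPECT/CT-derived time–activity concentrations: it

1. fits a biexponential blood input function to the descending-aorta curve,
   C_blood(t) = A₁e^(−λ₁t) + A₂e^(−λ₂t);
2. separates specific from nonspecific uptake at each skeletal site with a
   one-compartment model, dC_spec/dt = k₁·f·C_blood − k₂·C_spec, fitted by
   grid search on the RMSE against the measured tissue curve
   f·C_blood + C_spec;
3. integrates both components over [0, ∞), scales them with reference
   red-marrow volume fractions and volumes, and converts to absorbed dose
   per site with RM←RM S values:
   D_RM = (TIA_spec + TIA_nonspec)·S, in Gy per GBq administered;
4. computes the skeletal-average blood-based estimate
   D = S_avg·∫C_blood·f_RM·V_RM as the comparator.

A synthetic-cohort generator reproduces the statistical structure of the
study design (4 scan time points near 4.1/18.8/53/169.6 h, multiplicative
7% noise, biexponential blood kinetics) so every stage is testable without
patient images; the published 17-patient per-patient dose table is packaged
as a benchmark for the summary statistics. See `docs/methods.md` for the
full model description and design rationale.

## Layout

- `src/rmdose/` — the library: `core` (types, units, packaged reference
  constants), `blood`, `compartment`, `dosimetry`, `simulate`, `pipeline`,
  `cli`.
- `analysis/` — numbered drivers reproducing the analysis chain on a
  synthetic cohort; outputs land in `results/`.
- `scripts/acceptance.py` — end-to-end run (below).

## Worked example

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_fit_blood.py
python analysis/03_fit_compartments.py
python analysis/04_dosimetry.py --seed 1
python analysis/05_study_benchmark.py
python analysis/06_halflife_regression.py
```

The dosimetry step prints (seed 1):

```
34/34 site doses exceed the blood-based estimate (median ratio 3.8x)
 bone_metastases      site  n  median_total  sd_total  mean_specific_fraction  median_blood_based
           False hip_bones 10      0.034525  0.014093                0.579510            0.018089
           False vertebrae 10      0.071772  0.037336                0.665797            0.018089
            True hip_bones  7      0.020535  0.008108                0.609171            0.011096
            True vertebrae  7      0.068121  0.029005                0.786398            0.011096
```

Every synthetic patient's image-based total dose (Gy/GBq) exceeds the
blood-based estimate — blood-based methods systematically underestimate
marrow dose when specific uptake is present — and the specific component
carries ~58–79% of the total. The benchmark step recomputes the published
cohort's group statistics from the packaged per-patient table (the patient
with metastases in all analyzed sites excluded, as in the original
averages):

```
 bone_metastases      site  n  median_total  sd_total  ...  median_blood_based
           False hip_bones 10        0.0425  0.022147  ...              0.0130
           False vertebrae 10        0.0560  0.023286  ...              0.0130
            True hip_bones  6        0.0685  0.032866  ...              0.0175
            True vertebrae  6        0.0850  0.045976  ...              0.0175
excluded patient 5: vertebrae 0.52 Gy/GBq, hip bones 0.27 Gy/GBq
```

i.e. medians of 0.056 / 0.043 Gy/GBq (vertebrae / hips, no bone
metastases), 0.085 / 0.069 Gy/GBq (with bone metastases) against
blood-based medians of 0.013 / 0.017 Gy/GBq — a 3–4× underestimate.

A `rmdose` console script exposes the same stages
(`simulate`, `fit-blood`, `fit`, `dose`, `summarize`, `summarize-study`);
`rmdose dose --input patients.tsv --out run/` writes a reproducible run
directory (fit reports, dose tables, summary, run log with config snapshot
and reference-table hash).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole chain from scratch: it generates a seeded synthetic
cohort, fits blood and compartment models for every patient, computes
per-site absorbed doses and the blood-based comparator, verifies the dose
ordering, and recomputes the published-cohort summary from the packaged
table, writing its result JSON to `--out`.
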