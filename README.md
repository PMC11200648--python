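# gdmnir

Chemometric classification of near-infrared (NIR) serum spectra for
gestational diabetes mellitus (GDM) screening: spectral pretreatment grid
search, PLS-LDA and two-block SO-PLS-LDA classifiers, repeated double
cross-validation, and VIP-based variable relevance — plus a synthetic
cohort generator so the entire pipeline is testable end-to-end without any
clinical data.

## Who this is for

Chemometricians and biomedical-spectroscopy researchers who want a tested,
reproducible implementation of the standard "screen pretreatments × spectral
ranges under nested cross-validation" study design for two-class biofluid
fingerprinting problems (here: GDM = 1 vs normal glucose tolerance = 0,
serum transflectance spectra on 10,500–4000 cm⁻¹).

## The model

Classification is regression on a binary-coded response. PLS1 compresses
the predictor matrix X into scores **T = XR** with maximal covariance with
y, regresses y on the scores, **ŷ = Tq**, equivalently **ŷ = XRq = Xb**,
and a threshold on ŷ is set by one-dimensional two-class LDA with pooled
variance: samples with ŷ on the case side are predicted GDM. For two
blocks (spectra + clinical covariates), SO-PLS fits block 1, orthogonalizes
block 2 against the block-1 scores, fits the residuals on the
orthogonalized block, and sums: **ŷ_SO = X₁b₁ + X₂,orth b₂,orth**.

Every model is validated by repeated double cross-validation (DCV): a
10-segment inner loop selects the number of latent variables by non-error
rate (NER = (specificity + sensitivity)/2), a 20-segment outer loop
estimates performance, and the whole procedure repeats 50 times with
re-randomized splits; results are mean ± SD over repetitions. Variables
with repetition-averaged VIP scores above 1 are reported as merged
wavenumber intervals. See `docs/methods.md` for the full account.

## Worked example

```python
import gdmnir as g

cfg = g.second_trimester_config(seed=1)          # 39 controls, 8 cases
spectra = g.generate_spectra(cfg)                # 5 replicates/subject
subject = g.reflectance_to_absorbance(g.average_replicates(spectra))

screen = g.ScreeningConfig(grid=g.REDUCED_GRID,
                           dcv=g.DCVConfig(repetitions=10, seed=1))
table = g.run_screening(subject, screen)
best = g.best_per_range(table)
print(best[["range", "pretreatment", "sp_mean", "se_mean",
            "ner_mean", "ner_sd"]].round(4).to_string(index=False))

rep = g.report_best(subject, "R3", best.iloc[0]["pretreatment"],
                    g.DCVConfig(repetitions=10, seed=1))
print(f"AUROC {rep['summary']['auroc_mean']:.4f} "
      f"+/- {rep['summary']['auroc_sd']:.4f}")
print(rep["vip_intervals"].to_string(index=False))
```

prints

```
range    pretreatment  sp_mean  se_mean  ner_mean  ner_sd
   R3 SM(W=15)+WLS+MC   0.9641   0.8625    0.9133  0.0592
 Full SM(W=15)+SNV+MC   0.8923   0.5750    0.7337  0.0392
   R2 SM(W=15)+WLS+MC   0.6487   0.7625    0.7056  0.0643
   R1 2D(W=15)+SNV+MC   0.6590   0.1500    0.4045  0.0443
AUROC 0.9782 +/- 0.0144
 interval_high_cm-1  interval_low_cm-1  mean_VIP  n_points
             5100.0             5000.0  1.128685        51
             4762.0             4628.0  1.354036        68
             4528.0             4448.0  1.218590        41
             4390.0             4306.0  1.381486        43
             4258.0             4200.0  1.084099        30
             4044.0             4000.0  1.500300        23
```

Reading this: the synthetic cohort carries a class effect confined to the
low-wavenumber R3 region (4762–4348 cm⁻¹). The screening correctly ranks
R3 first (best mean NER 0.9133 over 10 DCV repetitions), the full range is
dragged down by the high-noise regions it includes, and R1 — pure noise —
sits at chance. The VIP>1 intervals at 4762–4628 and 4390–4306 cm⁻¹
recover the injected effect region. Each row's pretreatment string uses
the usual shorthand (MC = mean centering, SM/1D/2D = Savitzky–Golay
smoothing/derivatives with window W, SNV = standard normal variate,
WLS = weighted-least-squares baseline, N = 2-norm).

The same workflow is available from the shell:

```bash
gdmnir simulate --scenario second --seed 1 --out cohort/
gdmnir screen --spectra cohort/spectra.csv --manifest cohort/manifest.csv \
              --grid reduced --reps 10 --seed 1 --out runs/
gdmnir report --spectra cohort/spectra.csv --manifest cohort/manifest.csv \
              --range R3 --pretreatment "1D(W=15)+MC" --seed 1 --out runs/
gdmnir fuse   --spectra cohort/spectra.csv --manifest cohort/manifest.csv \
              --medical cohort/medical.csv --range Full --seed 1 --out runs/
```

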