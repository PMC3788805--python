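# mrst2 — synthetic ¹H-MRS T2 relaxometry of the aging brain

`mrst2` is a fully synthetic, end-to-end re-implementation of a classic
in vivo measurement: metabolite proton transverse relaxation times
(T2) are shorter in the occipital lobe of elderly than of young adults.
Because the underlying raw spectra of such studies are rarely public,
the package generates its own data with the reported group statistics
as ground truth and then recovers them with the same analysis chain a
spectroscopist would use. It is aimed at MRS methodologists who want a
tested sandbox for multi-echo-time (TE) quantification pipelines:
basis-set simulation, linear-combination fitting, CRLB-based quality
control, relaxometry, and echo-time-scheme design.

## What it computes

1. **STEAM basis simulation** (`mrst2.spin_sim`). Ideal-pulse
   density-matrix evolution of each metabolite moiety under
   `H = Σᵢ Ωᵢ Iᵢz + Σᵢ<ⱼ 2πJᵢⱼ Iᵢ·Iⱼ` through
   90°–TE/2–90°–TM–90°–TE/2–acquire, with coherence-order selection
   (+1, then populations/zero-quantum during the mixing time TM, then
   −1). An uncoupled spin retains exactly half of the one-pulse signal;
   coupled spins J-modulate. Defaults: TE = 10, 20, 30, 40, 60, 80,
   180 ms; TM = 42 ms; 6 kHz spectral width; 6144 complex points;
   169 MHz.
2. **Synthetic cohorts** (`mrst2.cohort`). 18 young and 14 elderly
   subjects; per-compound T2 truth drawn from truncated normals
   (young/elderly NAA 208 ± 18 / 161 ± 19 ms, tCr 157 ± 14 /
   132 ± 11 ms, tCho 164 ± 29 / 147 ± 16 ms, tissue water 52 ± 2 /
   47 ± 4 ms; CSF fraction 9 ± 3 % / 25 ± 11 %), a macromolecule
   background with a fast 25 ms T2, 12 Hz linewidth, and calibrated
   complex Gaussian noise. Water is a twelve-TE (5…5000 ms)
   two-compartment integral series.
3. **Linear-combination fitting** (`mrst2.lcfit`). Non-negative
   least-squares of each spectrum over 0.5–4.2 ppm against the basis
   plus a cubic-spline baseline; CRLB% per amplitude from the design
   matrix; compounds are retained only if CRLB < 30 % at **all** seven
   TEs (only the NAA, tCr and tCho singlets survive, as in vivo).
4. **Relaxometry** (`mrst2.relaxometry`). `S0·exp(−TE/T2)` per
   metabolite (trust-region NLLS), and
   `S0·[(1−f)·exp(−TE/T2_tissue) + f·exp(−TE/T2_CSF)]` for water with
   T2_CSF fixed at 1500 ms and the CSF fraction f box-constrained to
   [0, 1].
5. **Group statistics** (`mrst2.group_stats`). Wilcoxon rank-sum
   (exact for ≤ 20 untied observations), one- and two-sided, plus
   table-style summaries with the elderly/young ratio and percent
   shortening.
6. **Monte Carlo TE assessment** (`mrst2.monte_carlo`). 500-iteration
   recovery simulations testing whether the seven-TE schedule biases
   T2 and how much precision added TEs (120, 250, 400 ms) would buy.

The fitting stages are scikit-learn-style estimators
(`LinearCombinationModel`, `MonoExponentialT2`,
`BiexponentialWaterModel`) with `fit` and trailing-underscore
attributes; module functions wrap them for one-liners.

## Worked example

```python
from mrst2.pipeline import RunConfig, run_pipeline

result = run_pipeline(RunConfig(master_seed=1, log_level="WARNING"))
cols = ["compound", "young_mean", "elderly_mean", "p_two_sided",
        "ratio_elderly_young", "pct_shorter"]
print(result.summary[cols].round(4).to_string(index=False))
```

prints (seed 1):

```
    compound  young_mean  elderly_mean  p_two_sided  ratio_elderly_young  pct_shorter
         NAA    203.6412      167.9050       0.0001                 0.82           18
        tCho    161.3881      159.9934       0.7468                 0.99            1
         tCr    153.2931      135.7053       0.0103                 0.89           11
tissue water     52.3200       46.7246       0.0010                 0.89           11
```

Read this as: with ground-truth group means of 208/161 (NAA), 157/132
(tCr) and 52/47 ms (tissue water), one 32-subject cohort realisation
recovers group means within a few percent; the NAA, tCr and water
shortenings are significant (two-sided p < 0.05) while tCho — the
noisiest channel, exactly as in vivo — is not. `result.fits` holds the
per-subject fits (including recovered CSF fractions near 9 % young /
25 % elderly), `result.mc_results` the TE-scheme Monte Carlo, where
every added TE lowers the SD of recovered T2 and adding all three of
120/250/400 ms lowers it most, with group means unchanged.

The same run is available from the shell:

```bash
mrst2 run --out results/ --seed 1
mrst2 mc-te --t2 161 --add 120,250,400 --noise-bound 0.05 --iters 500 --seed 1
```

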