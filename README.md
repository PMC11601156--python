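# maldicrs

Curve Response Score analysis for whole-cell MALDI MS dose-response
bioassays.

Label-free MALDI-TOF cell assays measure one mass spectrum per target-plate
spot, with several technical replicates at each compound concentration, and
track hundreds of metabolite m/z features at once. The analytical question
is which of those features truly respond to the compound — with what
potency, what effect size, and in which direction — and which apparent
responses are measurement artefacts. `maldicrs` is a tested Python library
and CLI for that question, aimed at assay developers and screening groups
working with concentration-response MALDI data (cell-based or biochemical).

## Method

For every binned m/z feature, the per-concentration replicate means are
fitted with the four-parameter log-logistic model

    f(x) = c + (d − c) / (1 + exp(b·(ln x − ln e)))

(c ≤ d the asymptotes, e the inflection/EC50, b the slope), giving the
potency pEC50 = −log₁₀ e and the signed effect size
log₂FC = ±|log₂(d/c)|. Two assay-quality factors judge each curve: FZ, the
Z′-statistic of the endpoint window, 1 − 3(σ_high + σ_low)/|μ_high − μ_low|,
and FV, a V-factor analogue that replaces the endpoint SDs with the RMS
deviation of all replicates from the fitted curve. The Curve Response Score

    CRS = 100 · ( clip₀₁ FZ + clip₀₁ FV + clip₀₁(|log₂FC| / s) ) / 3   [%]

combines them with equal weights (s is a dataset-level fold-change
normalizer); features with no quality support score 0 and are called
nonregulated, the rest are up- or down-regulated by the sign of log₂FC.
The vector of CRS values over all features — the CRS fingerprint — ranks
features within a dataset and compares cellular effects across compounds.

Around this core the package provides mzML + plate-layout I/O, the standard
preprocessing chain (Savitzky–Golay smoothing, TopHat baseline removal,
square-root variance stabilization, SNR peak picking, monoisotopic
filtering, recalibration, TIC/median/internal-standard normalization,
alignment, binning), Chauvenet outlier QC on the plate map, PCA / sparse
PCA / curve-shape clustering, and a seeded synthetic plate simulator with
ground truth. See `docs/methods.md` for the full model description and
numerical choices.

## Worked example

Simulate a plate with two programmed responders among 12 features
(8 concentrations × 4 replicates, 10-fold dilutions, 5 % spot-level noise)
and analyse it with default settings:

```python
from maldicrs import (SimulationConfig, ResponderSpec, simulate_plate,
                      run_pipeline, Config)

cfg = SimulationConfig(
    n_features=12,
    mz_range=(420.0, 600.0),
    responder_specs=(
        ResponderSpec(mz=520.10, b=-2.0, c=1.0, d=8.0, e=1e-6),  # up-regulated
        ResponderSpec(mz=460.25, b=2.0, c=1.0, d=7.0, e=1e-6),   # down-regulated
    ),
    seed=1,
)
spectra, layout, truth = simulate_plate(cfg)
result = run_pipeline(spectra, layout, Config())
print(result.fingerprint.sort_values("crs_percent", ascending=False)
      .head(4).to_string(index=False))
```

prints

```
        mz  crs_percent direction    pec50    log2fc
520.100186         90.0        up 6.129120  1.476554
460.249053         85.2      down 5.903104 -1.407859
462.245008         36.5      down 5.631589 -1.533604
522.108140         29.3        up 6.065897  1.048007
```

The two programmed responders top the ranking with CRS ≈ 90 % and 85 %, in
the programmed directions, and their pEC50 values recover the simulated
potency of 6.0 (EC50 = 1 µM) to about a tenth of a log unit. The next two
rows are the responders' own isotope-envelope remnants (+2 Th), which
follow the same dose trend with weaker quality scores; every
dose-independent feature on the plate scores CRS = 0.

The same analysis from the shell:

```sh
maldicrs simulate --out plate/ --seed 1
maldicrs run --data plate/ --out results/          # scores, fingerprint, qc, clusters CSVs
maldicrs compare results_a/fingerprint.csv results_b/fingerprint.csv --out cmp/
```

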