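# sacsyn

Analysis pipeline for characterizing synaptic transmission at GABAergic
starburst amacrine cell (SAC) synapses from quasi-white-noise optogenetic
stimulation, in voltage-clamped retinal neurons.

SACs inhibit both direction-selective ganglion cells (DSGCs) and other
SACs. The question the pipeline addresses is where the striking difference
in temporal filtering between these two synapse classes comes from:
IPSCs in DSGCs are strongly low-pass filtered, while IPSCs in SACs are
fast and band-pass-like. The pipeline decomposes that difference into
presynaptic (release dynamics) and postsynaptic (receptor kinetics)
contributions, and rules out two artifacts (unclamped channelrhodopsin
photocurrent, GABA_A receptor desensitization).

## The methods at its core

* **LN cascade model.** A response to white-noise stimulation is modeled
  as `r(t) = N((f * s)(t))`: a linear temporal filter `f` (stimulus-response
  cross-correlation on unique stimulus segments, unit L2 norm) followed by a
  static nonlinearity `N(x) = β + α Φ((x−μ)/σ)` fit to 100 equal-count bin
  means of the prediction–response scatter. Filter shape is summarized by
  peak time, full width at 25 % of maximum, and the biphasicity index
  `b_φ = 2 f_min / (f_max + f_min)` (f extrema over 0 < t ≤ 60 ms);
  nonlinearity asymmetry by the rectification index
  `i_rect = |N(max r_L) + N(min r_L) − 2 N(0)| / (N(max r_L) − N(min r_L))`.
  Model accuracy is the r² between the model's repeat-segment response and
  the mean recorded repeat response; sessions enter analysis only if
  trial-to-trial repeat reliability exceeds 0.7.
* **emIPSC analysis.** Brief (<10 ms) pulses evoke unitary-like monophasic
  IPSCs on ~2/3 of trials. Trials are filtered, differenced and thresholded;
  failure-trial averages (isolated photocurrent) are subtracted; aligned
  averages are fit with
  `f_DSGC(t) = (a₁e^(−t/τ₁) + a₂e^(−t/τ₂))(1 − a₃e^(−t/τ₃))` and
  `f_SAC(t) = a₁e^(−t/τ₁)(1 − a₂e^(−t/τ₂))`.
* **Wiener deconvolution.** Each IPSC is deconvolved with its cell type's
  average emIPSC (`H = K̄S/(|K|²S + N)`, noise spectrum from a 1-s
  pre-stimulus baseline), yielding a delta-like release-rate train. Trains
  are reconvolved with the *other* type's kernel to form hybrid IPSCs, or
  analyzed directly (LN + 2.5-Hz-normalized power spectra).
* **Contamination simulation.** DSGC IPSCs downscaled to SAC amplitude are
  summed with conservatively scaled photocurrent estimates (scale 0.146 =
  mean + 3 SEM of the E_cation/E_Cl amplitude ratio; exponential cable
  filters τ = 10–316 ms, unit integral); Δr² against SAC IPSCs measures
  whether contamination could fake the fast SAC kinetics.
* **Desensitization estimator.** The IPSC convolved with a peak-normalized
  35-ms exponential, divided by single-vesicle charge (1.4 pC) and synapse
  count (500), gives vesicles per synapse interacting within the fast
  desensitization lifetime.

Raw recordings of this preparation are not publicly deposited, so the
package ships a first-class generative twin (`sacsyn.synthetic`): stimulus →
presynaptic filter → Gaussian-CDF rate nonlinearity → inhomogeneous Poisson
release (thinning) → unitary kernel with lognormal amplitudes → recording
noise. Every stage of the analysis is validated by parameter recovery
against this generator's ground truth.

## Worked example

```bash
python analysis/02_fit_ln_models.py --seed 0 --out results
```

fits LN models to ten gated synthetic sessions (five per cell type) and ends
with:

```
Mean filter width: DSGC 58.1 ms vs SAC 30.3 ms (ratio 1.91) -- DSGC filters
are wider, i.e. low-pass filtering is stronger onto DSGCs.
```

i.e. the SAC→DSGC synapse acts as the stronger low-pass filter.
Continuing the sequence:

```bash
python analysis/04_deconvolve_and_hybrid.py --seed 0 --out results
```

prints, per seed, the filter widths of the recorded SAC IPSC, the hybrid
IPSC (DSGC release ⊛ SAC kernel) and the recorded DSGC IPSC, e.g.

```
 seed  width_sac_ms  width_hybrid_ms  width_dsgc_ms  hybrid_intermediate
    0         30.06            46.14          55.54                 True
```

The hybrid width falls strictly between the two recorded widths: swapping
the postsynaptic kernel narrows the DSGC filter only partially, so most of
the filtering difference is presynaptic. `05_contamination.py` reports a
median Δr² of −0.0055 (contamination makes DSGC IPSCs *less* SAC-like), and
`06_desensitization.py` a median of ~0.001 vesicles per synapse — far too
few for fast desensitization to shape the IPSC.

The numbered scripts under `analysis/` run in order (01 simulate/gate,
02 LN fits, 03 events, 04 deconvolution/hybrids, 05 contamination,
06 desensitization) and write their tables to `results/`.
`sacsyn.pipeline.run_pipeline` executes the same stages as one call.

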