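# frozenemg

Training-free gesture recognition from multi-channel surface
electromyography (sEMG). The package implements a complete pipeline for
low-sampling-rate recordings (Ninapro-DB1-style: 10 electrodes at
100 Hz, 52 gesture classes, repetition-based train/test splits) in which
**no convolutional weight is ever trained**: feature extraction uses
randomly initialised, frozen multi-scale dilated convolutions, and the
only fitted component is a closed-form ridge readout. It is aimed at
researchers in myoelectric control and lightweight physiological signal
classification who need a reproducible, CPU-friendly baseline with
second-scale training times.

## The method

1. **Preprocessing and segmentation.** Signals are low-pass filtered
   (first-order Butterworth, 1 Hz cutoff, zero-phase), and motion
   segments are cut from per-sample gesture labels. Because manual
   labels carry onset/offset errors, each boundary is refined by a
   multi-channel **generalized-likelihood-ratio (GLR)** change-point
   scan under a two-state (rest/motion) Gaussian variance model, fused
   across channels by voting: earliest onset, latest offset. Segments
   are standardised to 1100 samples (zero-pad / head-truncate).
2. **Variational mode decomposition (VMD).** Each channel is decomposed
   into K = 2 band-limited intrinsic mode functions (IMFs) by ADMM in
   the frequency domain (bandwidth penalty α = 2000, dual step τ = 0,
   tolerance 1e−7), with DC correction, full-length least-squares
   amplitude calibration, and quality indicators. Modes are scored by

   `score_i = 0.4·ρ'_i + 0.4·E'_i + 0.2·(1 − S'_i)`

   (min–max-normalised Pearson correlation, energy ratio, and sample
   entropy) and the top mode per channel forms the IMF branch.
3. **Frozen dual-branch features.** The raw and IMF segments each pass
   through three frozen convolution modules with kernel/dilation pairs
   (3,1), (5,3), (11,8) and 256 Kaiming-normal filters. Each ReLU
   activation map is summarised per filter by GAP (temporal mean) and
   PPV (fraction of positive values): 512 values per module, 1536 per
   branch, a fused 3072-dimensional vector.
4. **Ridge readout.** `W = (DᵀD + αI)⁻¹DᵀY` with one-hot targets Y and
   α = 0.039; prediction is the argmax class score. Metrics: accuracy,
   macro precision/recall/F1, and multiclass MCC, plus exact McNemar
   tests with Holm–Bonferroni adjustment for paired model comparison.

A synthetic generator produces recordings with known class structure
(distinct 0–1 Hz envelopes per gesture), known true boundaries, and
label jitter, so every stage is testable without downloads.

## Worked example

```python
from frozenemg.pipeline import ExperimentConfig, run_experiment

res = run_experiment(ExperimentConfig())   # synthetic 8-class benchmark
s = res["summary"]["gap+ppv"]
print(f"mean test accuracy {s['mean_acc']:.1f}% "
      f"(SD {s['sd_acc']:.1f}, {s['n_seeds']} seeds)")
print("boundary error raw -> refined:",
      res["boundary"]["median_raw_error"], "->",
      res["boundary"]["median_refined_error"], "samples")
```

prints

```
mean test accuracy 100.0% (SD 0.0, 5 seeds)
boundary error raw -> refined: 15.0 -> 1.0 samples
```

i.e. on the synthetic benchmark (8 classes × 10 repetitions, testing on
repetitions {2, 5, 10}, one run per seed in {42, 123, 777, 2024, 2025})
the frozen pipeline separates all classes, and GLR refinement shrinks
the median boundary error from the injected ±30-sample label jitter
down to ~1 sample.

The same pipeline is scriptable from the shell:

```sh
frozenemg simulate --classes 8 --repetitions 10 --seed 0 --out data/demo
frozenemg run --seed 0 --ablation --out results/run.json
frozenemg compare results/pred_a.csv results/pred_b.csv
```

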