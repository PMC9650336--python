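# menet

EEG phase-locking brain-network analysis for micro-expression research.

Micro-expressions (MEs) are brief (≤ 500 ms), involuntary facial leakages of
a suppressed emotion. Electrophysiologically they are interesting because
producing one is thought to engage both emotional arousal and inhibitory
control — a load that should reorganise large-scale functional brain
networks. `menet` implements the scalp-EEG analysis chain used to test that
idea: it turns event-locked multichannel EEG epochs, labelled as
micro-expression (ME) or no-expression (NE), into phase-locking-value (PLV)
functional networks, compares their graph efficiency between groups, and
classifies the two brain states from connectivity features.

The pipeline:

1. **Preprocessing** — 0.5–60 Hz zero-phase band-pass, average reference,
   and selection of the 1-s analysis block centred on the peak of the global
   field power, GFP(t) = √(Σᵢ (Vᵢ(t) − V̄(t))² / K).
2. **Connectivity** — complex Morlet wavelet phases (7 cycles, 1-Hz bins)
   and, per channel pair and band (alpha 8–12, beta 12–30, gamma 30–60 Hz),
   PLVᵢⱼ = |(1/n) Σₜ e^(−i(φᵢ(t) − φⱼ(t)))| ∈ [0, 1].
3. **Networks** — binarise the PLV matrix at thresholds
   T ∈ {0.64, 0.67, 0.70, 0.73, 0.76} and compute
   E_global(G) = 1/(N(N−1)) Σ_{j≠k} 1/d_{j,k} and
   E_nodal(j) = 1/(N−1) Σ_{k≠j} 1/d_{j,k}, with hop-count distances and
   1/∞ = 0; regional efficiency is the mean E_nodal over each of the four
   scalp regions (frontal, parietal, temporal, occipital).
4. **Statistics** — Welch's t-test for the ME–NE contrast of global
   efficiency, and Benjamini–Hochberg FDR over the four regions within each
   (band, threshold) for regional efficiency.
5. **Classification** — 400-ms sliding windows (50 % overlap) of the 1-s
   block give per-window PLV feature vectors; a random forest ranks features
   by Gini importance on the training split, and SVMs on the top
   5/10/15/20/25/30 features are scored by 10-fold CV and a held-out test
   split (accuracy, AUC, ROC).

Because the recordings such studies use are rarely public, the package
includes a first-class synthetic-cohort generator: region-coherent
band-limited oscillators whose inter-channel phase coupling (von Mises
concentration κ) differs between groups, so every stage — including the
expected ME > NE efficiency direction — is testable end to end.

## Worked example

```python
import menet as m
from menet.pipeline import preprocess_cohort, efficiency_observations
from menet.groupstats import build_stats_table, render_markdown

cfg = m.SimulationConfig.desk_scale(n_me=20, n_ne=20, seed=1)
cohort = m.simulate_cohort(cfg)
blocks = preprocess_cohort(cohort)          # 0.5-60 Hz, avg ref, GFP 1-s block
alpha = m.DEFAULT_BANDS[0]
obs = efficiency_observations(blocks, cohort.labels, cohort.region_map,
                              [alpha], thresholds=(0.64, 0.70, 0.76))
table = build_stats_table(obs)
print(render_markdown(table, "alpha"))
```

prints

```
| Threshold | global MEs | global NEs | global p |
|---|---|---|---|
| 0.64 | 0.77 (0.06) | 0.68 (0.03) | <0.001 |
| 0.70 | 0.69 (0.07) | 0.58 (0.03) | <0.001 |
| 0.76 | 0.58 (0.09) | 0.41 (0.05) | <0.001 |
```

Cells are "mean (SD)" of per-epoch global efficiency. The planted contrast
(κ = 8 vs 0.5 in the frontal, occipital and temporal regions) shows up as
higher ME efficiency at every threshold, and efficiency falls as the
threshold rises and the network sparsifies — the two qualitative signatures
the analysis is built to detect. Non-significant cells print `ns`.

The same analysis is available from the shell:

```sh
menet run --seed 1 --out results_dir      # full pipeline on a demo cohort
menet simulate --seed 1 --out cohort_dir  # just the synthetic cohort
menet stats --efficiency results_dir/efficiency.csv --out stats.csv
menet classify --cohort cohort_dir --bands beta --out report.json
```

`menet run` writes `efficiency.csv`, `stats_table.csv` (+ Markdown
rendering), per-band classification reports (`report.json`, `roc_<band>.csv`,
`feature_importance_<band>.csv`) and a provenance manifest; reruns with the
same config and seed are byte-identical.

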