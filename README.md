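# scwb — single-cell western blot densitometry and subpopulation analysis

Single-cell western blotting (scWB) runs polyacrylamide gel
electrophoresis on individual cell lysates in a microwell array: each
cell's proteins migrate along a 1-mm lane, are immobilized, and are
detected by in-gel immunoprobing. Because separation is by size, a
single pan-HER2 antibody can distinguish the full-length 185 kDa HER2
receptor (p185HER2) from its truncated forms (t-erbB2: proteolytic
carboxy-terminal fragments such as p95, and alternative-translation
isoforms such as p110) — protein species that no isoform-specific
antibody panel separates, yet which are implicated in resistance to
antibody therapies in HER2-positive breast cancer.

`scwb` implements the full quantification and analysis chain for such
data, plus a ground-truthed synthetic-data generator so every stage is
testable without slide scans:

- **`scwb.synthetic`** — simulated cohorts: Gaussian bands on a
  0–1000 µm axis with a log-linear mass→distance map
  *x = a − b·log₁₀(M)*, lognormal per-cell loads, lane-wide migration
  jitter, planted truncated-HER2 subpopulations, marker-space cluster
  structure, optional rendered slide TIFFs.
- **`scwb.quant`** — robust linear background subtraction, single- and
  joint two-Gaussian band fitting in fixed migration windows
  (p185HER2: 40–150 µm, t-erbB2: 150–300 µm), band area (AUC) within
  µ ± 4σ, SNR = amplitude / baseline-noise SD, and the quality gates
  SNR > 3 ∧ R² > 0.7 (general targets) and SNR > 10 (t-erbB2).
- **`scwb.isoforms`** — separation resolution
  *Rs = Δpeak / mean(width)*, the log-linear mass calibration with 90%
  prediction intervals, p95-like / p110-like classification at the
  100 kDa boundary, and per-cell isoform calls with the
  truncated/full-length abundance ratio.
- **`scwb.phenotype`** — marker-hierarchy gating (loading controls →
  epithelial marker → HER2 → t-erbB2), population summaries (%Pos, AVG,
  staining = AVG × %Pos, CV, fold change), the ±4 SD outlier rule,
  rank-based empirical p-values, receptor copy-number estimates, exact
  binomial rare-cell capture probabilities, and the test battery
  (Mann-Whitney, Spearman, variance-ratio F, paired t).
- **`scwb.clustering`** — per-marker z-scoring, Ward-D2 hierarchical
  clustering on Euclidean distances, normalized-Laplacian spectra of
  ε-neighborhood graphs with eigengap cluster-number suggestion, cluster
  composition and within-cluster association statistics with
  Benjamini–Hochberg adjustment.

## Worked example

```python
import scwb
from scwb.quant import QCThresholds, default_windows, quantify_profiles

cfg = scwb.bt474_preset(seed=0)            # 391 lanes, 29 planted t-erbB2
profiles, truth = scwb.generate_cohort(cfg)

th = QCThresholds()
windows = default_windows(sorted(profiles["target"].unique()),
                          model=cfg.model, thresholds=th)
windows.setdefault("terbb2", th.window_terbb2)
fits  = quantify_profiles(profiles, windows, th)
calls = scwb.call_isoform_table(fits)
cells = scwb.gate_cells(fits, calls)
print(cells.is_her2_pos.sum(), cells.is_terbb2_pos.sum())
```

prints `391 29`: all 391 HER2-positive cells pass the gates and exactly
the 29 planted truncated-HER2 lanes (7.4%) are called positive, with no
false positives — the planted bands carry amplitude SNR ≥ 15, above the
SNR > 10 gate that guards the truncated window against the full-length
band's tail. The same chain on the `t0909` tumor preset recovers 36 of
90 (40%). Longer narrative walkthroughs, one per capability, are in
`examples/` (each is a plain script; run `python examples/01_simulate_cohort.py`
and so on), e.g. from `examples/03_mass_calibration.py`:

```
band at 188.2 um -> 128.8 kDa (90% CI 127-130 kDa)
isoform class: p110-like
```

A thin CLI mirrors the pipeline stages
(`scwb simulate|quantify|call|phenotype|cluster|run`); `scwb run
--preset bt474 --out-dir out/` executes the whole chain and writes a
manifest with per-stage cell counts.

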