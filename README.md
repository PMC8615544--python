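# fcnet

Paired-session resting-state fMRI functional connectome graph analysis.

`fcnet` is for researchers who scan the same cohort twice — before and
after an intervention such as cataract extraction with intraocular-lens
(IOL) implantation — and want to know whether the brain's functional
network topology changed, and whether that change tracks behavior. It
implements the full chain from region time series to a Table-style report:

- **Connectome construction**: region-mean BOLD extraction from 4D NIfTI +
  atlas labels, initial-volume discard, OLS nuisance regression, 0.01–0.08
  Hz zero-phase band-pass, motion QC (3 mm / 3° rule), and pairwise
  Pearson connectivity.
- **Binary graphs across a sparsity grid**: proportional thresholding at
  densities s ∈ {0.10, 0.15, …, 0.50} keeps exactly round(s·R(R−1)/2) of
  the strongest edges, so topology is compared at matched density.
- **Graph metrics**, computed directly on the adjacency matrix: per-region
  clustering coefficient C_i = 2t_i/(k_i(k_i−1)) and eigenvector
  centrality (non-negative principal eigenvector of A, ‖x‖₂ = 1), plus
  global mean clustering and degree assortativity.
- **Group statistics**: sign-flip permutation paired t-tests (default 5000
  flips, p = (b+1)/(B+1)) per (metric, threshold, region), Benjamini–
  Hochberg FDR at q = 0.05 within each (metric, threshold) family, and
  Pearson correlations of per-subject metric deltas with behavioral
  deltas.
- **Behavioral analytics**: psychomotor vigilance task (PVT) outcomes
  (mean/median RT, fastest/slowest-decile means, warm-up discard and
  false-start / too-slow exclusions) and the per-subject blue-light
  transmittance delta from the higher-transmittance eye (68% blue-filter
  vs 95% clear IOL classes).
- **Synthetic cohorts** with known ground truth — block-modular
  multivariate-normal time series with a planted correlation-scale session
  effect, ex-Gaussian PVT logs, transmittance tables — so every stage can
  be validated end to end without patient data.

## Worked example

Simulate a 14-subject cohort (30 regions, 150 timepoints) with a +0.30
correlation shift planted on regions 1–3 in the post session, then run the
whole pipeline:

```python
import fcnet

cfg = fcnet.RunConfig(
    out_dir="demo_run",
    seed=11,
    cohort=dict(n_subjects=14, n_regions=30, n_timepoints=150,
                n_communities=5, effect_regions=[1, 2, 3],
                effect_delta_corr=0.3),
    sparsity=[0.2, 0.3, 0.4],
    n_perm=2000,
)
results = fcnet.run_pipeline(cfg)
print(open("demo_run/report.txt").read())
```

The report opens with the FDR-significant session differences, split by
direction (excerpt):

```
Significant graph-metric session differences (FDR-corrected)
==============================================================

Preoperative-Postoperative
--------------------------
  ROI01        threshold 0.20  clustering             p_fdr = 0.004998
  ROI01        threshold 0.30  clustering             p_fdr = 0.0007139
  ...

Postoperative-Preoperative
--------------------------
  ROI01        threshold 0.20  eigenvector_centrality p_fdr = 0.003748
  ROI02        threshold 0.20  eigenvector_centrality p_fdr = 0.003748
  ROI03        threshold 0.20  eigenvector_centrality p_fdr = 0.003748
  ...

PVT session comparison (paired t)
---------------------------------
  mean_rt         t = +8.220  p = 1.659e-06  mean delta = +32.5 ms (pre_slower)
  median_rt       t = +5.959  p = 4.756e-05  mean delta = +37.6 ms (pre_slower)
  fastest10_mean  t = +4.236  p = 0.0009728  mean delta = +25.1 ms (pre_slower)
  slowest10_mean  t = +2.287  p = 0.03958  mean delta = +32.8 ms (pre_slower)
```

Reading it: the three planted regions gain eigenvector centrality after
the intervention ("Postoperative-Preoperative" direction) at every
threshold, exactly as planted; the planted correlation increase also
redistributes clustering across the rest of the network, which the test
picks up network-wide. The PVT block shows the simulated 30 ms
post-session speed-up (pre slower, positive t). The run directory also
holds every intermediate (`connectivity/`, `metrics.tsv`,
`group_results.tsv`, `pvt_tests.tsv`, `transmittance.tsv`,
`correlations.tsv`) and a `provenance.json` echoing the config and seed;
rerunning with the same config and seed reproduces every table byte for
byte.

The same pipeline is available from the shell:

```bash
fcnet simulate --out data/ --subjects 14 --regions 30 --timepoints 150 \
      --effect-regions 1,2,3 --effect-delta 0.3 --seed 11
fcnet run config.yaml        # full pipeline from a YAML config
fcnet connect data/sub001_pre_timeseries.tsv --out c.tsv   # single stages
```

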