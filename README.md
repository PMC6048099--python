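# longscn — longitudinal structural covariance network analysis

Structural covariance networks (SCNs) treat cortical regions as nodes and
the between-region correlations of cortical thickness, computed *across
the subjects of a group*, as weighted edges. They capture coordinated
cortical anatomy and its disruption in neurodegenerative disease, but
they come with a statistical catch: each group × timepoint yields one
network and therefore one value per network metric, so subject-level
statistics cannot test longitudinal change or group differences.

`longscn` implements a complete longitudinal SCN pipeline for small
clinical cohorts — the motivating setting is patients after a first
inflammatory-demyelinating attack, split into those who do and do not
convert to multiple sclerosis within a year, plus healthy controls:

* **preprocessing** — per-region linear imputation of a missed final
  visit from each subject's own trajectory, then one pooled regression
  residualizing thickness against age, sex, baseline lesion load and
  baseline mean thickness (the residuals are the *adjusted* values);
* **network construction** — per (group, month), edge weights
  `w_ij = |r_ij|` from Pearson correlations of adjusted thickness across
  subjects; complete weighted graphs, no thresholding;
* **graph metrics** — nodal strength, Onnela weighted clustering,
  characteristic path length `L = Σ_{i≠j} l_ij / (N(N−1))` on edge
  lengths `1/w`, global efficiency `E_glob = Σ_{i≠j} l_ij⁻¹ / (N(N−1))`,
  neighbour-subgraph local efficiency, and Louvain-maximized modularity
  Q;
* **bootstrap inference** — B subject-resamples per group, each
  rebuilding baseline *and* follow-up networks from the same resampled
  subjects (paired change), percentile 95% CIs, tail-counting p-values,
  and between-group tests from the combined B×B distribution of
  differences between two groups' bootstrap estimates;
* **synthetic cohorts** — a generator with signed one-factor covariance
  (target mean |off-diagonal| correlation per group and visit),
  within-subject persistence across visits, injected confound effects
  and visit-level missingness, so the whole pipeline runs and is tested
  without clinical data.

See `docs/methods.md` for the model details and design rationale.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (7 controls, 9 converters, 12 non-converters, 68
Desikan–Killiany regions, visits at months 0/3/6/12, 3 patients missing
month 12):

```sh
python analysis/01_simulate_cohort.py        # cohort CSVs
python analysis/02_preprocess.py             # imputation + adjustment
python analysis/03_build_networks.py         # 16 adjacency matrices
python analysis/04_network_metrics.py        # six metrics per network
python analysis/05_bootstrap_inference.py    # CIs, p-values, contrasts
python analysis/06_nodal_changes.py          # per-region monthly slopes
```

Step 04 prints, per (group, month), the six network-level metrics, e.g.:

```
    group  month  mean_strength  mean_clustering  char_path_length  global_efficiency  local_efficiency  modularity
       HC      0         24.743            0.311             2.457              0.450             0.450       0.113
       HC     12         24.977            0.322             2.457              0.450             0.450       0.109
converter      0         38.902            0.569             1.819              0.600             0.600       0.047
converter     12         31.709            0.449             2.159              0.517             0.517       0.066
```

Converters start with the best-connected, best-integrated network
(higher strength/clustering/efficiency, shorter paths than controls) and
lose connectivity by month 12, while the control network is stable —
the qualitative pattern the pipeline is built to detect. Step 05 then
quantifies each 12-month change with its bootstrap CI and p-value
(B = 200 in the demo):

```
  converter:
    mean_strength       -7.193 [ -9.546,  +0.594] p=0.109
    char_path_length    +0.340 [ -0.024,  +0.386] p=0.109
  nonconverter:
    mean_strength       -1.849 [ -7.693,  +4.349] p=0.577
```

and step 06 summarizes the nodal trajectories:

```
HC: mean strength slope +0.0603/month; largest nodal |changes| at lh_parsorbitalis, ...
converter: mean strength slope -0.6399/month; largest nodal |changes| at rh_parahippocampal, ...
```

At these group sizes (n = 9 converters) individual CIs are wide; the
suite's calibration tests run the same machinery at n = 30, verifying
that a rho 0.55 → 0.35 coupling decline is declared significant in at
least 80% of cohorts, that the 95% CI for mean strength covers the
known truth in at least 90%, and that the group comparison's
false-positive rate stays at or below 7.5%.

The same pipeline is scriptable via the `longscn` CLI
(`longscn simulate`, `longscn run --boot 1000 --seed 1 ...`,
`longscn compare report.json`) and usable as a library:

```python
from longscn import StudyConfig, run_study
from longscn.synthetic import generate_cohort, study_shaped_scenario

thickness, covariates = generate_cohort(study_shaped_scenario(seed=1))
report = run_study(StudyConfig(contrasts=[("converter", "nonconverter")],
                               B=1000, seed=1), thickness, covariates)
print(report.inference["converter"]["mean_strength"]["change"])
```

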