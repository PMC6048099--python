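# Methods

## The problem

Structural covariance networks (SCNs) describe the coordinated anatomy of
the cortex: nodes are cortical regions and edges are the correlations,
across the subjects of a group, of a morphometric measure — here cortical
thickness. Because one correlation matrix summarizes a whole group at one
timepoint, an SCN yields a *single* value per network metric, and classical
subject-level statistics cannot test change over time or differences
between groups. This package implements a longitudinal SCN pipeline for
small clinical cohorts (the motivating setting is a first
inflammatory-demyelinating attack, with patients split into those who do
and do not convert to multiple sclerosis within a year), with
subject-resampling bootstrap inference as the statistical engine, plus a
synthetic cohort generator so every stage is testable with known truth.

## Pipeline

1. **Imputation.** Subjects who attended months 0/3/6 but missed month 12
   get that visit imputed per region by evaluating, at month 12, an
   ordinary least-squares line fitted to their own three earlier values.
   Imputation is per region, so downstream correlations use
   region-resolved trajectories. Subjects missing month 12 *and* another
   visit are rejected with an explicit exclusion error.
2. **Confound adjustment.** One pooled least-squares regression over all
   subjects, regions and timepoints residualizes thickness against age,
   sex, baseline lesion load (controls enter with 0 mL, keeping a single
   model for everyone) and the subject's baseline *mean* thickness (a
   global atrophy proxy; a region-level baseline covariate would absorb
   the covariance under study). Total intracranial volume is offered to
   the model only under `tiv_rule` and retained only if significant at
   the 5% level, to avoid collinearity with age and sex. The residuals
   are the adjusted thickness values; they have mean zero and are exactly
   orthogonal to every retained covariate. Standard errors and the TIV
   test are cluster-robust by subject, since records of the same subject
   are correlated. Residual skew/kurtosis are reported as a normality
   diagnostic, not enforced.
3. **Network construction.** Per (group, month): Pearson correlations of
   adjusted thickness across the group's subjects, then edge weights
   w_ij = |r_ij| with zero diagonal. Networks are complete weighted
   graphs — no thresholding; a weight of exactly 0 is simply no edge in
   path computations. Groups can be regrouped in configuration (e.g.
   all patients = converters ∪ non-converters), so post-hoc group
   definitions are config changes.
4. **Graph metrics** (Brain Connectivity Toolbox conventions):
   * nodal strength s_i = Σ_j w_ij and its mean;
   * weighted clustering coefficient, Onnela form with weights
     normalized by the network maximum, C_i =
     Σ_{j,h}(ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i(k_i−1)); the binary form is
     available behind `weighted=False` for sensitivity checks;
   * shortest paths on edge lengths 1/w (Dijkstra); characteristic path
     length L = mean l_ij over ordered pairs (undefined, and an error,
     on disconnected graphs); global efficiency = mean 1/l_ij;
   * local efficiency of node i: efficiency of the subgraph induced by
     i's neighbours with paths confined to that subgraph (the literal
     neighbour-subgraph definition, not the full-graph variant);
   * modularity: Newman weighted Q maximized by seeded Louvain at
     resolution 1 with restarts (100 by default for single networks, 10
     inside bootstrap loops), best Q kept. The edge-length convention
     1/w was chosen over −log w to match toolbox practice.
5. **Bootstrap inference.** For each group, B replicates (default 1000)
   draw n subjects with replacement; each replicate rebuilds the
   baseline and follow-up networks from the *same* resampled subjects
   and recomputes the metrics, so the within-replicate change
   (follow-up − baseline) is paired. Replicates leaving any region with
   zero variance are redrawn and counted. Per metric and phase
   (baseline / follow-up / change): percentile 95% CI and the
   two-sided tail-counting p-value
   p = 2·min[(#{x ≤ 0}+1)/(B+1), (#{x ≥ 0}+1)/(B+1)], capped at 1 —
   consistent with a p-value floor of ≈0.002 at B = 1000. A change is
   significant when its CI excludes 0. Between-group tests use the
   combined distribution of all B×B differences between the two groups'
   bootstrap estimates; its percentile interval and tail counts give
   the CI and p for the observed difference. The interval is taken
   directly from the difference distribution's percentiles (not
   recentered on the observed difference — the two readings coincide up
   to bootstrap symmetry; the direct one is implemented). The B×B array
   is built by chunked broadcasting: exact percentiles at bounded peak
   memory (8 MB at B = 1000).
6. **Nodal change maps.** For strength, clustering and local efficiency,
   the per-node OLS slope against month over the four monthly networks
   (units: metric per month); an endpoint mode ((month-12 − month-0)/12)
   is available behind a flag. These feed node-size/colour brain maps.

The percentile CI was preferred over BCa for transparency at small n;
the paired-change design and the B×B comparison are the protocol's
defining features and are implemented exactly as stated above.

## The synthetic cohort generator

The generator emulates a small longitudinal MRI study: groups of 7–21
subjects (default 7 controls, 9 converters, 12 non-converters), 68
Desikan–Killiany regions, visits at months 0/3/6/12, and a configurable
fraction of patients (default 3/21) whose month-12 visit is missing
entirely (visit-level, never controls).

Region thickness at each visit is multivariate normal around the group's
mean (default 2.5 mm, SD 0.12 mm) with a **signed one-factor
(equicorrelation-magnitude) structure**: off-diagonal correlation
±rho_t, with half the regions loading positively and half negatively on
the shared factor. Three properties motivate this default:

* every |r| quantity is identical in law to plain equicorrelation, so
  the closed-form link E[mean strength] ≈ (N−1)·rho survives and
  calibration tests have known truth;
* mixing positive and negative correlations matches what covariance
  networks (which analyse |r|) actually see in cortical data;
* the factor is orthogonal to a subject's mean thickness, so the
  atrophy adjustment (which includes baseline mean thickness) removes
  confound and atrophy variance *without* absorbing the network
  structure. With an unsigned factor the baseline mean *is* the factor,
  and the adjustment provably destroys the covariance under study.
  Plain unsigned equicorrelation remains available
  (`signed_blocks=False`).

Visits of one subject share a stable latent anatomy component
(`subject_persistence`, default 0.9 — the within-subject cross-visit
correlation, chosen to match reported longitudinal test–retest
reliability of cortical thickness). This leaves every per-visit marginal
untouched but is essential to the realism of the paired bootstrap: with
independent visits the change estimator would have the variance of two
independent estimates and the protocol's pairing would buy nothing.

Confound effects (age slope −0.005 mm/yr, sex offset −0.03 mm, lesion
slope −0.004 mm/mL by default) shift each subject's records uniformly,
giving the adjustment step real work. The study-shaped defaults put
converters' coupling at rho 0.55 declining to 0.35 by month 12 and keep
controls and non-converters flat at 0.40 — *calibration choices*: the
motivating study reports no correlation magnitudes, so these were fixed
once at values giving baseline connectivity ordering (converters >
others) and a 12-month converter decline, and not revisited.

**What the generator does not emulate:** region-specific covariance
topology (hubs, modules beyond the two sign blocks), spatially
structured atrophy, measurement artefacts, scanner drift, or informative
missingness. Passing tests therefore demonstrate that the *machinery* —
estimators, pairing, CIs, error rates — behaves correctly under a known
covariance model at study-realistic sample sizes; they cannot certify
sensitivity on real cortical data.

## Numerical and design notes

* Zero-variance regions are an error at network build (named region);
  inside the bootstrap, offending resamples are redrawn and counted.
* C_i = 0 for nodes with fewer than two neighbours; E_loc(i) = 0 for
  neighbourhoods smaller than two; all-zero networks have no defined
  modularity (error).
* Equicorrelation admissibility: rho ∈ (−1/(N−1), 1), enforced with the
  interval named in the error message; signed loadings do not change
  the eigenvalues.
* Determinism: every stochastic stage (generator, bootstrap, Louvain
  restarts) is seeded; per-group seeds are derived from the study seed
  by hashing the group label, so adding a group never shifts another
  group's stream. Two runs with the same config serialize to identical
  reports; the config hash is recorded in the report.
* The `include_baseline_mean` switch exists because the baseline-mean
  covariate is an aggregate of the outcome: under a known generative
  model it absorbs part of any subject-constant covariate effect, so
  slope-recovery checks run the regression without it. The default
  (with it) is the pipeline's analysis model.
* Demo problem sizes: the numbered analysis scripts and the acceptance
  script run the study-shaped cohort with B = 200 bootstrap replicates;
  the library default is B = 1000. Monte-Carlo calibration tests use
  one-group cohorts (n = 30 subjects, 20 regions, B = 200) with 100–200
  replicates per claim.

## Known limitations

* Group-level networks mean the bootstrap is the only inference route;
  nothing here supports subject-level covariance networks.
* Percentile CIs at n ≤ 12 subjects are approximate; the suite checks
  that the combined-bootstrap comparison's false-positive rate stays
  ≤ 7.5% over 200 null group pairs at n = 30, but very small groups
  (n = 7) should be read descriptively.
* The pooled adjustment regression assumes linear confound effects and
  shares one coefficient vector across groups and visits (by design, to
  preserve group relationships); timepoint indicators are deliberately
  not included.
* Characteristic path length requires a connected network; |r| networks
  are complete almost surely, so this matters only for hand-built
  graphs.
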