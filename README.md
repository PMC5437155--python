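# fndecomp

Multi-subject decomposition of fMRI-like data with **GIG-ICA** and
**IVA-GL**, plus the simulation and evaluation machinery needed to
compare them.

## The problem

Spatial group ICA decomposes multi-subject fMRI data into spatially
independent component maps (candidate functional networks) and their
time courses.  Two families of methods keep components comparable
across subjects while estimating subject-specific maps:

* **GIG-ICA** (group-information-guided ICA) first estimates
  group-level independent components from temporally concatenated,
  PCA-reduced data with Infomax, then refines each subject's component
  by maximizing, on the unit sphere of the subject's whitened space,

  `F(w) = λ·J(y) + (1−λ)·corr(y, r)`, `y = wᵀX`,

  where `J(y) = (E[log cosh y] − E[log cosh ν])²` is the log-cosh
  negentropy (ν standard normal) and `r` the guiding group IC.  The
  correspondence term preserves component identity and order; the
  negentropy term adapts the map to the subject's own source.

* **IVA-GL** jointly decomposes all subjects, minimizing independence
  within each subject while maximizing dependence within each *source
  component vector* (SCV) — the set of corresponding components across
  subjects.  A multivariate-Gaussian SCV model (IVA-G, cost
  `Σ_c ½ log det Σ_c − Σ_m log|det W_m|`) runs first and a
  multivariate-Laplace model (IVA-L, score `y_m/‖y_SCV‖₂`) refines it.

The package is aimed at methods researchers who want a tested,
self-contained environment for studying when group guidance beats
joint estimation (subject-common networks, low CNR, few time points,
wrong model order) and when it does not (subject-unique sources).
It ships a simulator that generates multi-subject data with controlled
spatial variability (random translation/rotation/magnification of
common blob templates), Rician noise at a target contrast-to-noise
ratio (CNR), evaluation via greedy template matching and absolute
Pearson accuracy with paired t-tests, plus test–retest machinery
(one-way ANOVA ICC, FDR-masked t-maps, functional network
connectivity, signed-network modularity Q, AMI, weighted graph
metrics) for real resting-state data in NIfTI form.

## Worked example

Ten simulated subjects, eight subject-common sources on a 148×148
grid, 150 time points, CNR = 1; both methods at model order 8:

```python
from fndecomp import sim, evaluate
from fndecomp.gigica import GIGICA
from fndecomp.iva import IVAGL

datasets, truths = sim.generate_experiment("exp1_quality", seed=1, cnr=1.0)
gig = GIGICA(datasets, n_components=8).fit(seed=1)
iva = IVAGL(datasets, n_components=8).fit(seed=1)
print(gig.summary())
score = evaluate.score_experiment({"iva_gl": iva, "gigica": gig}, truths)
print(score.ttests.round(4).to_string(index=False))
```

prints

```
gigica decomposition
  subjects:       10
  components:     8
  map size:       21904 voxels
  converged:      True
  lambda:         0.5
  mean ref corr:  0.8306
  flagged comps:  0
  domain source       t      p
 spatial   mean -2.7764 0.0215
temporal   mean  3.1482 0.0118
```

Each subject's estimated maps were greedy-matched to the mean
ground-truth templates; `t` is the paired t-statistic across the 10
subjects of per-subject mean absolute correlation with the truth,
IVA-GL minus GIG-ICA.  The negative spatial `t` means GIG-ICA
recovered the subject-common spatial maps more accurately at this
noise level (mean accuracy 0.902 vs 0.901; the paired design makes
the small but consistent difference detectable), while the positive
temporal `t` means IVA-GL's time courses — which live in the
denoised subject PCA subspace — were closer to the true ones.

A command-line interface mirrors the library
(`fndecomp simulate|run-sim|run-real|score`); e.g.

```bash
fndecomp run-sim --preset exp1_quality --cnr-values 0.5,1,2 --seed 1 --outdir out/
```

writes long-format accuracy and paired-t-test CSV tables plus a JSON
manifest that makes every number reproducible from the seed alone.

## Layout

| module | contents |
| --- | --- |
| `fndecomp.sim` | blob templates, perturbations, HRF-smoothed TCs, Rician noise, experiment presets |
| `fndecomp.decomp` | PCA reduction/whitening, full-batch Infomax, temporal-concatenation group ICA |
| `fndecomp.gigica` | negentropy, reference-guided subject IC estimation, `GIGICA` model |
| `fndecomp.iva` | IVA-G, IVA-L, permutation-aligned IVA-GL, `IVAGL` model, joint ISI |
| `fndecomp.evaluate` | greedy matching, accuracy, paired t-tests, Bonferroni, experiment scoring |
| `fndecomp.reliability` | one-sample t + BH-FDR masks, one-way ANOVA ICC, network/connectivity reliability |
| `fndecomp.netgraph` | FNC, signed leading-eigenvector modularity, AMI, weighted graph metrics |
| `fndecomp.experiments` | simulation/real-data runners, cross-method matching, CLI backend |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
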