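# munet — MR-guided micro-network post-processing for low-count PET

Low-count (low-dose or short) PET scans are dominated by Poisson noise;
smoothing them trades noise for resolution and bias, and resolution
modeling (RM) inside MLEM adds ringing artefacts of its own. When a
co-registered T1 MR volume is available, its anatomy can guide the
denoising. `munet` implements and benchmarks a deliberately small
("micro") fully-3-D convolutional network for this task — small enough
(tens of thousands of parameters against tens of millions of training
voxels) to be trained on noise realizations of a *single* subject
without overfitting — alongside the classical alternatives it has to
beat, on fully synthetic data.

The toolkit covers the whole study, for researchers in PET image
processing:

- **Phantoms** (`munet.phantom`) — procedural brain-like volumes:
  gray/white/dura compartments (4:1:0.5 FDG-like contrast), randomized
  spherical lesions (5-15 mm, 6:1-8:1), multiplicative random texture
  `tau = phi o (1 + gamma[2 G_sigma(rho) - 1])`, a T1-like guide with
  an independent texture stream, and a bone/tissue attenuation map.
- **Acquisition + MLEM** (`munet.petsim`) — 4.5 mm PSF blur, slice-wise
  parallel-beam projection with attenuation (an exact-adjoint sparse
  Joseph projector), Poisson prompts with 26 % randoms / 28 % scatter,
  and MLEM `theta <- theta/(H^T X^T 1) o H^T X^T (m / (X H theta + rho))`
  with an optional Gaussian RM kernel `H`.
- **Reference filters** (`munet.filters`) — Gaussian post-smoothing and
  T1-guided NLM, `w_ij = exp(-((g_i-g_j)/Omega)^2/2)` over 5x5x5
  neighborhoods, each with an exhaustive NRMSE grid optimizer.
- **Metrics** (`munet.metrics`) — normalized bias `b`, standard
  deviation `sigma` across noise realizations and NRMSE `eps` with
  `eps^2 = b^2 + sigma^2` exactly.
- **Networks** (`munet.nets`) — the 3-layer micro-net (n={32,32,1},
  s={5,3,1}, sigmoid/sigmoid/ELU; 43 745 parameters, 7-voxel receptive
  field) and a ~2.9 M-parameter U-net comparator, implemented in
  numpy/BLAS with exact backprop (no GPU or DL framework needed).
- **Training + experiments** (`munet.train_eval`) — NRMSE-proportional
  loss, full-batch Adam, early stopping on a validation subject, and an
  end-to-end harness with channel ablations and an architecture sweep.

## Worked example

```python
import numpy as np
from munet import phantom, petsim, filters, metrics

p = phantom.make_phantom(shape=(64, 64, 64), voxel_size=(2, 2, 2), seed=1)
geom = petsim.default_geometry(p.tau.shape, p.voxel_size, n_angles=48)
cfg = petsim.CountConfig(total_counts=300_000, seed=7)   # "low count"
sinos = petsim.simulate_realizations(p.tau, geom, p.mu_map, cfg, 10)

rec = petsim.mlem_batch(sinos, n_iter=50, dtype=np.float32)
imgs = rec.image / sinos[0].count_scale          # activity units
print("MLEM     ", metrics.metrics_triple(list(imgs), p.tau))

nlm = [filters.nlm_guided(v, p.mr_t1, omega=0.13) for v in imgs]
print("guided NLM", metrics.metrics_triple(nlm, p.tau))
```

prints (bias / std / NRMSE, in percent of the ground truth's root
energy, over the 10 noise realizations):

```
MLEM       MetricsTriple(bias_pct=58.47, std_pct=146.46, nrmse_pct=157.69, ...)
guided NLM MetricsTriple(bias_pct=30.03, std_pct=16.07, nrmse_pct=34.06, ...)
```

— at this count level the raw 50-iteration MLEM image is noise-
dominated (sigma 146 %), and the MR-guided filter removes most of the
variance at the cost of residual bias. The full study (training the
micro-net to map these inputs to the ground truth, with optimized PS
and NLM as rivals) is one call:

```python
from munet import train_eval as te
result = te.run_experiment(te.desk_config(seed=1))
print(result.methods[result.methods.subject == "mean"])
```

or, from the shell, `munet experiment --seed 1 --out results/`. The
`munet` CLI also exposes the individual stages (`phantom`, `simulate`,
`reconstruct`, `filter`, `train`, `predict`, `evaluate`).

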