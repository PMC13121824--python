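# deepcdm

Multi-layer (deep) cognitive diagnostic models with binary latent attribute
layers, fitted bottom-up by a layer-wise L1-penalized EM algorithm with
non-iterative spectral initialization.

A model with `D` latent layers generates binary item responses through a
cascade of one-layer diagnostic measurement models (main-effect / LLM,
all-effect / LCDM, or DINA, with an inverse-logit or identity link); the
deepest layer follows a saturated categorical distribution over its
attribute profiles. Between adjacent layers a binary Q-matrix encodes which
attributes feed each unit. In *exploratory* mode all Q-matrices are unknown
and recovered from the sparsity pattern of the penalized coefficient
estimates; in *confirmatory* mode known Q-matrices restrict the coefficient
support.

## What's inside

| module | role |
|---|---|
| `deepcdm.model_core` | profile spaces, effect design bases, layerwise conditionals, transition matrices, exact (factorized and brute-force) likelihoods, ladder-structure checks |
| `deepcdm.synthetic_data` | forward simulator and a configurable three-layer study design factory (`make_design` / `sample`) |
| `deepcdm.one_layer_em` | one-layer penalized EM: log-space E-step, coordinate-descent M-step with soft thresholding, proportion update, BIC |
| `deepcdm.spectral_init` | truncated-SVD denoising + inverse-link linearization + second SVD + Varimax + thresholding + rescaling into starting values |
| `deepcdm.layerwise_driver` | bottom-up driver: per-layer λ path with BIC selection and support refit, Q recovery, pseudo-observation imputation, confirmatory mode, classical full-EM baseline |
| `deepcdm.evaluation` | label-switching alignment (permutations + reflections), RMSE/aBias for proportion distributions and response-probability tables, Q row/entry recovery, replication studies |
| `deepcdm.cli_io` | CSV/TSV/YAML/JSON readers and writers, fit serialization, the `deepcdm` CLI |

## Quick start (Python)

```python
from deepcdm import make_design, sample, fit_exploratory, evaluate_fit

design = make_design("main_effect", N=2000, seed=1)   # (J,K1,K2,K3)=(30,7,4,2)
truth = sample(design)
fit = fit_exploratory(truth.responses, design.spec, seed=1)
print(fit.q_hats[0])                 # recovered layer-1 Q-matrix
print(evaluate_fit(fit, design).to_frame())
```

## CLI

```bash
deepcdm simulate --case main_effect --n 2000 --seed 1 --out sim/
deepcdm init --data sim/responses.csv --k 7 --out init/
deepcdm fit  --data sim/responses.csv --spec spec.yaml --seed 1 --out fit/
deepcdm fit  --data sim/responses.csv --spec spec.yaml --seed 1 \
             --mode confirmatory --q-matrices sim/ --out cfit/
deepcdm evaluate --fit-dir fit/ --design sim/design.yaml --out metrics.csv
deepcdm study --config study.yaml --out study/
```

`spec.yaml` holds the architecture:

```yaml
widths: [30, 7, 4, 2]      # items, then latent layer widths (shallow→deep)
models: [main_effect, main_effect, main_effect]
links: [inverse_logit, inverse_logit, inverse_logit]
```

All artifacts are plain text (headered CSV, YAML, JSON); `deepcdm fit` writes
per-layer coefficient/Q/proportion tables plus a `fit.json` with the full
λ-path provenance, and every run is bit-reproducible from its `--seed`.

## Notes

- Fitting uses the inverse-logit link; identity-link (ACDM/GDINA) estimation
  is out of scope (the generative side supports both links).
- DINA layers are *fitted* in the all-effect basis and their single required
  set is recovered from the dominant coefficient; DINO models are obtainable
  by recoding responses (DINA/DINO duality) and are not implemented.
- Exploratory fits are identified up to per-layer attribute permutations and
  0/1 reflections; `deepcdm.evaluation.align` resolves both before metrics.
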