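import numpy as np
import pytest

from deepcdm.model_core import (
    DeepCDMParams,
    DeepCDMSpec,
    EffectBasis,
    LayerCoefficients,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_coefficients(rng, n_units, K, model="main_effect", scale=1.0):
    """Random dense coefficients in the given effect basis."""
    if model == "dina":
        required = [
            tuple(sorted(rng.choice(K, size=rng.integers(1, K + 1), replace=False)))
            for _ in range(n_units)
        ]
        values = np.column_stack([
            rng.normal(scale=scale, size=n_units),
            rng.normal(loc=1.0, scale=scale, size=n_units),
        ])
        return LayerCoefficients("dina", K, values, required_sets=required)
    basis = (EffectBasis.main_effect(K) if model == "main_effect"
             else EffectBasis.all_effect(K))
    values = rng.normal(scale=scale, size=(n_units, basis.n_columns))
    return LayerCoefficients(model, K, values)


def random_params(rng, widths, models=None, scale=1.0):
    """Random full parameter set for a spec with the given widths."""
    D = len(widths) - 1
    if models is None:
        models = ["main_effect"] * D
    spec = DeepCDMSpec.build(widths, models)
    coeffs = [
        random_coefficients(rng, widths[d - 1], widths[d], models[d - 1], scale)
        for d in range(1, D + 1)
    ]
    pi = rng.dirichlet(np.ones(2 ** widths[D]))
    return DeepCDMParams(spec, coeffs, pi)
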