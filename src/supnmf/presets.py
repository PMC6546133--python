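"""Named default hyperparameter sets for each NMF model.

Exact regularization weights are application-dependent; these presets are
sensible starting points for TIC-scale spectra (intensities of order one)
and are what the CLI uses unless flags override them.  The supervision
weight ``gamma`` trades data fidelity against label fit: for the Flda
family it multiplies a least-squares term of order n, for Flog a
per-spectrum-averaged logistic loss, hence the very different scales.
"""

from __future__ import annotations

from typing import Any, Dict

from .nmf_unsupervised import NMFConfig

#: per-model keyword overrides applied on top of NMFConfig defaults
PRESETS: Dict[str, Dict[str, Any]] = {
    "FR": {"lambda_l1": 0.01, "mu": 0.01, "nu": 0.01, "rescale": True},
    "FO": {"sigma1": 1.0, "sigma2": 1.0},
    "FRO": {"lambda_l1": 0.01, "mu": 0.01, "nu": 0.01,
            "sigma1": 1.0, "sigma2": 1.0},
    "Flda": {"gamma": 10.0},
    "FRlda": {"lambda_l1": 0.01, "mu": 0.01, "nu": 0.01, "gamma": 10.0},
    "FROlda": {"lambda_l1": 0.01, "mu": 0.01, "nu": 0.01,
               "sigma1": 1.0, "sigma2": 1.0, "gamma": 10.0},
    "Flog": {"gamma": 3000.0, "max_iter": 1000, "rel_tol": 1e-10},
}


def preset_config(model: str, **overrides: Any) -> NMFConfig:
    """An :class:`NMFConfig` for ``model`` with preset defaults applied.

    Keyword overrides win over the preset, which wins over the dataclass
    defaults.
    """
    kwargs: Dict[str, Any] = {"model": model}
    kwargs.update(PRESETS.get(model, {}))
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return NMFConfig(**kwargs)
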