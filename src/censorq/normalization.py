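"""Sample normalization factors for Cq data.

Two families are provided:

* **MOD** (modified global mean): center each target's values over the
  samples where it is expressed, then center each sample's values around the
  mean of the centered values of its expressed targets.  The per-sample
  second-pass means are the normalization factors.  ``common_only`` restricts
  the second pass to targets expressed in every sample.
* **LMN** (latent mean normalization): the per-sample effect estimates from
  the censored regression fit.  Unlike MOD, censored wells contribute
  through their likelihood terms instead of being dropped, which keeps the
  factors stable as censoring grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import CqDataset
from .model import FitResult

__all__ = ["NormalizationFactors", "mod_normalize", "lmn_factors"]


@dataclass
class NormalizationFactors:
    factors: pd.Series  # one per sample, cycles
    method: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.factors.to_numpy(float))):
            raise ValueError("normalization factors must be finite")


def mod_normalize(
    dataset: CqDataset,
    common_only: bool = False,
    imputed_values: pd.DataFrame | None = None,
):
    """Modified global mean normalization.

    "Expressed" means uncensored; censored wells are excluded from both
    centering passes unless ``imputed_values`` (a targets x samples frame)
    supplies values for them first.

    Returns ``(normalized, factors)`` where ``normalized`` is a targets x
    samples frame (NaN at cells excluded from centering) and ``factors`` the
    per-sample second-pass means.
    """
    if dataset.n_targets < 2:
        raise ValueError("MOD normalization needs at least 2 targets")
    mat = dataset.cq_matrix()
    mask = dataset.censored_matrix()
    values = mat.where(~mask)  # censored -> NaN
    if imputed_values is not None:
        imputed_values = imputed_values.reindex(index=values.index, columns=values.columns)
        values = values.where(~mask, imputed_values)

    # pass (a): center within target over expressed (or imputed) wells
    centered = values.sub(values.mean(axis=1, skipna=True), axis=0)
    # pass (b): center within sample over expressed targets
    if common_only:
        complete = centered.notna().all(axis=1)
        if not complete.any():
            raise ValueError("common_only: no target is expressed in every sample")
        factors = centered.loc[complete].mean(axis=0, skipna=True)
    else:
        factors = centered.mean(axis=0, skipna=True)
    if factors.isna().any():
        raise ValueError("a sample has no expressed target; cannot normalize")
    normalized = centered.sub(factors, axis=1)
    method = "MOD_common" if common_only else "MOD"
    return normalized, NormalizationFactors(factors, method)


def lmn_factors(fit: FitResult, absolute: bool = False) -> NormalizationFactors:
    """Latent mean normalization factors from a fitted model.

    Global variant: beta_j (plus mu if ``absolute``).  Reference-gene
    variant: mu + beta_j + zeta_j (the reference-gene normalization factor;
    ``absolute`` has no further effect there).
    """
    if not fit.converged:
        raise RuntimeError("cannot extract normalization factors from a non-converged fit")
    p = fit.params
    if fit.design.spec.variant == "reference_genes":
        factors = p.mu + p.beta + p.zeta
        method = "reference_genes"
    else:
        factors = p.beta + (p.mu if absolute else 0.0)
        method = "LMN"
    if fit.design.include_beta:
        for k, members in fit.design.beta_cols.items():
            if len(members) < 2:
                warnings.warn(
                    f"group {fit.design.groups[k]!r} has a single sample; its "
                    "normalization factor is pinned at zero (low information)",
                    RuntimeWarning, stacklevel=2,
                )
    return NormalizationFactors(pd.Series(factors, index=fit.design.sample_ids), method)
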