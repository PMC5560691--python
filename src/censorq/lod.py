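"""Data-driven selection of the limit-of-detection threshold.

Instruments report Cq values up to their cycle limit, but values close to
that limit are often pure noise rather than genuine low-abundance signal.
Choosing where to place the censoring threshold (LOD) therefore matters: too
high and noise enters the model as data; too low and genuine observations
are discarded into censoring.

The default criterion is a held-out predictive log likelihood.  A fixed
evaluation set is drawn once: a random fraction of the wells lying below the
smallest candidate (hence uncensored under every candidate) in targets
retained under every candidate.  For each candidate L the model is fitted to
the remaining wells censored at L, and the candidate is scored by the mean
log density the fit assigns to the held-out wells.  Candidates above the
true instrument boundary admit noise into the fit and score poorly;
candidates below it discard genuine signal and also score (mildly) poorly,
so the criterion peaks at or near the boundary.  Holding the evaluation set
out of every fit removes the in-sample optimism that would otherwise
monotonically favor small candidates.  The criterion is pluggable for users
with their own scoring rule; ties resolve to the smallest candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CqDataset
from .model import ModelSpec, fit_ucnr, remove_heavily_censored

__all__ = ["LodProfile", "select_lod", "predictive_logdensity_criterion"]


@dataclass
class LodProfile:
    candidates: np.ndarray
    criterion: np.ndarray      # NaN where a candidate was skipped
    selected: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lod": self.candidates, "criterion": self.criterion,
                             "selected": self.candidates == self.selected})


def predictive_logdensity_criterion(fit, eval_obs: pd.DataFrame) -> float:
    """Mean log density of held-out wells under a fitted model."""
    design = fit.design
    p = fit.params
    t_pos = {t: i for i, t in enumerate(design.target_ids)}
    s_pos = {s: j for j, s in enumerate(design.sample_ids)}
    g_pos = {g: k for k, g in enumerate(design.groups)}
    alpha = p.alpha.to_numpy()
    beta = p.beta.to_numpy()
    zeta = p.zeta.to_numpy() if p.zeta is not None else None
    sigma = p.sigma.to_numpy()
    total, n = 0.0, 0
    for _, r in eval_obs.iterrows():
        if r["target_id"] not in t_pos or r["sample_id"] not in s_pos:
            continue
        i, j, k = t_pos[r["target_id"]], s_pos[r["sample_id"]], g_pos[r["group"]]
        m = p.mu + alpha[i] + beta[j]
        if design.spec.variant == "reference_genes" and design.is_reference[i]:
            m += zeta[j]
        else:
            m += design.gamma_value(p.theta, i, k)
        total += float(stats.norm.logpdf(r["cq"], loc=m, scale=sigma[i]))
        n += 1
    if n == 0:
        raise ValueError("empty evaluation set")
    return total / n


def select_lod(
    dataset: CqDataset,
    candidates,
    spec: ModelSpec | None = None,
    criterion=predictive_logdensity_criterion,
    holdout_fraction: float = 0.2,
    n_splits: int = 5,
    seed: int = 0,
) -> LodProfile:
    """Profile the model fit over candidate LOD values and pick the best.

    Each candidate L re-censors the dataset at L (all stored Cq >= L become
    censored at L), refits the model without the held-out wells, and
    evaluates the criterion on them; scores are averaged over ``n_splits``
    random holdouts shared by all candidates (paired comparison, which keeps
    the split noise out of the candidate differences).  Candidates whose fit
    is infeasible (e.g. a target loses every uncensored training well) are
    skipped with a warning.
    """
    candidates = np.sort(np.asarray(list(candidates), float))
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate LOD values")
    if not (0.0 < holdout_fraction < 1.0):
        raise ValueError("holdout_fraction must be in (0, 1)")
    spec = spec or ModelSpec()

    # targets retained under every candidate
    lo = float(candidates.min())
    retained_everywhere = None
    for L in candidates:
        reduced, _ = remove_heavily_censored(dataset.with_lod(L),
                                             spec.removal_threshold)
        kept = set(reduced.target_ids)
        retained_everywhere = kept if retained_everywhere is None \
            else retained_everywhere & kept

    eligible = dataset.data.index[
        (~dataset.data["censored"])
        & (dataset.data["cq"] < lo)
        & dataset.data["target_id"].isin(retained_everywhere)
    ]
    if len(eligible) < 10:
        raise ValueError("too few observations below the smallest candidate LOD")
    rng = np.random.default_rng(seed)
    n_hold = max(int(round(holdout_fraction * len(eligible))), 5)
    splits = []
    for _ in range(n_splits):
        held = pd.Index(rng.choice(eligible, size=n_hold, replace=False))
        eval_obs = dataset.data.loc[held]
        train = CqDataset(
            dataset.data.drop(index=held).reset_index(drop=True),
            dataset.lod, dataset.samples.copy(), dataset.targets.copy(),
        )
        splits.append((train, eval_obs))

    scores = np.full((n_splits, len(candidates)), np.nan)
    for idx, L in enumerate(candidates):
        for s, (train, eval_obs) in enumerate(splits):
            try:
                fit = fit_ucnr(train.with_lod(L), spec, compute_covariance=False)
                scores[s, idx] = criterion(fit, eval_obs)
            except Exception as exc:  # noqa: BLE001 - candidate skipped, profile continues
                warnings.warn(f"candidate LOD {L} (split {s}): skipped ({exc})",
                              RuntimeWarning, stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(scores, axis=0)
    if not np.isfinite(values).any():
        raise RuntimeError("no candidate LOD produced a valid fit")
    best = int(np.nanargmax(values))  # ties: argmax returns the first = smallest L
    return LodProfile(candidates=candidates, criterion=values,
                      selected=float(candidates[best]))
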