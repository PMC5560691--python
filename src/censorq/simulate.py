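"""Synthetic Cq data and the censoring-sweep experiment.

The generator draws complete (censoring-free) Cq matrices from the latent
linear model -- intercept + target effects + per-sample effects +
target-by-group differential expression + per-target Gaussian noise -- with
known truth, emulating a two-group microRNA panel.  The sweep experiment then
censors the largest remaining Cq value one step at a time (a stepwise
decrease of the limit of detection), re-runs the unified censored regression
and the sequential imputation pipelines, and tracks per-target estimates,
p-values, bias and RMSE as censoring accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import sequential_pipeline
from .datasets import CqDataset, make_dataset
from .inference import test_differential_expression
from .model import ModelSpec, fit_ucnr
from .normalization import mod_normalize

__all__ = [
    "SimConfig",
    "SweepConfig",
    "SweepTrace",
    "generate_synthetic",
    "censor_at_fraction",
    "nullify_groups",
    "censoring_sweep",
    "robustness_proportion",
]

BASELINE_METHODS = ("lod_t", "mnv1_t", "knn_t")
ALL_METHODS = ("ucnr",) + BASELINE_METHODS


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-group panel.

    Defaults mirror a neuroblastoma-style design: 50 targets on 61 samples
    split 22 / 39 between the groups, 20 differentially expressed targets at
    |delta| = 2 cycles (fold change 4), split evenly up/down so the panel-wide
    average shift is zero; per-target noise sigma_i uniform on [1.0, 2.5]
    cycles (typical between-tumor biological spread, giving two-sample test
    statistics of ~3-7 for the injected effects, the regime where handling of
    undetermined wells matters), target offsets alpha_i ~ N(0, 2^2), sample
    effects beta_j ~ N(0, 1), intercept 28 cycles.
    """

    n_targets: int = 50
    group_sizes: tuple = (22, 39)
    n_de: int = 20
    delta: float = 2.0
    mu: float = 28.0
    alpha_sd: float = 2.0
    beta_sd: float = 1.0
    sigma_range: tuple = (1.0, 2.5)
    seed: int | None = None

    def __post_init__(self):
        if self.n_de > self.n_targets:
            raise ValueError("n_de cannot exceed n_targets")
        if len(self.group_sizes) < 2:
            raise ValueError("need at least two groups")


def generate_synthetic(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw a complete dataset from the latent model.

    Returns ``(dataset, truth)`` where ``truth`` holds the per-target delta
    (sign convention: group1 latent mean minus group2 latent mean), the true
    per-sample normalization factors beta (centered within group, the
    estimable version), sigma_i, alpha_i and mu.  Fully reproducible for a
    fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    I = config.n_targets
    sizes = list(config.group_sizes)
    J = int(sum(sizes))
    group_of = np.repeat(np.arange(len(sizes)), sizes)

    alpha = rng.normal(0.0, config.alpha_sd, size=I)
    beta = rng.normal(0.0, config.beta_sd, size=J)
    for k in range(len(sizes)):
        beta[group_of == k] -= beta[group_of == k].mean()
    sigma = rng.uniform(*config.sigma_range, size=I)

    delta = np.zeros(I)
    n_up = config.n_de // 2
    de_idx = rng.choice(I, size=config.n_de, replace=False)
    delta[de_idx[:n_up]] = config.delta
    delta[de_idx[n_up:]] = -config.delta

    eps = rng.normal(0.0, 1.0, size=(I, J)) * sigma[:, None]
    cq = config.mu + alpha[:, None] + beta[None, :] + eps
    # delta = group1 - group2 latent Cq contrast: shift group 2 down by delta
    cq[:, group_of == 1] -= delta[:, None]

    target_ids = [f"t{i:03d}" for i in range(I)]
    sample_ids = [f"s{j:03d}" for j in range(J)]
    groups = [f"g{k + 1}" for k in group_of]
    obs = pd.DataFrame({
        "sample_id": np.repeat([sample_ids], I, axis=0).ravel(),
        "target_id": np.repeat(target_ids, J),
        "group": np.repeat([groups], I, axis=0).ravel(),
        "cq": cq.ravel(),
        "censored": False,
    })
    lod = float(cq.max()) + 1.0
    dataset = make_dataset(obs, lod)
    truth = {
        "delta": pd.Series(delta, index=target_ids),
        "beta": pd.Series(beta, index=sample_ids),
        "sigma": pd.Series(sigma, index=target_ids),
        "alpha": pd.Series(alpha, index=target_ids),
        "mu": config.mu,
        "de_targets": [target_ids[i] for i in de_idx],
    }
    return dataset, truth


def censor_at_fraction(dataset: CqDataset, fraction: float) -> CqDataset:
    """Censor the top ``fraction`` of stored Cq values by setting the LOD to
    the corresponding upper quantile."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return dataset
    lod = float(np.quantile(dataset.data["cq"], 1.0 - fraction))
    return dataset.with_lod(lod)


def nullify_groups(dataset: CqDataset, shift_group=None) -> CqDataset:
    """Shift one group per target so the MOD-normalized group means coincide.

    Requires complete (uncensored) data.  Used to build a null starting
    matrix before injecting known differential expression.
    """
    if dataset.data["censored"].any():
        raise ValueError("nullify_groups is defined on complete data")
    groups = dataset.groups
    if len(groups) != 2:
        raise ValueError("nullify_groups expects exactly two groups")
    if shift_group is None:
        shift_group = groups[1]
    other = groups[0] if shift_group == groups[1] else groups[1]
    normalized, _ = mod_normalize(dataset)
    gmap = dataset.samples["group"]
    shift_cols = gmap.index[gmap == shift_group]
    other_cols = gmap.index[gmap == other]
    diff = normalized[shift_cols].mean(axis=1) - normalized[other_cols].mean(axis=1)
    data = dataset.data.copy()
    adj = data["target_id"].map(diff)
    in_shift = data["group"] == shift_group
    data.loc[in_shift, "cq"] = data.loc[in_shift, "cq"] - adj[in_shift]
    return CqDataset(data, dataset.lod, dataset.samples.copy(), dataset.targets.copy())


@dataclass
class SweepConfig:
    """Controls for the censoring sweep."""

    methods: tuple = ALL_METHODS
    n_steps: int | None = None        # default: run until ~max_fraction censored
    max_fraction: float = 0.35
    stride_ucnr: int = 25             # refit the unified model every m steps
    stride_baselines: int = 5
    removal_threshold: float = 0.8
    alpha: float = 0.05
    k: int = 10
    comparison: tuple | None = None
    heteroskedastic: bool = True


@dataclass
class SweepTrace:
    """Per-evaluated-step records of the sweep.

    ``records`` is long-form: step, lod, n_censored, method, target_id,
    delta_hat, p, censored_frac (that target's censored fraction), removed.
    """

    records: pd.DataFrame
    truth: dict
    n_obs_total: int

    def evaluated_steps(self, method: str) -> list:
        sub = self.records[self.records["method"] == method]
        return sorted(sub["step"].unique())

    def summary(self) -> pd.DataFrame:
        """Bias and RMSE per (step, method), over targets retained at that
        step."""
        truth_delta = self.truth["delta"]
        rows = []
        for (step, method), sub in self.records.groupby(["step", "method"]):
            sub = sub[~sub["removed"] & sub["delta_hat"].notna()]
            if len(sub) == 0:
                continue
            err = sub["delta_hat"].to_numpy() - truth_delta.reindex(sub["target_id"]).to_numpy()
            rows.append({
                "step": step, "method": method,
                "n_censored": int(sub["n_censored"].iloc[0]),
                "n_targets": len(sub),
                "bias": float(np.mean(err)),
                "rmse": float(np.sqrt(np.mean(err ** 2))),
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def plot_summary(self, path) -> None:
        """Bias and RMSE panels against the censored count, one line per
        method, written to an image file (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        s = self.summary()
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
        for method, sub in s.groupby("method"):
            sub = sub.sort_values("n_censored")
            axes[0].plot(sub["n_censored"], sub["bias"], label=method)
            axes[1].plot(sub["n_censored"], sub["rmse"], label=method)
        axes[0].set_ylabel("bias of log2 fold-change estimates")
        axes[1].set_ylabel("RMSE")
        for ax in axes:
            ax.set_xlabel("censored Cq values")
        axes[0].axhline(0.0, color="grey", lw=0.5)
        axes[1].legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _run_method(method, dataset, config):
    spec = ModelSpec(
        removal_threshold=config.removal_threshold,
        heteroskedastic=config.heteroskedastic,
    )
    if method == "ucnr":
        res = test_differential_expression(dataset, spec, comparison=config.comparison)
        return res[["target_id", "delta_hat", "p_value"]]
    impute = {"lod_t": "lod", "mnv1_t": "mnv1", "knn_t": "knn",
              "lod_w": "lod", "mnv1_w": "mnv1", "knn_w": "knn"}[method]
    test = "wilcoxon" if method.endswith("_w") else "t"
    from .model import remove_heavily_censored

    reduced, _ = remove_heavily_censored(dataset, config.removal_threshold)
    res = sequential_pipeline(reduced, impute=impute, test=test, k=config.k,
                              comparison=config.comparison)
    return res[["target_id", "delta_hat", "p_value"]]


def censoring_sweep(dataset: CqDataset, truth: dict, config: SweepConfig | None = None) -> SweepTrace:
    """Censor the maximum uncensored Cq step by step and re-run all methods.

    Ties at the maximum are censored together in one step (the LOD must stay
    a strict upper bound for uncensored values); the step count advances by
    the tie size.  A method failing at a step is recorded as missing and the
    sweep continues.
    """
    config = config or SweepConfig()
    if dataset.data["censored"].any():
        raise ValueError("the sweep starts from a fully observed dataset")
    data = dataset.data.copy().reset_index(drop=True)
    n_total = len(data)
    limit = config.n_steps if config.n_steps is not None else int(config.max_fraction * n_total)

    records = []
    step = 0
    evaluated_since = {m: np.inf for m in config.methods}  # force step-0 evaluation

    def evaluate(step, lod, n_censored):
        # all censored wells are observed as the *current* LOD (the censoring
        # relation ties every undetermined well to the prevailing threshold,
        # not to the step at which it was censored)
        current = CqDataset(data.copy(), lod, dataset.samples.copy(), dataset.targets.copy())
        if step > 0:
            current = current.with_lod(lod)
        cens_frac = data.groupby("target_id")["censored"].mean()
        from .model import remove_heavily_censored

        _, removed = remove_heavily_censored(current, config.removal_threshold)
        removed_ids = set(removed["target_id"]) if len(removed) else set()
        for method in config.methods:
            stride = config.stride_ucnr if method == "ucnr" else config.stride_baselines
            if evaluated_since[method] < stride:
                continue
            evaluated_since[method] = 0
            try:
                res = _run_method(method, current, config)
            except Exception as exc:  # noqa: BLE001 - recorded, sweep continues
                records.append({
                    "step": step, "lod": lod, "n_censored": n_censored,
                    "method": method, "target_id": None, "delta_hat": np.nan,
                    "p": np.nan, "censored_frac": np.nan, "removed": False,
                    "error": str(exc),
                })
                continue
            got = set(res["target_id"])
            for _, r in res.iterrows():
                records.append({
                    "step": step, "lod": lod, "n_censored": n_censored,
                    "method": method, "target_id": r["target_id"],
                    "delta_hat": r["delta_hat"], "p": r["p_value"],
                    "censored_frac": float(cens_frac[r["target_id"]]),
                    "removed": False, "error": "",
                })
            for tid in dataset.target_ids:
                if tid in got:
                    continue
                records.append({
                    "step": step, "lod": lod, "n_censored": n_censored,
                    "method": method, "target_id": tid, "delta_hat": np.nan,
                    "p": np.nan, "censored_frac": float(cens_frac[tid]),
                    "removed": tid in removed_ids, "error": "",
                })

    # step 0: no censoring
    evaluate(0, dataset.lod, 0)

    while step < limit:
        unc = ~data["censored"]
        if not unc.any():
            break
        vmax = data.loc[unc, "cq"].max()
        ties = unc & (data["cq"] == vmax)
        data.loc[ties, "censored"] = True
        n_tied = int(ties.sum())
        step += n_tied
        for m in evaluated_since:
            evaluated_since[m] += n_tied
        n_censored = int(data["censored"].sum())
        evaluate(step, float(vmax), n_censored)

    rec = pd.DataFrame(records)
    return SweepTrace(records=rec, truth=truth, n_obs_total=n_total)


def recovery_experiment(
    n_reps: int = 200,
    censor_fraction: float = 0.30,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    removal_threshold: float = 0.8,
) -> pd.DataFrame:
    """Monte-Carlo accuracy/precision comparison at a fixed censoring level.

    Each replicate draws a complete panel, censors the top
    ``censor_fraction`` of Cq values, and scores the unified model and the
    three sequential pipelines against the known truth.  Returns one row per
    replicate with the panel-mean bias and the RMSE of every method.
    """
    if rng is None:
        rng = np.random.default_rng()
    config = config or SimConfig()
    rows = []
    for _ in range(n_reps):
        ds, truth = generate_synthetic(config, rng=rng)
        dsc = censor_at_fraction(ds, censor_fraction)
        row = {}
        try:
            fit = fit_ucnr(dsc, ModelSpec(removal_threshold=removal_threshold),
                           compute_covariance=False)
            from .inference import delta_contrasts

            res = delta_contrasts(fit).set_index("target_id")["delta_hat"]
            err = res - truth["delta"].reindex(res.index)
            row["bias_ucnr"] = float(err.mean())
            row["rmse_ucnr"] = float(np.sqrt((err ** 2).mean()))
        except Exception:
            row["bias_ucnr"] = np.nan
            row["rmse_ucnr"] = np.nan
        from .model import remove_heavily_censored

        reduced, _ = remove_heavily_censored(dsc, removal_threshold)
        for name in ("lod", "mnv1", "knn"):
            try:
                b = sequential_pipeline(reduced, impute=name)
                eb = (b.set_index("target_id")["delta_hat"]
                      - truth["delta"].reindex(b["target_id"]).to_numpy())
                row[f"rmse_{name}"] = float(np.sqrt((eb ** 2).mean()))
            except Exception:
                row[f"rmse_{name}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def type1_experiment(
    n_reps: int = 200,
    censor_fraction: float = 0.20,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> float:
    """Empirical per-test rejection rate under the global null (no
    differential expression), at a fixed censoring level."""
    if rng is None:
        rng = np.random.default_rng()
    config = config or SimConfig(group_sizes=(20, 20), n_de=0)
    rates = []
    for _ in range(n_reps):
        ds, _ = generate_synthetic(config, rng=rng)
        dsc = censor_at_fraction(ds, censor_fraction)
        res = test_differential_expression(dsc)
        rates.append(float((res["p_value"] < alpha).mean()))
    return float(np.mean(rates))


def robustness_proportion(trace: SweepTrace, target_id, method, alpha: float = 0.05) -> float:
    """Fraction of a truly DE target's observations that can be censored
    before the method's test first fails to reject at level ``alpha``.

    Returns the target's censored fraction at the last evaluated step before
    the p-value first exceeds alpha; if rejection holds at every evaluated
    step up to the target's removal (or the end of the sweep), the fraction
    at that last significant step is returned.
    """
    truth_delta = trace.truth["delta"]
    if target_id not in truth_delta.index or truth_delta[target_id] == 0.0:
        raise ValueError(f"target {target_id!r} is not differentially expressed in truth")
    sub = trace.records[
        (trace.records["method"] == method)
        & (trace.records["target_id"] == target_id)
    ].sort_values("step")
    last_ok = 0.0
    for _, r in sub.iterrows():
        if r["removed"] or not np.isfinite(r["p"]):
            break
        if r["p"] > alpha:
            return float(last_ok)
        last_ok = r["censored_frac"]
    return float(min(last_ok, 1.0))
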