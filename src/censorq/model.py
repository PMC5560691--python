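"""Censored normal regression for Cq values.

The latent quantification cycle of target ``i`` in sample ``j`` (group ``k``)
is modelled as a linear model

    C*_ijk = mu + alpha_i + beta_j + gamma_ik + eps_ij,   eps_ij ~ N(0, sigma_i^2)

observed through right censoring at the limit of detection,
``C = min(C*, LOD)``.  ``alpha_i`` is the target's expression level,
``beta_j`` a per-sample normalization factor, and the target-by-group
interaction ``gamma_ik`` carries differential expression.  A variant for
reference-gene normalization adds per-sample effects ``zeta_j`` that act only
on designated reference genes,

    C*_ijk = mu + alpha_i + beta_j + R_i zeta_j + (1 - R_i) gamma_ik + eps_ij,

so that ``mu + beta_j + zeta_j`` is the reference-gene normalization factor.

The model is over-parameterized as written; a fixed full-rank coding is used:

* ``alpha`` sums to zero over targets,
* ``beta`` sums to zero within each group (per-sample technical effects;
  group-level location is carried by the interactions),
* interactions for the first group are pinned at zero,
* ``zeta`` sums to zero over all samples (reference-gene variant).

All parameters, including a per-target noise scale ``sigma_i`` (log
parameterized), are estimated jointly by maximum likelihood: uncensored wells
contribute normal log densities, censored wells normal log survival
probabilities.  Standard errors come from the observed information at the
optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import pinvh

from .datasets import CqDataset, CqValidationError

__all__ = [
    "ModelSpec",
    "Design",
    "ParameterVector",
    "FitResult",
    "build_design",
    "censored_loglik",
    "fit_ucnr",
    "remove_heavily_censored",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelSpec:
    """Which model variant to fit and how.

    variant
        ``"global"`` (global-mean style normalization through per-sample
        effects) or ``"reference_genes"`` (normalization anchored on flagged
        reference genes).
    heteroskedastic
        Per-target noise scales sigma_i (default) versus a single shared
        sigma -- useful for very small designs.
    removal_threshold
        Targets whose overall censoring fraction reaches this value are
        dropped before fitting (common practice for mostly-missing targets).
    """

    variant: str = "global"
    heteroskedastic: bool = True
    removal_threshold: float = 0.8
    sigma_floor: float = 1e-3
    max_iter: int = 2000
    grad_tol: float = 1e-6

    def __post_init__(self):
        if self.variant not in {"global", "reference_genes"}:
            raise ValueError("variant must be 'global' or 'reference_genes'")
        if not (0.0 < self.removal_threshold <= 1.0):
            raise ValueError("removal_threshold must be in (0, 1]")


class Design:
    """Full-rank incidence of observations on free parameters.

    Holds the dense mean design matrix ``X`` (n_obs x n_mean_params), the
    observation arrays (values, censoring flags, target indices) and the
    parameter layout.  The number of free parameters equals the rank of the
    assembled design by construction; estimability of the fold-change
    contrasts follows because they are linear in the interaction (and zeta)
    coefficients, all of which are free coordinates.
    """

    def __init__(self, dataset: CqDataset, spec: ModelSpec):
        self.spec = spec
        self.lod = dataset.lod
        self.target_ids = dataset.target_ids
        self.sample_ids = dataset.sample_ids
        self.groups = dataset.groups
        if len(self.groups) < 2:
            raise CqValidationError("at least two groups are required")
        I, J, K = len(self.target_ids), len(self.sample_ids), len(self.groups)

        t_pos = {t: i for i, t in enumerate(self.target_ids)}
        s_pos = {s: j for j, s in enumerate(self.sample_ids)}
        g_pos = {g: k for k, g in enumerate(self.groups)}
        sample_group = dataset.samples["group"].map(g_pos).to_numpy()
        group_sizes = np.bincount(sample_group, minlength=K)
        if (group_sizes == 0).any():
            raise CqValidationError("every group needs at least one sample")

        is_ref = dataset.targets["is_reference"].to_numpy().astype(bool)
        if spec.variant == "reference_genes":
            if not is_ref.any():
                raise CqValidationError("reference_genes variant needs >=1 reference gene")
            if is_ref.all():
                raise CqValidationError("reference_genes variant needs >=1 target of interest")
        self.is_reference = is_ref
        # targets that get interaction parameters
        self.interaction_targets = (
            np.arange(I) if spec.variant == "global" else np.flatnonzero(~is_ref)
        )

        d = dataset.data
        self.y = d["cq"].to_numpy(dtype=float)
        self.censored = d["censored"].to_numpy(dtype=bool)
        self.obs_target = d["target_id"].map(t_pos).to_numpy()
        self.obs_sample = d["sample_id"].map(s_pos).to_numpy()
        self.obs_group = sample_group[self.obs_sample]
        n = len(self.y)

        # ---- parameter layout ----
        names: list[str] = ["mu"]
        self.n_alpha = I - 1
        names += [f"alpha[{self.target_ids[i]}]" for i in range(self.n_alpha)]
        # beta: within-group sum-to-zero; dropped entirely for I == 1 where
        # per-sample effects would saturate the mean structure
        self.include_beta = I > 1
        self.beta_cols: dict[int, np.ndarray] = {}
        n_beta = 0
        if self.include_beta:
            for k in range(K):
                members = np.flatnonzero(sample_group == k)
                self.beta_cols[k] = members
                n_beta += max(len(members) - 1, 0)
        self.n_beta = n_beta
        self.n_zeta = (J - 1) if spec.variant == "reference_genes" else 0
        self.n_gamma = len(self.interaction_targets) * (K - 1)
        self.n_sigma = I if spec.heteroskedastic else 1

        ofs = 1
        self.sl_alpha = slice(ofs, ofs + self.n_alpha); ofs += self.n_alpha
        self.sl_beta = slice(ofs, ofs + self.n_beta); ofs += self.n_beta
        self.sl_zeta = slice(ofs, ofs + self.n_zeta); ofs += self.n_zeta
        self.sl_gamma = slice(ofs, ofs + self.n_gamma); ofs += self.n_gamma
        self.n_mean = ofs
        self.sl_logsigma = slice(ofs, ofs + self.n_sigma)
        self.n_params = ofs + self.n_sigma

        # ---- assemble X ----
        X = np.zeros((n, self.n_mean))
        X[:, 0] = 1.0
        # alpha, sum-to-zero coding
        for r in range(n):
            i = self.obs_target[r]
            if i < self.n_alpha:
                X[r, 1 + i] = 1.0
            else:
                X[r, self.sl_alpha] = -1.0
        # beta, sum-to-zero within group
        if self.include_beta:
            col = self.sl_beta.start
            self.beta_col_of_sample = np.full(J, -1)
            self.beta_last_sample = {}
            for k in range(K):
                members = self.beta_cols[k]
                for m in members[:-1]:
                    self.beta_col_of_sample[m] = col
                    col += 1
                self.beta_last_sample[k] = members[-1]
            for r in range(n):
                j = self.obs_sample[r]
                k = self.obs_group[r]
                members = self.beta_cols[k]
                if len(members) < 2:
                    continue
                if j == members[-1]:
                    for m in members[:-1]:
                        X[r, self.beta_col_of_sample[m]] = -1.0
                else:
                    X[r, self.beta_col_of_sample[j]] = 1.0
        # zeta, sum-to-zero over all samples, reference targets only
        if self.n_zeta:
            z0 = self.sl_zeta.start
            for r in range(n):
                if not is_ref[self.obs_target[r]]:
                    continue
                j = self.obs_sample[r]
                if j < J - 1:
                    X[r, z0 + j] = 1.0
                else:
                    X[r, self.sl_zeta] = -1.0
        # interactions, group 0 pinned at zero
        g0 = self.sl_gamma.start
        self.gamma_col = {}
        for a, i in enumerate(self.interaction_targets):
            for k in range(1, K):
                self.gamma_col[(i, k)] = g0 + a * (K - 1) + (k - 1)
        for r in range(n):
            i, k = self.obs_target[r], self.obs_group[r]
            if k >= 1 and (i, k) in self.gamma_col:
                X[r, self.gamma_col[(i, k)]] = 1.0
        self.X = X

        names += [f"beta[{self.sample_ids[j]}]"
                  for j in range(J) if self.include_beta and
                  getattr(self, "beta_col_of_sample", np.full(J, -1))[j] >= 0]
        names += [f"zeta[{self.sample_ids[j]}]" for j in range(self.n_zeta)]
        for a, i in enumerate(self.interaction_targets):
            for k in range(1, K):
                names.append(f"gamma[{self.target_ids[i]},{self.groups[k]}]")
        if spec.heteroskedastic:
            names += [f"log_sigma[{t}]" for t in self.target_ids]
        else:
            names += ["log_sigma"]
        self.param_names = names

        self.sigma_index = self.obs_target if spec.heteroskedastic else np.zeros(n, int)

    # ---- parameter bookkeeping ----
    def sigma_of(self, theta: np.ndarray) -> np.ndarray:
        return np.exp(theta[self.sl_logsigma])[self.sigma_index]

    def mean_of(self, theta: np.ndarray) -> np.ndarray:
        return self.X @ theta[: self.n_mean]

    def full_beta(self, theta: np.ndarray) -> np.ndarray:
        """Expand free beta coordinates to one value per sample."""
        J = len(self.sample_ids)
        beta = np.zeros(J)
        if not self.include_beta:
            return beta
        for k, members in self.beta_cols.items():
            if len(members) < 2:
                continue
            free = [theta[self.beta_col_of_sample[m]] for m in members[:-1]]
            beta[members[:-1]] = free
            beta[members[-1]] = -float(np.sum(free))
        return beta

    def full_zeta(self, theta: np.ndarray) -> np.ndarray:
        J = len(self.sample_ids)
        zeta = np.zeros(J)
        if self.n_zeta:
            free = theta[self.sl_zeta]
            zeta[: J - 1] = free
            zeta[J - 1] = -float(np.sum(free))
        return zeta

    def full_alpha(self, theta: np.ndarray) -> np.ndarray:
        I = len(self.target_ids)
        alpha = np.zeros(I)
        free = theta[self.sl_alpha]
        alpha[: I - 1] = free
        if I > 1:
            alpha[I - 1] = -float(np.sum(free))
        return alpha

    def gamma_value(self, theta: np.ndarray, i: int, k: int) -> float:
        if k == 0 or (i, k) not in self.gamma_col:
            return 0.0
        return float(theta[self.gamma_col[(i, k)]])

    # ---- contrasts ----
    def delta_contrast_matrix(self, ref_group, alt_group, flip: bool = False):
        """Rows: one log2 fold-change contrast per target of interest.

        The contrast is the interaction difference gamma_{i,ref} -
        gamma_{i,alt}, re-anchored so that it is identified jointly with
        normalization: under the global variant the across-target average
        interaction difference is subtracted (an overall shift is a
        normalization effect, exactly as in global-mean normalization); under
        the reference-gene variant the zeta group-mean difference is
        subtracted (differential expression relative to the reference genes).
        """
        groups = self.groups
        if ref_group not in groups or alt_group not in groups:
            raise CqValidationError("unknown group in comparison")
        kr, ka = groups.index(ref_group), groups.index(alt_group)
        tgts = self.interaction_targets
        m = len(tgts)
        C = np.zeros((m, self.n_params))
        for a, i in enumerate(tgts):
            if kr >= 1:
                C[a, self.gamma_col[(i, kr)]] += 1.0
            if ka >= 1:
                C[a, self.gamma_col[(i, ka)]] -= 1.0
        if self.spec.variant == "global" and m > 1:
            # anchor on targets whose group contrast is identified on both
            # sides (>= 1 uncensored well in each compared group); a target
            # with a fully censored group has a barely-identified interaction
            # whose variance would otherwise contaminate every contrast.
            # With a single target there is no panel to normalize against and
            # the contrast is the plain group difference.
            anchored = np.zeros(m, bool)
            for a, i in enumerate(tgts):
                rows = self.obs_target == i
                ok = True
                for k in (kr, ka):
                    grp = rows & (self.obs_group == k)
                    if not np.any(grp & ~self.censored):
                        ok = False
                        break
                anchored[a] = ok
            if not anchored.any():
                anchored[:] = True
            C -= C[anchored].mean(axis=0, keepdims=True)
        elif self.spec.variant == "reference_genes":
            # zeta group-mean contrast as a linear functional of free zeta
            J = len(self.sample_ids)
            M = np.zeros((J, self.n_params))
            for j in range(J - 1):
                M[j, self.sl_zeta.start + j] = 1.0
            M[J - 1, self.sl_zeta] = -1.0
            sample_group = np.zeros(J, int)
            # recover group of each sample from beta_cols / obs arrays
            for j in range(J):
                rows = np.flatnonzero(self.obs_sample == j)
                if len(rows):
                    sample_group[j] = self.obs_group[rows[0]]
            zr = M[sample_group == kr].mean(axis=0)
            za = M[sample_group == ka].mean(axis=0)
            C -= (zr - za)[None, :]
        if flip:
            C = -C
        ids = [self.target_ids[i] for i in tgts]
        return ids, C


@dataclass
class ParameterVector:
    """Named view of a flat parameter vector."""

    mu: float
    alpha: pd.Series
    beta: pd.Series
    zeta: pd.Series | None
    gamma: pd.DataFrame  # targets x groups, group 0 column identically 0
    log_sigma: pd.Series
    theta: np.ndarray = field(repr=False)

    @property
    def sigma(self) -> pd.Series:
        return np.exp(self.log_sigma)

    @classmethod
    def from_theta(cls, theta: np.ndarray, design: Design) -> "ParameterVector":
        tid, sid, grp = design.target_ids, design.sample_ids, design.groups
        gamma = pd.DataFrame(0.0, index=tid, columns=grp)
        for (i, k), c in design.gamma_col.items():
            gamma.iloc[i, k] = theta[c]
        if design.spec.heteroskedastic:
            ls = pd.Series(theta[design.sl_logsigma], index=tid)
        else:
            ls = pd.Series(float(theta[design.sl_logsigma][0]), index=tid)
        return cls(
            mu=float(theta[0]),
            alpha=pd.Series(design.full_alpha(theta), index=tid),
            beta=pd.Series(design.full_beta(theta), index=sid),
            zeta=pd.Series(design.full_zeta(theta), index=sid)
            if design.spec.variant == "reference_genes" else None,
            gamma=gamma,
            log_sigma=ls,
            theta=np.asarray(theta, float),
        )


@dataclass
class FitResult:
    params: ParameterVector
    loglik: float
    covariance: np.ndarray
    converged: bool
    n_iter: int
    removed_targets: pd.DataFrame
    design: Design
    warnings: list = field(default_factory=list)
    loglik_init: float = np.nan


def build_design(dataset: CqDataset, spec: ModelSpec | None = None) -> Design:
    """Construct the full-rank design for a dataset under a model spec."""
    return Design(dataset, spec or ModelSpec())


def _loglik_and_grad(theta: np.ndarray, design: Design):
    """Censored-normal log likelihood and its analytic gradient.

    Uncensored wells: log phi((y - m)/sigma) - log sigma.
    Censored wells:   log(1 - Phi((lod - m)/sigma)), evaluated through the
    normal log survival function, stable for standardized residuals out to
    +/- 40.  Censored wells use their stored bound (the LOD at the time of
    censoring), so sweeps with a moving LOD are handled naturally.
    """
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter vector")
    m = design.mean_of(theta)
    sigma = design.sigma_of(theta)
    y, cens = design.y, design.censored
    unc = ~cens

    ll = 0.0
    dl_dm = np.zeros_like(y)
    dl_dlogsig_obs = np.zeros_like(y)

    r = (y[unc] - m[unc]) / sigma[unc]
    ll += float(np.sum(-0.5 * _LOG2PI - 0.5 * r * r - np.log(sigma[unc])))
    dl_dm[unc] = r / sigma[unc]
    dl_dlogsig_obs[unc] = r * r - 1.0

    if cens.any():
        z = (y[cens] - m[cens]) / sigma[cens]
        logsf = stats.norm.logsf(z)
        ll += float(np.sum(logsf))
        lam = np.exp(stats.norm.logpdf(z) - logsf)  # hazard
        dl_dm[cens] = lam / sigma[cens]
        dl_dlogsig_obs[cens] = lam * z

    grad = np.empty_like(theta)
    grad[: design.n_mean] = design.X.T @ dl_dm
    grad[design.sl_logsigma] = np.bincount(
        design.sigma_index, weights=dl_dlogsig_obs, minlength=design.n_sigma
    )
    return ll, grad


def censored_loglik(params, dataset: CqDataset, spec: ModelSpec | None = None) -> float:
    """Evaluate the censored-normal log likelihood at given parameters.

    ``params`` may be a flat vector in design order or a
    :class:`ParameterVector`.
    """
    spec = spec or ModelSpec()
    design = Design(dataset, spec)
    theta = params.theta if isinstance(params, ParameterVector) else np.asarray(params, float)
    if theta.shape != (design.n_params,):
        raise ValueError(
            f"expected {design.n_params} parameters, got {theta.shape}"
        )
    ll, _ = _loglik_and_grad(theta, design)
    return ll


def remove_heavily_censored(dataset: CqDataset, threshold: float = 0.8):
    """Drop targets whose overall censoring fraction reaches ``threshold``.

    Returns the reduced dataset and a frame recording, for each removed
    target, the per-group censored counts.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    summary = dataset.censoring_by_target()
    removed = summary[summary["fraction"] >= threshold].reset_index()
    keep = summary.index[summary["fraction"] < threshold]
    return dataset.subset_targets(keep), removed


def _initial_theta(design: Design) -> np.ndarray:
    """Deterministic start: LOD-imputed values (censored wells already hold
    their bound), least squares on the design, per-target residual SD."""
    theta = np.zeros(design.n_params)
    eta, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    theta[: design.n_mean] = eta
    resid = design.y - design.X @ eta
    if design.spec.heteroskedastic:
        for i in range(len(design.target_ids)):
            ri = resid[design.obs_target == i]
            sd = float(np.sqrt(np.mean(ri * ri))) if len(ri) else 1.0
            theta[design.sl_logsigma.start + i] = np.log(max(sd, 0.05))
    else:
        sd = float(np.sqrt(np.mean(resid * resid)))
        theta[design.sl_logsigma.start] = np.log(max(sd, 0.05))
    return theta


def _maximize(theta0: np.ndarray, design: Design, spec: ModelSpec,
              sigma_lower: np.ndarray | None = None):
    """Blockwise ascent followed by a joint quasi-Newton polish.

    For fixed noise scales the censored-normal log likelihood is concave in
    the mean parameters, so the mean block converges to its unique optimum;
    the noise-scale block given interior means cannot collapse.  Alternating
    the two blocks keeps the iterate in the interior basin of attraction
    before the joint L-BFGS-B pass sharpens the optimum.
    """
    floor = np.log(spec.sigma_floor)
    if sigma_lower is None:
        sigma_lower = np.full(design.n_sigma, floor)
    opts = {"maxiter": spec.max_iter, "maxfun": 10 * spec.max_iter,
            "ftol": 1e-13, "gtol": spec.grad_tol}
    theta = theta0.copy()
    n_iter = 0
    mean_idx = np.arange(design.n_mean)
    sig_idx = np.arange(design.n_mean, design.n_params)

    def block_nll(sub, idx):
        th = theta.copy()
        th[idx] = sub
        ll, g = _loglik_and_grad(th, design)
        return -ll, -g[idx]

    for _ in range(2):
        r = optimize.minimize(block_nll, theta[mean_idx], args=(mean_idx,),
                              jac=True, method="L-BFGS-B", options=opts)
        theta[mean_idx] = r.x
        n_iter += r.nit
        r = optimize.minimize(block_nll, theta[sig_idx], args=(sig_idx,),
                              jac=True, method="L-BFGS-B",
                              bounds=[(lo, None) for lo in sigma_lower],
                              options=opts)
        theta[sig_idx] = r.x
        n_iter += r.nit

    def nll(th):
        ll, g = _loglik_and_grad(th, design)
        return -ll, -g

    bounds = [(None, None)] * design.n_mean + [(lo, None) for lo in sigma_lower]
    res = optimize.minimize(nll, theta, jac=True, method="L-BFGS-B",
                            bounds=bounds, options=opts)
    n_iter += res.nit
    return res.x, res, n_iter


def _numeric_hessian(theta: np.ndarray, design: Design) -> np.ndarray:
    """Observed information: central differences of the analytic gradient."""
    p = len(theta)
    H = np.zeros((p, p))
    for a in range(p):
        h = 1e-5 * (1.0 + abs(theta[a]))
        tp = theta.copy(); tp[a] += h
        tm = theta.copy(); tm[a] -= h
        _, gp = _loglik_and_grad(tp, design)
        _, gm = _loglik_and_grad(tm, design)
        H[a] = (gp - gm) / (2.0 * h)
    return -0.5 * (H + H.T)  # negative loglik Hessian, symmetrized


def fit_ucnr(
    dataset: CqDataset,
    spec: ModelSpec | None = None,
    compute_covariance: bool = True,
) -> FitResult:
    """Fit the censored normal regression by maximum likelihood.

    Applies the heavy-censoring removal rule, builds the full-rank design,
    starts from a deterministic least-squares initialization, maximizes the
    likelihood with L-BFGS-B using the analytic gradient, and (optionally)
    computes the observed-information covariance.
    """
    spec = spec or ModelSpec()
    ds, removed = remove_heavily_censored(dataset, spec.removal_threshold)
    if ds.n_targets == 0:
        raise CqValidationError("all targets removed by the censoring threshold")
    warn_list = []
    summary = ds.censoring_by_target()
    if (summary["n_censored"] == summary["n_obs"]).any():
        bad = summary.index[summary["n_censored"] == summary["n_obs"]].tolist()
        raise CqValidationError(
            f"targets with no uncensored observation after removal: {bad}"
        )
    for g in ds.groups:
        fully = summary[f"n_censored[{g}]"] == summary[f"n_obs[{g}]"]
        for t in summary.index[fully]:
            warn_list.append(
                f"target {t}: group '{g}' fully censored (estimates rely on censored terms)"
            )

    design = Design(ds, spec)
    theta0 = _initial_theta(design)
    ll0, _ = _loglik_and_grad(theta0, design)

    theta, res, n_iter = _maximize(theta0, design, spec)
    ll, grad = _loglik_and_grad(theta, design)
    gnorm = float(np.max(np.abs(grad)))

    # Degeneracy guard.  The per-target-variance likelihood is unbounded: the
    # per-sample effects can interpolate any single target exactly, sending
    # that sigma_i to zero with infinite likelihood gain.  The blockwise
    # ascent in _maximize stays in the interior basin in practice, but if a
    # sigma still collapses to the floor while its target has more uncensored
    # wells than groups (so a near-zero noise scale is not supported by the
    # data), refit once with that target's noise scale bounded below by a
    # fraction of its initial residual spread.
    floor = np.log(spec.sigma_floor)
    degenerate = []
    if spec.heteroskedastic:
        summary2 = ds.censoring_by_target()
        n_unc = (summary2["n_obs"] - summary2["n_censored"]).to_numpy()
        K = len(design.groups)
        for i in np.flatnonzero(theta[design.sl_logsigma] <= floor + 1e-6):
            if n_unc[i] > K:
                degenerate.append(i)
    if degenerate:
        lower = np.full(design.n_sigma, floor)
        init_ls = theta0[design.sl_logsigma]
        for i in degenerate:
            lower[i] = max(floor, init_ls[i] - np.log(2.0))
            warn_list.append(
                f"sigma collapsed for target {design.target_ids[i]}; refit with "
                "guarded lower bound"
            )
        theta, res, n2 = _maximize(theta0, design, spec, sigma_lower=lower)
        n_iter += n2
        ll, grad = _loglik_and_grad(theta, design)
        gnorm = float(np.max(np.abs(grad)))

    at_bound = theta[design.sl_logsigma] <= floor + 1e-9
    free_mask = np.ones(design.n_params, bool)
    free_mask[design.sl_logsigma] = ~at_bound
    converged = bool(res.success) or float(np.max(np.abs(grad[free_mask]))) <= 10 * spec.grad_tol
    if not converged:
        warn_list.append(f"optimizer did not converge: {res.message} (|grad|={gnorm:.2e})")
        warnings.warn(warn_list[-1], RuntimeWarning, stacklevel=2)
    for i in np.flatnonzero(at_bound):
        tid = design.target_ids[i] if spec.heteroskedastic else "(common)"
        warn_list.append(f"sigma at lower bound for target {tid}")

    if compute_covariance:
        H = _numeric_hessian(theta, design)
        cov = pinvh(H)
    else:
        cov = np.full((design.n_params, design.n_params), np.nan)

    return FitResult(
        params=ParameterVector.from_theta(theta, design),
        loglik=float(ll),
        covariance=cov,
        converged=converged,
        n_iter=int(res.nit),
        removed_targets=removed,
        design=design,
        warnings=warn_list,
        loglik_init=float(ll0),
    )
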