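"""The matched-pair Bayesian negative-binomial differential model.

For every feature j the counts follow a mean-dispersion negative
binomial, ``Var = lambda + alpha * lambda**2``, with log mean

    log lambda_ij = log N_i + C_{k(i),j} + D_j * I[i = case]

where ``N_i`` is the sample's raw sequencing depth (a fixed offset, so
the model is self-normalizing), ``C_{k(i),j}`` is a free per-pair
baseline log proportion, and ``D_j`` is the case/control natural-log
fold change.  The dispersion follows a DESeq2-style trend with linear
and quadratic variance terms plus a disease-group shift,

    alpha_ij = a0_{b(i),j} / lambda_ij + a1_{b(i),j} + beta_{p(i),j}

with ``b(i)`` the cohort/batch of sample i and ``p(i)`` its disease
group.  Priors:

    a0 ~ LogNormal(0, 1)            a1 ~ LogNormal(log 10, 0.1)
    beta_p ~ Normal(beta_mu, beta_sigma)
    beta_mu ~ Normal(0, 3)          beta_sigma ~ LogNormal(log 0.1, 0.1)
    C_k ~ Normal(C_mu, C_sigma)
    C_mu ~ Normal(1/d, 3)           C_sigma ~ Normal(1/d, 1) truncated > 0
    D ~ Normal(0, 3)

Features are conditionally independent, so all per-feature posteriors
are sampled jointly by a batched HMC run (features x chains chains at
once) with analytic gradients.  The group-averaged variant replaces the
per-pair baselines with one shared baseline per feature and is the
standard (unmatched) differential-ranking comparator.

Both variants are exposed as scikit-learn style estimators
(:class:`MatchedDifferentialModel`, :class:`GroupAveragedDifferentialModel`)
with ``fit`` / fitted attributes / ``get_params``; the module-level
``fit_matched_model`` / ``fit_group_averaged_model`` functions are thin
wrappers over them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln
from sklearn.base import BaseEstimator

from ._hmc import sample_hmc
from .io import FeatureTable, MetadataTable
from .matching import MatchedPairs

__all__ = [
    "ModelInput",
    "PosteriorDifferentials",
    "Diagnostics",
    "MatchedDifferentialModel",
    "GroupAveragedDifferentialModel",
    "build_model_input",
    "fit_matched_model",
    "fit_group_averaged_model",
    "compute_diagnostics",
    "joint_log_density",
    "nb_log_pmf",
]

log = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# model input


@dataclass
class ModelInput:
    """Counts and design information for one fit.

    Invariants: every pair index appears on exactly two samples, one
    carrying the case indicator; ``log_depth`` is the natural log of the
    sample's raw total count.
    """

    counts: np.ndarray          # (n_samples, d) int
    log_depth: np.ndarray       # (n_samples,)
    pair_index: np.ndarray      # (n_samples,) int in [0, n_pairs)
    case_indicator: np.ndarray  # (n_samples,) 0/1
    cohort_index: np.ndarray    # (n_samples,) int in [0, n_cohorts)
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.log_depth = np.asarray(self.log_depth, dtype=np.float64)
        self.pair_index = np.asarray(self.pair_index, dtype=np.int64)
        self.case_indicator = np.asarray(self.case_indicator, dtype=np.int64)
        self.cohort_index = np.asarray(self.cohort_index, dtype=np.int64)
        n = self.counts.shape[0]
        for name in ("log_depth", "pair_index", "case_indicator", "cohort_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match the number of samples")
        for k in range(self.n_pairs):
            members = self.case_indicator[self.pair_index == k]
            if len(members) != 2 or members.sum() != 1:
                raise ValueError(
                    f"pair {k} must have exactly one case and one control sample"
                )

    @property
    def n_pairs(self) -> int:
        return int(self.pair_index.max()) + 1 if len(self.pair_index) else 0

    @property
    def n_cohorts(self) -> int:
        return int(self.cohort_index.max()) + 1 if len(self.cohort_index) else 0

    @property
    def d(self) -> int:
        return self.counts.shape[1]


def build_model_input(
    table: FeatureTable,
    pairs: MatchedPairs,
    metadata: MetadataTable | None = None,
) -> ModelInput:
    """Assemble a :class:`ModelInput` from a table and a pairing.

    Samples outside any pair are excluded; offsets are the natural logs
    of the raw (unrarefied) per-sample totals.
    """
    order: list[str] = []
    pair_idx: list[int] = []
    case_ind: list[int] = []
    for k, case, ctrl in pairs.pairs:
        for sid, ind in ((ctrl, 0), (case, 1)):
            if sid not in table.sample_ids:
                raise ValueError(f"pair {k} references sample {sid!r} missing from the table")
            order.append(sid)
            pair_idx.append(k)
            case_ind.append(ind)
    sub = table.select_samples(order)
    totals = sub.totals()
    if np.any(totals <= 0):
        empty = [order[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"sample(s) with zero total count: {empty}")
    if metadata is not None:
        cohorts = sorted({str(metadata.row(s)["cohort_id"]) for s in order})
        cmap = {c: i for i, c in enumerate(cohorts)}
        cohort_idx = [cmap[str(metadata.row(s)["cohort_id"])] for s in order]
    else:
        cohort_idx = [0] * len(order)
    return ModelInput(
        counts=sub.counts,
        log_depth=np.log(totals.astype(float)),
        pair_index=np.array(pair_idx),
        case_indicator=np.array(case_ind),
        cohort_index=np.array(cohort_idx),
        sample_ids=order,
        feature_ids=list(table.feature_ids),
    )


# ---------------------------------------------------------------------------
# posterior containers


@dataclass
class Diagnostics:
    """Split-chain rank-normalized Rhat and bulk ESS per parameter."""

    rhat: np.ndarray
    ess: np.ndarray
    # the finite-sample floor of split-Rhat is sqrt((n-1)/n), so values a
    # little below 1 are expected at small draw counts
    rhat_floor: float = 1.0 - 1e-3

    def __post_init__(self) -> None:
        if np.any(self.rhat < self.rhat_floor):
            raise ValueError("Rhat below its finite-sample floor; draws look corrupted")


@dataclass
class PosteriorDifferentials:
    """Posterior draws and summaries of the per-feature log fold change D_j.

    ``chain_draws`` has shape (chains, draws_per_chain, d); ``summary``
    carries mean, sd, central 90% interval bounds, median, Rhat and bulk
    ESS per feature.  ``nuisance`` holds posterior-mean point summaries
    of the baseline and dispersion parameters.
    """

    feature_ids: list[str]
    chain_draws: np.ndarray
    summary: pd.DataFrame
    nuisance: dict = field(default_factory=dict)
    mcmc_config: dict = field(default_factory=dict)
    skipped_features: list[str] = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.chain_draws.shape[2]

    @property
    def m(self) -> int:
        """Total number of posterior draws (chains x draws per chain)."""
        return self.chain_draws.shape[0] * self.chain_draws.shape[1]

    @property
    def draws(self) -> np.ndarray:
        """Flattened draws, shape (m, d)."""
        return self.chain_draws.reshape(-1, self.d)

    def with_draws(self, chain_draws: np.ndarray) -> "PosteriorDifferentials":
        """Return a copy with replaced draws and recomputed summaries."""
        return PosteriorDifferentials(
            feature_ids=list(self.feature_ids),
            chain_draws=chain_draws,
            summary=summarize_draws(chain_draws, self.feature_ids),
            nuisance=dict(self.nuisance),
            mcmc_config=dict(self.mcmc_config),
            skipped_features=list(self.skipped_features),
        )


def summarize_draws(chain_draws: np.ndarray, feature_ids: list[str]) -> pd.DataFrame:
    """Per-feature posterior summary with convergence diagnostics."""
    flat = chain_draws.reshape(-1, chain_draws.shape[2])
    q05, q50, q95 = np.quantile(flat, [0.05, 0.5, 0.95], axis=0)
    if chain_draws.shape[0] >= 2 and chain_draws.shape[1] >= 4:
        diag = compute_diagnostics(chain_draws)
        rhat, ess = diag.rhat, diag.ess
    else:
        rhat = np.full(len(feature_ids), np.nan)
        ess = np.full(len(feature_ids), np.nan)
    return pd.DataFrame(
        {
            "feature": feature_ids,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "q05": q05,
            "q50": q50,
            "q95": q95,
            "rhat": rhat,
            "ess": ess,
        }
    )


def compute_diagnostics(draws: np.ndarray) -> Diagnostics:
    """Split-chain rank-normalized Rhat and bulk ESS (via ArviZ).

    ``draws`` must have shape (chains, draws_per_chain, n_parameters)
    with at least two chains and four draws per chain.
    """
    draws = np.asarray(draws)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    if draws.shape[0] < 2:
        raise ValueError("diagnostics require at least 2 chains; run more chains")
    if draws.shape[1] < 4:
        raise ValueError("diagnostics require at least 4 draws per chain")
    ds = az.convert_to_dataset(draws)
    rhat = np.atleast_1d(az.rhat(ds)["x"].to_numpy())
    ess = np.atleast_1d(az.ess(ds, method="bulk")["x"].to_numpy())
    # antithetic chains can push the ESS estimate past m; cap at the draw count
    ess = np.minimum(ess, draws.shape[0] * draws.shape[1])
    n_half = max(draws.shape[1] // 2, 2)
    floor = float(np.sqrt((n_half - 1) / n_half)) - 1e-3
    return Diagnostics(rhat=rhat, ess=ess, rhat_floor=floor)


# ---------------------------------------------------------------------------
# log density and gradients

_HYPER = {
    "la0_mu": 0.0, "la0_sd": 1.0,
    "la1_mu": np.log(10.0), "la1_sd": 0.1,
    "beta_mu_sd": 3.0,
    "lbs_mu": np.log(0.1), "lbs_sd": 0.1,
    "cmu_sd": 3.0, "csig_sd": 1.0,
    "d_sd": 3.0,
}


class _Layout:
    """Index layout of the unconstrained per-feature parameter vector.

    Order: D | C_1..C_K | C_mu | log C_sigma | log a0 (per cohort) |
    log a1 (per cohort) | phi_control, phi_case | beta_mu | log beta_sigma.

    ``phi_p = mean_b(a1_b) + beta_p`` is the sampled coordinate for the
    group-level dispersion: the likelihood identifies only this sum, so
    sampling it directly (with ``beta_p = phi_p - mean(a1)`` inside the
    prior) decouples the data-informed dispersion level from the
    prior-only ridge between a1 and beta_mu, which otherwise mixes
    slowly.  The joint density is unchanged up to the constant-free
    change of variables (unit Jacobian).
    """

    def __init__(self, n_pairs: int, n_cohorts: int):
        self.K = n_pairs
        self.B = n_cohorts
        self.D = 0
        self.C = slice(1, 1 + n_pairs)
        self.C_mu = 1 + n_pairs
        self.u = 2 + n_pairs
        self.la0 = slice(3 + n_pairs, 3 + n_pairs + n_cohorts)
        self.la1 = slice(3 + n_pairs + n_cohorts, 3 + n_pairs + 2 * n_cohorts)
        self.phi = slice(3 + n_pairs + 2 * n_cohorts, 5 + n_pairs + 2 * n_cohorts)
        self.beta_mu = 5 + n_pairs + 2 * n_cohorts
        self.w = 6 + n_pairs + 2 * n_cohorts
        self.dim = 7 + n_pairs + 2 * n_cohorts


def nb_log_pmf(y, lam, alpha):
    """Log pmf of the mean-dispersion negative binomial.

    Mean ``lam``, variance ``lam + alpha * lam**2`` (gamma-Poisson with
    gamma shape ``1/alpha``).  ``alpha`` must be positive.
    """
    y = np.asarray(y, dtype=np.float64)
    lam = np.asarray(lam, dtype=np.float64)
    r = 1.0 / np.asarray(alpha, dtype=np.float64)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + y * np.log(lam) + r * np.log(r) - (y + r) * np.log(r + lam)
    )


class _FeaturePosterior:
    """Vectorized joint log density + gradient over a flat batch.

    Batch element b = (feature, chain); per-element count rows are
    materialized up front so any subset of elements can be evaluated
    (as delayed-rejection retries require).
    """

    def __init__(self, model_input: ModelInput, pooled_baseline: bool,
                 alpha_floor: float = ALPHA_FLOOR, n_chains: int = 1):
        mi = model_input
        self.S = mi.counts.shape[0]
        self.F = mi.counts.shape[1]
        self.Cn = n_chains
        self.K = 1 if pooled_baseline else mi.n_pairs
        self.Bc = mi.n_cohorts
        self.pooled = pooled_baseline
        self.alpha_floor = alpha_floor
        self.layout = _Layout(self.K, self.Bc)
        self.y_feat = mi.counts.T.astype(np.float64)      # (F, S)
        self.y = np.repeat(self.y_feat, n_chains, axis=0)  # (F*Cn, S)
        self.logN = mi.log_depth                          # (S,)
        self.case = mi.case_indicator.astype(np.float64)  # (S,)
        self.pair = np.zeros(self.S, dtype=np.int64) if pooled_baseline else mi.pair_index
        self.cohort = mi.cohort_index
        self.group = mi.case_indicator                    # 0 = control, 1 = case
        # scatter matrices for segment sums
        self.P_pair = np.zeros((self.S, self.K))
        self.P_pair[np.arange(self.S), self.pair] = 1.0
        self.P_coh = np.zeros((self.S, self.Bc))
        self.P_coh[np.arange(self.S), self.cohort] = 1.0
        self.P_grp = np.zeros((self.S, 2))
        self.P_grp[np.arange(self.S), self.group] = 1.0
        self.d_inv = 1.0 / mi.d  # prior center 1/d, taken over the full table
        self.gammaln_y1 = gammaln(self.y + 1.0)

    def logp(self, theta: np.ndarray, rows: np.ndarray | None = None) -> np.ndarray:
        """Joint log density only (no gradient; used by slice updates)."""
        return self._eval(theta, rows, want_grad=False)[0]

    def logp_and_grad(self, theta: np.ndarray,
                      rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        return self._eval(theta, rows, want_grad=True)

    # theta: (B, dim); rows optionally selects batch elements
    def _eval(self, theta: np.ndarray, rows: np.ndarray | None = None,
              want_grad: bool = True):
        # warmup excursions can overflow transiently; the sampler rejects
        # non-finite states, so the warnings carry no information
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            return self._eval_inner(theta, rows, want_grad)

    def _eval_inner(self, theta: np.ndarray, rows: np.ndarray | None,
                    want_grad: bool):
        lo = self.layout
        H = _HYPER
        y = self.y if rows is None else self.y[rows]
        gln_y1 = self.gammaln_y1 if rows is None else self.gammaln_y1[rows]
        D = theta[..., lo.D][..., None]                    # (B, 1)
        eta = theta[..., lo.C]                             # (B, K), non-centered
        C_mu = theta[..., lo.C_mu][..., None]
        u = theta[..., lo.u][..., None]
        C_sig = np.exp(u)
        C = C_mu + C_sig * eta                             # pair baselines
        la0 = theta[..., lo.la0]
        la1 = theta[..., lo.la1]
        a1_all = np.exp(la1)                               # (B, Bc)
        a1_bar = a1_all.mean(axis=-1, keepdims=True)       # (B, 1)
        a0 = np.exp(la0)[..., self.cohort]                 # (B, S)
        a1_dev = (a1_all - a1_bar)[..., self.cohort]       # zero for one cohort
        phi = theta[..., lo.phi]                           # (B, 2)
        beta_mu = theta[..., lo.beta_mu][..., None]
        w = theta[..., lo.w][..., None]
        beta_sig = np.exp(w)
        beta_resid = (phi - a1_bar - beta_mu) / beta_sig   # (phi_p = a1_bar + beta_p)
        phi_i = phi[..., self.group]                       # (B, S)

        C_i = C[..., self.pair]
        log_lam = self.logN + C_i + D * self.case
        log_lam = np.clip(log_lam, -30.0, 30.0)
        lam = np.exp(log_lam)
        alpha_raw = a0 / lam + a1_dev + phi_i
        floored = alpha_raw < self.alpha_floor
        alpha = np.where(floored, self.alpha_floor, alpha_raw)
        r = 1.0 / alpha

        log_r_lam = np.log(r + lam)
        ll = (
            gammaln(y + r) - gammaln(r) - gln_y1
            + y * log_lam + r * np.log(r) - (y + r) * log_r_lam
        )
        loglik = ll.sum(axis=-1)

        # priors (constants dropped); C is non-centered so eta ~ N(0,1)
        logprior = (
            -0.5 * (D[..., 0] / H["d_sd"]) ** 2
            - 0.5 * (eta ** 2).sum(axis=-1)
            - 0.5 * ((C_mu[..., 0] - self.d_inv) / H["cmu_sd"]) ** 2
            - 0.5 * ((C_sig[..., 0] - self.d_inv) / H["csig_sd"]) ** 2 + u[..., 0]
            - 0.5 * (((la0 - H["la0_mu"]) / H["la0_sd"]) ** 2).sum(axis=-1)
            - 0.5 * (((la1 - H["la1_mu"]) / H["la1_sd"]) ** 2).sum(axis=-1)
            - 0.5 * (beta_resid ** 2).sum(axis=-1) - 2.0 * w[..., 0]
            - 0.5 * (beta_mu[..., 0] / H["beta_mu_sd"]) ** 2
            - 0.5 * ((w[..., 0] - H["lbs_mu"]) / H["lbs_sd"]) ** 2
        )
        logp = loglik + logprior
        if not want_grad:
            return logp, None

        # --- gradients ---
        frac = (y + r) / (r + lam)
        dll_dloglam_fix = y - lam * frac                  # alpha held fixed
        G_r = digamma(y + r) - digamma(r) + np.log(r) + 1.0 - log_r_lam - frac
        G_alpha = np.where(floored, 0.0, -G_r * r * r)    # dll/dalpha
        # alpha depends on lambda through a0/lambda
        T = dll_dloglam_fix - G_alpha * a0 / lam          # dll/dloglam total

        grad = np.zeros_like(theta)
        grad[..., lo.D] = (T * self.case).sum(axis=-1) - D[..., 0] / H["d_sd"] ** 2
        T_pair = T @ self.P_pair                           # (B, K)
        grad[..., lo.C] = C_sig * T_pair - eta
        grad[..., lo.C_mu] = T.sum(axis=-1) - (
            (C_mu[..., 0] - self.d_inv) / H["cmu_sd"] ** 2
        )
        grad[..., lo.u] = (
            C_sig[..., 0] * (T_pair * eta).sum(axis=-1)
            - C_sig[..., 0] * (C_sig[..., 0] - self.d_inv) / H["csig_sd"] ** 2 + 1.0
        )
        grad[..., lo.la0] = (G_alpha * a0 / lam) @ self.P_coh - (la0 - H["la0_mu"]) / H["la0_sd"] ** 2
        G_coh = G_alpha @ self.P_coh                       # (F, Cn, Bc)
        G_tot = G_coh.sum(axis=-1, keepdims=True)
        r_over_sig = (beta_resid / beta_sig).sum(axis=-1, keepdims=True)
        grad[..., lo.la1] = (
            a1_all * (G_coh - G_tot / self.Bc + r_over_sig / self.Bc)
            - (la1 - H["la1_mu"]) / H["la1_sd"] ** 2
        )
        grad[..., lo.phi] = G_alpha @ self.P_grp - beta_resid / beta_sig
        grad[..., lo.beta_mu] = r_over_sig[..., 0] - beta_mu[..., 0] / H["beta_mu_sd"] ** 2
        grad[..., lo.w] = (beta_resid ** 2).sum(axis=-1) - 2.0 - (
            (w[..., 0] - H["lbs_mu"]) / H["lbs_sd"] ** 2
        )
        return logp, grad

    def initial_positions(self, n_chains: int, rng: np.random.Generator) -> np.ndarray:
        """Data-driven start values with per-chain overdispersion."""
        lo = self.layout
        prop = np.log((self.y_feat + 0.5) / np.exp(self.logN))  # (F, S)
        ctrl = self.case == 0
        theta = np.zeros((self.F, n_chains, lo.dim))
        if self.pooled:
            C_init = prop.mean(axis=1, keepdims=True)      # (F, 1)
        else:
            # per pair, the control sample's observed log proportion
            ctrl_cols = np.array(
                [np.flatnonzero((self.pair == k) & ctrl)[0] for k in range(self.K)]
            )
            C_init = prop[:, ctrl_cols]                    # (F, K)
        case_cols = np.flatnonzero(self.case == 1)
        ctrl_cols_all = np.flatnonzero(ctrl)
        contrast = prop[:, case_cols].mean(axis=1) - prop[:, ctrl_cols_all].mean(axis=1)
        theta[..., lo.D] = contrast[:, None]
        c_mu0 = C_init.mean(axis=1)
        c_sig0 = C_init.std(axis=1) + 0.1
        theta[..., lo.C] = ((C_init - c_mu0[:, None]) / c_sig0[:, None])[:, None, :]
        theta[..., lo.C_mu] = c_mu0[:, None]
        theta[..., lo.u] = np.log(c_sig0)[:, None]
        theta[..., lo.la0] = 0.0
        theta[..., lo.la1] = np.log(10.0)
        # moment-based dispersion guess feeds beta_mu (can be negative);
        # within-pair contrast variance ~ 2*alpha + Poisson-scale noise
        if self.pooled:
            v = prop.var(axis=1)
        else:
            case_by_pair = np.array(
                [np.flatnonzero((self.pair == k) & (self.case == 1))[0] for k in range(self.K)]
            )
            v = 0.5 * (prop[:, case_by_pair] - C_init).var(axis=1)
        alpha_hat = np.clip(v - (1.0 / np.maximum(self.y_feat.mean(axis=1), 0.5)), 0.05, 50.0)
        theta[..., lo.phi] = alpha_hat[:, None, None]
        theta[..., lo.beta_mu] = (alpha_hat - 10.0)[:, None]
        theta[..., lo.w] = np.log(0.1)
        jitter = rng.normal(0.0, 0.2, size=theta.shape)
        jitter[..., lo.phi] *= 0.1 * alpha_hat[:, None, None]  # keep phi positive-ish
        jitter[..., lo.la1] *= 0.25
        jitter[..., lo.w] *= 0.25
        theta += jitter
        theta[..., lo.D] += rng.normal(0.0, 0.3, size=(self.F, n_chains))
        return theta


def joint_log_density(params: dict, model_input: ModelInput, feature: int | str,
                      pooled_baseline: bool = False,
                      alpha_floor: float = ALPHA_FLOOR) -> float:
    """Joint log density (likelihood + priors) for one feature.

    ``params`` carries constrained-scale values: ``D``, ``C`` (length
    n_pairs, or 1 when pooled), ``C_mu``, ``C_sigma``, ``a0``/``a1``
    (length n_cohorts), ``beta_control``, ``beta_case``, ``beta_mu``,
    ``beta_sigma``.  The density is evaluated in the sampler's
    unconstrained parameterization (log transforms of positive scales
    and non-centered beta), so values differ from the constrained-space
    density by constant Jacobian terms; differences of this function at
    fixed positive-scale parameters are parameterization-independent.
    """
    j = model_input.feature_ids.index(feature) if isinstance(feature, str) else int(feature)
    sub = ModelInput(
        counts=model_input.counts[:, [j]],
        log_depth=model_input.log_depth,
        pair_index=model_input.pair_index,
        case_indicator=model_input.case_indicator,
        cohort_index=model_input.cohort_index,
        sample_ids=list(model_input.sample_ids),
        feature_ids=[model_input.feature_ids[j]],
    )
    post = _FeaturePosterior(sub, pooled_baseline, alpha_floor)
    post.d_inv = 1.0 / model_input.d  # prior centers use the full table's d
    lo = post.layout
    theta = np.zeros((1, lo.dim))
    theta[..., lo.D] = float(params["D"])
    c_mu = float(params["C_mu"])
    c_sig = float(params["C_sigma"])
    theta[..., lo.C] = (np.asarray(params["C"], dtype=float) - c_mu) / c_sig
    theta[..., lo.C_mu] = c_mu
    theta[..., lo.u] = np.log(c_sig)
    theta[..., lo.la0] = np.log(np.asarray(params["a0"], dtype=float))
    theta[..., lo.la1] = np.log(np.asarray(params["a1"], dtype=float))
    bs = float(params["beta_sigma"])
    bm = float(params["beta_mu"])
    a1_bar = float(np.mean(np.asarray(params["a1"], dtype=float)))
    theta[..., lo.phi] = np.array(
        [a1_bar + float(params["beta_control"]), a1_bar + float(params["beta_case"])]
    )
    theta[..., lo.beta_mu] = bm
    theta[..., lo.w] = np.log(bs)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter value")
    logp, _ = post.logp_and_grad(theta)
    return float(logp[0])


# ---------------------------------------------------------------------------
# estimators


class _DifferentialModelBase(BaseEstimator):
    """Shared machinery of the matched and group-averaged estimators."""

    _pooled_baseline = False

    def __init__(self, chains: int = 4, warmup: int = 1000, draws: int = 1000,
                 seed: int = 0, target_accept: float = 0.9,
                 max_leapfrog: int = 16, alpha_floor: float = ALPHA_FLOOR):
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed
        self.target_accept = target_accept
        self.max_leapfrog = max_leapfrog
        self.alpha_floor = alpha_floor

    def fit(self, model_input: ModelInput, y=None) -> "_DifferentialModelBase":
        """Sample the per-feature posteriors by batched adaptive HMC."""
        if not isinstance(model_input, ModelInput):
            raise TypeError("fit expects a ModelInput; see build_model_input")
        for name in ("chains", "warmup", "draws"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be positive")
        nonzero = model_input.counts.sum(axis=0) > 0
        skipped = [f for f, keep in zip(model_input.feature_ids, nonzero) if not keep]
        if skipped:
            warnings.warn(
                f"skipping {len(skipped)} all-zero feature(s): {skipped[:5]}"
                + ("..." if len(skipped) > 5 else ""),
                stacklevel=2,
            )
        mi = ModelInput(
            counts=model_input.counts[:, nonzero],
            log_depth=model_input.log_depth,
            pair_index=model_input.pair_index,
            case_indicator=model_input.case_indicator,
            cohort_index=model_input.cohort_index,
            sample_ids=list(model_input.sample_ids),
            feature_ids=[f for f, keep in zip(model_input.feature_ids, nonzero) if keep],
        ) if skipped else model_input

        post = _FeaturePosterior(mi, self._pooled_baseline, self.alpha_floor,
                                 n_chains=self.chains)
        rng = np.random.default_rng(self.seed)
        theta0 = post.initial_positions(self.chains, rng)
        F, Cn, dim = theta0.shape

        lo = post.layout
        # all dispersion-side coordinates are slice-sampled: the alpha
        # floor kinks the phi conditionals, and the tight beta prior
        # couples (a1, beta_mu, beta_sigma) in a stiff curved valley that
        # would force tiny Hamiltonian steps.  None of them affect the
        # conditional of (D, C) except through phi, so the smooth block
        # keeps large steps and mixes fast.
        slice_coords = (
            tuple(range(lo.la0.start, lo.la1.stop))
            + (lo.phi.start, lo.phi.start + 1, lo.beta_mu, lo.w)
            # composite move: the tight beta prior tethers the group
            # dispersion levels to beta_mu, so a common offset along
            # (phi_control, phi_case, beta_mu) is the soft direction
            # when the likelihood only weakly pins the dispersion
            + ((lo.phi.start, lo.phi.start + 1, lo.beta_mu),)
        )
        # phi carries the likelihood-coupled dispersion level and is
        # refreshed every iteration; the prior-side coordinates mix fast
        # and are refreshed every third iteration
        slice_periods = (3,) * (lo.la1.stop - lo.la0.start) + (1, 1, 3, 3, 1)
        res = sample_hmc(
            post.logp_and_grad,
            theta0.reshape(F * Cn, dim),
            n_warmup=int(self.warmup),
            n_draws=int(self.draws),
            seed=int(rng.integers(0, 2**31 - 1)),
            target_accept=self.target_accept,
            max_leapfrog=self.max_leapfrog,
            slice_coords=slice_coords,
            slice_periods=slice_periods,
            logp_only=post.logp,
            chain_groups=np.repeat(np.arange(F), Cn),
        )
        all_draws = res.draws.reshape(F, Cn, self.draws, dim)
        chain_draws = np.moveaxis(all_draws[..., lo.D], 0, -1)  # (chains, draws, F)
        nuisance = self._nuisance_summary(all_draws, lo, mi)
        config = {
            "chains": int(self.chains), "warmup": int(self.warmup),
            "draws": int(self.draws), "seed": int(self.seed),
            "target_accept": self.target_accept,
            "mode": "group-averaged" if self._pooled_baseline else "matched",
            "divergences": int(res.divergences.sum()),
        }
        summary = summarize_draws(chain_draws, mi.feature_ids)
        n_flagged = int((summary["rhat"] > 1.1).sum())
        if n_flagged:
            log.warning("%d feature(s) have Rhat > 1.1; treat their differentials with caution",
                        n_flagged)
        self.differentials_ = PosteriorDifferentials(
            feature_ids=mi.feature_ids,
            chain_draws=chain_draws,
            summary=summary,
            nuisance=nuisance,
            mcmc_config=config,
            skipped_features=skipped,
        )
        n_half = max(int(self.draws) // 2, 2)
        self.diagnostics_ = Diagnostics(
            rhat=summary["rhat"].to_numpy(), ess=summary["ess"].to_numpy(),
            rhat_floor=float(np.sqrt((n_half - 1) / n_half)) - 1e-3,
        )
        self.n_features_in_ = model_input.d
        return self

    @staticmethod
    def _nuisance_summary(all_draws: np.ndarray, lo: _Layout, mi: ModelInput) -> dict:
        flat = all_draws.reshape(all_draws.shape[0], -1, all_draws.shape[-1])
        mean = flat.mean(axis=1)  # (F, dim)
        a1_bar = np.exp(flat[..., lo.la1]).mean(axis=-1)
        phi = flat[..., lo.phi]
        c_sig_draws = np.exp(flat[..., lo.u])
        C_draws = flat[..., lo.C_mu, None] + c_sig_draws[..., None] * flat[..., lo.C]
        return {
            "C": C_draws.mean(axis=1),
            "C_mu": mean[:, lo.C_mu],
            "C_sigma": np.exp(flat[..., lo.u]).mean(axis=1),
            "a0": np.exp(flat[..., lo.la0]).mean(axis=1),
            "a1": np.exp(flat[..., lo.la1]).mean(axis=1),
            "alpha_control": phi[..., 0].mean(axis=1),
            "alpha_case": phi[..., 1].mean(axis=1),
            "beta_control": (phi[..., 0] - a1_bar).mean(axis=1),
            "beta_case": (phi[..., 1] - a1_bar).mean(axis=1),
            "beta_mu": flat[..., lo.beta_mu].mean(axis=1),
            "beta_sigma": np.exp(flat[..., lo.w]).mean(axis=1),
        }


class MatchedDifferentialModel(_DifferentialModelBase):
    """Matched-pair negative-binomial differential model.

    Each pair carries its own baseline log proportion per feature, so
    within-pair contrasts cancel pair-level (age, sex, household, batch)
    structure.  Fitted attributes: ``differentials_`` and ``diagnostics_``.
    """

    _pooled_baseline = False


class GroupAveragedDifferentialModel(_DifferentialModelBase):
    """Group-averaged comparator: one shared baseline per feature."""

    _pooled_baseline = True


def fit_matched_model(model_input: ModelInput, mcmc_config: dict | None = None) -> PosteriorDifferentials:
    """Fit the matched model; thin wrapper over :class:`MatchedDifferentialModel`."""
    est = MatchedDifferentialModel(**(mcmc_config or {}))
    return est.fit(model_input).differentials_


def fit_group_averaged_model(model_input: ModelInput, mcmc_config: dict | None = None) -> PosteriorDifferentials:
    """Fit the group-averaged comparator model."""
    est = GroupAveragedDifferentialModel(**(mcmc_config or {}))
    return est.fit(model_input).differentials_
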