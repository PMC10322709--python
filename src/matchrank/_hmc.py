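"""Batched adaptive HMC with dense metric, delayed rejection, and slice-within-Gibbs.

A single sampler instance advances B independent chains at once (here,
features x chains), so every leapfrog step is one vectorized gradient
evaluation.  Three features make the sampler robust on the posteriors
this package fits:

* a dense (full-covariance) metric, estimated during warmup and applied
  by whitening positions through its Cholesky factor, removes global
  correlation ridges;
* delayed rejection: a proposal rejected at the adapted step size is
  retried along the same trajectory at a fraction of the step, with the
  Green-Mira correction (including the reverse-probability term)
  preserving detailed balance, so occasional stiff regions do not
  throttle the bulk step size;
* designated "slice coordinates" are excluded from the Hamiltonian and
  updated by batched univariate stepping-out slice sampling instead.
  This handles coordinates whose conditionals have kinks or plateaus -
  in the count model, the dispersion level whose floor ``max(alpha,
  eps)`` puts a curvature discontinuity exactly where posterior mass
  can sit.  Alternating HMC (smooth block) with slice updates (kinked
  block) is a standard Gibbs composition and leaves the joint invariant.

Warmup: dual-averaging step-size adaptation throughout, a diagonal
metric from an early window, the dense metric from a late window; slice
widths are refreshed from the same windows.  The number of leapfrog
steps is jittered uniformly per iteration, and a fraction of iterations
run at a tenth of the adapted step so chains near stiff curvature keep
making progress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HMCResult", "sample_hmc"]

_DIVERGENCE = 1000.0  # energy-error threshold counted as a divergence


@dataclass
class HMCResult:
    draws: np.ndarray        # (B, n_draws, dim)
    accept_rate: np.ndarray  # (B,) first-stage acceptance
    step_size: np.ndarray    # (B,)
    divergences: np.ndarray  # (B,) proposals divergent even at the retry step


class _DualAveraging:
    """Nesterov dual averaging of log step size (per chain)."""

    def __init__(self, step0: np.ndarray, target: float):
        self.mu = np.log(10.0 * step0)
        self.target = target
        self.log_step = np.log(step0)
        self.log_step_bar = np.log(step0)
        self.h_bar = np.zeros_like(step0)
        self.t = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: np.ndarray) -> np.ndarray:
        self.t += 1
        w = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_step = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        eta = self.t ** (-self.kappa)
        self.log_step_bar = eta * self.log_step + (1 - eta) * self.log_step_bar
        return np.exp(self.log_step)

    def finalize(self) -> np.ndarray:
        return np.exp(self.log_step_bar)

    def copy_state(self, dst: np.ndarray, src: np.ndarray) -> None:
        """Copy per-chain adaptation state from chains ``src`` to ``dst``."""
        for attr in ("mu", "log_step", "log_step_bar", "h_bar"):
            arr = getattr(self, attr)
            arr[dst] = arr[src]


def _regularized_chol(samples: np.ndarray, diag_only: bool,
                      frozen: np.ndarray | None,
                      var_cap: np.ndarray | None = None) -> np.ndarray:
    """Cholesky factors of shrinkage-regularized sample covariances.

    ``samples``: (B, n, dim).  Off-diagonals are shrunk toward zero and
    the diagonal floored, in the spirit of Stan's windowed estimator.
    Rows and columns of ``frozen`` coordinates are zeroed, which exactly
    removes them from the leapfrog dynamics.  ``var_cap`` bounds the
    per-coordinate variance (a window polluted by a basin jump would
    otherwise inflate the metric along the jump direction).
    """
    B, n, dim = samples.shape
    shrink = n / (n + 5.0)
    idx = np.arange(dim)
    if diag_only:
        var = samples.var(axis=1, ddof=1) if n > 1 else np.ones((B, dim))
        var = shrink * var + (1.0 - shrink) * 1e-3
        chol = np.zeros((B, dim, dim))
        chol[:, idx, idx] = np.sqrt(np.maximum(var, 1e-10))
    else:
        centered = samples - samples.mean(axis=1, keepdims=True)
        cov = np.einsum("bni,bnj->bij", centered, centered) / max(n - 1, 1)
        cov *= shrink
        cov[:, idx, idx] += (1.0 - shrink) * 1e-3 + 1e-8
        if var_cap is not None:
            scale = np.minimum(1.0, np.sqrt(var_cap / cov[:, idx, idx]))
            cov = cov * scale[:, :, None] * scale[:, None, :]
            cov[:, idx, idx] += 1e-10
        if frozen is not None and frozen.size:
            cov[:, frozen, :] = 0.0
            cov[:, :, frozen] = 0.0
            cov[:, frozen, frozen] = 1.0  # keep factorizable; zeroed below
        chol = np.empty_like(cov)
        for b in range(B):  # per-chain factorization; fall back to diagonal
            try:
                chol[b] = np.linalg.cholesky(cov[b])
            except np.linalg.LinAlgError:
                chol[b] = np.diag(np.sqrt(np.maximum(np.diag(cov[b]), 1e-10)))
    if frozen is not None and frozen.size:
        chol[:, frozen, :] = 0.0
        chol[:, :, frozen] = 0.0
    return chol


def _leapfrog(logp_and_grad, theta, p, grad, eps, L, chol, rows):
    """L leapfrog steps with whitened momentum; returns (theta', p', logp', grad')."""
    th = theta
    g = grad
    p = p + 0.5 * eps[:, None] * np.einsum("bji,bj->bi", chol, g)
    lp = None
    for leap in range(L):
        th = th + eps[:, None] * np.einsum("bij,bj->bi", chol, p)
        lp, g = logp_and_grad(th, rows)
        p = p + (0.5 if leap == L - 1 else 1.0) * eps[:, None] * np.einsum(
            "bji,bj->bi", chol, g
        )
    return th, p, lp, g


def _slice_update(logp_fn, theta, logp, coords, weights, width, rng,
                  max_stepout: int = 8, max_shrink: int = 40):
    """One batched stepping-out slice update along a coordinate direction.

    ``coords``/``weights`` define the move ``theta[:, coords] += t *
    weights``; a single coordinate is the unit-weight special case, and
    composite directions resolve soft ridges that coordinate-wise
    updates would random-walk along (e.g. a dispersion level tethered to
    its prior mean).  Standard Neal (2003) stepping-out over the offset
    t with per-chain widths; each loop pass evaluates only the chains
    whose bracket is still being resolved.  If shrinkage stalls the
    bracket collapses onto t = 0, leaving the point unchanged (which
    keeps the update correct).
    """
    B = theta.shape[0]
    logy = logp + np.log(rng.random(B))
    left = -width * rng.random(B)
    right = left + width

    def _sub_eval(rows, t):
        th_sub = theta[rows].copy()
        th_sub[:, coords] += t[:, None] * weights
        return logp_fn(th_sub, rows)

    for edge, sign in ((left, -1.0), (right, 1.0)):
        active = np.arange(B)
        for _ in range(max_stepout):
            grow = _sub_eval(active, edge[active]) > logy[active]
            active = active[grow]
            if active.size == 0:
                break
            edge[active] += sign * width[active]

    t_new = np.zeros(B)
    lp_new = logp.copy()
    active = np.arange(B)
    for _ in range(max_shrink):
        prop = left[active] + rng.random(active.size) * (right[active] - left[active])
        lp_prop = _sub_eval(active, prop)
        ok = lp_prop > logy[active]
        hit = active[ok]
        t_new[hit] = prop[ok]
        lp_new[hit] = lp_prop[ok]
        active, prop = active[~ok], prop[~ok]
        if active.size == 0:
            break
        below = prop < 0.0
        left[active[below]] = prop[below]
        right[active[~below]] = prop[~below]
    theta[:, coords] += t_new[:, None] * weights
    return theta, lp_new


def sample_hmc(
    logp_and_grad,
    theta0: np.ndarray,
    *,
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_accept: float = 0.9,
    max_leapfrog: int = 16,
    init_step: float = 0.1,
    retry_factor: float = 5.0,
    slice_coords: tuple[int, ...] = (),
    slice_periods: tuple[int, ...] | None = None,
    logp_only=None,
    chain_groups: np.ndarray | None = None,
) -> HMCResult:
    """Run adaptive delayed-rejection HMC (+ slice coordinates) on B chains.

    Parameters
    ----------
    logp_and_grad:
        Callable ``(theta, rows) -> (logp, grad)`` where ``theta`` has
        shape ``(len(rows), dim)`` and ``rows`` (or None for the full
        batch) selects which chains the rows correspond to.
    theta0:
        Initial positions, shape ``(B, dim)``.
    retry_factor:
        Step-size divisor for the delayed-rejection second stage.
    slice_coords:
        Coordinates excluded from the Hamiltonian and updated by
        univariate slice sampling each iteration (requires ``logp_only``).
    chain_groups:
        Optional integer array of length B marking chains that target the
        same posterior.  During warmup, a chain whose running mean log
        density lags its group's best by a wide margin (a metastable
        pseudo-mode whose relative mass is provably negligible at that
        gap) is restarted from the best chain's state.
    """
    rng = np.random.default_rng(seed)
    theta = np.array(theta0, dtype=np.float64)
    B, dim = theta.shape
    logp, grad = logp_and_grad(theta, None)
    if not np.all(np.isfinite(logp)):
        raise ValueError("non-finite log density at the initial position")
    if slice_periods is None:
        slice_periods = (1,) * len(slice_coords)
    moves: list[tuple[np.ndarray, np.ndarray]] = []
    frozen_set: set[int] = set()
    for entry in slice_coords:
        if isinstance(entry, (int, np.integer)):
            moves.append((np.array([entry], dtype=np.int64), np.ones(1)))
            frozen_set.add(int(entry))
        else:  # composite direction over already-sliced coordinates
            idx = np.asarray(entry, dtype=np.int64)
            moves.append((idx, np.ones(idx.size)))
    frozen = np.array(sorted(frozen_set), dtype=np.int64)
    periods = np.asarray(slice_periods, dtype=np.int64)
    if moves and logp_only is None:
        raise ValueError("slice_coords requires logp_only")

    step = np.full(B, float(init_step))
    chol = np.broadcast_to(np.eye(dim), (B, dim, dim)).copy()
    if frozen.size:
        chol[:, frozen, frozen] = 0.0
    slice_width = np.ones((B, len(moves)))
    da = _DualAveraging(step, target_accept)

    # warmup windows: [w0, w1) feeds the diagonal metric, [w1, w2) the
    # dense metric, [w2, n_warmup) re-adapts the step size under it
    w0 = int(0.10 * n_warmup)
    w1 = max(w0 + 2, int(0.30 * n_warmup))
    w2 = max(w1 + 2, int(0.70 * n_warmup))
    window: list[np.ndarray] = []

    draws = np.empty((B, n_draws, dim))
    n_accept = np.zeros(B)
    n_div = np.zeros(B, dtype=np.int64)
    all_rows = np.arange(B)
    logp_ema = logp.copy()  # running mean for pseudo-mode detection

    def _restart_lagging_chains() -> None:
        # position state only: the lagging chain keeps its own step and
        # metric, which remain scale-appropriate after the jump
        nonlocal theta, logp, grad
        for gid in np.unique(chain_groups):
            members = all_rows[chain_groups == gid]
            best = members[np.argmax(logp_ema[members])]
            lagging = members[logp_ema[members] < logp_ema[best] - 15.0]
            if lagging.size:
                theta[lagging] = theta[best]
                logp[lagging] = logp[best]
                grad[lagging] = grad[best]
                logp_ema[lagging] = logp_ema[best]

    total = n_warmup + n_draws
    for it in range(total):
        warming = it < n_warmup
        L = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
        # state-independent step mixture: occasional small-step sweeps
        # guarantee progress for chains wedged against stiff curvature
        small_sweep = rng.random() < 0.15
        eps_it = step * 0.1 if small_sweep else step
        p0 = rng.standard_normal((B, dim))
        kin0 = 0.5 * np.einsum("bd,bd->b", p0, p0)

        th1, p1, lp1, g1 = _leapfrog(logp_and_grad, theta, p0, grad, eps_it, L, chol, None)
        with np.errstate(invalid="ignore", over="ignore"):
            dh1 = (lp1 - 0.5 * np.einsum("bd,bd->b", p1, p1)) - (logp - kin0)
        bad1 = ~np.isfinite(dh1) | (dh1 < -_DIVERGENCE)
        a1 = np.where(bad1, 0.0, np.exp(np.minimum(0.0, dh1)))
        acc1 = rng.random(B) < a1
        theta = np.where(acc1[:, None], th1, theta)
        logp = np.where(acc1, lp1, logp)
        grad = np.where(acc1[:, None], g1, grad)

        # delayed rejection: retry rejected chains at step/retry_factor
        a2_full = np.zeros(B)
        idx = all_rows[~acc1]
        if idx.size:
            eps2 = eps_it[idx] / retry_factor
            th2, p2, lp2, g2 = _leapfrog(
                logp_and_grad, theta[idx], p0[idx], grad[idx], eps2, L, chol[idx], idx
            )
            with np.errstate(invalid="ignore", over="ignore"):
                dh2 = (lp2 - 0.5 * np.einsum("bd,bd->b", p2, p2)) - (logp[idx] - kin0[idx])
            bad2 = ~np.isfinite(dh2) | (dh2 < -_DIVERGENCE)
            # reverse first-stage proposal from (th2, p2): its acceptance
            # probability enters the Green-Mira correction
            _, p1r, lp1r, _ = _leapfrog(
                logp_and_grad, th2, p2, g2, eps_it[idx], L, chol[idx], idx
            )
            with np.errstate(invalid="ignore", over="ignore"):
                dh1r = (lp1r - 0.5 * np.einsum("bd,bd->b", p1r, p1r)) - (
                    lp2 - 0.5 * np.einsum("bd,bd->b", p2, p2)
                )
            # a divergent reverse proposal would itself be rejected: a1r = 0
            a1r = np.where(~np.isfinite(dh1r) | (dh1r < -_DIVERGENCE), 0.0,
                           np.exp(np.minimum(0.0, dh1r)))
            with np.errstate(divide="ignore", invalid="ignore"):
                log_num = np.log1p(-np.minimum(a1r, 1.0 - 1e-15))
                log_den = np.log1p(-np.minimum(a1[idx], 1.0 - 1e-15))
                log_a2 = dh2 + log_num - log_den
            a2 = np.where(bad2, 0.0, np.exp(np.minimum(0.0, log_a2)))
            acc2 = rng.random(idx.size) < a2
            upd = idx[acc2]
            theta[upd] = th2[acc2]
            logp[upd] = lp2[acc2]
            grad[upd] = g2[acc2]
            n_div[idx[bad2]] += 1
            a2_full[idx] = a2

        # slice-sampled coordinates (kinked conditionals); weakly coupled
        # ones may run on a slower schedule
        if moves:
            for ci, (coords, wts) in enumerate(moves):
                if it % periods[ci]:
                    continue
                theta, logp = _slice_update(
                    logp_only, theta, logp, coords, wts, slice_width[:, ci], rng
                )
            _, grad = logp_and_grad(theta, None)

        if warming:
            # adapt on first-stage acceptance (retries stay a safety net,
            # not the workhorse); the cap stops runaway growth on
            # momentarily flat regions
            if not small_sweep:
                step = np.minimum(da.update(a1), 2.0)
            logp_ema = 0.95 * logp_ema + 0.05 * logp
            if it >= w0:
                window.append(theta.copy())
            if it in (w1 - 1, w2 - 1):
                samples = np.stack(window, axis=1)
                if it == w1 - 1:
                    chol = _regularized_chol(samples, diag_only=True, frozen=frozen)
                    idxd = np.arange(dim)
                    var_cap = 25.0 * chol[:, idxd, idxd] ** 2 + 1e-6
                else:
                    chol = _regularized_chol(samples, diag_only=False, frozen=frozen,
                                             var_cap=var_cap)
                if moves:
                    for ci, (coords, wts) in enumerate(moves):
                        proj = samples[:, :, coords] @ (wts / (wts @ wts))
                        slice_width[:, ci] = np.maximum(2.5 * proj.std(axis=1), 1e-3)
                window.clear()
                step0 = np.maximum(step, 1e-8) if it == w1 - 1 else np.full(B, float(init_step))
                da = _DualAveraging(step0, target_accept)
                step = np.exp(da.log_step)
                if chain_groups is not None and it == w1 - 1:
                    _restart_lagging_chains()
            if it == n_warmup - 1:
                if chain_groups is not None:
                    _restart_lagging_chains()
                # whitened near-Gaussian targets need step <~ 1; larger
                # frozen values indicate adaptation ran off a plateau
                step = np.minimum(da.finalize(), 0.8)
        else:
            draws[:, it - n_warmup, :] = theta
            n_accept += a1

    return HMCResult(
        draws=draws,
        accept_rate=n_accept / max(n_draws, 1),
        step_size=step,
        divergences=n_div,
    )
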