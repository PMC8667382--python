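"""Gradient-based MCMC engines: No-U-Turn sampler and a random-walk fallback.

The NUTS implementation follows the classic recursive doubling scheme
with a slice variable, dual-averaging step-size adaptation toward a
target acceptance statistic, and windowed diagonal mass-matrix
adaptation during warmup.  It is generic over any differentiable log
density supplied as ``logp_and_grad(q) -> (float, ndarray)``.

The adaptive random-walk Metropolis sampler shares the same return
contract and exists for dependency-light testing and as a robustness
fallback; it adapts a global proposal scale toward ~0.3 acceptance
during warmup and freezes it afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["sample_nuts", "sample_metropolis", "ChainResult"]

_DELTA_MAX = 1000.0  # slice divergence threshold (energy error)


@dataclass
class ChainResult:
    """Post-warmup draws of one chain plus sampler statistics."""

    draws: np.ndarray  # (retained iterations, dim)
    step_size: float
    mean_accept: float
    n_divergent: int
    max_depth_hits: int


LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


def _leapfrog(
    logp_and_grad: LogpGrad,
    q: np.ndarray,
    r: np.ndarray,
    grad: np.ndarray,
    eps: float,
    inv_mass: np.ndarray,
):
    r1 = r + 0.5 * eps * grad
    q1 = q + eps * inv_mass * r1
    logp1, grad1 = logp_and_grad(q1)
    r1 = r1 + 0.5 * eps * grad1
    return q1, r1, logp1, grad1


def _joint(logp: float, r: np.ndarray, inv_mass: np.ndarray) -> float:
    return logp - 0.5 * float(np.sum(inv_mass * r * r))


def _find_reasonable_step_size(
    logp_and_grad: LogpGrad,
    q: np.ndarray,
    inv_mass: np.ndarray,
    rng: np.random.Generator,
) -> float:
    eps = 1.0
    logp, grad = logp_and_grad(q)
    r = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    joint0 = _joint(logp, r, inv_mass)
    _, r1, logp1, _ = _leapfrog(logp_and_grad, q, r, grad, eps, inv_mass)
    log_ratio = _joint(logp1, r1, inv_mass) - joint0
    if not np.isfinite(log_ratio):
        log_ratio = -np.inf
    direction = 1.0 if log_ratio > np.log(0.5) else -1.0
    for _ in range(64):
        eps *= 2.0**direction
        _, r1, logp1, _ = _leapfrog(logp_and_grad, q, r, grad, eps, inv_mass)
        log_ratio = _joint(logp1, r1, inv_mass) - joint0
        if not np.isfinite(log_ratio):
            log_ratio = -np.inf
        if direction * log_ratio <= direction * np.log(0.5):
            break
    return eps


class _TreeState:
    __slots__ = (
        "q_minus", "r_minus", "grad_minus", "q_plus", "r_plus", "grad_plus",
        "q_prop", "logp_prop", "n_valid", "keep_going", "sum_alpha", "n_alpha",
        "divergent",
    )


def _build_tree(
    logp_and_grad: LogpGrad,
    q: np.ndarray,
    r: np.ndarray,
    grad: np.ndarray,
    log_u: float,
    direction: int,
    depth: int,
    eps: float,
    joint0: float,
    inv_mass: np.ndarray,
    rng: np.random.Generator,
) -> _TreeState:
    out = _TreeState()
    if depth == 0:
        q1, r1, logp1, grad1 = _leapfrog(
            logp_and_grad, q, r, grad, direction * eps, inv_mass
        )
        joint = _joint(logp1, r1, inv_mass)
        out.q_minus = out.q_plus = out.q_prop = q1
        out.r_minus = out.r_plus = r1
        out.grad_minus = out.grad_plus = grad1
        out.logp_prop = logp1
        out.n_valid = int(log_u <= joint)
        out.divergent = not (log_u < joint + _DELTA_MAX) or not np.isfinite(joint)
        out.keep_going = not out.divergent
        out.sum_alpha = min(1.0, float(np.exp(min(joint - joint0, 0.0))))
        if not np.isfinite(joint):
            out.sum_alpha = 0.0
        out.n_alpha = 1
        return out

    first = _build_tree(
        logp_and_grad, q, r, grad, log_u, direction, depth - 1, eps, joint0,
        inv_mass, rng,
    )
    for slot in _TreeState.__slots__:
        setattr(out, slot, getattr(first, slot))
    if first.keep_going:
        if direction == -1:
            second = _build_tree(
                logp_and_grad, first.q_minus, first.r_minus, first.grad_minus,
                log_u, direction, depth - 1, eps, joint0, inv_mass, rng,
            )
            out.q_minus, out.r_minus, out.grad_minus = (
                second.q_minus, second.r_minus, second.grad_minus,
            )
        else:
            second = _build_tree(
                logp_and_grad, first.q_plus, first.r_plus, first.grad_plus,
                log_u, direction, depth - 1, eps, joint0, inv_mass, rng,
            )
            out.q_plus, out.r_plus, out.grad_plus = (
                second.q_plus, second.r_plus, second.grad_plus,
            )
        total = first.n_valid + second.n_valid
        if total > 0 and rng.random() < second.n_valid / total:
            out.q_prop, out.logp_prop = second.q_prop, second.logp_prop
        out.n_valid = total
        out.sum_alpha = first.sum_alpha + second.sum_alpha
        out.n_alpha = first.n_alpha + second.n_alpha
        out.divergent = first.divergent or second.divergent
        out.keep_going = (
            second.keep_going
            and not out.divergent
            and _no_u_turn(out.q_minus, out.q_plus, out.r_minus, out.r_plus, inv_mass)
        )
    return out


def _no_u_turn(q_minus, q_plus, r_minus, r_plus, inv_mass) -> bool:
    dq = q_plus - q_minus
    return (
        float(np.dot(dq, inv_mass * r_minus)) >= 0.0
        and float(np.dot(dq, inv_mass * r_plus)) >= 0.0
    )


def sample_nuts(
    logp_and_grad: LogpGrad,
    init: np.ndarray,
    *,
    iters: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.999,
    max_tree_depth: int = 25,
) -> ChainResult:
    """Run one NUTS chain; returns the ``iters - warmup`` retained draws."""
    q = np.asarray(init, float).copy()
    dim = q.shape[0]
    inv_mass = np.ones(dim)
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_step_size(logp_and_grad, q, inv_mass, rng)
    # dual averaging state; adapt_count restarts whenever the metric changes
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    adapt_count = 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # windowed diagonal-metric adaptation: re-estimate once or twice inside
    # warmup when there is room, Stan-style but simplified
    metric_updates = []
    if warmup >= 200:
        metric_updates = [int(warmup * 0.5), int(warmup * 0.85)]
    elif warmup >= 80:
        metric_updates = [int(warmup * 0.6)]
    window_samples: list[np.ndarray] = []

    retained = np.empty((iters - warmup, dim))
    accepts: list[float] = []
    n_div = 0
    depth_hits = 0

    for it in range(iters):
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = _joint(logp, r0, inv_mass)
        log_u = joint0 + np.log1p(-rng.random())  # log of u ~ U(0, exp(joint0))

        state = _TreeState()
        state.q_minus = state.q_plus = q
        state.r_minus = state.r_plus = r0
        state.grad_minus = state.grad_plus = grad
        q_cur, logp_cur = q, logp
        n_valid, keep_going, depth = 1, True, 0
        sum_alpha, n_alpha = 0.0, 0

        while keep_going and depth < max_tree_depth:
            direction = -1 if rng.random() < 0.5 else 1
            if direction == -1:
                sub = _build_tree(
                    logp_and_grad, state.q_minus, state.r_minus, state.grad_minus,
                    log_u, direction, depth, eps, joint0, inv_mass, rng,
                )
                state.q_minus, state.r_minus, state.grad_minus = (
                    sub.q_minus, sub.r_minus, sub.grad_minus,
                )
            else:
                sub = _build_tree(
                    logp_and_grad, state.q_plus, state.r_plus, state.grad_plus,
                    log_u, direction, depth, eps, joint0, inv_mass, rng,
                )
                state.q_plus, state.r_plus, state.grad_plus = (
                    sub.q_plus, sub.r_plus, sub.grad_plus,
                )
            if sub.keep_going and sub.n_valid > 0:
                if rng.random() < sub.n_valid / max(n_valid, 1):
                    q_cur, logp_cur = sub.q_prop, sub.logp_prop
            n_valid += sub.n_valid
            sum_alpha += sub.sum_alpha
            n_alpha += sub.n_alpha
            if sub.divergent:
                n_div += int(it >= warmup)
            keep_going = sub.keep_going and _no_u_turn(
                state.q_minus, state.q_plus, state.r_minus, state.r_plus, inv_mass
            )
            depth += 1
        if depth >= max_tree_depth:
            depth_hits += int(it >= warmup)

        if not np.array_equal(q_cur, q):
            q = q_cur
            logp, grad = logp_cur, logp_and_grad(q)[1]
        alpha_stat = sum_alpha / max(n_alpha, 1)

        if it < warmup:
            # dual averaging toward the target acceptance statistic
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - alpha_stat)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            weight = adapt_count ** (-kappa)
            log_eps_bar = weight * log_eps + (1.0 - weight) * log_eps_bar
            eps = float(np.exp(log_eps))
            window_samples.append(q.copy())
            if metric_updates and it + 1 == metric_updates[0]:
                metric_updates.pop(0)
                block = np.asarray(window_samples[len(window_samples) // 2 :])
                var = block.var(axis=0, ddof=1) if block.shape[0] > 4 else None
                if var is not None and np.all(var > 0):
                    inv_mass = var
                window_samples.clear()
                # re-initialize step-size search under the new metric
                eps = _find_reasonable_step_size(logp_and_grad, q, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar = 0.0, 0.0
                adapt_count = 0
            if it + 1 == warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            retained[it - warmup] = q
            accepts.append(alpha_stat)

    return ChainResult(
        draws=retained,
        step_size=eps,
        mean_accept=float(np.mean(accepts)) if accepts else float("nan"),
        n_divergent=n_div,
        max_depth_hits=depth_hits,
    )


def sample_metropolis(
    logp: Callable[[np.ndarray], float],
    init: np.ndarray,
    *,
    iters: int,
    warmup: int,
    rng: np.random.Generator,
    initial_scale: float = 0.1,
) -> ChainResult:
    """Adaptive spherical random-walk Metropolis chain (same contract as NUTS)."""
    q = np.asarray(init, float).copy()
    dim = q.shape[0]
    scale = initial_scale
    lp = logp(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")
    retained = np.empty((iters - warmup, dim))
    n_acc_post = 0
    acc_window = 0
    for it in range(iters):
        prop = q + scale * rng.standard_normal(dim)
        lp_prop = logp(prop)
        if np.log1p(-rng.random()) < lp_prop - lp:
            q, lp = prop, lp_prop
            acc_window += 1
            n_acc_post += int(it >= warmup)
        if it < warmup and (it + 1) % 50 == 0:
            rate = acc_window / 50.0
            scale *= np.exp(1.5 * (rate - 0.3))  # steer toward ~30% acceptance
            acc_window = 0
        if it >= warmup:
            retained[it - warmup] = q
    return ChainResult(
        draws=retained,
        step_size=scale,
        mean_accept=n_acc_post / max(iters - warmup, 1),
        n_divergent=0,
        max_depth_hits=0,
    )
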