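"""Blocked adaptive random-walk Metropolis engine.

Generic over the log-posterior: parameters live in one flat vector,
updated block-wise (coefficients, each hierarchy's free effects,
log-SDs, transformed dispersion). A block may carry an initial proposal
Cholesky factor (e.g. from a GLM covariance), in which case its step
size starts at the 2.38/sqrt(d) optimum for a matched proposal; during
the initialization and burn-in phases every block adapts its scalar step
size toward a target acceptance rate (Robbins-Monro on the log scale)
and, once enough history exists, re-estimates the proposal covariance
from the chain. Adaptation is frozen when sampling starts, so the
retained draws come from a valid Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Block:
    name: str
    idx: np.ndarray            # integer indices into the parameter vector
    chol0: np.ndarray | None = None  # initial proposal Cholesky (optional)


def _run_single_chain(
    logpost, theta0, blocks, n_adapt, n_burn, n_keep, rng,
    target_accept=0.26, cov_interval=100,
):
    theta = np.array(theta0, dtype=float)
    dim = theta.size
    lp = logpost(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log posterior")

    n_pre = n_adapt + n_burn
    scales, chol = {}, {}
    for b in blocks:
        k = len(b.idx)
        if b.chol0 is not None:
            chol[b.name] = b.chol0
            scales[b.name] = 2.38 / np.sqrt(k)
        else:
            chol[b.name] = None
            scales[b.name] = 0.5 / np.sqrt(k)
    hist = np.empty((min(n_pre, 2500), dim))
    h = 0
    accept = {b.name: 0 for b in blocks}
    draws = np.empty((n_keep, dim))

    for t in range(n_pre + n_keep):
        adapting = t < n_pre
        for b in blocks:
            k = len(b.idx)
            z = rng.standard_normal(k)
            step = scales[b.name] * (
                z if chol[b.name] is None else chol[b.name] @ z
            )
            prop = theta.copy()
            prop[b.idx] += step
            lp_prop = logpost(prop)
            log_u = np.log(rng.random())
            acc = lp_prop - lp > log_u
            if acc:
                theta, lp = prop, lp_prop
                accept[b.name] += 1
            if adapting:
                gamma = 1.0 / (1.0 + 0.1 * t) ** 0.6
                scales[b.name] *= np.exp(
                    gamma * ((1.0 if acc else 0.0) - target_accept)
                )
        if adapting:
            if h < hist.shape[0]:
                hist[h] = theta
                h += 1
            if t >= n_adapt // 2 and t % cov_interval == 0 and h > 3 * dim:
                recent = hist[max(0, h - 1500):h]
                for b in blocks:
                    if len(b.idx) > 1:
                        cov = np.cov(recent[:, b.idx], rowvar=False)
                        cov += 1e-10 * np.eye(len(b.idx)) + 1e-8 * np.diag(
                            np.diag(cov)
                        )
                        try:
                            L = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            continue
                        if chol[b.name] is None:
                            scales[b.name] = 2.38 / np.sqrt(len(b.idx))
                        chol[b.name] = L
        else:
            draws[t - n_pre] = theta
    rates = {name: a / (n_pre + n_keep) for name, a in accept.items()}
    return draws, rates


def run_chains(
    logpost,
    theta0: np.ndarray,
    blocks: list[Block],
    n_chains: int = 3,
    n_adapt: int = 500,
    n_burn: int = 2000,
    n_keep: int = 5000,
    seed: int = 0,
    init_scale=0.5,
):
    """Run ``n_chains`` independent adaptive Metropolis chains.

    Chains start from ``theta0`` plus overdispersed jitter of per-parameter
    magnitude ``init_scale`` (scalar or vector), so the Gelman-Rubin
    statistic sees genuinely distinct starting points. Returns draws of
    shape (n_chains, n_keep, dim) and per-chain block acceptance rates.
    """
    theta0 = np.asarray(theta0, dtype=float)
    init_scale = np.broadcast_to(np.asarray(init_scale, float), theta0.shape)
    ss = np.random.SeedSequence(int(seed) % (2**31))
    child = ss.spawn(n_chains)
    all_draws = np.empty((n_chains, n_keep, theta0.size))
    all_rates = []
    for c in range(n_chains):
        rng = np.random.default_rng(child[c])
        start = theta0 + init_scale * rng.standard_normal(theta0.size)
        # keep the start inside the posterior's support
        lp = logpost(start)
        tries = 0
        while not np.isfinite(lp) and tries < 50:
            start = theta0 + init_scale * 0.5**tries * rng.standard_normal(
                theta0.size
            )
            lp = logpost(start)
            tries += 1
        draws, rates = _run_single_chain(
            logpost, start, blocks, n_adapt, n_burn, n_keep, rng
        )
        all_draws[c] = draws
        all_rates.append(rates)
    return all_draws, all_rates


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` has shape (n_chains, n_iter). Classic between/within
    formula: R-hat = sqrt(((n-1)/n * W + B/n) / W).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains")
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))
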