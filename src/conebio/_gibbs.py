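"""Adaptive Metropolis-within-Gibbs sampler for the nested binomial model.

Target posterior, per endpoint, given side-level sufficient counts y_is out
of m_is (cones within a side share one rate, so side totals are sufficient):

    y_is ~ Binomial(m_is, expit(alpha + u_i + v_is))
    u_i  ~ Normal(0, sigma_net^2)      v_is ~ Normal(0, sigma_side^2)
    alpha ~ Normal(0, alpha_prior_sd^2)
    sigma_net, sigma_side ~ Half-Normal(sigma_prior_sd)

All random-effect updates are vectorized elementwise Metropolis steps; the
sweep adds two ancillarity ("recentering") moves — shifting mass between u_i
and its v_is, and between alpha and all u_i — which leave the likelihood
invariant and break the strong posterior correlation that otherwise stalls
plain componentwise samplers on hierarchical models.  Scale parameters are
updated on the log scale.  Proposal step sizes adapt toward 44% acceptance
during warmup only, so the post-warmup chain is a valid Markov chain.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_hierarchical_binomial"]

_TARGET_ACC = 0.44


def _loglik(eta: np.ndarray, y: np.ndarray, m: np.ndarray) -> np.ndarray:
    # y*log p + (m-y)*log(1-p) with p = expit(eta), up to a constant
    return y * eta - m * np.logaddexp(0.0, eta)


def _slice_update(logpost, x0: float, rng, w: float = 0.5, max_steps: int = 8) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    level = logpost(x0) + np.log(rng.random())
    left = x0 - w * rng.random()
    right = left + w
    j = int(max_steps * rng.random())
    k = max_steps - 1 - j
    while j > 0 and logpost(left) > level:
        left -= w
        j -= 1
    while k > 0 and logpost(right) > level:
        right += w
        k -= 1
    while True:
        x1 = left + rng.random() * (right - left)
        if logpost(x1) > level:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _init_state(y, m, rng):
    n, S = y.shape
    rate = (y.sum(1) + 0.5) / (m.sum(1) + 1.0)
    logit_net = np.log(rate / (1 - rate))
    alpha = float(np.mean(logit_net)) + rng.normal(0, 0.3)
    u = np.clip(logit_net - alpha, -4, 4) + rng.normal(0, 0.3, n)
    v = rng.normal(0, 0.1, (n, S))
    sn = max(float(np.std(u)), 0.2) * np.exp(rng.normal(0, 0.2))
    ss = 0.3 * np.exp(rng.normal(0, 0.2))
    return alpha, u, v, np.log(sn), np.log(ss)


def _run_chain(y, m, alpha_prior_sd, sigma_prior_sd, warmup, draws, thin, rng):
    n, S = y.shape
    alpha, u, v, lsn, lss = _init_state(y, m, rng)

    # adaptive log step sizes per block
    ls = {"v": np.log(0.8), "u": np.log(0.5), "a": np.log(0.1),
          "rn": np.log(0.4), "g": np.log(0.1), "sn": np.log(0.3), "ss": np.log(0.3)}

    out_alpha = np.empty(draws)
    out_sn = np.empty(draws)
    out_ss = np.empty(draws)
    out_q = np.empty((draws, n))

    total = warmup + draws * thin
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))

    for it in range(total):
        sn2 = np.exp(2 * lsn)
        ss2 = np.exp(2 * lss)
        acc: dict[str, float] = {}

        # side effects v (elementwise)
        eta = alpha + u[:, None] + v
        vp = v + rng.normal(0, np.exp(ls["v"]), (n, S))
        d = _loglik(alpha + u[:, None] + vp, y, m) - _loglik(eta, y, m)
        d -= (vp * vp - v * v) / (2 * ss2)
        take = np.log(rng.random((n, S))) < d
        v = np.where(take, vp, v)
        acc["v"] = float(take.mean())

        # net effects u (per net)
        eta = alpha + u[:, None] + v
        up = u + rng.normal(0, np.exp(ls["u"]), n)
        d = (_loglik(alpha + up[:, None] + v, y, m) - _loglik(eta, y, m)).sum(1)
        d -= (up * up - u * u) / (2 * sn2)
        take = np.log(rng.random(n)) < d
        u = np.where(take, up, u)
        acc["u"] = float(take.mean())

        # per-net recentering: u_i -> u_i + delta_i, v_is -> v_is - delta_i
        delta = rng.normal(0, np.exp(ls["rn"]), n)
        up = u + delta
        vp = v - delta[:, None]
        d = -(up * up - u * u) / (2 * sn2) - ((vp * vp - v * v) / (2 * ss2)).sum(1)
        take = np.log(rng.random(n)) < d
        u = np.where(take, up, u)
        v = np.where(take[:, None], vp, v)
        acc["rn"] = float(take.mean())

        # intercept
        eta = alpha + u[:, None] + v
        ap = alpha + rng.normal(0, np.exp(ls["a"]))
        d = (_loglik(eta + (ap - alpha), y, m) - _loglik(eta, y, m)).sum()
        d -= (ap * ap - alpha * alpha) / (2 * alpha_prior_sd**2)
        ok = np.log(rng.random()) < d
        if ok:
            alpha = ap
        acc["a"] = float(ok)

        # global recentering: alpha -> alpha + delta, all u_i -> u_i - delta
        delta = rng.normal(0, np.exp(ls["g"]))
        ap = alpha + delta
        up = u - delta
        d = -(ap * ap - alpha * alpha) / (2 * alpha_prior_sd**2)
        d -= ((up * up - u * u) / (2 * sn2)).sum()
        ok = np.log(rng.random()) < d
        if ok:
            alpha, u = ap, up
        acc["g"] = float(ok)

        # scales, on the log scale (half-normal prior + jacobian)
        for key, x, cnt in (("sn", u, n), ("ss", v, n * S)):
            lcur = lsn if key == "sn" else lss
            lp = lcur + rng.normal(0, np.exp(ls[key]))
            ssq = float((x * x).sum())
            d = -0.5 * ssq * (np.exp(-2 * lp) - np.exp(-2 * lcur))
            d -= cnt * (lp - lcur)
            d -= (np.exp(2 * lp) - np.exp(2 * lcur)) / (2 * sigma_prior_sd**2)
            d += lp - lcur
            ok = np.log(rng.random()) < d
            if ok:
                if key == "sn":
                    lsn = lp
                else:
                    lss = lp
            acc[key] = float(ok)

        # interweaved (non-centered) scale moves: rescale the effects along
        # with their scale, holding the standardized effects fixed — breaks
        # the funnel between a scale and the magnitude of its effects.
        # Slice-sampled (no tuning, always moves).
        def _ncp_ss(lp: float) -> float:
            vp = v * np.exp(lp - lss)
            return (
                float(_loglik(alpha + u[:, None] + vp, y, m).sum())
                - np.exp(2 * lp) / (2 * sigma_prior_sd**2)
                + lp
            )

        lss_new = _slice_update(_ncp_ss, lss, rng)
        v = v * np.exp(lss_new - lss)
        lss = lss_new

        def _ncp_sn(lp: float) -> float:
            up = u * np.exp(lp - lsn)
            return (
                float(_loglik(alpha + up[:, None] + v, y, m).sum())
                - np.exp(2 * lp) / (2 * sigma_prior_sd**2)
                + lp
            )

        lsn_new = _slice_update(_ncp_sn, lsn, rng)
        u = u * np.exp(lsn_new - lsn)
        lsn = lsn_new

        if it < warmup:
            gain = 1.0 / (1 + it) ** 0.6
            for key, a in acc.items():
                ls[key] = np.clip(ls[key] + gain * (a - _TARGET_ACC), -8, 3)
        else:
            j = it - warmup
            if j % thin == 0:
                k = j // thin
                out_alpha[k] = alpha
                out_sn[k] = np.exp(lsn)
                out_ss[k] = np.exp(lss)
                out_q[k] = expit(alpha + u[:, None] + v).mean(1)

    return out_alpha, out_sn, out_ss, out_q


def sample_hierarchical_binomial(
    y: np.ndarray,
    m: np.ndarray,
    *,
    alpha_prior_sd: float = 2.5,
    sigma_prior_sd: float = 1.0,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    thin: int = 1,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Run ``chains`` independent chains; returns stacked posterior arrays.

    Keys: ``alpha``, ``sigma_net``, ``sigma_side`` with shape (chains, draws)
    and ``q`` with shape (chains, draws, n_nets) holding the side-averaged
    success probability of each net at each draw.  Deterministic in ``seed``.
    """
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    if y.shape != m.shape or y.ndim != 2:
        raise ValueError("y and m must be matching 2-D arrays (nets x sides)")
    if np.any(y < 0) or np.any(y > m) or np.any(m <= 0):
        raise ValueError("require 0 <= y <= m and m > 0")
    if min(chains, warmup, draws, thin) < 1:
        raise ValueError("chains, warmup, draws, thin must be positive")

    seeds = np.random.SeedSequence(seed).spawn(chains)
    n = y.shape[0]
    alpha = np.empty((chains, draws))
    sn = np.empty((chains, draws))
    ss = np.empty((chains, draws))
    q = np.empty((chains, draws, n))
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        alpha[c], sn[c], ss[c], q[c] = _run_chain(
            y, m, alpha_prior_sd, sigma_prior_sd, warmup, draws, thin, rng
        )
    return {"alpha": alpha, "sigma_net": sn, "sigma_side": ss, "q": q}
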