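"""Independent reference implementations used to check the package.

Each oracle takes a deliberately different computational route from the code
under test: constrained least squares via a trust-region solver (the package
uses NNLS + SLSQP), LOH scoring by brute-force megabase enumeration (the
package merges segment intervals), Benjamini-Hochberg by the literal step-up
recursion, and Fisher p-values by direct hypergeometric enumeration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize

from ihrdkit.cn_features import CNSegmentProfile


def constrained_ls_weights(target: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """argmin ||target - profiles @ w||^2 s.t. w >= 0, sum(w) <= 1 via
    trust-constr (independent of the package's NNLS/SLSQP route)."""
    k = profiles.shape[1]
    res = optimize.minimize(
        lambda w: 0.5 * float(((profiles @ w - target) ** 2).sum()),
        x0=np.full(k, 1.0 / (2 * k)),
        jac=lambda w: profiles.T @ (profiles @ w - target),
        method="trust-constr",
        bounds=optimize.Bounds(np.zeros(k), np.full(k, np.inf)),
        constraints=[optimize.LinearConstraint(np.ones((1, k)), -np.inf, 1.0)],
        options={"gtol": 1e-14, "xtol": 1e-14, "maxiter": 5000},
    )
    w = np.clip(res.x, 0.0, None)
    return _polish_active_set(w, target, profiles)


def _polish_active_set(w, target, profiles):
    """Exact KKT solve on the active set identified by the solver: lstsq on
    the positive support, with an equality-constrained solve when the
    simplex bound binds.  Falls back to the unpolished point if the support
    guess proves inconsistent."""
    support = w > 1e-7
    if not support.any():
        return w
    S = profiles[:, support]
    ws, *_ = np.linalg.lstsq(S, target, rcond=None)
    if (ws >= -1e-12).all() and ws.sum() <= 1.0 + 1e-12:
        out = np.zeros_like(w)
        out[support] = np.clip(ws, 0.0, None)
        return out
    # simplex bound active: minimise subject to sum(ws) = 1 via KKT system
    k = S.shape[1]
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = S.T @ S
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([S.T @ target, [1.0]])
    sol = np.linalg.solve(kkt, rhs)
    ws = sol[:k]
    if (ws >= -1e-12).all():
        out = np.zeros_like(w)
        out[support] = np.clip(ws, 0.0, None)
        return out
    return w


def grid_two_signature_weights(
    target: np.ndarray, profiles: np.ndarray, step: float = 1e-4
) -> np.ndarray:
    """Dense grid search over two-signature mixtures minimising SSE."""
    assert profiles.shape[1] == 2
    best, best_sse = None, np.inf
    for w1 in np.arange(0.0, 1.0 + step / 2, step):
        for w2_max in (1.0 - w1,):
            # inner weight solved on the same grid
            w2 = np.arange(0.0, w2_max + step / 2, step)
            resid = target[:, None] - np.outer(profiles[:, 0], np.full(len(w2), w1)) \
                - np.outer(profiles[:, 1], w2)
            sse = (resid ** 2).sum(axis=0)
            i = int(sse.argmin())
            if sse[i] < best_sse:
                best_sse, best = sse[i], np.array([w1, w2[i]])
    return best


MB = 1_000_000


def loh_score_units(
    profile: CNSegmentProfile,
    bridge_gap_mb: int = 3,
    min_event_mb: int = 15,
    exclusion_fraction: float = 0.75,
) -> float:
    """Brute-force LOH score for profiles whose breakpoints all sit on 1 Mb
    boundaries: enumerate per-megabase unit states and scan runs directly."""
    states: dict[str, np.ndarray] = {}
    for chrom, length in profile.chromosome_lengths.items():
        assert length % MB == 0
        states[chrom] = np.zeros(length // MB, dtype=int)  # 0 unassessed
    for seg in profile.segments:
        assert (seg.start - 1) % MB == 0 and seg.end % MB == 0
        lo, hi = (seg.start - 1) // MB, seg.end // MB
        states[seg.chrom][lo:hi] = 2 if seg.is_loh else 1

    num = den = 0
    for chrom, st in states.items():
        assessed = int((st > 0).sum())
        # scan LOH runs: unassessed gaps <= bridge merge, assessed non-LOH breaks
        events = []
        run = 0
        gap = None  # unassessed units since last LOH unit, None = no open run
        for unit in st:
            if unit == 2:
                if gap is not None and gap > bridge_gap_mb:
                    events.append(run)
                    run = 0
                run += 1
                gap = 0
            elif unit == 0:
                if gap is not None:
                    gap += 1
            else:  # assessed, heterozygous: break any run
                if run:
                    events.append(run)
                run, gap = 0, None
        if run:
            events.append(run)
        event_units = sum(e for e in events if e > min_event_mb)
        if event_units / len(st) >= exclusion_fraction:
            continue
        num += event_units
        den += assessed
    if den == 0:
        raise ValueError("denominator zero")
    return num / den


def bh_stepup(p_values) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up recursion."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by hypergeometric enumeration: sum of probabilities
    of all tables with the same margins that are no more probable than the
    observed table (R convention, with a small relative tolerance)."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x: int) -> float:
        return math.exp(
            math.lgamma(row1 + 1) - math.lgamma(x + 1) - math.lgamma(row1 - x + 1)
            + math.lgamma(n - row1 + 1) - math.lgamma(col1 - x + 1)
            - math.lgamma(n - row1 - col1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(col1 + 1) - math.lgamma(n - col1 + 1))
        )

    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    p_obs = prob(a)
    total = sum(
        p for x in range(lo, hi + 1)
        if (p := prob(x)) <= p_obs * (1 + 1e-7)
    )
    return min(total, 1.0)
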