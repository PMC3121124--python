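"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — explicit loops, full state
enumeration, literal textbook formulas — and shares no code with the
implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_mi(fij: np.ndarray, fi: np.ndarray, fj: np.ndarray) -> float:
    """MI as an explicit double loop over the 441 joint cells."""
    total = 0.0
    for a in range(fi.size):
        for b in range(fj.size):
            total += fij[a, b] * math.log(fij[a, b] / (fi[a] * fj[b]))
    return total


def enumerate_pair_distribution(
    g: dict[tuple[int, int], float] | None,
    g11_per_dp: np.ndarray,
    lam: np.ndarray,
):
    """Brute-force enumeration over all (p, d) in {0,1} x {0,1}^K.

    ``g11_per_dp[k]`` is g(1,1) for the pair's k-th domain pair; g(0,1) = -1
    and g(1,0) = g(0,0) = 0 in both feature variants. Returns (S1, S0, Z).
    """
    K = len(lam)
    s = {0: 0.0, 1: 0.0}
    for p in (0, 1):
        for d in itertools.product((0, 1), repeat=K):
            expo = 0.0
            for k, t in enumerate(d):
                if (p, t) == (1, 1):
                    gval = g11_per_dp[k]
                elif (p, t) == (0, 1):
                    gval = -1.0
                else:
                    gval = 0.0
                expo += lam[k] * gval
            s[p] += math.exp(expo)
    return s[1], s[0], s[1] + s[0]


def finite_difference_grad(fun, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function."""
    g = np.empty_like(x, dtype=float)
    for k in range(x.size):
        e = np.zeros_like(x, dtype=float)
        e[k] = h
        g[k] = (fun(x + e) - fun(x - e)) / (2 * h)
    return g


def apm_probabilities(
    pair_domains: dict[tuple[str, str], frozenset],
    strengths: dict[tuple[str, str], float],
) -> dict[tuple[str, str], float]:
    """Literal APM estimator: λ_mn = Σ_{ij ∋ mn} ρ_ij / N_mn with interaction
    strengths ρ_ij in [0, 1]."""
    num: dict = {}
    den: dict = {}
    for pair, dps in pair_domains.items():
        rho = strengths[pair]
        for dp in dps:
            num[dp] = num.get(dp, 0.0) + rho
            den[dp] = den.get(dp, 0) + 1
    return {dp: num[dp] / den[dp] for dp in num}


def mannwhitney_auc(scores, labels) -> float:
    """AUC as the literal pairwise Mann-Whitney statistic with half ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def trapezoid_auc(curve: np.ndarray) -> float:
    """Area under a swept ROC curve by the trapezoid rule."""
    fpr, tpr = curve[:, 0], curve[:, 1]
    return float(np.trapezoid(tpr, fpr))


def enumerate_shuffle_null(col_a, col_b, mi_fn) -> float:
    """Exact shuffle-null mean: average MI over all M! pairings."""
    M = len(col_b)
    vals = [
        mi_fn(col_a, [col_b[k] for k in perm])
        for perm in itertools.permutations(range(M))
    ]
    return float(np.mean(vals))
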