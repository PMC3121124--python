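"""Association and EM baselines under the noisy-OR domain interaction model.

Both estimate probabilities λ_mn that domains D_m and D_n interact. The
generative model (Deng et al. style): each domain pair contained in a protein
pair interacts independently with probability λ_mn; the proteins interact iff
at least one contained domain pair does,

    Pr(P_ij = 1) = 1 − Π_{mn ∈ ij} (1 − λ_mn),

and the observation O_ij flips P_ij with false-negative rate fn
(Pr(O=1 | P=1) = 1 − fn) and false-positive rate fp (Pr(O=1 | P=0) = fp).

The association estimate is λ_mn = I_mn / N_mn (fraction of interacting among
protein pairs containing the domain pair); for binary interaction data it
coincides exactly with the APM weighted estimator. EM starts from the
association solution and iterates the posterior-mean update
λ_mn ← (1/N_mn) Σ_{ij ∋ mn} Pr(D_mn = 1 | O_ij = o_ij, λ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import DomainPair, FactorGraph, Protein, domain_pairs_of

logger = logging.getLogger(__name__)

DEFAULT_FN = 0.8
#: fp is required by the observation model but rarely reported; a small
#: nonzero default avoids the degenerate zero-probability observation o=1 on
#: pairs whose λ's are all zero.
DEFAULT_FP = 1e-4


@dataclass
class DomainProbabilities:
    """Per-domain-pair interaction probabilities from a baseline estimator."""

    lambdas: dict[DomainPair, float]
    method: str
    fn: float = DEFAULT_FN
    fp: float = DEFAULT_FP
    iterations: int = 0
    tolerance: float = 0.0
    log_likelihoods: list[float] = field(default_factory=list)

    def lam(self, dp: DomainPair) -> float:
        return self.lambdas.get(dp, 0.0)


def association(fg: FactorGraph) -> DomainProbabilities:
    """λ_mn = I_mn / N_mn over the labeled pairs of the factor graph."""
    lambdas = {dp: fg.I[dp] / fg.N[dp] for dp in fg.N}
    return DomainProbabilities(lambdas, method="association")


def baseline_predict(
    pi: Protein, pj: Protein, probs: DomainProbabilities
) -> float:
    """Noisy-OR prediction Pr(P_ij = 1) = 1 − Π (1 − λ_mn).

    Domain pairs without an estimate contribute λ = 0.
    """
    log_none = 0.0
    for dp in domain_pairs_of(pi, pj):
        lam = probs.lam(dp)
        if lam >= 1.0:
            return 1.0
        log_none += np.log1p(-lam)
    return float(-np.expm1(log_none))


def _interaction_proba(
    dps: list[DomainPair], lambdas: dict[DomainPair, float]
) -> float:
    prod = 1.0
    for dp in dps:
        prod *= 1.0 - lambdas.get(dp, 0.0)
    return 1.0 - prod


def em_observed_log_likelihood(
    fg: FactorGraph, lambdas: dict[DomainPair, float], fn: float, fp: float
) -> float:
    """Σ_ij log Pr(O_ij = o_ij | λ) under the noisy-OR observation model."""
    ll = 0.0
    tiny = 1e-300
    for lab in fg.labels:
        p1 = _interaction_proba(sorted(fg.pair_domains[lab.pair]), lambdas)
        p_obs1 = (1.0 - fn) * p1 + fp * (1.0 - p1)
        ll += np.log(max(p_obs1 if lab.observed == 1 else 1.0 - p_obs1, tiny))
    return float(ll)


def em_train(
    fg: FactorGraph,
    fn: float = DEFAULT_FN,
    fp: float = DEFAULT_FP,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> DomainProbabilities:
    """EM for the noisy-OR model, initialized from the association solution.

    E-step posterior for one domain pair k inside protein pair ij (marginal
    over the pair's other latent variables, using the product form):

        Pr(D_k=1 | O=1) = λ_k (1 − fn) / Pr(O=1)
        Pr(D_k=1 | O=0) = λ_k fn / Pr(O=0)

    M-step: λ_k ← mean of the posterior over the N_k containing pairs. Stops
    when the max-abs λ change drops below ``tol``. The observed-data
    log-likelihood trace (non-decreasing) is recorded per iteration.
    """
    if not 0.0 <= fn < 1.0 or not 0.0 <= fp < 1.0:
        raise ValueError("fn and fp must lie in [0, 1)")
    lambdas = dict(association(fg).lambdas)
    dp_list = sorted(lambdas)
    ll_trace = [em_observed_log_likelihood(fg, lambdas, fn, fp)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        post_sum = {dp: 0.0 for dp in dp_list}
        for lab in fg.labels:
            dps = sorted(fg.pair_domains[lab.pair])
            p1 = _interaction_proba(dps, lambdas)
            p_obs1 = (1.0 - fn) * p1 + fp * (1.0 - p1)
            for dp in dps:
                lam = lambdas[dp]
                if lab.observed == 1:
                    post = lam * (1.0 - fn) / p_obs1 if p_obs1 > 0 else 0.0
                else:
                    post = lam * fn / (1.0 - p_obs1) if p_obs1 < 1 else 0.0
                post_sum[dp] += post
        new = {dp: post_sum[dp] / fg.N[dp] for dp in dp_list}
        clipped = False
        for dp, v in new.items():
            if v < 0.0 or v > 1.0:
                clipped = True
                new[dp] = min(max(v, 1e-12), 1.0 - 1e-12)
        if clipped:
            logger.warning("EM probabilities escaped [0, 1]; clamped")
        delta = max(abs(new[dp] - lambdas[dp]) for dp in dp_list)
        lambdas = new
        ll_trace.append(em_observed_log_likelihood(fg, lambdas, fn, fp))
        if delta < tol:
            break
    return DomainProbabilities(
        lambdas,
        method="em",
        fn=fn,
        fp=fp,
        iterations=n_iter,
        tolerance=tol,
        log_likelihoods=ll_trace,
    )
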