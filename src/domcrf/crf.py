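"""Conditional random field over protein-pair and latent domain-pair variables.

Each labeled protein pair P_ij is coupled to one latent binary variable D_mn
per contained domain pair through a local feature g(s, t) (s = protein-pair
state, t = domain-pair state) weighted by a per-domain-pair parameter λ_mn:

    Pr(p_ij | M) ∝ Σ_d exp( Σ_mn λ_mn g^{(mn)}(p_ij, d_mn) )

Because the exponent is additive over domain pairs, the latent sum factorizes:

    S_p = Π_mn ( e^{λ_mn g(p,0)} + e^{λ_mn g(p,1)} ),   Z_ij = S_1 + S_0,

all handled in log space. Two feature variants are provided. With MI,
g(1,1) = σ(M_mn − c) with σ the logistic function and c a positive threshold
(default 0.8, on the same nat scale as M_mn); without MI, g(1,1) = +1. In both
variants g(0,1) = −1 — a domain pair "interacting" inside a non-interacting
protein pair is penalized — and g(1,0) = g(0,0) = 0. Training maximizes the
conditional log-likelihood with limited-memory BFGS from λ = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .dataset import (
    DomainPair,
    Protein,
    ProteinPairLabel,
    domain_pairs_of,
)

logger = logging.getLogger(__name__)

WITH_MI = "with_mi"
WITHOUT_MI = "without_mi"
DEFAULT_C = 0.8

MIScores = dict[tuple[str, str], float]


@dataclass(frozen=True)
class FeatureTable:
    """The local feature g(s, t), possibly conditioned on a pair's MI score."""

    variant: str = WITH_MI
    c: float = DEFAULT_C

    def __post_init__(self) -> None:
        if self.variant not in (WITH_MI, WITHOUT_MI):
            raise ValueError(f"unknown feature variant {self.variant!r}")
        if self.variant == WITH_MI and self.c <= 0:
            raise ValueError("c must be a positive constant")

    def g11(self, m_mn: float | None) -> float:
        """g(1,1): σ(M_mn − c) with MI, +1 without (or when MI is unavailable)."""
        if self.variant == WITHOUT_MI or m_mn is None or not math.isfinite(m_mn):
            return 1.0
        return float(expit(m_mn - self.c))

    def value(self, s: int, t: int, m_mn: float | None = None) -> float:
        if s not in (0, 1) or t not in (0, 1):
            raise ValueError("feature states are binary")
        if (s, t) == (1, 1):
            return self.g11(m_mn)
        if (s, t) == (0, 1):
            return -1.0
        return 0.0


def feature_value(
    variant: str, s: int, t: int, m_mn: float | None = None, c: float = DEFAULT_C
) -> float:
    """Functional form of :meth:`FeatureTable.value`."""
    return FeatureTable(variant, c).value(s, t, m_mn)


@dataclass(frozen=True)
class PairLikelihoodTerms:
    """Log-space likelihood pieces of one protein pair."""

    log_s1: float
    log_s0: float

    @property
    def log_z(self) -> float:
        return float(np.logaddexp(self.log_s1, self.log_s0))

    @property
    def proba(self) -> float:
        """Pr(P_ij = 1 | M) = S1 / Z, strictly inside (0, 1)."""
        return float(expit(self.log_s1 - self.log_s0))


def pair_log_terms(g11: np.ndarray, lam: np.ndarray) -> PairLikelihoodTerms:
    """Factorized log S1 / log S0 for one protein pair.

    ``g11[k]`` and ``lam[k]`` refer to the pair's k-th domain pair. Each latent
    factor is e^{λ·g(p,0)} + e^{λ·g(p,1)}, i.e. 1 + e^{λ·g11} for p = 1 and
    1 + e^{−λ} for p = 0 (using g(0,1) = −1), summed stably with logaddexp.
    """
    g11 = np.asarray(g11, float)
    lam = np.asarray(lam, float)
    if g11.size == 0:
        raise ValueError("cannot score a protein pair with no domain pairs")
    log_s1 = float(np.logaddexp(0.0, lam * g11).sum())
    log_s0 = float(np.logaddexp(0.0, -lam).sum())
    return PairLikelihoodTerms(log_s1, log_s0)


@dataclass
class CRFDesign:
    """Labeled pairs compiled to flat occurrence arrays for fast (re)scoring."""

    dp_ids: list[DomainPair]
    dp_index: dict[DomainPair, int]
    g11: np.ndarray  # per domain-pair index
    occ_pair: np.ndarray  # occurrence -> pair row
    occ_dp: np.ndarray  # occurrence -> domain-pair index
    labels: np.ndarray  # per pair, {0,1}
    pairs: list[tuple[str, str]]

    @property
    def n_pairs(self) -> int:
        return self.labels.size

    @property
    def n_params(self) -> int:
        return len(self.dp_ids)


def build_design(
    proteins: dict[str, Protein],
    labels: list[ProteinPairLabel],
    features: FeatureTable,
    mi_scores: MIScores | None = None,
) -> CRFDesign:
    """Compile labeled protein pairs into the flat design used for training."""
    if not labels:
        raise ValueError("no labeled pairs")
    mi_scores = mi_scores or {}
    dp_index: dict[DomainPair, int] = {}
    dp_ids: list[DomainPair] = []
    occ_pair: list[int] = []
    occ_dp: list[int] = []
    y = np.empty(len(labels), dtype=np.int8)
    pairs = []
    n_fallback = 0
    for row, lab in enumerate(labels):
        a, b = lab.pair
        dps = sorted(domain_pairs_of(proteins[a], proteins[b]))
        if not dps:
            raise ValueError(f"pair {lab.pair} has no domain pairs")
        y[row] = lab.label
        pairs.append(lab.pair)
        for dp in dps:
            k = dp_index.get(dp)
            if k is None:
                k = dp_index[dp] = len(dp_ids)
                dp_ids.append(dp)
            occ_pair.append(row)
            occ_dp.append(k)
    g11 = np.empty(len(dp_ids))
    for dp, k in dp_index.items():
        m = mi_scores.get(dp)
        if features.variant == WITH_MI and (m is None or not math.isfinite(m)):
            n_fallback += 1
        g11[k] = features.g11(m)
    if n_fallback:
        logger.info(
            "MI unavailable for %d/%d domain pairs; using the MI-free feature there",
            n_fallback, len(dp_ids),
        )
    return CRFDesign(
        dp_ids,
        dp_index,
        g11,
        np.asarray(occ_pair, dtype=np.intp),
        np.asarray(occ_dp, dtype=np.intp),
        y.astype(np.float64),
        pairs,
    )


def _log_terms(design: CRFDesign, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam_occ = lam[design.occ_dp]
    t1 = np.logaddexp(0.0, lam_occ * design.g11[design.occ_dp])
    t0 = np.logaddexp(0.0, -lam_occ)
    log_s1 = np.bincount(design.occ_pair, weights=t1, minlength=design.n_pairs)
    log_s0 = np.bincount(design.occ_pair, weights=t0, minlength=design.n_pairs)
    return log_s1, log_s0


def log_likelihood(design: CRFDesign, lam: np.ndarray) -> float:
    """Conditional log-likelihood l(λ) = Σ_ij [log S_{p_ij} − log Z_ij] ≤ 0."""
    log_s1, log_s0 = _log_terms(design, lam)
    log_z = np.logaddexp(log_s1, log_s0)
    chosen = np.where(design.labels == 1, log_s1, log_s0)
    return float((chosen - log_z).sum())


def log_likelihood_grad(design: CRFDesign, lam: np.ndarray) -> np.ndarray:
    """∂l/∂λ_mn in observed-minus-expected form.

    For each protein pair containing D_mn the contribution is
    E[g(p_ij, t) | p_ij] − Σ_p Pr(p | λ) E[g(p, t) | p], where the latent
    expectations are E[g | p=1] = g11·σ(λ·g11) and E[g | p=0] = −σ(−λ).
    """
    log_s1, log_s0 = _log_terms(design, lam)
    p1 = expit(log_s1 - log_s0)  # Pr(P_ij = 1 | λ)
    e1 = design.g11 * expit(lam * design.g11)  # per dp: E[g | p=1]
    e0 = -expit(-lam)  # per dp: E[g | p=0]
    e1_occ = e1[design.occ_dp]
    e0_occ = e0[design.occ_dp]
    obs = np.where(design.labels[design.occ_pair] == 1, e1_occ, e0_occ)
    exp = p1[design.occ_pair] * e1_occ + (1.0 - p1[design.occ_pair]) * e0_occ
    return np.bincount(
        design.occ_dp, weights=obs - exp, minlength=design.n_params
    )


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings mirroring common limited-memory BFGS defaults."""

    gtol: float = 1e-5
    max_iter: int = 500
    history: int = 6
    l1: float = 0.0  # optional l1 penalty weight; 0 disables


@dataclass
class CRFParams:
    """Trained per-domain-pair weights plus optimizer diagnostics."""

    weights: dict[DomainPair, float]
    features: FeatureTable
    log_likelihood: float = float("nan")
    n_iterations: int = 0
    converged: bool = False
    mi_scores: MIScores = field(default_factory=dict)

    def lam(self, dp: DomainPair) -> float:
        """Weight of a domain pair; pairs unseen in training are neutral (0)."""
        return self.weights.get(dp, 0.0)


def train(
    proteins: dict[str, Protein],
    labels: list[ProteinPairLabel],
    features: FeatureTable = FeatureTable(),
    mi_scores: MIScores | None = None,
    cfg: TrainConfig = TrainConfig(),
) -> CRFParams:
    """Maximize l(λ) with L-BFGS from λ = 0.

    With ``cfg.l1 > 0`` the l1-penalized objective is maximized exactly via
    the standard positive/negative split with bound-constrained L-BFGS-B.
    """
    design = build_design(proteins, labels, features, mi_scores)
    options = {"maxiter": cfg.max_iter, "gtol": cfg.gtol, "maxcor": cfg.history}

    if cfg.l1 > 0.0:
        n = design.n_params

        def fun_split(uv: np.ndarray):
            lam = uv[:n] - uv[n:]
            g = log_likelihood_grad(design, lam)
            f = -log_likelihood(design, lam) + cfg.l1 * uv.sum()
            return f, np.concatenate([-g + cfg.l1, g + cfg.l1])

        res = minimize(
            fun_split,
            np.zeros(2 * n),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * n),
            options={"maxiter": cfg.max_iter, "maxcor": cfg.history},
        )
        lam_opt = res.x[:n] - res.x[n:]
    else:

        def fun(lam: np.ndarray):
            f = -log_likelihood(design, lam)
            if not np.isfinite(f):
                raise FloatingPointError(
                    f"non-finite objective during optimization at |λ|max={np.abs(lam).max():g}"
                )
            return f, -log_likelihood_grad(design, lam)

        res = minimize(
            fun, np.zeros(design.n_params), jac=True, method="L-BFGS-B",
            options=options,
        )
        lam_opt = res.x

    return CRFParams(
        weights={dp: float(w) for dp, w in zip(design.dp_ids, lam_opt)},
        features=features,
        log_likelihood=float(-res.fun if cfg.l1 == 0 else log_likelihood(design, lam_opt)),
        n_iterations=int(res.nit),
        converged=bool(res.success),
        mi_scores=dict(mi_scores or {}),
    )


def predict_proba(
    pi: Protein,
    pj: Protein,
    params: CRFParams,
    mi_scores: MIScores | None = None,
) -> float:
    """Pr(P_ij = 1 | M) for one protein pair under trained parameters.

    Domain pairs unseen in training contribute neutral λ = 0 factors.
    ``mi_scores`` defaults to the scores stored at training time.
    """
    scores = mi_scores if mi_scores is not None else params.mi_scores
    dps = sorted(domain_pairs_of(pi, pj))
    g11 = np.array([params.features.g11(scores.get(dp)) for dp in dps])
    lam = np.array([params.lam(dp) for dp in dps])
    return pair_log_terms(g11, lam).proba
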