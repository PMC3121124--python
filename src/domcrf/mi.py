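"""Mutual information between alignment columns and between domains.

For two domain alignments whose rows have been paired by organism, the MI of
column pair (i, j) is the KL divergence between the joint amino-acid
distribution f_ij(A, B) and the product of marginals f_i(A) f_j(B), computed
over the 21-letter alphabet (gap included) after pseudocounting. MI is in nats.

Because finite-sample MI is biased upward, a shuffle null is subtracted: the
row pairing is permuted uniformly at random (marginals preserved, joint
broken), MI is recomputed, and the average over repetitions (default 400) is
taken. The domain-level score M_mn is the maximum of the corrected MI over all
column pairs, excluding columns with more than 20% gaps.

Pseudocounts use the normalization-preserving mixture
``f~ = (f_raw + eta/q) / (1 + eta)`` with q = 21 for marginals and q = 441 for
joint tables. This form makes the pseudocounted joint marginalize exactly to
the pseudocounted marginals, so MI decomposes as H_i + H_j - H_ij; the fast
paths below exploit that and are cross-checked against the literal 441-cell
sum in the test suite.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .alignments import DomainAlignment, PairedAlignment, pair_rows
from .alphabet import GAP_CODE, N_JOINT, N_SYMBOLS

DEFAULT_ETA = 1.0
DEFAULT_GAP_THRESHOLD = 0.20
DEFAULT_N_SHUFFLES = 400


@dataclass(frozen=True)
class MIConfig:
    """Knobs of the domain-MI computation (defaults as used throughout)."""

    eta: float = DEFAULT_ETA
    gap_threshold: float = DEFAULT_GAP_THRESHOLD
    n_shuffles: int = DEFAULT_N_SHUFFLES
    seed: int = 0


@dataclass(frozen=True)
class ColumnFrequencies:
    """Pseudocounted amino-acid frequencies of one column (21 entries)."""

    freqs: np.ndarray
    eta: float

    def __post_init__(self) -> None:
        assert self.freqs.shape == (N_SYMBOLS,)


@dataclass(frozen=True)
class JointFrequencies:
    """Pseudocounted joint frequencies of a column pair (21 x 21)."""

    freqs: np.ndarray
    eta: float

    def __post_init__(self) -> None:
        assert self.freqs.shape == (N_SYMBOLS, N_SYMBOLS)


@dataclass(frozen=True)
class DomainMIScore:
    """Shuffle-corrected, gap-filtered, max-over-positions MI of a domain pair.

    ``m_mn`` is None when the score is unavailable (fewer than two paired rows,
    or every column masked); downstream consumers then fall back to the MI-free
    feature for this pair.
    """

    domain_a: str
    domain_b: str
    m_mn: float | None
    n_positions_used: int
    M: int
    n_shuffles: int
    seed: int
    best_positions: tuple[int, int] | None = None

    @property
    def available(self) -> bool:
        return self.m_mn is not None


class UndefinedFrequencyError(ValueError):
    """Raised when frequencies are requested from an empty pairing (M = 0)."""


class ShuffleDegenerateError(ValueError):
    """Raised when a shuffle null is requested with fewer than two pairs."""


def pseudocount(raw: np.ndarray, eta: float, q: int) -> np.ndarray:
    """Mix raw frequencies with the uniform distribution over q cells."""
    return (raw + eta / q) / (1.0 + eta)


def column_frequencies(
    pa: PairedAlignment, which: str, i: int, eta: float = DEFAULT_ETA
) -> ColumnFrequencies:
    """Pseudocounted frequencies of column ``i`` over the paired rows.

    ``which`` selects the alignment ('a' or 'b'). Raw frequency is count/M.
    """
    if pa.M == 0:
        raise UndefinedFrequencyError("no paired rows: column frequencies undefined")
    A, B = pa.paired_codes()
    col = A[:, i] if which == "a" else B[:, i]
    counts = np.bincount(col, minlength=N_SYMBOLS).astype(float)
    return ColumnFrequencies(pseudocount(counts / pa.M, eta, N_SYMBOLS), eta)


def joint_frequencies(
    pa: PairedAlignment, i: int, j: int, eta: float = DEFAULT_ETA
) -> JointFrequencies:
    """Pseudocounted joint frequencies of column i of a and column j of b."""
    if pa.M == 0:
        raise UndefinedFrequencyError("no paired rows: joint frequencies undefined")
    A, B = pa.paired_codes()
    idx = A[:, i].astype(np.intp) * N_SYMBOLS + B[:, j]
    counts = np.bincount(idx, minlength=N_JOINT).astype(float)
    raw = counts.reshape(N_SYMBOLS, N_SYMBOLS) / pa.M
    return JointFrequencies(pseudocount(raw, eta, N_JOINT), eta)


def mi_position_pair(
    f_i: ColumnFrequencies | np.ndarray,
    f_j: ColumnFrequencies | np.ndarray,
    f_ij: JointFrequencies | np.ndarray,
) -> float:
    """MI of one column pair: KL(f_ij || f_i x f_j), in nats.

    All frequencies must be strictly positive (guaranteed after
    pseudocounting at eta > 0); tiny negative float noise is clamped to 0.
    """
    fi = f_i.freqs if isinstance(f_i, ColumnFrequencies) else np.asarray(f_i, float)
    fj = f_j.freqs if isinstance(f_j, ColumnFrequencies) else np.asarray(f_j, float)
    fij = f_ij.freqs if isinstance(f_ij, JointFrequencies) else np.asarray(f_ij, float)
    if np.any(fi <= 0) or np.any(fj <= 0) or np.any(fij <= 0):
        raise ValueError("MI requires strictly positive frequencies (pseudocount first)")
    mi = float(rel_entr(fij, np.outer(fi, fj)).sum())
    return max(mi, 0.0)


def gap_mask(
    al: DomainAlignment, threshold: float, pa: PairedAlignment
) -> np.ndarray:
    """Boolean mask of columns whose gap fraction over the PAIRED rows exceeds
    ``threshold`` (strict inequality); masked columns are excluded from M_mn.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("gap threshold must lie in [0, 1]")
    if pa.M == 0:
        return np.zeros(al.n_cols, dtype=bool)
    A, B = pa.paired_codes()
    if al is pa.alignment_a:
        codes = A
    elif al is pa.alignment_b:
        codes = B
    else:
        raise ValueError("alignment does not belong to this pairing")
    gap_frac = (codes == GAP_CODE).mean(axis=0)
    return gap_frac > threshold


# -- fast entropy machinery -------------------------------------------------
#
# With the mixture pseudocount, the joint's marginals equal the pseudocounted
# marginals exactly, so MI_ij = H_i + H_j - H_ij where every H is the Shannon
# entropy of the pseudocounted table. Joint entropies are evaluated through a
# lookup table phi[k] = f(k) ln f(k) indexed by the integer cell count k,
# which avoids recomputing logs across shuffles.


def _phi_table(M: int, eta: float, q: int) -> np.ndarray:
    k = np.arange(M + 1, dtype=float)
    f = (k / M + eta / q) / (1.0 + eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = f * np.log(f)
    phi[f == 0.0] = 0.0  # 0 log 0 = 0 (eta = 0 case)
    return phi


def _marginal_entropy(col: np.ndarray, M: int, eta: float) -> float:
    counts = np.bincount(col, minlength=N_SYMBOLS)
    phi = _phi_table(M, eta, N_SYMBOLS)
    return -float(phi[counts].sum())


def _joint_entropies_one_vs_many(
    col_a: np.ndarray, B: np.ndarray, M: int, phi441: np.ndarray
) -> np.ndarray:
    """Joint entropy of (col_a, B[:, j]) for every column j of B."""
    nb = B.shape[1]
    idx = col_a.astype(np.intp)[:, None] * N_SYMBOLS + B
    flat = idx + N_JOINT * np.arange(nb, dtype=np.intp)[None, :]
    counts = np.bincount(flat.ravel(), minlength=nb * N_JOINT).reshape(nb, N_JOINT)
    return -phi441[counts].sum(axis=1)


def _null_mi_mean(
    col_a: np.ndarray,
    col_b: np.ndarray,
    perms: np.ndarray,
    h_a: float,
    h_b: float,
    M: int,
    phi441: np.ndarray,
) -> float:
    """Mean MI over row-permuted pairings (marginals fixed, joint broken)."""
    S = perms.shape[0]
    idx = col_a.astype(np.intp)[perms] * N_SYMBOLS + col_b[None, :]
    flat = idx + N_JOINT * np.arange(S, dtype=np.intp)[:, None]
    counts = np.bincount(flat.ravel(), minlength=S * N_JOINT).reshape(S, N_JOINT)
    h_joint = -phi441[counts].sum(axis=1)
    mi = np.maximum(h_a + h_b - h_joint, 0.0)
    return float(mi.mean())


def shuffle_null(
    pa: PairedAlignment,
    i: int,
    j: int,
    eta: float = DEFAULT_ETA,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> float:
    """Average MI of column pair (i, j) after shuffling the row pairing.

    Each repetition permutes the b-side rows uniformly at random and
    recomputes the pseudocounted MI; the mean over ``n_shuffles`` repetitions
    is returned. Deterministic given ``seed``.
    """
    if pa.M < 2:
        raise ShuffleDegenerateError("shuffle null needs at least two paired rows")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    A, B = pa.paired_codes()
    col_a, col_b = A[:, i], B[:, j]
    rng = np.random.default_rng(seed)
    perms = np.vstack([rng.permutation(pa.M) for _ in range(n_shuffles)])
    phi441 = _phi_table(pa.M, eta, N_JOINT)
    h_a = _marginal_entropy(col_a, pa.M, eta)
    h_b = _marginal_entropy(col_b, pa.M, eta)
    return _null_mi_mean(col_a, col_b, perms, h_a, h_b, pa.M, phi441)


def _pair_seed(seed: int, domain_a: str, domain_b: str) -> np.random.SeedSequence:
    """Per-domain-pair seed: order-independent (ids are sorted by the caller)."""
    return np.random.SeedSequence(
        entropy=(int(seed), zlib.crc32(domain_a.encode()), zlib.crc32(domain_b.encode()))
    )


def compute_domain_mi(
    a: DomainAlignment,
    b: DomainAlignment,
    cfg: MIConfig = MIConfig(),
    exhaustive: bool = False,
) -> DomainMIScore:
    """Domain-pair MI score M_mn: max over column pairs of corrected MI.

    The correction subtracts the shuffle-null mean per column pair before the
    max; M_mn may be negative if every pair corrects negative. Columns with a
    gap fraction above ``cfg.gap_threshold`` (over paired rows) are excluded;
    for a self pair (a == b) the diagonal i == j is excluded as well, since
    its MI is the column entropy rather than coevolution.

    Symmetric and reproducible: the two domains are put in canonical (sorted)
    order and the shuffle RNG is seeded from (cfg.seed, domain pair), so
    ``compute_domain_mi(a, b)`` and ``compute_domain_mi(b, a)`` are
    bit-identical.

    Because each shuffle MI is >= 0, corrected MI <= raw MI; by default column
    pairs are scanned in decreasing raw-MI order and the scan stops once no
    remaining pair can exceed the best corrected value (exact pruning).
    ``exhaustive=True`` disables the pruning (identical result).
    """
    if b.domain_id < a.domain_id:
        a, b = b, a
    seed_seq = _pair_seed(cfg.seed, a.domain_id, b.domain_id)
    seed_repr = int(cfg.seed)

    def unavailable(M: int) -> DomainMIScore:
        return DomainMIScore(
            a.domain_id, b.domain_id, None, 0, M, cfg.n_shuffles, seed_repr
        )

    pa = pair_rows(a, b)
    if pa.M < 2:
        return unavailable(pa.M)
    A, B = pa.paired_codes()
    M = pa.M
    keep_a = np.flatnonzero((A == GAP_CODE).mean(axis=0) <= cfg.gap_threshold)
    keep_b = np.flatnonzero((B == GAP_CODE).mean(axis=0) <= cfg.gap_threshold)
    self_pair = a.domain_id == b.domain_id
    if keep_a.size == 0 or keep_b.size == 0:
        return unavailable(M)

    phi441 = _phi_table(M, cfg.eta, N_JOINT)
    h_a = np.array([_marginal_entropy(A[:, i], M, cfg.eta) for i in keep_a])
    h_b = np.array([_marginal_entropy(B[:, j], M, cfg.eta) for j in keep_b])

    raw = np.empty((keep_a.size, keep_b.size))
    for ai, i in enumerate(keep_a):
        h_joint = _joint_entropies_one_vs_many(A[:, i], B[:, keep_b], M, phi441)
        raw[ai] = np.maximum(h_a[ai] + h_b - h_joint, 0.0)
    if self_pair:
        same = keep_a[:, None] == keep_b[None, :]
        raw[same] = -np.inf
    n_positions = int(np.isfinite(raw).sum())
    if n_positions == 0:
        return unavailable(M)

    rng = np.random.default_rng(seed_seq)
    perms = np.vstack([rng.permutation(M) for _ in range(cfg.n_shuffles)])

    order = np.argsort(raw, axis=None)[::-1]
    best = -np.inf
    best_pos: tuple[int, int] | None = None
    for flat in order:
        ai, bj = np.unravel_index(flat, raw.shape)
        if not np.isfinite(raw[ai, bj]):
            break
        if not exhaustive and raw[ai, bj] <= best:
            break
        null_mean = _null_mi_mean(
            A[:, keep_a[ai]], B[:, keep_b[bj]], perms, h_a[ai], h_b[bj], M, phi441
        )
        corrected = raw[ai, bj] - null_mean
        if corrected > best:
            best = corrected
            best_pos = (int(keep_a[ai]), int(keep_b[bj]))
    return DomainMIScore(
        a.domain_id,
        b.domain_id,
        float(best),
        n_positions,
        M,
        cfg.n_shuffles,
        seed_repr,
        best_pos,
    )


def compute_mi_table(
    alignments: dict[str, DomainAlignment],
    pairs: list[tuple[str, str]],
    cfg: MIConfig = MIConfig(),
) -> pd.DataFrame:
    """M_mn for a list of unordered domain pairs, as a tidy table.

    Pairs whose domains lack an alignment, or whose score is unavailable, get
    ``m_mn = NaN``. Each unordered pair is computed once.
    """
    seen: set[tuple[str, str]] = set()
    records = []
    for m, n in pairs:
        key = (m, n) if m <= n else (n, m)
        if key in seen:
            continue
        seen.add(key)
        if key[0] not in alignments or key[1] not in alignments:
            records.append(
                {"domain_a": key[0], "domain_b": key[1], "m_mn": np.nan,
                 "n_positions_used": 0, "M": 0, "seed": cfg.seed}
            )
            continue
        score = compute_domain_mi(alignments[key[0]], alignments[key[1]], cfg)
        records.append(
            {
                "domain_a": score.domain_a,
                "domain_b": score.domain_b,
                "m_mn": score.m_mn if score.available else np.nan,
                "n_positions_used": score.n_positions_used,
                "M": score.M,
                "seed": score.seed,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["domain_a", "domain_b", "m_mn", "n_positions_used", "M", "seed"]
    )


def mi_scores_dict(table: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Collapse a compute_mi_table frame to {sorted pair: m_mn}, NaN dropped."""
    out: dict[tuple[str, str], float] = {}
    for row in table.itertuples(index=False):
        if np.isfinite(row.m_mn):
            key = tuple(sorted((row.domain_a, row.domain_b)))
            out[key] = float(row.m_mn)
    return out


def mi_histogram(scores: np.ndarray, bin_width: float = 0.1) -> pd.DataFrame:
    """Histogram of domain MI scores (distribution-plot style), as a table."""
    scores = np.asarray(scores, float)
    scores = scores[np.isfinite(scores)]
    if scores.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    lo = np.floor(scores.min() / bin_width) * bin_width
    hi = np.ceil(scores.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(scores, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
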