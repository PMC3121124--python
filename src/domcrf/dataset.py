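"""Proteins as domain multisets, labeled protein pairs, and the factor graph.

The model couples each protein-pair variable P_ij to one latent variable D_mn
per *unordered domain-type pair* contained in the pair: D_mn is in P_ij iff
D_m is a domain of P_i and D_n a domain of P_j (or the other way round).
Repeated domains within a protein do not multiply variables. The resulting
bipartite incidence structure, together with the counts N_mn (protein pairs
containing the domain pair) and I_mn (interacting ones among them), drives
both the CRF and the association/EM baselines.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

DomainPair = tuple[str, str]
ProteinPair = tuple[str, str]


@dataclass(frozen=True)
class Protein:
    protein_id: str
    domains: tuple[str, ...]  # multiset, order preserved from input

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError(f"protein {self.protein_id!r} has no domains")


@dataclass(frozen=True)
class ProteinPairLabel:
    """A labeled unordered protein pair; ``observed`` mirrors the label for
    binary data but is kept separate for the noisy-observation model."""

    pair: ProteinPair
    label: int
    observed: int | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r}")
        object.__setattr__(self, "pair", canonical_pair(*self.pair))
        if self.observed is None:
            object.__setattr__(self, "observed", self.label)


def canonical_pair(x: str, y: str) -> tuple[str, str]:
    return (x, y) if x <= y else (y, x)


def domain_pairs_of(pi: Protein, pj: Protein) -> frozenset[DomainPair]:
    """Set of unordered domain-type pairs contained in a protein pair.

    Duplicates collapse (one latent variable per domain-type pair); the self
    domain pair (D, D) appears when both proteins carry D.
    """
    return frozenset(
        canonical_pair(m, n) for m in pi.domains for n in pj.domains
    )


class DatasetError(ValueError):
    """Malformed composition/interaction input."""


def load_dataset(
    compositions: str | Path | pd.DataFrame,
    interactions: str | Path | pd.DataFrame,
) -> tuple[dict[str, Protein], list[ProteinPairLabel]]:
    """Load the protein->domains table and the labeled protein pairs.

    Compositions TSV: ``protein_id <TAB> comma-separated domain ids``;
    interactions TSV: ``protein_a <TAB> protein_b <TAB> label``. Proteins
    without any domain are dropped (with their labels); duplicate pairs with
    agreeing labels are kept once, contradictory duplicates are an error, as
    are labels that reference unknown proteins.
    """
    if isinstance(compositions, pd.DataFrame):
        comp = compositions.copy()
    else:
        comp = pd.read_csv(
            compositions, sep="\t", header=None, names=["protein_id", "domains"],
            dtype=str, keep_default_na=False, comment="#",
        )
    proteins: dict[str, Protein] = {}
    n_dropped = 0
    for row in comp.itertuples(index=False):
        pid = str(row.protein_id).strip()
        doms = tuple(d.strip() for d in str(row.domains).split(",") if d.strip())
        if not doms:
            n_dropped += 1
            continue
        if pid in proteins:
            raise DatasetError(f"duplicate protein id {pid!r} in compositions")
        proteins[pid] = Protein(pid, doms)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "dropped %d proteins without any domain", n_dropped
        )

    if isinstance(interactions, pd.DataFrame):
        inter = interactions.copy()
    else:
        inter = pd.read_csv(
            interactions, sep="\t", header=None,
            names=["protein_a", "protein_b", "label"],
            dtype={"protein_a": str, "protein_b": str}, comment="#",
        )
    seen: dict[ProteinPair, int] = {}
    labels: list[ProteinPairLabel] = []
    for row in inter.itertuples(index=False):
        a, b = str(row.protein_a).strip(), str(row.protein_b).strip()
        try:
            lab = int(row.label)
        except (TypeError, ValueError) as exc:
            raise DatasetError(f"non-integer label {row.label!r} for ({a}, {b})") from exc
        if a not in proteins or b not in proteins:
            missing = a if a not in proteins else b
            raise DatasetError(f"interaction references unknown protein {missing!r}")
        key = canonical_pair(a, b)
        if key in seen:
            if seen[key] != lab:
                raise DatasetError(f"contradictory labels for pair {key}")
            continue
        seen[key] = lab
        labels.append(ProteinPairLabel(key, lab))
    return proteins, labels


@dataclass
class FactorGraph:
    """Bipartite graph linking labeled protein pairs to their domain pairs."""

    proteins: dict[str, Protein]
    labels: list[ProteinPairLabel]
    pair_domains: dict[ProteinPair, frozenset[DomainPair]] = field(default_factory=dict)
    dp_pairs: dict[DomainPair, list[ProteinPair]] = field(default_factory=dict)
    N: dict[DomainPair, int] = field(default_factory=dict)
    I: dict[DomainPair, int] = field(default_factory=dict)

    @property
    def domain_pairs(self) -> list[DomainPair]:
        return sorted(self.N)

    def n_edges(self) -> int:
        return sum(len(v) for v in self.dp_pairs.values())


def build_factor_graph(
    proteins: dict[str, Protein], labels: list[ProteinPairLabel]
) -> FactorGraph:
    """Tally N_mn / I_mn and the two-way incidence over the labeled pairs."""
    if not labels:
        raise DatasetError("cannot build a factor graph from zero labeled pairs")
    fg = FactorGraph(proteins, list(labels))
    dp_pairs: dict[DomainPair, list[ProteinPair]] = defaultdict(list)
    N: dict[DomainPair, int] = defaultdict(int)
    I: dict[DomainPair, int] = defaultdict(int)
    for lab in labels:
        a, b = lab.pair
        dps = domain_pairs_of(proteins[a], proteins[b])
        fg.pair_domains[lab.pair] = dps
        for dp in dps:
            dp_pairs[dp].append(lab.pair)
            N[dp] += 1
            I[dp] += lab.label
    fg.dp_pairs = {dp: sorted(v) for dp, v in dp_pairs.items()}
    fg.N = dict(N)
    fg.I = dict(I)
    return fg
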