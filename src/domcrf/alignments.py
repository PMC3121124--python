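"""Domain alignments, organism-based row pairing, and alignment I/O.

A :class:`DomainAlignment` is one domain family's multiple sequence alignment
with an organism tag per row. MI between two domains is computed from the rows
that can be paired: within each organism, rows of the two alignments are paired
greedily in file order, and unpaired rows are dropped from all frequency
counts.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import encode

#: Default organism extractor: the token after the last '_' in UniProt-style
#: names, e.g. ``RL12_HUMAN`` -> ``HUMAN``. A trailing ``/start-end`` range
#: (Pfam convention) is stripped before matching.
DEFAULT_ORGANISM_REGEX = r"_([A-Za-z0-9]+)$"


@dataclass
class DomainAlignment:
    """One domain's multiple alignment with per-row organism tags."""

    domain_id: str
    rows: list[tuple[str, str, str]]  # (organism_id, seq_id, aligned_seq)
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"alignment {self.domain_id!r} has no rows")
        lengths = {len(seq) for _, _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError(
                f"alignment {self.domain_id!r} has ragged rows: lengths {sorted(lengths)}"
            )
        if self.n_cols < 1:
            raise ValueError(f"alignment {self.domain_id!r} has zero columns")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][2])

    @property
    def codes(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n_rows, n_cols), int8."""
        if self._codes is None:
            self._codes = np.vstack([encode(seq) for _, _, seq in self.rows])
        return self._codes

    def organisms(self) -> list[str]:
        return [org for org, _, _ in self.rows]


@dataclass(frozen=True)
class PairedAlignment:
    """Row pairing of two domain alignments by shared organism.

    ``pairs[k] = (row index in a, row index in b)``; ``M = len(pairs)`` is the
    number of paired sequences entering the frequency counts.
    """

    domain_a: str
    domain_b: str
    pairs: tuple[tuple[int, int], ...]
    alignment_a: DomainAlignment = field(repr=False, compare=False)
    alignment_b: DomainAlignment = field(repr=False, compare=False)

    @property
    def M(self) -> int:
        return len(self.pairs)

    def paired_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """Codes of the paired rows only: (M, n_cols_a), (M, n_cols_b)."""
        ia = np.fromiter((i for i, _ in self.pairs), dtype=np.intp, count=self.M)
        ib = np.fromiter((j for _, j in self.pairs), dtype=np.intp, count=self.M)
        return self.alignment_a.codes[ia], self.alignment_b.codes[ib]


def pair_rows(a: DomainAlignment, b: DomainAlignment) -> PairedAlignment:
    """Pair rows of two alignments that share an organism.

    Within one organism, rows are paired greedily in file order, up to
    ``min(count_a, count_b)`` pairs; leftover rows are dropped. ``M = 0``
    (no shared organism) is a valid empty pairing.
    """
    by_org_b: dict[str, list[int]] = defaultdict(list)
    for j, (org, _, _) in enumerate(b.rows):
        by_org_b[org].append(j)
    used: dict[str, int] = defaultdict(int)  # per-organism cursor into b
    pairs: list[tuple[int, int]] = []
    for i, (org, _, _) in enumerate(a.rows):
        cursor = used[org]
        if cursor < len(by_org_b.get(org, ())):
            pairs.append((i, by_org_b[org][cursor]))
            used[org] = cursor + 1
    return PairedAlignment(a.domain_id, b.domain_id, tuple(pairs), a, b)


def _parse_organism(seq_id: str, organism_regex: str) -> str:
    name = seq_id.split("/")[0]  # strip Pfam start-end range
    m = re.search(organism_regex, name)
    if m:
        return m.group(1)
    return name


def load_alignment(
    path: str | Path,
    domain_id: str | None = None,
    fmt: str | None = None,
    organism_regex: str = DEFAULT_ORGANISM_REGEX,
) -> DomainAlignment:
    """Read one domain alignment from Stockholm or aligned FASTA.

    The format is inferred from the file suffix unless ``fmt`` is given
    ('stockholm' or 'fasta'). The organism tag is extracted from each record
    id via ``organism_regex`` (first capture group).
    """
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
    msa = AlignIO.read(str(path), fmt)
    rows = [
        (_parse_organism(rec.id, organism_regex), rec.id, str(rec.seq))
        for rec in msa
    ]
    return DomainAlignment(domain_id or path.stem, rows)


def load_alignment_dir(
    directory: str | Path,
    organism_regex: str = DEFAULT_ORGANISM_REGEX,
) -> dict[str, DomainAlignment]:
    """Load every ``*.sto``/``*.stk``/``*.fasta``/``*.fa`` file in a directory."""
    directory = Path(directory)
    out: dict[str, DomainAlignment] = {}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() in {".sto", ".stk", ".stockholm", ".fasta", ".fa", ".afa"}:
            al = load_alignment(path, organism_regex=organism_regex)
            out[al.domain_id] = al
    if not out:
        raise FileNotFoundError(f"no alignment files found in {directory}")
    return out


def write_alignment(al: DomainAlignment, path: str | Path, fmt: str = "stockholm") -> None:
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=seq_id, description="") for _, seq_id, seq in al.rows]
    )
    AlignIO.write(msa, str(path), fmt)
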