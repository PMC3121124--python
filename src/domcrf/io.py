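"""Plain-text I/O: MI tables, model files, and dataset TSVs.

Model files are TSV with a one-line JSON header (prefixed ``#``) recording
the method and its settings, so a file round-trips to the object that wrote
it.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .baselines import DomainProbabilities
from .crf import CRFParams, FeatureTable
from .dataset import Protein, ProteinPairLabel
from .mi import mi_scores_dict


def write_mi_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_mi_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_mi_scores(path: str | Path) -> dict[tuple[str, str], float]:
    return mi_scores_dict(read_mi_table(path))


def _write_model(path: Path, header: dict, rows: list[tuple[str, str, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
        fh.write("domain_a\tdomain_b\tvalue\n")
        for a, b, v in rows:
            fh.write(f"{a}\t{b}\t{v:.17g}\n")


def _read_model(path: Path) -> tuple[dict, dict[tuple[str, str], float]]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[1:])
        df = pd.read_csv(fh, sep="\t")
    values = {
        (str(r.domain_a), str(r.domain_b)): float(r.value)
        for r in df.itertuples(index=False)
    }
    return header, values


def write_crf_model(params: CRFParams, path: str | Path) -> None:
    header = {
        "model": "crf",
        "variant": params.features.variant,
        "c": params.features.c,
        "log_likelihood": params.log_likelihood,
        "n_iterations": params.n_iterations,
        "converged": params.converged,
        "mi_scores": {f"{a}|{b}": v for (a, b), v in sorted(params.mi_scores.items())},
    }
    rows = [(a, b, v) for (a, b), v in sorted(params.weights.items())]
    _write_model(Path(path), header, rows)


def read_crf_model(path: str | Path) -> CRFParams:
    header, values = _read_model(Path(path))
    if header.get("model") != "crf":
        raise ValueError(f"{path}: not a CRF model file")
    mi_scores = {
        tuple(k.split("|")): v for k, v in header.get("mi_scores", {}).items()
    }
    return CRFParams(
        weights=values,
        features=FeatureTable(header["variant"], header["c"]),
        log_likelihood=header.get("log_likelihood", float("nan")),
        n_iterations=header.get("n_iterations", 0),
        converged=header.get("converged", False),
        mi_scores=mi_scores,  # type: ignore[arg-type]
    )


def write_baseline_model(probs: DomainProbabilities, path: str | Path) -> None:
    header = {
        "model": "baseline",
        "method": probs.method,
        "fn": probs.fn,
        "fp": probs.fp,
        "iterations": probs.iterations,
        "tolerance": probs.tolerance,
    }
    rows = [(a, b, v) for (a, b), v in sorted(probs.lambdas.items())]
    _write_model(Path(path), header, rows)


def read_baseline_model(path: str | Path) -> DomainProbabilities:
    header, values = _read_model(Path(path))
    if header.get("model") != "baseline":
        raise ValueError(f"{path}: not a baseline model file")
    return DomainProbabilities(
        lambdas=values,
        method=header["method"],
        fn=header["fn"],
        fp=header["fp"],
        iterations=header["iterations"],
        tolerance=header["tolerance"],
    )


def write_compositions(proteins: dict[str, Protein], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(proteins):
            fh.write(f"{pid}\t{','.join(proteins[pid].domains)}\n")


def write_interactions(labels: list[ProteinPairLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lab in labels:
            fh.write(f"{lab.pair[0]}\t{lab.pair[1]}\t{lab.label}\n")


def write_scores(
    pairs: list[tuple[str, str]], scores: list[float], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tscore\n")
        for (a, b), s in zip(pairs, scores):
            fh.write(f"{a}\t{b}\t{s:.10g}\n")
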