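"""Readers and writers for the package's tab-delimited and JSON artifacts.

All matrices travel as plain TSV (first column gene identifier, header row
of sample identifiers, log2 values), optionally gzip-compressed by file
extension.  Parse failures carry file and line context.
"""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path

import pandas as pd

from .booleannet import ImplicationRecord, Relation
from .errors import ParseError
from .network import CBIN, ClusterEdge
from .scoring import SignatureSpec

logger = logging.getLogger(__name__)


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_expression(path) -> pd.DataFrame:
    """Read a gene x sample TSV expression matrix.

    Rejects duplicate gene or sample identifiers, ragged rows, and
    non-numeric cells, naming the offending line.
    """
    path = Path(path)
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(path, 1, "empty file or blank header")
        cols = header.rstrip("\n").split("\t")
        samples = cols[1:]
        if not samples:
            raise ParseError(path, 1, "header has no sample columns")
        if len(set(samples)) != len(samples):
            dup = sorted({s for s in samples if samples.count(s) > 1})
            raise ParseError(path, 1, f"duplicate sample identifiers: {dup}")
        genes, rows = [], []
        seen = set()
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(samples) + 1:
                raise ParseError(
                    path, line_no,
                    f"expected {len(samples) + 1} fields, found {len(fields)}",
                )
            gene = fields[0]
            if gene in seen:
                raise ParseError(path, line_no, f"duplicate gene identifier {gene!r}")
            seen.add(gene)
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ParseError(path, line_no, f"non-numeric cell: {exc}") from exc
            genes.append(gene)
    if not genes:
        raise ParseError(path, 2, "no data rows")
    df = pd.DataFrame(rows, index=genes, columns=samples)
    if df.isna().any().any() or not df.apply(lambda r: r.map(lambda x: x == x)).all().all():
        raise ParseError(path, 0, "matrix contains missing values")
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        matrix.to_csv(fh, sep="\t", index_label="gene_id")


def read_thresholds(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df["degenerate"] = df["degenerate"].astype(bool)
    return df


def write_thresholds(thresholds: pd.DataFrame, path) -> None:
    thresholds.to_csv(path, sep="\t", index_label="gene_id")


_IMPLICATION_COLS = [
    "gene_a", "gene_b", "relation", "a00", "a01", "a10", "a11", "s", "p",
]

#: the quadrants whose sparsity defines each relation type
_DEFINING_QUADRANTS = {
    Relation.LOW_HIGH: [(0, 0)],
    Relation.LOW_LOW: [(0, 1)],
    Relation.HIGH_HIGH: [(1, 0)],
    Relation.HIGH_LOW: [(1, 1)],
    Relation.EQUIVALENT: [(0, 1), (1, 0)],
    Relation.OPPOSITE: [(0, 0), (1, 1)],
}


def write_implications(records, path) -> None:
    """Write an edge list: genes, relation, quadrant counts, defining S/p."""
    rows = []
    for r in records:
        quads = _DEFINING_QUADRANTS[r.relation]
        s = ";".join(f"{r.stats.s[q]:.4f}" for q in quads)
        p = ";".join(f"{r.stats.p[q]:.4f}" for q in quads)
        rows.append(
            (r.gene_a, r.gene_b, r.relation.value, *r.counts.as_tuple(), s, p)
        )
    pd.DataFrame(rows, columns=_IMPLICATION_COLS).to_csv(path, sep="\t", index=False)


def read_implication_edges(path) -> list:
    """Read (gene_a, gene_b, Relation) triples from an implication TSV."""
    df = pd.read_csv(path, sep="\t")
    return [
        (row.gene_a, row.gene_b, Relation(row.relation)) for row in df.itertuples()
    ]


def write_cbin(cbin: CBIN, path) -> None:
    payload = {
        "clusters": {cid: list(members) for cid, members in cbin.clusters.items()},
        "representatives": dict(cbin.representatives),
        "edges": [
            {
                "cluster_a": e.cluster_a,
                "cluster_b": e.cluster_b,
                "relation": e.relation.value,
                "support": e.support,
                "n_sampled": e.n_sampled,
            }
            for e in cbin.edges
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_cbin(path) -> CBIN:
    payload = json.loads(Path(path).read_text())
    return CBIN(
        clusters={cid: sorted(m) for cid, m in payload["clusters"].items()},
        representatives=payload["representatives"],
        edges=tuple(
            ClusterEdge(
                e["cluster_a"], e["cluster_b"], Relation(e["relation"]),
                e["support"], e["n_sampled"],
            )
            for e in payload["edges"]
        ),
    )


def read_gene_sets(path) -> dict:
    """Read GMT gene sets: name, description, members, tab-separated."""
    path = Path(path)
    sets = {}
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                logger.warning("%s:%d: blank line skipped", path, line_no)
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(path, line_no, "GMT line needs name, description, >=1 gene")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(path, line_no, f"empty gene set {name!r}")
            sets[name] = genes
    return sets


def write_gene_sets(sets: dict, path, description: str = "") -> None:
    with _open_text(path, "wt") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return df[["time", "event"]]


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index_label="sample_id")


def read_scores(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return df["score"]


def write_scores(scores: pd.Series, path) -> None:
    scores.rename("score").to_csv(path, sep="\t", index_label="sample_id")


def read_signature(path) -> SignatureSpec:
    """Read a signature spec from JSON: {"clusters": [[...]], "weights": [...]}"""
    payload = json.loads(Path(path).read_text())
    return SignatureSpec.make(payload["clusters"], payload["weights"])


def write_signature(spec: SignatureSpec, path) -> None:
    payload = {
        "clusters": [list(c) for c in spec.clusters],
        "weights": list(spec.weights),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[["gene", "log2fc", "padj"]]
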