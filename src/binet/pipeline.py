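"""End-to-end pipeline: threshold, discretize, filter, discover, cluster,
link, chart, and score — with a JSON run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import json
from importlib.metadata import version
from pathlib import Path

from . import booleannet, io, network, scoring, stepminer
from .errors import PipelineError


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Parameters of a full network run.

    All randomness (the 6-node cluster sampling) flows from ``seed``; with
    the same inputs and config, every artifact is reproduced bit-identically.
    """

    matrix_path: str
    out_dir: str
    preset: str = "network"
    margin: float = stepminer.DEFAULT_MARGIN
    min_state_frac: float = 0.05
    min_percentile_range: float = 1.0
    jaccard_min: float = 0.7
    sample_size: int = 6
    majority_frac: float = 2.0 / 3.0
    seed: int = 0
    seed_cluster_gene: str | None = None  # chart paths from this gene's cluster
    max_path_len: int = 4


def _stage(name):
    def wrap(fn):
        def inner(*args, **kw):
            try:
                return fn(*args, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline, persisting intermediate artifacts.

    Returns a dict of artifact paths.  Any stage failure aborts with the
    stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    matrix = _stage("read-matrix")(io.read_expression)(config.matrix_path)

    thresholds = _stage("threshold")(stepminer.threshold_matrix)(
        matrix, margin=config.margin
    )
    artifacts["thresholds"] = out / "thresholds.tsv"
    io.write_thresholds(thresholds, artifacts["thresholds"])

    usable = thresholds.index[~thresholds["degenerate"]]
    sub = matrix.loc[usable]
    states = _stage("discretize")(stepminer.discretize)(sub, thresholds)
    kept = _stage("filter")(stepminer.filter_genes)(
        sub, states,
        min_state_frac=config.min_state_frac,
        min_percentile_range=config.min_percentile_range,
    )

    params = booleannet.PRESETS[config.preset]
    records = _stage("implications")(booleannet.discover_implications)(
        states.loc[kept], params
    )
    artifacts["implications"] = out / "implications.tsv"
    io.write_implications(records, artifacts["implications"])

    bin_ = _stage("build-bin")(network.BIN.from_records)(records, genes=kept)
    cparams = network.ClusterParams(
        jaccard_min=config.jaccard_min,
        sample_size=config.sample_size,
        majority_frac=config.majority_frac,
        rng_seed=config.seed,
    )
    clusters = _stage("cluster")(network.cluster_equivalences)(bin_, cparams)
    cbin = _stage("link")(network.link_clusters)(clusters, bin_, cparams)
    artifacts["cbin"] = out / "cbin.json"
    io.write_cbin(cbin, artifacts["cbin"])

    if config.seed_cluster_gene is not None:
        seed_cluster = cbin.cluster_of(config.seed_cluster_gene)
        paths = _stage("paths")(network.chart_paths)(
            cbin, seed_cluster, max_len=config.max_path_len
        )
        artifacts["paths"] = out / "paths.json"
        Path(artifacts["paths"]).write_text(
            json.dumps(
                [
                    {
                        "clusters": list(p.clusters),
                        "edge_types": [t.value for t in p.edge_types],
                    }
                    for p in paths
                ],
                indent=1,
            )
            + "\n"
        )
        # score along the longest path (+1 weights) as the default ordering
        if paths:
            longest = max(paths, key=lambda p: (len(p.clusters), p.clusters))
            spec = scoring.SignatureSpec.make(
                [cbin.members(c) for c in longest.clusters],
                [1] * len(longest.clusters),
            )
            scores = _stage("score")(scoring.composite_score)(
                matrix, thresholds, spec
            )
            artifacts["scores"] = out / "scores.tsv"
            io.write_scores(scores, artifacts["scores"])

    manifest = {
        "config": {
            k: (v if not isinstance(v, Path) else str(v))
            for k, v in dataclasses.asdict(config).items()
        },
        "package_version": version("binet"),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "n_genes_input": int(matrix.shape[0]),
        "n_genes_kept": len(kept),
        "n_records": len(records),
        "n_clusters": len(cbin.clusters),
        "n_cluster_edges": len(cbin.edges),
    }
    artifacts["manifest"] = out / "manifest.json"
    Path(artifacts["manifest"]).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return {k: str(v) for k, v in artifacts.items()}
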