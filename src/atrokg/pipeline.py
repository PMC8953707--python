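"""End-to-end orchestration: expression matrices -> gene pairs -> knowledge
graphs -> features -> link predictors -> ranked candidate links.

A single structured YAML config drives all four stages; every artifact is a
TSV or JSON file stamped with the config hash and seed, and a fixed
config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import grn, synthetic
from .kg import KnowledgeGraph, graph_summary
from .linkpred import (
    CVConfig,
    LabeledEdgeSet,
    auroc,
    cross_validate,
    fit_scorer,
    make_labeled_set,
    roc_points,
    sample_negatives,
)

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ["rf", "gb", "mlp", "gcn", "preferential_attachment"]


@dataclass
class PipelineConfig:
    """Structured configuration for a full pipeline run."""

    seed: int = 0
    output_dir: str = "atrokg_run"
    expression: dict | None = None  # {"synthetic": {...}} or {"paths": [...]}
    p_threshold: float = grn.DEFAULT_P_THRESHOLD
    alpha: float = 0.01
    gdkg: dict = field(default_factory=dict)  # {"synthetic": {...}} or {"edge_table": path}
    ddkg: dict = field(default_factory=dict)
    gdkg_train_fraction: float = 0.8
    ddkg_train_fraction: float = 0.6
    gdkg_link_threshold: float = 0.8
    ddkg_link_threshold: float = 0.7
    methods: list[str] = field(default_factory=lambda: list(DEFAULT_METHODS))
    rank_method: str = "gcn"
    folds: int = 10
    negative_ratio: float = 1.0
    top_diseases: int = 100
    drugs_per_disease: int = 10
    features: dict = field(default_factory=dict)  # CVConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def cv_config(self) -> CVConfig:
        return CVConfig(negative_ratio=self.negative_ratio, **self.features)

    def digest(self) -> str:
        """Hash of the scientific configuration (the output location is not
        part of what defines a run)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage-4 ranking operations
# ---------------------------------------------------------------------------

def rank_new_links(
    scores: pd.DataFrame, kg: KnowledgeGraph, threshold: float
) -> pd.DataFrame:
    """Candidate novel links sorted by predicted probability.

    ``scores`` has columns (source, target, probability, method).  Existing
    edges of ``kg`` are excluded, rows below ``threshold`` dropped, and the
    result is sorted by descending probability with node-id lexicographic
    tie-breaks, so identical inputs give identical tables.
    """
    mask = [not kg.has_edge(u, v) for u, v in zip(scores["source"], scores["target"])]
    out = scores.loc[mask]
    out = out[out["probability"] >= threshold]
    out = out.sort_values(
        ["probability", "source", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return out


def select_top_diseases(
    predictions: pd.DataFrame, k: int = 100, diseases: set[str] | None = None
) -> list[str]:
    """The k diseases with the best predicted link probability.

    ``predictions`` rows must carry a disease in either endpoint column and a
    ``probability``; ``diseases`` restricts which node ids count as diseases.
    Ties break lexicographically; if fewer than k diseases appear, all are
    returned with a warning.
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to select diseases from")
    melted = predictions.melt(
        id_vars=["probability"], value_vars=["source", "target"], value_name="node"
    )
    if diseases is not None:
        melted = melted[melted["node"].isin(diseases)]
    best = (
        melted.groupby("node")["probability"].max().rename("best_probability").reset_index()
    )
    best = best.sort_values(["best_probability", "node"], ascending=[False, True])
    nodes = best["node"].tolist()
    if len(nodes) < k:
        logger.warning("only %d candidate diseases available (requested %d)", len(nodes), k)
    return nodes[:k]


def select_top_drugs_per_disease(drug_table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Up to k drugs per disease by usage ranking, as DDKG input edges.

    ``drug_table`` columns: disease, drug, weight (higher = more commonly
    used).  Ties break on drug id for determinism.
    """
    out = (
        drug_table.sort_values(["disease", "weight", "drug"], ascending=[True, False, True])
        .groupby("disease", group_keys=False)
        .head(k)
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _obtain_graph(
    block: dict, kind: str, seed: int
) -> tuple[KnowledgeGraph, LabeledEdgeSet | None]:
    if "edge_table" in block:
        return KnowledgeGraph.read_edgelist_tsv(block["edge_table"]), None
    params = dict(block.get("synthetic", {}))
    params.setdefault("seed", seed)
    spec = synthetic.SyntheticGraphSpec(**params)
    if kind == "gdkg":
        return synthetic.simulate_gdkg(spec)
    return synthetic.simulate_ddkg(spec)


def _stage1(config: PipelineConfig, outdir: Path) -> None:
    block = config.expression
    if not block:
        return
    matrices: list[pd.DataFrame] = []
    if "paths" in block:
        matrices = [grn.read_expression_tsv(p) for p in block["paths"]]
    else:
        params = dict(block.get("synthetic", {}))
        n_samples = params.pop("n_samples", 8)
        n_datasets = params.pop("n_datasets", 1)
        net = synthetic.random_regulatory_network(
            **{k: v for k, v in params.items() if k != "seed"},
            seed=params.get("seed", config.seed),
        )
        matrices = [
            synthetic.simulate_expression(net, n_samples, seed=config.seed + d)
            for d in range(n_datasets)
        ]
    # per-dataset extraction, then union across datasets
    all_pairs = []
    for i, expr in enumerate(matrices):
        pearson = grn.pearson_pairs(expr, p_threshold=config.p_threshold)
        blankets = grn.markov_blankets(expr, alpha=config.alpha)
        all_pairs.append(grn.combine_pair_lists(pearson, blankets))
        logger.info("stage 1 dataset %d: %d pairs", i, len(all_pairs[-1]))
    merged = (
        pd.concat(all_pairs, ignore_index=True)
        .drop_duplicates(subset=["gene_a", "gene_b"])
        .sort_values(["gene_a", "gene_b"], ignore_index=True)
        if all_pairs
        else pd.DataFrame(columns=grn.PAIR_COLUMNS)
    )
    grn.write_pairs_tsv(merged, outdir / "gene_pairs.tsv")


def _rank_graph(
    kg: KnowledgeGraph,
    heldout: LabeledEdgeSet | None,
    config: PipelineConfig,
    method: str,
    threshold: float,
    seed: int,
) -> pd.DataFrame:
    """Fit the ranking scorer on the full retained graph and score non-edges."""
    edges = kg.edges()
    negs = sample_negatives(kg, int(round(config.negative_ratio * len(edges))), seed=seed + 17)
    train = LabeledEdgeSet(
        edges + negs,
        np.r_[np.ones(len(edges), int), np.zeros(len(negs), int)],
        tag="rank-train",
        seed=seed,
    )
    scorer = fit_scorer(method, kg, train, config.cv_config(), seed=seed)
    type_pair = sorted({tuple(sorted((kg.node_type(u), kg.node_type(v)))) for u, v in edges})[0]
    left = kg.nodes_of_type(type_pair[0])
    right = kg.nodes_of_type(type_pair[1])
    candidates = [
        tuple(sorted((u, v))) for u in left for v in right if not kg.has_edge(u, v)
    ]
    candidates = sorted(candidates)
    probs = scorer.score_pairs(candidates)
    table = pd.DataFrame(
        {
            "source": [c[0] for c in candidates],
            "target": [c[1] for c in candidates],
            "probability": np.round(probs, 6),
            "method": method,
        }
    )
    return rank_new_links(table, kg, threshold)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and write tables, reports and logs to the run dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config_hash": config.digest(), "seed": config.seed}

    try:
        _stage1(config, outdir)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 1 (gene-pair inference) failed: {exc}") from exc

    for kind, train_fraction, threshold in (
        ("gdkg", config.gdkg_train_fraction, config.gdkg_link_threshold),
        ("ddkg", config.ddkg_train_fraction, config.ddkg_link_threshold),
    ):
        block = getattr(config, kind)
        if not block:
            continue
        try:
            kg, heldout = _obtain_graph(block, kind, config.seed)
            kg.write_edgelist_tsv(outdir / f"{kind}_edges.tsv")
            kg.write_graphml(outdir / f"{kind}.graphml")
            summary = graph_summary(kg)
            summary.to_json(outdir / f"{kind}_measures.json")
            summary.to_tsv(outdir / f"{kind}_node_measures.tsv")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 2 ({kind} construction) failed: {exc}") from exc

        try:
            cv_rows = []
            for method in config.methods:
                rep = cross_validate(
                    method, kg, k=config.folds, seed=config.seed, config=config.cv_config()
                )
                cv_rows.append(rep.to_row())
                logger.info("%s %s CV AUROC %.4f", kind, method, rep.auroc)
            cv_table = pd.DataFrame(cv_rows).round(6)
            cv_table.to_csv(outdir / f"{kind}_cv_report.tsv", sep="\t", index=False)
            report[f"{kind}_cv_auroc"] = {
                row["method"]: row["AUROC"] for row in cv_table.to_dict("records")
            }
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 3 ({kind} cross-validation) failed: {exc}") from exc

        try:
            # single train/test split at the configured fraction: test AUROC
            # and ROC curve points for the ranking method
            tr, te = make_labeled_set(
                kg,
                train_fraction=train_fraction,
                negative_ratio=config.negative_ratio,
                seed=config.seed,
            )
            train_graph = kg.subgraph_without_edges(te.positives)
            scorer = fit_scorer(
                config.rank_method, train_graph, tr, config.cv_config(), seed=config.seed
            )
            te_scores = scorer.score_pairs(te.pairs)
            roc_points(te_scores, te.labels).round(6).to_csv(
                outdir / f"{kind}_roc_points.tsv", sep="\t", index=False
            )
            report[f"{kind}_test_auroc_{config.rank_method}"] = round(
                auroc(te_scores, te.labels), 6
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 3 ({kind} holdout evaluation) failed: {exc}") from exc

        try:
            ranked = _rank_graph(
                kg, heldout, config, config.rank_method, threshold, config.seed
            )
            ranked.to_csv(outdir / f"{kind}_predicted_links.tsv", sep="\t", index=False)
            report[f"{kind}_predicted_links"] = int(len(ranked))
            if kind == "gdkg" and len(ranked):
                dis = [
                    n
                    for n in pd.unique(ranked[["source", "target"]].values.ravel())
                    if kg.node_type(n) == "disease"
                ]
                top = (
                    select_top_diseases(ranked, k=config.top_diseases, diseases=set(dis))
                    if dis
                    else []
                )
                (outdir / "top_diseases.txt").write_text("\n".join(top) + "\n")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 4 ({kind} ranking) failed: {exc}") from exc

    (outdir / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return outdir
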