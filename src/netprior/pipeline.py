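"""End-to-end run orchestration: build -> weight -> prioritize
(-> loocv -> enrich), with a provenance record.

Outputs are deterministic functions of the inputs and the configuration;
every output names the hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import io
from .enrichment import hypergeometric_enrichment
from .evaluation import loocv
from .network import build_disease_subnetwork, network_summary
from .propagation import (
    PropagationConfig,
    build_transition_matrix,
    initial_scores,
    propagate,
    rank_candidates,
)
from .weights import WeightingConfig, assign_edge_weights, assign_node_weights

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    edges_path: str
    seeds_path: str
    annotations_path: str
    out_dir: str
    dialect: str = "tsv"
    min_score: Optional[float] = None
    obo_path: Optional[str] = None
    weighting: WeightingConfig = field(default_factory=WeightingConfig)
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    run_loocv: bool = True
    run_enrichment: bool = True
    enrich_top: int = 100
    enrich_alpha: float = 0.05
    include_seeds_in_ranking: bool = False

    def config_hash(self) -> str:
        """Hash of the method parameters (paths excluded, so the same
        analysis on relocated inputs keeps the same hash)."""
        params = asdict(self)
        for key in ("edges_path", "seeds_path", "annotations_path",
                    "obo_path", "out_dir"):
            params.pop(key, None)
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full prioritization pipeline and write all outputs.

    Writes ``ranking.tsv`` (and optionally ``loocv.json`` and
    ``enrich.tsv``) plus ``provenance.json`` under ``cfg.out_dir``; the
    returned report mirrors the provenance record.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()

    edges = io.read_edge_list(cfg.edges_path, dialect=cfg.dialect, min_score=cfg.min_score)
    seeds = io.read_seed_list(cfg.seeds_path)
    ann = io.read_annotations(cfg.annotations_path, obo_path=cfg.obo_path)

    net = build_disease_subnetwork(edges, seeds)
    net = assign_edge_weights(net, ann, cfg.weighting)
    net = assign_node_weights(net, ann, seeds, cfg.weighting)
    summary = network_summary(net)

    Q = build_transition_matrix(net)
    d0 = initial_scores(net)
    scores, iterations = propagate(Q, d0, cfg.propagation)
    ranking = rank_candidates(scores, net, include_seeds=cfg.include_seeds_in_ranking)

    ranking_path = out_dir / "ranking.tsv"
    io.write_ranking(ranking, ranking_path, config_hash=chash)

    report: dict = {
        "config": asdict(cfg),
        "config_hash": chash,
        "inputs": {
            "edges": _sha256(cfg.edges_path),
            "seeds": _sha256(cfg.seeds_path),
            "annotations": _sha256(cfg.annotations_path),
        },
        "network": summary._asdict(),
        "missing_seeds": list(net.missing_seeds),
        "self_loops_skipped": edges.n_self_loops,
        "propagation_iterations": iterations,
        "outputs": {"ranking": str(ranking_path)},
    }

    if cfg.run_loocv:
        res = loocv(edges, ann, seeds, cfg.propagation, cfg.weighting)
        loocv_path = out_dir / "loocv.json"
        loocv_path.write_text(json.dumps(
            {
                "config_hash": chash,
                "auc": res.auc,
                "n_folds": res.n_folds,
                "excluded": res.excluded,
                "folds": [f._asdict() for f in res.folds],
                "roc_points": res.roc_points,
            },
            indent=1,
        ) + "\n")
        report["loocv_auc"] = res.auc
        report["outputs"]["loocv"] = str(loocv_path)

    if cfg.run_enrichment:
        top = [r.gene for r in ranking[: cfg.enrich_top]]
        background = set(net.nodes)
        term_to_genes: dict[str, set[str]] = {}
        for g in background:
            for t in (ann.terms(g) if isinstance(ann, io.AnnotationMap) else ann.get(g, set())):
                term_to_genes.setdefault(t, set()).add(g)
        results = hypergeometric_enrichment(
            top, term_to_genes, background, seeds=seeds
        )
        enrich_path = out_dir / "enrich.tsv"
        with enrich_path.open("w") as fh:
            fh.write(f"# config_hash={chash}\n")
            fh.write("term\tk\tn\tK\tN\tp_value\tadjusted_p\tdisease_related\n")
            for r in results:
                fh.write(
                    f"{r.term}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                    f"{r.p_value:.6g}\t{r.adjusted_p:.6g}\t{int(r.disease_related)}\n"
                )
        n_sig = sum(r.adjusted_p < cfg.enrich_alpha for r in results)
        report["enrichment_significant_terms"] = n_sig
        report["outputs"]["enrichment"] = str(enrich_path)

    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(report, indent=1, default=str) + "\n")
    report["outputs"]["provenance"] = str(prov_path)
    return report
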