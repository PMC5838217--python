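"""End-to-end pipeline orchestration with a single config and manifest.

Stages: read and pre-filter the expression matrix, discretize, detect
candidate interactions, permutation-validate them, assemble the network
against the backbone. Every intermediate artifact is written so each stage
is independently re-runnable, and a JSON manifest (config, seed, input
checksums, per-stage counts) makes a run byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import expression_io as eio
from .discretization import DiscretizationParams, discretize, write_discretized
from .interaction_detection import detect_interactions
from .network_assembly import GGINetwork, assemble, write_assembly_log
from .permutation_validation import null_census, validate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters and file paths.

    Defaults follow the reference protocol: gamma 0.45, theta 0.1, omega 1,
    1000 permutation replicates, strict alpha 0.01. ``seed`` is mandatory —
    every stochastic stage (the permutation null) derives its streams from
    it.
    """

    expression_path: str
    backbone_path: str
    output_dir: str
    seed: int
    gamma: float = 0.45
    sd_mode: str = "sample"
    theta: float = 0.1
    omega: int = 1
    replicates: int = 1000
    alpha: float = 0.01
    strict_alpha: bool = True
    pair_source: str = "all_pairs"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.pair_source not in ("all_pairs", "backbone"):
            raise ValueError("pair_source must be 'all_pairs' or 'backbone'")
        if self.seed is None:
            raise ValueError("seed is mandatory")


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a flat ``key = value`` config file; keyword overrides win."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
        k, v = (s.strip() for s in line.split("=", 1))
        raw[k] = v
    kwargs: dict = {}
    casts = {"seed": int, "omega": int, "replicates": int,
             "gamma": float, "theta": float, "alpha": float,
             "strict_alpha": lambda v: _BOOL[v.lower()]}
    for k, v in raw.items():
        kwargs[k] = casts.get(k, str)(v)
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    network: GGINetwork
    manifest: dict
    output_dir: Path


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage, write all artifacts, and return the final network
    plus its manifest. Any stage failure is re-raised with the stage name."""
    expr_path = Path(cfg.expression_path)
    kp_path = Path(cfg.backbone_path)
    for p, what in ((expr_path, "expression matrix"), (kp_path, "backbone")):
        if not p.exists():
            raise FileNotFoundError(f"config error: {what} file not found: {p}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config": asdict(cfg),
        "inputs": {"expression_sha256": eio.sha256_of(expr_path),
                   "backbone_sha256": eio.sha256_of(kp_path)},
        "counts": {},
        "complete": False,
    }
    counts = manifest["counts"]

    stage = "read"
    try:
        m = eio.read_expression_matrix(expr_path)
        kp = eio.read_backbone(kp_path)
        counts["genes_input"] = m.n_genes
        counts["samples"] = m.n_samples
        counts["backbone_nodes"] = kp.number_of_nodes()
        counts["backbone_edges"] = kp.number_of_edges()

        stage = "filter"
        m = eio.filter_unexpressed(m)
        counts["genes_expressed"] = m.n_genes

        stage = "discretize"
        d = discretize(m, DiscretizationParams(gamma=cfg.gamma, sd_mode=cfg.sd_mode))
        write_discretized(d, out / "disc.tsv")
        logger.info("discretized %d genes x %d samples (gamma=%g)",
                    d.n_genes, d.n_samples, cfg.gamma)

        stage = "detect"
        source = kp if cfg.pair_source == "backbone" else "all_pairs"
        candidates = detect_interactions(d, theta=cfg.theta, pair_source=source)
        eio.write_candidates(candidates, out / "candidates.tsv")
        counts["candidates"] = len(candidates)
        counts["candidates_con"] = sum(c.reg_type == "con" for c in candidates)
        counts["candidates_re"] = sum(c.reg_type == "re" for c in candidates)
        logger.info("detected %d candidate interactions at theta=%g",
                    len(candidates), cfg.theta)

        stage = "validate"
        census = null_census(d, theta=cfg.theta, replicates=cfg.replicates,
                             pair_source=source, seed=cfg.seed)
        validated = validate(candidates, census, alpha=cfg.alpha,
                             strict=cfg.strict_alpha)
        eio.write_candidates(validated, out / "validated.tsv")
        counts["validated"] = len(validated)
        logger.info("%d interactions survive %d-replicate permutation "
                    "validation at alpha=%g", len(validated), cfg.replicates,
                    cfg.alpha)

        stage = "assemble"
        net = assemble(validated, kp, omega=cfg.omega)
        counts["raw_edges"] = sum(e.stage == "raw" for e in net.provenance)
        counts["expanded_edges"] = sum(e.stage == "expanded" for e in net.provenance)
        counts["revised_edges"] = sum(e.stage == "revised" for e in net.provenance)
        counts["final_edges"] = net.n_edges
        counts["final_nodes"] = net.n_nodes
        counts["discarded_leftovers"] = len(net.discarded)
        logger.info("assembled network: %d nodes, %d edges (%d raw, %d "
                    "expanded, %d revised)", net.n_nodes, net.n_edges,
                    counts["raw_edges"], counts["expanded_edges"],
                    counts["revised_edges"])

        stage = "write"
        eio.write_network(net, out / "network.graphml", format="graphml")
        eio.write_network(net, out / "network.sif", format="sif")
        write_assembly_log(net, out / "assembly_log.tsv")
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest["complete"] = True
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(network=net, manifest=manifest, output_dir=out)
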