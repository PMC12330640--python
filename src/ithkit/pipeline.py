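"""End-to-end orchestration of the discovery / scoring / association stages,
with a run manifest recording config, seeds and output digests."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import AnnotationResult, annotate_programs
from .consensus import FilterConfig, ITHProgram, cluster_modules, filter_modules
from .nmf import GeneModule, NMFConfig, modules_for_sample
from .preprocessing import (
    ExpressionMatrix,
    ValidationError,
    center_and_clip,
    filter_detected_genes,
    normalize_log,
)
from .scoring import ScoringConfig, relative_score, score_program

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    stage: str
    config: dict
    seed: int
    package_version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    warnings: list[str] = field(default_factory=list)

    def record_output(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


@dataclass
class DiscoveryResult:
    programs: list[ITHProgram]
    retained_modules: list[GeneModule]
    all_modules: list[GeneModule]
    normalized: ExpressionMatrix


def discover_programs(
    counts: ExpressionMatrix,
    nmf_config: NMFConfig | None = None,
    filter_config: FilterConfig | None = None,
    min_detect_frac: float = 0.02,
    distance_cut: float = 0.9,
    n_clusters: int | None = None,
    min_cluster_size: int = 2,
    signature_min_frac: float = 0.25,
) -> DiscoveryResult:
    """Counts -> normalise -> per-sample center/clip -> NMF -> filter -> cluster.

    Runs the full module-discovery chain and returns the consensus
    programs with signatures, alongside the retained and raw modules and
    the normalised matrix reused by downstream scoring.
    """
    nmf_config = nmf_config or NMFConfig()
    filter_config = filter_config or FilterConfig()

    normalized = normalize_log(counts)
    all_modules: list[GeneModule] = []
    for sid in normalized.samples:
        sub = normalized.subset_sample(sid)
        keep = filter_detected_genes(sub, min_detect_frac)
        sub = ExpressionMatrix(
            sub.values[keep],
            [g for g, k in zip(sub.gene_ids, keep) if k],
            sub.cell_ids,
            sub.sample_of_cell,
        )
        centered = center_and_clip(sub, per_sample=True)[0]
        mods = modules_for_sample(centered, nmf_config)
        logger.info("sample %s: %d modules at ranks %s", sid, len(mods), nmf_config.ranks)
        all_modules.extend(mods)

    retained = filter_modules(all_modules, filter_config)
    logger.info("retained %d/%d modules after filtering", len(retained), len(all_modules))
    programs = cluster_modules(
        retained,
        distance_cut=distance_cut,
        n_clusters=n_clusters,
        min_cluster_size=min_cluster_size,
        signature_min_frac=signature_min_frac,
    )
    logger.info("discovered %d consensus programs", len(programs))
    return DiscoveryResult(programs, retained, all_modules, normalized)


def score_and_annotate(
    normalized: ExpressionMatrix,
    programs: list[ITHProgram],
    mps: dict[str, list[str]] | None = None,
    scoring_cfg: ScoringConfig | None = None,
    relative_pair: tuple[str, str] | None = None,
    n_perm: int = 100,
    confidence: float = 0.999,
    seed: int = 0,
    perm_mode: str = "gene_sets",
) -> tuple[pd.DataFrame, list[AnnotationResult] | None, pd.Series | None]:
    """Score all programs per cell; optionally annotate and form a relative score.

    Returns (scores long-format DataFrame, annotation results or None,
    relative score Series or None).  The relative pair (e.g. the hEMT and
    EpiSen program ids) is skipped with a warning when absent.
    """
    scoring_cfg = scoring_cfg or ScoringConfig()
    frames = {}
    for prog in programs:
        present = [g for g in prog.signature_genes if g in set(normalized.gene_ids)]
        if len(present) < 2:
            logger.warning("program %s: <2 signature genes in matrix, skipped", prog.program_id)
            continue
        frames[prog.program_id] = score_program(
            normalized, present, scoring_cfg, program_id=prog.program_id
        )
    if not frames:
        raise ValidationError("no scorable programs")
    scores = pd.concat(frames.values(), ignore_index=True)

    annotations = None
    if mps:
        annotations = annotate_programs(
            programs, mps, normalized,
            n_perm=n_perm, confidence=confidence, seed=seed, scoring_cfg=scoring_cfg,
            perm_mode=perm_mode,
        )

    rel = None
    if relative_pair is not None:
        a, b = relative_pair
        if a in frames and b in frames:
            rel = relative_score(frames[a], frames[b])
            rel.name = f"{a}_minus_{b}"
        else:
            logger.warning("relative-score pair (%s, %s) not found; skipped", a, b)
    return scores, annotations, rel
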