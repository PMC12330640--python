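"""Per-cell program scores calibrated against expression-matched background gene sets.

For a program signature, N background gene sets of the same size are
drawn with per-gene expression matching: genes are binned by mean
expression and each background draws a random gene from the bin of the
corresponding signature gene.  A cell's empirical p-value is the
(add-one corrected) proportion of background sets whose mean centered
expression is at least the signature's; the score is -log10(p) min-max
rescaled to [0, 1] across the cells of that program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import ExpressionMatrix, ValidationError, center_genes

logger = logging.getLogger(__name__)


@dataclass
class ScoringConfig:
    n_background_sets: int = 1000
    n_bins: int = 30
    seed: int = 0
    rescale: str = "minmax"  # or "pmin": divide by the attainable max -log10(p)

    def validate(self) -> None:
        if self.n_background_sets < 10:
            raise ValidationError("n_background_sets must be >= 10")
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if self.rescale not in ("minmax", "pmin"):
            raise ValidationError(f"unknown rescale mode {self.rescale!r}")


def build_expression_bins(matrix: ExpressionMatrix, n_bins: int = 30) -> dict[str, int]:
    """Assign every gene to one of ``n_bins`` mean-expression bins.

    Genes are ranked by mean expression across all cells (ties broken by
    gene id) and split into near-equal bins whose sizes differ by at most 1.
    """
    if n_bins > matrix.n_genes:
        raise ValidationError(f"n_bins={n_bins} exceeds gene count {matrix.n_genes}")
    means = matrix.values.mean(axis=1)
    order = sorted(range(matrix.n_genes), key=lambda i: (means[i], matrix.gene_ids[i]))
    bins: dict[str, int] = {}
    for b, chunk in enumerate(np.array_split(np.asarray(order), n_bins)):
        for i in chunk:
            bins[matrix.gene_ids[i]] = b
    return bins


def sample_background_sets(
    signature: list[str],
    bins: dict[str, int],
    cfg: ScoringConfig,
) -> list[list[str]]:
    """Draw N expression-matched background gene lists of size |signature|.

    The i-th gene of every background is a uniform draw from the bin of
    the i-th signature gene; a background may contain repeats when bins
    collide, which leaves its mean well-defined.
    """
    cfg.validate()
    missing = [g for g in signature if g not in bins]
    if missing:
        raise ValidationError(f"signature genes missing from matrix: {missing}")
    if not signature:
        raise ValidationError("empty signature")
    rng = np.random.default_rng(cfg.seed)
    by_bin: dict[int, list[str]] = {}
    for g, b in bins.items():
        by_bin.setdefault(b, []).append(g)
    for b in by_bin:
        by_bin[b].sort()
    sig_bins = [bins[g] for g in signature]
    backgrounds = []
    for _ in range(cfg.n_background_sets):
        backgrounds.append([by_bin[b][rng.integers(len(by_bin[b]))] for b in sig_bins])
    return backgrounds


def score_cells(
    matrix: ExpressionMatrix,
    signature: list[str],
    backgrounds: list[list[str]],
    cfg: ScoringConfig | None = None,
    program_id: str = "program",
) -> pd.DataFrame:
    """Score every cell for one program against its background sets.

    The matrix should hold normalised expression; centering (signed, no
    clipping) is applied internally per gene across the scored cells.
    p = (#{backgrounds with mean >= signature mean} + 1) / (N + 1), and
    the score is -log10(p) rescaled to [0, 1] across cells (min-max by
    default).  Returns a DataFrame with cell_id, sample_id, program_id,
    mean_centered_expression, p_value and score.
    """
    cfg = cfg or ScoringConfig()
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in signature if g not in gene_index]
    if missing:
        raise ValidationError(f"signature genes missing from matrix: {missing}")

    centered = center_genes(matrix.values)
    sig_rows = np.asarray([gene_index[g] for g in signature])
    m_sig = centered[sig_rows].mean(axis=0)  # per cell

    bg_means = np.empty((len(backgrounds), matrix.n_cells))
    for k, bg in enumerate(backgrounds):
        rows = np.asarray([gene_index[g] for g in bg])
        bg_means[k] = centered[rows].mean(axis=0)

    n_bg = len(backgrounds)
    count_ge = (bg_means >= m_sig[None, :]).sum(axis=0)
    p = (count_ge + 1) / (n_bg + 1)
    neglog = -np.log10(p)

    if cfg.rescale == "pmin":
        denom = -np.log10(1.0 / (n_bg + 1))
        score = neglog / denom
    else:
        span = neglog.max() - neglog.min()
        if span == 0:
            logger.warning(
                "program %s: all cells scored identically; scores set to 0", program_id
            )
            score = np.zeros_like(neglog)
        else:
            score = (neglog - neglog.min()) / span

    return pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "sample_id": matrix.sample_of_cell,
            "program_id": program_id,
            "mean_centered_expression": m_sig,
            "p_value": p,
            "score": score,
        }
    )


def score_program(
    matrix: ExpressionMatrix,
    signature: list[str],
    cfg: ScoringConfig | None = None,
    program_id: str = "program",
) -> pd.DataFrame:
    """Convenience wrapper: bins -> backgrounds -> score_cells."""
    cfg = cfg or ScoringConfig()
    bins = build_expression_bins(matrix, cfg.n_bins)
    backgrounds = sample_background_sets(signature, bins, cfg)
    return score_cells(matrix, signature, backgrounds, cfg, program_id=program_id)


def relative_score(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> pd.Series:
    """Per-cell difference of two program scores (e.g. hEMT minus EpiSen), in [-1, 1]."""
    a = scores_a.set_index("cell_id")["score"]
    b = scores_b.set_index("cell_id")["score"]
    if list(a.index) != list(b.index):
        raise ValidationError("relative_score requires the same cells in both inputs")
    return a - b


def rank_signature_score(sample_expression: pd.Series, signature: list[str]) -> float:
    """Rank-based bulk-sample signature score in [0, 1].

    Genes are ranked ascending by expression (average ranks on ties);
    gene percentile r = (rank - 0.5) / G, and the score is the mean
    percentile over signature genes — the unidirectional mean-percentile
    core of the singscore approach.  Invariant to monotone transforms.
    """
    from scipy.stats import rankdata

    if len(signature) == 0:
        raise ValidationError("empty signature")
    if len(sample_expression) < 2:
        raise ValidationError("need at least 2 genes to rank")
    missing = [g for g in signature if g not in sample_expression.index]
    if missing:
        raise ValidationError(f"signature genes missing from expression: {missing}")
    ranks = pd.Series(
        rankdata(sample_expression.to_numpy(), method="average"),
        index=sample_expression.index,
    )
    pct = (ranks - 0.5) / len(sample_expression)
    return float(pct.loc[signature].mean())
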