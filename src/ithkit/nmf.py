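"""Per-sample NMF over a range of ranks and top-gene module extraction.

Each sample's centered, non-negative relative-expression matrix X
(genes x cells) is factorised as X ~ W H at every rank K in the
configured range; each column of W defines one gene module via its
top-loading genes.  Running the default ranks 6-9 therefore yields
6+7+8+9 = 30 modules per sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .preprocessing import CenteredNonNegMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NMFConfig:
    ranks: list[int] = field(default_factory=lambda: [6, 7, 8, 9])
    top_n_genes: int = 50
    max_iter: int = 500
    tol: float = 1e-4
    seed: int = 0
    init: str = "nndsvd"  # deterministic non-negative double SVD

    def validate(self) -> None:
        if not self.ranks:
            raise ValidationError("ranks must be non-empty")
        if any(k < 1 for k in self.ranks):
            raise ValidationError("every rank must be >= 1")
        if self.top_n_genes < 5:
            raise ValidationError("top_n_genes must be >= 5")


@dataclass
class GeneModule:
    """Top-loading genes of one NMF factor from one sample at one rank."""

    sample_id: str
    rank: int
    factor_index: int
    genes: list[str]  # ordered by loading, non-increasing
    loadings: np.ndarray
    # number of other ranks of the same sample with a closely overlapping
    # module; recorded by the robustness filter so re-filtering an already
    # filtered list sees the same evidence
    rank_supporters: int | None = None

    @property
    def name(self) -> str:
        return f"{self.sample_id}|K{self.rank}|F{self.factor_index}"

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    @property
    def sort_key(self) -> tuple[str, int, int]:
        return (self.sample_id, self.rank, self.factor_index)


@dataclass
class Factor:
    """One gene-loading vector (a column of W) with provenance."""

    sample_id: str
    rank: int
    factor_index: int
    gene_ids: list[str]
    loadings: np.ndarray


def factorize_sample(matrix: CenteredNonNegMatrix, config: NMFConfig) -> list[Factor]:
    """Run NMF at every configured rank; return all gene-loading vectors.

    Genes with zero variance within the sample are dropped before the
    factorisation (they cannot contribute to any module) and their
    loadings reported as 0.  Non-convergence is logged as a warning with
    the achieved residual; the factors are still returned.
    """
    config.validate()
    X = matrix.values
    if X.min(initial=0.0) < 0:
        raise ValidationError("NMF input must be non-negative")
    if X.shape[1] < max(config.ranks):
        raise ValidationError(
            f"sample {matrix.sample_id!r} has {X.shape[1]} cells, "
            f"fewer than max rank {max(config.ranks)}"
        )

    variable = X.std(axis=1) > 0
    n_dropped = int((~variable).sum())
    if n_dropped:
        logger.info(
            "sample %s: dropped %d zero-variance genes before NMF",
            matrix.sample_id, n_dropped,
        )
    Xv = X[variable]
    kept_genes = [g for g, v in zip(matrix.gene_ids, variable) if v]

    factors: list[Factor] = []
    for k in config.ranks:
        model = NMF(
            n_components=k,
            init=config.init,
            solver="cd",
            beta_loss="frobenius",
            tol=config.tol,
            max_iter=config.max_iter,
            random_state=config.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(Xv)
        if model.n_iter_ >= config.max_iter:
            logger.warning(
                "sample %s rank %d: NMF stopped at max_iter=%d (residual %.4g)",
                matrix.sample_id, k, config.max_iter, model.reconstruction_err_,
            )
        for j in range(k):
            factors.append(
                Factor(matrix.sample_id, k, j, kept_genes, W[:, j].copy())
            )
    return factors


def extract_top_genes(factor: Factor, top_n: int) -> GeneModule:
    """Top ``top_n`` genes of a factor by loading; ties broken by gene id.

    Raises when the factor has fewer than ``top_n`` strictly positive
    loadings — such a factor does not define a module of the requested size.
    """
    pos = factor.loadings > 0
    if int(pos.sum()) < top_n:
        raise ValidationError(
            f"factor {factor.sample_id}|K{factor.rank}|F{factor.factor_index} has "
            f"{int(pos.sum())} positive loadings, fewer than top_n={top_n}"
        )
    order = sorted(
        np.flatnonzero(pos),
        key=lambda i: (-factor.loadings[i], factor.gene_ids[i]),
    )[:top_n]
    return GeneModule(
        sample_id=factor.sample_id,
        rank=factor.rank,
        factor_index=factor.factor_index,
        genes=[factor.gene_ids[i] for i in order],
        loadings=factor.loadings[list(order)].copy(),
    )


def modules_for_sample(matrix: CenteredNonNegMatrix, config: NMFConfig) -> list[GeneModule]:
    """Factorise one sample and extract a module per factor (sum of ranks modules)."""
    return [extract_top_genes(f, config.top_n_genes) for f in factorize_sample(matrix, config)]
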