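"""Annotate discovered programs against reference meta-programs with a permutation null.

Each discovered program is compared to a catalogue of reference
meta-programs (MPs) by Jaccard index on gene sets and by the Pearson
correlation of per-cell background-calibrated scores.  Significance is
assessed against a null of size-matched random gene sets drawn from the
matrix's gene universe: each null set's best Jaccard over all MPs is
recorded and the observed best Jaccard must exceed the null's
high-confidence quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .consensus import ITHProgram, jaccard
from .preprocessing import ExpressionMatrix, ValidationError
from .scoring import ScoringConfig, score_program

logger = logging.getLogger(__name__)

MIN_MP_GENES = 5  # an MP reduced below this after intersecting the matrix is unusable


@dataclass
class AnnotationResult:
    program_id: str
    best_mp_name: str
    jaccard: float
    score_correlation: float
    null_threshold_jaccard: float
    significant: bool


def mp_similarity(
    program: ITHProgram,
    mp_genes: list[str],
    matrix: ExpressionMatrix,
    cfg: ScoringConfig | None = None,
    correlation: str = "pearson",
) -> tuple[float, float]:
    """Jaccard index and single-cell score correlation for one program/MP pair.

    Jaccard is computed on the full gene sets as given.  For the score
    correlation the MP is intersected with the matrix's genes (absent
    genes dropped with a warning); an MP left with fewer than
    MIN_MP_GENES usable genes raises.
    """
    cfg = cfg or ScoringConfig()
    jac = jaccard(program.signature_genes, mp_genes)

    present = [g for g in mp_genes if g in set(matrix.gene_ids)]
    dropped = len(mp_genes) - len(present)
    if dropped:
        logger.warning("MP: %d/%d genes absent from matrix, dropped", dropped, len(mp_genes))
    if len(present) < MIN_MP_GENES:
        raise ValidationError(
            f"MP reduced to {len(present)} genes (<{MIN_MP_GENES}) after intersection"
        )
    sig_present = [g for g in program.signature_genes if g in set(matrix.gene_ids)]
    if len(sig_present) < 2:
        raise ValidationError("program signature shares <2 genes with the matrix")

    s_prog = score_program(matrix, sig_present, cfg, program_id=program.program_id)
    s_mp = score_program(matrix, present, cfg, program_id="mp")
    corr_fn = pearsonr if correlation == "pearson" else spearmanr
    r = corr_fn(s_prog["score"].to_numpy(), s_mp["score"].to_numpy())[0]
    return jac, float(r)


def _jaccard_max_over_mps(gene_set: set[str], mp_sets: list[set[str]]) -> float:
    best = 0.0
    n = len(gene_set)
    for mp in mp_sets:
        inter = len(gene_set & mp)
        j = inter / (n + len(mp) - inter)
        if j > best:
            best = j
    return best


def annotate_programs(
    programs: list[ITHProgram],
    mps: dict[str, list[str]],
    matrix: ExpressionMatrix,
    n_perm: int = 100,
    confidence: float = 0.999,
    seed: int = 0,
    scoring_cfg: ScoringConfig | None = None,
    compute_correlation: bool = True,
    perm_mode: str = "gene_sets",
) -> list[AnnotationResult]:
    """Annotate every program with its best-matching MP and a permutation call.

    The default null (``perm_mode='gene_sets'``) draws ``n_perm`` random
    gene sets of the program's size from the matrix's gene universe
    (without replacement within a set) and records each set's maximum
    Jaccard over all usable MPs; the significance threshold is the
    empirical ``confidence`` quantile (nearest-rank) of that null.
    ``perm_mode='labels'`` instead shuffles gene-program assignments:
    null sets are drawn from the pooled signature genes of all programs.
    With n_perm=100 the 99.9% quantile is the sample maximum — a warning
    recommends n_perm >= 1000.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not programs:
        raise ValidationError("no programs to annotate")
    if perm_mode not in ("gene_sets", "labels"):
        raise ValidationError(f"unknown perm_mode {perm_mode!r}")
    if np.ceil(confidence * n_perm) >= n_perm:
        logger.warning(
            "confidence %.4g with n_perm=%d makes the threshold the sample maximum; "
            "n_perm >= 1000 is recommended for a stable threshold",
            confidence, n_perm,
        )

    matrix_genes = set(matrix.gene_ids)
    usable: dict[str, set[str]] = {}
    for name, genes in mps.items():
        if len(set(genes) & matrix_genes) < MIN_MP_GENES:
            logger.warning("MP %s skipped: <%d genes in matrix", name, MIN_MP_GENES)
            continue
        usable[name] = set(genes)
    if not usable:
        raise ValidationError("no usable reference meta-programs")
    mp_names = sorted(usable)
    mp_sets = [usable[n] for n in mp_names]

    # dedicated child stream: a sibling component seeded with the same integer
    # must not replay the null draws (a null set equal to an MP would inflate
    # the threshold to that MP's self-similarity)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if perm_mode == "labels":
        universe = np.asarray(sorted({g for p in programs for g in p.signature_genes}))
    else:
        universe = np.asarray(sorted(matrix_genes))
    scoring_cfg = scoring_cfg or ScoringConfig()

    results: list[AnnotationResult] = []
    for prog in programs:
        sig = set(prog.signature_genes)
        jacs = [jaccard(sig, mp) for mp in mp_sets]
        best_j = max(jacs)
        tied = [i for i, j in enumerate(jacs) if j == best_j]
        if len(tied) > 1 and compute_correlation:
            # break ties by score correlation, then by name order
            corrs = {
                i: mp_similarity(prog, sorted(mp_sets[i]), matrix, scoring_cfg)[1]
                for i in tied
            }
            best_corr = max(corrs.values())
            best_i = min(
                (i for i in tied if corrs[i] == best_corr), key=lambda i: mp_names[i]
            )
            best_r = corrs[best_i]
        else:
            best_i = tied[0]
            best_r = (
                mp_similarity(prog, sorted(mp_sets[best_i]), matrix, scoring_cfg)[1]
                if compute_correlation
                else float("nan")
            )

        null = np.empty(n_perm)
        size = len(sig)
        for t in range(n_perm):
            draw = set(rng.choice(universe, size=size, replace=False).tolist())
            null[t] = _jaccard_max_over_mps(draw, mp_sets)
        threshold = float(np.quantile(null, confidence, method="inverted_cdf"))

        results.append(
            AnnotationResult(
                program_id=prog.program_id,
                best_mp_name=mp_names[best_i],
                jaccard=float(best_j),
                score_correlation=best_r,
                null_threshold_jaccard=threshold,
                significant=bool(best_j > threshold),
            )
        )
        prog.annotation = mp_names[best_i] if best_j > threshold else None
    return results
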