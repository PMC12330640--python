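"""Synthetic cohorts with planted, partially shared expression programs.

Stands in for a cohort of tumor cell lines profiled by scRNA-seq: each
sample expresses a subset of a small number of ITH programs, each program
is "on" in a fraction of the sample's cells, and two designated programs
(emulating the mutually exclusive hEMT and EpiSen states) are never
co-active in the same cell.  Per-sample phenotypes (metastatic potential
and penetrance) track the activity of one designated program, and a
compound-sensitivity table plants compounds whose AUC anti-correlates
with a biomarker's expression.

Counts are Poisson with log-normal per-gene baselines; program genes are
drawn brighter than background so the planted additive log2 shift remains
recoverable after count noise and log transformation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import ExpressionMatrix, ValidationError


@dataclass
class SyntheticSpec:
    """Parameters of the planted-program cohort generator.

    effect_size is the additive log2-expression shift applied to a
    program's genes in cells where that program is active.
    """

    n_samples: int = 16
    n_genes: int = 2000
    cells_per_sample: int = 300
    n_programs: int = 6
    genes_per_program: int = 50
    program_sharing: float = 0.5  # fraction of samples expressing each program
    active_cell_fraction: float = 0.3
    effect_size: float = 1.5
    baseline_dispersion: float = 0.75  # sd of log-normal gene baselines
    baseline_log_mean: float = float(np.log(0.5))  # log mean rate of background genes
    anticorrelated_pair: tuple[int, int] = (0, 1)
    phenotype_program: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_programs < 2:
            raise ValidationError("n_programs must be >= 2")
        if self.genes_per_program * self.n_programs > self.n_genes:
            raise ValidationError(
                "genes_per_program * n_programs exceeds n_genes "
                f"({self.genes_per_program} * {self.n_programs} > {self.n_genes})"
            )
        for name in ("program_sharing", "active_cell_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        a, b = self.anticorrelated_pair
        if a == b or not (0 <= a < self.n_programs and 0 <= b < self.n_programs):
            raise ValidationError(
                f"anticorrelated_pair must be two distinct program indices "
                f"< n_programs, got {self.anticorrelated_pair}"
            )
        if not 0 <= self.phenotype_program < self.n_programs:
            raise ValidationError(
                f"phenotype_program {self.phenotype_program} out of range "
                f"[0, {self.n_programs})"
            )
        for name in ("n_samples", "n_genes", "cells_per_sample", "genes_per_program"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """What was planted: program gene sets, per-cell activity, per-sample phenotypes."""

    program_gene_sets: list[set[str]]
    cell_program_labels: list[set[int]]  # parallel to cell ids
    sample_programs: dict[str, list[int]]  # sample -> programs it expresses
    sample_active_fraction: dict[str, float]  # phenotype-program active cell fraction
    sample_phenotypes: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "program_gene_sets": [sorted(s) for s in self.program_gene_sets],
            "cell_program_labels": [sorted(s) for s in self.cell_program_labels],
            "sample_programs": self.sample_programs,
            "sample_active_fraction": self.sample_active_fraction,
            "sample_phenotypes": self.sample_phenotypes,
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def generate_cohort(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a cohort of Poisson-count single-cell samples with planted programs.

    Returns the raw count matrix (genes x cells) plus the ground truth.
    Each program is expressed by a fixed number of samples,
    ``round(program_sharing * n_samples)`` clipped to at least 2, so every
    program recurs across samples as the consensus step assumes.  Within
    an expressing sample, each cell activates the program independently
    with probability ``active_cell_fraction``; the two programs of
    ``anticorrelated_pair`` are never both active in one cell.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_cells = spec.n_samples * spec.cells_per_sample
    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{i:02d}" for i in range(spec.n_samples)]

    # program gene sets: disjoint blocks at the front of the gene list
    program_sets: list[set[str]] = []
    for p in range(spec.n_programs):
        lo = p * spec.genes_per_program
        program_sets.append(set(gene_ids[lo : lo + spec.genes_per_program]))

    # log-normal baselines; program genes brighter so the log2 shift survives
    log_lam = rng.normal(spec.baseline_log_mean, spec.baseline_dispersion, size=spec.n_genes)
    n_prog_genes = spec.n_programs * spec.genes_per_program
    log_lam[:n_prog_genes] = rng.normal(np.log(4.0), 0.3, size=n_prog_genes)
    lam_base = np.exp(log_lam)

    # which samples express which programs (fixed count => guaranteed recurrence)
    n_expr = max(2, round(spec.program_sharing * spec.n_samples))
    n_expr = min(n_expr, spec.n_samples)
    sample_programs: dict[str, list[int]] = {s: [] for s in sample_ids}
    for p in range(spec.n_programs):
        for si in rng.choice(spec.n_samples, size=n_expr, replace=False):
            sample_programs[sample_ids[si]].append(p)

    a_idx, b_idx = spec.anticorrelated_pair
    counts = np.empty((spec.n_genes, n_cells), dtype=float)
    cell_ids: list[str] = []
    sample_of_cell: list[str] = []
    cell_labels: list[set[int]] = []
    active_frac: dict[str, float] = {}

    gene_rows = {p: np.asarray(sorted(range(p * spec.genes_per_program,
                                             (p + 1) * spec.genes_per_program)))
                 for p in range(spec.n_programs)}
    fold = 2.0 ** spec.effect_size

    col = 0
    for sid in sample_ids:
        progs = sample_programs[sid]
        on = np.zeros((spec.n_programs, spec.cells_per_sample), dtype=bool)
        for p in progs:
            on[p] = rng.random(spec.cells_per_sample) < spec.active_cell_fraction
        # enforce mutual exclusivity of the anticorrelated pair
        both = on[a_idx] & on[b_idx]
        drop_a = rng.random(spec.cells_per_sample) < 0.5
        on[a_idx, both & drop_a] = False
        on[b_idx, both & ~drop_a] = False

        lam = np.repeat(lam_base[:, None], spec.cells_per_sample, axis=1)
        for p in range(spec.n_programs):
            if on[p].any():
                lam[np.ix_(gene_rows[p], np.flatnonzero(on[p]))] *= fold
        counts[:, col : col + spec.cells_per_sample] = rng.poisson(lam)

        for j in range(spec.cells_per_sample):
            cell_ids.append(f"{sid}_C{j:04d}")
            sample_of_cell.append(sid)
            cell_labels.append(set(np.flatnonzero(on[:, j]).tolist()))
        if a_idx in progs or b_idx in progs:
            assert not (on[a_idx] & on[b_idx]).any()
        active_frac[sid] = float(on[spec.phenotype_program].mean())
        col += spec.cells_per_sample

    matrix = ExpressionMatrix(counts, gene_ids, cell_ids, sample_of_cell)
    truth = GroundTruth(
        program_gene_sets=program_sets,
        cell_program_labels=cell_labels,
        sample_programs=sample_programs,
        sample_active_fraction=active_frac,
    )
    return matrix, truth


def generate_phenotypes(
    truth: GroundTruth,
    spec: SyntheticSpec,
    noise_sd: float = 5.0,
) -> pd.DataFrame:
    """Per-sample metastatic potential / penetrance tracking the phenotype program.

    Both phenotypes are affine in the sample's phenotype-program active-cell
    fraction plus truncated Gaussian noise, clipped to the [0, 100] % scale.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for sid, frac in truth.sample_active_fraction.items():
        potential = np.clip(5.0 + 90.0 * frac + rng.normal(0, noise_sd), 0.0, 100.0)
        penetrance = np.clip(10.0 + 85.0 * frac + rng.normal(0, 1.6 * noise_sd), 0.0, 100.0)
        rows.append((sid, float(potential), float(penetrance)))
    df = pd.DataFrame(rows, columns=["sample_id", "metastatic_potential", "metastatic_penetrance"])
    truth.sample_phenotypes = {
        r.sample_id: (r.metastatic_potential, r.metastatic_penetrance)
        for r in df.itertuples()
    }
    return df


def generate_drug_screen(
    n_lines: int,
    n_compounds: int,
    n_hits: int,
    effect: float = 0.8,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Biomarker expression plus a line x compound AUC table with planted hits.

    Hit compounds' AUC is built with Pearson correlation ~ ``-effect`` to
    the biomarker's expression (lower AUC = more sensitive, so hits are
    more potent in high-expression lines); non-hits are independent noise.
    ``missing_rate`` optionally blanks AUC entries at random.
    """
    if n_lines < 3 or n_compounds < 1 or n_hits < 0:
        raise ValidationError("counts must be positive (n_lines >= 3)")
    if n_hits > n_compounds:
        raise ValidationError(f"n_hits {n_hits} exceeds n_compounds {n_compounds}")
    if not 0.0 <= effect <= 1.0:
        raise ValidationError("effect must be in [0, 1]")
    rng = np.random.default_rng(seed)

    line_ids = [f"L{i:03d}" for i in range(n_lines)]
    compound_ids = [f"CPD{j:04d}" for j in range(n_compounds)]
    hit_ids = compound_ids[:n_hits]

    expr_z = rng.normal(size=n_lines)
    expression = pd.Series(5.0 + expr_z, index=line_ids, name="expression")

    auc = np.empty((n_lines, n_compounds))
    noise_w = np.sqrt(max(0.0, 1.0 - effect**2))
    for j in range(n_compounds):
        if j < n_hits:
            z = -effect * expr_z + noise_w * rng.normal(size=n_lines)
        else:
            z = rng.normal(size=n_lines)
        auc[:, j] = 0.7 + 0.1 * z  # AUC-like scale; lower = more sensitive

    table = pd.DataFrame(auc, index=line_ids, columns=compound_ids)
    if missing_rate > 0:
        mask = rng.random(table.shape) < missing_rate
        table = table.mask(mask)
    return expression, table, hit_ids


def write_cohort(
    out_dir: str | Path,
    matrix: ExpressionMatrix,
    truth: GroundTruth,
    phenotypes: pd.DataFrame | None = None,
) -> None:
    """Write matrix (.mtx + sidecars), ground truth (JSON), signatures (GMT), phenotypes (TSV)."""
    from .io import write_gmt
    from .preprocessing import write_expression

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_expression(matrix, out_dir)
    truth.to_json(out_dir / "ground_truth.json")
    write_gmt(
        {f"planted_program_{i}": sorted(s) for i, s in enumerate(truth.program_gene_sets)},
        out_dir / "planted_programs.gmt",
    )
    if phenotypes is not None:
        phenotypes.to_csv(out_dir / "phenotypes.tsv", sep="\t", index=False)
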