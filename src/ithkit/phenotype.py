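"""Program-phenotype association: sample assignment, phenotype summaries,
quantile stratification and exact 2x2 incidence comparison."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .consensus import ITHProgram
from .nmf import GeneModule
from .preprocessing import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable2x2:
    """Counts with rows = groups and columns = event yes/no."""

    a: int
    b: int
    c: int
    d: int

    def validate(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValidationError("contingency counts must be non-negative integers")
        if sum(cells) < 1:
            raise ValidationError("contingency table must contain at least one observation")


def assign_samples(
    programs: list[ITHProgram],
    retained_modules: list[GeneModule] | None = None,
) -> dict[str, set[str]]:
    """Sample -> set of program ids the sample is enriched in.

    A sample is enriched in a program iff at least one of its retained
    modules is a member of that program; samples whose modules were all
    filtered out get an empty set.
    """
    assignment: dict[str, set[str]] = {}
    if retained_modules is not None:
        for m in retained_modules:
            assignment.setdefault(m.sample_id, set())
    for prog in programs:
        for m in prog.member_modules:
            assignment.setdefault(m.sample_id, set()).add(prog.program_id)
    return assignment


def assign_samples_by_score(
    programs: list[ITHProgram], scores: pd.DataFrame
) -> dict[str, set[str]]:
    """Alternative rule: each sample is assigned the program with the highest
    mean cell score (``scores`` as returned by score_program, concatenated)."""
    mean_scores = scores.groupby(["sample_id", "program_id"])["score"].mean().unstack()
    return {str(s): {str(mean_scores.loc[s].idxmax())} for s in mean_scores.index}


def summarize_phenotype(
    assignment: dict[str, set[str]],
    phenotypes: pd.DataFrame,
) -> pd.DataFrame:
    """Mean metastatic potential / penetrance over the samples enriched in each program.

    Programs with no enriched sample get n=0 and NaN means (flagged in the
    ``defined`` column).
    """
    pheno = phenotypes.set_index("sample_id")
    missing = [s for s in assignment if s not in pheno.index]
    if missing:
        raise ValidationError(f"samples missing from phenotype table: {sorted(missing)}")
    program_ids = sorted({p for progs in assignment.values() for p in progs})
    rows = []
    for pid in program_ids:
        members = [s for s, progs in assignment.items() if pid in progs]
        if members:
            sub = pheno.loc[members]
            rows.append(
                (pid, len(members),
                 float(sub["metastatic_potential"].mean()),
                 float(sub["metastatic_penetrance"].mean()), True)
            )
        else:
            rows.append((pid, 0, math.nan, math.nan, False))
    return pd.DataFrame(
        rows,
        columns=["program_id", "n", "mean_metastatic_potential",
                 "mean_metastatic_penetrance", "defined"],
    )


def stratify_by_quantile(values: pd.Series, q: float = 0.2) -> pd.Series:
    """Label samples 'high' / 'low' / 'excluded' by top and bottom ``q`` fraction.

    Nearest-rank quantiles: with n samples, the bottom k = ceil(q*n)
    order statistics define the low cutoff and the top k the high cutoff;
    ties at a boundary are included on that side (group sizes may then
    exceed k).  All-identical values cannot be stratified.
    """
    if not 0 < q <= 0.5:
        raise ValidationError("q must be in (0, 0.5]")
    n = len(values)
    if n < math.ceil(1 / q):
        raise ValidationError(f"need at least {math.ceil(1 / q)} samples for q={q}")
    vals = values.to_numpy(dtype=float)
    if np.all(vals == vals[0]):
        raise ValidationError("all values identical: no stratification possible")
    k = math.ceil(q * n)
    srt = np.sort(vals)
    low_cut = srt[k - 1]
    high_cut = srt[n - k]
    labels = pd.Series("excluded", index=values.index, dtype=object)
    labels[values <= low_cut] = "low"
    labels[values >= high_cut] = "high"
    if low_cut >= high_cut:
        raise ValidationError("quantile cutoffs overlap: groups are not separable")
    return labels


def compare_incidence(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 incidence table.

    Two-sided by summing the probabilities of all tables (with fixed
    margins) whose point probability does not exceed the observed one.
    A zero margin carries no information: p = 1 with a warning.
    """
    table.validate()
    arr = [[table.a, table.b], [table.c, table.d]]
    margins = (
        table.a + table.b, table.c + table.d,
        table.a + table.c, table.b + table.d,
    )
    if 0 in margins:
        logger.warning("contingency table has a zero margin; p = 1")
        return 1.0
    return float(fisher_exact(arr, alternative="two-sided")[1])
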