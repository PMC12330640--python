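"""In-silico compound vulnerability screen: biomarker expression vs drug AUC.

For every compound, the Pearson correlation between a biomarker gene's
expression and the compound's AUC is computed across cell lines on
pairwise-complete observations (lower AUC = more sensitive, so a
negative correlation marks compounds more potent in high-expression
lines).  P-values come from the t transform; q-values are
Benjamini-Hochberg over the tested compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .preprocessing import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DrugScreenResult:
    compound_id: str
    n_used: int
    pearson_r: float
    p_value: float
    q_value: float = float("nan")


def correlate_compound(
    expression: pd.Series,
    auc_column: pd.Series,
    min_lines: int = 20,
) -> tuple[float, float, int]:
    """Pearson r, two-sided p and n for one compound on pairwise-complete lines.

    Raises when fewer than ``min_lines`` complete pairs exist or either
    vector has zero variance over them.
    """
    joined = pd.concat([expression, auc_column], axis=1, join="inner").dropna()
    n = len(joined)
    if n < min_lines:
        raise ValidationError(f"only {n} complete pairs (< min_lines={min_lines})")
    x = joined.iloc[:, 0].to_numpy(float)
    y = joined.iloc[:, 1].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance in expression or AUC over complete pairs")
    r, p = pearsonr(x, y)
    return float(r), float(p), n


def screen_all(
    expression: pd.Series,
    auc_table: pd.DataFrame,
    min_lines: int = 20,
) -> pd.DataFrame:
    """Correlate expression with every compound's AUC; BH-adjust; sort by r.

    Returns a DataFrame (compound_id, n_used, pearson_r, p_value,
    q_value) sorted by r ascending, so the most "selectively lethal in
    high-expression lines" compounds come first.  Untestable compounds
    (too few pairs, zero variance) are skipped with a logged reason.
    """
    shared = expression.index.intersection(auc_table.index)
    if len(shared) == 0:
        raise ValidationError("no shared cell lines between expression and AUC table")
    rows = []
    for compound in auc_table.columns:
        try:
            r, p, n = correlate_compound(
                expression.loc[shared], auc_table.loc[shared, compound], min_lines
            )
        except ValidationError as e:
            logger.info("compound %s skipped: %s", compound, e)
            continue
        rows.append((str(compound), n, r, p))
    if not rows:
        logger.warning("no testable compounds; returning empty result")
        return pd.DataFrame(
            columns=["compound_id", "n_used", "pearson_r", "p_value", "q_value"]
        )
    df = pd.DataFrame(rows, columns=["compound_id", "n_used", "pearson_r", "p_value"])
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values("pearson_r", kind="mergesort").reset_index(drop=True)


def rank_hits(
    results: pd.DataFrame,
    direction: str = "sensitive",
    q_max: float = 0.05,
) -> list[str]:
    """Compounds passing the FDR gate in the requested direction.

    direction='sensitive': r < 0 (more potent in high-expression lines),
    sorted by r ascending; 'resistant': r > 0, sorted descending.
    """
    if results.empty:
        return []
    if direction == "sensitive":
        sel = results[(results["pearson_r"] < 0) & (results["q_value"] <= q_max)]
        sel = sel.sort_values("pearson_r", kind="mergesort")
    elif direction == "resistant":
        sel = results[(results["pearson_r"] > 0) & (results["q_value"] <= q_max)]
        sel = sel.sort_values("pearson_r", ascending=False, kind="mergesort")
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    return sel["compound_id"].tolist()


def volcano_data(results: pd.DataFrame) -> pd.DataFrame:
    """Per-compound (r, -log10 p) pairs for a volcano plot."""
    out = results[["compound_id", "pearson_r", "p_value"]].copy()
    out["neg_log10_p"] = -np.log10(out["p_value"])
    return out
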