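"""GMT gene-set files and delimited phenotype / sensitivity tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .preprocessing import ValidationError


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one gene set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
        name = parts[0]
        if name in sets:
            raise ValidationError(f"{path}:{ln}: duplicate gene-set name {name!r}")
        genes = [g for g in parts[2:] if g]
        if not genes:
            raise ValidationError(f"{path}:{ln}: gene set {name!r} is empty")
        sets[name] = genes
    if not sets:
        raise ValidationError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "ithkit") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of sample_id, metastatic_potential, metastatic_penetrance."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "metastatic_potential", "metastatic_penetrance"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in phenotype table")
    for col in ("metastatic_potential", "metastatic_penetrance"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValidationError(f"{col} must be a percentage in [0, 100]")
    return df


def read_auc_table(path: str | Path) -> pd.DataFrame:
    """Read a line x compound AUC table (first column = line ids; lower AUC = sensitive)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValidationError("duplicate line ids in AUC table")
    if df.columns.duplicated().any():
        raise ValidationError("duplicate compound ids in AUC table")
    return df


def read_expression_vector(path: str | Path) -> pd.Series:
    """Two-column TSV: line id, expression value."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValidationError("expression vector file must have exactly two columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    if s.index.duplicated().any():
        raise ValidationError("duplicate line ids in expression vector")
    return s
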