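"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and labels are tab-separated; gene sets use the GMT
convention (set name, description, then member genes, one set per line).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "write_profile",
    "write_comparison",
    "write_fdr_table",
]


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV; first column is the gene identifier."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        raise ValueError("expression table has duplicate gene identifiers")
    return df.astype(float)


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene")


def read_labels(path) -> pd.Series:
    """Sample class labels from a ``sample<TAB>class`` TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["sample", "class"]:
        raise ValueError("labels file must have header 'sample<TAB>class'")
    labels = df.set_index("sample")["class"].astype(str)
    if labels.index.has_duplicates:
        raise ValueError("labels file lists a sample twice")
    return labels


def write_labels(labels: pd.Series, path) -> None:
    out = labels.rename("class").rename_axis("sample")
    out.to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, list[str]]:
    """Gene sets from a GMT file: name -> member genes (descriptions dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: need name, description and >=1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "synthetic") -> None:
    with open(path, "wt") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_profile(profile, path) -> None:
    """Plot-ready TSV: position, relative_position, value."""
    profile.to_frame().to_csv(path, sep="\t", index=False)


def write_comparison(comparison, path) -> None:
    comparison.to_frame().to_csv(path, sep="\t", index=False)


def write_fdr_table(fdr_table: pd.Series, path) -> None:
    out = fdr_table.rename("fdr").rename_axis("threshold")
    out.to_csv(path, sep="\t", na_rep="NA")
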