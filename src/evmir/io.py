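"""Tabular I/O helpers shared by the pipeline and CLI.

Canonical tabular format: TSV with '.' decimal separator, no thousands
separators, and a leading '#' comment line naming the units and
conventions of the table.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_tsv(df: pd.DataFrame, path, comment: str | None = None, index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_counts(path) -> pd.DataFrame:
    """Read a features x samples count matrix (first column = feature name)."""
    df = read_tsv(path, index_col=0)
    df.index.name = "feature"
    return df


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
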