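"""Readers/writers for tip-set files, membership tables and distance
matrices.

Formats:

* tip-set file — one tip label per line; blank lines and ``#`` comments
  ignored.
* membership table — TSV with header ``sample<TAB>tip``, one row per
  (sample, tip) pair.
* distance matrix — TSV with labels in the first row and first column.
"""

from __future__ import annotations

import pandas as pd

from .errors import PhylosampleError

__all__ = ["read_tip_set", "read_membership", "write_membership",
           "read_distance_matrix", "write_distance_matrix"]


def read_tip_set(path) -> set[str]:
    tips: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                tips.add(line)
    return tips


def read_membership(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "tip"]:
        raise PhylosampleError(
            f"membership table must have header 'sample<TAB>tip', got {list(df.columns)}")
    return {str(s): set(g["tip"]) for s, g in df.groupby("sample")}


def write_membership(communities: dict[str, set[str]], path) -> None:
    rows = [(s, t) for s in sorted(communities) for t in sorted(communities[s])]
    pd.DataFrame(rows, columns=["sample", "tip"]).to_csv(path, sep="\t", index=False)


def read_distance_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_distance_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
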