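"""The per-cytosine methylation table ("allc") and its helpers.

An allc table has one row per covered cytosine per strand:

    chrom  pos  strand  context  class  mc  cov  methylated

with ``pos`` the 1-based cytosine coordinate, ``context`` the reference
trinucleotide read 5'->3' on the cytosine's strand, ``class`` either
``CG`` or ``CH`` (H = A/C/T), ``mc <= cov`` the methylated and total
call counts, and ``methylated = 1`` when ``mc > 0``.  Tables are plain
pandas DataFrames; files are tab-separated without header, mirroring
the widely used allc text format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dropmet.seq import to_array

ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "class", "mc", "cov", "methylated"]

# categorical text columns and compact integers keep tables of a few
# hundred thousand sites per cell at a few MB
_DTYPES = {
    "chrom": "category",
    "pos": np.int64,
    "strand": "category",
    "context": "category",
    "class": "category",
    "mc": np.int32,
    "cov": np.int32,
    "methylated": np.int8,
}


def empty_allc() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _DTYPES.items()})


def validate_allc(allc: pd.DataFrame) -> None:
    """Raise on structural violations (negative counts, mc > cov, dupes)."""
    if list(allc.columns) != ALLC_COLUMNS:
        raise ValueError(f"allc columns must be {ALLC_COLUMNS}")
    if len(allc) == 0:
        return
    if (allc["cov"] < 1).any() or (allc["mc"] < 0).any():
        raise ValueError("allc requires cov >= 1 and mc >= 0")
    if (allc["mc"] > allc["cov"]).any():
        raise ValueError("allc requires mc <= cov")
    if allc.duplicated(["chrom", "pos", "strand"]).any():
        raise ValueError("duplicate (chrom, pos, strand) rows in allc")


def write_allc(allc: pd.DataFrame, path) -> None:
    allc.to_csv(path, sep="\t", header=False, index=False)


def read_allc(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=ALLC_COLUMNS, dtype=_DTYPES)


def context_strings(seq: str, positions: np.ndarray, strand: str) -> np.ndarray:
    """Reference trinucleotide contexts at cytosine ``positions`` (0-based).

    Plus strand: bases i..i+2; minus strand: reverse complement of bases
    i-2..i.  Positions too close to a contig edge are padded with N.
    """
    padded = "NN" + seq + "NN"
    arr = to_array(padded)
    if strand == "+":
        tri = np.stack([arr[positions + 2 + k] for k in range(3)], axis=1)
    else:
        comp = np.zeros(256, dtype=np.uint8)
        for a, b in zip(b"ACGTN", b"TGCAN"):
            comp[a] = b
        tri = np.stack([comp[arr[positions + k]] for k in range(2, -1, -1)], axis=1)
    return np.ascontiguousarray(tri).view("S3").ravel().astype("U3")


def assemble_allc(
    chrom: str,
    seq: str,
    positions: np.ndarray,
    strand: str,
    site_class: np.ndarray,
    mc: np.ndarray,
    cov: np.ndarray,
) -> pd.DataFrame:
    """Rows for one contig/strand from parallel arrays (0-based positions)."""
    if len(positions) == 0:
        return empty_allc()
    class_str = np.where(site_class == 1, "CG", "CH")
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": pd.Categorical([chrom] * n),
            "pos": positions.astype(np.int64) + 1,
            "strand": pd.Categorical([strand] * n, categories=["+", "-"]),
            "context": pd.Categorical(context_strings(seq, positions, strand)),
            "class": pd.Categorical(class_str, categories=["CG", "CH"]),
            "mc": mc.astype(np.int32),
            "cov": cov.astype(np.int32),
            "methylated": (mc > 0).astype(np.int8),
        }
    )


def concat_allc(parts: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate allc parts, restoring categorical text columns."""
    out = pd.concat(parts, ignore_index=True)
    for col in ("chrom", "strand", "context", "class"):
        if out[col].dtype != "category":
            out[col] = out[col].astype("category")
    return out


def collapse_cg_strands(allc: pd.DataFrame) -> pd.DataFrame:
    """Merge the two strands of each CpG into one row at the C position.

    Returns CG-class rows only, keyed to the plus-strand cytosine
    coordinate (minus-strand rows contribute at ``pos - 1``), with mc
    and cov summed.  Useful for CpG-count reporting and per-CpG tests.
    """
    cg = allc[allc["class"] == "CG"]
    if cg.empty:
        return cg.copy()
    pos = cg["pos"].where(cg["strand"] == "+", cg["pos"] - 1)
    grouped = (
        cg.assign(pos=pos)
        .groupby(["chrom", "pos"], as_index=False, sort=True, observed=True)[
            ["mc", "cov"]
        ]
        .sum()
    )
    grouped["methylated"] = (grouped["mc"] > 0).astype(np.int8)
    return grouped
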