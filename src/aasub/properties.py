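"""Amino-acid property tables, pairwise absolute differences, correlations.

A *property table* is a pandas DataFrame with the 20 amino acids (PAML order)
as index and one column per property scale; the accession of each scale is
kept in ``table.attrs["provenance"]``.  Tables come from three sources: the
embedded default set (:func:`builtin_properties`), an AAIndex1 flat file
(:func:`parse_aaindex`), or a plain CSV (:func:`read_property_csv`).

Dissimilarity between two amino acids on a scale is the absolute difference
of their values; :func:`pairwise_differences` assembles the 190 x P table of
those differences that feeds the PCA stage.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from ._aaindex_builtin import BUILTIN_SCALES
from .genetic_code import AA_ORDER

__all__ = [
    "builtin_properties",
    "parse_aaindex",
    "read_property_csv",
    "write_aaindex",
    "pairwise_differences",
    "property_correlations",
    "AAIndexFormatError",
]

# AAIndex1 "I" block column order: first row A R N D C Q E G H I,
# second row L K M F P S T W Y V (the "A/L R/K ..." header).
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


class AAIndexFormatError(ValueError):
    """Malformed AAIndex1 record."""


def builtin_properties() -> pd.DataFrame:
    """The embedded default property set (8 scales, each a published AAIndex record)."""
    data = {name: vals for name, (_, _, vals) in BUILTIN_SCALES.items()}
    table = pd.DataFrame(data, index=list(AA_ORDER))
    table.index.name = "aa"
    table.attrs["provenance"] = {
        name: acc for name, (acc, _, _) in BUILTIN_SCALES.items()
    }
    table.attrs["descriptions"] = {
        name: desc for name, (_, desc, _) in BUILTIN_SCALES.items()
    }
    return table


def parse_aaindex(path: str | Path, missing: str = "drop") -> pd.DataFrame:
    """Parse an AAIndex1 flat file into a property table.

    Records are delimited by ``//``; the accession comes from the ``H`` line
    and the 20 values from the two numeric rows following the ``I`` header.
    ``NA`` values are handled per ``missing``: ``"drop"`` discards the whole
    record with a warning, ``"error"`` raises.
    """
    if missing not in ("drop", "error"):
        raise ValueError(f"missing policy must be 'drop' or 'error', got {missing!r}")
    text = Path(path).read_text()
    columns: dict[str, list[float]] = {}
    provenance: dict[str, str] = {}
    for chunk in text.split("//"):
        lines = [ln for ln in chunk.splitlines() if ln.strip()]
        if not lines:
            continue
        accession = None
        ivals: list[str] = []
        in_i = False
        for ln in lines:
            tag, _, rest = ln.partition(" ")
            if tag == "H":
                accession = rest.strip().split()[0]
                in_i = False
            elif tag == "I":
                in_i = True
                ivals = []
            elif in_i and ln.startswith(" "):
                ivals.extend(ln.split())
            elif tag in {"D", "R", "A", "T", "J", "C", "*"}:
                in_i = False
        if accession is None:
            raise AAIndexFormatError(f"{path}: record without an H (accession) line")
        if len(ivals) != 20:
            raise AAIndexFormatError(
                f"{path}: record {accession}: expected 20 values in I block, "
                f"found {len(ivals)}"
            )
        if accession in columns:
            raise AAIndexFormatError(f"{path}: duplicate accession {accession}")
        vals: dict[str, float] = {}
        has_na = False
        for aa, tok in zip(_AAINDEX_ROW1 + _AAINDEX_ROW2, ivals):
            if tok.upper() == "NA":
                has_na = True
                vals[aa] = np.nan
            else:
                try:
                    vals[aa] = float(tok)
                except ValueError as exc:
                    raise AAIndexFormatError(
                        f"{path}: record {accession}: bad value {tok!r}"
                    ) from exc
        if has_na:
            if missing == "error":
                raise AAIndexFormatError(
                    f"{path}: record {accession} contains NA values"
                )
            warnings.warn(
                f"dropping AAIndex record {accession}: contains NA values",
                stacklevel=2,
            )
            continue
        columns[accession] = [vals[aa] for aa in AA_ORDER]
        provenance[accession] = accession
    table = pd.DataFrame(columns, index=list(AA_ORDER))
    table.index.name = "aa"
    table.attrs["provenance"] = provenance
    return table


def write_aaindex(table: pd.DataFrame, path: str | Path) -> None:
    """Write a property table as a minimal AAIndex1 flat file (round-trippable)."""
    prov = table.attrs.get("provenance", {})
    out = []
    for col in table.columns:
        acc = prov.get(col, col)
        out.append(f"H {acc}")
        out.append(f"D {col}")
        out.append("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V")
        row1 = "  " + "  ".join(f"{table.loc[aa, col]:.6g}" for aa in _AAINDEX_ROW1)
        row2 = "  " + "  ".join(f"{table.loc[aa, col]:.6g}" for aa in _AAINDEX_ROW2)
        out.append(row1)
        out.append(row2)
        out.append("//")
    Path(path).write_text("\n".join(out) + "\n")


def read_property_csv(path: str | Path) -> pd.DataFrame:
    """Read a plain CSV property table: first column amino acid, one column per scale."""
    table = pd.read_csv(path, index_col=0)
    if sorted(table.index) != sorted(AA_ORDER):
        raise ValueError(f"{path}: index must be the 20 one-letter amino-acid codes")
    table = table.loc[list(AA_ORDER)]
    table.index.name = "aa"
    if table.isna().any().any():
        raise ValueError(f"{path}: missing values in property CSV")
    table.attrs["provenance"] = {c: str(Path(path)) for c in table.columns}
    return table


def pairwise_differences(table: pd.DataFrame) -> pd.DataFrame:
    """Absolute property differences for all 190 unordered amino-acid pairs.

    Returns a DataFrame with ``aa1``/``aa2`` columns (aa1 before aa2 in PAML
    order) and one column of |x_i - x_j| per property.
    """
    if list(table.index) != list(AA_ORDER):
        table = table.loc[list(AA_ORDER)]
    rows = []
    for a1, a2 in combinations(AA_ORDER, 2):
        diff = (table.loc[a1] - table.loc[a2]).abs()
        rows.append({"aa1": a1, "aa2": a2, **diff.to_dict()})
    out = pd.DataFrame(rows)
    out.attrs["provenance"] = dict(table.attrs.get("provenance", {}))
    return out


def property_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix between property scales.

    Computed across the rows of whatever table is supplied: the 20 amino
    acids for a property table, or the 190 pairs for a difference table
    (non-numeric pair-key columns are ignored).
    """
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        raise ValueError("need at least two numeric property columns")
    constant = [c for c in numeric.columns if np.isclose(numeric[c].std(), 0.0)]
    if constant:
        raise ValueError(
            f"correlation undefined for constant column(s): {', '.join(constant)}"
        )
    return numeric.corr(method="pearson")
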