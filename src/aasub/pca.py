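"""Principal component analysis of the pair-difference table.

The PCA condenses the P correlated property-difference columns into a small
number of orthogonal axes.  With a property set spanning the two major
families, one leading axis is dominated by charge/hydrophobicity-family
differences and the other by size-family differences, so PC1 and PC2 serve
downstream as the "difference in charge" and "difference in size" covariates
(which family leads depends on the property list).

The decomposition is computed by SVD of the centered (and, by default,
unit-variance scaled) data; with standardization this is the
eigendecomposition of the correlation matrix.  Variable diagnostics follow
the usual conventions: *contributions* are the percentage share of each
variable in a component (100 x squared loading) and *cos²* is the squared
correlation between a variable and a component, i.e. the quality of the
variable's representation on that axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCAResult", "run_pca", "pc_scores_for_pairs", "default_anchors"]


@dataclass
class PCAResult:
    """Full-rank PCA decomposition of a 190-pair difference table."""

    loadings: pd.DataFrame            # P x K, orthonormal columns
    scores: pd.DataFrame              # 190 x K, indexed by (aa1, aa2)
    eigenvalues: pd.Series            # K variances of the score columns
    explained_fraction: pd.Series     # K fractions summing to 1
    contributions: pd.DataFrame       # P x K, percent, each column sums to 100
    cos2: pd.DataFrame                # P x K squared variable-component correlation
    standardized: bool

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def default_anchors(columns) -> dict[int, str]:
    """Sign anchors for the builtin property set.

    PC1 is anchored on the hydropathy-family variable and PC2 on molecular
    weight, so that larger scores mean larger differences on the dominant
    family and fitted slope signs are reproducible run to run.
    """
    anchors = {}
    cols = list(columns)
    if "hydropathy" in cols:
        anchors[1] = "hydropathy"
    if "molecular_weight" in cols:
        anchors[2] = "molecular_weight"
    return anchors


def run_pca(
    diff_table: pd.DataFrame,
    standardize: bool = True,
    anchors: dict[int, str] | None = None,
) -> PCAResult:
    """PCA of the unordered pair-difference table.

    Parameters
    ----------
    diff_table
        190-row table with ``aa1``/``aa2`` columns and P numeric columns.
    standardize
        Center and scale each column to unit variance (correlation PCA,
        default) rather than covariance PCA.  Mixed-unit property scales
        require standardization.
    anchors
        Map from 1-based component number to column name; each component's
        sign is flipped so the anchor variable's loading is positive.
        Components without an anchor use the variable with the largest
        absolute loading.  If None, anchors are auto-detected for the
        builtin property set.
    """
    keys = diff_table[["aa1", "aa2"]]
    X = diff_table.drop(columns=["aa1", "aa2"]).astype(float)
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("PCA needs at least two property columns")
    n = len(X)
    arr = X.to_numpy()
    mean = arr.mean(axis=0)
    centered = arr - mean
    scale = centered.std(axis=0, ddof=1)
    if standardize:
        zero = [c for c, s in zip(cols, scale) if np.isclose(s, 0.0)]
        if zero:
            raise ValueError(
                f"cannot standardize constant column(s): {', '.join(zero)}"
            )
        centered = centered / scale
    if anchors is None:
        anchors = default_anchors(cols)

    u, sing, vt = np.linalg.svd(centered, full_matrices=False)
    k = len(sing)
    eig = sing**2 / (n - 1)
    loadings = vt.T  # P x K
    scores = u * sing  # n x K

    # deterministic sign convention
    for comp in range(k):
        anchor_col = anchors.get(comp + 1)
        if anchor_col is not None:
            if anchor_col not in cols:
                raise ValueError(f"anchor column {anchor_col!r} not in table")
            ref = loadings[cols.index(anchor_col), comp]
        else:
            ref = loadings[np.argmax(np.abs(loadings[:, comp])), comp]
        if ref < 0:
            loadings[:, comp] *= -1
            scores[:, comp] *= -1

    names = [f"PC{i + 1}" for i in range(k)]
    explained = eig / eig.sum()
    # variable coordinates = correlation with components (standardized case)
    coords = loadings * np.sqrt(eig)
    contrib = 100.0 * loadings**2
    if standardize:
        cos2 = coords**2
    else:
        cos2 = coords**2 / (scale**2)[:, None]

    idx = pd.MultiIndex.from_frame(keys)
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=cols, columns=names),
        scores=pd.DataFrame(scores, index=idx, columns=names),
        eigenvalues=pd.Series(eig, index=names, name="eigenvalue"),
        explained_fraction=pd.Series(explained, index=names, name="explained_fraction"),
        contributions=pd.DataFrame(contrib, index=cols, columns=names),
        cos2=pd.DataFrame(cos2, index=cols, columns=names),
        standardized=standardize,
    )


def pc_scores_for_pairs(
    result: PCAResult,
    k: int,
    pairs: pd.DataFrame | None = None,
) -> pd.Series:
    """Score column of component ``k`` (1-based), joined to a pair table.

    If ``pairs`` is given (with ``aa1``/``aa2`` or directed ``aa_from``/
    ``aa_to`` columns), scores are looked up per row; directed tables reuse
    the unordered pair's score for both directions, since the difference
    covariates are symmetric.
    """
    if not 1 <= k <= result.n_components:
        raise ValueError(
            f"component {k} out of range 1..{result.n_components}"
        )
    col = result.scores[f"PC{k}"]
    if pairs is None:
        return col
    lookup = {frozenset(key): val for key, val in col.items()}
    if "aa_from" in pairs.columns:
        a, b = pairs["aa_from"], pairs["aa_to"]
    else:
        a, b = pairs["aa1"], pairs["aa2"]
    vals = [lookup[frozenset((x, y))] for x, y in zip(a, b)]
    return pd.Series(vals, index=pairs.index, name=f"PC{k}")
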