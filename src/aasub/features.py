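"""Assembly of the per-pair feature table that feeds the mixed models.

One row per amino-acid pair (directed or unordered) holding the response
(log substitution rate) and all covariates: PC scores of the property
differences, minimum mutational steps, |Δ pyrimidine proportion| and
|Δ GC content|.
"""

from __future__ import annotations

import pandas as pd

from . import genetic_code
from .pca import PCAResult, pc_scores_for_pairs

__all__ = ["build_feature_table", "feature_skeleton"]


def _pair_keys(table: pd.DataFrame) -> list[str]:
    return ["aa_from", "aa_to"] if "aa_from" in table.columns else ["aa1", "aa2"]


def _attach_pair_metrics(table: pd.DataFrame) -> pd.DataFrame:
    metrics = genetic_code.pair_metric_table()
    lookup = {
        frozenset((r.aa1, r.aa2)): (r.min_steps, r.gc_diff, r.pyr_diff)
        for r in metrics.itertuples(index=False)
    }
    k1, k2 = _pair_keys(table)
    vals = [lookup[frozenset((a, b))] for a, b in zip(table[k1], table[k2])]
    out = table.copy()
    out[["min_steps", "gc_diff", "pyr_diff"]] = pd.DataFrame(vals, index=table.index)
    return out


def _attach_pc_scores(
    table: pd.DataFrame, pca_result: PCAResult, n_components: int = 2
) -> pd.DataFrame:
    out = table.copy()
    for k in range(1, n_components + 1):
        out[f"PC{k}"] = pc_scores_for_pairs(pca_result, k, pairs=table)
    return out


def feature_skeleton(
    pca_result: PCAResult, mode: str = "directed", n_components: int = 2
) -> pd.DataFrame:
    """Covariates-only feature table (no rates): the simulation design matrix."""
    pairs = pca_result.scores.index.to_frame(index=False)  # aa1, aa2
    if mode == "directed":
        fwd = pairs.rename(columns={"aa1": "aa_from", "aa2": "aa_to"})
        rev = pairs.rename(columns={"aa1": "aa_to", "aa2": "aa_from"})
        base = pd.concat([fwd, rev], ignore_index=True)[["aa_from", "aa_to"]]
    elif mode == "undirected":
        base = pairs
    else:
        raise ValueError(f"mode must be 'directed' or 'undirected', got {mode!r}")
    base = _attach_pair_metrics(base)
    return _attach_pc_scores(base, pca_result, n_components)


def build_feature_table(
    rate_table: pd.DataFrame,
    pca_result: PCAResult,
    n_components: int = 2,
) -> pd.DataFrame:
    """Join a pair-rate table with PC scores and genetic-code metrics.

    The rate table fixes the mode (directed/undirected); PC scores computed
    on the 190 unordered pairs are replicated to both directions of a
    directed table, since every covariate is symmetric in the pair.
    """
    out = _attach_pair_metrics(rate_table)
    out = _attach_pc_scores(out, pca_result, n_components)
    out.attrs.update(rate_table.attrs)
    return out
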