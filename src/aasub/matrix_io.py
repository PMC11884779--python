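"""Reading, writing and tabulating empirical amino-acid substitution models.

Two model flavours are supported, matching the text dialects used by PAML and
IQ-TREE:

* **Time-reversible** models: 190 lower-triangular exchangeabilities
  ``s_ij`` plus 20 equilibrium frequencies ``pi``.  The instantaneous
  substitution rate from amino acid *i* to *j* is ``Q_ij = s_ij * pi_j``
  (detailed balance holds by construction).
* **Time non-reversible** models: a full 20x20 matrix of directed rates
  ``q_ij``, optionally followed by frequencies.  No detailed-balance
  constraint.

All matrices use the PAML amino-acid order.  Files are whitespace-separated
ASCII floats; blank lines and ``#`` comments are tolerated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import AA_ORDER

__all__ = [
    "ExchangeModel",
    "NonreversibleModel",
    "read_reversible_model",
    "read_nonreversible_model",
    "write_reversible_model",
    "write_nonreversible_model",
    "to_rate_table",
    "write_rate_table",
    "read_rate_table",
    "matrix_similarity",
    "ModelFormatError",
    "DegenerateRateError",
]


class ModelFormatError(ValueError):
    """Malformed model file (wrong count, bad token, bad frequencies)."""


class DegenerateRateError(ValueError):
    """A zero or negative rate would enter the log transform."""


@dataclass
class ExchangeModel:
    """Symmetric exchangeabilities + equilibrium frequencies (reversible)."""

    s: np.ndarray
    pi: np.ndarray
    name: str = ""
    reversible: bool = field(default=True, init=False)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.s.shape != (20, 20):
            raise ValueError(f"s must be 20x20, got {self.s.shape}")
        if self.pi.shape != (20,):
            raise ValueError(f"pi must have 20 entries, got {self.pi.shape}")
        if not np.allclose(self.s, self.s.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(np.diag(self.s) != 0):
            raise ValueError("exchangeability diagonal must be zero")
        if np.any(self.s < 0):
            raise ValueError("negative exchangeability value")
        if np.any(self.pi <= 0):
            raise ValueError("all equilibrium frequencies must be positive")
        total = self.pi.sum()
        if abs(total - 1.0) > 1e-4:
            raise ModelFormatError(
                f"equilibrium frequencies sum to {total:.6g}, expected 1 within 1e-4"
            )
        if abs(total - 1.0) > 1e-6:
            self.pi = self.pi / total


@dataclass
class NonreversibleModel:
    """Full matrix of directed rates; diagonal is ignored on input."""

    q: np.ndarray
    pi: np.ndarray | None = None
    name: str = ""
    reversible: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (20, 20):
            raise ValueError(f"q must be 20x20, got {self.q.shape}")
        off = self.q[~np.eye(20, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("negative off-diagonal rate")
        # store with the convention diagonal = -row sum of off-diagonals
        q = self.q.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        self.q = q
        if self.pi is not None:
            self.pi = np.asarray(self.pi, dtype=float)
            if self.pi.shape != (20,):
                raise ValueError("pi must have 20 entries")


def _numeric_tokens(path: str | Path) -> list[float]:
    tokens: list[float] = []
    for line in Path(path).read_text().splitlines():
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        for tok in body.split():
            try:
                tokens.append(float(tok))
            except ValueError as exc:
                raise ModelFormatError(
                    f"{path}: non-numeric token {tok!r}"
                ) from exc
    return tokens


def read_reversible_model(path: str | Path, name: str | None = None) -> ExchangeModel:
    """Parse a PAML-style reversible model: 190 lower-triangle values + 20 frequencies."""
    vals = _numeric_tokens(path)
    if len(vals) != 210:
        raise ModelFormatError(
            f"{path}: expected 210 values (190 exchangeabilities + 20 frequencies), "
            f"found {len(vals)}"
        )
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = vals[k]
            k += 1
    pi = np.array(vals[190:])
    if np.any(s < 0):
        raise ModelFormatError(f"{path}: negative exchangeability value")
    return ExchangeModel(s=s, pi=pi, name=name or Path(path).stem)


def read_nonreversible_model(
    path: str | Path, name: str | None = None
) -> NonreversibleModel:
    """Parse a full 20x20 rate matrix, optionally followed by 20 frequencies."""
    vals = _numeric_tokens(path)
    if len(vals) == 400:
        pi = None
    elif len(vals) == 420:
        pi = np.array(vals[400:])
    else:
        raise ModelFormatError(
            f"{path}: expected 400 values (full matrix) or 420 (matrix + frequencies), "
            f"found {len(vals)}"
        )
    q = np.array(vals[:400]).reshape(20, 20)
    off = q[~np.eye(20, dtype=bool)]
    if np.any(off < 0):
        raise ModelFormatError(f"{path}: negative off-diagonal rate")
    return NonreversibleModel(q=q, pi=pi, name=name or Path(path).stem)


def write_reversible_model(model: ExchangeModel, path: str | Path) -> None:
    lines = []
    for i in range(1, 20):
        lines.append(" ".join(f"{model.s[i, j]:.10g}" for j in range(i)))
    lines.append("")
    lines.append(" ".join(f"{p:.10g}" for p in model.pi))
    Path(path).write_text("\n".join(lines) + "\n")


def write_nonreversible_model(model: NonreversibleModel, path: str | Path) -> None:
    q = model.q.copy()
    np.fill_diagonal(q, 0.0)
    lines = [" ".join(f"{v:.10g}" for v in row) for row in q]
    if model.pi is not None:
        lines.append("")
        lines.append(" ".join(f"{p:.10g}" for p in model.pi))
    Path(path).write_text("\n".join(lines) + "\n")


def _directed_rates(model: ExchangeModel | NonreversibleModel) -> np.ndarray:
    if isinstance(model, ExchangeModel):
        return model.s * model.pi[np.newaxis, :]
    q = model.q.copy()
    np.fill_diagonal(q, 0.0)
    return q


def to_rate_table(
    model: ExchangeModel | NonreversibleModel,
    mode: str = "directed",
    normalize: bool = False,
    log_base: float = math.e,
) -> pd.DataFrame:
    """Per-pair substitution rates and log rates.

    Parameters
    ----------
    mode
        ``"directed"`` gives 380 rows (``aa_from``, ``aa_to``); ``"undirected"``
        gives 190 rows (``aa1`` < ``aa2`` in PAML order) where the rate is the
        arithmetic mean of the two directed rates.
    normalize
        Divide all rates by their mean before taking logs.  Only relative
        rates matter to regression slopes; normalization shifts the intercept.
    log_base
        Base of the log transform (natural log by default).
    """
    if mode not in ("directed", "undirected"):
        raise ValueError(f"mode must be 'directed' or 'undirected', got {mode!r}")
    rates = _directed_rates(model)
    rows = []
    if mode == "directed":
        for i, a in enumerate(AA_ORDER):
            for j, b in enumerate(AA_ORDER):
                if i != j:
                    rows.append((a, b, rates[i, j]))
        tab = pd.DataFrame(rows, columns=["aa_from", "aa_to", "rate"])
    else:
        for i in range(20):
            for j in range(i + 1, 20):
                rows.append(
                    (AA_ORDER[i], AA_ORDER[j], 0.5 * (rates[i, j] + rates[j, i]))
                )
        tab = pd.DataFrame(rows, columns=["aa1", "aa2", "rate"])
    if normalize:
        tab["rate"] = tab["rate"] / tab["rate"].mean()
    bad = tab[tab["rate"] <= 0]
    if len(bad):
        pairs = ", ".join("-".join(r[:2]) for r in bad.itertuples(index=False))
        raise DegenerateRateError(
            f"model {model.name!r}: zero/negative rate for pairs: {pairs}"
        )
    tab["log_rate"] = np.log(tab["rate"].to_numpy()) / math.log(log_base)
    tab.attrs["mode"] = mode
    tab.attrs["log_base"] = log_base
    tab.attrs["normalized"] = normalize
    tab.attrs["model_name"] = model.name
    return tab


def write_rate_table(tab: pd.DataFrame, path: str | Path) -> None:
    """Write a pair-rate table as CSV plus a JSON metadata sidecar.

    The sidecar (``<path>.meta.json``) records the model name, mode, log
    base and normalization flag, so a table on disk is self-describing.
    """
    import json

    path = Path(path)
    tab.to_csv(path, index=False)
    meta = {
        "model_name": tab.attrs.get("model_name"),
        "mode": tab.attrs.get("mode"),
        "log_base": tab.attrs.get("log_base"),
        "normalized": tab.attrs.get("normalized"),
        "n_rows": int(len(tab)),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_rate_table(path: str | Path) -> pd.DataFrame:
    """Read a pair-rate table written by :func:`write_rate_table`."""
    import json

    tab = pd.read_csv(path)
    sidecar = Path(str(path) + ".meta.json")
    if sidecar.exists():
        tab.attrs.update(json.loads(sidecar.read_text()))
    return tab


def matrix_similarity(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Pearson correlation of log rates between two pair-rate tables.

    Both tables must be in the same mode; rows are matched on the pair key,
    so row order does not matter.
    """
    mode_a, mode_b = a.attrs.get("mode"), b.attrs.get("mode")
    if mode_a != mode_b:
        raise ValueError(f"mode mismatch: {mode_a!r} vs {mode_b!r}")
    keys = ["aa_from", "aa_to"] if "aa_from" in a.columns else ["aa1", "aa2"]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"), validate="one_to_one")
    if len(merged) != len(a):
        raise ValueError("pair keys do not match between tables")
    r, _ = stats.pearsonr(merged["log_rate_a"], merged["log_rate_b"])
    return float(r)
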