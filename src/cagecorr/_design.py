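"""Design-matrix construction shared by the estimation modules.

Numeric columns enter as-is; categorical/object/bool columns are expanded
to indicator contrasts (treatment coding, first level dropped, or
sum-to-zero coding where a centered effect per level is needed).  An
intercept column is always first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_design", "find_aliased"]


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s)


def build_design(df: pd.DataFrame, terms, coding: str = "treatment"):
    """Build (X, names, spans) for ``terms`` with an intercept.

    ``spans`` maps each term to the slice of its columns in X, used for
    joint Wald tests on multi-level factors.  ``coding`` applies to
    categorical terms: ``treatment`` drops the first level; ``sum`` uses
    sum-to-zero contrasts (last level = minus the sum of the others).
    """
    n = len(df)
    cols = [np.ones(n)]
    names = ["Intercept"]
    spans: dict[str, slice] = {}
    for term in terms:
        if term not in df.columns:
            raise KeyError(f"column {term!r} not in data "
                           f"(have {list(df.columns)})")
        s = df[term]
        start = len(names)
        if _is_numeric(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(term)
        else:
            codes, levels = pd.factorize(s, sort=True)
            if len(levels) < 2:
                # constant factor contributes nothing beyond the intercept
                spans[term] = slice(start, start)
                continue
            L = len(levels)
            ind = np.zeros((n, L))
            ind[np.arange(n), codes] = 1.0
            if coding == "treatment":
                for j in range(1, L):
                    cols.append(ind[:, j])
                    names.append(f"{term}[{levels[j]}]")
            elif coding == "sum":
                for j in range(L - 1):
                    cols.append(ind[:, j] - ind[:, L - 1])
                    names.append(f"{term}[S.{levels[j]}]")
            else:
                raise ValueError(f"unknown coding {coding!r}")
        spans[term] = slice(start, len(names))
    X = np.column_stack(cols)
    return X, names, spans


def find_aliased(X: np.ndarray, names) -> list[str]:
    """Names of columns linearly dependent on earlier columns (QR pivot)."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return [names[j] for j in sorted(piv[rank:])]
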