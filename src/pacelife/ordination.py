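"""PCA / phylogenetic PCA machinery with broken-stick retention.

All trait tables are log-transformed (fecundity shifted by +1 first so
that zero annual fecundity stays finite) and z-scored with the sample
(n-1) standard deviation before any eigen-decomposition.  The plain PCA
eigen-decomposes the sample covariance of the standardized matrix; the
phylogenetic PCA eigen-decomposes the evolutionary covariance

    R = (Z - 1a)' C^-1 (Z - 1a) / (n - 1),

where C is the Brownian-motion tree covariance and a the GLS mean, with
scores taken as (Z - 1a) V.  Standardization is ordinary (non-
phylogenetic); the pPCA then centers on the phylogenetic mean
internally.

Component retention follows the broken-stick null: component i is
interpretable only while its variance proportion exceeds the expected
share b_i = (1/k) sum_{j=i..k} 1/j of a stick broken at random into k
pieces, applied sequentially from the first component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import phylo_mean, _ensure_invertible

__all__ = [
    "TransformedMatrix",
    "OrdinationResult",
    "transform",
    "pca",
    "phylo_pca",
    "broken_stick",
    "retain_components",
    "relative_importance",
    "canonicalize_signs",
]

_ZERO_VAR_TOL = 1e-12


class TransformError(ValueError):
    pass


@dataclass
class TransformedMatrix:
    """Log-transformed, standardized trait matrix with transform metadata."""

    values: np.ndarray            # rows x retained traits
    row_labels: list[str]
    columns: list[str]            # retained trait names, input order
    dropped: list[str]            # zero-variance traits, never silently kept
    zero_filled: list[str]        # constant traits kept as all-zero columns
    meta: dict                    # per trait: plus_one, mean, sd (log scale)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.columns)


def transform(
    raw: pd.DataFrame,
    fecundity_plus_one: bool = True,
    fecundity_column: str = "fecundity",
    on_constant: str = "drop",
) -> TransformedMatrix:
    """Natural-log then z-score each trait column.

    Parameters
    ----------
    raw : DataFrame
        Rows are species or individuals, columns are traits; all values
        must be strictly positive after the fecundity +1 shift.
    fecundity_plus_one : bool
        Add 1 to the fecundity column before the log, so individuals that
        bred without ever producing an independent offspring (fecundity 0)
        remain usable.
    on_constant : {"drop", "zero"}
        Zero-variance columns are either dropped (reducing the component
        count k downstream) or kept as all-zero columns -- the latter is
        used when projecting individuals onto axes fitted elsewhere, where
        the column set must stay aligned with the loadings.
    """
    if on_constant not in ("drop", "zero"):
        raise ValueError("on_constant must be 'drop' or 'zero'")
    X = raw.astype(float).copy()
    meta: dict = {}
    if fecundity_plus_one and fecundity_column in X.columns:
        X[fecundity_column] = X[fecundity_column] + 1.0
    for col in X.columns:
        bad = X.index[X[col] <= 0]
        if len(bad):
            raise TransformError(
                f"non-positive value before log in column {col!r}, "
                f"row {bad[0]!r}"
            )
    logged = np.log(X)
    cols, dropped, zero_filled = [], [], []
    out = []
    for col in X.columns:
        v = logged[col].to_numpy()
        mu = float(v.mean())
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        meta[col] = {
            "plus_one": bool(fecundity_plus_one and col == fecundity_column),
            "mean": mu,
            "sd": sd,
        }
        if sd <= _ZERO_VAR_TOL:
            if on_constant == "drop":
                dropped.append(col)
                continue
            zero_filled.append(col)
            out.append(np.zeros_like(v))
            cols.append(col)
        else:
            out.append((v - mu) / sd)
            cols.append(col)
    if not cols:
        raise TransformError("all trait columns have zero variance")
    return TransformedMatrix(
        values=np.column_stack(out),
        row_labels=[str(i) for i in raw.index],
        columns=cols,
        dropped=dropped,
        zero_filled=zero_filled,
        meta=meta,
    )


@dataclass
class OrdinationResult:
    """Eigenvalues, loadings, scores and retention flags of one PCA/pPCA."""

    eigenvalues: np.ndarray       # descending
    loadings: np.ndarray          # traits x components, unit-norm columns
    scores: np.ndarray            # rows x components
    proportions: np.ndarray       # eigenvalues / sum
    columns: list[str]            # trait names (loading rows)
    row_labels: list[str]
    mode: str                     # "plain" | "phylogenetic"
    retained: np.ndarray | None = None
    sign_flips: list[int] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.columns)

    def loadings_frame(self) -> pd.DataFrame:
        pcs = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.columns, columns=pcs)

    def scores_frame(self) -> pd.DataFrame:
        pcs = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.row_labels, columns=pcs)


def _eigen_sorted(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, V = np.linalg.eigh(S)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    V = V[:, order]
    # deterministic orientation: make each column's largest-|.| entry
    # positive (tie -> lowest trait index); canonicalize_signs may flip
    # PC1 again against the anchor trait
    for j in range(V.shape[1]):
        a = np.abs(V[:, j])
        i = int(np.flatnonzero(a == a.max())[0])
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return lam, V


def pca(Z: TransformedMatrix) -> OrdinationResult:
    """Plain PCA of the covariance of a standardized trait matrix."""
    X = Z.values
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if X.shape[1] < 2:
        raise ValueError(
            "PCA needs at least 2 varying traits; a continuum is undefined "
            f"with k = {X.shape[1]}"
        )
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / (X.shape[0] - 1)
    lam, V = _eigen_sorted(S)
    lam = np.clip(lam, 0.0, None)
    return OrdinationResult(
        eigenvalues=lam,
        loadings=V,
        scores=Xc @ V,
        proportions=lam / lam.sum(),
        columns=list(Z.columns),
        row_labels=list(Z.row_labels),
        mode="plain",
    )


def phylo_pca(
    Z: TransformedMatrix, C: np.ndarray, ridge_log: list | None = None
) -> OrdinationResult:
    """Phylogenetic PCA of species trait data under tree covariance C.

    With C = identity this reduces exactly to :func:`pca` on the
    column-centered matrix (star-phylogeny equivalence).
    """
    X = Z.values
    n = X.shape[0]
    if C.shape != (n, n):
        raise ValueError(f"C is {C.shape} but Z has {n} rows")
    if X.shape[1] < 2:
        raise ValueError("pPCA needs at least 2 varying traits")
    Creg = _ensure_invertible(C, ridge_log)
    a = phylo_mean(X, Creg)
    Xc = X - a
    R = (Xc.T @ np.linalg.solve(Creg, Xc)) / (n - 1)
    lam, V = _eigen_sorted(R)
    lam = np.clip(lam, 0.0, None)
    return OrdinationResult(
        eigenvalues=lam,
        loadings=V,
        scores=Xc @ V,
        proportions=lam / lam.sum(),
        columns=list(Z.columns),
        row_labels=list(Z.row_labels),
        mode="phylogenetic",
    )


def broken_stick(k: int) -> np.ndarray:
    """Broken-stick expected variance proportions b_1..b_k.

    b_i = (1/k) * sum_{j=i..k} 1/j; sums to 1, strictly decreasing.  For
    k = 4 the leading share is 0.5208…, i.e. the familiar 52% retention
    threshold for PC1 of a four-trait analysis.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    inv = 1.0 / np.arange(1, k + 1)
    return np.cumsum(inv[::-1])[::-1] / k


def retain_components(
    result: OrdinationResult, bs: np.ndarray | None = None
) -> np.ndarray:
    """Sequential broken-stick retention flags.

    Component i is retained iff p_i > b_i strictly, walking from PC1 and
    stopping at the first failure (later components are never retained
    once an earlier one fails).
    """
    if bs is None:
        bs = broken_stick(result.k)
    if len(bs) != len(result.proportions):
        raise ValueError("broken-stick length does not match component count")
    flags = np.zeros(len(bs), dtype=bool)
    for i, (p, b) in enumerate(zip(result.proportions, bs)):
        if p > b:
            flags[i] = True
        else:
            break
    result.retained = flags
    return flags


def relative_importance(V: np.ndarray) -> np.ndarray:
    """Per-trait relative importance: |loading| / row sum of |loadings|."""
    A = np.abs(np.asarray(V, dtype=float))
    row_sums = A.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("trait with all-zero loadings")
    return A / row_sums[:, None]


def canonicalize_signs(
    result: OrdinationResult, anchor_trait: str = "adult_lifespan"
) -> OrdinationResult:
    """Fix the arbitrary sign of each component, in place.

    PC1 is flipped so the anchor trait (adult lifespan by convention, the
    slow end of the continuum) loads negatively; every other component is
    flipped iff its largest-magnitude loading is negative (ties broken by
    lowest trait index).  Idempotent.
    """
    if anchor_trait not in result.columns:
        raise ValueError(f"anchor trait {anchor_trait!r} not in {result.columns}")
    ai = result.columns.index(anchor_trait)
    flips = []
    for j in range(result.loadings.shape[1]):
        if j == 0:
            flip = result.loadings[ai, 0] > 0
        else:
            a = np.abs(result.loadings[:, j])
            i = int(np.flatnonzero(a == a.max())[0])
            flip = result.loadings[i, j] < 0
        if flip:
            result.loadings[:, j] = -result.loadings[:, j]
            result.scores[:, j] = -result.scores[:, j]
            flips.append(j + 1)
    result.sign_flips = flips
    return result
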