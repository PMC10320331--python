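"""Decision layer: the four-condition slow-fast verdict and cross-level tools.

A slow-fast continuum is deemed present in an ordination when, on the
sign-canonicalized PC1:

  (i)   PC1 is retained by the broken-stick rule;
  (ii)  the two time-duration traits (age at first reproduction, adult
        lifespan) load with the same sign;
  (iii) the two time-frequency traits (breeding frequency, fecundity)
        load with the same sign;
  (iv)  the duration block and the frequency block load with opposite
        signs.

The cross-level test rotates each species' standardized individual data
by the interspecific eigenvectors and compares the share of rotated
variance on pPC1 with the interspecific pPC1 share: individuals whose
variation is not organized along the across-species axis put most of
their rotated variance elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ordination import OrdinationResult, TransformedMatrix, broken_stick
from .records import TRAITS

__all__ = [
    "SlowFastVerdict",
    "VerdictUndefined",
    "slow_fast_verdict",
    "ProjectionResult",
    "project_individuals",
    "EllipseParams",
    "data_ellipse",
    "RegressionSummary",
    "ols",
    "cross_level_report",
]

_DURATION = ("afr", "adult_lifespan")
_FREQUENCY = ("breeding_frequency", "fecundity")


class VerdictUndefined(ValueError):
    """A verdict cannot be evaluated (a required trait dropped out)."""


@dataclass(frozen=True)
class SlowFastVerdict:
    pc1_retained: bool
    duration_coherent: bool
    frequency_coherent: bool
    opposition: bool
    p1: float
    b1: float
    pc1_loadings: dict[str, float]

    @property
    def present(self) -> bool:
        return (
            self.pc1_retained
            and self.duration_coherent
            and self.frequency_coherent
            and self.opposition
        )


def slow_fast_verdict(
    result: OrdinationResult, bs: np.ndarray
) -> SlowFastVerdict:
    """Evaluate the four presence conditions on canonicalized PC1 loadings.

    Raises :class:`VerdictUndefined` if any of the four traits was dropped
    for zero variance -- species where, say, breeding frequency does not
    vary among individuals cannot be assessed for the continuum at all.
    """
    missing = [t for t in TRAITS if t not in result.columns]
    if missing:
        raise VerdictUndefined(
            f"trait(s) {missing} absent (no variance); the slow-fast "
            "continuum cannot be evaluated"
        )
    idx = {t: result.columns.index(t) for t in TRAITS}
    l1 = {t: float(result.loadings[idx[t], 0]) for t in TRAITS}
    p1 = float(result.proportions[0])
    b1 = float(bs[0])
    dur = [l1[t] for t in _DURATION]
    freq = [l1[t] for t in _FREQUENCY]
    duration_coherent = dur[0] * dur[1] > 0
    frequency_coherent = freq[0] * freq[1] > 0
    opposition = dur[0] * freq[0] < 0
    return SlowFastVerdict(
        pc1_retained=p1 > b1,
        duration_coherent=duration_coherent,
        frequency_coherent=frequency_coherent,
        opposition=opposition and duration_coherent and frequency_coherent,
        p1=p1,
        b1=b1,
        pc1_loadings=l1,
    )


@dataclass
class ProjectionResult:
    """Individual data rotated onto interspecific axes, per species."""

    scores: dict[str, np.ndarray]          # species -> individuals x PCs
    variances: pd.DataFrame                # species x PCs, var of rotated scores
    pc1_share: pd.Series                   # species -> var share on pPC1
    columns: list[str]                     # trait order of the loadings used

    def shares(self) -> pd.DataFrame:
        v = self.variances
        return v.div(v.sum(axis=1), axis=0)


def project_individuals(
    Z_by_species: dict[str, TransformedMatrix],
    interspecific: OrdinationResult,
) -> ProjectionResult:
    """Rotate each species' standardized individual matrix by V.

    Each species' matrix must carry exactly the traits (and order) of the
    interspecific loadings; V being orthonormal, the total rotated
    variance equals the total pre-rotation variance per species.
    """
    V = interspecific.loadings
    cols = list(interspecific.columns)
    scores, var_rows, labels = {}, [], []
    for sp, Z in Z_by_species.items():
        if list(Z.columns) != cols:
            raise ValueError(
                f"species {sp!r}: trait order {Z.columns} does not match "
                f"loadings order {cols}"
            )
        U = Z.values @ V
        scores[sp] = U
        var_rows.append(U.var(axis=0, ddof=1) if U.shape[0] > 1 else U.var(axis=0))
        labels.append(sp)
    pcs = [f"PC{i + 1}" for i in range(V.shape[1])]
    variances = pd.DataFrame(var_rows, index=labels, columns=pcs)
    totals = variances.sum(axis=1)
    pc1_share = variances.iloc[:, 0] / totals
    pc1_share.name = "pc1_share"
    return ProjectionResult(
        scores=scores, variances=variances, pc1_share=pc1_share, columns=cols
    )


@dataclass(frozen=True)
class EllipseParams:
    center: tuple[float, float]
    semi_axes: tuple[float, float]     # major, minor
    angle: float                       # radians, major axis vs x-axis
    coverage: float
    degenerate: bool


def data_ellipse(scores: np.ndarray, coverage: float = 0.95) -> EllipseParams:
    """Data ellipse of a bivariate point cloud.

    The ellipse is centered on the column means with axes along the
    eigenvectors of the 2x2 sample covariance, semi-axis lengths
    sqrt(lambda_i * q) with q the chi-square(2) quantile at the coverage
    level.  A rank-deficient covariance collapses the ellipse to a
    segment, flagged rather than raised.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("scores must be an n x 2 matrix")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points for a data ellipse")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    center = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1)
    lam, V = np.linalg.eigh(S)
    lam = np.clip(lam[::-1], 0.0, None)    # descending
    V = V[:, ::-1]
    q = stats.chi2.ppf(coverage, df=2)
    axes = np.sqrt(lam * q)
    angle = math.atan2(V[1, 0], V[0, 0])
    return EllipseParams(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(axes[0]), float(axes[1])),
        angle=angle,
        coverage=coverage,
        degenerate=bool(lam[1] <= 1e-12 * max(lam[0], 1.0)),
    )


@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    p_value: float
    n: int


def ols(x, y) -> RegressionSummary:
    """Simple ordinary-least-squares fit with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("OLS needs n >= 3")
    if np.var(x) == 0:
        raise ValueError("constant predictor")
    fit = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def cross_level_report(
    interspecific: OrdinationResult,
    projections: ProjectionResult,
    per_species: dict[str, OrdinationResult],
    per_species_verdicts: dict[str, SlowFastVerdict | None],
    bs_full: np.ndarray,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-species cross-level summary plus the mean within-species spectrum.

    Returns
    -------
    table : DataFrame
        One row per species: rotated pPC1 share, interspecific p1, the
        alignment flag (rotated share < interspecific p1 means the
        species' individual variation fails to align with the
        across-species axis), own-PCA p1 and its broken-stick threshold,
        and the within-species verdict.
    within_spectrum : Series
        Mean per-component variance proportion over species whose own PCA
        kept the full trait set -- the "within" bars next to the
        interspecific spectrum.
    """
    inter_p1 = float(interspecific.proportions[0])
    rows = []
    for sp in projections.pc1_share.index:
        rotated = float(projections.pc1_share[sp])
        own = per_species.get(sp)
        verdict = per_species_verdicts.get(sp)
        row = {
            "species": sp,
            "rotated_pc1_share": rotated,
            "interspecific_p1": inter_p1,
            "aligned": rotated >= inter_p1,
            "own_p1": float(own.proportions[0]) if own is not None else math.nan,
            "own_k": own.k if own is not None else 0,
            "own_b1": math.nan if own is None else float(broken_stick(own.k)[0]),
            "verdict_defined": verdict is not None,
            "verdict_present": bool(verdict.present) if verdict is not None else False,
        }
        rows.append(row)
    table = pd.DataFrame(rows).set_index("species")

    k_full = len(bs_full)
    full = [
        sp for sp, own in per_species.items()
        if own is not None and own.k == k_full
    ]
    if full:
        mat = np.vstack([per_species[sp].proportions for sp in full])
        within = pd.Series(
            mat.mean(axis=0), index=[f"PC{i + 1}" for i in range(k_full)]
        )
    else:
        within = pd.Series(dtype=float)
    within.name = "mean_within_proportion"
    return table, within
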