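"""Compositional accuracy metrics: CLR, grading, diversity, similarity.

Sequencing counts are compositional — only relative information is
meaningful — so observed and theoretical profiles are compared in
centered log-ratio (CLR) coordinates:

    clr_i = ln(x_i / g(x)),   g(x) = geometric mean,

which are scale-invariant and sum to zero.  Zeros are first replaced
multiplicatively with a pseudo-proportion of half the smallest nonzero
proportion.  Accuracy per taxon is graded against the theoretical CLR
value as a relative percent error: within +/-5% "+", within +/-25%
"○", beyond "-", and "×" for taxa the reference database does
not register at all.  Shannon diversity uses log base 2; rank
concordance with theory is Spearman's correlation; between-sample
structure comes from PCA of the CLR matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GRADE_ACCURATE",
    "GRADE_FAIR",
    "GRADE_POOR",
    "GRADE_UNREGISTERED",
    "GradingThresholds",
    "filter_low_abundance",
    "shannon",
    "multiplicative_zero_replacement",
    "clr_transform",
    "grade_accuracy",
    "grade_table",
    "spearman_vs_theory",
    "pca_clr",
]

GRADE_ACCURATE = "+"
GRADE_FAIR = "○"  # ○
GRADE_POOR = "-"
GRADE_UNREGISTERED = "×"  # ×


@dataclass(frozen=True)
class GradingThresholds:
    """Percent-error bounds of the accuracy grades (inner 5, outer 25)."""

    inner: float = 5.0
    outer: float = 25.0

    def __post_init__(self) -> None:
        if not 0 < self.inner < self.outer:
            raise ValueError(f"need 0 < inner < outer, got {self.inner}, {self.outer}")


def filter_low_abundance(table: pd.DataFrame, min_mean: float = 1.0) -> pd.DataFrame:
    """Drop rows whose mean count across samples is below ``min_mean``.

    The comparison is strict ("fewer than one read on average"), so a
    row averaging exactly 1.0 is retained.
    """
    if table.empty:
        return table
    return table.loc[table.mean(axis=1) >= min_mean]


def shannon(counts: Sequence[float] | np.ndarray | pd.Series, base: float = 2.0) -> float:
    """Shannon diversity of a count vector (base 2 by default).

    Uniform over k taxa gives log2(k): ~3.907 bits for 15 taxa, ~2.585
    for 6.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be 1-D")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("Shannon index needs at least one positive count")
    return float(sps.entropy(x, base=base))


def multiplicative_zero_replacement(x: np.ndarray | Sequence[float]) -> np.ndarray:
    """Closure to proportions with zeros replaced multiplicatively.

    Zeros become delta = 0.5 * (smallest nonzero proportion); nonzero
    proportions are shrunk by the factor (1 - n_zeros * delta) so the
    vector still sums to 1.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("composition must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero composition")
    p = x / total
    zero = p == 0
    if not zero.any():
        return p
    delta = 0.5 * p[~zero].min()
    out = np.where(zero, delta, p * (1.0 - zero.sum() * delta))
    return out


def clr_transform(x: np.ndarray | Sequence[float] | pd.Series) -> np.ndarray:
    """Centered log-ratio coordinates of a non-negative composition.

    Zeros are replaced first (see ``multiplicative_zero_replacement``).
    The result sums to zero (to 1e-10) and is invariant to rescaling the
    input by any positive scalar.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("clr needs a 1-D composition with >= 2 components")
    p = multiplicative_zero_replacement(arr)
    logs = np.log(p)
    out = logs - logs.mean()
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index)
    return out


def grade_accuracy(
    observed: float,
    theoretical: float,
    registered: bool = True,
    thresholds: GradingThresholds = GradingThresholds(),
) -> str:
    """Accuracy symbol for one taxon.

    The error is the relative percent difference of the observed CLR
    value from the theoretical one, ``100 * (obs - theo) / |theo|``:
    within the inner band "+", within the outer band "○", beyond
    "-".  Unregistered taxa are "×" regardless of values.  When the
    theoretical value is exactly 0 the relative error is undefined and
    an absolute-difference fallback (same bands read as absolute CLR
    units / 100) is used with a warning.
    """
    if not registered:
        return GRADE_UNREGISTERED
    if theoretical == 0:
        warnings.warn(
            "theoretical CLR is 0; grading on absolute difference", stacklevel=2
        )
        err = 100.0 * abs(observed - theoretical)
    else:
        err = 100.0 * abs(observed - theoretical) / abs(theoretical)
    if err <= thresholds.inner:
        return GRADE_ACCURATE
    if err <= thresholds.outer:
        return GRADE_FAIR
    return GRADE_POOR


def grade_table(
    observed: pd.Series,
    theoretical: pd.Series,
    registered: set[str] | Sequence[str] | None = None,
    thresholds: GradingThresholds = GradingThresholds(),
) -> pd.Series:
    """Grade every taxon of an observed CLR vector against theory.

    Both series are aligned on the theoretical index; ``registered``
    lists the taxa the database knows (default: all).
    """
    reg = set(registered) if registered is not None else set(theoretical.index)
    return pd.Series(
        {
            taxon: grade_accuracy(
                float(observed.get(taxon, np.nan)),
                float(theoretical[taxon]),
                registered=taxon in reg,
                thresholds=thresholds,
            )
            for taxon in theoretical.index
        },
        name="grade",
    )


def spearman_vs_theory(
    observed: Sequence[float] | pd.Series, theoretical: Sequence[float] | pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, two-sided p).

    Returns (nan, nan) with a warning when either vector is constant.
    """
    obs = np.asarray(observed, dtype=float)
    theo = np.asarray(theoretical, dtype=float)
    if obs.shape != theo.shape or obs.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if obs.size < 3:
        raise ValueError("need at least 3 matched taxa")
    if np.ptp(obs) == 0 or np.ptp(theo) == 0:
        warnings.warn("constant vector: Spearman r undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = sps.spearmanr(obs, theo)
    # identical (or exactly opposite) rankings have rho = +/-1 by
    # definition; avoid the roundoff of computing Pearson on ranks
    rx, ry = sps.rankdata(obs), sps.rankdata(theo)
    if np.array_equal(rx, ry):
        r = 1.0
    elif np.array_equal(rx, len(rx) + 1 - ry):
        r = -1.0
    return float(r), float(p)


def pca_clr(clr_matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a samples x taxa CLR matrix.

    Columns are mean-centered and decomposed by SVD; components are
    ordered by decreasing explained variance, and each component's sign
    is fixed so its largest-magnitude loading is positive.  Returns
    (coordinates as samples x PCs, explained variances).  The explained
    variances sum to the total variance of the centered matrix.
    """
    X = clr_matrix.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 taxa")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    coords = u * s
    var = s**2 / (X.shape[0] - 1)
    cols = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return pd.DataFrame(coords, index=clr_matrix.index, columns=cols), var
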