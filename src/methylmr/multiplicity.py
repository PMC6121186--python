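"""Family-wise testing thresholds, with correlation-aware effective counts.

Traits tested against the methylome are often strongly correlated (BMI and
obesity, say), so dividing alpha by the raw trait count over-corrects. The
effective number of independent tests is estimated from the eigenvalues
lambda_i of the trait correlation matrix (Li & Ji estimator, the basis of
spectral-decomposition methods for phenotype panels):

    Meff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]

Identity correlation gives Meff = M; perfect correlation gives Meff = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


def effective_tests(correlation_matrix) -> float:
    """Li–Ji effective number of independent tests for a correlation matrix.

    The input must be square, symmetric and unit-diagonal.
    """
    C = np.asarray(correlation_matrix, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have a unit diagonal")
    lam = np.linalg.eigvalsh((C + C.T) / 2.0)
    # the floor/indicator bookkeeping is discontinuous at integer
    # eigenvalues; round to 10 decimals so lambda = 2 - 1e-16 counts as 2
    lam = np.round(np.clip(lam, 0.0, None), 10)
    meff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return meff


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class ThresholdPlan:
    """The multiplicity bookkeeping for one pipeline stage."""

    stage: str
    n_tests: int
    meff: Optional[float] = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.meff is not None and not (1 <= self.meff <= self.n_tests + 1e-9):
            raise ValueError("Meff must lie in [1, raw test count]")

    @property
    def threshold(self) -> float:
        denom = self.meff if self.meff is not None else self.n_tests
        return self.alpha / denom

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_tests": int(self.n_tests),
            "meff": None if self.meff is None else float(self.meff),
            "alpha": self.alpha,
            "threshold": self.threshold,
        }


def zscore_trait_correlation(z: pd.DataFrame) -> np.ndarray:
    """Trait correlation estimated from MR z-scores across CpGs (rows are
    CpGs, columns traits) — the fallback when phenotypic correlations are
    unavailable."""
    C = np.corrcoef(z.to_numpy(dtype=float), rowvar=False)
    np.fill_diagonal(C, 1.0)
    return C
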