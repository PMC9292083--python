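"""Shared linear-bilinear (SVD) machinery for the AMMI and GGE models.

Both models decompose a centered genotype x environment residual matrix by
singular value decomposition into multiplicative terms
lambda_k * alpha_ik * gamma_jk with orthonormal score/loading columns; they
differ only in what is removed before the SVD (AMMI: both main effects;
GGE: environment means only).  Sign ambiguity of each SVD axis is resolved
deterministically by flipping so that the largest-magnitude environment
loading on the axis is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TwoWayMeans
from .errors import ValidationError


@dataclass
class BilinearFit:
    model_kind: str                  # "AMMI" | "GGE"
    grand_mean: float
    genotype_main: pd.Series | None  # AMMI only
    env_main: pd.Series
    singular_values: np.ndarray      # non-increasing
    genotype_scores: pd.DataFrame    # alpha columns IPC1.. (unit norm)
    env_loadings: pd.DataFrame       # gamma columns IPC1.. (unit norm)
    ss_table: pd.DataFrame
    K: int                           # retained axes
    table: TwoWayMeans = field(repr=False, default=None)

    @property
    def genotypes(self) -> list[str]:
        return list(self.genotype_scores.index)

    @property
    def environments(self) -> list[str]:
        return list(self.env_loadings.index)

    @property
    def interaction_ss(self) -> float:
        return float(np.sum(self.singular_values**2))

    def scaled_scores(self, exponent: float = 0.5, k: int | None = None) -> pd.DataFrame:
        """Genotype scores scaled as lambda^exponent * alpha."""
        k = k if k is not None else self.K
        lam = self.singular_values[:k] ** exponent
        return self.genotype_scores.iloc[:, :k] * lam

    def scaled_loadings(self, exponent: float = 0.5, k: int | None = None) -> pd.DataFrame:
        k = k if k is not None else self.K
        lam = self.singular_values[:k] ** exponent
        return self.env_loadings.iloc[:, :k] * lam

    def fitted_values(self, k: int | None = None) -> pd.DataFrame:
        """Model fitted values truncated at k multiplicative terms."""
        k = k if k is not None else self.K
        lowrank = (
            self.genotype_scores.to_numpy()[:, :k]
            @ np.diag(self.singular_values[:k])
            @ self.env_loadings.to_numpy()[:, :k].T
        )
        base = self.grand_mean + np.add.outer(
            (self.genotype_main.to_numpy() if self.genotype_main is not None
             else np.zeros(len(self.genotypes))),
            self.env_main.to_numpy(),
        )
        return pd.DataFrame(base + lowrank, index=self.genotypes, columns=self.environments)


def svd_decompose(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD with the deterministic sign convention (see module docstring)."""
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    V = Vt.T
    for k in range(len(s)):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] *= -1.0
            U[:, k] *= -1.0
    return U, s, V


def require_complete(table: TwoWayMeans) -> np.ndarray:
    if not table.is_complete:
        miss = np.argwhere(table.missing_mask)
        cells = [
            (table.genotypes[i], table.environments[j]) for i, j in miss[:10]
        ]
        raise ValidationError(
            f"table has {len(miss)} missing cell(s), e.g. {cells}; impute first"
        )
    return table.means
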