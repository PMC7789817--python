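"""Reference-based blood cell-type deconvolution.

Estimates leukocyte-subtype proportions per sample by constrained
projection of the sample's beta profile onto cell-type reference
profiles (non-negative weights summing to at most one). The estimated
proportions enter the differential model as confounder covariates, so
methylation differences driven by shifted blood composition are not
mistaken for a disease epi-signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class CellReference:
    """Cell-type reference beta profiles.

    ``profile`` is cell types x probes (values in [0, 1]); rows are the
    cell-type labels, columns the discriminating probe ids.
    """

    profile: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.profile.to_numpy(dtype=float)
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("reference profiles must be beta values in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profile.index)

    @property
    def probes(self) -> list[str]:
        return list(self.profile.columns)

    @classmethod
    def from_tsv(cls, path) -> "CellReference":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.profile.to_csv(path, sep="\t")


def _solve_one(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||R^T w - b||^2 subject to w >= 0, sum(w) <= 1."""
    k = R.shape[0]
    # quadratic objective in w; SLSQP handles the simplex-with-slack set
    A = R @ R.T
    c = R @ b

    def obj(w):
        return 0.5 * w @ A @ w - c @ w

    def grad(w):
        return A @ w - c

    cons = [{"type": "ineq", "fun": lambda w: 1.0 - w.sum(), "jac": lambda w: -np.ones(k)}]
    res = optimize.minimize(
        obj,
        x0=np.full(k, 1.0 / (k + 1)),
        jac=grad,
        bounds=[(0.0, 1.0)] * k,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None)
    if w.sum() > 1.0:
        w = w / w.sum()
    return w


def estimate_cell_proportions(
    sample_betas: pd.DataFrame | pd.Series, reference: CellReference
) -> pd.DataFrame:
    """Constrained least-squares projection of each sample onto the
    reference profiles.

    ``sample_betas`` is probes x samples (or a single Series); it must
    cover the reference's probe set. Returns samples x cell_types with
    non-negative entries summing to at most 1.
    """
    if isinstance(sample_betas, pd.Series):
        sample_betas = sample_betas.to_frame()
    missing = [p for p in reference.probes if p not in sample_betas.index]
    if missing:
        raise ValueError(f"sample betas do not cover reference probes (missing {len(missing)})")
    R = reference.profile.to_numpy(dtype=float)  # k x p
    if np.linalg.matrix_rank(R) < R.shape[0]:
        raise ValueError("reference profile matrix is rank-deficient")
    B = sample_betas.loc[reference.probes].to_numpy(dtype=float)  # p x n
    W = np.stack([_solve_one(R, B[:, j]) for j in range(B.shape[1])])
    return pd.DataFrame(W, index=sample_betas.columns, columns=reference.cell_types)
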