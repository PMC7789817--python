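"""Per-probe differential methylation with empirical-Bayes moderation.

The model regresses each probe's M values on a case/control indicator
plus confounder covariates (estimated blood cell proportions, and any
others supplied), shares information across probes by shrinking the
residual variances toward a common prior (moderated t-statistics), and
corrects the resulting p-values by Benjamini-Hochberg. Epi-signature
probes are those passing both an effect-size guard on the beta scale
(|delta beta| > 10%) and a corrected significance threshold (q < 0.01).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets import MethylationDataset
from .qc import beta_to_m


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_probe_models(
    m_matrix, design: pd.DataFrame | np.ndarray, group_col: int | str = "group"
) -> pd.DataFrame:
    """Ordinary least squares per probe against a shared design matrix.

    ``m_matrix`` is probes x samples; ``design`` is samples x covariates and
    must include an intercept column and the group indicator. Returns a
    frame with coef (group effect), se_unscaled (group-column leverage),
    s2 (residual variance), df (shared residual degrees of freedom).
    """
    M = np.asarray(m_matrix, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if M.shape[1] != n:
        raise ValueError("design rows must match the number of samples")
    if n <= p:
        raise ValueError("need more samples than design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        cols = (
            list(design.columns) if isinstance(design, pd.DataFrame) else list(range(p))
        )
        raise ValueError(f"design matrix is rank-deficient (columns: {cols})")
    if isinstance(design, pd.DataFrame) and isinstance(group_col, str):
        g = list(design.columns).index(group_col)
    else:
        g = int(group_col)

    XtX_inv = np.linalg.inv(X.T @ X)
    # all-probe OLS in one shot: B = M X (X'X)^{-1}
    B = M @ X @ XtX_inv
    resid = M - B @ X.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df
    se_unscaled = np.sqrt(XtX_inv[g, g])
    index = m_matrix.index if isinstance(m_matrix, pd.DataFrame) else pd.RangeIndex(M.shape[0])
    return pd.DataFrame(
        {"coef": B[:, g], "se_unscaled": se_unscaled, "s2": s2, "df": df}, index=index
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(s2, df: float) -> dict:
    """Empirical-Bayes variance shrinkage (method of moments on log s^2).

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed
    residual variances and returns posterior variances
    s~^2 = (d0 s0^2 + df s2) / (d0 + df) together with the prior. When the
    variances carry no excess spread beyond chi-square sampling noise the
    prior is degenerate (d0 = inf) and the posterior equals the common
    variance, so moderated t equals ordinary t.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise ValueError("variance moderation needs at least 10 probes")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    if np.allclose(s2, s2[0]):
        d0, s0_sq = np.inf, float(s2[0])
        post = np.full_like(s2, s0_sq)
        return {"d0": d0, "s0_sq": s0_sq, "s2_post": post}
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
        post = np.full_like(s2, s0_sq)
    return {"d0": float(d0), "s0_sq": s0_sq, "s2_post": post}


def moderated_t_test(fit: pd.DataFrame) -> pd.DataFrame:
    """Moderated t and two-sided p for the group coefficient of an OLS fit."""
    mod = moderate_variances(fit["s2"].to_numpy(), float(fit["df"].iloc[0]))
    se = fit["se_unscaled"].to_numpy() * np.sqrt(mod["s2_post"])
    t_mod = fit["coef"].to_numpy() / se
    df_total = float(fit["df"].iloc[0]) + mod["d0"]
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = fit.copy()
    out["t_mod"] = t_mod
    out["p"] = p
    out.attrs["d0"] = mod["d0"]
    out.attrs["s0_sq"] = mod["s0_sq"]
    return out


def select_signature_probes(
    results: pd.DataFrame, min_delta: float = 0.10, max_q: float = 0.01
) -> list[str]:
    """Probes with |delta beta| strictly above ``min_delta`` AND q strictly
    below ``max_q``, sorted by |delta beta| descending."""
    if len(results) == 0:
        return []
    sel = results[(results["delta_beta"].abs() > min_delta) & (results["q"] < max_q)]
    sel = sel.reindex(sel["delta_beta"].abs().sort_values(ascending=False).index)
    return list(sel["probe_id"])


class DifferentialMethylation:
    """Probe-wise moderated regression of M values on case status.

    Parameters
    ----------
    m_values : probes x samples DataFrame of M values.
    beta : probes x samples DataFrame of beta values (effect sizes are
        reported on this scale).
    group : per-sample 0/1 indicator (1 = case), aligned with columns.
    covariates : optional samples x k DataFrame of confounders (e.g.
        estimated cell proportions).
    manifest : optional probe manifest for chrom/pos annotation.
    """

    def __init__(self, m_values, beta, group, covariates=None, manifest=None):
        self.m_values = m_values
        self.beta = beta
        self.group = np.asarray(group, dtype=float)
        self.covariates = covariates
        self.manifest = manifest

    @classmethod
    def from_dataset(
        cls,
        ds: MethylationDataset,
        case_label: str = "case",
        control_label: str = "control",
        cell_proportions: pd.DataFrame | None = None,
    ) -> "DifferentialMethylation":
        ids = ds.sample_ids(case_label) + ds.sample_ids(control_label)
        sub = ds.subset_samples(ids)
        group = (sub.samples["cohort"] == case_label).astype(float).to_numpy()
        m = pd.DataFrame(
            beta_to_m(sub.beta.to_numpy()), index=sub.beta.index, columns=sub.beta.columns
        )
        # proportions sum to ~1, collinear with the intercept: drop one type
        cov = cell_proportions.loc[ids].iloc[:, :-1] if cell_proportions is not None else None
        return cls(m, sub.beta, group, covariates=cov, manifest=sub.manifest)

    def _design(self) -> pd.DataFrame:
        n = len(self.group)
        design = pd.DataFrame({"intercept": np.ones(n), "group": self.group})
        if self.covariates is not None:
            cov = pd.DataFrame(np.asarray(self.covariates, dtype=float))
            cov.columns = [f"cov_{c}" for c in (
                self.covariates.columns if isinstance(self.covariates, pd.DataFrame) else cov.columns
            )]
            design = pd.concat([design.reset_index(drop=True), cov.reset_index(drop=True)], axis=1)
        return design

    def fit(self) -> "DifferentialResults":
        design = self._design()
        fit = fit_probe_models(self.m_values, design, group_col="group")
        fit = moderated_t_test(fit)
        case = self.group == 1
        beta = self.beta.to_numpy()
        delta = beta[:, case].mean(axis=1) - beta[:, ~case].mean(axis=1)
        table = pd.DataFrame(
            {
                "probe_id": self.m_values.index,
                "delta_beta": delta,
                "coef": fit["coef"].to_numpy(),
                "s2": fit["s2"].to_numpy(),
                "df": fit["df"].to_numpy(),
                "t_mod": fit["t_mod"].to_numpy(),
                "p": fit["p"].to_numpy(),
            }
        )
        table["q"] = adjust_bh(table["p"].to_numpy())
        if self.manifest is not None:
            ann = self.manifest.set_index("probe_id")[["chrom", "pos"]]
            table = table.join(ann, on="probe_id")
        return DifferentialResults(table, d0=fit.attrs["d0"], s0_sq=fit.attrs["s0_sq"])


class DifferentialResults:
    """Per-probe differential methylation table with selection helpers."""

    def __init__(self, table: pd.DataFrame, d0: float, s0_sq: float):
        self.table = table.reset_index(drop=True)
        self.d0 = d0
        self.s0_sq = s0_sq

    def select(self, min_delta: float = 0.10, max_q: float = 0.01) -> list[str]:
        return select_signature_probes(self.table, min_delta=min_delta, max_q=max_q)

    def to_tsv(self, path, min_delta: float = 0.10, max_q: float = 0.01) -> None:
        out = self.table.copy()
        selected = set(self.select(min_delta, max_q))
        out["selected"] = out["probe_id"].isin(selected)
        out.to_csv(path, sep="\t", index=False)

    def summary(self, min_delta: float = 0.10, max_q: float = 0.01) -> str:
        n_sel = len(self.select(min_delta, max_q))
        lines = [
            "Differential methylation (moderated t on M values)",
            f"  probes tested:        {len(self.table)}",
            f"  prior df (d0):        {self.d0:.3g}",
            f"  prior variance s0^2:  {self.s0_sq:.4g}",
            f"  q < {max_q:g}:            {int((self.table['q'] < max_q).sum())}",
            f"  signature probes (|delta beta| > {min_delta:g} & q < {max_q:g}): {n_sel}",
        ]
        return "\n".join(lines)
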