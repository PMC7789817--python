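"""Quality control and preprocessing for methylation-array cohorts.

Implements the standard pre-analysis pipeline: beta and M-value
computation, probe filtering (detection failures, sex chromosomes,
SNP-overlapping and cross-reactive probes), per-sample QC (failed-probe
rate, sex prediction from X/Y intensities, genome-wide bimodality),
PCA-based outlier detection, and 4:1 age/sex/batch-matched control
selection with iterative outlier removal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import MethylationDataset

DEFAULT_M_EPS = 1e-6
#: median log2 total-intensity difference (Y - X) above which a sample is
#: called male; females have Y probes at background, far below this.
DEFAULT_SEX_THRESHOLD = -2.0


def compute_beta(meth, unmeth, offset: float = 100.0):
    """Beta value: methylated / (methylated + unmethylated + offset).

    Zero denominators are defined as beta 0 with a warning.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if (meth < 0).any() or (unmeth < 0).any():
        raise ValueError("intensities must be non-negative")
    denom = meth + unmeth + offset
    zero = denom == 0
    if np.any(zero):
        warnings.warn("zero total intensity; beta defined as 0 there")
        denom = np.where(zero, 1.0, denom)
    beta = np.where(zero, 0.0, meth / denom)
    return beta if beta.ndim else float(beta)


def beta_to_m(beta, eps: float = DEFAULT_M_EPS):
    """Logit transform: M = log2(b / (1 - b)), with b clipped to [eps, 1-eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    return m if m.ndim else float(m)


def m_to_beta(m):
    """Inverse logit: b = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.exp2(-m))
    return b if b.ndim else float(b)


@dataclass
class QcReport:
    """Per-sample and per-probe QC outcomes.

    ``samples``: sample_id, failed_fraction, predicted_sex, sex_discordant,
    bimodal_pass, pca_outlier, excluded, reason.
    ``probes``: probe_id, pass, reason (single primary reason per failure).
    """

    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    probes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "samples": self.samples.to_dict(orient="records"),
            "probes_failed": int((~self.probes["pass"]).sum()) if len(self.probes) else 0,
            "probe_fail_reasons": self.probes.loc[~self.probes["pass"], "reason"]
            .value_counts()
            .to_dict()
            if len(self.probes)
            else {},
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))

    def __str__(self) -> str:  # human-readable summary
        lines = ["QC report"]
        if len(self.probes):
            failed = self.probes.loc[~self.probes["pass"], "reason"].value_counts()
            lines.append(f"  probes: {int(self.probes['pass'].sum())} pass / {len(self.probes)} total")
            for reason, n in failed.items():
                lines.append(f"    removed ({reason}): {n}")
        if len(self.samples):
            lines.append(f"  samples flagged: {int(self.samples['excluded'].sum())} / {len(self.samples)}")
        return "\n".join(lines)


def filter_probes(
    ds: MethylationDataset, detection_threshold: float = 0.01
) -> tuple[MethylationDataset, QcReport]:
    """Remove sex-chromosome, SNP-flagged, cross-reactive and
    detection-failing probes (fail = detection p > threshold in any sample).

    Probe order is preserved. Raises if nothing survives.
    """
    man = ds.manifest
    reason = pd.Series("", index=man["probe_id"], dtype=object)

    def _mark(mask: pd.Series, label: str) -> None:
        mask = mask.to_numpy()
        unset = reason.to_numpy() == ""
        reason.iloc[mask & unset] = label

    _mark(man.set_index("probe_id")["is_sex_chrom"].astype(bool), "sex_chromosome")
    _mark(man.set_index("probe_id")["flag_snp"].astype(bool), "snp")
    _mark(man.set_index("probe_id")["flag_cross_reactive"].astype(bool), "cross_reactive")
    if ds.detection_p is not None:
        fails = (ds.detection_p > detection_threshold).any(axis=1)
        _mark(fails.reindex(reason.index, fill_value=False), "detection")

    keep = reason[reason == ""].index
    if len(keep) == 0:
        raise ValueError("probe filtering removed every probe")
    report = QcReport(
        probes=pd.DataFrame(
            {"probe_id": reason.index, "pass": reason.to_numpy() == "", "reason": reason.to_numpy()}
        )
    )
    return ds.subset_probes(keep), report


def sample_qc(
    ds: MethylationDataset,
    max_fail_rate: float = 0.05,
    detection_threshold: float = 0.01,
    sex_threshold: float = DEFAULT_SEX_THRESHOLD,
) -> QcReport:
    """Flag samples with failed-probe fraction strictly above
    ``max_fail_rate``; record predicted sex and bimodality per sample."""
    if ds.detection_p is None:
        raise ValueError("sample QC requires detection p-values")
    failed_fraction = (ds.detection_p > detection_threshold).mean(axis=0)

    predicted_sex = pd.Series("unknown", index=ds.beta.columns, dtype=object)
    if ds.meth is not None and ds.manifest["is_sex_chrom"].any():
        try:
            predicted_sex = predict_sex(ds, threshold=sex_threshold)
        except ValueError:
            pass
    sheet_sex = ds.samples.set_index("sample_id")["sex"]
    discordant = (predicted_sex != "unknown") & (predicted_sex != sheet_sex.reindex(predicted_sex.index))

    bimodal = ds.beta.apply(lambda col: check_bimodality(col.to_numpy()), axis=0) \
        if ds.n_probes >= 100 else pd.Series(True, index=ds.beta.columns)

    excluded = failed_fraction > max_fail_rate
    reason = np.where(excluded, "failed_probe_rate", "")
    samples = pd.DataFrame(
        {
            "sample_id": ds.beta.columns,
            "failed_fraction": failed_fraction.to_numpy(),
            "predicted_sex": predicted_sex.to_numpy(),
            "sex_discordant": discordant.to_numpy(),
            "bimodal_pass": np.asarray(bimodal, dtype=bool),
            "excluded": excluded.to_numpy(),
            "reason": reason,
        }
    )
    return QcReport(samples=samples)


def predict_sex(
    ds: MethylationDataset, threshold: float = DEFAULT_SEX_THRESHOLD
) -> pd.Series:
    """Classify sample sex from median log2 total intensity on Y vs X.

    Males carry one X and one Y, so both chromosomes sit near half the
    autosomal level and the Y - X difference is near 0; females have Y
    probes at background, giving a strongly negative difference.
    """
    if ds.meth is None or ds.unmeth is None:
        raise ValueError("sex prediction requires intensity matrices")
    man = ds.manifest
    on_x = man["chrom"].isin(["chrX", "X"]).to_numpy()
    on_y = man["chrom"].isin(["chrY", "Y"]).to_numpy()
    if not on_x.any() or not on_y.any():
        raise ValueError("no sex-chromosome probes in the dataset")
    total = ds.total_intensity().to_numpy()
    log_total = np.log2(np.maximum(total, 1.0))
    diff = np.median(log_total[on_y], axis=0) - np.median(log_total[on_x], axis=0)
    return pd.Series(np.where(diff > threshold, "male", "female"), index=ds.beta.columns)


def check_bimodality(
    beta_vector, mid_low: float = 0.3, mid_high: float = 0.7, max_mid_fraction: float = 0.35
) -> bool:
    """Pass (True) when the genome-wide beta density is bimodal, judged by
    the mass in the mid-range (mid_low, mid_high) staying below the cutoff."""
    b = np.asarray(beta_vector, dtype=float)
    if b.size < 100:
        raise ValueError("bimodality check needs at least 100 probes")
    mid_mass = np.mean((b > mid_low) & (b < mid_high))
    return bool(mid_mass < max_mid_fraction)


def pca_scores(m_matrix, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Sample scores of a column-centred SVD of the samples x probes matrix.

    ``m_matrix`` is probes x samples (pandas or ndarray); samples are the
    observations. Returns (scores: samples x k, explained_variance: k).
    Components are sign-fixed so the largest-|loading| entry is positive.
    """
    X = np.asarray(m_matrix, dtype=float).T
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size and S[0] > 0 else 0
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; truncating")
        k = max(rank, 1)
    # deterministic sign: flip so each component's largest-|u| entry is positive
    for j in range(min(k, U.shape[1])):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    scores = U[:, :k] * S[:k]
    explained = (S[:k] ** 2) / max(n - 1, 1)
    return scores, explained


def _greedy_match(cases: pd.DataFrame, pool: pd.DataFrame, ratio: int) -> list[str]:
    """Greedy nearest-age matching within exact (sex, batch) strata."""
    available = pool.copy()
    chosen: list[str] = []
    for _, case in cases.iterrows():
        stratum = available[
            (available["sex"] == case["sex"]) & (available["batch"] == case["batch"])
        ]
        if len(stratum) < ratio:
            # fall back to same sex only, then to the whole pool
            stratum = available[available["sex"] == case["sex"]]
        if len(stratum) < ratio:
            stratum = available
        if len(stratum) < ratio:
            raise ValueError(
                f"control pool exhausted for case {case['sample_id']} "
                f"(sex={case['sex']}, batch={case['batch']}): "
                f"{len(stratum)} candidates for ratio {ratio}"
            )
        # stable sort on |age difference|; ties broken by pool order
        dist = (stratum["age"] - case["age"]).abs().to_numpy()
        order = np.argsort(dist, kind="mergesort")
        picked = stratum.iloc[order[:ratio]]["sample_id"].tolist()
        chosen.extend(picked)
        available = available[~available["sample_id"].isin(picked)]
    return chosen


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    m_matrix: pd.DataFrame,
    ratio: int = 4,
    sd_threshold: float = 3.0,
    max_iter: int = 10,
) -> list[str]:
    """Select ``ratio`` age/sex/batch-matched controls per case, iterating
    PCA outlier removal on the matched set until PC1/PC2 are clean.

    ``m_matrix`` is probes x samples covering cases and pool (M values or
    betas). An outlier is a matched sample scoring beyond ``sd_threshold``
    standard deviations on PC1 or PC2; outlying controls are returned to
    the excluded set and matching repeats. Returns exactly
    ``ratio * len(cases)`` control ids.
    """
    banned: set[str] = set()
    case_ids = list(cases["sample_id"])
    for _ in range(max_iter):
        usable = pool[~pool["sample_id"].isin(banned)]
        chosen = _greedy_match(cases, usable, ratio)
        ids = case_ids + chosen
        scores, _ = pca_scores(m_matrix[ids], k=2)
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        z = np.abs(scores - scores.mean(axis=0)) / sd
        outliers = [ids[i] for i in np.where((z > sd_threshold).any(axis=1))[0]]
        outlier_controls = [s for s in outliers if s in chosen]
        if not outlier_controls:
            return chosen
        banned.update(outlier_controls)
    warnings.warn("PCA outlier iteration did not converge; returning last matching")
    return chosen
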