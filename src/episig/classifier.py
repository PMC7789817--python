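"""The MVP (methylation variant pathogenicity) classifier and its
validation harnesses.

A linear support vector machine is trained one-vs-rest on signature
probes (betas); the cost parameter C is chosen by stratified 10-fold
cross-validation, and each class's decision values are converted to a
0-1 score with a Platt sigmoid fitted on *cross-validated* decision
values. The class with the greatest score is the predicted phenotype.
Validation harnesses mirror the study design: leave-2-out
cross-validation of the 11-case cohort with MDS centroid assignment,
classical MDS embedding, and Ward hierarchical clustering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score
from sklearn.svm import SVC


def select_features(
    betas: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    min_diff: float = 0.10,
    shared_mask: list[str] | None = None,
) -> list[str]:
    """Probes (within the shared-platform mask) whose absolute mean beta
    difference between cases and controls is at least ``min_diff``."""
    sub = betas.loc[shared_mask] if shared_mask is not None else betas
    diff = sub[case_ids].mean(axis=1) - sub[control_ids].mean(axis=1)
    sel = diff.abs() >= min_diff
    if not sel.any():
        raise ValueError(
            f"no probes pass |mean difference| >= {min_diff}; lower the threshold"
        )
    return list(diff[sel].abs().sort_values(ascending=False).index)


def _fit_platt(decision: np.ndarray, is_pos: np.ndarray) -> tuple[float, float]:
    """Platt sigmoid P(y=1|f) = 1 / (1 + exp(A f + B)) by regularized
    maximum likelihood on (decision value, label) pairs."""
    n_pos = int(is_pos.sum())
    n_neg = int(is_pos.size - n_pos)
    t = np.where(is_pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        a, b = ab
        z = a * decision + b
        # stable log(1 + exp(z)) formulations
        log1p_exp = np.where(z > 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z)))
        return float(np.sum(t * log1p_exp + (1.0 - t) * (log1p_exp - z)))

    x0 = np.array([-1.0, np.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    return float(res.x[0]), float(res.x[1])


def _platt_score(decision: np.ndarray, a: float, b: float) -> np.ndarray:
    z = a * decision + b
    return np.where(z > 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))


class MvpModel:
    """Linear-SVM epi-signature classifier with Platt-scaled class scores.

    Parameters
    ----------
    X : samples x feature-probes DataFrame of beta values.
    y : per-sample class labels (e.g. "phmds" / "control"); two or more
        classes, scored one-vs-rest.
    """

    def __init__(self, X: pd.DataFrame, y):
        self.X = X
        self.y = np.asarray(y)
        if len(np.unique(self.y)) < 2:
            raise ValueError("training needs at least two classes")

    def fit(
        self,
        c_grid=(0.01, 0.1, 1.0, 10.0),
        folds: int = 10,
        seed: int = 0,
    ) -> "MvpResults":
        X = self.X.to_numpy(dtype=float)
        _, counts = np.unique(self.y, return_counts=True)
        max_folds = int(counts.min())
        if max_folds < folds:
            warnings.warn(f"smallest class has {max_folds} members; reducing folds")
            folds = max(2, max_folds)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

        accuracies = {}
        for C in c_grid:
            svm = SVC(kernel="linear", C=C, random_state=seed)
            accuracies[C] = float(np.mean(cross_val_score(svm, X, self.y, cv=cv)))
        best_acc = max(accuracies.values())
        best_c = min(c for c, a in accuracies.items() if a >= best_acc - 1e-12)

        classes = list(np.unique(self.y))
        per_class = {}
        for cls in classes:
            y_bin = (self.y == cls).astype(int)
            svm = SVC(kernel="linear", C=best_c, random_state=seed)
            cv_dec = cross_val_predict(
                svm, X, y_bin, cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
                method="decision_function",
            )
            a, b = _fit_platt(np.asarray(cv_dec, dtype=float), y_bin.astype(bool))
            svm.fit(X, y_bin)
            per_class[cls] = {
                "weights": svm.coef_.ravel().tolist(),
                "bias": float(svm.intercept_[0]),
                "platt_a": a,
                "platt_b": b,
            }
        control_mean = self.X.mean(axis=0)
        return MvpResults(
            feature_probes=list(self.X.columns),
            classes=classes,
            per_class=per_class,
            c_selected=best_c,
            cv_accuracy=accuracies[best_c],
            cv_accuracies=accuracies,
            seed=seed,
            impute_values=control_mean,
        )


class MvpResults:
    """Fitted MVP model: feature list, per-class linear decision function
    and Platt sigmoid, training metadata; produces 0-1 scores per class."""

    def __init__(
        self,
        feature_probes,
        classes,
        per_class,
        c_selected,
        cv_accuracy,
        cv_accuracies,
        seed,
        impute_values,
    ):
        self.feature_probes = list(feature_probes)
        self.classes = list(classes)
        self.per_class = per_class
        self.c_selected = c_selected
        self.cv_accuracy = cv_accuracy
        self.cv_accuracies = cv_accuracies
        self.seed = seed
        self.impute_values = pd.Series(impute_values, index=self.feature_probes)

    def score(self, betas: pd.DataFrame) -> pd.DataFrame:
        """MVP scores for samples x probes (or probes x samples) betas.

        Missing feature probes (up to 10%) are imputed with training
        means; more raises. Returns one row per sample with per-class
        scores in [0, 1], the argmax prediction, and a flag for a
        case-class score above 0.5.
        """
        if not set(self.feature_probes) <= set(betas.columns):
            if set(self.feature_probes) <= set(betas.index):
                betas = betas.T
        present = [p for p in self.feature_probes if p in betas.columns]
        missing = [p for p in self.feature_probes if p not in betas.columns]
        if len(missing) > 0.10 * len(self.feature_probes):
            raise ValueError(
                f"{len(missing)}/{len(self.feature_probes)} feature probes missing"
            )
        X = betas.reindex(columns=self.feature_probes)
        if missing:
            warnings.warn(f"imputing {len(missing)} missing feature probes with training means")
            X[missing] = np.nan
            X = X.fillna(self.impute_values)
        Xv = X.to_numpy(dtype=float)
        out = {}
        for cls in self.classes:
            prm = self.per_class[cls]
            dec = Xv @ np.asarray(prm["weights"]) + prm["bias"]
            out[cls] = _platt_score(dec, prm["platt_a"], prm["platt_b"])
        scores = pd.DataFrame(out, index=betas.index)
        scores["predicted_class"] = scores[self.classes].idxmax(axis=1)
        return scores

    def summary(self) -> str:
        lines = [
            "MVP classifier (linear SVM, Platt-scaled one-vs-rest scores)",
            f"  features: {len(self.feature_probes)} probes",
            f"  classes:  {self.classes}",
            f"  C selected by {len(self.cv_accuracies)}-point grid CV: {self.c_selected}",
            f"  CV accuracy at selected C: {self.cv_accuracy:.3f}",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_probes": self.feature_probes,
            "classes": self.classes,
            "per_class": self.per_class,
            "c_selected": self.c_selected,
            "cv_accuracy": self.cv_accuracy,
            "cv_accuracies": {str(k): v for k, v in self.cv_accuracies.items()},
            "seed": self.seed,
            "impute_values": self.impute_values.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MvpResults":
        d = json.loads(Path(path).read_text())
        return cls(
            d["feature_probes"],
            d["classes"],
            d["per_class"],
            d["c_selected"],
            d["cv_accuracy"],
            {float(k): v for k, v in d["cv_accuracies"].items()},
            d["seed"],
            pd.Series(d["impute_values"], index=d["feature_probes"]),
        )


def train_mvp(X: pd.DataFrame, y, c_grid=(0.01, 0.1, 1.0, 10.0), folds: int = 10, seed: int = 0) -> MvpResults:
    """Functional wrapper: fit an :class:`MvpModel` and return the results."""
    return MvpModel(X, y).fit(c_grid=c_grid, folds=folds, seed=seed)


def mvp_score(model: MvpResults, betas: pd.DataFrame) -> pd.DataFrame:
    """Functional wrapper over :meth:`MvpResults.score`."""
    return model.score(betas)


def mds_embed(X, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of samples x features data on Euclidean
    distances. Exact for data of intrinsic rank <= k; deterministic up to
    the sign convention (largest-|coordinate| entry positive)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("MDS needs at least 3 samples")
    D2 = squareform(pdist(X) ** 2)
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals[0] <= 1e-12:
        warnings.warn("degenerate (all-equal) input; returning zero coordinates")
        return np.zeros((n, k))
    coords = np.zeros((n, k))
    for j in range(min(k, n)):
        if vals[j] > 1e-12:
            v = vecs[:, j] * np.sqrt(vals[j])
            i = np.argmax(np.abs(v))
            coords[:, j] = v if v[i] >= 0 else -v
    return coords


def ward_cluster(X, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Ward-linkage agglomerative clustering on Euclidean distance.

    Returns (labels cut at k clusters, scipy linkage matrix)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least 2 samples")
    if k > X.shape[0]:
        raise ValueError("more clusters than samples")
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


def leave_two_out(
    case_betas: pd.DataFrame,
    control_betas: pd.DataFrame,
    min_diff: float = 0.10,
    k: int = 2,
) -> pd.DataFrame:
    """Leave-2-out validation of the epi-signature.

    Enumerates every pair of cases; per fold, signature probes are
    re-selected from the remaining cases against the controls, all
    samples are MDS-embedded on those probes, and each held-out case is
    assigned to the nearer of the training-case / control centroids.
    Returns one row per fold with the held-out ids and their assignments.
    """
    case_ids = list(case_betas.columns)
    if len(case_ids) < 3:
        raise ValueError("leave-2-out needs at least 3 cases")
    control_ids = list(control_betas.columns)
    betas = pd.concat([case_betas, control_betas], axis=1)
    rows = []
    for pair in combinations(case_ids, 2):
        train_cases = [c for c in case_ids if c not in pair]
        probes = select_features(betas, train_cases, control_ids, min_diff=min_diff)
        ids = train_cases + control_ids + list(pair)
        emb = mds_embed(betas.loc[probes, ids].T.to_numpy(), k=k)
        n_train = len(train_cases)
        n_ctrl = len(control_ids)
        case_centroid = emb[:n_train].mean(axis=0)
        ctrl_centroid = emb[n_train : n_train + n_ctrl].mean(axis=0)
        held = emb[n_train + n_ctrl :]
        d = cdist(held, np.vstack([case_centroid, ctrl_centroid]))
        assign = np.where(d[:, 0] < d[:, 1], "case", "control")
        rows.append(
            {
                "held_out": pair,
                "n_train_cases": n_train,
                "n_features": len(probes),
                "assignment_1": assign[0],
                "assignment_2": assign[1],
                "both_case": bool((assign == "case").all()),
            }
        )
    return pd.DataFrame(rows)
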