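"""Diagnostic panel evaluation: LOOCV logistic models, ROC, operating points.

Five logistic models are compared for separating controls from cancer
patients: serum PSA alone, the three mature-miRNA assays, mature + PSA,
the three isomiR assays, and isomiR + PSA.  Each model's per-sample
disease probabilities come from leave-one-out cross-validation (every
sample predicted by a model fit on all other samples), so the resulting
ROC curves measure out-of-sample discrimination.

The ROC is built over a fixed probability-threshold grid (0.01 to 0.99,
step 0.01): a sample is called diseased when its probability is at least
the threshold; AUC is the trapezoidal area with the (0,0) and (1,1)
endpoints appended.  The operating point maximizes Youden's J
(sensitivity + specificity), ties broken toward higher specificity.

PSA enters models as ln(PSA) by default: serum PSA spans several orders
of magnitude (roughly 1-400 ng/ml in a mixed biopsy population) and would
otherwise dominate the fit by leverage; raw-scale PSA is available via
``log_psa=False``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qpcr import ISOMIR_ASSAYS, MATURE_ASSAYS

THRESHOLD_GRID = np.round(np.arange(1, 100) / 100.0, 2)

PSA_COLUMN = "ln_psa"

#: The five standard model specifications, by covariate set.
MODEL_SPECS: dict[str, tuple[str, ...]] = {
    "PSA": (PSA_COLUMN,),
    "mature3": MATURE_ASSAYS,
    "mature3+PSA": MATURE_ASSAYS + (PSA_COLUMN,),
    "isomir3": ISOMIR_ASSAYS,
    "isomir3+PSA": ISOMIR_ASSAYS + (PSA_COLUMN,),
}


class SeparationWarning(UserWarning):
    """Perfect separation: coefficients are large but finite under the ridge."""


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-8,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Maximum-likelihood logistic regression by IRLS.

    ``X`` must already contain the intercept column.  A fixed tiny ridge on
    the coefficients keeps the Newton step defined under perfect separation
    (coefficients then converge to large finite values and a warning is
    emitted).  Convergence: max |coefficient change| < ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) aligned with y")
    n, p = X.shape
    beta = np.zeros(p)
    eye = np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X.T * w) @ X + ridge * eye
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    if np.max(np.abs(X @ beta)) > 15:  # fitted probabilities saturated at 0/1
        warnings.warn(
            "near-perfect separation: coefficients bounded only by the ridge",
            SeparationWarning,
            stacklevel=2,
        )
    return beta


def predict_proba(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    eta = np.clip(np.asarray(X, float) @ beta, -35, 35)
    return 1.0 / (1.0 + np.exp(-eta))


def _design(features: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    missing = [c for c in covariates if c not in features.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    block = features[list(covariates)].astype(float)
    if block.isna().any().any():
        bad = block.columns[block.isna().any()].tolist()
        raise ValueError(f"missing values in covariate(s): {bad}")
    return np.column_stack([np.ones(len(block)), block.values])


def loocv_probabilities(
    features: pd.DataFrame, labels: pd.Series | np.ndarray, covariates: Sequence[str]
) -> pd.Series:
    """One out-of-fold disease probability per sample.

    Each sample is predicted by a model fit on the remaining n-1; a fold
    whose training set loses a label class is an error (the model would be
    degenerate).  Deterministic and invariant to sample order.
    """
    y = np.asarray(pd.Series(labels).reindex(features.index) if isinstance(labels, pd.Series) else labels, dtype=float)
    if features.shape[0] != y.shape[0]:
        raise ValueError("features and labels are not aligned")
    if features.shape[0] < 3:
        raise ValueError("need at least 3 samples for LOOCV")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes, coded 0/1")
    X = _design(features, covariates)
    probs = np.empty(len(y))
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        if len(set(y[mask])) < 2:
            raise ValueError(
                f"leaving out sample {features.index[i]!r} removes an entire class"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            beta = fit_logistic(X[mask], y[mask])
        probs[i] = predict_proba(X[i : i + 1], beta)[0]
    return pd.Series(probs, index=features.index, name="probability")


@dataclass
class RocCurve:
    """Grid ROC: per-threshold sensitivity/specificity and trapezoid AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class OperatingPoint:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def roc_curve(probabilities: Sequence[float], labels: Sequence[float]) -> RocCurve:
    """ROC over the fixed 0.01..0.99 threshold grid (classify when p >= t)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    pos = y == 1
    neg = y == 0
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    sens = np.empty(len(THRESHOLD_GRID))
    spec = np.empty(len(THRESHOLD_GRID))
    for k, t in enumerate(THRESHOLD_GRID):
        pred = p >= t
        sens[k] = (pred & pos).sum() / n1
        spec[k] = (~pred & neg).sum() / n0
    # descending threshold = increasing FPR; endpoints appended
    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        thresholds=THRESHOLD_GRID.copy(), sensitivity=sens, specificity=spec, auc=auc
    )


def operating_point(
    roc: RocCurve, probabilities: Sequence[float], labels: Sequence[float]
) -> OperatingPoint:
    """Youden-optimal grid cutoff plus the confusion statistics there.

    Ties in J go to the higher-specificity threshold.  With no predicted
    positives PPV is reported as the prevalence (and with no predicted
    negatives NPV as 1 - prevalence) — the no-information values.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    j = roc.sensitivity + roc.specificity
    best = np.lexsort((roc.thresholds, roc.specificity, j))[-1]
    cutoff = float(roc.thresholds[best])
    pred = p >= cutoff
    pos = y == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    tn = int((~pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    prevalence = pos.mean()
    ppv = tp / (tp + fp) if (tp + fp) else float(prevalence)
    npv = tn / (tn + fn) if (tn + fn) else float(1.0 - prevalence)
    return OperatingPoint(
        cutoff=cutoff,
        sensitivity=float(roc.sensitivity[best]),
        specificity=float(roc.specificity[best]),
        ppv=float(ppv),
        npv=float(npv),
    )


@dataclass
class PanelReport:
    """LOOCV results for the five diagnostic models."""

    probabilities: pd.DataFrame
    rocs: dict[str, RocCurve]
    operating_points: dict[str, OperatingPoint]
    labels: pd.Series = field(repr=False, default=None)

    @property
    def aucs(self) -> dict[str, float]:
        return {name: roc.auc for name, roc in self.rocs.items()}

    def to_dict(self) -> dict:
        return {
            name: {
                "auc": roc.auc,
                "operating_point": vars(self.operating_points[name]),
                "roc": {
                    "thresholds": roc.thresholds.tolist(),
                    "sensitivity": roc.sensitivity.tolist(),
                    "specificity": roc.specificity.tolist(),
                },
            }
            for name, roc in self.rocs.items()
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_panels(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    models: Mapping[str, Sequence[str]] | None = None,
    log_psa: bool = True,
) -> PanelReport:
    """Run the five-model LOOCV -> ROC -> operating-point comparison.

    ``expr``: samples x assays ln-expression matrix (the six panel assays);
    ``clinical``: per-sample ``label`` (0 control / 1 cancer) and ``psa``
    (ng/ml), indexed by sample_id or with a sample_id column.
    """
    if models is None:
        models = MODEL_SPECS
    if "sample_id" in clinical.columns:
        clinical = clinical.set_index("sample_id")
    clinical = clinical.loc[expr.index]
    labels = clinical["label"].astype(int)
    if set(labels.unique()) != {0, 1}:
        raise ValueError("clinical labels must contain both classes (0 and 1)")

    features = expr.copy()
    needs_psa = any(PSA_COLUMN in cov for cov in models.values())
    if needs_psa:
        if "psa" not in clinical.columns or clinical["psa"].isna().any():
            raise ValueError("PSA required (column 'psa') for a PSA-containing model")
        if (clinical["psa"] <= 0).any():
            raise ValueError("PSA must be positive (ng/ml)")
        features[PSA_COLUMN] = (
            np.log(clinical["psa"]) if log_psa else clinical["psa"].astype(float)
        )

    probs = {}
    rocs = {}
    ops = {}
    for name, covariates in models.items():
        missing = [c for c in covariates if c not in features.columns]
        if missing:
            raise ValueError(f"model {name!r}: missing assay/covariate {missing}")
        pr = loocv_probabilities(features, labels, covariates)
        roc = roc_curve(pr.values, labels.values)
        probs[name] = pr
        rocs[name] = roc
        ops[name] = operating_point(roc, pr.values, labels.values)
    return PanelReport(
        probabilities=pd.DataFrame(probs),
        rocs=rocs,
        operating_points=ops,
        labels=labels,
    )


def plot_rocs(report: PanelReport, path: str | Path) -> None:
    """One ROC figure for all models (matplotlib, Agg-safe)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in report.rocs.items():
        fpr = np.concatenate([[0.0], (1.0 - roc.specificity)[::-1], [1.0]])
        tpr = np.concatenate([[0.0], roc.sensitivity[::-1], [1.0]])
        ax.plot(fpr, tpr, label=f"{name} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
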