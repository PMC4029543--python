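"""L1- and L2-regularized logistic pair classifiers.

The model scores a drug-protein pair with f(D, P) = w^T Phi(D, P) where Phi is
a tensor-product or combined descriptor. Weights are learned by minimising

    R(w) + C * sum_ij log(1 + exp(-y_ij w^T Phi(D_i, P_j)))

with R(w) = sum of absolute weights (L1, sparsity-inducing) or sum of squared
weights (L2). C trades data fit against the penalty: under L1, larger C keeps
more descriptor positions alive. C is chosen on a fixed grid spanning 1e-4 to
1e4 by cross-validated AUC.

The optimisation itself is delegated to liblinear (via scikit-learn), whose
primal objectives are ``|w|_1 + C_s * loss`` for L1 and ``w'w/2 + C_s * loss``
for L2; the algebraic mapping from the parameterisation above (L1: C_s = C,
L2: C_s = C/2) is applied internally and recorded in ``fit_metadata`` so the
reported (penalty, C) always refer to the objective written here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .data import InteractionDataset, ProfileMatrix
from .descriptors import DescriptorSpec, build_pair

__all__ = [
    "FitConfig",
    "CGrid",
    "TrainedModel",
    "fit",
    "objective",
    "score",
    "score_design",
    "select_C",
    "save_model",
    "load_model",
]

#: below this magnitude a weight is declared exactly zero (L1 solutions)
ZERO_TRUNCATION = 1e-8


@dataclass(frozen=True)
class FitConfig:
    """Solver settings for one model fit.

    ``C`` follows the objective documented in this module (loss-side
    multiplier). No intercept by default: the pair-scoring objective has no
    bias term, and an intercept would not change within-model ranking anyway.
    """

    penalty: str = "L1"  # "L1" | "L2"
    C: float = 1.0
    tolerance: float = 1e-4  # liblinear's native stopping tolerance
    max_iterations: int = 100  # iteration budget; overruns are recorded, not fatal
    intercept: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penalty not in ("L1", "L2"):
            raise ValueError(f"penalty must be 'L1' or 'L2', got {self.penalty!r}")
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class CGrid:
    """Candidate regularization strengths, strictly increasing."""

    values: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0, 1000.0, 10000.0)

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("CGrid must be non-empty")
        if any(c <= 0 for c in self.values):
            raise ValueError("all C values must be positive")
        if any(b <= a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("CGrid must be strictly increasing")


@dataclass
class TrainedModel:
    """Weight vector over descriptor positions plus the settings that produced it."""

    weights: np.ndarray
    descriptor_spec: DescriptorSpec
    penalty: str
    C: float
    intercept: float = 0.0
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (self.descriptor_spec.dimension,):
            raise ValueError(
                f"weight length {self.weights.shape} != descriptor dimension "
                f"{self.descriptor_spec.dimension}"
            )

    def nonzero_count(self, threshold: float = ZERO_TRUNCATION) -> int:
        """Number of weights whose magnitude exceeds ``threshold``."""
        return int(np.sum(np.abs(self.weights) > threshold))


def objective(
    w: np.ndarray,
    X: sp.spmatrix | np.ndarray,
    y: np.ndarray,
    penalty: str,
    C: float,
    intercept: float = 0.0,
) -> float:
    """R(w) + C * logistic loss, in this module's parameterisation."""
    z = np.asarray(X @ w).ravel() + intercept
    loss = float(np.logaddexp(0.0, -y * z).sum())
    if penalty == "L1":
        reg = float(np.abs(w).sum())
    elif penalty == "L2":
        reg = float(np.dot(w, w))
    else:
        raise ValueError(f"unknown penalty {penalty!r}")
    return reg + C * loss


def fit(
    X: sp.spmatrix,
    y: np.ndarray,
    spec: DescriptorSpec,
    config: FitConfig,
) -> TrainedModel:
    """Fit one regularized logistic model on a realised design.

    Requires both classes present. Non-convergence is recorded in
    ``fit_metadata['converged']`` (the model is still returned). L1 weights
    below :data:`ZERO_TRUNCATION` in magnitude are truncated to exact zeros.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if not (len(classes) == 2 and set(classes) <= {-1, 1}):
        raise ValueError(
            f"need both +1 and -1 labels, got classes {classes.tolist()}"
        )
    solver_C = config.C if config.penalty == "L1" else config.C / 2.0
    clf = LogisticRegression(
        l1_ratio=1.0 if config.penalty == "L1" else 0.0,
        C=solver_C,
        solver="liblinear",
        fit_intercept=config.intercept,
        tol=config.tolerance,
        max_iter=config.max_iterations,
        random_state=config.seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X, y)
    # liblinear orders classes ascending: coef_ is for the +1 class vs -1
    w = clf.coef_.ravel().astype(np.float64).copy()
    if config.penalty == "L1":
        w[np.abs(w) < ZERO_TRUNCATION] = 0.0
    b = float(clf.intercept_[0]) if config.intercept else 0.0
    meta = {
        "solver": "liblinear",
        "solver_C": solver_C,
        "C_mapping": "L1: solver_C=C; L2: solver_C=C/2 (solver uses w'w/2)",
        "tolerance": config.tolerance,
        "max_iterations": config.max_iterations,
        "n_iterations": int(np.asarray(clf.n_iter_).ravel()[0]),
        "converged": converged,
        "zero_truncation": ZERO_TRUNCATION if config.penalty == "L1" else None,
        "seed": config.seed,
        "n_samples": int(X.shape[0]),
    }
    return TrainedModel(w, spec, config.penalty, config.C, intercept=b, fit_metadata=meta)


def score(model: TrainedModel, drug_vec: Sequence[int], prot_vec: Sequence[int]) -> float:
    """f(D, P) = w^T Phi(D, P) (+ intercept if fitted with one)."""
    pv = build_pair(drug_vec, prot_vec, model.descriptor_spec)
    idx = list(pv.nonzero_positions)
    return float(model.weights[idx].sum() + model.intercept)


def score_design(model: TrainedModel, X: sp.spmatrix | np.ndarray) -> np.ndarray:
    """Scores for a batch of realised pair descriptors (rows of X)."""
    if X.shape[1] != model.descriptor_spec.dimension:
        raise ValueError("design width does not match model descriptor spec")
    return np.asarray(X @ model.weights).ravel() + model.intercept


def select_C(
    dataset: InteractionDataset,
    drug_profiles: ProfileMatrix,
    protein_profiles: ProfileMatrix,
    spec: DescriptorSpec,
    penalty: str,
    grid: CGrid | None = None,
    cv_protocol: str = "pairwise",
    n_folds: int = 5,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pick C on the grid by cross-validated pooled AUC.

    Ties go to the smaller C (the sparser model). Grid points whose fits fail
    are marked in the returned table rather than aborting the sweep. The same
    folds (derived from ``seed``) are reused for every grid point.
    """
    from .evaluation import make_folds, run_blockwise_cv, run_pairwise_cv

    grid = grid or CGrid()
    fit_kwargs = fit_kwargs or {}
    folds = make_folds(dataset, cv_protocol, n_folds=n_folds, seed=seed)
    rows = []
    best_C, best_auc = None, -np.inf
    for C in grid.values:
        config = FitConfig(penalty=penalty, C=C, seed=seed, **fit_kwargs)
        try:
            if cv_protocol == "pairwise":
                result = run_pairwise_cv(
                    dataset, drug_profiles, protein_profiles, spec, config, folds=folds
                )
                auc = result.aucs["pairwise"]
            else:
                result = run_blockwise_cv(
                    dataset, drug_profiles, protein_profiles, spec, config, folds=folds
                )
                auc = result.pooled_auc_all_categories()
        except Exception as exc:  # noqa: BLE001 - sweep robustness by contract
            rows.append({"C": C, "auc": np.nan, "status": f"failed: {exc}"})
            continue
        rows.append({"C": C, "auc": auc, "status": "ok"})
        if auc > best_auc:  # strict: ties keep the smaller (earlier) C
            best_auc, best_C = auc, C
    table = pd.DataFrame(rows, columns=["C", "auc", "status"])
    if best_C is None:
        raise RuntimeError("every grid point failed during C selection")
    return best_C, table


# ---------------------------------------------------------------------------
# persistence — JSON text, exact round trip
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Save as JSON: sparse weight map + descriptor spec sidecar content."""
    nz = np.flatnonzero(model.weights)
    payload = {
        "penalty": model.penalty,
        "C": model.C,
        "intercept": model.intercept,
        "dimension": int(model.descriptor_spec.dimension),
        "weights": {int(k): float(model.weights[k]) for k in nz},
        "fit_metadata": model.fit_metadata,
        "descriptor_spec": json.loads(model.descriptor_spec.to_json()),
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    spec = DescriptorSpec(
        payload["descriptor_spec"]["kind"],
        tuple(payload["descriptor_spec"]["drug_feature_names"]),
        tuple(payload["descriptor_spec"]["protein_feature_names"]),
    )
    w = np.zeros(spec.dimension, dtype=np.float64)
    for k, v in payload["weights"].items():
        w[int(k)] = v
    return TrainedModel(
        w,
        spec,
        payload["penalty"],
        payload["C"],
        intercept=payload["intercept"],
        fit_metadata=payload["fit_metadata"],
    )
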