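"""Cross-validated prediction of directed resolution.

Predictors combine system encodings (one-hot CSP / eluent), the fitted
thermodynamic parameters, and molecular descriptors of the analytes; the
response is the directed resolution.  Preprocessing follows the standard
caret-style chain — range scaling to [0, 1], missing-value imputation,
removal of zero-variance features, and elimination of highly correlated
features (|r| >= 0.999) — and is idempotent.  Model assessment uses
3-fold cross-validation repeated 5 times (15 resamples) scored by RMSE,
with hyperparameters tuned by grid search inside each training split.

Two learners are provided: a random forest, and a single-hidden-layer
feedforward network whose L2 penalty is selected by the inner grid
search — the regularization playing the overfitting-control role a
Bayesian-regularized network fills in the original workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import GridSearchCV, KFold, RepeatedKFold
from sklearn.neural_network import MLPRegressor

__all__ = [
    "MLDataset",
    "CVResult",
    "preprocess_features",
    "crossvalidate",
    "permutation_baseline",
    "analyte_descriptors",
    "MODELS",
]

CORR_CUTOFF = 0.999

#: canonical SMILES of the three proton pump inhibitors (racemates)
PPI_SMILES = {
    "omeprazole": "CC1=CN=C(C(=C1OC)C)CS(=O)C2=NC3=CC=C(C=C3N2)OC",
    "rabeprazole": "CC1=C(C=CN=C1CS(=O)C2=NC3=CC=CC=C3N2)OCCCOC",
    "lansoprazole": "CC1=C(C=CN=C1CS(=O)C2=NC3=CC=CC=C3N2)OCC(F)(F)F",
}


def analyte_descriptors(smiles: dict[str, str] | None = None) -> pd.DataFrame:
    """RDKit molecular descriptors per analyte (MW, logP, TPSA, counts).

    Computed from SMILES at call time — no network retrieval.  Returns a
    DataFrame indexed by analyte name.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    smiles = smiles or PPI_SMILES
    rows = {}
    for name, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid SMILES for {name}: {smi!r}")
        rows[name] = {
            "mol_weight": Descriptors.MolWt(mol),
            "logp": Crippen.MolLogP(mol),
            "tpsa": rdMolDescriptors.CalcTPSA(mol),
            "h_donors": rdMolDescriptors.CalcNumHBD(mol),
            "h_acceptors": rdMolDescriptors.CalcNumHBA(mol),
            "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds(mol),
            "ring_count": rdMolDescriptors.CalcNumRings(mol),
            "heavy_atoms": mol.GetNumHeavyAtoms(),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "analyte"
    return df


@dataclass
class MLDataset:
    """Preprocessed predictors + response, with per-feature provenance."""

    X: pd.DataFrame
    y: pd.Series | None
    dropped_zero_variance: list[str] = field(default_factory=list)
    dropped_correlated: list[str] = field(default_factory=list)
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.X.isna().any().any():
            raise ValueError("preprocessed predictors must not contain missing values")
        if self.y is not None and not np.isfinite(self.y).all():
            raise ValueError("response must be finite")


def preprocess_features(
    raw: pd.DataFrame,
    y: pd.Series | None = None,
    corr_cutoff: float = CORR_CUTOFF,
    impute: str = "mean",
) -> MLDataset:
    """caret-style preprocessing chain, applied in order.

    1. one-hot encode categorical columns;
    2. range-scale numeric features to [0, 1] (constant columns pass
       through for the zero-variance step);
    3. impute missing values with the column mean;
    4. drop zero-variance features;
    5. drop the later member of each feature pair with |r| >= cutoff
       (keeping the first by column order).

    Applying the chain twice equals applying it once.
    """
    if raw.empty:
        raise ValueError("empty predictor table")
    X = pd.get_dummies(raw, dtype=float)
    scaling: dict[str, tuple[float, float]] = {}
    for col in X.columns:
        lo, hi = X[col].min(), X[col].max()
        scaling[col] = (float(lo), float(hi))
        if hi > lo:
            X[col] = (X[col] - lo) / (hi - lo)
    if X.isna().any().any():
        if impute != "mean":
            raise ValueError(f"unknown imputation method {impute!r}")
        X = X.fillna(X.mean(axis=0))
    variances = X.var(axis=0, ddof=0)
    zero_var = list(X.columns[(variances == 0) | variances.isna()])
    X = X.drop(columns=zero_var)
    if X.shape[1] == 0:
        raise ValueError("all features eliminated by preprocessing")
    corr = X.corr().abs().to_numpy()
    keep: list[int] = []
    dropped_corr: list[str] = []
    for j in range(X.shape[1]):
        if any(corr[j, i] >= corr_cutoff for i in keep):
            dropped_corr.append(X.columns[j])
        else:
            keep.append(j)
    X = X.iloc[:, keep]
    return MLDataset(
        X=X,
        y=None if y is None else y.astype(float),
        dropped_zero_variance=zero_var,
        dropped_correlated=dropped_corr,
        scaling={c: scaling[c] for c in X.columns},
    )


def _make_search(model: str, seed: int) -> GridSearchCV:
    inner = KFold(n_splits=3, shuffle=True, random_state=seed)
    if model == "random_forest":
        est = RandomForestRegressor(n_estimators=200, random_state=seed)
        grid = {"max_features": [1.0, "sqrt"]}
    elif model == "regularized_nn":
        est = MLPRegressor(
            hidden_layer_sizes=(8,),
            solver="lbfgs",
            max_iter=5000,
            random_state=seed,
        )
        grid = {"alpha": [1e-4, 1e-2, 1.0]}
    else:
        raise ValueError(f"unknown model {model!r}")
    return GridSearchCV(est, grid, cv=inner, scoring="neg_root_mean_squared_error")


MODELS = ("random_forest", "regularized_nn")


@dataclass
class CVResult:
    model: str
    rmse_per_resample: np.ndarray  # length folds * repeats
    folds: int
    repeats: int
    seed: int
    best_params: list[dict]
    oof_predictions: pd.DataFrame  # columns: resample, row, y_true, y_pred
    fold_assignments: list[np.ndarray]

    @property
    def rmse_mean(self) -> float:
        return float(np.mean(self.rmse_per_resample))

    @property
    def rmse_sd(self) -> float:
        return float(np.std(self.rmse_per_resample, ddof=1))

    def r2_oof(self) -> float:
        """Out-of-fold R^2 pooled over all resamples."""
        df = self.oof_predictions
        ss_res = float(((df["y_true"] - df["y_pred"]) ** 2).sum())
        ss_tot = float(((df["y_true"] - df["y_true"].mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot

    def to_json_dict(self) -> dict:
        return {
            "model": self.model,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "rmse_per_resample": self.rmse_per_resample.tolist(),
            "rmse_mean": self.rmse_mean,
            "rmse_sd": self.rmse_sd,
            "r2_oof": self.r2_oof(),
            "best_params": self.best_params,
        }


def crossvalidate(
    data: MLDataset,
    model: str = "random_forest",
    folds: int = 3,
    repeats: int = 5,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold cross-validation scored by RMSE.

    Produces exactly ``folds * repeats`` resamples with fold assignment
    reproducible from ``seed``; hyperparameters are tuned by grid search
    inside each training split only.
    """
    if data.y is None:
        raise ValueError("dataset has no response")
    X = data.X.to_numpy(dtype=float)
    y = data.y.to_numpy(dtype=float)
    if len(X) < folds:
        raise ValueError(f"need at least {folds} rows, got {len(X)}")
    rkf = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    rmses, best_params, oof_rows, assignments = [], [], [], []
    for resample, (train, test) in enumerate(rkf.split(X)):
        assignments.append(test.copy())
        search = _make_search(model, seed)
        search.fit(X[train], y[train])
        pred = search.predict(X[test])
        rmses.append(float(np.sqrt(mean_squared_error(y[test], pred))))
        best_params.append(dict(search.best_params_))
        for row, yt, yp in zip(test, y[test], pred):
            oof_rows.append(
                {"resample": resample, "row": int(row), "y_true": float(yt),
                 "y_pred": float(yp)}
            )
    return CVResult(
        model=model,
        rmse_per_resample=np.asarray(rmses),
        folds=folds,
        repeats=repeats,
        seed=seed,
        best_params=best_params,
        oof_predictions=pd.DataFrame(oof_rows),
        fold_assignments=assignments,
    )


def permutation_baseline(
    data: MLDataset,
    model: str = "random_forest",
    n_shuffles: int = 20,
    folds: int = 3,
    seed: int = 0,
) -> dict:
    """Null reference: CV RMSE after permuting the response.

    Returns the mean RMSE over ``n_shuffles`` permutations (one CV repeat
    each) together with the response standard deviation — the RMSE a
    mean-only predictor attains, which an informative model should beat
    and a signal-free one should not.
    """
    if data.y is None:
        raise ValueError("dataset has no response")
    rng = np.random.default_rng(seed)
    y = data.y.to_numpy(dtype=float)
    rmses = []
    for s in range(n_shuffles):
        perm = rng.permutation(len(y))
        shuffled = MLDataset(X=data.X, y=pd.Series(y[perm], index=data.X.index))
        res = crossvalidate(
            shuffled, model=model, folds=folds, repeats=1, seed=seed + s + 1
        )
        rmses.append(res.rmse_mean)
    return {
        "rmse_mean": float(np.mean(rmses)),
        "rmse_sd": float(np.std(rmses, ddof=1)),
        "response_sd": float(np.std(y, ddof=0)),
        "n_shuffles": n_shuffles,
    }
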