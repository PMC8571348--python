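"""Per-scale gradient-boosted classifiers and their stacked ensemble.

One gradient-boosted tree classifier is trained per property scale on that
scale's 40-feature vectors; a second-stage gradient-boosted classifier then
takes the ten per-scale probabilities as input and produces the final
secretability probability.  Everything is evaluated out of fold under the
gene-grouped cross-validation, with per-fold hyperparameters picked by a
small seeded randomized search on a gene-grouped validation split of the
training data (so no gene ever informs its own prediction).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier

from .biophys import AAScale, load_scales
from .features import (
    FoldAssignment,
    SecretabilityDataset,
    auroc,
    feature_matrix,
)

__all__ = [
    "GBTrainConfig",
    "ScaleModelResult",
    "EnsembleResult",
    "train_scale_models",
    "train_ensemble",
    "run_gb_cv",
    "predict_scales",
]

# small fixed search space: tree complexity, shrinkage, boosting length
_PARAM_SPACE = {
    "num_leaves": [15, 31, 63],
    "learning_rate": [0.05, 0.1, 0.2],
    "n_estimators": [60, 120],
    "min_child_samples": [10, 20, 40],
}


@dataclass(frozen=True)
class GBTrainConfig:
    """Training controls for the per-scale models and the ensemble."""

    n_search: int = 3  # randomized-search samples per fold and model
    val_fraction: float = 0.2  # gene-grouped validation split for the search
    seed: int = 0


@dataclass
class ScaleModelResult:
    """Out-of-fold per-scale probabilities plus the fitted fold models."""

    oof: pd.DataFrame  # records x scales, out-of-fold probabilities
    models: dict[str, list[LGBMClassifier]]  # scale -> one model per fold
    full_models: dict[str, LGBMClassifier] = field(default_factory=dict)


@dataclass
class EnsembleResult:
    """Final out-of-fold ensemble probabilities plus fold models."""

    prob: pd.Series
    models: list[LGBMClassifier]
    full_model: LGBMClassifier | None = None


def _predict_proba(model: LGBMClassifier, x: np.ndarray) -> np.ndarray:
    # lightgbm's sklearn wrapper warns spuriously about feature names when
    # fitting and predicting on plain arrays; silence just that warning
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        return model.predict_proba(x)[:, 1]


def _make_model(params: dict, seed: int) -> LGBMClassifier:
    return LGBMClassifier(
        **params,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
        deterministic=True,
        force_row_wise=True,
    )


def _sample_params(rng: np.random.Generator, n: int) -> list[dict]:
    out = []
    for _ in range(n):
        out.append(
            {k: v[rng.integers(0, len(v))] for k, v in _PARAM_SPACE.items()}
        )
    return out


def _grouped_val_split(
    genes: list[str], rng: np.random.Generator, val_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean train/val masks splitting whole genes."""
    unique = sorted(set(genes))
    rng.shuffle(unique)
    n_val = max(1, int(round(val_fraction * len(unique))))
    val_genes = set(unique[:n_val])
    val_mask = np.array([g in val_genes for g in genes])
    return ~val_mask, val_mask


def _fit_with_search(
    x: np.ndarray,
    y: np.ndarray,
    genes: list[str],
    cfg: GBTrainConfig,
    rng: np.random.Generator,
) -> LGBMClassifier:
    """Randomized hyperparameter search on a grouped split, then refit."""
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class training data")
    candidates = _sample_params(rng, cfg.n_search)
    tr_mask, val_mask = _grouped_val_split(genes, rng, cfg.val_fraction)
    if len(np.unique(y[tr_mask])) < 2 or len(np.unique(y[val_mask])) < 2:
        # validation split unusable (tiny data): fall back to first candidate
        best = candidates[0]
    else:
        best, best_score = None, -np.inf
        for params in candidates:
            model = _make_model(params, int(rng.integers(0, 2**31 - 1)))
            model.fit(x[tr_mask], y[tr_mask])
            score = auroc(y[val_mask], _predict_proba(model, x[val_mask]))
            if score > best_score:
                best, best_score = params, score
    final = _make_model(best, int(rng.integers(0, 2**31 - 1)))
    final.fit(x, y)
    return final


def train_scale_models(
    dataset: SecretabilityDataset,
    folds: FoldAssignment,
    scales: dict[str, AAScale] | None = None,
    cfg: GBTrainConfig | None = None,
) -> ScaleModelResult:
    """Per-scale classifiers with out-of-fold probabilities.

    For every fold and every property scale, a classifier is trained on the
    training split (hyperparameters from a seeded randomized search) and
    predicts the held-out fold, yielding out-of-fold probabilities aligned
    to the dataset.
    """
    scales = scales or load_scales()
    cfg = cfg or GBTrainConfig()
    y = dataset.labels
    genes = np.array(dataset.gene_ids, dtype=object)
    oof = pd.DataFrame(
        np.nan, index=pd.Index(dataset.keys, name="fragment_key"),
        columns=list(scales),
    )
    models: dict[str, list[LGBMClassifier]] = {name: [] for name in scales}
    for name, scale in scales.items():
        x = feature_matrix(dataset.peptides, scale)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, zlib.crc32(name.encode())])
        )
        for fold in range(folds.n_folds):
            tr = folds.train_indices(fold)
            te = folds.test_indices(fold)
            model = _fit_with_search(x[tr], y[tr], list(genes[tr]), cfg, rng)
            models[name].append(model)
            if te.size:
                oof.iloc[te, oof.columns.get_loc(name)] = _predict_proba(
                    model, x[te]
                )
    return ScaleModelResult(oof=oof, models=models)


def train_ensemble(
    oof: pd.DataFrame,
    labels: np.ndarray,
    folds: FoldAssignment,
    genes: list[str],
    cfg: GBTrainConfig | None = None,
) -> EnsembleResult:
    """Second-stage classifier over the per-scale probability columns.

    Trained per fold on the out-of-fold probabilities of the other folds,
    predicting the held-out fold, so the final probabilities stay strictly
    out of fold.
    """
    cfg = cfg or GBTrainConfig()
    x = oof.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    genes_arr = np.array(genes, dtype=object)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 999]))
    prob = pd.Series(np.nan, index=oof.index, name="ensemble_prob")
    models = []
    for fold in range(folds.n_folds):
        tr = folds.train_indices(fold)
        te = folds.test_indices(fold)
        model = _fit_with_search(x[tr], y[tr], list(genes_arr[tr]), cfg, rng)
        models.append(model)
        if te.size:
            prob.iloc[te] = _predict_proba(model, x[te])
    return EnsembleResult(prob=prob, models=models)


def run_gb_cv(
    dataset: SecretabilityDataset,
    folds: FoldAssignment,
    scales: dict[str, AAScale] | None = None,
    cfg: GBTrainConfig | None = None,
) -> tuple[ScaleModelResult, EnsembleResult, float]:
    """Full cross-validated pipeline; returns (scale result, ensemble, AUROC)."""
    scale_res = train_scale_models(dataset, folds, scales, cfg)
    ens = train_ensemble(
        scale_res.oof, dataset.labels, folds, dataset.gene_ids, cfg
    )
    score = auroc(dataset.labels, ens.prob.to_numpy())
    return scale_res, ens, score


def fit_full(
    dataset: SecretabilityDataset,
    scale_res: ScaleModelResult,
    ens: EnsembleResult,
    scales: dict[str, AAScale] | None = None,
    cfg: GBTrainConfig | None = None,
) -> None:
    """Refit per-scale models on the full dataset for external prediction.

    The ensemble stage is refit on the cross-validated out-of-fold
    probabilities (standard stacking), so external predictions combine
    full-data per-scale models with an ensemble that never saw its own
    training probabilities in-fold.
    """
    scales = scales or load_scales()
    cfg = cfg or GBTrainConfig()
    y = dataset.labels
    for name, scale in scales.items():
        x = feature_matrix(dataset.peptides, scale)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 7, zlib.crc32(name.encode())])
        )
        scale_res.full_models[name] = _fit_with_search(
            x, y, dataset.gene_ids, cfg, rng
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7, 999]))
    ens.full_model = _fit_with_search(
        scale_res.oof.to_numpy(dtype=float), y, dataset.gene_ids, cfg, rng
    )


def predict_scales(
    scale_res: ScaleModelResult,
    ens: EnsembleResult,
    peptides: list[str],
    scales: dict[str, AAScale] | None = None,
) -> np.ndarray:
    """Ensemble probabilities for new peptides from the full-data models."""
    scales = scales or load_scales()
    if not scale_res.full_models or ens.full_model is None:
        raise ValueError("call fit_full before predicting external data")
    cols = []
    for name, scale in scales.items():
        x = feature_matrix(peptides, scale)
        cols.append(_predict_proba(scale_res.full_models[name], x))
    stacked = np.column_stack(cols)
    return _predict_proba(ens.full_model, stacked)
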