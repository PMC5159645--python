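"""Epsilon-SVR with an RBF kernel mapping windowed features to normalized ASA.

Training targets are ASA / 400 Å²; predictions are clipped to [0, 1.25]
(i.e. at most 500 Å²) before being reported, a small overshoot allowance so
genuinely large accessible areas are not censored at exactly 400 Å².

Model selection uses chain-level k-fold cross-validation: every position of
an RNA chain shares that chain's fold, so no chain contributes to both the
training and the test side of any fold.  The headline metric is the pooled
Pearson r over all held-out positions; a (C, γ) grid search maximizes it.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .evaluation_metrics import pearson

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1
CLIP_RANGE = (0.0, 1.25)  # normalized; 1.25 × 400 Å² = 500 Å²
MIN_TRAINING_ROWS = 10

# log2-spaced default grids for (C, γ)
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-3, 8))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-9, 2))


@dataclass(frozen=True)
class SvrConfig:
    """SVR hyperparameters plus the encoder window they were chosen for.

    ``gamma`` may be a positive float or "auto" (libsvm's 1/n_features
    default).  ``tol`` is the solver's stopping tolerance; it is kept tight
    so the converged solution is independent of training-row order.
    """

    C: float = 1.0
    gamma: float | str = "auto"
    epsilon: float = 0.1
    window: int = 40
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.epsilon <= 0:
            raise ValueError("C and epsilon must be > 0")
        if not (self.gamma == "auto" or (isinstance(self.gamma, (int, float)) and self.gamma > 0)):
            raise ValueError("gamma must be > 0 or 'auto'")


@dataclass
class TrainedModel:
    """Fitted regressor with everything needed to reproduce its predictions."""

    regressor: SVR
    config: SvrConfig
    mode: str = "seq"  # encoder mode the features came from
    profile_bounds: tuple[float, float] | None = None
    norm_constant: float = 400.0
    metadata: dict = field(default_factory=dict)
    format_version: int = MODEL_FORMAT_VERSION


@dataclass
class CVResult:
    """Chain-level cross-validation output."""

    predictions: dict[str, np.ndarray]  # held-out normalized predictions per chain
    targets: dict[str, np.ndarray]
    fold_of_chain: dict[str, int]
    pooled_r: float
    per_chain_r: dict[str, float]

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        order = sorted(self.predictions)
        p = np.concatenate([self.predictions[c] for c in order])
        t = np.concatenate([self.targets[c] for c in order])
        return p, t


def chain_kfold_split(
    chain_ids: Sequence[str], k: int, seed: int
) -> dict[str, int]:
    """Random chain-level partition into k folds of near-equal size.

    Deterministic for a given seed; fold sizes differ by at most one.
    """
    ids = list(chain_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate chain ids")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of chains ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            assignment[ids[idx]] = fold
    return assignment


def train(
    features: np.ndarray,
    targets: np.ndarray,
    cfg: SvrConfig | None = None,
    *,
    mode: str = "seq",
    profile_bounds: tuple[float, float] | None = None,
    metadata: dict | None = None,
) -> TrainedModel:
    """Fit the epsilon-SVR.  Only completeness-filtered rows should be passed."""
    cfg = cfg or SvrConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, d) aligned with (n,) targets")
    if X.shape[0] < MIN_TRAINING_ROWS:
        raise ValueError(
            f"refusing to train on {X.shape[0]} rows (< {MIN_TRAINING_ROWS})"
        )
    reg = SVR(
        kernel="rbf",
        C=cfg.C,
        gamma=cfg.gamma,
        epsilon=cfg.epsilon,
        tol=cfg.tol,
        cache_size=500,
    )
    reg.fit(X, y)
    return TrainedModel(
        regressor=reg,
        config=cfg,
        mode=mode,
        profile_bounds=profile_bounds,
        metadata=dict(metadata or {}),
    )


def predict(model: TrainedModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict (normalized, Å²) ASA; normalized output clipped to [0, 1.25]."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    d_model = model.regressor.n_features_in_
    if X.shape[1] != d_model:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model dimension {d_model}"
        )
    raw = model.regressor.predict(X)
    norm = np.clip(raw, *CLIP_RANGE)
    return norm, norm * model.norm_constant


def clip_prediction(raw: float | np.ndarray, norm_constant: float = 400.0):
    """The reporting rule applied to a raw regressor output."""
    norm = np.clip(raw, *CLIP_RANGE)
    return norm, norm * norm_constant


def cross_validate(
    chains: Mapping[str, tuple[np.ndarray, np.ndarray]],
    k: int = 5,
    seed: int = 0,
    cfg: SvrConfig | None = None,
    *,
    mode: str = "seq",
) -> CVResult:
    """Chain-level k-fold CV: each position predicted once, by a model that
    never saw its chain; returns held-out predictions and the pooled r."""
    cfg = cfg or SvrConfig(seed=seed)
    fold_of_chain = chain_kfold_split(list(chains), k, seed)
    predictions: dict[str, np.ndarray] = {}
    targets: dict[str, np.ndarray] = {}
    for fold in range(k):
        train_ids = [c for c, f in fold_of_chain.items() if f != fold]
        test_ids = [c for c, f in fold_of_chain.items() if f == fold]
        X_tr = np.concatenate([chains[c][0] for c in train_ids])
        y_tr = np.concatenate([chains[c][1] for c in train_ids])
        model = train(X_tr, y_tr, cfg, mode=mode)
        for c in test_ids:
            norm, _ = predict(model, chains[c][0])
            predictions[c] = norm
            targets[c] = np.asarray(chains[c][1], dtype=float)
    p = np.concatenate([predictions[c] for c in sorted(predictions)])
    t = np.concatenate([targets[c] for c in sorted(targets)])
    pooled_r = pearson(p, t)
    per_chain_r = {}
    for c in predictions:
        pc, tc = predictions[c], targets[c]
        if len(pc) >= 2 and np.ptp(pc) > 0 and np.ptp(tc) > 0:
            per_chain_r[c] = pearson(pc, tc)
    return CVResult(predictions, targets, fold_of_chain, pooled_r, per_chain_r)


def grid_search(
    chains: Mapping[str, tuple[np.ndarray, np.ndarray]],
    k: int = 5,
    seed: int = 0,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    base_cfg: SvrConfig | None = None,
) -> tuple[SvrConfig, pd.DataFrame]:
    """Exhaustive (C, γ) search maximizing pooled CV Pearson r.

    Ties break toward smaller C, then smaller γ.  Returns the winning config
    and the full audit table with one row per grid point.
    """
    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("grids must be non-empty")
    base_cfg = base_cfg or SvrConfig(seed=seed)
    rows = []
    best: tuple[float, float, float] | None = None  # (-r, C, gamma)
    best_cfg = None
    for C in C_grid:
        for gamma in gamma_grid:
            cfg = replace(base_cfg, C=C, gamma=gamma)
            try:
                r = cross_validate(chains, k=k, seed=seed, cfg=cfg).pooled_r
            except ValueError as exc:  # e.g. constant fold targets
                logger.warning("grid point C=%g gamma=%g skipped: %s", C, gamma, exc)
                r = np.nan
            rows.append({"C": C, "gamma": gamma, "pooled_r": r})
            if np.isfinite(r):
                key = (-r, C, gamma)
                if best is None or key < best:
                    best = key
                    best_cfg = cfg
    if best_cfg is None:
        raise ValueError("no grid point produced a defined correlation")
    return best_cfg, pd.DataFrame(rows)


def save_model(model: TrainedModel, path: str) -> None:
    """Persist the full model state (single pickle archive, version-stamped)."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh, protocol=4)


def load_model(path: str) -> TrainedModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, TrainedModel):
        raise ValueError(f"{path} does not contain a TrainedModel")
    if model.format_version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {model.format_version} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return model
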