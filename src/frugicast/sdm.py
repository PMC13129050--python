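"""Species distribution model (SDM) scaffolding.

The pieces around a habitat-suitability learner: spatial thinning of
occurrence records, collinearity pruning of predictors (pairwise r with
variance-inflation-factor tie-breaking), background definition and
pseudo-absence sampling, evaluation by the true skill statistic (TSS)
and ROC AUC, TSS-weighted ensembling of replicate models, and conversion
of continuous suitability into binary range maps at the TSS-maximizing
threshold.

Learners are pluggable behind a fit/predict contract (`fit(X, y)`,
`predict_suitability(X) -> scores in [0, 1]`).  The bundled baseline is a
regularized additive logistic model on standardized predictors — enough
signal to exercise every downstream stage; tree boosting or other
learners can be registered without touching the rest of the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .grids import BinaryRangeMap, GridSpec, check_same_grid

log = logging.getLogger(__name__)

__all__ = [
    "OccurrenceSet",
    "PredictorStack",
    "ModelEvaluation",
    "EnsemblePrediction",
    "thin_occurrences",
    "vif_prune",
    "make_background",
    "sample_pseudo_absences",
    "tss",
    "auc",
    "select_threshold",
    "BaselineLogisticLearner",
    "LEARNERS",
    "fit_learner",
    "run_replicates",
    "ensemble",
    "binarize",
    "fit_species_sdm",
]


@dataclass
class OccurrenceSet:
    """Point records with presence (1) / pseudo-absence (0) labels."""

    points: np.ndarray  # (n, 2) x,y
    labels: np.ndarray  # (n,) in {0, 1}

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.points.shape[0] != self.labels.shape[0]:
            raise ValueError("points and labels must align")
        if self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be 0/1")

    @property
    def presences(self) -> np.ndarray:
        return self.points[self.labels == 1]

    @property
    def absences(self) -> np.ndarray:
        return self.points[self.labels == 0]


@dataclass
class PredictorStack:
    """Named environmental layers sharing one grid."""

    grid: GridSpec
    layers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
            clean[name] = arr
        self.layers = clean

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def subset(self, names: Sequence[str]) -> "PredictorStack":
        return PredictorStack(self.grid, {n: self.layers[n] for n in names})

    def design_matrix(self) -> np.ndarray:
        """(n_cells, n_layers) matrix in row-major cell order."""
        return np.column_stack([self.layers[n].ravel() for n in self.names])

    def values_at(self, points: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) predictor values at the cells containing points."""
        pts = np.atleast_2d(points)
        row, col = self.grid.cell_of(pts[:, 0], pts[:, 1])
        return np.column_stack([self.layers[n][row, col] for n in self.names])


@dataclass(frozen=True)
class ModelEvaluation:
    """Holdout skill of one member model."""

    tss: float
    auc: float
    threshold: float

    def __post_init__(self) -> None:
        if not -1 <= self.tss <= 1:
            raise ValueError("TSS must lie in [-1, 1]")
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must lie in [0, 1]")


@dataclass
class EnsemblePrediction:
    """TSS-weighted mean suitability surface."""

    suitability: np.ndarray
    member_weights: np.ndarray
    grid: GridSpec = field(repr=False)

    def __post_init__(self) -> None:
        self.member_weights = np.asarray(self.member_weights, dtype=float)
        if not np.isclose(self.member_weights.sum(), 1.0):
            raise ValueError("member weights must sum to 1")
        if np.any(self.member_weights < 0):
            raise ValueError("member weights must be non-negative")


# ---------------------------------------------------------------------------
# Occurrence preparation


def thin_occurrences(
    points: np.ndarray, min_distance: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Spatially thin points so no retained pair is closer than ``min_distance``.

    Greedy: repeatedly delete the point with the most neighbours inside the
    radius, breaking ties at random with the given seed.  Euclidean planar
    distance.
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] <= 1:
        return pts.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    close = cdist(pts, pts) < min_distance
    np.fill_diagonal(close, False)
    alive = np.ones(pts.shape[0], dtype=bool)
    degree = close.sum(axis=1)
    while True:
        deg_alive = np.where(alive, degree, -1)
        worst = deg_alive.max()
        if worst <= 0:
            break
        candidates = np.flatnonzero(deg_alive == worst)
        victim = rng.choice(candidates)
        alive[victim] = False
        degree[close[victim]] -= 1
        degree[victim] = 0
    return pts[alive]


def vif_prune(stack: PredictorStack, r_threshold: float = 0.6) -> list[str]:
    """Iteratively drop the higher-VIF member of each over-correlated pair.

    While any retained pair of layers has |Pearson r| above ``r_threshold``,
    the member with the larger variance inflation factor (from regressing it
    on all other retained layers) is removed.  Constant layers are undefined
    under correlation and are dropped up front with a warning.  Returns the
    retained layer names; all retained pairwise |r| ≤ threshold.
    """
    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least two layers to prune")
    X = stack.design_matrix()
    keep: list[str] = []
    cols: list[int] = []
    for j, name in enumerate(names):
        if np.std(X[:, j]) == 0:
            warnings.warn(f"dropping constant predictor layer {name!r}", stacklevel=2)
        else:
            keep.append(name)
            cols.append(j)

    def _vif(idx: int, retained: list[int]) -> float:
        others = [k for k in retained if k != idx]
        if not others:
            return 1.0
        y = X[:, idx]
        A = np.column_stack([X[:, others], np.ones(X.shape[0])])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        return np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)

    retained = cols[:]
    while len(retained) >= 2:
        sub = X[:, retained]
        corr = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        if abs(corr[i, j]) <= r_threshold:
            break
        a, b = retained[i], retained[j]
        drop = a if _vif(a, retained) >= _vif(b, retained) else b
        retained.remove(drop)
    return [names[k] for k in retained]


def make_background(
    points: np.ndarray,
    pad: float = 10.0,
    clip_to: tuple[float, float, float, float] | None = None,
) -> tuple[float, float, float, float]:
    """Background extent: presence bounding box padded by ``pad`` per side,
    optionally clipped to the landscape extent.  Returns (xmin, ymin, xmax, ymax)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("at least one presence required")
    xmin, ymin = pts.min(axis=0) - pad
    xmax, ymax = pts.max(axis=0) + pad
    if clip_to is not None:
        xmin = max(xmin, clip_to[0])
        ymin = max(ymin, clip_to[1])
        xmax = min(xmax, clip_to[2])
        ymax = min(ymax, clip_to[3])
    return (float(xmin), float(ymin), float(xmax), float(ymax))


def sample_pseudo_absences(
    extent: tuple[float, float, float, float],
    n_presences: int,
    grid: GridSpec,
    presence_cells: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample pseudo-absence points, one per draw, equal in number to presences.

    Draws cells uniformly (with replacement) from the background extent,
    excluding cells that contain a presence, and places each point at the
    cell centre.  Reproducible under ``seed``.
    """
    if n_presences == 0:
        return np.empty((0, 2))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x0, y0 = grid.origin
    s = grid.cell_size
    col_lo = max(0, int(np.floor((extent[0] - x0) / s)))
    row_lo = max(0, int(np.floor((extent[1] - y0) / s)))
    col_hi = min(grid.n_cols, int(np.ceil((extent[2] - x0) / s)))
    row_hi = min(grid.n_rows, int(np.ceil((extent[3] - y0) / s)))
    rows, cols = np.meshgrid(np.arange(row_lo, row_hi), np.arange(col_lo, col_hi), indexing="ij")
    eligible = np.ones(rows.shape, dtype=bool)
    if presence_cells is not None and len(presence_cells):
        occupied = np.zeros(grid.shape, dtype=bool)
        pc = np.asarray(presence_cells)
        occupied[pc[:, 0], pc[:, 1]] = True
        eligible = ~occupied[rows, cols]
    flat_rows = rows[eligible].ravel()
    flat_cols = cols[eligible].ravel()
    if flat_rows.size == 0:
        raise ValueError("no eligible background cells for pseudo-absences")
    idx = rng.integers(0, flat_rows.size, size=n_presences)
    xs = x0 + (flat_cols[idx] + 0.5) * s
    ys = y0 + (flat_rows[idx] + 0.5) * s
    return np.column_stack([xs, ys])


# ---------------------------------------------------------------------------
# Evaluation


def tss(tp: int, fp: int, tn: int, fn: int) -> float:
    """True skill statistic: sensitivity + specificity − 1."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("TSS undefined when a class is empty")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens + spec - 1.0


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC: probability a random presence outscores a random absence,
    ties counting one half (rank statistic)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _tss_at(scores: np.ndarray, labels: np.ndarray, thr: float) -> float:
    pred = scores >= thr
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tss(tp, fp, tn, fn)


def select_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """TSS-maximizing binarization threshold.

    Candidates are the observed score values plus 0 and 1; among maximizers
    the smallest threshold is returned (favouring sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold selection needs both classes")
    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    best_thr, best_tss = None, -np.inf
    for thr in candidates:  # ascending, so first maximizer is the smallest
        t = _tss_at(scores, labels, thr)
        if t > best_tss + 1e-12:
            best_tss, best_thr = t, thr
    return float(best_thr)


# ---------------------------------------------------------------------------
# Learners


class BaselineLogisticLearner:
    """Regularized additive logistic suitability model on standardized
    predictors.  Satisfies the learner contract: ``fit(X, y)`` then
    ``predict_suitability(X)`` returning scores in [0, 1].

    Each predictor enters with a linear and a quadratic term, so the log
    odds are an additive sum of per-predictor parabolas — unimodal
    (Gaussian-niche-like) responses are representable, not only monotone
    ones.
    """

    def __init__(self, C: float = 1.0, seed: int = 0):
        self._model = make_pipeline(
            StandardScaler(), LogisticRegression(C=C, max_iter=1000, random_state=seed)
        )

    @staticmethod
    def _augment(X: np.ndarray) -> np.ndarray:
        return np.column_stack([X, X**2])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaselineLogisticLearner":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D design matrix")
        if np.all(np.std(X, axis=0) == 0):
            raise ValueError("all predictors are constant; cannot fit")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self._model.fit(self._augment(X), np.asarray(y, dtype=int))
        return self

    def predict_suitability(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict_proba(self._augment(np.asarray(X, dtype=float)))[:, 1]


#: Registry of learner factories; each takes a seed and returns an unfitted learner.
LEARNERS: dict[str, Callable[[int], object]] = {
    "logistic": lambda seed: BaselineLogisticLearner(seed=seed),
}


def fit_learner(
    train: OccurrenceSet, predictors: PredictorStack, algorithm: str = "logistic", seed: int = 0
):
    """Fit one suitability model on the training occurrences."""
    if algorithm not in LEARNERS:
        raise ValueError(f"unknown algorithm {algorithm!r}; registered: {list(LEARNERS)}")
    X = predictors.values_at(train.points)
    learner = LEARNERS[algorithm](seed)
    return learner.fit(X, train.labels)


@dataclass
class MemberModel:
    """One fitted replicate: its suitability surface and holdout skill.

    ``model`` retains the fitted learner so the member can be projected
    onto predictor stacks for other climate scenarios.
    """

    prediction: np.ndarray
    evaluation: ModelEvaluation
    algorithm: str
    replicate: int
    model: object = None


def run_replicates(
    data: OccurrenceSet,
    predictors: PredictorStack,
    n_replicates: int = 15,
    algorithms: Sequence[str] = ("logistic",),
    split: float = 0.75,
    seed: int = 0,
) -> list[MemberModel]:
    """Repeated random-split model runs.

    Each replicate draws a seeded random split (``split`` fraction for
    calibration, remainder for evaluation), fits each algorithm, scores TSS
    and AUC on the holdout only, and predicts suitability over the full grid.
    """
    n = data.labels.shape[0]
    n_train = int(round(split * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("too few records for the requested split")
    rng = np.random.default_rng(seed)
    members: list[MemberModel] = []
    grid_X = predictors.design_matrix()
    for rep in range(n_replicates):
        # stratified shuffle so both classes appear on both sides of the split
        for _ in range(100):
            perm = rng.permutation(n)
            tr, ho = perm[:n_train], perm[n_train:]
            if len(np.unique(data.labels[tr])) == 2 and len(np.unique(data.labels[ho])) == 2:
                break
        else:
            raise ValueError("could not form a split with both classes on each side")
        train = OccurrenceSet(data.points[tr], data.labels[tr])
        member_seed = int(rng.integers(0, 2**31 - 1))
        for algo in algorithms:
            model = fit_learner(train, predictors, algorithm=algo, seed=member_seed)
            ho_scores = model.predict_suitability(predictors.values_at(data.points[ho]))
            ho_labels = data.labels[ho]
            thr = select_threshold(ho_scores, ho_labels)
            ev = ModelEvaluation(
                tss=_tss_at(ho_scores, ho_labels, thr),
                auc=auc(ho_scores, ho_labels),
                threshold=thr,
            )
            surface = model.predict_suitability(grid_X).reshape(predictors.grid.shape)
            members.append(MemberModel(surface, ev, algo, rep, model))
    return members


def ensemble(members: Sequence[MemberModel], grid: GridSpec) -> EnsemblePrediction:
    """TSS-weighted ensemble of member predictions.

    Weights are proportional to max(TSS, 0) and normalized to sum to one;
    members with TSS ≤ 0 (no better than random) get zero weight.
    """
    if not members:
        raise ValueError("ensemble needs at least one member")
    raw = np.array([max(m.evaluation.tss, 0.0) for m in members])
    if raw.sum() <= 0:
        raise ValueError("all members have TSS <= 0; no skillful model to ensemble")
    w = raw / raw.sum()
    surface = np.tensordot(w, np.stack([m.prediction for m in members]), axes=1)
    return EnsemblePrediction(suitability=surface, member_weights=w, grid=grid)


def binarize(
    prediction: EnsemblePrediction | np.ndarray,
    threshold: float,
    species_id: str,
    scenario: str,
    grid: GridSpec | None = None,
) -> BinaryRangeMap:
    """Binary range map: presence wherever suitability ≥ threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if isinstance(prediction, EnsemblePrediction):
        surface, grid = prediction.suitability, prediction.grid
    else:
        surface = np.asarray(prediction, dtype=float)
        if grid is None:
            raise ValueError("grid required for raw-array input")
    return BinaryRangeMap((surface >= threshold).astype(np.int8), species_id, scenario, grid)


# ---------------------------------------------------------------------------
# Species-level convenience


def fit_species_sdm(
    presences: np.ndarray,
    predictors_by_scenario: dict[str, PredictorStack],
    species_id: str,
    n_replicates: int = 15,
    algorithms: Sequence[str] = ("logistic",),
    split: float = 0.75,
    thin_distance: float | None = None,
    pad: float = 10.0,
    seed: int = 0,
) -> dict[str, BinaryRangeMap]:
    """Full per-species workflow: thin, background, pseudo-absences,
    replicated fits, TSS-weighted ensemble, threshold on the current-scenario
    ensemble, then projection and binarization under every scenario.

    ``predictors_by_scenario`` must include a ``"current"`` stack; all stacks
    share one grid.  The same TSS-maximizing threshold (selected on the
    current ensemble at the training points) is applied to every projection.
    """
    current = predictors_by_scenario["current"]
    grid = check_same_grid(*(s.grid for s in predictors_by_scenario.values()))
    rng = np.random.default_rng(seed)
    pts = np.atleast_2d(np.asarray(presences, dtype=float))
    if thin_distance is not None:
        pts = thin_occurrences(pts, thin_distance, seed=rng)
    extent = make_background(pts, pad=pad, clip_to=grid.extent)
    row, col = grid.cell_of(pts[:, 0], pts[:, 1])
    presence_cells = np.column_stack([row, col])
    pa = sample_pseudo_absences(extent, len(pts), grid, presence_cells, seed=rng)
    data = OccurrenceSet(
        np.vstack([pts, pa]), np.concatenate([np.ones(len(pts), int), np.zeros(len(pa), int)])
    )
    members = run_replicates(
        data, current, n_replicates=n_replicates, algorithms=algorithms, split=split,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ens = ensemble(members, grid)
    row_all, col_all = grid.cell_of(data.points[:, 0], data.points[:, 1])
    ens_scores = ens.suitability[row_all, col_all]
    thr = select_threshold(ens_scores, data.labels)

    # project every member onto each scenario's predictor stack, then take the
    # same TSS-weighted mean and apply the one threshold chosen above
    weights = ens.member_weights
    maps: dict[str, BinaryRangeMap] = {}
    for scen, stack in predictors_by_scenario.items():
        surfaces = np.stack(
            [m.model.predict_suitability(stack.design_matrix()) for m in members]
        )
        surface = np.tensordot(weights, surfaces, axes=1).reshape(grid.shape)
        maps[scen] = binarize(surface, thr, species_id, scen, grid)
    return maps
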