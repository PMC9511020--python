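"""Training and evaluation under stratified protocols.

Implements the study protocol: a stratified 80:20 train/test split over
age groups (and sex when available), optional stratified 5-fold
cross-validation, mini-batch training (batch 16) with Adam on
cross-entropy (classification) or mean-squared-error (regression), and
the reported metrics — accuracy with per-class confusion counts, and
MAE / RMSE / r² for age regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import StratifiedKFold

from .autodiff import Tensor, gather_rows, logsumexp
from .models import ModelSpec, Network, build_model, predict
from .types import GROUP_ORDER, Subject

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "MetricsReport",
    "stratified_split",
    "train",
    "evaluate_classification",
    "evaluate_regression",
    "cross_validate",
]


@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"subjects in both sets: {sorted(overlap)[:5]}")


@dataclass
class TrainConfig:
    epochs: int = 100
    lr: float = 1e-3
    batch_size: int = 16
    seed: int = 0
    # Adam moments; weight decay intentionally zero
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


@dataclass
class MetricsReport:
    task: str
    n: int
    accuracy: float | None = None           # percent
    confusion: np.ndarray | None = None     # rows = true class, cols = predicted
    mae: float | None = None                # years
    rmse: float | None = None               # years
    r2: float | None = None                 # coefficient of determination
    r2_pearson: float | None = None         # squared Pearson correlation, for reference
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"task": self.task, "n": self.n}
        for k in ("accuracy", "mae", "rmse", "r2", "r2_pearson"):
            v = getattr(self, k)
            if v is not None:
                d[k] = float(v)
        if self.confusion is not None:
            d["confusion"] = self.confusion.tolist()
        return d


def stratified_split(subjects: list[Subject], ratio: float = 0.2, seed: int = 0,
                     use_sex: bool = True) -> SplitPlan:
    """Hold out ``ratio`` of each age group (x sex stratum when available).

    Per-group test counts are round(ratio * n) aggregated over sex strata,
    so they deviate from the exact fraction by at most one subject.
    Deterministic under ``seed``.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strata: dict[tuple, list[Subject]] = {}
    have_sex = use_sex and all(s.sex not in ("", "NA") for s in subjects)
    for s in subjects:
        key = (s.group, s.sex) if have_sex else (s.group,)
        strata.setdefault(key, []).append(s)
    if have_sex and any(len(m) < 2 for m in strata.values()):
        # degrade to age-group-only stratification rather than failing
        logger.warning("a (group, sex) stratum has < 2 subjects; stratifying by age group only")
        strata = {}
        for s in subjects:
            strata.setdefault((s.group,), []).append(s)
    for key, members in strata.items():
        if len(members) < 2:
            raise ValueError(f"stratum {key} has fewer than 2 subjects; cannot split")
    test_ids, train_ids = [], []
    # per age group, round the group-level test count then spread over sex strata
    groups: dict[str, list[tuple]] = {}
    for key in strata:
        groups.setdefault(key[0], []).append(key)
    for group in sorted(groups):
        keys = sorted(groups[group], key=str)
        n_group = sum(len(strata[k]) for k in keys)
        n_test_group = int(round(ratio * n_group))
        n_test_group = min(max(n_test_group, 1), n_group - 1)
        # largest-remainder allocation across sex strata
        quotas = [ratio * len(strata[k]) for k in keys]
        base = [int(np.floor(q)) for q in quotas]
        short = n_test_group - sum(base)
        order = np.argsort([base[i] - quotas[i] for i in range(len(keys))])
        for i in order[:max(short, 0)]:
            base[i] += 1
        for k, n_test in zip(keys, base):
            members = sorted(strata[k], key=lambda s: s.subject_id)
            perm = rng.permutation(len(members))
            chosen = set(perm[:n_test].tolist())
            for pos, s in enumerate(members):
                (test_ids if pos in chosen else train_ids).append(s.subject_id)
    return SplitPlan(sorted(train_ids), sorted(test_ids), ratio, seed)


class _Adam:
    def __init__(self, params, cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros(p.data.shape) for p in params]
        self.v = [np.zeros(p.data.shape) for p in params]
        self.t = 0

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.tensor.grad
            if g is None:
                continue
            self.m[i] = c.beta1 * self.m[i] + (1 - c.beta1) * g
            self.v[i] = c.beta2 * self.v[i] + (1 - c.beta2) * g * g
            m_hat = self.m[i] / (1 - c.beta1 ** self.t)
            v_hat = self.v[i] / (1 - c.beta2 ** self.t)
            p.tensor.data -= c.lr * m_hat / (np.sqrt(v_hat) + c.eps)


def _batch_loss(model: Network, xb: np.ndarray, yb: np.ndarray) -> Tensor:
    out = model.forward(Tensor(xb[:, None, :, :]))
    if model.spec.task == "classification":
        return (logsumexp(out, axis=-1) - gather_rows(out, yb.astype(np.intp))).mean()
    resid = out.reshape(out.shape[0]) - Tensor(yb.astype(np.float64))
    return (resid * resid).mean()


def train(model: Network, x: np.ndarray, y: np.ndarray, config: TrainConfig | None = None
          ) -> tuple[Network, list[float]]:
    """Mini-batch Adam training; returns the model and per-epoch mean loss.

    ``x`` is (n, p, p) standardized connectivity matrices; ``y`` is integer
    class labels (classification) or ages in years (regression).  Epoch
    shuffling is seeded, so two runs with the same seed produce identical
    weights.
    """
    cfg = config or TrainConfig()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y length mismatch")
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, cfg)
    trace: list[float] = []
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            model.zero_grad()
            loss = _batch_loss(model, x[idx], y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    return model, trace


def classification_report(y_pred: np.ndarray, y_true: np.ndarray, n_classes: int = 4) -> MetricsReport:
    """Accuracy (percent, = 100 * correct/total) and confusion counts."""
    y_true = np.asarray(y_true, dtype=np.intp)
    y_pred = np.asarray(y_pred, dtype=np.intp)
    if y_true.size == 0:
        raise ValueError("empty test set")
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (y_true, y_pred), 1)
    acc = 100.0 * float((y_pred == y_true).mean())
    return MetricsReport(task="classification", n=int(y_true.size), accuracy=acc, confusion=confusion)


def evaluate_classification(model: Network, x: np.ndarray, y: np.ndarray) -> MetricsReport:
    """Accuracy and 4x4 confusion counts of a model on a held-out set."""
    if np.asarray(y).size == 0:
        raise ValueError("empty test set")
    probs = predict(model, x)
    return classification_report(probs.argmax(axis=1), y, n_classes=model.spec.n_classes)


def evaluate_regression(y_pred: np.ndarray, y_true: np.ndarray) -> MetricsReport:
    """MAE, RMSE and r² between predicted and chronological age.

    r² is the coefficient of determination (can be negative); the squared
    Pearson correlation is reported alongside for reference.
    """
    y_pred = np.asarray(y_pred, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.float64)
    if y_pred.shape != y_true.shape or y_pred.ndim != 1 or y_pred.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.var(y_true) == 0:
        raise ValueError("zero variance in true ages: r2 undefined")
    mae = float(mean_absolute_error(y_true, y_pred))
    rmse = float(np.sqrt(mean_squared_error(y_true, y_pred)))
    r2 = float(r2_score(y_true, y_pred))
    r = np.corrcoef(y_pred, y_true)[0, 1] if np.var(y_pred) > 0 else 0.0
    return MetricsReport(task="regression", n=int(y_true.size), mae=mae, rmse=rmse,
                         r2=r2, r2_pearson=float(r * r))


def _labels_for_task(subjects_y: np.ndarray, task: str) -> np.ndarray:
    if task == "classification":
        return subjects_y.astype(np.intp)
    return subjects_y.astype(np.float64)


def cross_validate(spec: ModelSpec, x: np.ndarray, y: np.ndarray, groups: np.ndarray,
                   k: int = 5, config: TrainConfig | None = None
                   ) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold CV with fresh Kaiming initialization per fold.

    ``groups`` gives the age-group index per subject and drives the
    stratification (for regression too, as group bins are the natural
    strata of age).  Returns per-fold reports and their arithmetic mean.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    cfg = config or TrainConfig()
    groups = np.asarray(groups)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    reports: list[MetricsReport] = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(groups)), groups)):
        if spec.task == "classification" and len(np.unique(y[tr])) < spec.n_classes:
            raise ValueError(f"fold {fold}: training part is missing a class")
        model = build_model(spec, seed=cfg.seed + fold)
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + fold})
        model, _ = train(model, x[tr], _labels_for_task(y[tr], spec.task), fold_cfg)
        if spec.task == "classification":
            reports.append(evaluate_classification(model, x[te], y[te].astype(np.intp)))
        else:
            reports.append(evaluate_regression(predict(model, x[te]), y[te].astype(np.float64)))
    mean = MetricsReport(task=spec.task, n=int(sum(r.n for r in reports)))
    for attr in ("accuracy", "mae", "rmse", "r2", "r2_pearson"):
        vals = [getattr(r, attr) for r in reports]
        if all(v is not None for v in vals):
            setattr(mean, attr, float(np.mean(vals)))
    return reports, mean


def group_index(subjects: list[Subject]) -> np.ndarray:
    """Integer age-group label per subject, in cohort order young..old."""
    return np.array([GROUP_ORDER.index(s.group) for s in subjects], dtype=np.intp)
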