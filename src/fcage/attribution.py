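"""Integrated-gradients attribution and connectome-level aggregation.

Attributions follow the straight-path Riemann approximation

    IG_i(x) ≈ (x_i − x'_i) · (1/m) Σ_{k=1..m} ∂F(x' + (k/m)(x − x'))/∂x_i

with the all-zero connectivity matrix as the default baseline x'.  For
classification F is, by default, the softmax probability of the predicted
class (a flag switches to the pre-softmax logit); for regression F is the
predicted age.  Because the input matrix is symmetric, the raw gradient
w.r.t. positions (i, j) and (j, i) both describe the same undirected
edge: the attribution matrix folds the two triangles (sum) and mirrors,
so entry (i, j) carries the full attribution of edge {i, j}.

Aggregations: group-mean attribution matrices, signed per-ROI node
strengths, the thresholded edge-contribution table, per-ROI age
trajectory labels (decreasing / inverted-U / flat), and per-network
distribution summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor, gather_rows, softmax
from .models import Network
from .types import GROUP_ORDER

__all__ = [
    "AttributionMatrix",
    "integrated_gradients",
    "mean_group_attribution",
    "node_strength",
    "edge_contribution_table",
    "trajectory_classification",
    "group_density_summary",
]


@dataclass
class AttributionMatrix:
    """Per-edge integrated-gradient attribution, folded to symmetric form.

    ``total`` is the raw (unfolded) attribution sum, the quantity the
    completeness property compares with F(x) − F(baseline).
    """

    values: np.ndarray  # (p, p), symmetric
    target: str         # class label or "regression"
    subject_id: str | None = None
    total: float = 0.0
    f_x: float = 0.0
    f_baseline: float = 0.0
    steps: int = 0


def _model_scalar(model: Network, xb: Tensor, target_class: int | None, use_logit: bool) -> Tensor:
    """Batch of scalar outputs F per interpolated input."""
    out = model.forward(xb)
    if model.spec.task == "regression":
        return out.reshape(out.shape[0])
    idx = np.full(xb.shape[0], target_class, dtype=np.intp)
    if use_logit:
        return gather_rows(out, idx)
    return gather_rows(softmax(out, axis=-1), idx)


def integrated_gradients(
    model: Network,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 50,
    target: int | str = "predicted",
    use_logit: bool = False,
    subject_id: str | None = None,
    auto_escalate: bool = True,
    batch_size: int = 50,
) -> AttributionMatrix:
    """Attribute a model output to the edges of one connectivity matrix.

    ``target`` is "predicted" (classification: the argmax class at x),
    an explicit class index, or ignored for regression.  When
    ``auto_escalate`` is set, the step count doubles (up to 8x) while the
    completeness residual |Σ IG − (F(x) − F(x'))| exceeds 5% of |ΔF|.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    p = model.spec.input_size
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (p, p):
        raise ValueError(f"expected a ({p}, {p}) matrix, got {x.shape}")
    x0 = np.zeros((p, p)) if baseline is None else np.asarray(baseline, dtype=np.float64)
    if x0.shape != (p, p):
        raise ValueError("baseline shape mismatch")

    if model.spec.task == "classification":
        if target == "predicted":
            out = model.forward(Tensor(x[None, None]))
            target_class = int(out.data[0].argmax())
        else:
            target_class = int(target)
        target_name = GROUP_ORDER[target_class] if target_class < len(GROUP_ORDER) else str(target_class)
    else:
        target_class = None
        target_name = "regression"

    f_x = float(_model_scalar(model, Tensor(x[None, None]), target_class, use_logit).data[0])
    f_b = float(_model_scalar(model, Tensor(x0[None, None]), target_class, use_logit).data[0])

    m = steps
    max_m = steps * 8
    while True:
        grads = np.zeros((p, p))
        alphas = (np.arange(1, m + 1) / m)
        for start in range(0, m, batch_size):
            chunk = alphas[start : start + batch_size]
            xb_data = x0[None] + chunk[:, None, None] * (x - x0)[None]
            xb = Tensor(xb_data[:, None, :, :], requires_grad=True)
            f = _model_scalar(model, xb, target_class, use_logit)
            if not np.all(np.isfinite(f.data)):
                bad = int(np.flatnonzero(~np.isfinite(f.data))[0]) + start + 1
                raise FloatingPointError(f"non-finite model output at interpolation step {bad}")
            f.sum().backward()
            if not np.all(np.isfinite(xb.grad)):
                bad = int(np.flatnonzero(~np.isfinite(xb.grad).all(axis=(1, 2, 3)))[0]) + start + 1
                raise FloatingPointError(f"non-finite gradient at interpolation step {bad}")
            grads += xb.grad[:, 0].sum(axis=0)
        raw = (x - x0) * grads / m
        total = float(raw.sum())
        delta_f = f_x - f_b
        if not auto_escalate or m >= max_m or abs(total - delta_f) <= 0.05 * max(abs(delta_f), 1e-12):
            break
        m *= 2

    off = raw - np.diag(np.diag(raw))
    folded = off + off.T  # each undirected edge counted once, then mirrored
    values = folded + np.diag(np.diag(raw))
    return AttributionMatrix(values=values, target=target_name, subject_id=subject_id,
                             total=total, f_x=f_x, f_baseline=f_b, steps=m)


def mean_group_attribution(attributions: list[AttributionMatrix], groups: list[str]
                           ) -> dict[str, AttributionMatrix]:
    """Elementwise mean attribution matrix within each of the 4 age groups."""
    if len(attributions) != len(groups):
        raise ValueError("one group label per attribution required")
    out: dict[str, AttributionMatrix] = {}
    for g in GROUP_ORDER:
        members = [a for a, gg in zip(attributions, groups) if gg == g]
        if not members:
            raise ValueError(f"age group {g!r} is empty")
        mean_vals = np.mean([a.values for a in members], axis=0)
        out[g] = AttributionMatrix(values=mean_vals, target=g,
                                   total=float(np.mean([a.total for a in members])),
                                   steps=members[0].steps)
    return out


def node_strength(attr: AttributionMatrix | np.ndarray, roi_labels: list[str] | None = None
                  ) -> pd.DataFrame:
    """Signed per-ROI strengths: sums of positive / negative incident edges.

    net = positive + negative; the diagonal is excluded (not an edge).
    """
    vals = attr.values if isinstance(attr, AttributionMatrix) else np.asarray(attr, dtype=np.float64)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("attribution matrix must be square")
    if np.abs(vals - vals.T).max() > 1e-9:
        raise ValueError("attribution matrix must be symmetric")
    p = vals.shape[0]
    off = vals - np.diag(np.diag(vals))
    pos = np.clip(off, 0, None).sum(axis=1)
    neg = np.clip(off, None, 0).sum(axis=1)
    labels = roi_labels or [f"ROI{i:03d}" for i in range(p)]
    return pd.DataFrame({"roi": labels, "positive": pos, "negative": neg, "net": pos + neg})


def edge_contribution_table(
    group_means: dict[str, AttributionMatrix],
    atlas: pd.DataFrame | None = None,
    threshold: float = 0.2,
    roi_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Edge table with one strength column per age group.

    An edge is retained only if its |strength| reaches ``threshold`` in at
    least one group; edges below the threshold in every group are omitted.
    ROI names are resolved (and validated) against the atlas when given.
    """
    missing = [g for g in GROUP_ORDER if g not in group_means]
    if missing:
        raise ValueError(f"missing group(s): {missing}")
    mats = [group_means[g].values for g in GROUP_ORDER]
    p = mats[0].shape[0]
    labels = roi_labels or [f"ROI{i:03d}" for i in range(p)]
    if atlas is not None:
        known = set(atlas["roi_label"])
        unknown = [lab for lab in labels if lab not in known]
        if unknown:
            raise KeyError(f"ROI label(s) not in atlas: {unknown[:5]}")
        net_of = dict(zip(atlas["roi_label"], atlas["network"]))
    rows = []
    for i in range(1, p):
        for j in range(i):
            strengths = [m[i, j] for m in mats]
            if max(abs(s) for s in strengths) < threshold:
                continue
            row = {"roi1": labels[j], "roi2": labels[i]}
            if atlas is not None:
                row["network1"] = net_of[labels[j]]
                row["network2"] = net_of[labels[i]]
            row.update({g: s for g, s in zip(GROUP_ORDER, strengths)})
            rows.append(row)
    cols = ["roi1", "roi2"] + (["network1", "network2"] if atlas is not None else []) + list(GROUP_ORDER)
    return pd.DataFrame(rows, columns=cols)


def trajectory_classification(values, tau: float = 0.01) -> str:
    """Label an ordered young→old 4-value profile.

    Rules (documented tolerance ``tau``):

    * ``inverted_U`` — the maximum sits at adult or middle_old, the young
      end is lower by more than ``tau``, and the old end is strictly lower.
    * ``decreasing`` — otherwise, if the profile is non-increasing within
      ``tau`` and the total young→old decline exceeds ``tau``.
    * ``flat`` — everything else.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.shape != (4,):
        raise ValueError("need exactly 4 ordered group values (young, adult, middle_old, old)")
    if not np.all(np.isfinite(v)):
        raise ValueError("missing/non-finite group value")
    peak = int(v.argmax())
    if peak in (1, 2) and v[0] < v[peak] - tau and v[3] < v[peak]:
        return "inverted_U"
    if np.all(np.diff(v) <= tau) and (v[0] - v[3]) > tau:
        return "decreasing"
    return "flat"


def group_density_summary(cells: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    """Distribution summaries per (network, age group) cell.

    ``cells[network][group]`` holds the within-network connectivity or
    attribution values of that group.  Each row reports n, mean, sd and
    quartiles; cells with fewer than 2 values are flagged rather than
    fatal.  Per network, the age direction is the trajectory label of the
    four group means.
    """
    rows = []
    for network, by_group in cells.items():
        means = []
        for g in GROUP_ORDER:
            vals = np.asarray(by_group.get(g, []), dtype=np.float64)
            if vals.size < 2:
                rows.append({"network": network, "group": g, "n": int(vals.size),
                             "flag": "insufficient"})
                means.append(np.nan)
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"network": network, "group": g, "n": int(vals.size),
                         "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                         "q1": float(q1), "median": float(med), "q3": float(q3), "flag": ""})
            means.append(float(vals.mean()))
        direction = (trajectory_classification(means) if np.all(np.isfinite(means)) else "NA")
        for row in rows[-4:]:
            row["direction"] = direction
    return pd.DataFrame(rows)
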