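"""Synthetic multi-subject ROI time series with planted age effects.

Real resting-state cohorts are not redistributable, so every pipeline
stage is exercised on simulated data whose inter-regional correlation
structure varies with age along planted trajectories:

* ``E_dec``   — edges whose correlation declines linearly from young to old,
* ``E_invU``  — edges following an inverted-U profile peaking in mid-life,
* ``E_null``  — edges with an age-constant correlation,

with all remaining edges at zero.  Each subject's target correlation
matrix is repaired to the nearest positive-semidefinite correlation
matrix (eigenvalue clipping, unit-diagonal rescale), sampled as T
multivariate-normal timepoints, and overlaid with independent
observation noise.  The planted edges are disjoint and each node carries
at most one trajectory edge plus at most one null edge with total
off-diagonal mass < 1, so the target matrix is diagonally dominant and
the PSD repair is a no-op under the defaults.

Defaults (n = 600 subjects, p = 32 regions, T = 200 timepoints, ages
uniform over 20-88, noise sd 0.2) give a planted signal strong enough
for end-to-end recovery at desk scale; a ``reference_cohort`` preset
reproduces the reference cohort's group sizes (172/152/154/160) and
p = 100 for shape-fidelity checks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .types import AGE_GROUPS, AGE_MAX, AGE_MIN, GROUP_ORDER, RoiTimeSeries, Subject, assign_age_group

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "target_correlation",
    "nearest_psd_correlation",
    "sample_subject",
    "generate_cohort",
    "default_config",
    "reference_cohort_config",
]

Edge = tuple[int, int]


@dataclass
class GeneratorConfig:
    n_subjects: int = 600
    p: int = 32
    T: int = 200
    seed: int = 0
    #: (r at age 20, r at age 88) for linearly decreasing edges
    dec_range: tuple[float, float] = (0.6, 0.2)
    #: (peak r, r at the farther endpoint) for inverted-U edges
    invu_range: tuple[float, float] = (0.6, 0.2)
    invu_peak_age: float = 60.0
    null_r: float = 0.3
    noise_sd: float = 0.2
    edges_dec: list[Edge] = field(default_factory=list)
    edges_invu: list[Edge] = field(default_factory=list)
    edges_null: list[Edge] = field(default_factory=list)
    #: per-group subject counts; None = ages uniform over [20, 88]
    group_sizes: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if not self.edges_dec and not self.edges_invu and not self.edges_null:
            self._default_edges()
        self._validate()

    def _default_edges(self) -> None:
        # disjoint node pairs: trajectory edges pair consecutive nodes,
        # null edges connect across pairs, keeping row mass < 1 (PSD safe)
        half = self.p // 2
        self.edges_dec = [(2 * i, 2 * i + 1) for i in range(min(8, half // 2))]
        self.edges_invu = [(half + 2 * i, half + 2 * i + 1) for i in range(min(8, half // 2))]
        self.edges_null = [(4 * i, 4 * i + 2) for i in range(min(8, self.p // 4))]

    def _validate(self) -> None:
        sets = [set(self.edges_dec), set(self.edges_invu), set(self.edges_null)]
        for a in range(3):
            for b in range(a + 1, 3):
                if sets[a] & sets[b]:
                    raise ValueError("planted edge sets must be disjoint")
        for i, j in self.edges_dec + self.edges_invu + self.edges_null:
            if not (0 <= j < i < self.p or 0 <= i < j < self.p) or i == j:
                raise ValueError(f"bad edge ({i}, {j}) for p={self.p}")
        for r in (*self.dec_range, *self.invu_range, self.null_r):
            if not -0.95 < r < 0.95:
                raise ValueError("target correlations must lie in (-0.95, 0.95)")

    def roi_labels(self) -> list[str]:
        return [f"ROI{i:03d}" for i in range(self.p)]

    def atlas_rows(self) -> list[tuple[str, str, str]]:
        """Synthetic atlas: 8 ROIs per network, alternating hemispheres."""
        rows = []
        for i, lab in enumerate(self.roi_labels()):
            rows.append((lab, f"SynNet{i // 8 + 1}", "LH" if i % 2 == 0 else "RH"))
        return rows

    def to_dict(self) -> dict:
        d = asdict(self)
        d["edges_dec"] = [list(e) for e in self.edges_dec]
        d["edges_invu"] = [list(e) for e in self.edges_invu]
        d["edges_null"] = [list(e) for e in self.edges_null]
        if d["group_sizes"] is not None:
            d["group_sizes"] = list(d["group_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for k in ("edges_dec", "edges_invu", "edges_null"):
            d[k] = [tuple(e) for e in d[k]]
        d["dec_range"] = tuple(d["dec_range"])
        d["invu_range"] = tuple(d["invu_range"])
        if d.get("group_sizes") is not None:
            d["group_sizes"] = tuple(d["group_sizes"])
        return cls(**d)


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    return GeneratorConfig(seed=seed, **overrides)


def reference_cohort_config(seed: int = 0) -> GeneratorConfig:
    """Cohort with the reference group sizes 172/152/154/160 and p = 100."""
    return GeneratorConfig(n_subjects=638, p=100, seed=seed, group_sizes=(172, 152, 154, 160))


@dataclass
class SyntheticCohort:
    config: GeneratorConfig
    subjects: list[Subject]
    timeseries: list[RoiTimeSeries]
    target_matrices: list[np.ndarray]  # per-subject pre-noise correlation targets

    def edge_truth(self) -> dict[str, list[Edge]]:
        return {
            "decreasing": list(self.config.edges_dec),
            "inverted_U": list(self.config.edges_invu),
            "null": list(self.config.edges_null),
        }

    def node_truth(self) -> dict[int, str]:
        """Planted trajectory class per node incident to a trajectory edge."""
        truth: dict[int, str] = {}
        for i, j in self.config.edges_dec:
            truth[i] = truth[j] = "decreasing"
        for i, j in self.config.edges_invu:
            truth[i] = truth[j] = "inverted_U"
        return truth


def target_correlation(age: float, edge_class: str, config: GeneratorConfig) -> float:
    """Planted target correlation of an edge class at a given age."""
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age {age} outside [{AGE_MIN}, {AGE_MAX}]")
    if edge_class == "decreasing":
        r_hi, r_lo = config.dec_range
        return r_hi + (age - AGE_MIN) / (AGE_MAX - AGE_MIN) * (r_lo - r_hi)
    if edge_class == "inverted_U":
        r_peak, r_end = config.invu_range
        span = max(config.invu_peak_age - AGE_MIN, AGE_MAX - config.invu_peak_age)
        frac = (age - config.invu_peak_age) / span
        return r_peak - (r_peak - r_end) * frac * frac
    if edge_class == "null":
        return config.null_r
    raise ValueError(f"unknown edge class {edge_class!r}")


def _target_matrix(age: float, config: GeneratorConfig) -> np.ndarray:
    c = np.eye(config.p)
    for cls, edges in (("decreasing", config.edges_dec), ("inverted_U", config.edges_invu),
                       ("null", config.edges_null)):
        r = target_correlation(age, cls, config)
        for i, j in edges:
            c[i, j] = c[j, i] = r
    return c


def nearest_psd_correlation(c: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``eig_floor`` and rescale to unit diagonal."""
    c = (c + c.T) / 2.0
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= eig_floor:
        return c
    vals = np.clip(vals, eig_floor, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    if np.any(d <= 0):
        raise ValueError("PSD repair failed: non-positive diagonal")
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def sample_subject(age: float, config: GeneratorConfig, seed: int,
                   subject_id: str | None = None) -> tuple[RoiTimeSeries, np.ndarray]:
    """Draw one subject's T x p series from the age-specific target matrix.

    Returns the series and the (PSD-repaired, pre-noise) target matrix.
    Deterministic under ``seed``.
    """
    target = nearest_psd_correlation(_target_matrix(age, config))
    chol = np.linalg.cholesky(target + 1e-12 * np.eye(config.p))
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((config.T, config.p)) @ chol.T
    observed = latent + config.noise_sd * rng.standard_normal((config.T, config.p))
    sid = subject_id or f"sub{seed:06d}"
    return RoiTimeSeries(sid, observed, config.roi_labels()), target


def _draw_ages(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if config.group_sizes is None:
        return rng.uniform(AGE_MIN, AGE_MAX, size=config.n_subjects)
    if sum(config.group_sizes) != config.n_subjects:
        raise ValueError("group_sizes must sum to n_subjects")
    ages = []
    for label, n in zip(GROUP_ORDER, config.group_sizes):
        lo, hi = AGE_GROUPS[label]
        ages.append(rng.uniform(lo, hi + 0.999, size=n))  # closed integer bins
    return np.clip(np.concatenate(ages), AGE_MIN, AGE_MAX)


def generate_cohort(config: GeneratorConfig, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate the full cohort; optionally write TSV/JSON artifacts.

    Writes (when ``out_dir`` is given) one time-series TSV per subject,
    a subject manifest, a synthetic atlas, the config, and the planted
    edge ground truth — in the exact dialects the readers expect.
    """
    if config.n_subjects < 8:
        warnings.warn("fewer than 8 subjects: a 4-group stratified split downstream will fail",
                      stacklevel=2)
    rng = np.random.default_rng(config.seed)
    ages = _draw_ages(config, rng)
    sexes = rng.choice(["F", "M"], size=config.n_subjects)
    child_seeds = rng.integers(0, 2**31 - 1, size=config.n_subjects)
    subjects, series, targets = [], [], []
    for k in range(config.n_subjects):
        sid = f"sub{k:04d}"
        ts, target = sample_subject(float(ages[k]), config, int(child_seeds[k]), subject_id=sid)
        subjects.append(Subject(sid, round(float(ages[k]), 2), str(sexes[k])))
        series.append(ts)
        targets.append(target)
    cohort = SyntheticCohort(config, subjects, series, targets)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, out: Path) -> None:
    from .io import write_atlas, write_manifest, write_timeseries  # local import: io imports types only

    out.mkdir(parents=True, exist_ok=True)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for ts in cohort.timeseries:
        write_timeseries(ts, ts_dir / f"{ts.subject_id}.tsv")
    write_manifest(cohort.subjects, out / "manifest.tsv")
    write_atlas(cohort.config.atlas_rows(), out / "atlas.tsv")
    (out / "generator_config.json").write_text(json.dumps(cohort.config.to_dict(), indent=2))
    truth = {k: [list(e) for e in v] for k, v in cohort.edge_truth().items()}
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
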