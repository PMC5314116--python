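"""Synthetic ground-truth data for every pipeline input.

Generates (i) multi-subject linear non-Gaussian structural-equation time
series over the circuit regions, (ii) the probabilistic sucrose-tasting task
schedule, (iii) streamline-count matrices with injected group effects, and
(iv) per-subject behavioral tables whose group moments match given targets
exactly. All generators are pure functions of (spec, seed).

The SEM draws each time point i.i.d. from x = B'x + e, B[i, j] being the
coefficient of edge i -> j, solved by topological substitution; the implied
covariance is (I - B')^{-1} D (I - B')^{-T} with D the noise variances. No
hemodynamic model is applied by default, since the causal search operates on
extracted ROI series; an optional double-gamma HRF convolution is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionTaxonomy, enumerate_tracts
from .graphs import PDAG, GraphError
from .scores import ROITimeSeriesSet
from .stats import GroupMoments, GroupSummary
from .tracts import StreamlineData

NOISE_FAMILIES = ("gaussian", "uniform", "laplace", "exponential")

DEFAULT_CIRCUIT_REGIONS: tuple[str, ...] = (
    "thalamus",
    "dorsal_anterior_insula",
    "posterior_insula",
    "central_nucleus_amygdala",
    "medial_OFC",
    "ventral_striatum",
    "hypothalamus",
    "anterior_cingulate",
)

# Ground-truth edges of the default 8-node circuit simulation, following the
# taste hierarchy: thalamic relay -> insula -> amygdala/OFC -> striatum, with
# hypothalamic and cingulate inputs converging on the ventral striatum.
DEFAULT_CIRCUIT_EDGES: tuple[tuple[str, str, float], ...] = (
    ("thalamus", "dorsal_anterior_insula", 0.6),
    ("thalamus", "posterior_insula", 0.5),
    ("dorsal_anterior_insula", "central_nucleus_amygdala", 0.5),
    ("dorsal_anterior_insula", "medial_OFC", 0.45),
    ("posterior_insula", "ventral_striatum", 0.5),
    ("central_nucleus_amygdala", "hypothalamus", 0.55),
    ("medial_OFC", "ventral_striatum", 0.4),
    ("hypothalamus", "ventral_striatum", 0.5),
    ("anterior_cingulate", "ventral_striatum", 0.45),
)


@dataclass
class SimulationSpec:
    """Ground-truth DAG, noise family and sampling plan for the SEM generator."""

    region_labels: tuple[str, ...]
    coefficients: np.ndarray  # B[i, j] = weight of edge i -> j
    noise_family: str = "uniform"
    noise_scale: np.ndarray | float = 1.0
    n_subjects: int = 20
    n_timepoints: int = 200
    seed: int = 0
    hrf_convolve: bool = False

    def __post_init__(self) -> None:
        self.region_labels = tuple(self.region_labels)
        p = len(self.region_labels)
        self.coefficients = np.asarray(self.coefficients, float)
        if self.coefficients.shape != (p, p):
            raise GraphError(f"coefficient matrix must be {p} x {p}")
        if np.any(np.diag(self.coefficients) != 0):
            raise GraphError("coefficient matrix must have a zero diagonal")
        if self.noise_family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.noise_family!r}")
        if np.isscalar(self.noise_scale):
            self.noise_scale = np.full(p, float(self.noise_scale))
        else:
            self.noise_scale = np.asarray(self.noise_scale, float)
        if np.any(self.noise_scale <= 0):
            raise ValueError("noise_scale must be positive")
        if self.n_timepoints < 10:
            raise ValueError("need at least 10 time points")
        if self.topological_order() is None:
            raise GraphError("coefficient matrix encodes a cyclic graph")

    def topological_order(self) -> list[int] | None:
        """Kahn's algorithm on the nonzero pattern; None when cyclic."""
        p = len(self.region_labels)
        adj = self.coefficients != 0
        indeg = adj.sum(axis=0)
        order, ready = [], [i for i in range(p) if indeg[i] == 0]
        indeg = indeg.copy()
        while ready:
            u = ready.pop()
            order.append(u)
            for v in np.nonzero(adj[u])[0]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    ready.append(int(v))
        return order if len(order) == p else None

    def true_dag(self) -> PDAG:
        g = PDAG(len(self.region_labels))
        for i, j in zip(*np.nonzero(self.coefficients)):
            g.add_directed(int(i), int(j))
        return g

    def implied_covariance(self) -> np.ndarray:
        """Closed-form stationary covariance (I - B')^{-1} D (I - B')^{-T}."""
        p = len(self.region_labels)
        a = np.linalg.inv(np.eye(p) - self.coefficients.T)
        d = np.diag(np.asarray(self.noise_scale) ** 2)
        return a @ d @ a.T

    @classmethod
    def default_circuit(cls, **overrides) -> "SimulationSpec":
        """The default 8-node taste-reward circuit simulation."""
        labels = DEFAULT_CIRCUIT_REGIONS
        idx = {v: i for i, v in enumerate(labels)}
        b = np.zeros((len(labels), len(labels)))
        for u, v, w in DEFAULT_CIRCUIT_EDGES:
            b[idx[u], idx[v]] = w
        return cls(region_labels=labels, coefficients=b, **overrides)

    def with_reversed_edge(self, source: str, target: str) -> "SimulationSpec":
        """Copy of the spec with one edge's direction reversed (must stay acyclic)."""
        idx = {v: i for i, v in enumerate(self.region_labels)}
        i, j = idx[source], idx[target]
        if self.coefficients[i, j] == 0:
            raise GraphError(f"no edge {source} -> {target} to reverse")
        b = self.coefficients.copy()
        b[j, i], b[i, j] = b[i, j], 0.0
        return SimulationSpec(
            self.region_labels, b, self.noise_family, self.noise_scale.copy(),
            self.n_subjects, self.n_timepoints, self.seed, self.hrf_convolve,
        )

    def to_json(self) -> str:
        return json.dumps({
            "region_labels": list(self.region_labels),
            "coefficients": self.coefficients.tolist(),
            "noise_family": self.noise_family,
            "noise_scale": np.asarray(self.noise_scale).tolist(),
            "n_subjects": self.n_subjects,
            "n_timepoints": self.n_timepoints,
            "seed": self.seed,
            "hrf_convolve": self.hrf_convolve,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationSpec":
        d = json.loads(text)
        return cls(
            tuple(d["region_labels"]), np.asarray(d["coefficients"], float),
            d.get("noise_family", "uniform"), np.asarray(d.get("noise_scale", 1.0)),
            d.get("n_subjects", 20), d.get("n_timepoints", 200),
            d.get("seed", 0), d.get("hrf_convolve", False),
        )


def _draw_noise(rng: np.random.Generator, family: str, scale: np.ndarray,
                size: tuple[int, int]) -> np.ndarray:
    """Zero-mean noise with SD ``scale`` per column."""
    if family == "gaussian":
        e = rng.normal(0.0, 1.0, size)
    elif family == "uniform":
        e = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size)
    elif family == "laplace":
        e = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size)
    elif family == "exponential":
        e = rng.exponential(1.0, size) - 1.0
    else:  # pragma: no cover - guarded by SimulationSpec
        raise ValueError(family)
    return e * scale


def double_gamma_hrf(n_taps: int = 16, tr: float = 2.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(n_taps) * tr
    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    return h / h.sum()


def generate_sem_timeseries(spec: SimulationSpec) -> tuple[ROITimeSeriesSet, PDAG]:
    """Multi-subject SEM time series plus the generating DAG.

    Each row is an independent draw of x = B'x + e; subjects differ only in
    their noise realizations. Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    p = len(spec.region_labels)
    inv = np.linalg.inv(np.eye(p) - spec.coefficients)
    subjects = []
    for s in range(spec.n_subjects):
        e = _draw_noise(rng, spec.noise_family, np.asarray(spec.noise_scale),
                        (spec.n_timepoints, p))
        x = e @ inv  # row form of x = (I - B')^{-1} e
        if spec.hrf_convolve:
            h = double_gamma_hrf()
            x = np.column_stack([np.convolve(x[:, j], h)[: spec.n_timepoints]
                                 for j in range(p)])
        subjects.append((f"sub-{s + 1:03d}", x))
    return ROITimeSeriesSet(subjects, spec.region_labels), spec.true_dag()


def random_dag_spec(
    n_nodes: int,
    rng: np.random.Generator,
    edge_prob: float = 0.3,
    coef_range: tuple[float, float] = (0.3, 0.8),
    noise_family: str = "uniform",
    **overrides,
) -> SimulationSpec:
    """Random DAG over generic labels: random order, Bernoulli edges, signed
    coefficients with |beta| in ``coef_range``."""
    order = rng.permutation(n_nodes)
    b = np.zeros((n_nodes, n_nodes))
    for ii in range(n_nodes):
        for jj in range(ii + 1, n_nodes):
            if rng.random() < edge_prob:
                mag = rng.uniform(*coef_range)
                sign = rng.choice([-1.0, 1.0])
                b[order[ii], order[jj]] = sign * mag
    labels = tuple(f"v{i}" for i in range(n_nodes))
    seed = int(rng.integers(0, 2**31 - 1))
    return SimulationSpec(labels, b, noise_family=noise_family, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Task schedule
# ---------------------------------------------------------------------------

@dataclass
class TaskSchedule:
    """Ordered CS/US trials of the probabilistic sucrose-tasting paradigm.

    280 trials: 100 sucrose-CS (80 deliver sucrose, 20 nothing), 100 null-CS
    (80 deliver nothing, 20 sucrose), 80 saliva-CS (always saliva). The first
    10 trials are fixed reinforced sucrose trials establishing the CS-US
    association and count toward the 80 reinforced sucrose trials.
    """

    trials: list[tuple[str, str]] = field(default_factory=list)

    def counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for t in self.trials:
            out[t] = out.get(t, 0) + 1
        return out

    def validate(self) -> None:
        c = self.counts()
        checks = {
            ("sucrose", "sucrose"): 80,
            ("sucrose", "none"): 20,
            ("null", "none"): 80,
            ("null", "sucrose"): 20,
            ("saliva", "saliva"): 80,
        }
        for key, want in checks.items():
            if c.get(key, 0) != want:
                raise ValueError(f"trial count {key} = {c.get(key, 0)}, expected {want}")
        if self.trials[:10] != [("sucrose", "sucrose")] * 10:
            raise ValueError("first 10 trials must be fixed reinforced sucrose trials")


def generate_task_schedule(seed: int = 0) -> TaskSchedule:
    """Seeded task schedule: fixed first 10 trials, uniform shuffle of the rest."""
    pool = (
        [("sucrose", "sucrose")] * 70
        + [("sucrose", "none")] * 20
        + [("null", "none")] * 80
        + [("null", "sucrose")] * 20
        + [("saliva", "saliva")] * 80
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    schedule = TaskSchedule([("sucrose", "sucrose")] * 10 + [pool[i] for i in order])
    schedule.validate()
    return schedule


# ---------------------------------------------------------------------------
# Streamline counts
# ---------------------------------------------------------------------------

def generate_streamline_dataset(
    taxonomy: RegionTaxonomy,
    n_subjects_per_group: Mapping[str, int],
    seed: int = 0,
    baseline_probability: tuple[float, float] = (0.005, 0.05),
    dispersion: float = 20.0,
    samples_per_voxel: int = 5000,
    path_length_range: tuple[float, float] = (10.0, 60.0),
    group_effects: Mapping[str, Mapping[tuple[str, str, str], float]] | None = None,
) -> dict[str, dict[str, dict[tuple[str, str], StreamlineData]]]:
    """Per-subject streamline inputs with optional multiplicative group effects.

    Per-tract baseline connection probabilities are drawn once (log-uniform over
    ``baseline_probability``); per-subject counts are negative-binomial around
    the implied mean with the given dispersion. ``group_effects[group]`` maps
    (hemisphere, seed, target) to a factor applied to that tract's forward and
    reverse means. Returns {group: {subject_id: {(region, hemisphere):
    StreamlineData}}}.
    """
    rng = np.random.default_rng(seed)
    tracts = enumerate_tracts(taxonomy)
    base = {
        t.key(): float(np.exp(rng.uniform(np.log(baseline_probability[0]),
                                          np.log(baseline_probability[1]))))
        for t in tracts
    }
    lengths = {t.key(): float(rng.uniform(*path_length_range)) for t in tracts}
    group_effects = group_effects or {}

    def nb(mean: float) -> int:
        p = dispersion / (dispersion + mean)
        return int(rng.negative_binomial(dispersion, p))

    dataset: dict[str, dict[str, dict[tuple[str, str], StreamlineData]]] = {}
    for group in sorted(n_subjects_per_group):
        effects = group_effects.get(group, {})
        dataset[group] = {}
        for s in range(n_subjects_per_group[group]):
            sid = f"{group}-{s + 1:03d}"
            counts: dict[tuple[str, str], dict[str, int]] = {}
            plens: dict[tuple[str, str], dict[str, float]] = {}
            for t in tracts:
                key = t.key()
                factor = effects.get(key, 1.0)
                p_fwd = min(base[key] * factor, 0.5)
                total_fwd = t.seed.volume * samples_per_voxel
                total_rev = t.target.volume * samples_per_voxel
                fwd = min(nb(p_fwd * total_fwd), total_fwd)
                rev = min(nb(0.5 * p_fwd * total_rev), total_rev)
                counts.setdefault((t.seed.label, t.hemisphere), {})[t.target.label] = fwd
                counts.setdefault((t.target.label, t.hemisphere), {})[t.seed.label] = rev
                jitter = float(rng.normal(0.0, 1.0))
                plen = max(1.0, lengths[key] + jitter)
                plens.setdefault((t.seed.label, t.hemisphere), {})[t.target.label] = plen
                plens.setdefault((t.target.label, t.hemisphere), {})[t.seed.label] = plen
            dataset[group][sid] = {
                (label, hemi): StreamlineData(
                    seed=taxonomy.get(label, hemi),
                    n_seed_voxels=taxonomy.get(label, hemi).volume,
                    counts=counts[(label, hemi)],
                    mean_path_length=plens[(label, hemi)],
                    samples_per_voxel=samples_per_voxel,
                )
                for (label, hemi) in counts
            }
    return dataset


# ---------------------------------------------------------------------------
# Behavioral tables
# ---------------------------------------------------------------------------

def load_behavioral_targets() -> list[GroupSummary]:
    """The packaged demographic/behavioral summary table as generator targets."""
    text = resources.files("tastecircuit.data").joinpath(
        "behavioral_summaries.json").read_text()
    payload = json.loads(text)
    ns = payload["groups"]
    summaries = []
    for variable, groups in payload["variables"].items():
        moments = [GroupMoments(g, mean, sd, ns[g]) for g, (mean, sd) in groups.items()]
        summaries.append(GroupSummary(variable, moments))
    return summaries


def generate_behavioral_table(
    targets: Sequence[GroupSummary], seed: int = 0
) -> pd.DataFrame:
    """Tidy per-subject table whose group moments match the targets exactly.

    Normal draws are affinely rescaled per group so the sample mean and sample
    SD (n-1) equal the target moments; the same subject ids are reused across
    variables.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for summary in targets:
        for g in summary.groups:
            draws = rng.normal(0.0, 1.0, g.n)
            draws = (draws - draws.mean()) / draws.std(ddof=1)
            values = g.mean + g.sd * draws
            for i, v in enumerate(values):
                rows.append((f"{g.label}-{i + 1:03d}", g.label, summary.variable, float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "variable", "value"])
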