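"""Normalized tract connection strength from probabilistic-tractography streamline counts.

Probabilistic tractography launches ``samples_per_voxel`` Monte-Carlo streamlines
from every seed voxel; the fraction reaching a target indexes anatomical
connection probability. The normalized connection strength of a seed->target
tract divides the seed->target probability by the seed's total connection
probability, multiplies by the mean of the forward and reverse probabilities,
and divides by the target volume, rescaling for seed and target size. Physical
path length is corrected by weighting streamline counts with the mean path
length (distance correction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .atlas import Region, RegionTaxonomy, TractDefinition, enumerate_tracts

logger = logging.getLogger(__name__)

DEFAULT_SAMPLES_PER_VOXEL = 5000


class StreamlineInputError(ValueError):
    pass


@dataclass
class StreamlineData:
    """Per-seed streamline counts toward each target, with sampling metadata."""

    seed: Region
    n_seed_voxels: int
    counts: dict[str, int]
    mean_path_length: dict[str, float] = field(default_factory=dict)
    samples_per_voxel: int = DEFAULT_SAMPLES_PER_VOXEL

    def __post_init__(self) -> None:
        if self.n_seed_voxels <= 0 or self.samples_per_voxel <= 0:
            raise StreamlineInputError("n_seed_voxels and samples_per_voxel must be positive")
        total = self.total_samples
        for target, count in self.counts.items():
            if count < 0 or count > total:
                raise StreamlineInputError(
                    f"count for {target} must be in [0, {total}], got {count}"
                )
            if count > 0 and self.mean_path_length.get(target, 1.0) <= 0:
                raise StreamlineInputError(f"non-positive path length for {target}")

    @property
    def total_samples(self) -> int:
        return self.n_seed_voxels * self.samples_per_voxel


@dataclass
class PathwayMeasure:
    """Connection strength (and optional mean FA) for one tract of one subject."""

    tract: TractDefinition
    connection_strength: float
    mean_path_length: float | None = None
    mean_fa: float | None = None
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing and self.connection_strength < 0:
            raise ValueError("connection_strength must be non-negative")
        if self.mean_fa is not None and not 0.0 <= self.mean_fa <= 1.0:
            raise ValueError("mean_fa must lie in [0, 1]")


def connection_probability(
    data: StreamlineData, target: str, distance_correct: bool = False
) -> float:
    """Fraction of launched samples reaching ``target``.

    With ``distance_correct`` the count is weighted by the tract's mean path
    length in mm before dividing by the number of samples (probtrackx
    distance-correction semantics); the result is then probability-like but
    not bounded by 1.
    """
    if target not in data.counts:
        raise KeyError(f"target {target!r} absent from streamline counts")
    count = data.counts[target]
    if count == 0:
        return 0.0
    weight = data.mean_path_length[target] if distance_correct else 1.0
    return count * weight / data.total_samples


def total_seed_probability(data: StreamlineData, distance_correct: bool = False) -> float:
    """Sum of connection probabilities over all recorded targets of the seed."""
    return sum(
        connection_probability(data, target, distance_correct) for target in data.counts
    )


def normalize_connection_strength(
    forward: StreamlineData,
    reverse: StreamlineData | None,
    target_volume: int,
    target: str | None = None,
    distance_correct: bool = False,
) -> float:
    """Normalized, dimensionless connection strength of one seed->target tract.

    With p_st the forward seed->target probability, P_seed the seed's total
    connection probability and p_ts the reverse (target->seed) probability,

        strength = ((p_st / P_seed) * mean(p_st, p_ts)) / target_volume

    A missing reverse run falls back to mean(p_st, p_st) = p_st with a logged
    warning. A seed that reaches nothing (P_seed = 0) yields 0 with a warning.
    """
    if target_volume <= 0:
        raise StreamlineInputError("target_volume must be positive")
    if target is None:
        if len(forward.counts) != 1:
            raise StreamlineInputError("target must be named when forward has several targets")
        target = next(iter(forward.counts))
    p_st = connection_probability(forward, target, distance_correct)
    p_seed = total_seed_probability(forward, distance_correct)
    if p_seed == 0.0:
        logger.warning("seed %s reaches no target; connection strength set to 0",
                       forward.seed.label)
        return 0.0
    if reverse is None:
        logger.warning("no reverse run for %s -> %s; using forward probability only",
                       forward.seed.label, target)
        p_ts = p_st
    else:
        p_ts = connection_probability(reverse, forward.seed.label, distance_correct)
    p_mean = 0.5 * (p_st + p_ts)
    return (p_st / p_seed) * p_mean / target_volume


def mean_fa_along_tract(
    fa_values: Sequence[float], visitation_counts: Sequence[int]
) -> float:
    """Visitation-count-weighted mean FA over the voxels a tract traverses.

    FA (fractional anisotropy) lies in [0, 1]; voxels never visited carry no
    weight. All-zero visitation means the pathway is undefined.
    """
    fa = np.asarray(fa_values, dtype=float)
    counts = np.asarray(visitation_counts, dtype=float)
    if fa.shape != counts.shape:
        raise ValueError("fa_values and visitation_counts must have equal length")
    if fa.size and (fa.min() < 0 or fa.max() > 1):
        raise ValueError("FA values must lie in [0, 1]")
    total = counts.sum()
    if total <= 0:
        raise StreamlineInputError("pathway undefined: all visitation counts are zero")
    return float(np.dot(fa, counts) / total)


def build_pathway_table(
    streamlines: Mapping[tuple[str, str], StreamlineData],
    taxonomy: RegionTaxonomy,
    distance_correct: bool = False,
) -> list[PathwayMeasure]:
    """One PathwayMeasure per enumerated tract from per-seed streamline runs.

    ``streamlines`` maps (seed label, hemisphere) to that seed's StreamlineData.
    A tract whose forward seed run is absent is recorded as missing (NaN
    strength) and the table construction continues; a missing reverse run
    degrades to the forward-only fallback.
    """
    measures: list[PathwayMeasure] = []
    for tract in enumerate_tracts(taxonomy):
        forward = streamlines.get((tract.seed.label, tract.hemisphere))
        if forward is None or tract.target.label not in forward.counts:
            logger.warning("missing forward data for %s -> %s (%s)",
                           tract.seed.label, tract.target.label, tract.hemisphere)
            measures.append(PathwayMeasure(tract, math.nan, missing=True))
            continue
        reverse = streamlines.get((tract.target.label, tract.hemisphere))
        if reverse is not None and tract.seed.label not in reverse.counts:
            reverse = None
        volume = tract.target.volume
        if volume is None:
            raise StreamlineInputError(
                f"target volume unknown for {tract.target.label} ({tract.hemisphere})"
            )
        strength = normalize_connection_strength(
            forward, reverse, volume, target=tract.target.label,
            distance_correct=distance_correct,
        )
        measures.append(
            PathwayMeasure(
                tract, strength,
                mean_path_length=forward.mean_path_length.get(tract.target.label),
            )
        )
    return measures
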