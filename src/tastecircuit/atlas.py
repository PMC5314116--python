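"""Taste-reward circuit taxonomy: regions, hemispheres and allowed seed->target tracts.

The circuit follows the gustatory/food-reward hierarchy: thalamic taste relay
projects to insular subregions and the frontal operculum; insula projects to
amygdala nuclei, ventral striatum and prefrontal/orbitofrontal cortex; amygdala
and OFC subregions project onward to hypothalamus, ventral striatum, medial PFC
and anterior cingulate. Tracts are strictly ipsilateral. The default taxonomy
enumerates 49 seed->target pairs per hemisphere, 98 in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

REGION_VOCABULARY: tuple[str, ...] = (
    "thalamus",
    "dorsal_anterior_insula",
    "ventral_anterior_insula",
    "posterior_insula",
    "frontal_operculum",
    "substantia_nigra",
    "central_nucleus_amygdala",
    "basolateral_amygdala",
    "medial_OFC",
    "middle_OFC",
    "gyrus_rectus",
    "inferior_OFC",
    "ventral_striatum",
    "medial_PFC",
    "hypothalamus",
    "anterior_cingulate",
)

HEMISPHERES: tuple[str, str] = ("left", "right")

_INSULA_SUBREGIONS = (
    "dorsal_anterior_insula",
    "ventral_anterior_insula",
    "posterior_insula",
)
_INSULA_TARGETS = (
    "basolateral_amygdala",
    "central_nucleus_amygdala",
    "ventral_striatum",
    "medial_PFC",
    "medial_OFC",
    "middle_OFC",
    "gyrus_rectus",
    "inferior_OFC",
)
_AMYGDALA_TARGETS = (
    "hypothalamus",
    "substantia_nigra",
    "ventral_striatum",
    "anterior_cingulate",
)
_OFC_SUBREGIONS = ("medial_OFC", "middle_OFC", "gyrus_rectus", "inferior_OFC")
_OFC_TARGETS = ("hypothalamus", "ventral_striatum", "medial_PFC")


class TaxonomyError(ValueError):
    """Raised when a region label or taxonomy structure is invalid."""


@dataclass(frozen=True)
class Region:
    """A circuit region in one hemisphere.

    ``volume`` is the region size in voxels; it enters the connection-strength
    normalization as the target-volume divisor.
    """

    label: str
    hemisphere: str
    volume: int | None = None

    def __post_init__(self) -> None:
        if self.label not in REGION_VOCABULARY:
            raise TaxonomyError(f"unknown region label: {self.label!r}")
        if self.hemisphere not in HEMISPHERES:
            raise TaxonomyError(f"unknown hemisphere: {self.hemisphere!r}")
        if self.volume is not None and self.volume <= 0:
            raise TaxonomyError(f"region volume must be positive, got {self.volume}")


@dataclass(frozen=True)
class TractDefinition:
    """An ipsilateral seed->target white-matter tract."""

    seed: Region
    target: Region

    def __post_init__(self) -> None:
        if self.seed.label == self.target.label:
            raise TaxonomyError("seed and target must differ")
        if self.seed.hemisphere != self.target.hemisphere:
            raise TaxonomyError("tracts are ipsilateral: seed and target hemispheres differ")
        allowed = allowed_pairs().get(self.seed.label, ())
        if self.target.label not in allowed:
            raise TaxonomyError(
                f"{self.seed.label} -> {self.target.label} is not an allowed pair"
            )

    @property
    def hemisphere(self) -> str:
        return self.seed.hemisphere

    def key(self) -> tuple[str, str, str]:
        return (self.hemisphere, self.seed.label, self.target.label)


def allowed_pairs() -> dict[str, tuple[str, ...]]:
    """Static seed-label -> target-labels table of the circuit (49 pairs/hemisphere)."""
    table: dict[str, tuple[str, ...]] = {
        "thalamus": _INSULA_SUBREGIONS + ("frontal_operculum",),
        "substantia_nigra": ("ventral_striatum",),
        "central_nucleus_amygdala": _AMYGDALA_TARGETS,
        "basolateral_amygdala": _AMYGDALA_TARGETS,
    }
    for insula in _INSULA_SUBREGIONS:
        table[insula] = _INSULA_TARGETS
    for ofc in _OFC_SUBREGIONS:
        table[ofc] = _OFC_TARGETS
    return table


class RegionTaxonomy:
    """A set of regions (label x hemisphere, optional volumes) defining the circuit.

    (label, hemisphere) pairs are unique. ``enumerate_tracts`` yields every
    allowed ipsilateral pair whose seed and target are both present.
    """

    def __init__(self, regions: Iterable[Region]):
        self._regions: dict[tuple[str, str], Region] = {}
        for region in regions:
            key = (region.label, region.hemisphere)
            if key in self._regions:
                raise TaxonomyError(f"duplicate region {key}")
            self._regions[key] = region

    @classmethod
    def default(cls) -> "RegionTaxonomy":
        """The packaged full taxonomy (all 16 regions, both hemispheres)."""
        text = resources.files("tastecircuit.data").joinpath("taxonomy.json").read_text()
        return cls.from_dict(json.loads(text))

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RegionTaxonomy":
        regions = [
            Region(r["label"], r["hemisphere"], r.get("volume"))
            for r in payload["regions"]
        ]
        return cls(regions)

    @classmethod
    def from_json(cls, path) -> "RegionTaxonomy":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "regions": [
                {"label": r.label, "hemisphere": r.hemisphere, "volume": r.volume}
                for r in self.regions()
            ]
        }

    def regions(self) -> list[Region]:
        return [self._regions[k] for k in sorted(self._regions)]

    def get(self, label: str, hemisphere: str) -> Region:
        if label not in REGION_VOCABULARY:
            raise TaxonomyError(f"unknown region label: {label!r}")
        try:
            return self._regions[(label, hemisphere)]
        except KeyError:
            raise TaxonomyError(f"region not in taxonomy: ({label}, {hemisphere})") from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._regions

    def __len__(self) -> int:
        return len(self._regions)


def enumerate_tracts(taxonomy: RegionTaxonomy) -> list[TractDefinition]:
    """Every allowed seed->target tract present in ``taxonomy``.

    Deterministically ordered by (hemisphere, seed label, target label) with
    left before right, so outputs are diff-stable. The default taxonomy yields
    98 tracts (49 per hemisphere).
    """
    pairs = allowed_pairs()
    tracts: list[TractDefinition] = []
    for hemisphere in HEMISPHERES:
        for seed_label in sorted(pairs):
            if (seed_label, hemisphere) not in taxonomy:
                continue
            seed = taxonomy.get(seed_label, hemisphere)
            for target_label in sorted(pairs[seed_label]):
                if (target_label, hemisphere) not in taxonomy:
                    continue
                tracts.append(TractDefinition(seed, taxonomy.get(target_label, hemisphere)))
    return tracts
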