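"""Archetype classification of leaves into historical shape types.

Shepherd's-purse leaf shapes were historically sorted into four Shull types
(Simplex, Rhomboidea, Tenius, Heteris) and a finer Iannetta panel series
(1a-1d, 2a-2b, 3/4, 5, 6, 7a-7b).  Here each leaf is superimposed pairwise
onto every archetypal configuration of a scheme and assigned to the type
with the smallest Procrustes distance; ties break to the canonical order of
the scheme.  The eleven Iannetta panels can be grouped into the seven
coarse types for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CorrespondenceError, JoinError
from .landmarking import LandmarkConfiguration
from .procrustes import superimpose_pair

__all__ = [
    "ArchetypeSet",
    "TypeAssignment",
    "SHULL_NAMES",
    "IANNETTA_NAMES",
    "IANNETTA_COARSE",
    "classify",
    "classify_all",
    "type_frequency_table",
]

# Canonical ordering of the type names; ties in classification break to the
# earlier name.  "Heteris" is canonical; "Hetersis" is accepted as an alias.
SHULL_NAMES = ("Simplex", "Rhomboidea", "Tenius", "Heteris")
SHULL_ALIASES = {"Hetersis": "Heteris"}
IANNETTA_NAMES = ("1a", "1b", "1c", "1d", "2a", "2b", "3/4", "5", "6", "7a", "7b")
# Panel -> coarse Iannetta type for reporting.
IANNETTA_COARSE = {
    "1a": "1", "1b": "1", "1c": "1", "1d": "1",
    "2a": "2", "2b": "2",
    "3/4": "3/4", "5": "5", "6": "6",
    "7a": "7", "7b": "7",
}


@dataclass
class ArchetypeSet:
    """An ordered, named set of archetypal landmark configurations."""

    scheme: str  # "shull" | "iannetta"
    names: tuple[str, ...]
    configurations: list[LandmarkConfiguration]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.configurations):
            raise ValueError("names and configurations must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"duplicate archetype names in scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class TypeAssignment:
    """Best-matching archetype for one leaf, with the full distance vector."""

    id: str
    scheme: str
    best_type: str
    distances: dict[str, float]

    @property
    def min_distance(self) -> float:
        return self.distances[self.best_type]


def classify(leaf: LandmarkConfiguration, archetypes: ArchetypeSet) -> TypeAssignment:
    """Assign a leaf to the archetype at smallest Procrustes distance.

    Each comparison is an independent pairwise superimposition of the leaf
    onto the archetype, so the assignment is invariant to translation,
    rotation, and scale of the input.
    """
    for a in archetypes.configurations:
        if a.n_points != leaf.n_points:
            raise CorrespondenceError(
                f"leaf {leaf.id!r} has {leaf.n_points} points but archetype "
                f"{a.id!r} has {a.n_points}"
            )
    dists = np.array(
        [superimpose_pair(leaf, a)[1] for a in archetypes.configurations]
    )
    best = int(np.argmin(dists))  # argmin takes the first minimum: canonical tie-break
    return TypeAssignment(
        id=leaf.id,
        scheme=archetypes.scheme,
        best_type=archetypes.names[best],
        distances=dict(zip(archetypes.names, dists.tolist())),
    )


def classify_all(
    leaves: list[LandmarkConfiguration], archetypes: ArchetypeSet
) -> pd.DataFrame:
    """Classify a list of leaves; returns (id, scheme, best_type, min_distance)."""
    rows = [classify(leaf, archetypes) for leaf in leaves]
    return pd.DataFrame(
        {
            "id": [r.id for r in rows],
            "scheme": [r.scheme for r in rows],
            "best_type": [r.best_type for r in rows],
            "min_distance": [r.min_distance for r in rows],
        }
    )


def type_frequency_table(
    assignments: pd.DataFrame, regions: pd.Series, coarse: dict[str, str] | None = None
) -> pd.DataFrame:
    """Contingency table of shape type (rows) by climate region (columns).

    ``assignments`` is the classify_all frame; ``regions`` maps leaf id to
    region.  ``coarse`` optionally collapses panel labels (e.g. the eleven
    Iannetta panels into the seven coarse types).
    """
    reg = regions.rename("region")
    reg.index.name = "id"
    merged = assignments.merge(reg.reset_index(), on="id", how="left")
    missing = merged.loc[merged["region"].isna(), "id"].tolist()
    extra = set(reg.index) - set(assignments["id"])
    if missing or extra:
        raise JoinError(
            f"unmatched ids between assignments and regions: "
            f"no region for {missing}; no assignment for {sorted(extra)}"
        )
    types = merged["best_type"]
    if coarse is not None:
        types = types.map(lambda t: coarse.get(t, t))
    return pd.crosstab(types.rename("type"), merged["region"])
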