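"""Specimen aggregation, per-tissue metal ranking and range summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Metal, StudyDataset, Tissue
from .errors import DomainError, IncompleteProfileError

__all__ = [
    "aggregate_specimens",
    "TissueProfile",
    "rank_metals",
    "metal_range",
    "ranking_report",
]


def aggregate_specimens(values) -> tuple[float, float, int]:
    """Summarize per-specimen concentrations as (mean, sd, n).

    Sample standard deviation (n − 1 denominator); a single specimen has
    sd = 0 by convention. Empty input is a domain error.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("cannot aggregate an empty specimen list")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise DomainError("specimen concentrations must be finite and >= 0")
    n = int(arr.size)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n >= 2 else 0.0
    return mean, sd, n


@dataclass(frozen=True)
class TissueProfile:
    """Metals of one (species, tissue) cell ordered by descending mean.

    Ties break alphabetically by metal code, so the ordering is a total
    order and re-ranking a permuted dataset reproduces it exactly.
    """

    species: str
    tissue: Tissue
    ranking: tuple[tuple[Metal, float], ...]

    @property
    def order(self) -> tuple[Metal, ...]:
        return tuple(m for m, _ in self.ranking)

    def __str__(self) -> str:
        return " > ".join(m.code for m in self.order)


def rank_metals(ds: StudyDataset, species: str, tissue: Tissue | str
                ) -> TissueProfile:
    """Rank all seven metals of one (species, tissue) cell by mean.

    Always computed from the data. The study's narrative prints some
    orderings that contradict its own concentration table; those printed
    orderings are treated as claims to check, never as the answer.
    """
    tissue = Tissue.parse(tissue)
    pairs: list[tuple[Metal, float]] = []
    for metal in Metal:
        try:
            pairs.append((metal, ds.get(species, tissue, metal).mean))
        except KeyError:
            raise IncompleteProfileError(
                f"no cell for ({species}, {tissue}, {metal})") from None
    pairs.sort(key=lambda p: (-p[1], p[0].code))
    return TissueProfile(species, tissue, tuple(pairs))


def metal_range(ds: StudyDataset, metal: Metal | str,
                tissues=None) -> tuple[float, float]:
    """(min, max) of cell means for one metal over a tissue subset.

    ``tissues`` defaults to all three tissues; pass e.g. ``["muscle"]``
    to restrict. Raises on an empty selection.
    """
    metal = Metal.parse(metal)
    wanted = ({Tissue.parse(t) for t in tissues} if tissues is not None
              else set(Tissue))
    means = [c.mean for c in ds
             if c.metal == metal and c.tissue in wanted]
    if not means:
        raise DomainError(
            f"no cells for metal {metal} in tissues {sorted(t.value for t in wanted)}")
    return (min(means), max(means))


def ranking_report(ds: StudyDataset) -> dict[tuple[str, str], str]:
    """Per (species, tissue), the ' > '-joined descending-mean ranking."""
    report = {}
    for species in ds.species:
        for tissue in Tissue:
            profile = rank_metals(ds, species, tissue)
            report[(species, tissue.value)] = str(profile)
    return report
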