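"""Domain types for dietary heavy-metal risk assessment.

The central objects are:

* :class:`Metal` / :class:`Tissue` — the seven metal(loid)s (As, Cd, Cr,
  Hg, Pb, Sr, V) and three organs (liver, gills, muscle) covered by the
  study design.
* :class:`TissueConcentration` — one (species, tissue, metal) cell:
  mean ± SD concentration in μg/kg dry weight over ``n`` specimens.
* :class:`StudyDataset` — a keyed collection of cells with CSV I/O.
* :class:`CohortParams` — an exposure population (ingestion rate, body
  weight, exposure frequency/duration, averaging time).
* :class:`ReferenceValueSet` — per-metal toxicological constants (RfD,
  PTWI, CSF), each with a provenance flag, stored as a TOML registry.

The packaged concentration fixture (:func:`load_fixture`) holds the
3 species × 3 tissues × 7 metals grid of organ-level means and SDs
(n = 6 fish per species) on which the published exposure and risk
tables were computed.

Back-derivation helpers (:func:`derive_rfd`, :func:`derive_ptwi`,
:func:`derive_csf`) invert the published output tables to recover the
toxicological constants the study used but never printed; the shipped
default registry was produced that way and is flagged ``back-derived``.
"""

from __future__ import annotations

import enum
import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import DatasetValidationError, DomainError, MissingReferenceError

__all__ = [
    "Metal",
    "Tissue",
    "TissueConcentration",
    "CohortParams",
    "CHILDREN",
    "ADULTS",
    "DEFAULT_COHORTS",
    "ReferenceValue",
    "ReferenceValueSet",
    "StudyDataset",
    "load_fixture",
    "load_published_table",
    "validate_dataset",
    "derive_rfd",
    "derive_ptwi",
    "derive_csf",
]

_DATA_PKG = "fishrisk.data"


class Metal(enum.Enum):
    """The seven metal(loid)s quantified in the study tissues."""

    AS = "As"
    CD = "Cd"
    CR = "Cr"
    HG = "Hg"
    PB = "Pb"
    SR = "Sr"
    V = "V"

    @property
    def code(self) -> str:
        return self.value

    @classmethod
    def parse(cls, code: str) -> "Metal":
        """Case-insensitive lookup; unknown codes are rejected."""
        if isinstance(code, Metal):
            return code
        for m in cls:
            if m.value.lower() == str(code).strip().lower():
                return m
        raise DomainError(f"unknown metal code {code!r}; valid: "
                          f"{[m.value for m in cls]}")

    def __str__(self) -> str:  # canonical on write
        return self.value


class Tissue(enum.Enum):
    """Fish organs sampled: detox organ, respiratory surface, edible flesh."""

    LIVER = "liver"
    GILLS = "gills"
    MUSCLE = "muscle"

    @classmethod
    def parse(cls, name: str) -> "Tissue":
        if isinstance(name, Tissue):
            return name
        for t in cls:
            if t.value == str(name).strip().lower():
                return t
        raise DomainError(f"unknown tissue {name!r}; valid: "
                          f"{[t.value for t in cls]}")

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class TissueConcentration:
    """One (species, tissue, metal) summary cell, μg/kg dry weight."""

    species: str
    tissue: Tissue
    metal: Metal
    mean: float  # μg/kg dw
    sd: float    # μg/kg dw
    n: int       # specimen count behind the summary

    def __post_init__(self):
        object.__setattr__(self, "tissue", Tissue.parse(self.tissue))
        object.__setattr__(self, "metal", Metal.parse(self.metal))
        if not self.species or not str(self.species).strip():
            raise DomainError("species label must be non-empty")
        if not (self.mean >= 0):
            raise DomainError(f"mean must be >= 0, got {self.mean}")
        if not (self.sd >= 0):
            raise DomainError(f"sd must be >= 0, got {self.sd}")
        if not (isinstance(self.n, int) and self.n >= 1):
            raise DomainError(f"n must be a positive integer, got {self.n}")

    @property
    def key(self) -> tuple[str, Tissue, Metal]:
        return (self.species, self.tissue, self.metal)


@dataclass(frozen=True)
class CohortParams:
    """An exposure population for intake calculations.

    Parameters
    ----------
    name : cohort label, e.g. ``"children"``.
    ingestion_rate : fish ingestion rate IR, g/day.
    body_weight : body weight BW, kg.
    exposure_frequency : EFr, days/year (default 365).
    exposure_duration : ED, years (default 70).
    averaging_time : AT, days; defaults to ``EFr × ED`` (chronic,
        non-carcinogenic convention), under which the THQ formula
        collapses to intake / RfD.
    """

    name: str
    ingestion_rate: float
    body_weight: float
    exposure_frequency: float = 365.0
    exposure_duration: float = 70.0
    averaging_time: float | None = None

    def __post_init__(self):
        if self.averaging_time is None:
            object.__setattr__(
                self, "averaging_time",
                self.exposure_frequency * self.exposure_duration,
            )
        for fname in ("ingestion_rate", "body_weight", "exposure_frequency",
                      "exposure_duration", "averaging_time"):
            v = getattr(self, fname)
            if not (isinstance(v, (int, float)) and v > 0 and math.isfinite(v)):
                raise DomainError(f"{fname} must be strictly positive, got {v}")


#: Default cohorts of the study design: children eat 75 g fish/day at
#: 20 kg body weight, adults 150 g/day at 70 kg.
CHILDREN = CohortParams("children", ingestion_rate=75.0, body_weight=20.0)
ADULTS = CohortParams("adults", ingestion_rate=150.0, body_weight=70.0)
DEFAULT_COHORTS: tuple[CohortParams, ...] = (CHILDREN, ADULTS)

_PROVENANCES = ("paper-stated", "back-derived", "user")
_REF_METRICS = ("rfd", "ptwi", "csf")


@dataclass(frozen=True)
class ReferenceValue:
    """A toxicological constant plus where it came from."""

    value: float
    provenance: str

    def __post_init__(self):
        if self.provenance not in _PROVENANCES:
            raise DomainError(
                f"provenance must be one of {_PROVENANCES}, got {self.provenance!r}")
        if not (self.value >= 0 and math.isfinite(self.value)):
            raise DomainError(f"reference value must be finite and >= 0, got {self.value}")


class ReferenceValueSet:
    """Per-metal registry of RfD, PTWI and CSF with provenance flags.

    Units: RfD μg/kg bw/day; PTWI μg/kg bw/week; CSF (mg/kg bw/day)⁻¹.
    Operations that need an absent value raise
    :class:`~fishrisk.errors.MissingReferenceError` — never a silent default.
    """

    def __init__(self, values: dict[Metal, dict[str, ReferenceValue]] | None = None):
        self._values: dict[Metal, dict[str, ReferenceValue]] = {}
        for metal, metrics in (values or {}).items():
            metal = Metal.parse(metal)
            self._values[metal] = {}
            for metric, rv in metrics.items():
                self.set(metal, metric, rv.value, rv.provenance)

    def set(self, metal: Metal, metric: str, value: float,
            provenance: str = "user") -> None:
        metal = Metal.parse(metal)
        if metric not in _REF_METRICS:
            raise DomainError(f"unknown reference metric {metric!r}")
        if metric in ("rfd", "ptwi") and not value > 0:
            raise DomainError(f"{metric} must be > 0, got {value}")
        self._values.setdefault(metal, {})[metric] = ReferenceValue(value, provenance)

    def has(self, metal: Metal, metric: str) -> bool:
        return metric in self._values.get(Metal.parse(metal), {})

    def get(self, metal: Metal, metric: str) -> ReferenceValue:
        metal = Metal.parse(metal)
        try:
            return self._values[metal][metric]
        except KeyError:
            raise MissingReferenceError(metal.code, metric) from None

    def rfd(self, metal: Metal) -> float:
        return self.get(metal, "rfd").value

    def ptwi(self, metal: Metal) -> float:
        return self.get(metal, "ptwi").value

    def csf(self, metal: Metal) -> float:
        return self.get(metal, "csf").value

    def metals(self) -> list[Metal]:
        return sorted(self._values, key=lambda m: m.code)

    def __eq__(self, other) -> bool:
        return isinstance(other, ReferenceValueSet) and self._values == other._values

    # ---- TOML round trip -------------------------------------------------

    @classmethod
    def from_toml(cls, path: str | Path | None = None) -> "ReferenceValueSet":
        """Load a registry; with no path, the packaged defaults."""
        if path is None:
            text = resources.files(_DATA_PKG).joinpath("reference_values.toml").read_text()
        else:
            text = Path(path).read_text()
        raw = tomllib.loads(text)
        rvs = cls()
        for key, stanza in raw.items():
            if not isinstance(stanza, dict):
                continue  # top-level scalars like `schema`
            metal = Metal.parse(key)
            for metric in _REF_METRICS:
                if metric in stanza:
                    rvs.set(metal, metric, float(stanza[metric]),
                            stanza.get(f"{metric}_provenance", "user"))
        return rvs

    @classmethod
    def defaults(cls) -> "ReferenceValueSet":
        return cls.from_toml(None)

    def to_toml(self, path: str | Path) -> None:
        lines = ["schema = 1", ""]
        for metal in self.metals():
            lines.append(f"[{metal.code}]")
            for metric in _REF_METRICS:
                if self.has(metal, metric):
                    rv = self.get(metal, metric)
                    lines.append(f"{metric} = {rv.value!r}")
                    lines.append(f'{metric}_provenance = "{rv.provenance}"')
            lines.append("")
        Path(path).write_text("\n".join(lines))


_CSV_COLUMNS = ["species", "tissue", "metal", "mean_ug_per_kg", "sd_ug_per_kg", "n"]


@dataclass(frozen=True)
class StudyDataset:
    """A collection of tissue-concentration cells keyed by (species, tissue, metal)."""

    cells: tuple[TissueConcentration, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "cells", tuple(self.cells))

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterator[TissueConcentration]:
        return iter(self.cells)

    def get(self, species: str, tissue: Tissue | str, metal: Metal | str
            ) -> TissueConcentration:
        tissue, metal = Tissue.parse(tissue), Metal.parse(metal)
        for c in self.cells:
            if c.key == (species, tissue, metal):
                return c
        raise KeyError((species, str(tissue), str(metal)))

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cells:
            seen.setdefault(c.species)
        return list(seen)

    def subset(self, *, species: str | None = None,
               tissue: Tissue | str | None = None,
               metal: Metal | str | None = None) -> "StudyDataset":
        tissue = Tissue.parse(tissue) if tissue is not None else None
        metal = Metal.parse(metal) if metal is not None else None
        kept = [c for c in self.cells
                if (species is None or c.species == species)
                and (tissue is None or c.tissue == tissue)
                and (metal is None or c.metal == metal)]
        return StudyDataset(tuple(kept), dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.species, c.tissue.value, c.metal.code, c.mean, c.sd, c.n)
             for c in self.cells],
            columns=_CSV_COLUMNS,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None
                   ) -> "StudyDataset":
        missing = set(_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise DomainError(f"concentration table missing columns: {sorted(missing)}")
        cells = [
            TissueConcentration(
                species=str(r.species),
                tissue=Tissue.parse(r.tissue),
                metal=Metal.parse(r.metal),
                mean=float(r.mean_ug_per_kg),
                sd=float(r.sd_ug_per_kg),
                n=int(r.n),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(tuple(cells), metadata or {})

    @classmethod
    def from_csv(cls, path: str | Path, metadata: dict | None = None
                 ) -> "StudyDataset":
        meta = {"source": str(path), "basis": "dry weight", "units": "ug/kg"}
        meta.update(metadata or {})
        return cls.from_frame(pd.read_csv(path), meta)


def load_fixture() -> StudyDataset:
    """The packaged organ-level concentration table.

    63 cells — 3 species × 3 tissues (liver, gills, muscle) × 7 metals —
    each a mean ± SD over n = 6 fish, μg/kg dry weight. The third species
    is keyed by its table label "Lates niloticus"; the study's title calls
    the same fish "Lates calcarifer", kept here as an alias.
    """
    with resources.as_file(
        resources.files(_DATA_PKG).joinpath("tissue_concentrations.csv")
    ) as p:
        return StudyDataset.from_csv(
            p,
            metadata={
                "source": "packaged fixture: tissue_concentrations.csv",
                "species_alias": {"Lates niloticus": "Lates calcarifer"},
            },
        )


def load_published_table(name: str) -> pd.DataFrame:
    """Load one of the packaged published output tables.

    ``name`` is one of ``"exposure"`` (EDI/EWI/DIL/CRlim), ``"limits"``
    (MDI/MWI), ``"risk"`` (THQ/CR) or ``"hazard_index"`` (HI). These are
    the study's printed results, kept as regression oracles and as input
    for back-deriving the reference registry — they are never used to
    *produce* results.
    """
    fname = f"published_{name}.csv"
    with resources.as_file(resources.files(_DATA_PKG).joinpath(fname)) as p:
        return pd.read_csv(p)


def validate_dataset(ds: StudyDataset) -> list[str]:
    """Return a list of invariant violations (empty list means valid).

    Checks non-negative means/SDs, positive specimen counts, and
    uniqueness of the (species, tissue, metal) key.
    """
    violations: list[str] = []
    seen: set[tuple] = set()
    for c in ds:
        label = f"({c.species}, {c.tissue}, {c.metal})"
        if c.mean < 0:
            violations.append(f"{label}: negative mean concentration {c.mean}")
        if c.sd < 0:
            violations.append(f"{label}: negative SD {c.sd}")
        if c.n < 1:
            violations.append(f"{label}: non-positive specimen count {c.n}")
        if c.key in seen:
            violations.append(f"{label}: duplicate (species, tissue, metal) key")
        seen.add(c.key)
    if len(ds) == 0:
        violations.append("dataset contains no cells")
    return violations


def require_valid(ds: StudyDataset) -> None:
    """Raise :class:`DatasetValidationError` if the dataset is invalid."""
    violations = validate_dataset(ds)
    if violations:
        raise DatasetValidationError(violations)


# ---- back-derivation of reference values --------------------------------

def derive_rfd(dil: float, c: float, bw: float) -> float:
    """Recover an RfD (μg/kg bw/day) from a daily intake limit.

    Inverts DIL = RfD × BW / C: given the published DIL (kg fish/day), the
    concentration C (μg/kg) and body weight BW (kg), the implied reference
    dose is ``dil × c / bw``.
    """
    for name, v in (("dil", dil), ("c", c), ("bw", bw)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    return dil * c / bw


def derive_ptwi(mdi: float, bw: float) -> float:
    """Recover a PTWI (μg/kg bw/week) from a maximum daily intake.

    Inverts MDI = PTWI × BW / 7.
    """
    for name, v in (("mdi", mdi), ("bw", bw)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    return mdi * 7.0 / bw


def derive_csf(cr: float, edi_si: float) -> float:
    """Recover a cancer slope factor from a lifetime cancer risk.

    Inverts CR = EDI × CSF with EDI in mg/kg bw/day: returns ``cr / edi_si``.
    """
    if not edi_si > 0:
        raise DomainError(f"edi_si must be > 0, got {edi_si}")
    if cr < 0:
        raise DomainError(f"cr must be >= 0, got {cr}")
    return cr / edi_si
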