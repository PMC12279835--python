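"""Risk-side computations: THQ per metal, HI per species, CR per carcinogen.

The target hazard quotient compares chronic intake against the oral
reference dose:

    THQ = (EFr × ED × IR × C) / (RfD × BW × AT × 1000)

with EFr in days/year, ED in years, IR in g/day, C in μg/kg, RfD in
μg/kg bw/day, BW in kg, AT in days, and the factor 1000 converting IR
from g to kg. Under the chronic non-carcinogenic convention AT = EFr × ED
this reduces to intake(μg/kg bw/day) / RfD. The hazard index is the sum
of THQs over co-occurring metals; lifetime cancer risk is
CR = EDI(mg/kg bw/day) × CSF. Metals without an oral slope factor
(Hg, Sr, V in the default registry) carry no CR — absence, not zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datamodel import (
    CohortParams,
    DEFAULT_COHORTS,
    Metal,
    ReferenceValueSet,
    StudyDataset,
    Tissue,
    require_valid,
)
from .errors import DomainError
from .exposure import edi_si

__all__ = [
    "thq",
    "hazard_index",
    "cancer_risk",
    "classify",
    "cr_band",
    "RiskResult",
    "risk_results",
    "risk_table",
    "CR_NEGLIGIBLE",
    "CR_UNACCEPTABLE",
]

#: conventional lifetime-cancer-risk band edges
CR_NEGLIGIBLE = 1.0e-6
CR_UNACCEPTABLE = 1.0e-4


def thq(c: float, cohort: CohortParams, rfd: float) -> float:
    """Target hazard quotient for one metal (dimensionless).

    ``c`` in μg/kg, ``rfd`` in μg/kg bw/day; the cohort supplies IR
    (g/day), BW (kg), EFr, ED and AT.
    """
    if c < 0:
        raise DomainError(f"concentration must be >= 0, got {c}")
    if not rfd > 0:
        raise DomainError(f"rfd must be > 0, got {rfd}")
    numer = (cohort.exposure_frequency * cohort.exposure_duration
             * cohort.ingestion_rate * c)
    denom = rfd * cohort.body_weight * cohort.averaging_time * 1000.0
    return numer / denom


def hazard_index(thqs) -> float:
    """Hazard index: the sum of per-metal THQs.

    Accepts any iterable of THQ values (or a mapping metal → THQ).
    """
    values = list(thqs.values()) if hasattr(thqs, "values") else list(thqs)
    if not values:
        raise DomainError("hazard index requires at least one THQ")
    if any(v < 0 for v in values):
        raise DomainError("THQ values must be >= 0")
    return float(sum(values))


def cancer_risk(edi_si_value: float, csf: float) -> float:
    """Lifetime cancer probability: EDI (mg/kg bw/day) × CSF ((mg/kg bw/day)⁻¹)."""
    if edi_si_value < 0:
        raise DomainError(f"edi_si must be >= 0, got {edi_si_value}")
    if csf < 0:
        raise DomainError(f"csf must be >= 0, got {csf}")
    return edi_si_value * csf


def cr_band(cr: float) -> str:
    """Band a lifetime cancer risk: negligible < 10⁻⁶ ≤ acceptable ≤ 10⁻⁴ < unacceptable."""
    if cr < 0:
        raise DomainError(f"cr must be >= 0, got {cr}")
    if cr < CR_NEGLIGIBLE:
        return "negligible"
    if cr <= CR_UNACCEPTABLE:
        return "acceptable"
    return "unacceptable"


@dataclass
class RiskResult:
    """All risk metrics for one (species, cohort) pair.

    ``thq`` maps every metal with an RfD to its quotient; ``hi`` is their
    sum; ``cr`` maps each metal to a lifetime risk or ``None`` when no
    slope factor exists. ``flags`` is filled by :func:`classify`.
    """

    species: str
    cohort: str
    thq: dict[Metal, float]
    hi: float
    cr: dict[Metal, float | None]
    flags: dict = field(default_factory=dict)


def classify(result: RiskResult) -> dict:
    """Attach qualitative safety flags to a risk result.

    Flags ``thq_exceeds_1`` (any metal), ``hi_exceeds_1``, and a
    ``cr_band`` per metal with a slope factor. Mutates ``result.flags``
    and returns it.
    """
    flags = {
        "thq_exceeds_1": {m.code: q > 1.0 for m, q in result.thq.items()},
        "any_thq_exceeds_1": any(q > 1.0 for q in result.thq.values()),
        "hi_exceeds_1": result.hi > 1.0,
        "cr_band": {m.code: cr_band(v)
                    for m, v in result.cr.items() if v is not None},
    }
    result.flags = flags
    return flags


def risk_results(
    ds: StudyDataset,
    refs: ReferenceValueSet,
    cohorts: tuple[CohortParams, ...] = DEFAULT_COHORTS,
    tissue: Tissue | str = Tissue.MUSCLE,
) -> list[RiskResult]:
    """Compute THQ/HI/CR for every (species, cohort) from one tissue.

    The hazard index sums THQs over all seven metals (every metal has an
    RfD in the default registry). CR is computed only where a CSF exists.
    """
    require_valid(ds)
    tissue = Tissue.parse(tissue)
    out: list[RiskResult] = []
    for species in ds.species:
        for cohort in cohorts:
            thqs: dict[Metal, float] = {}
            crs: dict[Metal, float | None] = {}
            for metal in Metal:
                cell = ds.get(species, tissue, metal)
                thqs[metal] = thq(cell.mean, cohort, refs.rfd(metal))
                if refs.has(metal, "csf"):
                    crs[metal] = cancer_risk(edi_si(cell.mean, cohort),
                                             refs.csf(metal))
                else:
                    crs[metal] = None
            res = RiskResult(species, cohort.name, thqs,
                             hazard_index(thqs), crs)
            classify(res)
            out.append(res)
    return out


def risk_table(
    ds: StudyDataset,
    refs: ReferenceValueSet,
    cohorts: tuple[CohortParams, ...] = DEFAULT_COHORTS,
    tissue: Tissue | str = Tissue.MUSCLE,
) -> pd.DataFrame:
    """Tidy frame: one row per species × metal × cohort with thq, cr, hi.

    ``cr`` is NaN for metals without a slope factor; ``hi`` repeats the
    species/cohort hazard index on every row for convenience.
    """
    rows = []
    for res in risk_results(ds, refs, cohorts, tissue):
        for metal in Metal:
            rows.append({
                "species": res.species,
                "metal": metal.code,
                "cohort": res.cohort,
                "thq": res.thq[metal],
                "cr": res.cr[metal] if res.cr[metal] is not None else float("nan"),
                "hi": res.hi,
            })
    return pd.DataFrame(rows)
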