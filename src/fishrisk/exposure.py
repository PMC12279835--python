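"""Intake-side computations: EDI, EWI and the intake-limit quantities.

Two unit dialects coexist on purpose. The study's published exposure
table computes EDI as ``C[μg/kg] × IR[g/day] / BW[kg]`` with no g→kg
conversion, so its printed numbers sit a factor of 10⁶ above the
dimensionally consistent value in mg/kg bw/day (μg→mg is 10³ and
g/day→kg/day another 10³). Both scales are exposed:

* :func:`edi_published` — reproduces the published numeric scale;
* :func:`edi_si` — mg/kg bw/day, the scale all risk computations
  (THQ denominators, CR) actually use.

Limit quantities:

* :func:`mdi` / :func:`mwi` — maximum daily/weekly intake from a PTWI
  and a body weight (published on PTWI-arithmetic scale; the study
  labels the column mg/day but the arithmetic is PTWI[μg/kg/wk]×BW/7);
* :func:`dil` / :func:`crlim` — kg of fish per day before the RfD is
  exceeded; the two are the same formula (RfD × BW / C) under different
  report headings, and both are kept for report fidelity.
"""

from __future__ import annotations

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

__all__ = [
    "edi_published",
    "edi_si",
    "ewi",
    "mdi",
    "mwi",
    "dil",
    "crlim",
    "exposure_table",
    "intake_limits_table",
]

#: published-scale EDI = 10^6 × SI EDI (μg→mg and g→kg factors omitted
#: in the published table's arithmetic).
PUBLISHED_PER_SI = 1.0e6


def edi_published(c: float, cohort: CohortParams) -> float:
    """Estimated daily intake on the published numeric scale.

    ``c × IR / BW`` with c in μg/kg and IR in g/day, no unit conversion —
    exactly how the published exposure table was computed.
    """
    if c < 0:
        raise DomainError(f"concentration must be >= 0, got {c}")
    return c * cohort.ingestion_rate / cohort.body_weight


def edi_si(c: float, cohort: CohortParams) -> float:
    """Estimated daily intake in mg/kg body weight/day.

    ``c[mg/kg] × IR[kg/day] / BW[kg]``; equals the published-scale EDI
    divided by 10⁶.
    """
    return edi_published(c, cohort) / PUBLISHED_PER_SI


def ewi(edi: float) -> float:
    """Estimated weekly intake: 7 × EDI, same scale as the input EDI."""
    if edi < 0:
        raise DomainError(f"edi must be >= 0, got {edi}")
    return 7.0 * edi


def mdi(ptwi: float, bw: float) -> float:
    """Maximum daily intake from a PTWI: ``ptwi × bw / 7``."""
    for name, v in (("ptwi", ptwi), ("bw", bw)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    return ptwi * bw / 7.0


def mwi(ptwi: float, bw: float) -> float:
    """Maximum weekly intake from a PTWI: ``ptwi × bw`` (= 7 × MDI)."""
    for name, v in (("ptwi", ptwi), ("bw", bw)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    return ptwi * bw


def dil(rfd: float, bw: float, c: float) -> float:
    """Daily intake limit, kg fish/day: ``rfd × bw / c``.

    The maximum daily mass of fish at concentration ``c`` (μg/kg) that a
    consumer of body weight ``bw`` (kg) can eat before exceeding the
    reference dose ``rfd`` (μg/kg bw/day). A zero concentration has no
    finite limit and is rejected rather than returned as infinity.
    """
    for name, v in (("rfd", rfd), ("bw", bw)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    if not c > 0:
        raise DomainError(
            f"daily intake limit undefined for concentration {c} (must be > 0)")
    return rfd * bw / c


def crlim(rfd: float, bw: float, c: float) -> float:
    """Maximum acceptable daily intake (CRlim/MADI): alias of :func:`dil`."""
    return dil(rfd, bw, c)


def exposure_table(
    ds: StudyDataset,
    refs: ReferenceValueSet,
    cohorts: tuple[CohortParams, ...] = DEFAULT_COHORTS,
    tissue: Tissue | str = Tissue.MUSCLE,
) -> pd.DataFrame:
    """Per species × metal × cohort exposure and consumption-limit table.

    Uses the selected tissue (default muscle, the edible one) as the
    dietary concentration. Columns: ``edi`` and ``ewi`` on the published
    scale, ``edi_si`` in mg/kg bw/day, and ``dil``/``crlim`` in kg
    fish/day from the registry RfD.
    """
    require_valid(ds)
    tissue = Tissue.parse(tissue)
    rows = []
    for species in ds.species:
        for metal in Metal:
            cell = ds.get(species, tissue, metal)
            for cohort in cohorts:
                e_pub = edi_published(cell.mean, cohort)
                limit = dil(refs.rfd(metal), cohort.body_weight, cell.mean) \
                    if cell.mean > 0 else float("nan")
                rows.append({
                    "species": species,
                    "metal": metal.code,
                    "cohort": cohort.name,
                    "tissue": tissue.value,
                    "edi": e_pub,
                    "ewi": ewi(e_pub),
                    "edi_si": e_pub / PUBLISHED_PER_SI,
                    "dil": limit,
                    "crlim": limit,
                })
    return pd.DataFrame(rows)


def intake_limits_table(
    refs: ReferenceValueSet,
    cohorts: tuple[CohortParams, ...] = DEFAULT_COHORTS,
) -> pd.DataFrame:
    """Per metal × cohort MDI/MWI table from the registry PTWIs."""
    rows = []
    for metal in Metal:
        p = refs.ptwi(metal)
        for cohort in cohorts:
            rows.append({
                "metal": metal.code,
                "cohort": cohort.name,
                "mdi": mdi(p, cohort.body_weight),
                "mwi": mwi(p, cohort.body_weight),
            })
    return pd.DataFrame(rows)
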