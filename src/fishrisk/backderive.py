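"""Recover the toxicological constants implied by published output tables.

The study prints its exposure limits (DIL), intake ceilings (MDI) and
cancer risks (CR) but not the RfD, PTWI and CSF values behind them.
Each published cell, combined with the concentration that produced it
and the cohort's body weight, pins down the constant:

    RfD  = DIL × C / BW        (per species × cohort cell)
    PTWI = MDI × 7 / BW        (per cohort cell)
    CSF  = CR / EDI_si         (per species × cohort cell)

With three species and two cohorts, each RfD and CSF is implied by six
independent cells; agreement across them (max spread relative to the
median) is the diagnostic that the back-derivation is self-consistent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import (
    ADULTS,
    CHILDREN,
    CohortParams,
    Metal,
    ReferenceValueSet,
    StudyDataset,
    Tissue,
    derive_csf,
    derive_ptwi,
    derive_rfd,
)
from .errors import DomainError
from .exposure import edi_si

__all__ = ["derive_reference_set", "SPREAD_WARN"]

#: warn when implied values for one constant disagree by more than this
SPREAD_WARN = 0.05


def _spread(values: list[float]) -> float:
    med = float(np.median(values))
    return (max(values) - min(values)) / med if med else float("inf")


def derive_reference_set(
    exposure_df: pd.DataFrame,
    limits_df: pd.DataFrame,
    risk_df: pd.DataFrame,
    concentrations: StudyDataset,
    cohorts: tuple[CohortParams, ...] = (CHILDREN, ADULTS),
    tissue: Tissue | str = Tissue.MUSCLE,
) -> tuple[ReferenceValueSet, pd.DataFrame]:
    """Back-derive a full reference registry from published result tables.

    ``exposure_df`` needs columns species/metal/cohort/dil, ``limits_df``
    metal/cohort/mdi, ``risk_df`` species/metal/cohort/cr (NaN or blank
    where no slope factor applies). Returns the registry (all values
    flagged ``back-derived``, per-metal medians) plus a diagnostics frame
    with the implied-value spread per constant. Spreads beyond 5% emit a
    warning; the median is reported regardless.
    """
    tissue = Tissue.parse(tissue)
    by_name = {c.name: c for c in cohorts}

    implied: dict[tuple[Metal, str], list[float]] = {}

    def _push(metal: Metal, metric: str, value: float) -> None:
        implied.setdefault((metal, metric), []).append(value)

    for r in exposure_df.itertuples(index=False):
        cohort = by_name[r.cohort]
        c = concentrations.get(r.species, tissue, r.metal).mean
        _push(Metal.parse(r.metal), "rfd",
              derive_rfd(float(r.dil), c, cohort.body_weight))

    for r in limits_df.itertuples(index=False):
        cohort = by_name[r.cohort]
        _push(Metal.parse(r.metal), "ptwi",
              derive_ptwi(float(r.mdi), cohort.body_weight))

    for r in risk_df.itertuples(index=False):
        cr = getattr(r, "cr", float("nan"))
        if cr is None or (isinstance(cr, float) and np.isnan(cr)):
            continue
        cohort = by_name[r.cohort]
        c = concentrations.get(r.species, tissue, r.metal).mean
        intake = edi_si(c, cohort)
        if intake == 0:
            raise DomainError(
                f"cannot derive CSF for {r.metal} from a zero intake")
        _push(Metal.parse(r.metal), "csf", derive_csf(float(cr), intake))

    refs = ReferenceValueSet()
    diag_rows = []
    for (metal, metric), values in sorted(
            implied.items(), key=lambda kv: (kv[0][0].code, kv[0][1])):
        median = float(np.median(values))
        spread = _spread(values)
        if spread > SPREAD_WARN:
            warnings.warn(
                f"implied {metric} values for {metal.code} disagree by "
                f"{spread:.1%} across cells; reporting the median {median:g}",
                stacklevel=2,
            )
        refs.set(metal, metric, median, provenance="back-derived")
        diag_rows.append({
            "metal": metal.code,
            "metric": metric,
            "n_cells": len(values),
            "median": median,
            "min": min(values),
            "max": max(values),
            "rel_spread": spread,
        })
    return refs, pd.DataFrame(diag_rows)
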