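"""Human-readable report tables and tidy serializations.

Layouts mirror the study's three published result tables: an exposure
table (EDI/EWI/DIL/CRlim per species × metal, children and adult
columns), an intake-limits table (MDI/MWI per metal) and a risk table
(THQ per metal, one HI per species, CR with "–" where no slope factor
exists). Rounding is half-even to the published precision: 3 decimals
for exposure/limit/THQ/HI numbers, 3 significant figures for CR.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = [
    "exposure_markdown",
    "limits_markdown",
    "risk_markdown",
    "tidy_results",
]

ABSENT = "–"


def _fmt3(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ABSENT
    return f"{round(float(v), 3):.3f}"


def _fmt_sci3(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ABSENT
    return f"{float(v):.2e}"


def _md_table(headers: list[str], rows: list[list[str]]) -> str:
    lines = ["| " + " | ".join(headers) + " |",
             "| " + " | ".join("---" for _ in headers) + " |"]
    lines += ["| " + " | ".join(r) + " |" for r in rows]
    return "\n".join(lines) + "\n"


def _cohort_names(df: pd.DataFrame) -> list[str]:
    return list(dict.fromkeys(df["cohort"]))


def exposure_markdown(df: pd.DataFrame, dialect: str = "published") -> str:
    """Render the exposure/limit table (one row per species × metal).

    ``dialect`` selects the EDI/EWI scale: ``published`` (the study's
    unconverted μg·g·kg⁻²·day⁻¹ numbers) or ``si`` (mg/kg bw/day).
    """
    if dialect not in ("published", "si"):
        raise ValueError(f"unknown dialect {dialect!r}")
    cohorts = _cohort_names(df)
    headers = ["Species", "Metal"]
    for quantity in ("EDI", "EWI", "DIL (kg/day)", "CRlim (kg/day)"):
        headers += [f"{quantity} {c}" for c in cohorts]
    rows = []
    for (species, metal), grp in df.groupby(["species", "metal"], sort=False):
        by_cohort = {r.cohort: r for r in grp.itertuples(index=False)}
        row = [species, metal]
        if dialect == "published":
            row += [_fmt3(by_cohort[c].edi) for c in cohorts]
            row += [_fmt3(by_cohort[c].ewi) for c in cohorts]
        else:
            row += [_fmt_sci3(by_cohort[c].edi_si) for c in cohorts]
            row += [_fmt_sci3(by_cohort[c].edi_si * 7.0) for c in cohorts]
        row += [_fmt3(by_cohort[c].dil) for c in cohorts]
        row += [_fmt3(by_cohort[c].crlim) for c in cohorts]
        rows.append(row)
    unit = ("μg·g·kg⁻²·day⁻¹ (published scale)" if dialect == "published"
            else "mg/kg bw/day")
    title = f"### Estimated intake and consumption limits (EDI/EWI in {unit})\n\n"
    return title + _md_table(headers, rows)


def limits_markdown(df: pd.DataFrame) -> str:
    """Render the MDI/MWI table (one row per metal)."""
    cohorts = _cohort_names(df)
    headers = ["Metal"]
    for quantity in ("MDI", "MWI"):
        headers += [f"{quantity} {c}" for c in cohorts]
    rows = []
    for metal, grp in df.groupby("metal", sort=False):
        by_cohort = {r.cohort: r for r in grp.itertuples(index=False)}
        rows.append([metal]
                    + [_fmt3(by_cohort[c].mdi) for c in cohorts]
                    + [_fmt3(by_cohort[c].mwi) for c in cohorts])
    title = "### Maximum daily/weekly intake limits (PTWI × BW scale)\n\n"
    return title + _md_table(headers, rows)


def risk_markdown(df: pd.DataFrame) -> str:
    """Render the THQ/HI/CR table (HI shown once per species)."""
    cohorts = _cohort_names(df)
    headers = ["Species", "Metal"]
    headers += [f"THQ {c}" for c in cohorts]
    headers += [f"HI {c}" for c in cohorts]
    headers += [f"CR {c}" for c in cohorts]
    rows = []
    for species, sp_grp in df.groupby("species", sort=False):
        first = True
        for metal, grp in sp_grp.groupby("metal", sort=False):
            by_cohort = {r.cohort: r for r in grp.itertuples(index=False)}
            row = [species, metal]
            row += [_fmt3(by_cohort[c].thq) for c in cohorts]
            if first:
                row += [_fmt3(by_cohort[c].hi) for c in cohorts]
                first = False
            else:
                row += ["" for _ in cohorts]
            row += [_fmt_sci3(by_cohort[c].cr) for c in cohorts]
            rows.append(row)
    title = ("### Non-carcinogenic and carcinogenic risk "
             "(THQ/HI dimensionless; CR lifetime probability)\n\n")
    return title + _md_table(headers, rows)


def tidy_results(exposure_df: pd.DataFrame, limits_df: pd.DataFrame,
                 risk_df: pd.DataFrame) -> pd.DataFrame:
    """One row per (species, metal, cohort, metric) with value and unit."""
    records = []
    for r in exposure_df.itertuples(index=False):
        for metric, value, unit in (
            ("edi", r.edi, "ug*g/kg^2/day (published scale)"),
            ("ewi", r.ewi, "ug*g/kg^2/week (published scale)"),
            ("edi_si", r.edi_si, "mg/kg bw/day"),
            ("dil", r.dil, "kg fish/day"),
            ("crlim", r.crlim, "kg fish/day"),
        ):
            records.append((r.species, r.metal, r.cohort, metric, value, unit))
    for r in limits_df.itertuples(index=False):
        for metric, value in (("mdi", r.mdi), ("mwi", r.mwi)):
            records.append(("", r.metal, r.cohort, metric, value,
                            "PTWI*BW scale"))
    for r in risk_df.itertuples(index=False):
        records.append((r.species, r.metal, r.cohort, "thq", r.thq, "dimensionless"))
        records.append((r.species, r.metal, r.cohort, "cr", r.cr, "lifetime probability"))
        records.append((r.species, r.metal, r.cohort, "hi", r.hi, "dimensionless"))
    return pd.DataFrame(records, columns=["species", "metal", "cohort",
                                          "metric", "value", "unit"])
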