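# Methods

## Scope and data model

The package computes deterministic dietary-exposure and health-risk
indices from summary statistics: each input cell is a (species, tissue,
metal) triple carrying a mean and sample SD of the metal concentration
in μg/kg **dry weight** over `n` specimens. No wet-weight conversion is
attempted (no moisture data exist for the packaged dataset), so all
intakes are on a dry-weight basis; users comparing against wet-weight
guidance values must convert their reference values, not the data.

The packaged fixture covers 3 species × 3 tissues × 7 metals (n = 6
fish per species). The third species is keyed "Lates niloticus", as in
the concentration table it comes from; the alias "Lates calcarifer"
(used elsewhere for the same fish) is carried in dataset metadata
rather than silently resolved.

Intake calculations use **muscle** by default: it is the edible tissue,
and it is the unique tissue choice under which the pipeline reproduces
every published exposure and risk cell of the source dataset (verified
in `tests/test_acceptance.py`). The tissue is an explicit argument
(`--tissue`) everywhere, so liver/gill scenarios are one flag away.

## Unit conventions: the "published" vs SI dialects

The published exposure table that this package reproduces computes
EDI = C·IR/BW with C in μg/kg and IR in g/day and no unit conversion,
so its printed numbers are 10⁶ × the dimensionally consistent intake in
mg/kg bw/day (a 10³ factor for μg→mg and another for g→kg). Both scales
are first-class:

* `edi_published` — reproduces the published numeric scale exactly;
* `edi_si` — mg/kg bw/day, defined as `edi_published / 10⁶`.

All risk arithmetic uses consistent units internally: THQ divides the
μg/kg bw/day intake (`edi_si × 1000`) by the RfD in μg/kg bw/day, and
CR multiplies `edi_si` (mg/kg bw/day) by the slope factor in
(mg/kg bw/day)⁻¹. That is the only combination that reproduces the
published THQ and CR tables, which confirms those tables were produced
with converted units even though the published EDI column was not.
Similarly, MDI/MWI are reported on the PTWI×BW scale the published
limits table uses (its "mg/day" column label is inconsistent with its
own arithmetic; unit strings are carried as metadata and not
re-labelled).

## Cohorts

Defaults: children IR = 75 g/day, BW = 20 kg; adults IR = 150 g/day,
BW = 70 kg; EFr = 365 days/year, ED = 70 years, AT = EFr × ED days.
With AT = EFr × ED the THQ formula reduces to intake/RfD; AT is kept an
independent, strictly positive field so sub-chronic averaging can be
expressed. A consequence of the defaults worth knowing: child intake
per unit concentration is exactly (75/20)/(150/70) = 1.75 × the adult
intake, so every child risk number is 1.75 × its adult counterpart.

## Reference values

RfD, PTWI and CSF are shipped as a TOML registry, not constants in
code. Each value carries a provenance flag. Four PTWIs are stated in
the source material (As 15, Cd 7, Pb 25, Hg 4 μg/kg bw/week); every
other default — all seven RfDs, PTWIs for Cr/Sr/V, and CSFs for
As/Cd/Cr/Pb — is **back-derived**: recovered by inverting the published
output tables (RfD = DIL·C/BW per cell, PTWI = MDI·7/BW, CSF =
CR/EDI_si) and taking the median across the cells that determine it.
The registry is transparently replaceable (`--refs`) because some
implied values differ from common literature values (e.g. the implied
Sr RfD of 3.5 μg/kg/day is far below the widely used 600, and the
implied Pb RfD 0.3 and Cd CSF 5 × 10⁻⁵ match no single standard
source); `fishrisk derive-refs` re-runs the derivation and reports the
max relative spread of the implied values per constant (warning above
5%). Observed spreads on the packaged tables are ≤ 0.23% for RfDs and
≤ 1.2% for CSFs.

Absent values fail loudly: a THQ without an RfD or a CR without a CSF
raises `MissingReferenceError`; Hg, Sr and V have no oral slope factor
in the defaults and render as "–" in reports, excluded from any CR
aggregate (no total-CR statistic is produced).

## Risk classification

THQ and HI are flagged against the conventional threshold of 1. CR is
banded negligible (< 10⁻⁶), acceptable (10⁻⁶–10⁻⁴; both edges
inclusive), unacceptable (> 10⁻⁴). HI sums THQs over all seven metals;
it is reported per (species, cohort).

## Summaries

Tissue rankings (the "Pb > Cr > …" strings) are always recomputed by
descending mean with alphabetical tie-break on the metal code; printed
orderings in source narratives are treated as claims under test, since
several contradict their own concentration tables. `metal_range` takes
the tissue subset as an explicit argument and makes no claim about
which subset any abstract-style range refers to. The SD convention is
the sample SD (n − 1 denominator; sd = 0 for a single specimen) — the
source material does not state its convention, and n − 1 is the
standard summary-statistics choice.

## Synthetic specimen generator

`generate_specimens` emulates per-fish measurements whose cell-wise
first two moments match a target table. Default family is a normal with
the target mean/SD truncated at zero: several real cells have CV near
or above 1 (e.g. V 1.208 ± 1.371 μg/kg in tilapia muscle), where an
untruncated normal emits negative masses. Truncation inflates the
realized mean and shrinks the SD when sd ≳ mean; for cells with
mean ≥ 3·sd the distortion is below 1% (asserted at n = 10⁵). The
moment-matched lognormal (σ² = ln(1 + (sd/mean)²),
μ = ln mean − σ²/2) is offered where exact moment matching matters more
than the bell shape. sd = 0 is degenerate: every draw equals the mean.

Reproducibility: each cell draws from its own substream, seeded from
(master seed, CRC-32 of "species|tissue|metal" [, replicate index]).
The same seed reproduces the whole table bit-for-bit, and editing one
cell's parameters cannot shift another cell's draws.

What the generator does **not** emulate: inter-metal or inter-organ
correlation within a fish, covariate effects (fish size/weight),
measurement error structure, censoring at detection limits. Passing
end-to-end tests on synthetic data therefore demonstrates the
*arithmetic* pipeline, not distributional realism of real specimens —
the true specimen-level distributions are unknowable from summary
statistics, and the generator claims only the first two moments.

`recovery_report` repeats generate→aggregate and reports per-cell mean
bias and the fraction of replicates whose sample mean falls within
2·sd/√n of the target (≈ 95% nominal for low-CV cells); the default
check uses 500 replicates of n = 6, the fixture's specimen count.

## Numerical choices

* Report rounding is half-even to the published precision (3 decimals
  for exposure/limit/THQ/HI, 3 significant figures for CR); all
  comparisons in tests use tolerances, never formatted strings, because
  the published tables round inconsistently (several cells are
  truncated rather than rounded).
* DIL at zero concentration is rejected (`DomainError`) rather than
  returned as infinity.
* Degenerate (sd = 0) cells bypass floating-point summation in the
  recovery report so zero noise yields exactly zero bias.
* Regression tolerances: exposure cells ±0.005 absolute; limit cells
  0.1% relative or 0.001 absolute (the print precision of the
  small-magnitude Pb cells); THQ/HI ±0.001; CR 2% relative. Test
  problem sizes: the full 63-cell table everywhere, 10⁵ draws for
  moment checks, 500 × 6 for coverage.

## Known limitations

* Deterministic point estimates only: no probabilistic THQ/Monte-Carlo
  uncertainty propagation from the SDs into the risk metrics.
* Ingestion route only — no dermal/inhalation exposure, no
  age-interpolated cohorts, no cooking-loss adjustment.
* Total chromium is treated as one analyte; no Cr(III)/Cr(VI)
  speciation, although toxicity differs by orders of magnitude.
* No inferential statistics across species/tissues; the package
  summarizes and ranks, it does not test differences.
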