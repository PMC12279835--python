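"""Seeded specimen generator: determinism, moments, recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import fishrisk as fr
from fishrisk.errors import ConfigError

from conftest import NJ, OM


def _degenerate(ds: fr.StudyDataset) -> fr.StudyDataset:
    """Same means, zero SDs."""
    return fr.StudyDataset(tuple(dataclasses.replace(c, sd=0.0) for c in ds))


class TestConfig:
    def test_invalid_family_rejected(self, fixture_ds):
        with pytest.raises(ConfigError):
            fr.GeneratorConfig(fixture_ds, family="cauchy")

    def test_nonpositive_count_rejected(self, fixture_ds):
        with pytest.raises(ConfigError):
            fr.GeneratorConfig(fixture_ds, n_specimens=0)

    def test_lognormal_needs_positive_mean(self):
        zero = fr.StudyDataset((fr.TissueConcentration("x", "muscle", "Pb",
                                                       0.0, 0.0, 6),))
        with pytest.raises(ConfigError):
            fr.GeneratorConfig(zero, family="lognormal")


class TestDeterminism:
    def test_same_seed_same_table(self, fixture_ds):
        cfg = fr.GeneratorConfig(fixture_ds, seed=7)
        a = fr.generate_specimens(cfg).frame
        b = fr.generate_specimens(cfg).frame
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_different_table(self, fixture_ds):
        a = fr.generate_specimens(fr.GeneratorConfig(fixture_ds, seed=1)).frame
        b = fr.generate_specimens(fr.GeneratorConfig(fixture_ds, seed=2)).frame
        assert not a.concentration_ug_per_kg.equals(b.concentration_ug_per_kg)

    def test_cell_substreams_isolated(self, fixture_ds):
        """Perturbing one cell's target leaves every other cell's draws unchanged."""
        base = fr.generate_specimens(fr.GeneratorConfig(fixture_ds, seed=9)).frame
        cells = list(fixture_ds.cells)
        cells[0] = dataclasses.replace(cells[0], mean=cells[0].mean * 10)
        mod = fr.generate_specimens(
            fr.GeneratorConfig(fr.StudyDataset(tuple(cells)), seed=9)).frame
        pd.testing.assert_frame_equal(base.iloc[6:].reset_index(drop=True),
                                      mod.iloc[6:].reset_index(drop=True))
        assert not base.iloc[:6].concentration_ug_per_kg.equals(
            mod.iloc[:6].concentration_ug_per_kg)


class TestDraws:
    @pytest.mark.parametrize("family", ["truncnorm", "lognormal"])
    def test_non_negative(self, fixture_ds, family):
        tab = fr.generate_specimens(
            fr.GeneratorConfig(fixture_ds, n_specimens=50, family=family, seed=13))
        assert (tab.frame.concentration_ug_per_kg >= 0).all()

    def test_degenerate_noise_reproduces_means(self, fixture_ds):
        tab = fr.generate_specimens(fr.GeneratorConfig(_degenerate(fixture_ds), seed=1))
        agg = tab.aggregate()
        for cell in fixture_ds:
            got = agg.get(cell.species, cell.tissue, cell.metal)
            assert got.mean == pytest.approx(cell.mean, rel=1e-12)
            assert got.sd == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_pipeline_matches_fixture_risk(self, fixture_ds, refs):
        """sd = 0 synthetic data must reproduce the fixture's hazard indices."""
        agg = fr.generate_specimens(
            fr.GeneratorConfig(_degenerate(fixture_ds), seed=1)).aggregate()
        got = {(r.species, r.cohort): r.hi for r in fr.risk_results(agg, refs)}
        want = {(r.species, r.cohort): r.hi for r in fr.risk_results(fixture_ds, refs)}
        assert got == pytest.approx(want, rel=1e-12)

    def test_clt_bound_on_sample_mean(self):
        cell = fr.TissueConcentration("x", "muscle", "Pb", 10.0, 2.0, 6)
        cfg = fr.GeneratorConfig(fr.StudyDataset((cell,)), n_specimens=10_000, seed=3)
        mean = fr.generate_specimens(cfg).frame.concentration_ug_per_kg.mean()
        assert abs(mean - 10.0) <= 3 * 2.0 / np.sqrt(10_000)

    @pytest.mark.parametrize("family", ["truncnorm", "lognormal"])
    def test_moment_matching_low_cv_cells(self, fixture_ds, family):
        """At n = 1e5, low-CV cells recover both target moments within 1%.

        Truncation at zero distorts moments only when sd is comparable to
        the mean, so the check is restricted to cells with mean >= 3 sd.
        """
        low_cv = fr.StudyDataset(tuple(
            c for c in fixture_ds.subset(tissue="muscle")
            if c.sd > 0 and c.mean >= 3 * c.sd))
        assert len(low_cv) >= 10
        agg = fr.generate_specimens(
            fr.GeneratorConfig(low_cv, n_specimens=100_000,
                               family=family, seed=17)).aggregate()
        for cell in low_cv:
            got = agg.get(cell.species, cell.tissue, cell.metal)
            assert got.mean == pytest.approx(cell.mean, rel=0.01)
            assert got.sd == pytest.approx(cell.sd, rel=0.01)


class TestRecoveryReport:
    def test_zero_noise_zero_bias(self, fixture_ds):
        rep = fr.recovery_report(
            fr.GeneratorConfig(_degenerate(fixture_ds), seed=2), n_reps=5)
        assert (rep.mean_bias == 0).all()
        assert (rep.coverage_2se == 1.0).all()

    def test_single_replicate(self, fixture_ds):
        rep = fr.recovery_report(fr.GeneratorConfig(fixture_ds, seed=2), n_reps=1)
        assert (rep.n_reps == 1).all()
        assert len(rep) == len(fixture_ds)

    def test_two_se_coverage_near_nominal(self, fixture_ds):
        """~95% of replicate sample means fall within 2 SE of the target."""
        low_cv = fr.StudyDataset(tuple(
            c for c in fixture_ds.subset(tissue="muscle") if c.mean >= 3 * c.sd))
        rep = fr.recovery_report(fr.GeneratorConfig(low_cv, seed=11), n_reps=500)
        # binomial(500, .954) per cell: allow generous Monte-Carlo slack
        assert rep.coverage_2se.between(0.90, 0.99).all()

    def test_invalid_reps_rejected(self, fixture_ds):
        with pytest.raises(ConfigError):
            fr.recovery_report(fr.GeneratorConfig(fixture_ds, seed=1), n_reps=0)
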