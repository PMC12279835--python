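"""Domain types, packaged fixture, reference registry and back-derivation."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import fishrisk as fr
from fishrisk.errors import DomainError, MissingReferenceError

from conftest import LN, NJ, OM


class TestFixture:
    def test_grid_shape(self, fixture_ds):
        assert len(fixture_ds) == 63  # 3 species x 3 tissues x 7 metals
        assert all(c.n == 6 for c in fixture_ds)
        assert fixture_ds.species == [NJ, OM, LN]
        for sp in fixture_ds.species:
            for tissue in fr.Tissue:
                metals = {c.metal for c in fixture_ds
                          if c.species == sp and c.tissue == tissue}
                assert metals == set(fr.Metal)

    @pytest.mark.parametrize("species,tissue,metal,mean,sd", [
        (OM, "muscle", "Cr", 12.399, 5.384),
        (NJ, "liver", "Hg", 0.020, 0.004),
        (LN, "gills", "Sr", 15.200, 12.859),
        (NJ, "muscle", "Pb", 15.524, 0.087),
    ])
    def test_printed_cells(self, fixture_ds, species, tissue, metal, mean, sd):
        cell = fixture_ds.get(species, tissue, metal)
        assert cell.mean == mean
        assert cell.sd == sd

    def test_species_alias_recorded(self, fixture_ds):
        assert fixture_ds.metadata["species_alias"][LN] == "Lates calcarifer"

    def test_validates_clean(self, fixture_ds):
        assert fr.validate_dataset(fixture_ds) == []


class TestCodes:
    def test_metal_parse_case_insensitive(self):
        assert fr.Metal.parse("pb") is fr.Metal.PB
        assert fr.Metal.parse(" HG ") is fr.Metal.HG

    @pytest.mark.parametrize("bad", ["Fe", "Zn", "", "Pb2"])
    def test_unknown_metal_rejected(self, bad):
        with pytest.raises(DomainError):
            fr.Metal.parse(bad)

    def test_tissue_parse(self):
        assert fr.Tissue.parse("MUSCLE") is fr.Tissue.MUSCLE
        with pytest.raises(DomainError):
            fr.Tissue.parse("kidney")


class TestCohorts:
    def test_defaults(self):
        assert (fr.CHILDREN.ingestion_rate, fr.CHILDREN.body_weight) == (75.0, 20.0)
        assert (fr.ADULTS.ingestion_rate, fr.ADULTS.body_weight) == (150.0, 70.0)
        for cohort in fr.DEFAULT_COHORTS:
            assert cohort.exposure_frequency == 365.0
            assert cohort.exposure_duration == 70.0
            assert cohort.averaging_time == 365.0 * 70.0

    @pytest.mark.parametrize("kwargs", [
        {"ingestion_rate": 0.0}, {"body_weight": -5.0},
        {"exposure_frequency": 0.0}, {"averaging_time": -1.0},
    ])
    def test_positivity_enforced(self, kwargs):
        base = dict(name="x", ingestion_rate=75.0, body_weight=20.0)
        base.update(kwargs)
        with pytest.raises(DomainError):
            fr.CohortParams(**base)


class TestValidation:
    def test_negative_mean_flagged(self):
        cell = fr.load_fixture().cells[0]
        object.__setattr__(cell, "mean", -1.0)  # bypass constructor guard
        out = fr.validate_dataset(fr.StudyDataset((cell,)))
        assert len(out) == 1 and "negative mean" in out[0]

    def test_duplicate_key_flagged(self, fixture_ds):
        cell = fixture_ds.cells[0]
        out = fr.validate_dataset(fr.StudyDataset((cell, cell)))
        assert len(out) == 1 and "duplicate" in out[0]

    def test_empty_dataset_flagged(self):
        assert fr.validate_dataset(fr.StudyDataset(())) != []


class TestReferenceRegistry:
    def test_default_values(self, refs):
        assert refs.rfd("Pb") == 0.3
        assert refs.ptwi("As") == 15.0
        assert refs.csf("Cd") == 5.0e-5
        assert refs.get("As", "ptwi").provenance == "paper-stated"
        assert refs.get("Cr", "ptwi").provenance == "back-derived"

    @pytest.mark.parametrize("metal", ["Hg", "Sr", "V"])
    def test_no_slope_factor(self, refs, metal):
        assert not refs.has(metal, "csf")
        with pytest.raises(MissingReferenceError):
            refs.csf(metal)

    def test_toml_round_trip_preserves_provenance(self, refs, tmp_path):
        path = tmp_path / "refs.toml"
        refs.to_toml(path)
        again = fr.ReferenceValueSet.from_toml(path)
        assert again == refs
        assert again.get("As", "rfd").provenance == "back-derived"

    def test_invalid_provenance_rejected(self):
        rvs = fr.ReferenceValueSet()
        with pytest.raises(DomainError):
            rvs.set("As", "rfd", 0.3, provenance="guessed")


class TestCsvIO:
    def test_round_trip(self, fixture_ds, tmp_path):
        path = tmp_path / "conc.csv"
        fixture_ds.to_csv(path)
        again = fr.StudyDataset.from_csv(path)
        assert again.cells == fixture_ds.cells

    def test_case_insensitive_read(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "species,tissue,metal,mean_ug_per_kg,sd_ug_per_kg,n\n"
            "Fishy,MUSCLE,pb,1.5,0.1,6\n")
        ds = fr.StudyDataset.from_csv(path)
        cell = ds.cells[0]
        assert cell.tissue is fr.Tissue.MUSCLE and cell.metal is fr.Metal.PB


class TestBackDerivation:
    def test_rfd_from_printed_arsenic_cell(self):
        # DIL 19.480 kg/day at 0.308 ug/kg, 20 kg child -> implied RfD 0.3
        assert fr.derive_rfd(19.480, 0.308, 20) == pytest.approx(0.300, abs=1e-3)

    def test_rfd_from_printed_chromium_cell(self):
        assert fr.derive_rfd(2419.549, 12.399, 20) == pytest.approx(1500, abs=1)

    def test_csf_from_printed_arsenic_cr(self):
        assert fr.derive_csf(1.7325e-6, 1.155e-6) == pytest.approx(1.5, rel=1e-9)

    def test_csf_from_printed_lead_cr(self):
        assert fr.derive_csf(4.95e-7, 5.8215e-5) == pytest.approx(0.0085, rel=0.02)

    def test_zero_risk_implies_zero_slope(self):
        assert fr.derive_csf(0.0, 1e-6) == 0.0

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(DomainError):
            fr.derive_rfd(bad, 1.0, 20.0)
        with pytest.raises(DomainError):
            fr.derive_csf(1e-6, bad if bad else 0.0)

    @settings(deadline=None, derandomize=True)
    @given(rfd=st.floats(1e-3, 1e4), bw=st.floats(1.0, 200.0),
           c=st.floats(1e-3, 1e5))
    def test_round_trip_with_dil(self, rfd, bw, c):
        assert fr.derive_rfd(fr.dil(rfd, bw, c), c, bw) == pytest.approx(rfd, rel=1e-12)

    def test_ptwi_round_trip(self):
        assert fr.derive_ptwi(fr.mdi(15.0, 20.0), 20.0) == pytest.approx(15.0, rel=1e-12)
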