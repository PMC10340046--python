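"""Synthetic study generator: distribution targets, consistency, determinism."""

import numpy as np
import pytest

import faecalnirs as fn
from faecalnirs.simulate import (
    ChemistryParams,
    ConstituentDist,
    SpectraGenParams,
    StudyDesign,
    draw_constituent,
    simulate_chemistry,
    simulate_spectra,
)


class TestChemistryDraws:
    def test_total_set_cp_moments(self):
        """10 000 draws of total-set crude protein land on the target
        mean 266.0 and SD 23.90 (g/kg DM) within Monte-Carlo error."""
        values = draw_constituent(ChemistryParams(), "Total", "cp", 10_000, seed=7)
        assert values.mean() == pytest.approx(266.0, abs=1.0)
        assert values.std(ddof=1) == pytest.approx(23.90, abs=1.0)
        assert values.min() >= 218.0 and values.max() <= 320.0

    def test_degenerate_sd_collapses_to_mean(self):
        params = ChemistryParams()
        params.chemistry = dict(params.chemistry)
        params.chemistry["Total"] = dict(params.chemistry["Total"])
        params.chemistry["Total"]["cp"] = ConstituentDist(266.0, 1e-6, 218.0, 320.0)
        values = draw_constituent(params, "Total", "cp", 100, seed=1)
        np.testing.assert_allclose(values, 266.0, atol=1e-4)

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(ValueError):
            ConstituentDist(250.0, 10.0, 260.0, 240.0)

    def test_attd_block_draws_are_fractions(self):
        values = draw_constituent(ChemistryParams(), "Control", "dm", 500, seed=3, kind="attd")
        assert np.all((values >= 0.82) & (values <= 0.90))
        assert values.mean() == pytest.approx(0.87, abs=0.005)


class TestSimulateChemistry:
    def test_counts_and_design_labels(self):
        fae, feed, attd = simulate_chemistry(ChemistryParams(), StudyDesign(), seed=0)
        assert len(fae) == 240
        assert sorted(fae["batch"].unique()) == ["B1", "B2"]
        assert set(fae["diet"]) == {"Control", "LCP", "HCP", "LNE", "HNE"}
        assert len(feed) == 5
        assert len(attd) == 240 * 5

    def test_marker_consistency_by_construction(self):
        fae, feed, attd = simulate_chemistry(ChemistryParams(), StudyDesign(), seed=5)
        feed = feed.set_index("diet")
        wide = attd.pivot(index="sample_id", columns="constituent", values="attd")
        for c in ("dm", "cp", "om", "ge", "fat"):
            recomputed = 1.0 - (
                fae[c].to_numpy() / feed.loc[fae["diet"], c].to_numpy()
            ) * (feed.loc[fae["diet"], "aia"].to_numpy() / fae["aia"].to_numpy())
            np.testing.assert_allclose(recomputed, wide.loc[fae["sample_id"], c], atol=1e-12)

    def test_attd_moments_near_targets(self):
        fae, _, attd = simulate_chemistry(ChemistryParams(), StudyDesign(days=30), seed=9)
        wide = attd.pivot(index="sample_id", columns="constituent", values="attd")
        # derived (non-anchor) coefficients inherit the target moments
        assert wide["cp"].mean() == pytest.approx(0.71, abs=0.02)
        assert wide["cp"].std(ddof=1) == pytest.approx(0.065, abs=0.02)
        assert wide["om"].mean() == pytest.approx(0.85, abs=0.02)

    def test_batch_shift_direction(self):
        params = ChemistryParams(batch_shift_sd=1.0)
        fae, _, _ = simulate_chemistry(params, StudyDesign(days=20), seed=2)
        b1 = fae[fae["batch"] == "B1"]["cp"].mean()
        b2 = fae[fae["batch"] == "B2"]["cp"].mean()
        assert b2 > b1


class TestSimulateSpectra:
    def _chem(self, seed=0, n_days=1):
        fae, _, _ = simulate_chemistry(ChemistryParams(), StudyDesign(days=n_days), seed=seed)
        return fae

    def test_noise_free_mixture_matches_closed_form(self):
        chem = self._chem().head(3)
        params = SpectraGenParams(
            scatter_sd={"FDG": 0.0, "FDNG": 0.0},
            baseline_sd={"FDG": 0.0, "FDNG": 0.0},
            baseline_mean=0.0, slope_mean=0.0, noise_sd=0.0, n_replicates=1,
        )
        sset = simulate_spectra(chem, params, "FDG", seed=0)
        wl = sset.wavelengths
        conc = {c: chem[c].to_numpy() for c in ("dm", "cp", "om", "ge", "fat")}
        conc["moisture"] = 1000.0 - conc["dm"]
        expected = np.zeros((3, wl.size))
        for constituent, bands in params.bands.items():
            for centre, width, weight in bands:
                shape = weight * np.exp(-0.5 * ((wl - centre) / width) ** 2)
                expected += np.outer(conc[constituent], shape)
        np.testing.assert_allclose(sset.absorbance, expected, atol=1e-12)

    def test_same_seed_forms_share_chemistry_differ_in_scatter(self):
        chem = self._chem()
        params = SpectraGenParams()
        a = simulate_spectra(chem, params, "FDG", seed=11)
        b = simulate_spectra(chem, params, "FDNG", seed=11)
        assert list(a.sample_ids) == list(b.sample_ids)
        assert not np.allclose(a.absorbance, b.absorbance)

    def test_doubling_cp_raises_band_absorbance(self):
        chem = self._chem().head(1).copy()
        params = SpectraGenParams(
            scatter_sd={"FDG": 0.0, "FDNG": 0.0},
            baseline_sd={"FDG": 0.0, "FDNG": 0.0},
            baseline_mean=0.0, slope_mean=0.0, noise_sd=0.0, n_replicates=1,
        )
        low = simulate_spectra(chem, params, "FDG", seed=0)
        chem2 = chem.copy()
        chem2["cp"] = chem2["cp"] * 2
        high = simulate_spectra(chem2, params, "FDG", seed=0)
        idx = int(np.argmin(np.abs(low.wavelengths - 2055)))
        assert high.absorbance[0, idx] > low.absorbance[0, idx]

    def test_two_replicates_per_sample(self):
        chem = self._chem()
        sset = simulate_spectra(chem, SpectraGenParams(), "FDG", seed=1)
        assert len(sset) == 2 * len(chem)
        assert sorted(set(sset.meta["replicate_id"])) == ["1", "2"]

    def test_scatter_ordering_enforced(self):
        with pytest.raises(ValueError):
            SpectraGenParams(scatter_sd={"FDG": 0.2, "FDNG": 0.1})


class TestSimulateStudy:
    def test_default_counts(self, bundle42):
        assert bundle42.manifest["n_collected"] == 240
        assert len(bundle42.chemistry) == 230
        assert len(bundle42.outlier_ids) == 7
        assert len(bundle42.spectra_fdg) == 460  # two replicates each

    def test_no_discards_keeps_all(self):
        bundle = fn.simulate_study(design=StudyDesign(days=1, n_discard=0, n_outliers=0), seed=1)
        assert len(bundle.chemistry) == 40

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        design = StudyDesign(days=1, n_discard=2, n_outliers=1)
        for run in ("a", "b"):
            fn.simulate_study(design=design, seed=99).write(tmp_path / run)
        for name in ("spectra_fdg.csv", "spectra_fdng.csv", "chemistry.csv",
                     "feed.csv", "attd.csv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_planted_outliers_recovered_by_screening(self, bundle42, screened42):
        """GH screening finds at least 6 of the 7 planted anomalies in
        each presentation form."""
        planted = set(bundle42.outlier_ids)
        for form in ("FDG", "FDNG"):
            _, result = screened42[form]
            assert len(set(result.flagged_ids) & planted) >= 6
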