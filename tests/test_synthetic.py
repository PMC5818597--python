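import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats

from iscpipe import synthetic
from iscpipe.bioenergetics import classify_phenotype, flux_folds
from iscpipe.synthetic import (AssayDesign, HillCurve, default_panel,
                               generate_cbmn, generate_cellcycle,
                               generate_expression_and_densitometry,
                               generate_flux, generate_morphology,
                               generate_study, gc_archetype, inert_archetype,
                               ngc_archetype)


class TestValidation:
    def test_doses_must_increase_and_include_zero(self):
        with pytest.raises(ValueError):
            AssayDesign(doses=(0.0, 10.0, 5.0))
        with pytest.raises(ValueError):
            AssayDesign(doses=(1.0, 10.0))

    def test_inert_archetype_has_flat_curves_everywhere(self, inert):
        assert all(c.flat for c in inert.effects.values())
        eff = dict(inert.effects)
        eff["mn_percent"] = HillCurve(0.8, 3.0, 10.0)
        with pytest.raises(ValueError, match="non-flat"):
            synthetic.ChemicalArchetype("bad", "inert", eff, cytotox_ec50=10.0)

    def test_invalid_hill_parameters_rejected(self):
        with pytest.raises(ValueError):
            HillCurve(0.0, 1.0, ec50=-1.0)
        with pytest.raises(ValueError):
            HillCurve(0.0, 1.0, ec50=1.0, hill_slope=0.0)


class TestCBMN:
    def test_default_scoring_depth_is_9000_per_replicate(self, gc, small_design):
        df = generate_cbmn(gc, small_design, seed=1)
        assert (df.binucleates_scored == 9000).all()
        assert (df.micronucleated <= df.binucleates_scored).all()

    def test_inert_mn_within_exact_binomial_bounds(self, inert, small_design):
        """Every dose of an inert chemical stays inside the exact binomial
        99.9% band around the baseline MN rate."""
        df = generate_cbmn(inert, small_design, seed=3)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 9000, 0.008)
        assert df.micronucleated.between(lo, hi).all()

    def test_rpd_declines_to_50pct_at_cytotox_ec50(self):
        arch = gc_archetype("g", cytotox_ec50=31.6)
        assert arch.rpd_fraction(31.6) == pytest.approx(0.5)
        assert arch.rpd_fraction(0.0) == pytest.approx(1.0)

    def test_biphasic_curve_supported(self):
        c = HillCurve(1.0, 3.0, 10.0, biphasic_ec50=100.0, biphasic_amplitude=1.5)
        assert c.value(10_000) < c.value(30.0)


class TestMorphology:
    def test_nuclear_always_smaller_than_cell(self, gc, small_design):
        df = generate_morphology(gc, small_design, seed=2)
        assert (df.nuclear_area_um2 < df.cell_area_um2).all()

    def test_programmed_log_shift_moves_median(self, small_design):
        """+0.3 log shift at the top dose: treated/control median cell-area
        ratio is about e^0.3."""
        arch = gc_archetype("g", cell_shift=0.3, signalling_ec50=0.001)
        design = AssayDesign(cells_imaged_per_condition=9000, seed=0)
        df = generate_morphology(arch, design, seed=5)
        med = df.groupby("dose_uM").cell_area_um2.median()
        ratio = med[100.0] / med[0.0]
        assert ratio == pytest.approx(np.exp(0.3), rel=0.05)

    def test_inert_treated_matches_control_in_law(self, inert, small_design):
        df = generate_morphology(inert, small_design, seed=8)
        ctl = df[df.dose_uM == 0].cell_area_um2
        top = df[df.dose_uM == 100.0].cell_area_um2
        assert stats.ks_2samp(ctl, top).pvalue > 0.005


class TestCellCycle:
    def test_events_total_per_dose_is_36000(self, gc):
        design = AssayDesign(seed=0)
        df = generate_cellcycle(gc, design, seed=1)
        totals = df.groupby("dose_uM")[["g1_events", "s_events", "g2_events"]].sum()
        assert (totals.sum(axis=1) == 36000).all()

    def test_inert_mean_proportions_match_baseline_simplex(self, inert):
        design = AssayDesign(seed=0)
        df = generate_cellcycle(inert, design, seed=2)
        g2 = df.g2_events / (df.g1_events + df.s_events + df.g2_events)
        assert g2.mean() == pytest.approx(0.20, abs=0.02)

    def test_arrest_archetype_reaches_g2_target(self):
        """Top-dose G2 mean over 200 draws within 2 points of the 45%
        programmed target."""
        arch = gc_archetype("g", g2_max=45.0, signalling_ec50=0.001)
        design = AssayDesign(doses=(0.0, 100.0), seed=0)
        means = []
        for s in range(200):
            df = generate_cellcycle(arch, design, seed=s)
            top = df[df.dose_uM == 100.0]
            means.append(100 * top.g2_events.sum()
                         / top[["g1_events", "s_events", "g2_events"]].sum().sum())
        assert np.mean(means) == pytest.approx(45.0, abs=2.0)


class TestExpressionDensitometry:
    def test_zero_shift_gives_fold_one_in_expectation(self, inert, small_design):
        expr, dens = generate_expression_and_densitometry(inert, small_design, 4)
        dcq = expr.cq_target - expr.cq_reference
        # batch offsets cancel in expectation across replicates
        assert 2 ** -(dcq.mean() - 6.0) == pytest.approx(1.0, abs=0.25)
        ratio = dens.target_intensity / dens.loading_intensity
        assert ratio.mean() == pytest.approx(1.0, abs=0.1)

    def test_programmed_fold_shifts_cq(self, small_design):
        arch = gc_archetype("g", cdkn1a_max=4.0, expression_ec50=0.001)
        expr, _ = generate_expression_and_densitometry(arch, small_design, 4)
        sub = expr[expr.gene == "CDKN1A"]
        shift = (sub[sub.dose_uM == 0].cq_target.mean()
                 - sub[sub.dose_uM == 100].cq_target.mean())
        assert shift == pytest.approx(-np.log2(1 / 4.0), abs=0.5)


class TestFlux:
    def test_zero_noise_no_shift_reproduces_centroid_exactly(self, small_design):
        arch = inert_archetype("i", replicate_cv=0.0)
        df = generate_flux(arch, small_design, seed=1)
        assert (df.ocr_pmol_min == synthetic.CONTROL_OCR).all()
        assert (df.ecar_mph_min == synthetic.CONTROL_ECAR).all()

    def test_quiescent_archetype_classified_quiescent(self, small_design):
        arch = ngc_archetype("n", ocr_max=1 / 3, ecar_max=1 / 1.8,
                             effect_ec50=0.001)
        df = generate_flux(arch, small_design, seed=2)
        ocr_f, ecar_f = flux_folds(df[df.dose_uM == 100.0], df[df.dose_uM == 0])
        assert classify_phenotype(ocr_f, ecar_f).label == "quiescent"

    def test_inert_classified_unchanged_in_most_runs(self, small_design, inert):
        hits = 0
        for s in range(60):
            df = generate_flux(inert, small_design, seed=s)
            ocr_f, ecar_f = flux_folds(df[df.dose_uM == 100.0],
                                       df[df.dose_uM == 0])
            hits += classify_phenotype(ocr_f, ecar_f).label == "unchanged"
        assert hits / 60 >= 0.95


class TestStudyBundle:
    def test_three_archetypes_give_three_complete_datasets(self, small_design):
        bundle = generate_study([gc_archetype("a"), ngc_archetype("b"),
                                 inert_archetype("c")], small_design, 1)
        for name, df in bundle.tables().items():
            assert set(df.chemical.unique()) == {"a", "b", "c"}, name
            for chem in ("a", "b", "c"):
                sub = df[df.chemical == chem]
                assert set(sub.dose_uM.unique()) == set(small_design.doses)

    def test_duplicate_names_rejected(self, small_design):
        with pytest.raises(ValueError, match="duplicate"):
            generate_study([inert_archetype("x"), gc_archetype("x")],
                           small_design, 1)

    def test_same_seed_gives_identical_tables_and_csv_bytes(self, small_design,
                                                            tmp_path):
        panel = [gc_archetype("a"), ngc_archetype("b")]
        b1 = generate_study(panel, small_design, 42)
        b2 = generate_study(panel, small_design, 42)
        for name in b1.TABLE_NAMES:
            assert_frame_equal(getattr(b1, name), getattr(b2, name))
        p1 = b1.to_csv(tmp_path / "one")
        p2 = b2.to_csv(tmp_path / "two")
        for name in p1:
            assert open(p1[name], "rb").read() == open(p2[name], "rb").read()

    def test_tables_can_be_regenerated_independently(self, small_design):
        """Child seeds are independent per table: the morphology table does
        not depend on whether other tables were generated."""
        arch = gc_archetype("a")
        alone = generate_morphology(arch, small_design, seed=9)
        bundle = generate_study([arch], small_design, seed=9)
        assert_frame_equal(alone, bundle.morphology)

    def test_default_panel_composition(self):
        panel = default_panel()
        classes = [a.mechanism_class for a in panel]
        assert len(panel) == 8
        assert classes.count("GC") == 4
        assert classes.count("NGC") == 4
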