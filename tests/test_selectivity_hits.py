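import statistics

import pytest
from hypothesis import given
from hypothesis import strategies as st

import bmscreen as b
from bmscreen.screen_io import ValidationError
from bmscreen.selectivity_hits import DrugMetrics


def _metrics(cid="d", r2=0.95, auc=0.5, z=-5.0, family="", converged=True):
    return DrugMetrics(compound_id=cid, auc_tumor=auc, auc_hfb=0.9, auc_pbc=1.0,
                       zprime=z, r2_tumor=r2, converged=converged,
                       target_family=family)


class TestZPrimeSelectivity:
    def test_centered_tumor_scores_zero(self):
        assert b.compute_zprime_selectivity(0.95, [0.9, 1.0]) == pytest.approx(0.0)

    def test_two_control_arithmetic(self):
        z = b.compute_zprime_selectivity(0.3, [0.9, 1.0])
        assert z == pytest.approx((0.3 - 0.95) / statistics.stdev([0.9, 1.0]), abs=1e-12)
        assert z == pytest.approx(-9.192388, abs=1e-6)

    def test_sd_floor_engages_on_identical_controls(self):
        assert b.compute_zprime_selectivity(0.3, [0.95, 0.95]) == pytest.approx(-13.0)

    def test_requires_two_controls(self):
        with pytest.raises(ValidationError):
            b.compute_zprime_selectivity(0.3, [0.9])

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_antisymmetric_about_control_mean(self, auc_t, c1, c2):
        mean = (c1 + c2) / 2
        z1 = b.compute_zprime_selectivity(auc_t, [c1, c2])
        z2 = b.compute_zprime_selectivity(2 * mean - auc_t, [c1, c2])
        assert z1 == pytest.approx(-z2, abs=1e-9)


class TestZPrimeFactor:
    def test_textbook_value(self):
        assert b.compute_zprime_factor(1.0, 0.05, 0.0, 0.05) == pytest.approx(0.7)

    def test_perfect_separation(self):
        assert b.compute_zprime_factor(1.0, 0.0, 0.0, 0.0) == 1.0

    def test_overlapping_distributions_go_negative(self):
        assert b.compute_zprime_factor(1.0, 0.5, 0.9, 0.5) == pytest.approx(-29.0)

    def test_equal_means_rejected(self):
        with pytest.raises(ValidationError):
            b.compute_zprime_factor(1.0, 0.1, 1.0, 0.1)


class TestSelectHits:
    def test_staged_funnel_on_four_drugs(self):
        metrics = [
            _metrics("a", r2=0.95, auc=0.5, z=-5),
            _metrics("b", r2=0.70, auc=0.3, z=-9),
            _metrics("c", r2=0.90, auc=0.8, z=-4),
            _metrics("d", r2=0.90, auc=0.5, z=-1),
        ]
        annotated, funnel = b.select_hits(metrics)
        assert {m.compound_id for m in annotated if m.is_hit} == {"a"}
        assert (funnel.n_screened, funnel.n_fit_pass, funnel.n_effective,
                funnel.n_selective) == (4, 3, 2, 1)

    def test_all_flat_drugs_pass_nothing_past_fit(self):
        metrics = [_metrics(f"d{i}", r2=0.9, auc=0.95, z=0.0) for i in range(5)]
        _, funnel = b.select_hits(metrics)
        assert (funnel.n_effective, funnel.n_selective) == (0, 0)
        assert funnel.n_fit_pass == 5

    def test_unconverged_fit_fails_first_stage(self):
        m = _metrics("u", r2=float("nan"), converged=False)
        annotated, funnel = b.select_hits([m])
        assert not annotated[0].pass_r2
        assert funnel.n_fit_pass == 0

    def test_empty_input_gives_zero_funnel(self):
        annotated, funnel = b.select_hits([])
        assert annotated == []
        assert funnel == b.FunnelCounts(0, 0, 0, 0)

    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1), st.floats(-15, 5)),
                    max_size=30),
           st.floats(0.5, 0.95), st.floats(0.3, 0.9), st.floats(-4, 0))
    def test_threshold_monotonicity(self, rows, r2_min, auc_max, z_max):
        metrics = [_metrics(f"c{i}", r2=r, auc=a, z=z)
                   for i, (r, a, z) in enumerate(rows)]

        def hits(**kw):
            ann, _ = b.select_hits(metrics, **kw)
            return {m.compound_id for m in ann if m.is_hit}

        base = hits(r2_min=r2_min, auc_max=auc_max, z_max=z_max)
        assert base <= hits(r2_min=r2_min, auc_max=auc_max + 0.05, z_max=z_max)
        assert base <= hits(r2_min=r2_min, auc_max=auc_max, z_max=z_max + 0.5)
        assert hits(r2_min=r2_min + 0.02, auc_max=auc_max, z_max=z_max) <= base

    def test_funnel_monotonicity_enforced(self):
        with pytest.raises(ValidationError):
            b.FunnelCounts(4, 5, 1, 0)


class TestTargetFamilySummary:
    def test_counts_and_fractions(self):
        lib = {
            "a": b.CompoundRecord("a", "a", ("JAK3",), "JAK", b.ClinicalStatus.FDA_APPROVED),
            "b": b.CompoundRecord("b", "b", ("JAK1",), "JAK", b.ClinicalStatus.FDA_APPROVED),
            "c": b.CompoundRecord("c", "c", ("ERBB2",), "HER2", b.ClinicalStatus.FDA_APPROVED),
        }
        hits = [_metrics(cid) for cid in ("a", "b", "c")]
        table = b.summarize_target_families(hits, lib)
        assert table == [("JAK", 2, pytest.approx(2 / 3)), ("HER2", 1, pytest.approx(1 / 3))]
        assert sum(frac for _, _, frac in table) == pytest.approx(1.0, abs=1e-9)

    def test_no_hits_gives_empty_table(self):
        assert b.summarize_target_families([], {}) == []

    def test_hit_missing_from_library_rejected(self):
        with pytest.raises(ValidationError, match="ghost"):
            b.summarize_target_families([_metrics("ghost")], {})


class TestGeneticSupport:
    LIB = {
        "pacritinib": b.CompoundRecord("pacritinib", "pacritinib",
                                       ("JAK2", "FLT3"), "JAK",
                                       b.ClinicalStatus.FDA_APPROVED),
        "nintedanib": b.CompoundRecord("nintedanib", "nintedanib",
                                       ("FGFR1", "FGFR2", "FGFR3"), "FGFR",
                                       b.ClinicalStatus.FDA_APPROVED),
    }

    def test_jak3_variant_supports_jak_family_hit(self):
        variants = [v for v in b.load_reference_variants() if v.sample_id == "BM36"]
        out = b.flag_genetic_support([_metrics("pacritinib", family="JAK")],
                                     variants, self.LIB, b.load_gene_to_family())
        assert out[0].genetic_support

    def test_fgfr3_variant_supports_pan_fgfr_inhibitor_directly(self):
        variants = [v for v in b.load_reference_variants()
                    if v.sample_id == "BM35" and v.gene == "FGFR3"]
        out = b.flag_genetic_support([_metrics("nintedanib", family="FGFR")],
                                     variants, self.LIB, gene_to_family={})
        assert out[0].genetic_support  # FGFR3 is an annotated target gene

    def test_no_variants_means_no_support(self):
        out = b.flag_genetic_support(
            [_metrics("pacritinib", family="JAK")], [], self.LIB,
            b.load_gene_to_family())
        assert not out[0].genetic_support

    def test_unmapped_gene_ignored(self):
        variants = [b.VariantCall("BM99", b.VariantSource.TISSUE, "GENEX",
                                  "c.1A>G", "", 50.0)]
        out = b.flag_genetic_support([_metrics("pacritinib", family="JAK")],
                                     variants, self.LIB, b.load_gene_to_family())
        assert not out[0].genetic_support


class TestBuildDrugMetrics:
    def test_end_to_end_recovery_on_small_screen(self, small_screen):
        cfg, _, truths, fits, library = small_screen
        metrics = b.build_drug_metrics(
            fits, tumor_model_id=cfg.tumor_model_id, library=library,
            exclude=("panobinostat", "staurosporine"))
        annotated, funnel = b.select_hits(metrics)
        assert {m.compound_id for m in annotated if m.is_hit} == b.truth_hit_set(truths)
        assert funnel.n_screened == cfg.n_compounds

    def test_positive_controls_excluded(self, small_screen):
        cfg, _, _, fits, library = small_screen
        metrics = b.build_drug_metrics(
            fits, tumor_model_id=cfg.tumor_model_id, library=library,
            exclude=("panobinostat", "staurosporine"))
        ids = {m.compound_id for m in metrics}
        assert "panobinostat" not in ids and "staurosporine" not in ids
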