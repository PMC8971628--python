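import math

import numpy as np
import pytest

from _oracles import enumeration_lnl
from famvar.core.pedigree import Member, Pedigree, PedigreeError, make_groups
from famvar.core.variants import VariantRecord
from famvar.segregation import (
    ALL_MODEL_KINDS,
    MENDELIAN_AD,
    MENDELIAN_AR,
    SPORADIC,
    SPORADIC_RESIDUAL,
    SegregationFit,
    SegregationModel,
    best_models,
    cosegregation_filter,
    fit_models,
    mendelian_consistency,
    pedigree_likelihood,
)
from famvar.synth import SimulationConfig, simulate_affection, simulate_pedigree


def _ad_model(q, fc, f0):
    return SegregationModel(
        MENDELIAN_AD, {"allele_freq": q, "f_carrier": fc, "f_noncarrier": f0}, k=3
    )


class TestPedigreeLikelihood:
    def test_sporadic_closed_form_single_founder(self):
        ped = Pedigree([Member("A", "male", "unaffected", 1)])
        model = SegregationModel(SPORADIC, {"prevalence": 0.5}, k=1)
        assert pedigree_likelihood(ped, model) == pytest.approx(math.log(0.5))

    def test_impossible_data_is_neg_inf(self, trio):
        # q = 0 means no carriers; phenocopy 0 makes an affected child impossible
        model = _ad_model(q=0.0, fc=0.9, f0=0.0)
        assert pedigree_likelihood(trio, model) == -math.inf

    @pytest.mark.parametrize("kind", [MENDELIAN_AD, MENDELIAN_AR])
    def test_matches_enumeration_oracle(self, kind, trio, six_member_pedigree):
        rng = np.random.default_rng(5)
        for _ in range(25):
            q = rng.uniform(0.02, 0.98)
            fc = rng.uniform(0.05, 0.95)
            f0 = rng.uniform(0.0, 0.5)
            for ped in (trio, six_member_pedigree):
                model = SegregationModel(
                    kind,
                    {"allele_freq": q, "f_carrier": fc, "f_noncarrier": f0},
                    k=3,
                )
                got = pedigree_likelihood(ped, model)
                want = enumeration_lnl(ped, kind, q, fc, f0)
                assert got == pytest.approx(want, abs=1e-9)

    def test_invariant_to_member_reordering(self, six_member_pedigree):
        model = _ad_model(0.3, 0.8, 0.05)
        base = pedigree_likelihood(six_member_pedigree, model)
        reordered = Pedigree(
            list(reversed(six_member_pedigree.members)),
            family_id=six_member_pedigree.family_id,
        )
        assert pedigree_likelihood(reordered, model) == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize("q,pen_index", [(0.0, "f_noncarrier"), (1.0, "f_carrier")])
    def test_boundary_q_collapses_to_sporadic(self, six_member_pedigree, q, pen_index):
        params = {"allele_freq": q, "f_carrier": 0.8, "f_noncarrier": 0.1}
        got = pedigree_likelihood(
            six_member_pedigree, SegregationModel(MENDELIAN_AD, params, k=3)
        )
        prevalence = params[pen_index]
        sporadic = pedigree_likelihood(
            six_member_pedigree,
            SegregationModel(SPORADIC, {"prevalence": prevalence}, k=1),
        )
        assert got == pytest.approx(sporadic, abs=1e-9)

    def test_adding_affected_carrier_never_decreases_ad_likelihood(self):
        # likelihood of the shared members' statuses cannot drop when a
        # consistent affected carrier child is appended (pen >= phenocopy)
        base = Pedigree(
            [
                Member("F", "male", "affected", 1),
                Member("M", "female", "unaffected", 1),
                Member("C1", "male", "affected", 2, "F", "M"),
            ]
        )
        extended = Pedigree(
            base.members
            + [Member("C2", "female", "affected", 2, "F", "M")]
        )
        model = _ad_model(0.3, 0.9, 0.05)
        lnl_base = pedigree_likelihood(base, model)
        lnl_ext = pedigree_likelihood(extended, model)
        # the extra member multiplies in a probability <= 1, but the
        # conditional P(new affected | rest) must be >= phenocopy rate
        assert lnl_ext - lnl_base >= math.log(0.05) - 1e-9
        assert lnl_ext <= lnl_base + 1e-12

    def test_loop_pedigree_rejected(self):
        # first cousins marrying: their union closes a cycle
        ped = Pedigree(
            [
                Member("GF", "male", "unaffected", 1),
                Member("GM", "female", "unaffected", 1),
                Member("U1", "male", "unaffected", 2, "GF", "GM"),
                Member("U2", "female", "unaffected", 2, "GF", "GM"),
                Member("W1", "female", "unaffected", 1),
                Member("H2", "male", "unaffected", 1),
                Member("C1", "male", "unaffected", 3, "U1", "W1"),
                Member("C2", "female", "unaffected", 3, "H2", "U2"),
                Member("X", "male", "affected", 4, "C1", "C2"),
            ]
        )
        assert ped.has_loop()
        with pytest.raises(PedigreeError, match="loop"):
            pedigree_likelihood(ped, _ad_model(0.1, 0.9, 0.01))


class TestFitModels:
    def test_aic_identity(self, template_pedigree):
        for fit in fit_models(template_pedigree):
            assert fit.neg2lnL == pytest.approx(-2 * fit.lnL)
            assert fit.aic == pytest.approx(fit.neg2lnL + 2 * fit.model.k)

    def test_fits_sorted_by_aic(self, template_pedigree):
        fits = fit_models(template_pedigree)
        aics = [f.aic for f in fits]
        assert aics == sorted(aics)
        assert {f.model.kind for f in fits} == set(ALL_MODEL_KINDS)

    def test_sporadic_mle_closed_form(self, template_pedigree):
        (fit,) = fit_models(template_pedigree, [SPORADIC])
        p = fit.model.params["prevalence"]
        assert p == pytest.approx(5 / 17)
        want = 5 * math.log(p) + 12 * math.log(1 - p)
        assert fit.lnL == pytest.approx(want)

    def test_residual_fit_at_least_sporadic(self, template_pedigree):
        fits = {f.model.kind: f for f in fit_models(template_pedigree)}
        # the frailty model nests the sporadic model (pi -> 0 or odds -> 1)
        assert fits[SPORADIC_RESIDUAL].lnL >= fits[SPORADIC].lnL - 1e-6

    def test_mendelian_fit_at_least_boundary_sporadic(self, template_pedigree):
        fits = {f.model.kind: f for f in fit_models(template_pedigree)}
        assert fits[MENDELIAN_AD].lnL >= fits[SPORADIC].lnL - 1e-6

    def test_sporadic_data_prefers_simple_models(self, template_pedigree):
        # under label-shuffled (sporadic) affection the sporadic model should
        # usually sit within 2 AIC of the best fit
        hits = 0
        n = 15
        for seed in range(n):
            ped = simulate_affection(
                template_pedigree, allele_freq=0.0, f_carrier=0.3,
                f_noncarrier=0.3, seed=seed,
            )
            if not ped.affected_ids() or not ped.unaffected_ids():
                hits += 1
                continue
            fits = fit_models(ped)
            by = {f.model.kind: f.aic for f in fits}
            if by[SPORADIC] <= min(by.values()) + 2.0:
                hits += 1
        assert hits >= 0.6 * n

    def test_best_models_reports_ties(self, template_pedigree):
        fits = fit_models(template_pedigree)
        best = best_models(fits, tol=1e-3)
        assert min(f.aic for f in fits) == best[0].aic


class TestMendelianConsistency:
    def _record(self, genotypes):
        return VariantRecord(
            chrom="chr1", pos=1, ref="A", alt="G", genotypes=genotypes
        )

    def test_impossible_transmission(self, trio):
        rec = self._record({"DAD": 0, "MOM": 1, "KID": 2})
        assert not mendelian_consistency(rec, trio)

    def test_valid_transmission(self, trio):
        rec = self._record({"DAD": 0, "MOM": 1, "KID": 1})
        assert mendelian_consistency(rec, trio)

    def test_missing_summed_over(self, trio):
        rec = self._record({"DAD": 0, "MOM": None, "KID": 2})
        # MOM could be 1 or 2... but DAD 0 forces KID <= 1: inconsistent
        assert not mendelian_consistency(rec, trio)
        rec2 = self._record({"DAD": None, "MOM": None, "KID": 2})
        assert mendelian_consistency(rec2, trio)

    def test_hom_parents_must_transmit(self, trio):
        rec = self._record({"DAD": 2, "MOM": 2, "KID": 1})
        assert not mendelian_consistency(rec, trio)


class TestCosegregation:
    def test_driver_pattern_passes_ad(self, template_pedigree, default_variant_set):
        records, truth = default_variant_set
        groups = make_groups(template_pedigree)
        (driver,) = [r for r in records if r.key == truth.driver_key]
        assert cosegregation_filter(driver, groups, "AD")

    def test_healthy_comparator_carrier_fails_ad(
        self, template_pedigree, default_variant_set
    ):
        records, truth = default_variant_set
        groups = make_groups(template_pedigree)
        (driver,) = [r for r in records if r.key == truth.driver_key]
        comparator = sorted(groups.healthy_comparator_ids)[0]
        spoiled = driver.with_genotypes({**driver.genotypes, comparator: 1})
        assert not cosegregation_filter(spoiled, groups, "AD")

    def test_het_affected_mode_contrast(self, template_pedigree):
        groups = make_groups(template_pedigree)
        genotypes = {m: 0 for m in template_pedigree.member_ids}
        for m in groups.affected_ids:
            genotypes[m] = 1
        rec = VariantRecord(
            chrom="chr1", pos=1, ref="A", alt="G", genotypes=genotypes
        )
        assert cosegregation_filter(rec, groups, "AD")
        assert not cosegregation_filter(rec, groups, "AR")
        assert cosegregation_filter(rec, groups, ("AD", "AR"))

    def test_exempt_members_unconstrained(self, template_pedigree):
        groups = make_groups(template_pedigree)
        genotypes = {m: 0 for m in template_pedigree.member_ids}
        for m in groups.affected_ids | groups.exempt_ids:
            genotypes[m] = 1
        rec = VariantRecord(
            chrom="chr1", pos=1, ref="A", alt="G", genotypes=genotypes
        )
        assert cosegregation_filter(rec, groups, "AD")

    def test_unknown_mode_rejected(self, template_pedigree):
        groups = make_groups(template_pedigree)
        rec = VariantRecord(chrom="chr1", pos=1, ref="A", alt="G", genotypes={})
        with pytest.raises(ValueError, match="mode"):
            cosegregation_filter(rec, groups, "XL")


def test_segregation_fit_identity_direct():
    model = SegregationModel(SPORADIC, {"prevalence": 0.2}, k=1)
    fit = SegregationFit(model=model, lnL=-8.3785)
    assert fit.neg2lnL == pytest.approx(16.757)
    assert fit.aic == pytest.approx(18.757)
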