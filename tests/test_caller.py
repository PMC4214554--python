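"""Caller orchestration: individual posteriors, candidate filter, the
de novo over-correction guard, method dispatch and end-to-end runs."""

import filecmp

import numpy as np
import pytest

from pedcall.caller import (
    RunConfig,
    call_file,
    call_records,
    call_site,
    individual_posteriors,
    overcorrection_guard,
)
from pedcall.errors import LoopedPedigreeError
from pedcall.evidence import SiteEvidence
from pedcall.genetic_model import build_transmission, default_prior
from pedcall.inference.exact import exact_posteriors
from pedcall.inference.mcmc import McmcConfig
from pedcall.inference.peeling import peel_posteriors
from pedcall.pedigree import read_pedigree
from pedcall.simdata import SimConfig, template_pedigree, write_fixture
from pedcall.variant_io import read_vcf

from conftest import random_evidence


class TestIndividualPosteriors:
    def test_bayes_rule_example(self, trio):
        lik = np.array([[0.1, 0.9, 0.0]] * 3)
        ev = SiteEvidence(lik, default_prior(False), build_transmission(0.0))
        post = individual_posteriors(ev).posteriors[0]
        expected = np.array([0.1 * 0.9985, 0.9 * 0.001, 0.0])
        expected /= expected.sum()
        np.testing.assert_allclose(post, expected, atol=1e-12)
        np.testing.assert_allclose(post, [0.99107, 0.00893, 0.0], atol=5e-6)

    def test_uniform_likelihood_returns_prior(self, trio):
        ev = SiteEvidence(np.ones((3, 3)), default_prior(True), build_transmission(0.0))
        np.testing.assert_allclose(
            individual_posteriors(ev).posteriors,
            np.tile([0.45, 0.1, 0.45], (3, 1)),
            atol=1e-12,
        )

    def test_single_member_family_call_equals_individual(self, rng):
        from pedcall.pedigree import Gender, Individual, Pedigree

        ped = Pedigree.from_individuals([Individual("X", None, None, Gender.MALE, "X")])
        ev = random_evidence(ped, rng)
        np.testing.assert_allclose(
            individual_posteriors(ev).posteriors,
            exact_posteriors(ev, ped).posteriors,
            atol=1e-12,
        )


def denovo_like_evidence(trio, ratio_child=1e6):
    """Parents decisively RR, child decisively RA: Mendelian-impossible
    at m=0 with per-member best/second likelihood ratios of ~1e6."""
    lik = np.array(
        [
            [1.0, 1e-6, 1e-12],
            [1.0, 1e-6, 1e-12],
            [1.0 / ratio_child, 1.0, 1e-6],
        ]
    )
    return SiteEvidence(lik, default_prior(False), build_transmission(1e-7))


class TestOvercorrectionGuard:
    def test_triggers_on_decisive_mendelian_violation(self, trio):
        ev = denovo_like_evidence(trio)
        ind = individual_posteriors(ev)
        assert ind.genotypes.tolist() == [0, 0, 1]
        assert overcorrection_guard(ev, trio, ind, cutoff=1e3)

    def test_requires_all_members_decisive(self, trio):
        # child still individually called RA, but its likelihood ratio
        # (1e4) sits below the cutoff: the "all individuals" clause fails
        ev = denovo_like_evidence(trio, ratio_child=1e4)
        ind = individual_posteriors(ev)
        assert ind.genotypes.tolist() == [0, 0, 1]
        assert not overcorrection_guard(ev, trio, ind, cutoff=1e5)

    def test_never_triggers_when_consistent(self, trio):
        lik = np.array([[1.0, 1e-9, 1e-12]] * 3)
        ev = SiteEvidence(lik, default_prior(False), build_transmission(1e-7))
        ind = individual_posteriors(ev)
        assert not overcorrection_guard(ev, trio, ind, cutoff=1e3)

    def test_guard_replaces_family_call(self, tmp_path, trio):
        from pedcall.variant_io import VariantRecord

        ev = denovo_like_evidence(trio)
        rec = VariantRecord(
            chrom="1", pos=1, vid=None, ref="A", alts=("T",), is_dbsnp=False,
            candidate=True, skip_reason=None, likelihoods=ev.likelihoods,
            source=None, source_format="table", table_samples=("F", "M", "C"),
        )
        _, ind, fam = call_site(rec, trio, RunConfig(lr_cutoff=1e3))
        np.testing.assert_array_equal(fam.posteriors, ind.posteriors)
        assert fam.mode == "family"
        # without the guard the family call drags the child back to RR
        _, _, fam_unguarded = call_site(rec, trio, RunConfig())
        assert fam_unguarded.genotypes[2] == 0


class TestMethodDispatch:
    def _record(self, ped, ev):
        from pedcall.variant_io import VariantRecord

        return VariantRecord(
            chrom="1", pos=10, vid=None, ref="A", alts=("T",), is_dbsnp=False,
            candidate=True, skip_reason=None, likelihoods=ev.likelihoods,
            source=None, source_format="table",
            table_samples=tuple(ped.sequenced_index),
        )

    def test_auto_uses_peeling_on_trees(self, rng):
        ped = template_pedigree("tree7")
        ev = random_evidence(ped, rng)
        _, _, fam = call_site(self._record(ped, ev), ped, RunConfig(method="auto"))
        np.testing.assert_array_equal(fam.posteriors, peel_posteriors(ev, ped).posteriors)

    def test_auto_uses_enumeration_on_loops(self, loop7, rng):
        ev = random_evidence(loop7, rng)
        _, _, fam = call_site(self._record(loop7, ev), loop7, RunConfig(method="auto"))
        np.testing.assert_array_equal(
            fam.posteriors, exact_posteriors(ev, loop7).posteriors
        )

    def test_explicit_peeling_on_loop_raises_with_site_context(self, loop7, rng):
        ev = random_evidence(loop7, rng)
        with pytest.raises(LoopedPedigreeError, match="1:10"):
            call_site(self._record(loop7, ev), loop7, RunConfig(method="elston_stewart"))

    def test_mcmc_dispatch_close_to_exact(self, trio, rng):
        ev = random_evidence(trio, rng)
        cfg = RunConfig(method="mcmc", mcmc=McmcConfig(seed=1))
        _, _, fam = call_site(self._record(trio, ev), trio, cfg)
        assert np.abs(fam.posteriors - exact_posteriors(ev, trio).posteriors).max() < 0.02


class TestCallFile:
    def test_engines_agree_over_a_whole_file(self, tmp_path):
        paths = write_fixture(SimConfig(template="tree7", n_sites=40, seed=5), tmp_path / "f")
        ped = read_pedigree(paths["ped"])
        sites_es = list(
            call_records(read_vcf(paths["vcf"], ped), ped, RunConfig(method="elston_stewart"))
        )
        sites_bn = list(
            call_records(read_vcf(paths["vcf"], ped), ped, RunConfig(method="exact"))
        )
        for (r1, i1, f1), (r2, i2, f2) in zip(sites_es, sites_bn):
            np.testing.assert_array_equal(i1.posteriors, i2.posteriors)
            assert np.abs(f1.posteriors - f2.posteriors).max() <= 1e-10

    def test_end_to_end_deterministic(self, tmp_path):
        paths = write_fixture(SimConfig(n_sites=25, seed=6), tmp_path / "f")
        ped = read_pedigree(paths["ped"])
        out1, out2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        call_file(paths["vcf"], ped, out1, RunConfig())
        call_file(paths["vcf"], ped, out2, RunConfig())
        assert filecmp.cmp(out1, out2, shallow=False)

    def test_summary_counts(self, tmp_path):
        ped_path = tmp_path / "p.ped"
        ped_path.write_text("F 0 0 1 F\nM 0 0 2 M\nC M F 1 C\n")
        vcf = tmp_path / "in.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="PL">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF\tM\tC\n"
            "1\t1\t.\tA\t.\t.\t.\t.\tPL\t0,9,99\t0,9,99\t0,9,99\n"
            "1\t2\t.\tA\tT\t.\t.\t.\tPL\t0,9,99\t0,9,99\t9,0,99\n"
        )
        summary = call_file(vcf, ped_path, tmp_path / "o.vcf", RunConfig())
        assert summary == {
            "records": 2, "called": 1, "skipped": 1, "method": "auto", "has_loop": False,
        }
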