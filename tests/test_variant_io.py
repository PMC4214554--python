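"""PL conversion, VCF and likelihood-table reading, annotated output."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedcall.caller import RunConfig, call_file, call_records
from pedcall.errors import (
    MalformedPLError,
    MissingPLError,
    SampleMismatchError,
    VariantIOError,
)
from pedcall.pedigree import read_pedigree
from pedcall.simdata import SimConfig, write_fixture
from pedcall.variant_io import (
    likelihood_to_pl,
    pl_to_likelihood,
    read_likelihood_table,
    read_vcf,
    write_output,
)

MINIMAL_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="PL">\n'
)


def make_vcf(tmp_path, body, samples=("F", "M", "C"), header=MINIMAL_VCF_HEADER):
    p = tmp_path / "in.vcf"
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    p.write_text(header + cols + "\n" + body)
    return p


def trio_ped(tmp_path):
    p = tmp_path / "trio.ped"
    p.write_text("F 0 0 1 F\nM 0 0 2 M\nC M F 1 C\n")
    return read_pedigree(p)


class TestPlConversion:
    @pytest.mark.parametrize(
        "pl, expected",
        [
            ((0, 30, 300), (1.0, 1e-3, 1e-30)),
            ((0, 0, 0), (1.0, 1.0, 1.0)),
            ((10, 0, 40), (1e-1, 1.0, 1e-4)),
        ],
    )
    def test_phred_definition(self, pl, expected):
        np.testing.assert_allclose(pl_to_likelihood(pl), expected, rtol=1e-12)

    @pytest.mark.parametrize("bad", [(0, 30), (0, 30, 300, 10), (-1, 0, 5)])
    def test_malformed(self, bad):
        with pytest.raises(MalformedPLError):
            pl_to_likelihood(bad)

    @given(
        st.lists(st.integers(min_value=0, max_value=2000), min_size=3, max_size=3)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_identity_on_min_shifted_pls(self, pl):
        shifted = tuple(x - min(pl) for x in pl)  # writer always min-shifts
        assert likelihood_to_pl(pl_to_likelihood(shifted)) == shifted


class TestReadVcf:
    def test_fixture_round_trip(self, tmp_path):
        cfg = SimConfig(n_sites=20, seed=3)
        paths = write_fixture(cfg, tmp_path / "fix")
        ped = read_pedigree(paths["ped"])
        recs = list(read_vcf(paths["vcf"], ped))
        assert len(recs) == 20
        assert all(r.candidate for r in recs)
        assert recs[0].pos == 1000 and recs[0].alts == ("G",)
        assert not recs[0].is_dbsnp

    def test_unsequenced_member_absent_from_vcf(self, tmp_path):
        ped_path = tmp_path / "p.ped"
        # grandfather in the pedigree but never sequenced (sample NA)
        ped_path.write_text(
            "GF 0 0 1 NA\nGM 0 0 2 GM\nF GM GF 1 F\nM 0 0 2 M\nC M F 1 C\n"
        )
        ped = read_pedigree(ped_path)
        vcf = make_vcf(
            tmp_path,
            "1\t5\t.\tA\tT\t.\t.\t.\tPL\t0,10,100\t0,10,100\t0,10,100\t0,10,100\n",
            samples=("GM", "F", "M", "C"),
        )
        (rec,) = list(read_vcf(vcf, ped))
        np.testing.assert_array_equal(rec.likelihoods[0], [1.0, 1.0, 1.0])

    def test_sequenced_member_missing_is_error(self, tmp_path):
        ped = trio_ped(tmp_path)
        vcf = make_vcf(tmp_path, "", samples=("F", "M"))
        with pytest.raises(SampleMismatchError):
            list(read_vcf(vcf, ped))

    def test_missing_pl_format_is_error(self, tmp_path):
        ped = trio_ped(tmp_path)
        vcf = make_vcf(
            tmp_path,
            "",
            header="##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n',
        )
        with pytest.raises(MissingPLError):
            list(read_vcf(vcf, ped))

    def test_no_alt_is_non_candidate(self, tmp_path):
        ped = trio_ped(tmp_path)
        vcf = make_vcf(
            tmp_path, "1\t7\t.\tA\t.\t.\t.\t.\tPL\t0,10,99\t0,10,99\t0,10,99\n"
        )
        (rec,) = list(read_vcf(vcf, ped))
        assert not rec.candidate and rec.skip_reason == "no alternative allele"

    def test_multiallelic_skipped_by_default_called_with_first_alt(self, tmp_path):
        ped = trio_ped(tmp_path)
        body = "1\t9\t.\tA\tT,G\t.\t.\t.\tPL\t0,10,99,20,30,99\t0,9,99,20,30,99\t9,0,99,20,30,99\n"
        (rec,) = list(read_vcf(make_vcf(tmp_path, body), ped))
        assert not rec.candidate and rec.skip_reason == "multi-allelic site"
        (rec2,) = list(read_vcf(make_vcf(tmp_path, body), ped, first_alt=True))
        assert rec2.candidate
        np.testing.assert_allclose(rec2.likelihoods[2], pl_to_likelihood((9, 0, 99)))

    def test_missing_sample_pl_is_uninformative(self, tmp_path):
        ped = trio_ped(tmp_path)
        vcf = make_vcf(tmp_path, "1\t3\trs7\tA\tT\t.\t.\t.\tPL\t0,10,99\t.\t0,5,50\n")
        (rec,) = list(read_vcf(vcf, ped))
        assert rec.is_dbsnp
        np.testing.assert_array_equal(rec.likelihoods[1], [1.0, 1.0, 1.0])


TABLE = """\
#chrom\tpos\tid\tref\talt\tF_RR\tF_RA\tF_AA\tM_RR\tM_RA\tM_AA\tC_RR\tC_RA\tC_AA
1\t100\t.\tA\tG\t1.0\t0.01\t1e-8\t1.0\t0.02\t1e-9\t0.5\t1.0\t0.001
1\t101\trs99\tT\t.\t1.0\t0.01\t1e-8\t1.0\t0.02\t1e-9\t0.5\t1.0\t0.001
"""


class TestLikelihoodTable:
    def test_read(self, tmp_path):
        ped = trio_ped(tmp_path)
        p = tmp_path / "t.tsv"
        p.write_text(TABLE)
        recs = list(read_likelihood_table(p, ped))
        assert len(recs) == 2
        assert recs[0].candidate and not recs[1].candidate
        np.testing.assert_allclose(recs[0].likelihoods[2], [0.5, 1.0, 0.001])

    def test_all_zero_triple_rejected(self, tmp_path):
        ped = trio_ped(tmp_path)
        p = tmp_path / "t.tsv"
        p.write_text(
            "#chrom\tpos\tid\tref\talt\tF_RR\tF_RA\tF_AA\tM_RR\tM_RA\tM_AA\tC_RR\tC_RA\tC_AA\n"
            "1\t100\t.\tA\tG\t0\t0\t0\t1\t0\t0\t1\t0\t0\n"
        )
        with pytest.raises(VariantIOError):
            list(read_likelihood_table(p, ped))

    def test_round_trip_through_writer(self, tmp_path):
        ped = trio_ped(tmp_path)
        p = tmp_path / "t.tsv"
        p.write_text(TABLE)
        sites = list(call_records(read_likelihood_table(p, ped), ped, RunConfig()))
        out = tmp_path / "out.tsv"
        assert write_output(sites, out, ped) == 2
        again = list(read_likelihood_table(out, ped))
        assert len(again) == 2
        for a, b in zip(sites, again):
            np.testing.assert_allclose(
                a[0].likelihoods if a[0].likelihoods is not None else 0,
                b.likelihoods if b.likelihoods is not None else 0,
            )

    def test_cross_format_agreement(self, tmp_path):
        # the same evidence via table (exact) and VCF (PL-quantised) must
        # give nearly identical posteriors
        ped = trio_ped(tmp_path)
        lik = np.array(
            [[1.0, 0.01, 1e-8], [1.0, 0.02, 1e-9], [0.5, 1.0, 0.001]]
        )
        tbl = tmp_path / "t.tsv"
        tbl.write_text(TABLE)
        pls = [",".join(str(x) for x in likelihood_to_pl(row)) for row in lik]
        vcf = make_vcf(tmp_path, f"1\t100\t.\tA\tG\t.\t.\t.\tPL\t{pls[0]}\t{pls[1]}\t{pls[2]}\n")
        cfg = RunConfig()
        (site_t, *_rest) = list(call_records(read_likelihood_table(tbl, ped), ped, cfg))
        (site_v,) = list(call_records(read_vcf(vcf, ped), ped, cfg))
        assert np.abs(site_t[2].posteriors - site_v[2].posteriors).max() < 0.02


class TestWriteOutput:
    def test_vcf_output_round_trips_and_calls_are_argmax(self, tmp_path):
        cfg = SimConfig(n_sites=30, seed=9)
        paths = write_fixture(cfg, tmp_path / "fix")
        ped = read_pedigree(paths["ped"])
        out = tmp_path / "out.vcf"
        sites = list(call_records(read_vcf(paths["vcf"], ped), ped, RunConfig()))
        assert write_output(sites, out, ped) == 30

        # output parses with the module's own reader, records in order
        again = list(read_vcf(out, ped))
        assert [r.pos for r in again] == [r[0].pos for r in sites]

        # GPI/GPF equal the argmax of the printed posterior triples
        import pysam

        gt_index = {"0/0": 0, "0/1": 1, "1/1": 2}
        vf = pysam.VariantFile(str(out))
        for rec, (r0, ind, fam) in zip(vf, sites):
            for name, i in ped.sequenced_index.items():
                s = rec.samples[name]
                assert gt_index[s["GPI"]] == ind.genotypes[i]
                assert gt_index[s["GPF"]] == fam.genotypes[i]
                assert float(s["PPI"]) == pytest.approx(
                    ind.called_probability(i), abs=5.1e-5
                )
                assert float(s["PPF"]) == pytest.approx(
                    fam.called_probability(i), abs=5.1e-5
                )

    def test_non_candidate_records_pass_through(self, tmp_path):
        ped = trio_ped(tmp_path)
        body = (
            "1\t7\t.\tA\t.\t.\t.\t.\tPL\t0,10,99\t0,10,99\t0,10,99\n"
            "1\t8\t.\tA\tT\t.\t.\t.\tPL\t0,10,99\t0,10,99\t0,10,99\n"
        )
        vcf = make_vcf(tmp_path, body)
        out = tmp_path / "out.vcf"
        sites = list(call_records(read_vcf(vcf, ped), ped, RunConfig()))
        assert sites[0][1] is None  # skipped, not called
        write_output(sites, out, ped)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 2
        assert "GPI" not in lines[0].split("\t")[8]  # skipped record unchanged
        assert "GPI" in lines[1].split("\t")[8]
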