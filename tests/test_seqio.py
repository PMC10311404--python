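"""Parser and site-filter behavior for ms, VCF and FASTA inputs."""

import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sweepnet as sn
from sweepnet.seqio import ANCESTRAL, DERIVED, OTHER, from_replicate


class TestParseMs:
    def test_direct_transcription_and_scaling(self):
        text = "ms 2 1\n1 2 3\n\n//\nsegsites: 2\npositions: 0.10 0.50\n01\n10\n"
        mats = sn.parse_ms(text, region_len=100_000)
        assert len(mats) == 1
        m = mats[0]
        assert m.states.shape == (2, 2)
        np.testing.assert_array_equal(m.positions_bp, [10_000, 50_000])
        np.testing.assert_array_equal(m.states, [[0, 1], [1, 0]])

    def test_zero_segsites(self):
        text = "//\nsegsites: 0\n"
        mats = sn.parse_ms(text)
        assert mats[0].n_sites == 0

    def test_two_blocks(self):
        text = ("//\nsegsites: 1\npositions: 0.5\n0\n1\n"
                "\n//\nsegsites: 1\npositions: 0.2\n1\n0\n")
        assert len(sn.parse_ms(text)) == 2

    def test_row_length_mismatch_names_replicate(self):
        text = ("//\nsegsites: 2\npositions: 0.1 0.2\n01\n10\n"
                "\n//\nsegsites: 2\npositions: 0.1 0.2\n011\n10\n")
        with pytest.raises(ValueError, match="replicate 2"):
            sn.parse_ms(text)

    def test_position_ties_bumped_to_strictly_increasing(self):
        text = "//\nsegsites: 3\npositions: 0.5 0.5 0.5\n010\n101\n"
        m = sn.parse_ms(text, region_len=10)[0]
        assert np.all(np.diff(m.positions_bp) > 0)

    def test_non_binary_character_becomes_other(self):
        text = "//\nsegsites: 2\npositions: 0.1 0.2\n0x\n10\n"
        m = sn.parse_ms(text)[0]
        assert m.states[0, 1] == OTHER


@st.composite
def replicate_lists(draw):
    n = draw(st.integers(2, 6))
    n_reps = draw(st.integers(1, 3))
    reps = []
    for _ in range(n_reps):
        t = draw(st.integers(0, 12))
        pos = np.sort(draw(st.lists(
            st.floats(0.0, 1.0, width=32), min_size=t, max_size=t
        )))
        haps = np.zeros((n, t), dtype=np.uint8)
        for j in range(t):
            ones = draw(st.sets(st.integers(0, n - 1), min_size=1, max_size=n - 1))
            haps[list(ones), j] = 1
        reps.append(sn.MsReplicate(positions=pos, haplotypes=haps,
                                   region_len=1_000_000))
    return reps


class TestRoundTrip:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(replicate_lists())
    def test_write_then_parse_is_identity(self, reps):
        text = sn.write_ms(reps)
        parsed = sn.parse_ms(text, region_len=1_000_000)
        assert len(parsed) == len(reps)
        for rep, mat in zip(reps, parsed):
            assert mat.n_sites == rep.segsites
            if rep.segsites:
                np.testing.assert_array_equal(rep.haplotypes, mat.states)
                expected = np.ceil(np.round(rep.positions, 6) * 1_000_000)
                # ties are bumped upward by at most the tie-run length
                assert np.all(mat.positions_bp >= np.maximum(expected, 1))
                assert np.all(np.diff(mat.positions_bp) > 0)


def _write_vcf(tmp_path, body, name="test.vcf", samples=("S1",)):
    header = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=100000>
        ##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        """)
    header += "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    header += "\t".join(samples) + "\n"
    path = tmp_path / name
    path.write_text(header + body)
    return path


class TestParseVcf:
    def test_phased_het_expands_to_two_haplotypes(self, tmp_path):
        p = _write_vcf(tmp_path, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\n")
        m = sn.parse_vcf(p)
        assert m.states.shape == (2, 1)
        assert set(m.states[:, 0]) == {ANCESTRAL, DERIVED}
        assert m.positions_bp[0] == 100

    def test_missing_genotype_becomes_other(self, tmp_path):
        p = _write_vcf(tmp_path, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t.|.\n")
        m = sn.parse_vcf(p)
        assert set(m.states[:, 0]) == {OTHER}

    def test_empty_body(self, tmp_path):
        p = _write_vcf(tmp_path, "")
        m = sn.parse_vcf(p)
        assert m.n_sites == 0
        assert m.n_samples == 2

    def test_unphased_heterozygote_rejected_by_default(self, tmp_path):
        p = _write_vcf(tmp_path, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(ValueError, match="unphased"):
            sn.parse_vcf(p)
        with pytest.warns(UserWarning):
            m = sn.parse_vcf(p, on_unphased="warn")
        assert m.n_sites == 1

    def test_aa_tag_flips_polarity(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t.\tPASS\tAA=G\tGT\t0|1\n"
        p = _write_vcf(tmp_path, body)
        m = sn.parse_vcf(p, ancestral="aa")
        # REF allele A is now the derived state
        np.testing.assert_array_equal(m.states[:, 0], [DERIVED, ANCESTRAL])
        m_ref = sn.parse_vcf(p, ancestral="ref")
        np.testing.assert_array_equal(m_ref.states[:, 0], [ANCESTRAL, DERIVED])

    def test_multiallelic_flagged_for_filter(self, tmp_path):
        body = ("chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0|1\n"
                "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0|1\n")
        p = _write_vcf(tmp_path, body)
        m = sn.parse_vcf(p)
        np.testing.assert_array_equal(m.n_source_alleles, [3, 2])
        filtered, report = sn.filter_sites(m)
        assert report.n_infinite_sites_violations == 1
        assert filtered.n_sites == 1


class TestParseFasta:
    def _write(self, tmp_path, seqs):
        path = tmp_path / "aln.fasta"
        path.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        return path

    def test_single_polymorphic_column(self, tmp_path):
        p = self._write(tmp_path, {"a": "ACGT", "b": "ACGT", "c": "AGGT"})
        m = sn.parse_fasta(p)
        assert m.n_sites == 1
        assert m.positions_bp[0] == 2  # 1-based

    def test_gap_becomes_other(self, tmp_path):
        p = self._write(tmp_path, {"a": "ACGT", "b": "A-GT", "c": "AGGT"})
        m = sn.parse_fasta(p)
        col = m.states[:, 0]
        assert col[1] == OTHER

    def test_outgroup_excluded_and_polarises(self, tmp_path):
        p = self._write(tmp_path, {"a": "AC", "b": "AG", "out": "AG"})
        m = sn.parse_fasta(p, ancestral_source="outgroup:out")
        assert m.n_samples == 2
        assert "out" not in m.sample_ids
        # outgroup carries G, so G is ancestral and C derived
        np.testing.assert_array_equal(m.states[:, 0], [DERIVED, ANCESTRAL])

    def test_ragged_alignment_rejected(self, tmp_path):
        p = self._write(tmp_path, {"a": "ACGT", "b": "ACG"})
        with pytest.raises(ValueError, match="ragged"):
            sn.parse_fasta(p)

    def test_missing_outgroup_rejected(self, tmp_path):
        p = self._write(tmp_path, {"a": "AC", "b": "AG"})
        with pytest.raises(ValueError, match="not found"):
            sn.parse_fasta(p, ancestral_source="outgroup:nope")


class TestFilterSites:
    def _matrix(self, cols, n_alleles=None):
        states = np.array(cols, dtype=np.uint8).T
        return sn.SNPMatrix(
            states=states,
            positions_bp=np.arange(1, states.shape[1] + 1),
            region_len=1000,
            n_source_alleles=(None if n_alleles is None
                              else np.asarray(n_alleles)),
        )

    def test_monomorphic_column_removed(self):
        m = self._matrix([[0, 0, 0], [0, 1, 0]])
        filtered, report = sn.filter_sites(m)
        assert filtered.n_sites == 1
        assert report.n_monomorphic == 1

    def test_all_other_column_removed_as_monomorphic(self):
        m = self._matrix([[2, 2, 2], [0, 1, 1]])
        filtered, report = sn.filter_sites(m)
        assert filtered.n_sites == 1
        assert report.n_monomorphic == 1

    def test_triallelic_column_removed(self):
        m = self._matrix([[0, 1, 0], [0, 1, 1]], n_alleles=[3, 2])
        filtered, report = sn.filter_sites(m)
        assert filtered.n_sites == 1
        assert report.n_infinite_sites_violations == 1

    def test_clean_matrix_unchanged(self):
        m = self._matrix([[0, 1, 0], [1, 0, 1]])
        filtered, report = sn.filter_sites(m)
        np.testing.assert_array_equal(filtered.states, m.states)
        assert report.n_kept == 2

    def test_idempotent(self):
        m = self._matrix([[0, 0, 0], [0, 1, 2], [1, 1, 1]],
                         n_alleles=[2, 3, 2])
        once, _ = sn.filter_sites(m)
        twice, report = sn.filter_sites(once)
        np.testing.assert_array_equal(once.states, twice.states)
        assert report.n_monomorphic == 0
        assert report.n_infinite_sites_violations == 0

    def test_report_tsv(self):
        m = self._matrix([[0, 1, 0], [0, 1, 1]])
        _, report = sn.filter_sites(m)
        assert "sites_kept\t" in report.to_tsv()


class TestSNPMatrixInvariants:
    def test_positions_must_strictly_increase(self):
        with pytest.raises(ValueError):
            sn.SNPMatrix(
                states=np.zeros((2, 2), np.uint8),
                positions_bp=np.array([5, 5]),
                region_len=10,
            )

    def test_from_replicate_preserves_order(self, tiny_neutral_reps):
        m = from_replicate(tiny_neutral_reps[0])
        assert np.all(np.diff(m.positions_bp) > 0)
        assert m.n_samples == tiny_neutral_reps[0].n_samples
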