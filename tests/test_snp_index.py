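"""Read QC, substituted reference, SNP-index, and homozygous extraction."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from rhizoquant.snp_index import (
    compute_snp_index,
    extract_homozygous,
    fastq_quality_filter,
    passes_quality,
    read_allele_counts_tsv,
    read_allele_counts_vcf,
    substitute_reference,
)
from rhizoquant.synthgen import VariantSimParams, make_allele_counts


def _read(quals, seq=None):
    seq = seq or "A" * len(quals)
    rec = SeqRecord(Seq(seq), id="r1")
    rec.letter_annotations["phred_quality"] = list(quals)
    return rec


class TestFastqFilter:
    def test_high_quality_read_kept(self):
        kept, discarded = fastq_quality_filter([_read([40] * 100)])
        assert len(kept) == 1 and not discarded

    def test_exactly_ten_percent_low_quality_kept(self):
        # the exclusion rule is strictly "more than 10%"
        quals = [20] * 10 + [40] * 90
        kept, discarded = fastq_quality_filter([_read(quals)])
        assert len(kept) == 1 and not discarded

    def test_eleven_percent_low_quality_discarded(self):
        quals = [29] * 11 + [40] * 89
        kept, discarded = fastq_quality_filter([_read(quals)])
        assert not kept and len(discarded) == 1

    def test_q30_is_not_low_quality(self):
        assert passes_quality([30] * 100)

    def test_phred64_looking_input_rejected(self):
        with pytest.raises(ValueError, match="Phred"):
            fastq_quality_filter([_read([70] * 50)])

    def test_parses_fastq_file(self, tmp_path):
        path = tmp_path / "reads.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\n!!!!\n")
        kept, discarded = fastq_quality_filter(path)
        assert [r.id for r in kept] == ["r1"]
        assert [r.id for r in discarded] == ["r2"]

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.integers(0, 41), min_size=1, max_size=60),
           st.randoms(use_true_random=False))
    def test_decision_is_permutation_invariant(self, quals, rnd):
        shuffled = list(quals)
        rnd.shuffle(shuffled)
        assert passes_quality(quals) == passes_quality(shuffled)


class TestSubstituteReference:
    TABLE = pd.DataFrame({"chrom": ["c1"], "position": [2],
                          "ref_base": ["C"], "sub_base": ["T"]})

    def test_single_substitution(self):
        out, n = substitute_reference({"c1": "ACGT"}, self.TABLE)
        assert str(out[0].seq) == "ATGT"
        assert n == 1

    def test_empty_table_is_identity(self):
        table = self.TABLE.iloc[:0]
        out, n = substitute_reference({"c1": "ACGT"}, table)
        assert str(out[0].seq) == "ACGT" and n == 0

    def test_lenient_reapplication_is_idempotent(self):
        once, n1 = substitute_reference({"c1": "ACGT"}, self.TABLE)
        twice, n2 = substitute_reference({rec.id: str(rec.seq) for rec in once},
                                         self.TABLE, strict=False)
        assert n1 == 1 and n2 == 0
        assert str(twice[0].seq) == str(once[0].seq)

    def test_strict_mismatch_raises(self):
        bad = self.TABLE.assign(ref_base=["G"])
        with pytest.raises(ValueError, match="reference base"):
            substitute_reference({"c1": "ACGT"}, bad)

    def test_position_out_of_range_raises(self):
        bad = self.TABLE.assign(position=[99])
        with pytest.raises(ValueError, match="outside"):
            substitute_reference({"c1": "ACGT"}, bad)

    def test_hamming_distance_equals_substitution_count(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        positions = rng.choice(np.arange(1, 301), size=25, replace=False)
        rows = []
        for pos in positions:
            ref_b = seq[pos - 1]
            sub_b = rng.choice([b for b in "ACGT" if b != ref_b])
            rows.append({"chrom": "c1", "position": int(pos),
                         "ref_base": ref_b, "sub_base": sub_b})
        table = pd.DataFrame(rows)
        out, n = substitute_reference({"c1": seq}, table)
        hamming = sum(a != b for a, b in zip(seq, str(out[0].seq)))
        assert hamming == n == 25
        assert len(out[0].seq) == len(seq)


class TestSnpIndex:
    def test_direct_ratios(self):
        df = pd.DataFrame({"chrom": "c1", "position": [1, 2, 3],
                           "ref_count": [0, 10, 3], "alt_count": [20, 10, 7]})
        out = compute_snp_index(df)
        assert list(out["snp_index"]) == pytest.approx([1.0, 0.5, 0.7])

    def test_zero_depth_is_undefined_not_zero(self):
        df = pd.DataFrame({"chrom": "c1", "position": [1],
                           "ref_count": [0], "alt_count": [0]})
        out = compute_snp_index(df)
        assert np.isnan(out.loc[0, "snp_index"])
        assert len(out) == 1  # reported, not dropped

    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"chrom": "c1", "position": [1],
                           "ref_count": [-1], "alt_count": [5]})
        with pytest.raises(ValueError):
            compute_snp_index(df)


class TestExtractHomozygous:
    def test_strict_threshold_edges(self):
        df = pd.DataFrame({
            "chrom": "c1", "position": [1, 2, 3],
            "ref_count": [0, 0, 2], "alt_count": [6, 5, 18],
        })
        # depth 6 / index 1.0 kept; depth 5 discarded; index 0.90 discarded
        out = extract_homozygous(compute_snp_index(df))
        assert list(out["position"]) == [1]

    def test_matches_brute_force_scan(self):
        table, _ = make_allele_counts(VariantSimParams(seed=13))
        indexed = compute_snp_index(table)
        fast = extract_homozygous(indexed)
        brute = {
            (r.chrom, r.position)
            for r in indexed.itertuples()
            if (r.ref_count + r.alt_count) > 5
            and r.alt_count / (r.ref_count + r.alt_count) > 0.9
        }
        assert set(zip(fast["chrom"], fast["position"])) == brute

    def test_heterozygous_pass_rate_matches_binomial_tail(self):
        table, genotypes = make_allele_counts(
            VariantSimParams(n_sites=20_000, seed=5))
        indexed = compute_snp_index(table)
        het = indexed[genotypes == "het"]
        deep = het[het["depth"] > 5]
        observed = (deep["snp_index"] > 0.9).sum()
        # exact binomial tail P(X > 0.9 d) at each observed depth
        expected = sum(binom.sf(int(np.floor(0.9 * d)), int(d), 0.5)
                       for d in deep["depth"])
        sd = np.sqrt(max(expected, 1.0))
        assert abs(observed - expected) <= 5 * sd + 1

    def test_error_free_deep_sites_classify_exactly(self):
        table, genotypes = make_allele_counts(VariantSimParams(
            n_sites=2000, error_rate=0.0, mean_depth=40,
            depth_dispersion=200.0, seed=3))
        indexed = compute_snp_index(table)
        deep = indexed["depth"] >= 10
        kept = extract_homozygous(indexed[deep])
        kept_pos = set(kept["position"])
        hom_pos = set(indexed.loc[deep & (genotypes == "hom"), "position"])
        absent_pos = set(indexed.loc[deep & (genotypes == "absent"), "position"])
        assert hom_pos <= kept_pos
        assert not (absent_pos & kept_pos)


class TestCountsIO:
    def test_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame({"chrom": ["c1", "c2"], "position": [5, 9],
                           "ref_count": [3, 0], "alt_count": [7, 12]})
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t", index=False)
        assert read_allele_counts_tsv(path).equals(df)
        headerless = tmp_path / "plain.tsv"
        df.to_csv(headerless, sep="\t", index=False, header=False)
        assert read_allele_counts_tsv(headerless).equals(df)

    def test_vcf_ad_fields(self, tmp_path):
        vcf = tmp_path / "sites.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Depths">\n'
            "##contig=<ID=c1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "c1\t10\t.\tA\tG\t.\t.\t.\tAD\t3,17\n"
            "c1\t20\t.\tC\tT,G\t.\t.\t.\tAD\t1,2,3\n"  # multiallelic: skipped
            "c1\t30\t.\tG\tA\t.\t.\t.\tAD\t8,2\n"
        )
        df = read_allele_counts_vcf(vcf)
        assert list(df["position"]) == [10, 30]
        assert list(df["alt_count"]) == [17, 2]
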