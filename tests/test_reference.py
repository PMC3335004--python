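"""Promoter reference: census enumeration, partitioning, bisulfite chemistry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methylmarker.reference import (
    CpGCensus,
    ReferenceRegion,
    Region,
    Strand,
    bisulfite_read_antisense,
    bisulfite_read_sense,
    census_table,
    enumerate_cpg_sites,
    full_state,
    non_cpg_conversion_rate,
    partition_sites,
    read_census_tsv,
    read_region,
    synthetic_promoter,
    write_census_tsv,
)


def region_of(seq, start=1, tss=None, name="toy"):
    return ReferenceRegion(name, seq, start, tss if tss is not None else start + len(seq))


class TestReadRegion:
    def test_reads_single_record_and_upcases(self, tmp_path):
        p = tmp_path / "toy.fa"
        p.write_text(">toy\nacGT\n")
        reg = read_region(p, start_offset=1, tss_position=3)
        assert len(reg) == 4
        assert reg.sequence == "ACGT"
        assert reg.end_offset == 4

    def test_rejects_invalid_base_naming_position(self, tmp_path):
        p = tmp_path / "toy.fa"
        p.write_text(">toy\nacgn\n")
        with pytest.raises(ValueError, match="position 4"):
            read_region(p, 1, 3)

    def test_rejects_multi_record_fasta(self, tmp_path):
        p = tmp_path / "two.fa"
        p.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(ValueError, match="exactly one"):
            read_region(p, 1, 3)

    def test_tss_outside_window_rejected(self):
        with pytest.raises(ValueError, match="tss_position"):
            ReferenceRegion("toy", "ACGT", 1, 10)


class TestEnumerateAndPartition:
    def test_scan_and_upstream_numbering(self):
        # TSS after the last base: both CpGs are upstream, numbered -2, -1.
        reg = region_of("TACGACGG", tss=9)
        sites = enumerate_cpg_sites(reg)
        assert [(s.site_number, s.c_position) for s in sites] == [(-2, 3), (-1, 6)]

    def test_numbering_skips_zero_across_tss(self):
        # 3 CpGs before the TSS, 2 at/after it.
        reg = region_of("ACGTCGTCGTACGTCG", tss=11)
        sites = enumerate_cpg_sites(reg)
        assert [s.site_number for s in sites] == [-3, -2, -1, 1, 2]

    def test_cpg_at_tss_gets_plus_one(self):
        reg = region_of("AACGTT", tss=3)
        (site,) = enumerate_cpg_sites(reg)
        assert site.site_number == 1

    def test_partition_threshold_rule(self):
        # Sites at TSS-60 and TSS-10 with boundary at -48: one per block.
        seq = ["A"] * 100
        seq[40 - 1 : 40 + 1] = "CG"  # tss 100 -> offset -60
        seq[90 - 1 : 90 + 1] = "CG"  # offset -10
        reg = region_of("".join(seq), tss=100)
        sites = enumerate_cpg_sites(reg)
        part = partition_sites(sites, reg, boundary_nt=-48)
        assert part.five_prime_sites == (-2,)
        assert part.three_prime_sites == (-1,)

    def test_boundary_at_five_prime_edge_puts_all_three_prime(self):
        reg = region_of("TACGACGG", tss=8)
        sites = enumerate_cpg_sites(reg)
        part = partition_sites(sites, reg, boundary_nt=-7)  # coordinate 1 = 5' edge
        assert part.five_prime_sites == ()
        assert len(part.three_prime_sites) == 2

    def test_boundary_outside_region_rejected(self):
        reg = region_of("TACGACGG", tss=8)
        sites = enumerate_cpg_sites(reg)
        with pytest.raises(ValueError, match="outside region"):
            partition_sites(sites, reg, boundary_nt=-100)

    @given(
        st.text(alphabet="ACGT", min_size=2, max_size=120),
        st.integers(min_value=0, max_value=120),
    )
    def test_numbering_properties(self, seq, tss_delta):
        """No zero; consecutive ordinals differ by 1 except across -1/+1."""
        tss = min(1 + tss_delta, len(seq) + 1)
        reg = ReferenceRegion("h", seq, 1, tss)
        numbers = [s.site_number for s in enumerate_cpg_sites(reg)]
        assert 0 not in numbers
        for a, b in zip(numbers, numbers[1:]):
            assert b - a == 1 or (a, b) == (-1, 1)
        neg = [n for n in numbers if n < 0]
        if neg:
            assert neg[-1] == -1
        pos = [n for n in numbers if n > 0]
        if pos:
            assert pos[0] == 1

    @given(st.text(alphabet="ACGT", min_size=2, max_size=120))
    def test_partition_is_bijection_onto_census(self, seq):
        tss = len(seq) + 1
        reg = ReferenceRegion("h", seq, 1, tss)
        sites = enumerate_cpg_sites(reg)
        part = partition_sites(sites, reg, boundary_nt=-1)
        both = set(part.five_prime_sites) | set(part.three_prime_sites)
        assert both == {s.site_number for s in sites}
        assert not (set(part.five_prime_sites) & set(part.three_prime_sites))
        assert len(part.five_prime_sites) + len(part.three_prime_sites) == len(sites)


class TestBisulfiteConversion:
    def test_sense_rule_application(self):
        reg = region_of("ACGTCCGA")
        state = {-2: (True, True), -1: (False, False)}
        assert bisulfite_read_sense(reg, state) == "ACGTTTGA"

    def test_sense_all_methylated_converts_only_non_cpg(self):
        reg = region_of("ACGTCCGA")
        sites = enumerate_cpg_sites(reg)
        assert bisulfite_read_sense(reg, full_state(sites, True, True)) == "ACGTTCGA"

    def test_full_conversion_leaves_no_cytosine(self):
        reg = region_of("ACGTCCGA")
        sites = enumerate_cpg_sites(reg)
        read = bisulfite_read_sense(reg, full_state(sites, False, False))
        assert read == "ATGTTTGA"
        assert "C" not in read

    def test_missing_site_state_rejected(self):
        reg = region_of("ACGTCCGA")
        with pytest.raises(ValueError, match="missing census sites"):
            bisulfite_read_sense(reg, {-2: (True, True)})

    def test_antisense_unmethylated_converts(self):
        reg = region_of("ACGA")  # antisense 5'->3' is TCGT
        assert bisulfite_read_antisense(reg, {-1: (False, False)}) == "TTGT"

    def test_antisense_methylated_protected(self):
        reg = region_of("ACGA")
        assert bisulfite_read_antisense(reg, {-1: (False, True)}) == "TCGT"

    def test_symmetric_methylation_retains_cpg_c_on_both_strands(self):
        reg = region_of("TACGATTCGA")
        sites = enumerate_cpg_sites(reg)
        state = full_state(sites, True, True)
        sense_read = bisulfite_read_sense(reg, state)
        anti_read = bisulfite_read_antisense(reg, state)
        L = len(reg)
        for s in sites:
            i = reg.index(s.c_position)
            assert sense_read[i] == "C"
            assert anti_read[L - 2 - i] == "C"

    @given(st.text(alphabet="ACGT", min_size=1, max_size=80))
    def test_full_conversion_invariant(self, seq):
        """Efficiency 1.0 + all-unmethylated leaves zero C on either strand."""
        reg = ReferenceRegion("h", seq, 1, len(seq) + 1)
        state = full_state(enumerate_cpg_sites(reg), False, False)
        assert "C" not in bisulfite_read_sense(reg, state)
        assert "C" not in bisulfite_read_antisense(reg, state)
        assert len(bisulfite_read_sense(reg, state)) == len(seq)


class TestConversionRate:
    def test_single_converted_non_cpg_c(self):
        reg = region_of("ACGTCCGA")
        assert non_cpg_conversion_rate(reg, "ACGTTCGA") == 1.0

    def test_partial_conversion_below_bound(self):
        # 10 non-CpG Cs, 9 converted -> 0.90.
        reg = region_of("CA" * 10, tss=21)
        read = "TA" * 9 + "CA"
        assert non_cpg_conversion_rate(reg, read) == pytest.approx(0.9)

    def test_length_mismatch_rejected(self):
        reg = region_of("ACGT")
        with pytest.raises(ValueError, match="length"):
            non_cpg_conversion_rate(reg, "ACG")

    def test_no_non_cpg_c_warns_and_passes(self):
        reg = region_of("ACGT")
        with pytest.warns(UserWarning, match="undefined"):
            assert non_cpg_conversion_rate(reg, "ATGT") == 1.0

    def test_stochastic_efficiency_recovered(self, rng):
        # 1000 non-CpG Cs converted at efficiency 0.9: binomial expectation.
        reg = region_of("CA" * 1000, tss=2001)
        read = bisulfite_read_sense(reg, {}, efficiency=0.9, rng=rng)
        assert non_cpg_conversion_rate(reg, read) == pytest.approx(0.90, abs=0.03)

    @given(st.text(alphabet="ACGT", min_size=4, max_size=60), st.integers(0, 2**16))
    def test_rate_matches_exhaustive_position_scan(self, seq, seed):
        reg = ReferenceRegion("h", seq, 1, len(seq) + 1)
        sites = enumerate_cpg_sites(reg)
        r = np.random.default_rng(seed)
        read = bisulfite_read_sense(
            reg, full_state(sites, False, False), efficiency=0.7, rng=r
        )
        cpg_idx = {reg.index(s.c_position) for s in sites}
        denom = sum(
            1 for i, ch in enumerate(seq.upper()) if ch == "C" and i not in cpg_idx
        )
        num = sum(
            1
            for i, ch in enumerate(seq.upper())
            if ch == "C" and i not in cpg_idx and read[i] == "T"
        )
        if denom:
            assert non_cpg_conversion_rate(reg, read) == pytest.approx(num / denom)


class TestSyntheticPromoterAndCensusIO:
    def test_core_census_geometry(self):
        reg = synthetic_promoter(include_extension=False)
        assert len(reg) == 389
        c = CpGCensus.from_region(reg)
        assert c.n_sites == 32
        assert c.site_numbers[0] == -28 and c.site_numbers[-1] == 4
        assert len(c.region_site_numbers(Region.FIVE_PRIME)) == 21
        assert len(c.region_site_numbers(Region.THREE_PRIME)) == 11

    def test_extension_adds_reverse_primer_sites(self, census):
        assert census.n_sites == 35
        assert census.site_numbers[-3:] == (5, 6, 7)
        assert all(
            census.sites[census.index_of(n)].region == Region.THREE_PRIME
            for n in (5, 6, 7)
        )

    def test_deterministic_and_qc_usable(self, promoter):
        assert promoter.sequence == synthetic_promoter().sequence
        # Both strands must carry non-CpG Cs for the conversion QC statistic.
        for strand in Strand:
            seq = (
                promoter.sequence
                if strand == Strand.SENSE
                else promoter.antisense_sequence
            )
            assert seq.count("C") > 35

    def test_census_roundtrip_tsv(self, census, tmp_path):
        path = tmp_path / "census.tsv"
        write_census_tsv(census, path)
        back = read_census_tsv(path)
        assert back == census
        df = census_table(census)
        assert list(df.columns) == ["site_number", "c_position", "tss_offset", "region"]
        assert (df["tss_offset"] == df["c_position"] - census.tss_position).all()
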