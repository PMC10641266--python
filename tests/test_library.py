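"""Library enumeration, diversity accounting and mutagenic oligo design."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from cysscan import (STRANDS, VH_TEMPLATE, CodingSequence, apply_oligos,
                     build_manifest, design_oligos, enumerate_pairs,
                     expected_copies, theoretical_diversity)
from cysscan.library import LibrarySizeRecord, StrandPairLibrary

# The published 17-library slate: name -> (category, theoretical diversity,
# functional library size).
PUBLISHED_TABLE = {
    "A-F": ("inter", 112, 5.1e3),
    "A-G": ("inter", 154, 4.5e3),
    "B-C": ("inter", 88, 6.3e3),
    "B-F": ("inter", 88, 1.9e4),
    "C-D": ("inter", 80, 1.8e4),
    "C-E": ("inter", 96, 8.3e3),
    "C'-D": ("inter", 90, 3.2e3),
    "C'-E": ("inter", 108, 9.5e3),
    "C''-D": ("inter", 80, 3.9e3),
    "E-F": ("inter", 96, 8.5e3),
    "A-B": ("intra", 154, 1.9e4),
    "B-E": ("intra", 132, 1.8e4),
    "C-C'": ("intra", 72, 1.9e4),
    "C-F": ("intra", 64, 4.6e3),
    "C'-C''": ("intra", 72, 6.4e3),
    "D-E": ("intra", 120, 1.6e4),
    "F-G": ("intra", 88, 8.3e3),
}


class TestDiversity:
    @pytest.mark.parametrize("s1,s2,expected", [
        ("A", "F", 112), ("C", "C'", 72), ("A", "G", 154),
        ("C'", "D", 90), ("B", "E", 132), ("C", "F", 64),
    ])
    def test_printed_values(self, s1, s2, expected):
        assert theoretical_diversity(s1, s2) == expected

    def test_toy_strands(self):
        from cysscan.imgt import StrandDef
        a = StrandDef("A", (1, 2), "ABED")
        b = StrandDef("B", (16, 17, 18), "ABED")
        assert theoretical_diversity(a, b) == 6

    def test_identical_strands_rejected(self):
        with pytest.raises(ValueError):
            theoretical_diversity("A", "A")

    def test_all_17_reproduced_from_strand_table_alone(self, manifest):
        assert len(manifest) == len(PUBLISHED_TABLE) == 17
        for lib in manifest.libraries:
            category, diversity, size = PUBLISHED_TABLE[lib.name]
            assert lib.theoretical_diversity == diversity, lib.name
            assert lib.category == category, lib.name
            assert lib.library_size == size, lib.name


class TestEnumeratePairs:
    def test_cprime_d_bounds(self):
        pairs = enumerate_pairs("C'", "D")
        assert len(pairs) == 90
        assert pairs[0] == (47, 75) and pairs[-1] == (55, 84)

    def test_a_g_contains_the_enriched_inter_pairs(self):
        pairs = set(enumerate_pairs("A", "G"))
        assert len(pairs) == 154
        assert {(4, 118), (5, 120), (6, 119)} <= pairs

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(names=st.tuples(st.sampled_from(sorted(STRANDS)),
                           st.sampled_from(sorted(STRANDS))))
    def test_swap_gives_the_transpose_and_length_matches_diversity(self, names):
        s1, s2 = names
        if s1 == s2:
            return
        fwd = enumerate_pairs(s1, s2)
        rev = enumerate_pairs(s2, s1)
        assert len(fwd) == theoretical_diversity(s1, s2)
        assert sorted((b, a) for a, b in fwd) == sorted(rev)
        assert len(set(fwd)) == len(fwd)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(data=st.data())
    def test_random_strand_subsets(self, data):
        """Cartesian enumeration on arbitrary sub-strands."""
        from cysscan.imgt import StrandDef
        p1 = data.draw(st.sets(st.sampled_from(STRANDS["A"].positions),
                               min_size=1))
        p2 = data.draw(st.sets(st.sampled_from(STRANDS["G"].positions),
                               min_size=1))
        a = StrandDef("A", tuple(sorted(p1)), "ABED")
        g = StrandDef("G", tuple(sorted(p2)), "CC'C''FG")
        pairs = enumerate_pairs(a, g)
        assert len(pairs) == len(p1) * len(p2)
        assert set(pairs) == set(itertools.product(sorted(p1), sorted(p2)))


class TestManifest:
    def test_study_slate_counts(self, manifest):
        assert manifest.count_by_category() == {"intra": 7, "inter": 10}
        assert manifest.total_reactions == sum(
            d for _, d, _ in PUBLISHED_TABLE.values())

    def test_empty_config(self):
        assert len(build_manifest([])) == 0

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError):
            build_manifest([("A", "Z")])

    def test_known_pair_flagging(self, manifest):
        flagged = {lib.name for lib in manifest.libraries
                   if lib.contains_known_pair()}
        assert flagged == {"B-F", "C-C'", "C'-D"}


class TestExpectedCopies:
    def test_division(self):
        assert expected_copies(5100, 112) == pytest.approx(45.5357, abs=1e-3)
        assert expected_copies(0, 5) == 0

    def test_zero_diversity_rejected(self):
        with pytest.raises(ValueError):
            expected_copies(1000, 0)

    def test_each_pair_expected_multiple_times_in_all_17(self, manifest):
        copies = [lib.expected_copies() for lib in manifest.libraries]
        assert min(copies) > 1

    def test_library_size_record(self):
        rec = LibrarySizeRecord(cfu=10_000, fraction_correct=0.7)
        assert rec.functional_size == pytest.approx(7000)
        assert rec.functional_size <= rec.cfu
        with pytest.raises(ValueError):
            LibrarySizeRecord(cfu=100, fraction_correct=1.5)


@pytest.fixture(scope="module")
def parent_coding():
    codon = {aa: c for c, aa in standard_dna_table.forward_table.items()}
    dna = "".join(codon[a] for a in VH_TEMPLATE.raw)
    return CodingSequence(VH_TEMPLATE, dna)


class TestOligoDesign:
    def test_distant_pair_gets_two_oligos_and_exact_mutant(self, parent_coding):
        oligos = design_oligos(parent_coding, (54, 78))
        assert len(oligos) == 2
        mutant = apply_oligos(parent_coding, oligos)
        diffs = {p for p in VH_TEMPLATE.positions
                 if mutant.protein.mapping[p] != VH_TEMPLATE.mapping[p]}
        assert diffs == {54, 78}
        assert mutant.protein.mapping[54] == mutant.protein.mapping[78] == "C"

    def test_contiguous_pair_gets_one_oligo(self, parent_coding):
        oligos = design_oligos(parent_coding, (47, 55))
        assert len(oligos) == 1
        mutant = apply_oligos(parent_coding, oligos)
        diffs = {p for p in VH_TEMPLATE.positions
                 if mutant.protein.mapping[p] != VH_TEMPLATE.mapping[p]}
        assert diffs == {47, 55}

    @pytest.mark.parametrize("pair", [(4, 25), (6, 119), (40, 55), (22, 88)])
    def test_mutagenize_translate_roundtrip(self, parent_coding, pair):
        mutant = apply_oligos(parent_coding, design_oligos(parent_coding, pair))
        diffs = {p for p in VH_TEMPLATE.positions
                 if mutant.protein.mapping[p] != VH_TEMPLATE.mapping[p]}
        assert diffs == set(pair)
        assert all(mutant.protein.mapping[p] == "C" for p in pair)

    def test_flanks_match_parent(self, parent_coding):
        (oligo,) = design_oligos(parent_coding, (47, 55), flank_length=12)
        patch = oligo.coding_patch
        assert patch[:12] == parent_coding.dna[oligo.start:oligo.start + 12]
        assert patch[-12:] == parent_coding.dna[oligo.end - 12:oligo.end]

    def test_zero_flank_rejected(self, parent_coding):
        with pytest.raises(ValueError):
            design_oligos(parent_coding, (54, 78), flank_length=0)

    def test_gap_position_rejected(self, parent_coding):
        with pytest.raises(ValueError):
            design_oligos(parent_coding, (10, 78))

    def test_oligo_is_reverse_complement_of_its_patch(self, parent_coding):
        (oligo,) = design_oligos(parent_coding, (47, 55))
        assert str(Seq(oligo.dna).reverse_complement()) == oligo.coding_patch
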