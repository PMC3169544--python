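"""Alignment I/O, polymorphism extraction, and marker-table round trips."""

import numpy as np
import pytest

import dendropy
from hybridhallmarks import seqio
from hybridhallmarks.seqio import FormatError, Inheritance, Sex

from conftest import make_aflp, make_locus


def write_fasta(path, records):
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")


class TestFastaReading:
    def test_parses_records_and_metadata(self, tmp_path):
        p = tmp_path / "toy.fasta"
        write_fasta(p, [("s1|popA|F|0", "ACGTACGTAC"),
                        ("s2|popA|M|0", "ACGTACGTAC"),
                        ("s3|popB|M|1", "ACGTACGTAT")])
        locus = seqio.read_fasta_alignment(p, "z_linked")
        assert locus.n_sequences == 3
        assert locus.alignment_length == 10
        assert locus.records[0].population == "popA"
        assert locus.records[2].sex is Sex.MALE

    def test_gaps_preserved_verbatim(self, tmp_path):
        p = tmp_path / "gap.fasta"
        write_fasta(p, [("s1|p|F|0", "AC--GT"), ("s2|p|F|0", "ACGTGT")])
        locus = seqio.read_fasta_alignment(p, "autosomal")
        assert locus.records[0].seq == "AC--GT"

    def test_ragged_alignment_names_offender(self, tmp_path):
        p = tmp_path / "ragged.fasta"
        write_fasta(p, [("s1|p|F|0", "ACGTACGTAC"), ("s2|p|F|0", "ACGTACGTA")])
        with pytest.raises(FormatError, match="s2"):
            seqio.read_fasta_alignment(p, "autosomal")

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FormatError, match="empty"):
            seqio.read_fasta_alignment(p, "autosomal")

    def test_mitochondrial_requires_one_sequence_per_sample(self):
        with pytest.raises(FormatError, match="mitochondrial"):
            make_locus(["ACGT", "ACGT"], inheritance=Inheritance.MITOCHONDRIAL,
                       samples=["s1", "s1"])


class TestHeterozygousMaleExpansion:
    def _z_locus(self, n_samples, sexes=None):
        seqs = ["ACGTACGT"] * n_samples
        sexes = sexes or [Sex.MALE if i % 2 else Sex.FEMALE for i in range(n_samples)]
        return make_locus(seqs, inheritance=Inheritance.Z_LINKED, sexes=sexes)

    @pytest.mark.parametrize("n_samples,n_het,expected", [(20, 2, 22), (18, 1, 19)])
    def test_sequence_count_grows_by_heterozygote_count(self, n_samples, n_het, expected):
        # published per-gene counts like 20 samples -> 22 sequences arise this way
        locus = self._z_locus(n_samples)
        males = [r.sample_id for r in locus.records if r.sex is Sex.MALE][:n_het]
        pairs = {m: ("ACGTACGT", "ACGAACGT") for m in males}
        out = seqio.expand_heterozygous_males(locus, pairs)
        assert out.n_sequences == expected

    def test_no_heterozygotes_is_identity(self):
        locus = self._z_locus(6)
        out = seqio.expand_heterozygous_males(locus, {})
        assert [r.seq for r in out.records] == [r.seq for r in locus.records]

    def test_phased_pair_for_female_rejected(self):
        locus = self._z_locus(4, sexes=[Sex.FEMALE] * 4)
        with pytest.raises(ValueError, match="female"):
            seqio.expand_heterozygous_males(locus, {"s0": ("ACGTACGT", "ACGTACGT")})

    def test_wrong_inheritance_rejected(self):
        locus = make_locus(["ACGT"], inheritance=Inheritance.MITOCHONDRIAL)
        with pytest.raises(ValueError):
            seqio.expand_heterozygous_males(locus, {})


def brute_force_site_count(seqs):
    """Independent column scanner: SNP columns plus maximal identical-gap runs."""
    L = len(seqs[0])
    n_snp = 0
    for j in range(L):
        col = [s[j] for s in seqs]
        obs = {c for c in col if c not in "-N"}
        if len(obs) >= 2:
            n_snp += 1
    runs = 0
    prev = None
    for j in range(L):
        pat = tuple(s[j] == "-" for s in seqs)
        nontrivial = any(pat) and not all(pat)
        if nontrivial and pat != prev:
            runs += 1
        prev = pat if nontrivial else None
    return n_snp + runs


class TestExtractPolymorphisms:
    def test_identical_sequences_empty_table(self):
        locus = make_locus(["ACGTACGT"] * 4)
        assert seqio.extract_polymorphisms(locus).n_sites == 0

    def test_snp_plus_multibase_indel(self):
        # one SNP column and one 3-bp deletion shared by two sequences
        locus = make_locus(["ACGTTTACGT", "ACG---ACGT", "ACG---ACGT", "ACGTTTACTT"])
        table = seqio.extract_polymorphisms(locus)
        kinds = sorted(s.kind for s in table.sites)
        assert kinds == ["indel", "snp"]
        indel = next(s for s in table.sites if s.kind == "indel")
        assert (indel.start, indel.end) == (3, 6)

    def test_adjacent_gap_columns_one_event(self):
        locus = make_locus(["AC--GT", "ACTAGT", "ACTAGT"])
        table = seqio.extract_polymorphisms(locus)
        assert [s.kind for s in table.sites] == ["indel"]

    def test_distinct_gap_patterns_are_distinct_events(self):
        # the two gap columns belong to different sequences -> two indel sites
        locus = make_locus(["AC-TGT", "ACT-GT", "ACTAGT"])
        table = seqio.extract_polymorphisms(locus)
        assert sum(s.kind == "indel" for s in table.sites) == 2

    def test_site_count_matches_brute_force_on_random_alignments(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 7))
            L = int(rng.integers(4, 16))
            seqs = [
                "".join(rng.choice(list("ACGT-N"), size=L, p=[0.25, 0.25, 0.2, 0.1, 0.1, 0.1]))
                for _ in range(n)
            ]
            # avoid all-gap columns, which are alignment artifacts
            seqs = [
                "".join("A" if all(s[j] == "-" for s in seqs) else s[j] for j in range(L))
                for s in seqs
            ]
            locus = make_locus(seqs)
            assert seqio.extract_polymorphisms(locus).n_sites == brute_force_site_count(seqs)

    def test_missing_coded_missing_at_snp_sites(self):
        locus = make_locus(["ACGT", "ANGT", "TCGT"])
        table = seqio.extract_polymorphisms(locus)
        snp = next(s for s in table.sites if s.start == 0)
        col = table.calls[snp.site_id]
        assert col.isna().sum() == 0
        assert table.calls.shape[0] == 3


class TestTableRoundTrips:
    def test_aflp_round_trip(self, tmp_path):
        aflp = make_aflp([[0, 1, 1, 0], [1, 0, 1, 0], [0, 0, 1, 1]])
        p = tmp_path / "aflp.tsv"
        seqio.write_aflp_matrix(aflp, p)
        back = seqio.read_aflp_matrix(p)
        assert back.shape == (3, 4)
        assert np.array_equal(back.bands.to_numpy(), aflp.bands.to_numpy())

    def test_population_map_round_trip_and_duplicates(self, tmp_path, two_pop_map):
        p = tmp_path / "map.tsv"
        seqio.write_population_map(two_pop_map, p)
        back = seqio.read_population_map(p)
        assert back.population("a3") == "popA"
        p.write_text("sample_id\tpopulation\tsex\nx\tp\tU\nx\tp\tU\n")
        with pytest.raises(FormatError, match="duplicate"):
            seqio.read_population_map(p)

    def test_unknown_sample_raises_cross_reference_error(self, two_pop_map):
        with pytest.raises(KeyError, match="absent"):
            two_pop_map.groups_for(["a1", "zz"])

    def test_newick_round_trip(self, tmp_path):
        nwk = "((A:1.5,B:2.25):0.5,(C:3.125,D:1.0):0.75,E:2.0);"
        t = dendropy.Tree.get(data=nwk, schema="newick")
        p = tmp_path / "t.nwk"
        seqio.write_newick(t, p)
        back = seqio.read_newick(p)
        d1 = {leaf.taxon.label: leaf.distance_from_root() for leaf in t.leaf_node_iter()}
        d2 = {leaf.taxon.label: leaf.distance_from_root() for leaf in back.leaf_node_iter()}
        assert set(d1) == set(d2)
        for k in d1:
            assert abs(d1[k] - d2[k]) < 1e-9

    def test_polymorphic_filter_drops_fixed_markers(self):
        aflp = make_aflp([[1, 1, 0], [1, 0, 0], [1, 1, 0]])
        assert aflp.polymorphic().markers == ["m1"]
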