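"""Tryptic digestion and peptide-uniqueness classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from _oracles import brute_force_digest
from lepscan.digest import (
    DigestConfig,
    IndexMode,
    ProteinRecord,
    build_reference_index,
    classify_peptide,
    cleavage_fragments,
    digest_protein,
    lep_unique_peptide_count,
    read_proteome,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n, acc="P", origin="reference"):
    return ProteinRecord(acc, "".join(np.array(list(AA))[rng.integers(20, size=n)]), origin)


class TestDigest:
    def test_minimal_cleavage(self):
        peps = digest_protein(ProteinRecord("p", "MKR"), DigestConfig(0, 1, 50))
        assert [(p.sequence, p.missed_cleavages) for p in peps] == [("MK", 0), ("R", 0)]

    def test_no_cleavage_sites_gives_whole_protein(self):
        peps = digest_protein(ProteinRecord("p", "MAGIC"), DigestConfig(2, 1, 50))
        assert [p.sequence for p in peps] == ["MAGIC"]

    def test_proline_blocks_cleavage(self):
        peps = digest_protein(ProteinRecord("p", "AKPGGK" + "R"), DigestConfig(0, 1, 50))
        assert [p.sequence for p in peps] == ["AKPGGK", "R"]

    def test_length_window_applied(self):
        peps = digest_protein(ProteinRecord("p", "MKRAAAK"), DigestConfig(1, 3, 50))
        assert all(3 <= len(p.sequence) <= 50 for p in peps)
        assert {p.sequence for p in peps} == {"MKR", "RAAAK", "AAAK"}

    def test_matches_bruteforce_enumeration(self, rng):
        cfg = DigestConfig(max_missed_cleavages=2, min_len=1, max_len=1000)
        for _ in range(30):
            prot = random_protein(rng, int(rng.integers(5, 200)))
            got = {(p.sequence, p.missed_cleavages) for p in digest_protein(prot, cfg)}
            assert got == brute_force_digest(prot.sequence, 2, 1, 1000)

    @given(hst.text(alphabet=AA, min_size=1, max_size=120))
    def test_zero_missed_fragments_reconstruct_protein(self, seq):
        assert "".join(cleavage_fragments(seq)) == seq


class TestIndex:
    def make_db(self, rng, n=15):
        refs = [random_protein(rng, 80, f"R{i}") for i in range(n)]
        return refs, build_reference_index(refs, DigestConfig(2, 5, 60))

    def test_self_containment(self, rng):
        refs, index = self.make_db(rng)
        for pep in digest_protein(refs[0], DigestConfig(2, 5, 60)):
            assert "R0" in index.lookup(pep.sequence)

    def test_absent_peptide_gives_empty_set(self, rng):
        _, index = self.make_db(rng)
        assert index.lookup("WWWWWWWWWW") == set()

    def test_il_equivalence_collapses_variants(self, rng):
        refs, index = self.make_db(rng)
        target = next(
            p.sequence
            for p in digest_protein(refs[0], DigestConfig(2, 5, 60))
            if "I" in p.sequence or "L" in p.sequence
        )
        swapped = target.replace("I", "?").replace("L", "I").replace("?", "L")
        assert index.lookup(swapped) == index.lookup(target)

    def test_il_strict_mode_distinguishes(self, rng):
        refs, _ = self.make_db(rng)
        index = build_reference_index(refs, DigestConfig(2, 5, 60, il_equivalent=False))
        target = next(
            p.sequence
            for p in digest_protein(refs[0], DigestConfig(2, 5, 60))
            if ("I" in p.sequence) != ("L" in p.sequence)
        )
        swapped = target.replace("I", "?").replace("L", "I").replace("?", "L")
        assert index.lookup(target) and index.lookup(swapped) != index.lookup(target)

    def test_duplicate_accessions_rejected(self, rng):
        refs = [random_protein(rng, 50, "X"), random_protein(rng, 50, "X")]
        with pytest.raises(ValueError, match="duplicate"):
            build_reference_index(refs)

    def test_invalid_peptide_characters_rejected(self, rng):
        _, index = self.make_db(rng)
        with pytest.raises(ValueError, match="invalid peptide"):
            index.lookup("PEPT1DE")

    def test_substring_mode_catches_nontryptic_matches(self, rng):
        refs = [ProteinRecord("R0", "MAAAGHIKWQESTVDDDK")]
        cfg = DigestConfig(0, 5, 50)
        tryptic = build_reference_index(refs, cfg, IndexMode.TRYPTIC)
        substr = build_reference_index(refs, cfg, IndexMode.SUBSTRING)
        # an internal (non-tryptic) window of R0
        assert tryptic.lookup("AAGHIKW") == set()
        assert substr.lookup("AAGHIKW") == {"R0"}


class TestClassification:
    def build(self, rng):
        refs = [random_protein(rng, 100, f"R{i}") for i in range(10)]
        lep_novel = random_protein(rng, 60, "LEP1", "lep")
        # LEP2 is an exact copy of R0: every peptide must match the reference
        lep_copy = ProteinRecord("LEP2", refs[0].sequence, "lep")
        cfg = DigestConfig(2, 5, 60)
        index = build_reference_index(refs + [lep_novel, lep_copy], cfg)
        return refs, lep_novel, lep_copy, cfg, index

    def test_reference_peptide_classified_reference(self, rng):
        refs, _, _, cfg, index = self.build(rng)
        pep = digest_protein(refs[3], cfg)[0].sequence
        assert classify_peptide(pep, index).status == "reference"

    def test_novel_lep_peptides_unique(self, rng):
        _, lep_novel, _, cfg, index = self.build(rng)
        calls = [classify_peptide(p.sequence, index) for p in digest_protein(lep_novel, cfg)]
        assert calls and all(c.status == "unique_lep" for c in calls)
        assert lep_unique_peptide_count(lep_novel, calls) == len(calls)

    def test_lep_identical_to_reference_has_zero_unique(self, rng):
        _, _, lep_copy, cfg, index = self.build(rng)
        calls = [classify_peptide(p.sequence, index) for p in digest_protein(lep_copy, cfg)]
        assert all(c.status == "reference" for c in calls)
        assert lep_unique_peptide_count(lep_copy, calls) == 0

    def test_shared_lep_status(self, rng):
        twin_seq = random_protein(rng, 60).sequence
        leps = [ProteinRecord("L1", twin_seq, "lep"), ProteinRecord("L2", twin_seq, "lep")]
        ref = [random_protein(rng, 100, "R0")]
        cfg = DigestConfig(2, 5, 60)
        index = build_reference_index(ref + leps, cfg)
        calls = [classify_peptide(p.sequence, index) for p in digest_protein(leps[0], cfg)]
        assert calls and all(c.status == "shared_lep" for c in calls)

    def test_planted_partial_homolog_counts_match_construction(self, rng):
        """A LEP sharing a block of tryptic peptides with a reference
        homolog: shared peptides go to 'reference', the rest stay unique."""
        cfg = DigestConfig(0, 5, 60)
        shared_block = "AAAWESTK" + "CCCHHHDDK"  # two shared tryptic peptides
        lep = ProteinRecord("LEP1", shared_block + "MMMQQQFFK" + "GGGYYYVVK", "lep")
        homolog = ProteinRecord("R0", shared_block + "WWWWWNNNK", "reference")
        index = build_reference_index([homolog, lep], cfg)
        calls = [classify_peptide(p.sequence, index) for p in digest_protein(lep, cfg)]
        by_status = {s: sum(1 for c in calls if c.status == s) for s in
                     ("reference", "unique_lep")}
        assert by_status == {"reference": 2, "unique_lep": 2}
        assert lep_unique_peptide_count(lep, calls) == 2

    def test_unmatched_peptide_is_an_error(self, rng):
        _, _, _, _, index = self.build(rng)
        with pytest.raises(ValueError, match="matches no protein"):
            classify_peptide("WWWWWWWWWW", index)

    def test_il_equivalence_shrinks_or_preserves_unique_set(self, rng):
        """Collapsing I/L can only merge peptides into the reference, never
        create new unique ones."""
        for trial in range(10):
            refs = [random_protein(rng, 120, f"R{i}") for i in range(8)]
            lep = random_protein(rng, 70, "LEP1", "lep")
            unique = {}
            for il in (True, False):
                cfg = DigestConfig(2, 5, 60, il_equivalent=il)
                index = build_reference_index(refs + [lep], cfg)
                calls = [classify_peptide(p.sequence, index) for p in digest_protein(lep, cfg)]
                unique[il] = {c.peptide for c in calls if c.status == "unique_lep"}
            assert len(unique[True]) <= len(unique[False])


def test_read_proteome_parses_uniprot_headers(tmp_path):
    fasta = tmp_path / "ref.fasta"
    fasta.write_text(">sp|P12345|NAME_HUMAN some description\nMAGICK\n>PLAIN1\nMKRR\n")
    recs = read_proteome(fasta)
    assert [(r.accession, r.sequence) for r in recs] == [("P12345", "MAGICK"), ("PLAIN1", "MKRR")]
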