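"""QC, seed-and-extend aligner vs. full Smith-Waterman, best-hit rules, census."""

import math

import numpy as np
import pytest
from Bio import Align

from hybridcensus import (
    AlignmentParams,
    HitAssignment,
    Read,
    ReadSet,
    align_read,
    best_hit,
    census,
    quality_filter,
)
from hybridcensus.fragdb import Fragment, FragmentDatabase, build_index
from hybridcensus.hitcensus import Alignment, assign_reads
from hybridcensus.simdata import decode_seq, encode_seq, revcomp

Q40 = chr(33 + 40)
Q20 = chr(33 + 20)


def _read(seq, qual=None, rid="r0"):
    return Read(rid, seq, qual or Q40 * len(seq))


def _db(seqs_by_species, k=11):
    frags = []
    for sp, seqs in seqs_by_species.items():
        for i, s in enumerate(seqs):
            frags.append(Fragment(sp, f"{sp}|c|{i*100}", encode_seq(s)))
    db = FragmentDatabase(frags, len(frags[0].seq))
    return build_index(db, k=k)


def _sw_oracle():
    """Independent full-matrix local aligner (Biopython) on the same scheme.

    Gap of length g costs 5 + 2g, i.e. first gap base -7, each further -2.
    """
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -7
    a.extend_gap_score = -2
    return a


class TestQualityFilter:
    def test_clean_read_retained_unchanged(self):
        rs = ReadSet([_read("ACGT" * 25)])
        out = quality_filter(rs)
        assert len(out) == 1 and out.reads[0].seq == "ACGT" * 25

    def test_more_than_30_masked_bases_dropped(self):
        keep = _read("N" * 30 + "ACGT" * 20, rid="keep30")
        drop = _read("N" * 31 + "ACGT" * 20, rid="drop31")
        out = quality_filter(ReadSet([keep, drop]))
        assert [r.id for r in out] == ["keep30"]

    def test_trimmed_below_min_length_dropped(self):
        # 29 high-quality bases followed by a low-quality tail
        seq = "ACGTACGTACGTACGTACGTACGTACGTA" + "ACGT" * 10
        qual = Q40 * 29 + Q20 * 40
        out = quality_filter(ReadSet([_read(seq, qual)]))
        assert len(out) == 0
        # one more high-quality base and it survives at length 30
        qual2 = Q40 * 30 + Q20 * 39
        out2 = quality_filter(ReadSet([_read(seq, qual2)]))
        assert len(out2) == 1 and len(out2.reads[0].seq) == 30

    def test_malformed_record_raises_with_name(self):
        with pytest.raises(ValueError, match="badread"):
            quality_filter(ReadSet([Read("badread", "ACGT", Q40 * 3)]))


class TestAligner:
    def test_perfect_match_scores_read_length(self, rng):
        frag = decode_seq(rng.integers(0, 4, 100, dtype=np.uint8))
        db = _db({"a": [frag], "b": [decode_seq(rng.integers(0, 4, 100, dtype=np.uint8))]})
        hits = align_read(_read(frag), db)
        assert hits[0].score == 100
        assert hits[0].species == "a"
        assert hits[0].evalue == min(h.evalue for h in hits)

    def test_reverse_complement_scores_identically(self, rng):
        frag = decode_seq(rng.integers(0, 4, 100, dtype=np.uint8))
        db = _db({"a": [frag]})
        fwd = align_read(_read(frag), db)
        rev = align_read(_read(decode_seq(revcomp(encode_seq(frag)))), db)
        assert fwd[0].score == rev[0].score == 100
        assert {fwd[0].strand, rev[0].strand} == {"+", "-"}

    def test_two_mismatch_read_matches_dp_oracle(self, rng):
        frag = rng.integers(0, 4, 100, dtype=np.uint8)
        read = frag[20:80].copy()
        for pos in (10, 40):
            read[pos] = (read[pos] + 1) % 4
        db = _db({"a": [decode_seq(frag)]})
        hits = align_read(_read(decode_seq(read)), db)
        oracle = _sw_oracle().score(decode_seq(frag), decode_seq(read))
        assert hits[0].score == oracle == 60 - 3 * 2

    def test_read_shorter_than_seed_gets_no_hit(self, rng):
        frag = decode_seq(rng.integers(0, 4, 100, dtype=np.uint8))
        db = _db({"a": [frag]})
        assert align_read(_read(frag[:8]), db) == []
        assignments = assign_reads(ReadSet([_read(frag[:8])]), db)
        assert assignments[0].outcome == "no_hit"

    def test_evalue_monotone_decreasing_in_score(self):
        p = AlignmentParams()
        evs = [p.evalue(s, 100, 200_000) for s in range(20, 101)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_seed_and_extend_equals_full_sw_exhaustively(self, rng):
        """On a <=50-fragment database, the heuristic score equals full DP.

        Reads are fragment copies with 0-8 substitutions (long clean runs
        guarantee a shared 11-mer), some reverse-complemented, some
        straddling two fragments of the same source contig.
        """
        contig = rng.integers(0, 4, 2000, dtype=np.uint8)
        contig2 = rng.integers(0, 4, 500, dtype=np.uint8)
        frags = {"a": [], "b": []}
        for i in range(20):
            frags["a"].append(decode_seq(contig[i * 100 : i * 100 + 100]))
        for i in range(5):
            frags["b"].append(decode_seq(contig2[i * 100 : i * 100 + 100]))
        db = _db(frags)
        oracle = _sw_oracle()
        all_frag_strs = frags["a"] + frags["b"]
        reads = []
        for t in range(40):
            length = int(rng.integers(60, 151))
            n_mut = int(rng.integers(0, 5))  # <=4 keeps a clean 11-mer run
            if length <= 100:  # read within one fragment
                start = int(rng.integers(0, 20)) * 100 + int(
                    rng.integers(0, 100 - length + 1)
                )
            else:  # read straddles two fragments, fully covering the first
                start = int(rng.integers(0, 19)) * 100
            r = contig[start : start + length].copy()
            for pos in rng.choice(length, size=n_mut, replace=False):
                r[pos] = (r[pos] + int(rng.integers(1, 4))) % 4
            if t % 3 == 0:
                r = revcomp(r)
            reads.append(decode_seq(r))
        for i, rs in enumerate(reads):
            hits = align_read(_read(rs, rid=f"r{i}"), db)
            assert hits, f"read {i} found no hit"
            best_heuristic = max(h.score for h in hits)
            rc = decode_seq(revcomp(encode_seq(rs)))
            best_full = max(
                max(oracle.score(f, rs), oracle.score(f, rc))
                for f in all_frag_strs
            )
            assert best_heuristic == best_full, f"read {i}"


class TestBestHit:
    P = AlignmentParams()

    def _aln(self, sp, score, frag="f0"):
        return Alignment(
            "r0", sp, 0, f"{sp}|{frag}", score,
            self.P.bit_score(score), self.P.evalue(score, 100, 200_000), "+",
        )

    def test_single_best_species_assigned(self):
        out = best_hit([self._aln("a", 90), self._aln("b", 70)])
        assert out.outcome == "assigned" and out.species == "a"

    def test_cross_species_tie_discarded(self):
        out = best_hit([self._aln("a", 90), self._aln("b", 90)])
        assert out.outcome == "tie_discarded"
        assert out.tied_species == frozenset({"a", "b"})

    def test_same_species_tie_not_discarded(self):
        out = best_hit(
            [self._aln("a", 90, "f0"), self._aln("a", 90, "f1"), self._aln("b", 70)]
        )
        assert out.outcome == "assigned" and out.species == "a"

    def test_empty_alignments_no_hit(self):
        assert best_hit([]).outcome == "no_hit"


class TestCensus:
    def _assign(self, sp, rid):
        return HitAssignment(rid, "assigned", species=sp)

    def test_single_species_proportion_one(self):
        cen = census([self._assign("a", f"r{i}") for i in range(5)])
        assert cen.proportions["a"] == 1.0

    def test_conservation_of_queries(self):
        items = (
            [self._assign("a", f"r{i}") for i in range(3)]
            + [HitAssignment("t0", "tie_discarded")]
            + [HitAssignment("n0", "no_hit"), HitAssignment("n1", "no_hit")]
        )
        cen = census(items)
        assert cen.n_assigned + cen.n_tie_discarded + cen.n_no_hit == len(items)
        assert cen.n_assigned == 3 and cen.n_tie_discarded == 1 and cen.n_no_hit == 2
        assert sum(cen.proportions.values()) == pytest.approx(1.0)

    def test_order_invariance(self):
        items = [self._assign(sp, f"r{i}") for i, sp in enumerate("aabbbc")]
        assert census(items).to_dict() == census(items[::-1]).to_dict()

    def test_species_relabeling_equivariance(self):
        items = [self._assign(sp, f"r{i}") for i, sp in enumerate("aabbbc")]
        relabeled = [
            HitAssignment(a.read_id, a.outcome, species={"a": "x", "b": "y", "c": "z"}[a.species])
            for a in items
        ]
        p1 = census(items).proportions
        p2 = census(relabeled).proportions
        assert p1["a"] == p2["x"] and p1["b"] == p2["y"] and p1["c"] == p2["z"]
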