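"""Pair extraction: grouping, contact selection, filtering, deduplication."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hicqc.pairs import (
    AlignmentRecord,
    ContactPair,
    SamParseError,
    candidate_rank,
    classify_orientation,
    deduplicate,
    extract_pairs,
    filter_valid,
    group_alignments,
    iter_sam_records,
    pairs_to_frame,
    read_pairs_tsv,
    select_contact,
    write_pairs_tsv,
)

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n@SQ\tSN:chr5\tLN:100000\n"


def rec(read_id="r", mate=1, chrom="chr1", start=0, end=100, strand="+",
        mapq=60, supp=False):
    return AlignmentRecord(read_id, mate, chrom, start, end, strand, mapq, supp)


def brute_force_call(mapped):
    """Independent enumeration of all candidate pairs under the documented
    ranking: one-per-mate dominant, then trans, then greatest 5' distance,
    then primary count, then lexicographic canonical sides."""
    best = None
    for a, b in itertools.combinations(mapped, 2):
        sa = (a.chrom, a.five_prime, a.strand)
        sb = (b.chrom, b.five_prime, b.strand)
        c1, c2 = sorted([sa, sb])
        key = (
            a.mate == b.mate,
            sa[0] == sb[0],
            -(0 if sa[0] != sb[0] else abs(sa[1] - sb[1])),
            -((not a.is_supplementary) + (not b.is_supplementary)),
            c1,
            c2,
        )
        if best is None or key < best[0]:
            best = (key, (c1, c2))
    return best[1]


class TestGrouping:
    def test_groups_by_read_id(self, tmp_path):
        sam = tmp_path / "t.sam"
        sam.write_text(
            SAM_HEADER
            + "r1\t65\tchr1\t100\t60\t50M\t=\t500\t0\t*\t*\n"
            + "r1\t129\tchr1\t500\t60\t50M\t=\t100\t0\t*\t*\n"
            + "r1\t2113\tchr5\t900\t60\t20M30S\t=\t100\t0\t*\t*\n"
            + "r2\t65\tchr1\t700\t60\t50M\t=\t800\t0\t*\t*\n"
        )
        groups = group_alignments(iter_sam_records(str(sam)))
        assert set(groups) == {"r1", "r2"}
        assert len(groups["r1"]) == 3 and len(groups["r2"]) == 1

    def test_unmapped_records_retained_with_none_chrom(self, tmp_path):
        sam = tmp_path / "t.sam"
        sam.write_text(SAM_HEADER + "r1\t69\tchr1\t100\t0\t*\t=\t100\t0\t*\t*\n")
        groups = group_alignments(iter_sam_records(str(sam)))
        (only,) = groups["r1"]
        assert only.chrom is None and not only.is_mapped

    def test_malformed_sam_names_record(self, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text(SAM_HEADER + "r1\t65\tchr1\tnot_a_position\t60\t50M\t=\t1\t0\t*\t*\n")
        with pytest.raises(SamParseError, match="record #1"):
            list(iter_sam_records(str(sam)))


class TestSelectContact:
    def test_single_candidate_pair(self):
        group = [
            rec(mate=1, start=1000, end=1100, strand="+"),
            rec(mate=2, start=1100, end=1181, strand="-"),
        ]
        pair = select_contact("r", group)
        assert pair.side1 == ("chr1", 1000, "+")
        assert pair.side2 == ("chr1", 1180, "-")
        assert pair.separation == 180
        assert pair.orientation == "FR"

    def test_trans_supplementary_outranks_cis(self):
        # mate1 primary chr1:1000(+) with supplementary chr5:2000(+),
        # mate2 primary chr1:1150(-): the interchromosomal candidate wins
        # and the one-per-mate rule selects mate2's chr1 record
        group = [
            rec(mate=1, chrom="chr1", start=1000, end=1100, strand="+"),
            rec(mate=1, chrom="chr5", start=2000, end=2050, strand="+", supp=True),
            rec(mate=2, chrom="chr1", start=1051, end=1151, strand="-"),
        ]
        pair = select_contact("r", group)
        assert pair.side1 == ("chr1", 1150, "-")
        assert pair.side2 == ("chr5", 2000, "+")
        assert not pair.is_cis

    def test_degenerate_groups(self):
        unmapped = AlignmentRecord("r", 1, None, -1, -1, "+", 0, False)
        assert select_contact("r", [unmapped, unmapped]).status == "unmapped"
        assert select_contact("r", [unmapped, rec()]).status == "single_side"

    def test_input_order_invariance(self, rng):
        group = [
            rec(mate=1, start=100, end=200, strand="+"),
            rec(mate=1, chrom="chr5", start=5000, end=5100, strand="-", supp=True),
            rec(mate=2, start=4000, end=4100, strand="-"),
            rec(mate=2, start=180, end=260, strand="+", supp=True),
        ]
        calls = set()
        for _ in range(10):
            rng.shuffle(group)
            p = select_contact("r", list(group))
            calls.add((p.side1, p.side2))
        assert len(calls) == 1

    def test_matches_brute_force_on_random_groups(self, rng):
        chroms = ["chr1", "chr2", "chr3"]
        for _ in range(2000):
            n = rng.integers(2, 7)
            group = []
            for k in range(n):
                start = int(rng.integers(0, 10_000))
                group.append(
                    AlignmentRecord(
                        "r", int(rng.integers(1, 3)),
                        chroms[rng.integers(0, len(chroms))],
                        start, start + int(rng.integers(20, 150)),
                        "+-"[rng.integers(0, 2)], 60, bool(rng.integers(0, 2)),
                    )
                )
            pair = select_contact("r", group)
            assert (pair.side1, pair.side2) == brute_force_call(group)


class TestFilterValid:
    def test_mapq_rules(self):
        good = select_contact("r", [rec(mate=1), rec(mate=2, start=500, end=600)])
        assert filter_valid(good).status == "valid"
        low = select_contact(
            "r", [rec(mate=1, mapq=0), rec(mate=2, start=500, end=600)]
        )
        assert filter_valid(low).status == "low_mapq"
        m29 = select_contact(
            "r", [rec(mate=1, mapq=29), rec(mate=2, start=500, end=600)]
        )
        assert filter_valid(m29, min_mapq=30).status == "low_mapq"
        assert filter_valid(m29, min_mapq=29).status == "valid"


class TestDeduplicate:
    def p(self, pos1=100, strand1="+", pos2=500, strand2="-", rid="r"):
        return ContactPair(rid, ("chr1", pos1, strand1), ("chr1", pos2, strand2),
                           "valid", 60, 60)

    def test_identical_key_flagged(self):
        out = deduplicate([self.p(rid="a"), self.p(rid="b")])
        assert [q.status for q in out] == ["valid", "duplicate"]

    def test_strand_is_part_of_key(self):
        out = deduplicate([self.p(strand1="+"), self.p(strand1="-")])
        assert [q.status for q in out] == ["valid", "valid"]

    def test_distinct_keys_no_duplicates(self):
        out = deduplicate([self.p(pos1=i) for i in range(10)])
        assert all(q.status == "valid" for q in out)

    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)), max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_idempotent_and_count_preserving(self, keys):
        pairs = [
            ContactPair(f"r{i}", ("chr1", a, "+"), ("chr1", b + 10, "-"), "valid", 60, 60)
            for i, (a, b) in enumerate(keys)
        ]
        once = deduplicate(pairs)
        twice = deduplicate(once)
        assert [p.status for p in once] == [p.status for p in twice]
        kept = sum(p.status == "valid" for p in once)
        dup = sum(p.status == "duplicate" for p in once)
        assert kept + dup == len(pairs)
        assert kept == len({(*p.side1, *p.side2) for p in pairs})


class TestOrientation:
    def test_definitions(self):
        fr = ContactPair("r", ("chr1", 100, "+"), ("chr1", 500, "-"), "valid")
        rf = ContactPair("r", ("chr1", 100, "-"), ("chr1", 500, "+"), "valid")
        assert classify_orientation(fr) == "FR"
        assert classify_orientation(rf) == "RF"

    def test_trans_is_an_error(self):
        trans = ContactPair("r", ("chr1", 100, "+"), ("chr2", 500, "-"), "valid")
        with pytest.raises(ValueError, match="trans"):
            classify_orientation(trans)


class TestExtractPipeline:
    def test_stage_counts_non_increasing(self, sim_pairs):
        c = sim_pairs.attrs["stage_counts"]
        assert c["total"] >= c["mapped"] >= c["two_sided"] >= c["valid"] >= c["deduplicated"]

    def test_recovers_truth_for_separated_contacts(self, sim_library, sim_pairs):
        lib, _ = sim_library
        truth = lib.truth.set_index("pair_id")
        merged = sim_pairs.set_index("read_id").join(truth, rsuffix="_t")
        contacts = merged[(merged["class"] == "contact")
                          & (merged["separation"].fillna(-1) > 300)]
        exact = (
            (contacts["chrom1"] == contacts["chrom1_t"])
            & (contacts["pos1"] == contacts["pos1_t"])
            & (contacts["chrom2"] == contacts["chrom2_t"])
            & (contacts["pos2"] == contacts["pos2_t"])
        )
        assert exact.mean() >= 0.99

    def test_tsv_round_trip_is_one_based_on_disk(self, sim_pairs, tmp_path):
        path = tmp_path / "pairs.tsv"
        write_pairs_tsv(sim_pairs.head(100), str(path))
        on_disk = pd.read_csv(path, sep="\t")
        back = read_pairs_tsv(str(path))
        valid = sim_pairs.head(100)["status"] == "valid"
        assert (on_disk.loc[valid.to_numpy(), "pos1"].to_numpy()
                == sim_pairs.head(100).loc[valid, "pos1"].to_numpy() + 1).all()
        pd.testing.assert_frame_equal(back, sim_pairs.head(100).reset_index(drop=True))
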