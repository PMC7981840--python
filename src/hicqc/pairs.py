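"""Contact-pair extraction from paired-end SAM alignments.

DNase Hi-C reads frequently span the ligation junction, so one mate aligns
as a primary record plus one or more supplementary records.  A contact is
called per read pair by considering *all* mapped alignments of both mates
and keeping the most distal pair of coordinates: an interchromosomal
candidate outranks every intrachromosomal one, and among intrachromosomal
candidates the largest coordinate difference wins.  Pairs are then filtered
on mapping quality (both sides mapq >= min_mapq, default 1, i.e. mapq > 0)
and deduplicated on the alignment positions and strands of both sides.

Coordinates are 0-based internally; the reported position of a side is the
5' mapping coordinate of its alignment (leftmost base for ``+``, rightmost
for ``-``).  TSV output converts to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

import pandas as pd
import pysam


class SamParseError(ValueError):
    """Raised when a SAM record cannot be parsed, with its record number."""


# -- statuses ---------------------------------------------------------------
VALID = "valid"
LOW_MAPQ = "low_mapq"
UNMAPPED = "unmapped"
SINGLE_SIDE = "single_side"
DUPLICATE = "duplicate"

PAIRS_COLUMNS = [
    "read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
    "status", "orientation", "separation",
]


class AlignmentRecord(NamedTuple):
    """One mapped (or unmapped) segment of one mate."""

    read_id: str
    mate: int                    # 1 or 2
    chrom: str | None            # None when unmapped
    start: int                   # 0-based leftmost reference position
    end: int                     # 0-based exclusive reference end
    strand: str                  # '+' or '-'
    mapq: int
    is_supplementary: bool

    @property
    def is_mapped(self) -> bool:
        return self.chrom is not None

    @property
    def five_prime(self) -> int:
        """5' mapping coordinate: leftmost for '+', rightmost for '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def aligned_span(self) -> int:
        return self.end - self.start


@dataclass
class ContactPair:
    """A called two-sided contact (sides in canonical order)."""

    read_id: str
    side1: tuple[str, int, str] | None = None   # (chrom, pos, strand)
    side2: tuple[str, int, str] | None = None
    status: str = VALID
    mapq1: int = 0
    mapq2: int = 0

    @property
    def is_cis(self) -> bool:
        return (
            self.side1 is not None
            and self.side2 is not None
            and self.side1[0] == self.side2[0]
        )

    @property
    def separation(self) -> int | None:
        if not self.is_cis:
            return None
        return abs(self.side2[1] - self.side1[1])

    @property
    def orientation(self) -> str | None:
        if not self.is_cis:
            return None
        return classify_orientation(self)

    @property
    def dedup_key(self):
        return (*self.side1, *self.side2)


def classify_orientation(pair: ContactPair) -> str:
    """FR/RF/FF/RR on the position-sorted sides of a cis pair.

    FR = (+,-) is the inward orientation, RF = (-,+) outward.
    """
    if not pair.is_cis:
        raise ValueError(f"orientation undefined for trans pair {pair.read_id}")
    s1, s2 = pair.side1[2], pair.side2[2]
    return {"+": "F", "-": "R"}[s1] + {"+": "F", "-": "R"}[s2]


# ---------------------------------------------------------------------------
# SAM input
# ---------------------------------------------------------------------------

def iter_sam_records(path: str) -> Iterator[AlignmentRecord]:
    """Yield primary and supplementary AlignmentRecords from SAM/BAM.

    Secondary alignments (flag 0x100) are ignored; unmapped records are
    yielded with ``chrom=None`` so status accounting can see them.
    """
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        names = list(sam.references)
        i = 0
        try:
            for rec in sam.fetch(until_eof=True):
                i += 1
                flag = rec.flag
                if flag & 0x100:  # secondary
                    continue
                mate = 2 if flag & 0x80 else 1
                if flag & 0x4:  # unmapped
                    yield AlignmentRecord(rec.query_name, mate, None, -1, -1, "+", 0, False)
                    continue
                yield AlignmentRecord(
                    rec.query_name,
                    mate,
                    names[rec.reference_id],
                    rec.reference_start,
                    rec.reference_end,
                    "-" if flag & 0x10 else "+",
                    rec.mapping_quality,
                    bool(flag & 0x800),
                )
        except SamParseError:
            raise
        except Exception as exc:  # malformed line inside pysam iteration
            raise SamParseError(f"malformed SAM record #{i + 1} in {path}: {exc}") from exc


def group_alignments(records: Iterable[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    """Group all records (both mates, primary + supplementary) by read id."""
    groups: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        groups.setdefault(rec.read_id, []).append(rec)
    return groups


# ---------------------------------------------------------------------------
# contact selection
# ---------------------------------------------------------------------------

def _side(rec: AlignmentRecord) -> tuple[str, int, str]:
    return (rec.chrom, rec.five_prime, rec.strand)


def _canonical(a: tuple[str, int, str], b: tuple[str, int, str]):
    return (a, b) if (a[0], a[1], a[2]) <= (b[0], b[1], b[2]) else (b, a)


def candidate_rank(a: AlignmentRecord, b: AlignmentRecord):
    """Sort key of a candidate alignment pair; the minimum wins.

    Ranking: candidates joining one alignment from each mate dominate
    same-mate candidates; then interchromosomal first, then largest
    coordinate difference, then number of primary records, then the
    lexicographically smallest canonical side tuple.

    The one-per-mate preference must dominate the distance rule: a mate
    crossing the ligation junction aligns at the partner locus on the
    opposite strand of the partner mate, so letting a same-mate candidate
    win on raw distance systematically flips one side's strand outward and
    inflates the FR class of genuine contacts — breaking the 1:1:1:1
    orientation assumption the dangling-ends statistic relies on.  With
    cross-mate candidates dominant the contest is between strand pairs
    (s1, s2) and (-s1, -s2), which leaves FR+RF and FF+RR totals invariant.
    Same-mate candidates still allow a call when only one mate maps.
    """
    sa, sb = _side(a), _side(b)
    trans = sa[0] != sb[0]
    dist = 0 if trans else abs(sa[1] - sb[1])
    diff_mates = a.mate != b.mate
    n_primary = (not a.is_supplementary) + (not b.is_supplementary)
    c1, c2 = _canonical(sa, sb)
    return (not diff_mates, not trans, -dist, -n_primary, c1, c2)


def select_contact(read_id: str, group: Iterable[AlignmentRecord]) -> ContactPair:
    """Call the contact of one read pair from all its alignments.

    Searches for the greatest distance between the coordinates of all
    primary and supplementary alignments from both mates; trans candidates
    outrank all cis candidates.  Degenerate groups map to ``single_side``
    (one mapped alignment) or ``unmapped`` statuses.
    """
    mapped = [r for r in group if r.chrom is not None]
    if not mapped:
        return ContactPair(read_id, status=UNMAPPED)
    if len(mapped) == 1:
        return ContactPair(read_id, status=SINGLE_SIDE)
    if len(mapped) == 2:
        a, b = mapped
    else:
        # inline ranking (same ordering as candidate_rank, kept hot-path fast)
        sides = [
            (r.chrom, r.start if r.strand == "+" else r.end - 1, r.strand)
            for r in mapped
        ]
        best_key = None
        a = b = None
        for i in range(len(mapped)):
            ri, si = mapped[i], sides[i]
            for j in range(i + 1, len(mapped)):
                rj, sj = mapped[j], sides[j]
                trans = si[0] != sj[0]
                dist = 0 if trans else abs(si[1] - sj[1])
                c1, c2 = (si, sj) if si <= sj else (sj, si)
                key = (
                    ri.mate == rj.mate,
                    not trans,
                    -dist,
                    -((not ri.is_supplementary) + (not rj.is_supplementary)),
                    c1,
                    c2,
                )
                if best_key is None or key < best_key:
                    best_key, a, b = key, ri, rj
    s1, s2 = _canonical(_side(a), _side(b))
    if s1 == _side(a):
        m1, m2 = a.mapq, b.mapq
    else:
        m1, m2 = b.mapq, a.mapq
    return ContactPair(read_id, side1=s1, side2=s2, status=VALID, mapq1=m1, mapq2=m2)


def filter_valid(pair: ContactPair, min_mapq: int = 1) -> ContactPair:
    """Flag pairs whose selected alignments are not both uniquely mapped.

    ``min_mapq`` is inclusive: mapq >= min_mapq passes, so the default of 1
    implements the "mapq > 0" uniqueness rule.
    """
    if pair.status != VALID:
        return pair
    if pair.mapq1 < min_mapq or pair.mapq2 < min_mapq:
        return replace_status(pair, LOW_MAPQ)
    return pair


def replace_status(pair: ContactPair, status: str) -> ContactPair:
    out = ContactPair(pair.read_id, pair.side1, pair.side2, status, pair.mapq1, pair.mapq2)
    return out


def deduplicate(pairs: Iterable[ContactPair]) -> list[ContactPair]:
    """Flag PCR duplicates: pairs sharing both sides' positions and strands.

    The first occurrence in input order is kept; later occurrences get
    status ``duplicate``.  Non-valid pairs pass through untouched.
    """
    seen: set = set()
    out: list[ContactPair] = []
    for p in pairs:
        if p.status == VALID:
            key = p.dedup_key
            if key in seen:
                p = replace_status(p, DUPLICATE)
            else:
                seen.add(key)
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# pipeline + I/O
# ---------------------------------------------------------------------------

def extract_pairs(sam_path: str, min_mapq: int = 1) -> pd.DataFrame:
    """SAM -> pairs table: group, select, mapq-filter and deduplicate.

    Returns a DataFrame with :data:`PAIRS_COLUMNS` (0-based positions in
    memory) and stage counts in ``df.attrs['stage_counts']``.
    """
    groups = group_alignments(iter_sam_records(sam_path))
    pairs = [select_contact(rid, grp) for rid, grp in groups.items()]
    pairs = [filter_valid(p, min_mapq=min_mapq) for p in pairs]
    n_total = len(pairs)
    n_mapped = sum(p.status != UNMAPPED for p in pairs)
    n_two_sided = sum(p.status in (VALID, LOW_MAPQ) for p in pairs)
    n_valid = sum(p.status == VALID for p in pairs)
    pairs = deduplicate(pairs)
    n_dedup = sum(p.status == VALID for p in pairs)
    df = pairs_to_frame(pairs)
    df.attrs["stage_counts"] = {
        "total": n_total,
        "mapped": n_mapped,
        "two_sided": n_two_sided,
        "valid": n_valid,
        "deduplicated": n_dedup,
    }
    return df


_ORI = {("+", "+"): "FF", ("+", "-"): "FR", ("-", "+"): "RF", ("-", "-"): "RR"}


def pairs_to_frame(pairs: list[ContactPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        s1, s2 = p.side1, p.side2
        if s1 is None or s2 is None:
            rows.append((p.read_id, None, -1, ".", None, -1, ".", p.status, ".", -1))
        elif s1[0] == s2[0]:
            rows.append((p.read_id, s1[0], s1[1], s1[2], s2[0], s2[1], s2[2],
                         p.status, _ORI[s1[2], s2[2]], abs(s2[1] - s1[1])))
        else:
            rows.append((p.read_id, s1[0], s1[1], s1[2], s2[0], s2[1], s2[2],
                         p.status, "trans", -1))
    return pd.DataFrame(rows, columns=PAIRS_COLUMNS)


def write_pairs_tsv(df: pd.DataFrame, path: str) -> None:
    """Write the pairs table with 1-based positions."""
    out = df.copy()
    for col in ("pos1", "pos2"):
        out[col] = out[col].where(out[col] < 0, out[col] + 1)
    out.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str) -> pd.DataFrame:
    """Read a pairs TSV back to the in-memory (0-based) convention."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    for col in ("pos1", "pos2"):
        df[col] = df[col].where(df[col] < 0, df[col] - 1)
    return df
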