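"""Raw-read structure analysis for proximity-ligation libraries.

Adapter-marked Hi-C protocols leave the junction oligonucleotide — and,
when adapters self-ligate, concatemers of it — inside the sequenced reads.
This module provides the read-level primitives the QC stage builds on:

* ``match_noninternal`` — end-anchored partial adapter matching (the
  "non-internal" mode of read trimmers: at the 5' end only a suffix of the
  adapter may overhang into the read, symmetrically at the 3' end);
* ``trim_iterative`` — repeated rounds of end trimming that also enumerate
  adapter multimer variants, so concatemers are peeled off layer by layer;
* ``profile_patterns`` — a FastContext-style decomposition of each read into
  genomic and adapter segments, tabulating pattern abundances;
* ``mate_overlap_insert`` / ``merge_mates`` — overlap-based insert-size
  calling for read pairs whose insert is shorter than the summed read
  lengths; this implements the "insert < 300 bp" short-fragment selection
  used by the back-ligation estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import find_all, revcomp
from .adapters import AdapterSpec

GENOMIC_LABEL = "G"


# ---------------------------------------------------------------------------
# non-internal adapter matching
# ---------------------------------------------------------------------------

def _hamming_leq(a: str, b: str, limit: int) -> bool:
    if a == b:
        return True
    if limit <= 0:
        return False
    errors = 0
    for x, y in zip(a, b):
        if x != y:
            errors += 1
            if errors > limit:
                return False
    return True


def match_noninternal(seq: str, adapter: AdapterSpec, end: str = "5prime"):
    """Longest end-anchored partial adapter match, or ``None``.

    At the 5' end a *suffix* of the adapter is compared against the read
    prefix (the adapter body may overhang off the read start); at the 3' end
    a *prefix* of the adapter against the read suffix.  The longest match of
    length >= ``adapter.min_overlap`` within ``adapter.max_error_rate``
    wins.  Returns ``(start, end)`` span in read coordinates.
    """
    if end not in ("5prime", "3prime"):
        raise ValueError(f"end must be '5prime' or '3prime', got {end!r}")
    aseq = adapter.sequence
    n = len(seq)
    if n < adapter.min_overlap:
        return None
    for k in range(min(len(aseq), n), adapter.min_overlap - 1, -1):
        limit = int(adapter.max_error_rate * k)
        if end == "5prime":
            if _hamming_leq(aseq[len(aseq) - k:], seq[:k], limit):
                return (0, k)
        else:
            if _hamming_leq(aseq[:k], seq[n - k:], limit):
                return (n - k, n)
    return None


# ---------------------------------------------------------------------------
# iterative trimming with multimer enumeration
# ---------------------------------------------------------------------------

def multimer_variants(adapters: Sequence[AdapterSpec], max_copies: int = 3) -> list[AdapterSpec]:
    """All concatenations of 1..max_copies adapter copies (mixed allowed).

    Variants inherit min_overlap/max_error_rate from the first constituent.
    Longer concatemers than ``max_copies`` are removed across successive
    trimming iterations rather than enumerated.
    """
    variants: list[AdapterSpec] = []
    for k in range(1, max_copies + 1):
        for combo in product(adapters, repeat=k):
            variants.append(
                AdapterSpec(
                    "+".join(a.name for a in combo),
                    "".join(a.sequence for a in combo),
                    min_overlap=combo[0].min_overlap,
                    max_error_rate=combo[0].max_error_rate,
                )
            )
    return variants


@dataclass
class TrimEvent:
    iteration: int
    end: str
    variant: str
    removed: int


def trim_iterative(
    seq: str,
    adapters: Sequence[AdapterSpec],
    iterations: int = 5,
    min_length: int = 7,
    max_copies: int = 3,
) -> tuple[str | None, list[TrimEvent]]:
    """Trim adapters and their multimers from both read ends.

    Each iteration removes, per end, the longest non-internal match among
    all adapters and their multimer variants; iterations stop early at a
    fixpoint.  Reads shorter than ``min_length`` after trimming are
    discarded (``None``).
    """
    if not adapters:
        raise ValueError("at least one adapter required")
    variants = multimer_variants(adapters, max_copies=max_copies)
    log: list[TrimEvent] = []
    for it in range(1, iterations + 1):
        removed_any = False
        for end in ("5prime", "3prime"):
            best = None
            for var in variants:
                m = match_noninternal(seq, var, end)
                if m is not None and (best is None or m[1] - m[0] > best[0][1] - best[0][0]):
                    best = (m, var)
            if best is not None:
                (s, e), var = best
                seq = seq[e:] if end == "5prime" else seq[:s]
                log.append(TrimEvent(it, end, var.name, e - s))
                removed_any = True
        if not removed_any:
            break
    if len(seq) < min_length:
        return None, log
    return seq, log


# ---------------------------------------------------------------------------
# FastContext-style pattern profiling
# ---------------------------------------------------------------------------

def read_pattern(seq: str, adapters: Sequence[AdapterSpec], both_strands: bool = True) -> tuple[str, bool, int]:
    """Decompose one read into ordered genomic/adapter segments.

    Scans for exact full-length adapter occurrences (forward and, by
    default, reverse-complement — mate 2 reads the fragment in reverse);
    overlapping hits are resolved greedily left to right.  Returns
    ``(pattern, is_multimer, n_adapter_segments)`` where the pattern joins
    segment labels with '-', e.g. ``G-bridge7-G``.  Two adapter segments
    that abut with no genomic gap mark a multimer.
    """
    hits: list[tuple[int, int, str]] = []
    for ad in adapters:
        motifs = {ad.sequence}
        if both_strands:
            motifs.add(revcomp(ad.sequence))
        for m in motifs:
            for s in find_all(seq, m):
                hits.append((s, s + len(m), ad.name))
    hits.sort()
    chosen: list[tuple[int, int, str]] = []
    cursor = 0
    for s, e, name in hits:
        if s >= cursor:
            chosen.append((s, e, name))
            cursor = e
    labels: list[str] = []
    multimer = False
    pos = 0
    prev_end = None
    for s, e, name in chosen:
        if s > pos:
            labels.append(GENOMIC_LABEL)
        if prev_end is not None and s == prev_end and labels and labels[-1] != GENOMIC_LABEL:
            multimer = True
        labels.append(name)
        prev_end = e
        pos = e
    if pos < len(seq) or not labels:
        labels.append(GENOMIC_LABEL)
    # collapse adjacent genomic labels (can only arise from empty reads)
    return "-".join(labels), multimer, len(chosen)


def profile_patterns(
    reads: Iterable[str],
    adapters: Sequence[AdapterSpec],
    both_strands: bool = True,
) -> pd.DataFrame:
    """Tabulate read-structure patterns over a collection of read sequences.

    Returns a DataFrame with columns ``pattern, count, fraction,
    is_multimer`` sorted by count, plus ``df.attrs['n_reads']`` and
    ``df.attrs['frac_with_adapter']``.
    """
    counts: dict[str, int] = {}
    multimer_flag: dict[str, bool] = {}
    n_reads = 0
    n_with = 0
    for seq in reads:
        pat, multi, n_ad = read_pattern(seq, adapters, both_strands=both_strands)
        counts[pat] = counts.get(pat, 0) + 1
        multimer_flag[pat] = multi
        n_reads += 1
        if n_ad:
            n_with += 1
    df = pd.DataFrame(
        {
            "pattern": list(counts),
            "count": list(counts.values()),
            "is_multimer": [multimer_flag[p] for p in counts],
        }
    )
    if len(df):
        df["fraction"] = df["count"] / n_reads
        df = df.sort_values("count", ascending=False, ignore_index=True)
        df = df[["pattern", "count", "fraction", "is_multimer"]]
    else:
        df = pd.DataFrame(columns=["pattern", "count", "fraction", "is_multimer"])
    df.attrs["n_reads"] = n_reads
    df.attrs["frac_with_adapter"] = (n_with / n_reads) if n_reads else float("nan")
    return df


# ---------------------------------------------------------------------------
# mate-overlap insert calling
# ---------------------------------------------------------------------------

def _count_mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def merge_mates(
    read1: str,
    read2: str,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
):
    """Align reverse-complemented mate 2 against mate 1 and merge.

    Slides mate2' (reverse complement of mate 2) over mate 1 at every
    offset, including negative offsets (read-through past the fragment
    start), and keeps the largest overlap of length >= ``min_overlap``
    whose mismatch fraction is <= ``max_mismatch_rate``.  Returns
    ``(insert_length, merged_sequence)`` or ``None`` when no acceptable
    overlap exists.  For an error-free pair sequenced from a fragment
    shorter than the summed read lengths the insert equals the fragment
    length exactly.
    """
    r2c = revcomp(read2)
    n1, n2 = len(read1), len(r2c)
    if min(n1, n2) < min_overlap:
        return None
    # offset t = start of mate2' relative to mate1 start
    best = None  # (overlap, t)
    for t in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        o = min(n1, t + n2) - max(0, t)
        if o < min_overlap:
            continue
        a = read1[max(0, t): max(0, t) + o]
        b = r2c[max(0, -t): max(0, -t) + o]
        if a == b:
            mism = 0
        else:
            limit = int(max_mismatch_rate * o)
            if limit == 0:
                continue
            mism = _count_mismatches(a, b)
            if mism > limit:
                continue
        if best is None or o > best[0]:
            best = (o, t)
    if best is None:
        return None
    o, t = best
    insert = n1 + n2 - o
    if t >= 0:
        # union span: mate1 prefix, overlap, then whatever mate2' adds
        merged = read1[:max(0, t)] + r2c if t + n2 >= n1 else read1
    else:
        merged = r2c[:-t] + read1
    return insert, merged


def mate_overlap_insert(
    read1: str,
    read2: str,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
):
    """Insert length from mate overlap, or ``None`` when mates do not overlap."""
    res = merge_mates(read1, read2, min_overlap=min_overlap, max_mismatch_rate=max_mismatch_rate)
    return None if res is None else res[0]


def merge_inserts_batch(
    reads1: Sequence[str],
    reads2: Sequence[str],
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
) -> tuple[np.ndarray, list[str | None]]:
    """Vectorised :func:`merge_mates` over many pairs.

    Pairs whose reads share one common length are processed with a single
    NumPy sweep over offsets (largest overlap first per pair); remaining
    pairs fall back to the per-pair routine.  Returns an int array of
    insert lengths (-1 = no overlap) and the merged sequences.
    """
    n = len(reads1)
    inserts = np.full(n, -1, dtype=np.int64)
    merged: list[str | None] = [None] * n

    by_len: dict[tuple[int, int], list[int]] = {}
    for i, (a, b) in enumerate(zip(reads1, reads2)):
        by_len.setdefault((len(a), len(b)), []).append(i)

    for (n1, n2), idx in by_len.items():
        if n1 != n2 or len(idx) < 4 or n1 < min_overlap:
            for i in idx:
                res = merge_mates(reads1[i], reads2[i], min_overlap, max_mismatch_rate)
                if res is not None:
                    inserts[i], merged[i] = res
            continue
        L = n1
        m = len(idx)
        r1 = np.frombuffer("".join(reads1[i] for i in idx).encode(), dtype=np.uint8).reshape(m, L)
        r2c_str = [revcomp(reads2[i]) for i in idx]
        r2 = np.frombuffer("".join(r2c_str).encode(), dtype=np.uint8).reshape(m, L)

        # non-negative offsets: t ascending means overlap descending, so the
        # first acceptable offset per row is its best on this side
        pos_t = np.full(m, -1, dtype=np.int64)
        pos_o = np.zeros(m, dtype=np.int64)
        found = np.zeros(m, dtype=bool)
        for t in range(0, L - min_overlap + 1):
            o = L - t
            mism = np.count_nonzero(r1[:, t:] != r2[:, :o], axis=1)
            newly = (~found) & (mism <= int(max_mismatch_rate * o))
            pos_t[newly] = t
            pos_o[newly] = o
            found |= newly
            if found.all():
                break
        # negative offsets (read-through geometry): overlap o = L + t; scan
        # o descending so the first acceptable is the best negative offset
        neg_t = np.full(m, 0, dtype=np.int64)
        neg_o = np.zeros(m, dtype=np.int64)
        nfound = np.zeros(m, dtype=bool)
        if not (found & (pos_o >= L)).all():
            for t in range(-1, -(L - min_overlap) - 1, -1):
                o = L + t
                mism = np.count_nonzero(r1[:, :o] != r2[:, L - o:], axis=1)
                newly = (~nfound) & (mism <= int(max_mismatch_rate * o))
                neg_t[newly] = t
                neg_o[newly] = o
                nfound |= newly
                if nfound.all():
                    break
        # equal overlaps favour the negative offset, matching the per-pair
        # reference which scans offsets in ascending order
        use_neg = nfound & (neg_o >= pos_o)
        for j, i in enumerate(idx):
            if use_neg[j]:
                t = int(neg_t[j])
                inserts[i] = 2 * L - int(neg_o[j])
                merged[i] = r2c_str[j][:-t] + reads1[i]
            elif found[j]:
                t = int(pos_t[j])
                inserts[i] = L + t
                merged[i] = reads1[i][:t] + r2c_str[j]
    return inserts, merged
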