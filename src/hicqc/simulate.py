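"""Synthetic DNase Hi-C library simulator.

Generates a random genome and a proximity-ligation library with four read
classes mixed at configurable fractions:

* **contacts** — true ligation products joining two loci; cis with
  probability ``cis_fraction``, cis separations drawn from a truncated
  power law P(d) ~ d^-alpha; alignment strands of the two sides are
  independent and uniform, so FR/RF/FF/RR are produced 1:1:1:1;
* **back-ligations** — two adjacent genomic fragments re-joined in their
  original order, yielding inward (FR) pairs at near-zero separation that
  are indistinguishable from dangling ends unless the junction carries an
  adapter;
* **dangling ends** — undigested/unligated contiguous fragments, sequenced
  as inward (FR) pairs;
* adapter *incidental* matches are not injected: they arise naturally
  wherever the random genome happens to contain the adapter sequence,
  mirroring how the incidental rate is measured on adapter-free libraries.

A junction adapter is inserted with probability ``adapter_ligation_freq``
(y) for contact and back-ligation classes, never for dangling fragments.

The simulator plays the role of the aligner: each mate that spans a
junction is emitted as a primary plus supplementary SAM record (with SA
tags), so the pair-extraction stage can be exercised without an external
mapper.  The truth table records, per pair, the class, the contact call
that the documented max-distance ranking yields on the true alignment
layout, adapter presence and the fragment (insert) length.

All internal coordinates are 0-based half-open; SAM output is 1-based.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import PHRED_CONST, revcomp

TRUTH_COLUMNS = [
    "pair_id", "class", "chrom1", "pos1", "strand1",
    "chrom2", "pos2", "strand2", "adapter", "insert_length",
]

CLASS_CONTACT = "contact"
CLASS_BACK = "back_ligation"
CLASS_DANGLING = "dangling"

_MARGIN = 700  # keep fragment anchors clear of chromosome ends


class ConfigError(ValueError):
    """Invalid simulation or genome configuration."""


@dataclass(frozen=True)
class GenomeSpec:
    """Random genome to simulate from (a small stand-in for a reference)."""

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    gc_content: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.chrom_length < 10_000:
            raise ConfigError("chrom_length must be >= 10,000")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ConfigError("gc_content must be in [0, 1]")


def generate_genome(spec: GenomeSpec) -> dict[str, str]:
    """Simulate chromosome sequences (A/C/G/T) at the requested GC content."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for i in range(spec.n_chromosomes):
        seq = rng.choice(alphabet, size=spec.chrom_length, p=probs)
        genome[f"chr{i + 1}"] = seq.tobytes().decode()
    return genome


def write_genome_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


@dataclass(frozen=True)
class SimulationConfig:
    """Library composition and sequencing parameters.

    ``frac_contact + frac_back_ligation + frac_dangling`` must sum to 1.
    ``adapter_ligation_freq`` is y, the probability that a ligation
    junction incorporates the adapter; ``incidental_rate`` documents the
    assumed chance-match rate c of the adapter in genomic sequence (used
    downstream by the estimator, never injected here).
    """

    n_pairs: int = 10_000
    frac_contact: float = 0.6
    frac_back_ligation: float = 0.15
    frac_dangling: float = 0.25
    cis_fraction: float = 0.7
    decay_exponent: float = 1.0
    adapter_ligation_freq: float = 0.5
    incidental_rate: float = 0.0
    adapter_sequences: tuple[str, ...] = ()
    insert_mean: float = 250.0
    insert_sd: float = 80.0
    insert_min: int = 60
    insert_max: int = 600
    read_length: int = 150
    dist_min: int = 1_000
    dist_max: int | None = None
    mapq: int = 60
    mapq0_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    min_chimeric_len: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_contact": self.frac_contact,
            "frac_back_ligation": self.frac_back_ligation,
            "frac_dangling": self.frac_dangling,
            "cis_fraction": self.cis_fraction,
            "adapter_ligation_freq": self.adapter_ligation_freq,
            "mapq0_fraction": self.mapq0_fraction,
            "duplicate_fraction": self.duplicate_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        total = self.frac_contact + self.frac_back_ligation + self.frac_dangling
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class fractions must sum to 1, got {total}")
        if self.decay_exponent <= 0:
            raise ConfigError("decay_exponent must be > 0")
        if self.read_length < 30:
            raise ConfigError("read_length must be >= 30")
        if self.insert_min < 2 * self.min_chimeric_len + 1:
            raise ConfigError("insert_min must exceed 2 * min_chimeric_len")
        if not 0.0 <= self.incidental_rate < 1.0:
            raise ConfigError("incidental_rate must be in [0, 1)")
        for a in self.adapter_sequences:
            if not a or set(a.upper()) - set("ACGT"):
                raise ConfigError(f"adapter sequence must be A/C/G/T, got {a!r}")


@dataclass(slots=True)
class _Segment:
    """One alignable piece of one mate (as an ideal aligner would report)."""

    mate: int
    read_start: int
    read_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    is_primary: bool = False

    @property
    def five_prime(self) -> int:
        return self.ref_start if self.strand == "+" else self.ref_end - 1


@dataclass
class SimPair:
    pair_id: str
    class_label: str
    fragment: str
    segments: list[_Segment]
    adapter: bool
    call: tuple  # (chrom1, pos1, strand1, chrom2, pos2, strand2), canonical


def _sample_distances(u: np.ndarray, alpha: float, dmin: float, dmax: float) -> np.ndarray:
    """Inverse-CDF sampling from P(d) ~ d^-alpha on [dmin, dmax]."""
    if abs(alpha - 1.0) < 1e-12:
        return dmin * (dmax / dmin) ** u
    a1 = 1.0 - alpha
    return (dmin ** a1 + u * (dmax ** a1 - dmin ** a1)) ** (1.0 / a1)


def _ideal_call(segments: list[_Segment]) -> tuple:
    """Contact call of the documented ranking on the true alignment layout.

    Kept local to the simulator (small and independent of the extraction
    module) so round-trip tests compare two separate code paths.
    """
    best_key = None
    best = None
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            a, b = segments[i], segments[j]
            sa = (a.chrom, a.five_prime, a.strand)
            sb = (b.chrom, b.five_prime, b.strand)
            trans = sa[0] != sb[0]
            dist = 0 if trans else abs(sa[1] - sb[1])
            c1, c2 = (sa, sb) if sa <= sb else (sb, sa)
            key = (
                a.mate == b.mate,
                not trans,
                -dist,
                -(a.is_primary + b.is_primary),
                c1,
                c2,
            )
            if best_key is None or key < best_key:
                best_key, best = key, (c1, c2)
    return (*best[0], *best[1])


def _mate_segments(
    blocks: list[tuple],
    frag_len: int,
    read_length: int,
    min_chimeric: int,
) -> list[_Segment]:
    """Project both mates onto the genomic blocks of the fragment.

    ``blocks`` holds tuples ``(frag_start, frag_end, chrom, g_start, g_end,
    orient)`` with orient +1 when the block enters the fragment in genomic
    forward orientation; adapter blocks carry ``chrom=None`` and are
    soft-clipped.  The longest segment per mate becomes its primary; other
    segments at least ``min_chimeric`` long become supplementary records.
    """
    len1 = min(read_length, frag_len)
    len2 = min(read_length, frag_len)
    segs: list[_Segment] = []
    for fs, fe, chrom, gs, ge, orient in blocks:
        if chrom is None:
            continue
        # mate 1: read coords == fragment coords
        a, b = max(fs, 0), min(fe, len1)
        if b - a >= 1:
            if orient == 1:
                seg = _Segment(1, a, b, chrom, gs + (a - fs), gs + (b - fs), "+")
            else:
                seg = _Segment(1, a, b, chrom, ge - (b - fs), ge - (a - fs), "-")
            segs.append(seg)
        # mate 2: covers fragment tail, read coords reversed
        a, b = max(fs, frag_len - len2), min(fe, frag_len)
        if b - a >= 1:
            rs, re = frag_len - b, frag_len - a
            if orient == 1:
                seg = _Segment(2, rs, re, chrom, gs + (a - fs), gs + (b - fs), "-")
            else:
                seg = _Segment(2, rs, re, chrom, ge - (b - fs), ge - (a - fs), "+")
            segs.append(seg)
    out: list[_Segment] = []
    for mate in (1, 2):
        mine = [s for s in segs if s.mate == mate]
        if not mine:
            continue
        primary = max(mine, key=lambda s: s.read_end - s.read_start)
        primary.is_primary = True
        out.append(primary)
        out.extend(
            s for s in mine
            if s is not primary and s.read_end - s.read_start >= min_chimeric
        )
    return out


class SimulatedLibrary:
    """A fully simulated library: truth, fragments, reads and alignments."""

    def __init__(self, config: SimulationConfig, genome: dict[str, str]):
        self.config = config
        self.genome = genome
        self.pairs: list[SimPair] = _simulate(config, genome)

    @property
    def truth(self) -> pd.DataFrame:
        rows = [
            (p.pair_id, p.class_label, *p.call, p.adapter, len(p.fragment))
            for p in self.pairs
        ]
        return pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    def reads(self) -> tuple[list[str], list[str], list[str]]:
        """Read ids, mate-1 and mate-2 sequences (mate 2 reverse-complemented)."""
        rl = self.config.read_length
        ids, r1, r2 = [], [], []
        for p in self.pairs:
            ids.append(p.pair_id)
            r1.append(p.fragment[:rl])
            r2.append(revcomp(p.fragment[-rl:]) if len(p.fragment) > rl else revcomp(p.fragment))
        return ids, r1, r2

    # -- writers ------------------------------------------------------------

    def write_truth(self, path: str) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_fastq(self, path_r1: str, path_r2: str) -> None:
        ids, r1, r2 = self.reads()
        _write_fastq(path_r1, ids, r1)
        _write_fastq(path_r2, ids, r2)

    def write_sam(self, path: str) -> None:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11]))
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for name, seq in self.genome.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
            fh.write("@PG\tID:hicqc-sim\tPN:hicqc-sim\n")
            buf: list[str] = []
            for p in self.pairs:
                buf.extend(_sam_records(p, cfg, rng))
                if len(buf) >= 20_000:
                    fh.write("\n".join(buf) + "\n")
                    buf.clear()
            if buf:
                fh.write("\n".join(buf) + "\n")

    def write_all(self, outdir: str, gzip_fastq: bool = True) -> dict[str, str]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        ext = ".fastq.gz" if gzip_fastq else ".fastq"
        paths = {
            "genome": str(out / "genome.fa"),
            "truth": str(out / "truth.tsv"),
            "r1": str(out / f"reads_R1{ext}"),
            "r2": str(out / f"reads_R2{ext}"),
            "sam": str(out / "reads.sam"),
        }
        write_genome_fasta(self.genome, paths["genome"])
        self.write_truth(paths["truth"])
        self.write_fastq(paths["r1"], paths["r2"])
        self.write_sam(paths["sam"])
        return paths


def _simulate(cfg: SimulationConfig, genome: dict[str, str]) -> list[SimPair]:
    chroms = list(genome)
    n_chrom = len(chroms)
    clen = {c: len(s) for c, s in genome.items()}
    min_clen = min(clen.values())
    dmax = cfg.dist_max if cfg.dist_max is not None else min_clen // 2
    if dmax <= cfg.dist_min:
        raise ConfigError("dist_max must exceed dist_min")
    if min_clen < 2 * _MARGIN + max(dmax - min_clen // 2, 0) + cfg.insert_max:
        raise ConfigError("chromosomes too short for the configured distances")
    if cfg.frac_contact > 0 and cfg.cis_fraction < 1 and n_chrom < 2:
        raise ConfigError("trans contacts require at least 2 chromosomes")

    n = cfg.n_pairs
    rng = np.random.default_rng(cfg.seed)
    adapters = tuple(a.upper() for a in cfg.adapter_sequences)

    classes = rng.choice(3, size=n, p=[cfg.frac_contact, cfg.frac_back_ligation, cfg.frac_dangling])
    inserts = np.clip(
        np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n)),
        cfg.insert_min, cfg.insert_max,
    ).astype(np.int64)
    junc_u = rng.random(n)
    strand_draw = rng.integers(0, 2, size=(n, 2))
    has_adapter = rng.random(n) < cfg.adapter_ligation_freq
    which_adapter = rng.integers(0, max(len(adapters), 1), size=n)
    is_cis = rng.random(n) < cfg.cis_fraction
    dists = np.rint(_sample_distances(rng.random(n), cfg.decay_exponent, cfg.dist_min, dmax)).astype(np.int64)
    side_u = rng.integers(0, 2, size=n)
    pos_u = rng.random(n)
    pos_u2 = rng.random(n)
    chrom_i = rng.integers(0, n_chrom, size=n)
    chrom_shift = rng.integers(1, max(n_chrom, 2), size=n)

    width = len(str(n))
    pairs: list[SimPair] = []
    for i in range(n):
        L = int(inserts[i])
        klass = classes[i]
        c1 = chroms[chrom_i[i]]
        seq1 = genome[c1]
        adapter = ""
        ad_flag = False
        if klass == 0:  # contact
            # keep a mappable chimeric seed on both sides of the junction:
            # shorter overhangs cannot be aligned and would be observed as
            # one-sided products, which the dangling class models instead
            mc = cfg.min_chimeric_len
            L1 = mc + int(junc_u[i] * (L - 2 * mc))
            L2 = L - L1
            s1 = "+" if strand_draw[i, 0] == 0 else "-"
            s2 = "+" if strand_draw[i, 1] == 0 else "-"
            if is_cis[i]:
                c2 = c1
                d = int(min(dists[i], clen[c1] // 2))
                lo = _MARGIN
                hi = clen[c1] - _MARGIN - d
                pl = lo + int(pos_u[i] * (hi - lo))
                p1, p2 = (pl, pl + d) if side_u[i] == 0 else (pl + d, pl)
            else:
                c2 = chroms[(chrom_i[i] + chrom_shift[i]) % n_chrom]
                p1 = _MARGIN + int(pos_u[i] * (clen[c1] - 2 * _MARGIN))
                p2 = _MARGIN + int(pos_u2[i] * (clen[c2] - 2 * _MARGIN))
            seq2 = genome[c2]
            if adapters and has_adapter[i]:
                adapter = adapters[which_adapter[i] % len(adapters)]
                ad_flag = True
            # fragment-left block holds the mate-1 5' coordinate p1
            if s1 == "+":
                b1 = (c1, p1, p1 + L1, 1)
            else:
                b1 = (c1, p1 - L1 + 1, p1 + 1, -1)
            if s2 == "-":
                b2 = (c2, p2 - L2 + 1, p2 + 1, 1)
            else:
                b2 = (c2, p2, p2 + L2, -1)
            frag = _block_seq(genome, b1) + adapter + _block_seq(genome, b2)
            blocks = _layout([b1, ("*", 0, len(adapter), 1) if adapter else None, b2])
            label = CLASS_CONTACT
        elif klass == 1:  # back-ligation: adjacent fragments re-joined in order
            j = 1 + int(junc_u[i] * (L - 1))
            lo = _MARGIN
            hi = clen[c1] - _MARGIN - L
            a = lo + int(pos_u[i] * (hi - lo))
            if adapters and has_adapter[i]:
                adapter = adapters[which_adapter[i] % len(adapters)]
                ad_flag = True
            frag = seq1[a: a + j] + adapter + seq1[a + j: a + L]
            if adapter:
                blocks = _layout([(c1, a, a + j, 1), ("*", 0, len(adapter), 1), (c1, a + j, a + L, 1)])
            else:
                # adapter-free back-ligation restores contiguous genomic
                # sequence: an aligner reports one alignment, not a split
                blocks = _layout([(c1, a, a + L, 1)])
            label = CLASS_BACK
        else:  # dangling: one contiguous fragment, no ligation junction
            lo = _MARGIN
            hi = clen[c1] - _MARGIN - L
            a = lo + int(pos_u[i] * (hi - lo))
            frag = seq1[a: a + L]
            blocks = _layout([(c1, a, a + L, 1)])
            label = CLASS_DANGLING

        segs = _mate_segments(blocks, len(frag), cfg.read_length, cfg.min_chimeric_len)
        call = _ideal_call(segs)
        pairs.append(SimPair(f"sim{i:0{width}d}", label, frag, segs, ad_flag, call))

    n_dup = int(round(cfg.duplicate_fraction * n))
    if n_dup:
        dup_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD0]))
        for k, idx in enumerate(dup_rng.choice(n, size=n_dup, replace=False)):
            src = pairs[idx]
            pairs.append(
                SimPair(f"{src.pair_id}.dup{k}", src.class_label, src.fragment,
                        src.segments, src.adapter, src.call)
            )
    return pairs


def _block_seq(genome: dict[str, str], block: tuple) -> str:
    chrom, gs, ge, orient = block
    s = genome[chrom][gs:ge]
    return s if orient == 1 else revcomp(s)


def _layout(raw_blocks: list) -> list[tuple]:
    """Assign fragment coordinates to a list of blocks (None entries skipped)."""
    out = []
    pos = 0
    for blk in raw_blocks:
        if blk is None:
            continue
        chrom, gs, ge, orient = blk
        w = ge - gs
        out.append((pos, pos + w, None if chrom == "*" else chrom, gs, ge, orient))
        pos += w
    return out


def _sam_records(pair: SimPair, cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    rl = cfg.read_length
    frag = pair.fragment
    len1 = min(rl, len(frag))
    reads = {1: frag[:len1], 2: revcomp(frag[-len1:])}
    primaries = {s.mate: s for s in pair.segments if s.is_primary}
    by_mate: dict[int, list[_Segment]] = {1: [], 2: []}
    for s in pair.segments:
        by_mate[s.mate].append(s)

    mapqs = {}
    for s in pair.segments:
        mapqs[id(s)] = 0 if (cfg.mapq0_fraction and rng.random() < cfg.mapq0_fraction) else cfg.mapq

    lines = []
    for mate in (1, 2):
        other = primaries.get(3 - mate)
        for s in by_mate[mate]:
            flag = 1 | (64 if mate == 1 else 128)
            if _stored_reversed(s):
                flag |= 16
            if other is not None and _stored_reversed(other):
                flag |= 32
            if not s.is_primary:
                flag |= 2048
            # supplementary records omit SEQ/QUAL (as hard-clipping aligners do)
            if s.is_primary:
                seq = reads[mate] if not _stored_reversed(s) else revcomp(reads[mate])
                qual = PHRED_CONST * len(seq)
            else:
                seq = qual = "*"
            rnext, pnext = ("=", other.ref_start + 1) if other is not None and other.chrom == s.chrom else (
                (other.chrom, other.ref_start + 1) if other is not None else ("*", 0)
            )
            tags = []
            others_same_mate = [t for t in by_mate[mate] if t is not s]
            if others_same_mate:
                sa = "".join(
                    f"{t.chrom},{t.ref_start + 1},{t.strand},"
                    f"{_cigar_str(t.read_start, t.read_end - t.read_start, len(reads[mate]) - t.read_end, flip=_stored_reversed(t))},"
                    f"{mapqs[id(t)]},0;"
                    for t in others_same_mate
                )
                tags.append(f"SA:Z:{sa}")
            lines.append(
                "\t".join(
                    (
                        pair.pair_id,
                        str(flag),
                        s.chrom,
                        str(s.ref_start + 1),
                        str(mapqs[id(s)]),
                        _cigar_str(s.read_start, s.read_end - s.read_start,
                                   len(reads[mate]) - s.read_end, flip=_stored_reversed(s)),
                        rnext,
                        str(pnext),
                        "0",
                        seq,
                        qual,
                        *tags,
                    )
                )
            )
    return lines


def _stored_reversed(s: _Segment) -> bool:
    """Whether the SAM record stores the read reverse-complemented.

    Per the SAM convention this is exactly the reverse-strand flag: SEQ is
    the reverse complement of the sequenced read iff the alignment is on
    the reverse strand, for either mate.
    """
    return s.strand == "-"


def _cigar_str(pre: int, mlen: int, post: int, flip: bool) -> str:
    if flip:
        pre, post = post, pre
    parts = []
    if pre:
        parts.append(f"{pre}S")
    parts.append(f"{mlen}M")
    if post:
        parts.append(f"{post}S")
    return "".join(parts)


def _write_fastq(path: str, ids: list[str], seqs: list[str]) -> None:
    def dump(fh) -> None:
        buf = []
        for rid, seq in zip(ids, seqs):
            buf.append(f"@{rid}\n{seq}\n+\n{PHRED_CONST * len(seq)}\n")
            if len(buf) >= 20_000:
                fh.write("".join(buf))
                buf.clear()
        fh.write("".join(buf))

    if str(path).endswith(".gz"):
        with open(path, "wb") as raw, gzip.GzipFile(
            filename="", mode="wb", fileobj=raw, mtime=0, compresslevel=1
        ) as gz:
            import io

            with io.TextIOWrapper(gz) as txt:
                dump(txt)
    else:
        with open(path, "w") as fh:
            dump(fh)


# -- spec-level convenience operations --------------------------------------

def simulate_pairs(config: SimulationConfig, genome: dict[str, str]):
    """Simulate a library; returns ``(truth table, fragment sequences)``."""
    lib = SimulatedLibrary(config, genome)
    return lib.truth, [p.fragment for p in lib.pairs]


def write_fastq(fragments: list[str], ids: list[str], config: SimulationConfig,
                path_r1: str, path_r2: str) -> None:
    """Write paired FASTQ: mate 1 = fragment head, mate 2 = revcomp tail."""
    rl = config.read_length
    _write_fastq(path_r1, ids, [f[:rl] for f in fragments])
    _write_fastq(path_r2, ids, [revcomp(f[-rl:]) if len(f) > rl else revcomp(f) for f in fragments])
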