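# Methods

`hicqc` analyses DNase Hi-C libraries: it extracts contact pairs from
chimeric paired-end alignments, computes library quality metrics, and
separates the dangling-ends signal into back-ligation events and genuinely
undigested/unligated DNA using junction-adapter information. A bundled
simulator generates fully ground-truthed synthetic libraries to exercise and
validate every stage. This note records the models, the parameters that
matter, the numerical choices, and the limits of what the synthetic data can
show.

## The quality-control model

A proximity-ligation read pair is classified by the relative orientation of
its two mates after sorting the sides by genomic position: FR (inward), RF
(outward), FF and RR. For true ligation products the four classes occur
1:1:1:1, because the two fragment ends are joined with random relative
orientation. Library artefacts break this symmetry: undigested or unligated
fragments and re-ligations of adjacent ends ("back-ligations") are always
read inward, so their presence shows up as FR excess. The dangling-ends
statistic is

    DE = (FR + RF) - (FF + RR),

a signed excess that is zero in expectation for a pure-contact library.
Negative values are reported with an anomaly flag, never clipped.

### The back-ligation estimator

In protocols that ligate a biotinylated adapter into the junction, the
adapter marks true ligation events. Let

* `N`  — number of FF/RR pairs (these are necessarily true ligations),
* `P1` — FF/RR pairs whose fragment contains the adapter,
* `P2` — FR/RF pairs whose fragment contains the adapter,
* `y`  — probability that a ligation junction incorporated the adapter,
* `c`  — probability of an incidental (chance) adapter match in genomic
  sequence,
* `B`  — back-ligation events among the FR/RF excess,
* `G`  — undigested/unligated fragments, with `G + B = DE`.

Then `P1 = N(y + c)` and `P2 = P1 + DE*c + B*y`, which invert to

    y = P1/N - c,        B = (P2 - P1 - DE*c) / y.

The corrected dangling-ends statistic is `DE - B`, and `B/DE` is the
back-ligation share. The estimator is undefined when `P1/N <= c` (no
evidence of adapter ligation); that condition raises an error rather than
returning a junk value. `B` is reported raw and, separately, clamped to
`[0, max(DE, 0)]` with a flag — a strongly negative or super-DE estimate
usually diagnoses a mis-specified `c`.

`c` is estimated from a library prepared *without* the adapter (`y = 0`),
as the adapter-containing fraction of short-insert FF/RR pairs. Bundled
presets carry the typical scales: a 7-bp bridge-style adapter matches by
chance at roughly 5% of fragments, a 19-bp linker essentially never.

### Short-insert subset

With 150-bp reads, an adapter inside the fragment is only guaranteed to be
sequenced when the fragment is shorter than the two reads combined.
`P1`, `P2`, `N` and the `DE` used inside the estimator are therefore
computed on the subset of pairs whose mates overlap and reconstruct a
fragment shorter than 300 bp; the adapter is searched for (exact match,
either strand) in the *merged* fragment sequence, so an adapter straddling
the two mate ends is still seen. The headline `DE` of a library report is
computed over all cis valid pairs; both numbers are reported.

Note a subtlety this induces: the `y` the estimator measures is the adapter
frequency *within the short-insert subset*. Fragments carrying the adapter
are ~19 bp longer and slightly less likely to pass the 300-bp cut, so the
measured `y` sits a few percent below the generative adapter-ligation
frequency. Because `P1`, `P2` and `B` are measured on the same subset, the
estimate of `B` is unaffected — parameter-recovery tests confirm this.

### Uncertainty

The closed-form equations are a method-of-moments inversion with no native
uncertainty. `BackLigationModel.fit` attaches bootstrap standard errors:
pairs in the subset are resampled via the equivalent 4-category multinomial
(same/opposite orientation × adapter/no adapter), 200 replicates by
default, seeded. Replicates falling outside the estimator's domain are
dropped and counted; percentile confidence intervals are available from
`conf_int()`.

## Pair extraction

All primary and supplementary alignments of both mates are grouped per read
id (secondary alignments are ignored). The contact is the candidate pair of
alignments with the most distal evidence: candidates joining one alignment
from each mate dominate same-mate candidates, then interchromosomal
candidates outrank intrachromosomal ones, then the largest 5'-coordinate
difference wins, with ties broken by primary count and lexicographic order.
A side's reported position is the 5' mapping coordinate of its alignment
(leftmost base on `+`, rightmost on `-`); positions are 0-based in memory
and 1-based in TSV output.

The one-per-mate preference must dominate raw distance: a mate crossing the
ligation junction aligns at the partner locus on the strand *opposite* the
partner mate, so a same-mate candidate winning on distance would
systematically flip one side's strand outward and inflate FR among genuine
contacts, corrupting the orientation symmetry the DE statistic relies on.
With cross-mate candidates dominant the residual contest is between the
strand pairs `(s1, s2)` and `(-s1, -s2)`, which leaves `FF+RR`, `FR+RF`,
and hence DE, `N`, `P1`, `P2` all invariant.

One consequence is documented rather than hidden: for short fragments where
*both* mates cross the junction (possible only when the insert is below the
summed read lengths), the greatest-distance rule picks the junction-side
supplementary coordinates, which always face inward. Drawn-RF short
contacts are therefore reported FR, and FF/RR swap depending on fragment
geometry. Every aggregate the QC model consumes is invariant under these
swaps; only the individual FR-vs-RF split among short-insert contacts
shifts. Orientation-balance tests assert the 1:1:1:1 symmetry on contacts
with inserts ≥ 300 bp, and DE neutrality overall.

Validity filtering keeps pairs with both selected alignments at
`mapq >= min_mapq` (default 1, i.e. `mapq > 0`). Duplicates share the
positions *and strands* of both sides; the first occurrence in input order
is kept. Strands are included in the key because strand-discordant pairs at
equal positions are distinct ligation products.

## Read-context analysis

* **Non-internal matching** — at the 5' end, the longest adapter *suffix*
  equal to a read prefix (symmetric at 3'), minimum overlap 5. The error
  tolerance defaults to 0; a 10% rate on matches of ≤ 9 bp rounds to zero
  allowed mismatches anyway, so matching is effectively exact for short
  adapters.
* **Iterative trimming** — five rounds; each round tries every adapter and
  every concatemer variant up to 3 copies (mixed pairs included) at both
  ends and removes the longest match per end, stopping early at a fixpoint.
  Longer concatemers fall to later rounds — that is what the multiple
  rounds are for. Reads shorter than 7 bp after trimming are discarded.
* **Pattern profiling** — reads are decomposed by exact full-length adapter
  occurrences (both strands; greedy left-to-right on overlaps) into
  patterns like `G-bridge7-G`; abutting adapter segments flag multimers.
  Partial internal matches are unclassifiable and counted as genomic.
* **Mate-overlap merging** — reverse-complemented mate 2 is slid against
  mate 1 over all offsets (negative offsets included for read-through);
  the largest overlap ≥ 10 bp with mismatch fraction ≤ 0.1 wins and the
  insert is `len1 + len2 - overlap`. For error-free 150-bp pairs the
  recoverable insert range is [20, 290] bp; fragments ≥ 291 bp report "no
  overlap", which is exactly how the < 300 bp subset is selected. A
  vectorised batch implementation is used by the pipeline and is
  property-tested to agree exactly with the per-pair reference.

## The simulator

The generator emulates a DNase Hi-C library over a uniform random genome
(default two chromosomes, GC content 0.41). Per pair it draws one of three
classes — contact, back-ligation, dangling — builds the fragment sequence,
and plays the role of an ideal aligner, emitting primary plus supplementary
SAM records (with SA tags) for junction-spanning mates.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| class fractions | 0.60 / 0.15 / 0.25 | a mid-quality adapter-marked library with substantial FR excess |
| `cis_fraction` | 0.7 | moderate-noise library |
| `decay_exponent` | 1.0 | canonical contact-probability decay `P(d) ~ 1/d` |
| cis distance range | 1 kb – chrom/2 | below ~1 kb contacts are confounded with dangling ends |
| `adapter_ligation_freq` (y) | 0.5 | roughly half of junctions pick up the adapter |
| `insert_mean`/`insert_sd` | 250 / 80 bp, clipped to [60, 600] | a 150–500 bp sequencing library; the exact distribution is a modelling choice, not a measured one |
| `read_length` | 150 | paired-end 150 sequencing |
| `min_chimeric_len` | 20 | smallest split-alignment seed an aligner would report |
| qualities | constant `I` (Q40) | qualities play no role downstream |

Class constructions:

* **contact** — cis with probability `cis_fraction`; cis separation from
  the truncated power law via inverse-CDF sampling; strands of the two
  sides independent and uniform (hence 1:1:1:1); the junction position
  leaves at least `min_chimeric_len` on both sides so each locus has a
  mappable seed (shorter overhangs would be unmappable one-sided products,
  which the dangling class already represents).
* **back-ligation** — two adjacent fragments rejoined in original order:
  one contiguous locus split at a junction uniform within the fragment,
  read inward (FR), separation below 1 kb. Without an adapter the fragment
  restores contiguous genomic sequence, so it is emitted as a single
  unsplit alignment, as a real aligner would.
* **dangling** — one contiguous fragment, read inward, drawn from the same
  insert distribution as the ligation classes so the short-insert filter
  treats classes symmetrically.

A junction adapter (drawn from the configured sequences) is inserted with
probability `y` for contact and back-ligation classes, never for dangling
fragments; incidental adapter matches are *not* injected — they arise
naturally where the random genome happens to contain the adapter, which is
how `c` is defined operationally.

The truth table records, per pair, the class and the contact call that the
documented ranking yields on the true alignment layout (computed inside the
simulator by a small independent re-implementation of the ranking over the
known segments). Round-trip tests therefore verify SAM emission, parsing,
grouping and ranking fidelity end to end, while a separate brute-force
enumeration oracle guards the ranking itself on randomized alignment
groups. An optional duplication knob re-emits a chosen fraction of pairs
under new read ids for deduplication tests. All outputs (FASTA, FASTQ,
SAM, truth TSV) are byte-identical under a fixed seed; gzip members are
written with a zeroed timestamp for this reason.

What the simulator deliberately does not model: sequencing errors and
quality decay, PCR-duplicate family-size structure, restriction-site or
chromatin-domain structure, mappability variation, and adapter partial
degradation. Passing tests therefore demonstrate the correctness of the
algorithms under clean alignments and error-free reads — they do not
establish robustness to alignment noise or base-calling error in real
libraries.

## Numerical and design choices

* Internal coordinates 0-based half-open; SAM/TSV output 1-based.
* Canonical pair ordering is lexicographic by (chromosome, position,
  strand); orientation is defined only after this ordering, which makes it
  invariant to mate swapping.
* The estimator treats pairs (not reads) as the unit throughout: each pair
  counts once in `N`, `P1`, `P2`.
* "Reported pairs" counts pairs reaching valid status before
  deduplication, divided by total read pairs — a mapping-efficiency
  metric, not a complexity metric.
* Degenerate inputs map to typed errors (`EstimatorError`,
  `EmptyInputError`, `ConfigError`, `PipelineConfigError`), never to NaN
  propagation, except where a statistic is legitimately undefined
  (back-ligation share at `DE <= 0` is NaN with a flag).
* Test problem sizes: statistical recovery tests run at 2×10^4–2×10^5
  pairs with 3-SE tolerances computed from the binomial/multinomial
  sampling model; the 20-library parameter-recovery check runs at 2×10^5
  pairs per library on a 2-Mb genome, sizes at which every tolerance is
  dominated by sampling noise rather than implementation artefacts.

## Known limitations

* Adapter sequences are user-supplied; the bundled `bridge7`/`linker19`
  presets are synthetic example sequences of the right length classes, not
  any published protocol's oligos.
* The incidental rate `c` is assumed constant across orientation classes
  and fragment lengths; in real genomes local composition could violate
  this.
* Bootstrap SEs treat pairs as i.i.d.; they ignore any dependence
  introduced by PCR families beyond the dedup filter.
* The estimator needs `P1/N > c` by a safe margin; libraries with very low
  adapter incorporation will raise estimator-domain errors rather than
  produce estimates.
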