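# hicqc

Quality control for DNase Hi-C libraries: contact-pair extraction from
chimeric paired-end alignments, library quality metrics, and an estimator
that splits the classical "dangling ends" signal into **back-ligation
events** and genuinely undigested/unligated DNA. A bundled simulator
generates fully ground-truthed synthetic libraries for validation.

## The problem

Hi-C libraries are judged by a handful of read-level metrics: the fraction
of read pairs that map into valid contacts, the cis/trans ratio, and the
excess of inward-oriented (FR) read pairs,

```
DE = (FR + RF) − (FF + RR),
```

classically interpreted as undigested or unligated DNA ("dangling ends")
and treated as a defect of the protocol. In DNase Hi-C, however, a large
part of this excess comes from *back-ligation*: digested ends re-joined in
their original genomic order. These are real ligation products that merely
look like dangling ends. In protocols that place a biotinylated adapter in
the ligation junction, the adapter content of each orientation class
separates the two. With

* `N` = FF/RR pairs, `P1` = those containing the adapter,
* `P2` = FR/RF pairs containing the adapter,
* `y` = adapter-ligation frequency, `c` = incidental adapter-match rate,

the forward model `P1 = N(y+c)`, `P2 = P1 + DE·c + B·y` inverts to

```
y = P1/N − c          B = (P2 − P1 − DE·c) / y
```

giving the back-ligation count `B`, the corrected dangling-ends statistic
`DE − B`, and the back-ligation share `B/DE`. `hicqc` implements this
estimator with bootstrap standard errors, together with the supporting
machinery: chimeric-alignment pair calling, mapq filtering and
deduplication, mate-overlap insert calling for the <300 bp subset where the
adapter is observable, and adapter/multimer read-structure profiling.

## Worked example

```python
import tempfile
from hicqc import (LINKER19, BackLigationModel, GenomeSpec, SimulationConfig,
                   SimulatedLibrary, annotate_pairs, extract_pairs,
                   generate_genome, read_fastq_pairs, summarize_library)

genome = generate_genome(GenomeSpec(n_chromosomes=2, chrom_length=1_000_000, seed=1))
cfg = SimulationConfig(n_pairs=50_000, seed=1,
                       adapter_sequences=(LINKER19.sequence,))
lib = SimulatedLibrary(cfg, genome)
with tempfile.TemporaryDirectory() as d:
    paths = lib.write_all(d, gzip_fastq=False)          # FASTA/FASTQ/SAM/truth
    pairs = extract_pairs(paths["sam"])                 # chimera-aware pair calling
    reads = read_fastq_pairs(paths["r1"], paths["r2"])
ann = annotate_pairs(pairs, reads, LINKER19)            # insert + adapter flags
results = BackLigationModel.from_annotated_pairs(ann, c=0.0).fit(n_boot=200, seed=1)
print(results.summary())
```

prints

```
Back-ligation estimator (short-insert subset)
==============================================
N (FF+RR pairs)                6795
P1 (with adapter)              3251
FR+RF pairs                   20505
P2 (with adapter)              5439
DE (subset)                   13710
c (incidental rate)          0.0000
----------------------------------------------
y  adapter-ligation freq        0.4784 +/- 0.005607
B  back-ligation events           4573 +/- 207.3
G  undigested/unligated           9137 +/- 189.8
----------------------------------------------
corrected DE (subset)          9137
back-ligation share          33.36%
```

Reading this: of the 13,710-pair FR/RF excess in the short-insert subset,
about a third (4,573 ± 207 pairs) is explained by back-ligation — real
ligation events — and only the corrected remainder (9,137) reflects
undigested/unligated DNA. The measured adapter-ligation frequency is
`y ≈ 0.48` (this library was simulated with y = 0.5; adapter-carrying
fragments are slightly longer and pass the 300-bp cut slightly less often,
see `docs/methods.md`). The library-level report adds mapping and noise
metrics:

```python
report = summarize_library(ann, raw_read_count=50_000, results=results)
print(f"cis fraction      {report.cis_fraction:.3f}")   # 0.820
print(f"DE (all cis)      {report.de}")                 # 20110
print(f"DE fraction       {report.de_fraction:.3f}")    # 0.402
```

## Command line

One executable with subcommands:

```
hicqc simulate --config sim.yaml --out simdir/
hicqc extract  --sam reads.sam --out pairs.tsv --min-mapq 1
hicqc context  --r1 R1.fastq.gz --r2 R2.fastq.gz --preset linker19 --out ctx/
hicqc qc       --pairs pairs.tsv --reads-total 50000 \
               --r1 R1.fastq.gz --r2 R2.fastq.gz --adapter linker19 \
               --out report.json
hicqc run      --config run.yaml          # extract -> context -> qc
hicqc compare  report1.json report2.json --out combined.tsv
```

`pairs.tsv` columns (positions 1-based): `read_id, chrom1, pos1, strand1,
chrom2, pos2, strand2, status, orientation, separation`. The JSON report is
schema-versioned; `compare` emits one row per library with
`reported_pairs_pct, cis_pct, de, de_fraction, b, b_se, corrected_de_subset,
back_ligation_share, ...` exactly as in the JSON.

Adapter sequences are protocol-specific and user-supplied; the bundled
`bridge7` / `linker19` presets are synthetic example sequences of the two
length classes (with default incidental rates c = 0.05 and c = 0) intended
for simulation and testing.

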