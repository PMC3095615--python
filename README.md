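# mirseek

Discovery and annotation of plant microRNAs from small-RNA sequencing data.

Plant miRNAs are ~21-nt regulatory RNAs excised by DCL1 from single-stranded
stem-loop precursors as a miRNA/miRNA* duplex with 2-nt 3' overhangs. Given a
collapsed sRNA read set and a (draft) genome, `mirseek` profiles the library,
identifies known miRNA families against a miRBase-style reference, and
discovers novel candidate miRNAs by validating hairpin precursors around
genomic read loci — the workflow used to build the first miRNA inventories
for non-model crops such as cucumber. A synthetic-data generator with
recorded ground truth makes the whole pipeline testable without downloads.

The pipeline, per unique tag *t* with read count *c*:

1. clean/collapse reads, length-filter to 18–30 nt, report the per-length
   redundancy profile (Σ reads / # unique tags);
2. match *t* against reference mature miRNAs allowing each end to shift ≤ 2
   nt (known-family profiling, conserved/non-conserved from metadata);
3. map *t* exactly to the genome on both strands; discard it as a
   repeat-associated siRNA if it hits > 50 loci;
4. excise windows around each hit, fold them (Nussinov-style maximum-scoring
   DP with stacking, G:U allowed, loops ≥ 3 nt) and validate the duplex: the
   star arm is the pairing partner region shifted to leave 2-nt 3' overhangs,
   and a candidate needs ≥ 16 matched pairs and |len(miR) − len(miR*)| ≤ 4;
5. tier candidates — **Class A** if the predicted star sequence was itself
   sequenced (± 2 nt ends), **Class B** if ≥ 5 reads without a star,
   **Class C** otherwise;
6. optionally predict targets by plant complementarity rules (mismatch 1,
   G:U 0.5, bulge 1, doubled at positions 2–13, cutoff 4.0).

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a small study — a 30 kb genome carrying 5 planted MIR loci (with
star reads), a 60-copy repeat family and 100 background reads — then run
discovery on it:

```sh
$ cat sim.yaml
genome_len: 30000
n_scaffolds: 2
n_planted: 5
repeat_copies: 60
background_reads: 100
seed: 7

$ mirseek simulate --config sim.yaml --out sim/
wrote genome/reads/truth to sim/ (5 planted loci, 115 read records)

$ mirseek discover --genome sim/genome.fa --reads sim/reads.fa --out run/
17 novel candidates (10 Class A); reports in run/

$ head -8 run/novel_mirnas.tsv
# config_hash=1e82ce1c8a09
csa-MIR	Location	Orientation	Abundance	Sequence	Length (nt)	Hairpin Length (nt)	Minimum Free Energy	Class	miRNA*
cand-2	scaffold00001:6967.6987	+	7	CGTTGTCCATAGAGAAAAATG	21	129	-184.0	A	TTTTTCTCTATAAACAACGTGTG(15)
cand-3	scaffold00001:7003.7023	+	15	TTTTTCTCTATAAACAACGTG	21	129	-184.0	A	GTTGTCCATAGAGAAAAATG(7)
cand-6	scaffold00001:10239.10259	+	4	AAATTAACAGCACCATAGTGG	21	144	-201.0	A	ACTATGGTACTTTTAATTTTG(17)
cand-7	scaffold00001:10275.10295	+	17	ACTATGGTACTTTTAATTTTG	21	144	-201.0	A	AAATTAACAGCACCATAGTGG(4)
cand-9	scaffold00002:5210.5230	+	36	CAAAAACCATACGTGTGGTGT	21	165	-244.0	A	ACCACACGTTTGGTCTTTGGA(6)
cand-10	scaffold00002:5246.5266	+	6	ACCACACGTTTGGTCTTTGGA	21	165	-244.0	A	CAAAAACCATACGTGTGGTGT(36)
```

Each row is one candidate locus: its genomic interval and strand, mature
read count (Abundance), mature sequence and length, the trimmed stem-loop
length and its folding score (arbitrary units, more negative = more stable),
the evidence class, and the star sequence with its read count. Planted loci
appear twice — once from the mature arm and once from the sequenced star arm
(each is the other's star, e.g. `cand-2`/`cand-3`), exactly as reciprocal
miR/miR* pairs behave in real libraries. The run log
(`run/run_log.txt`) narrates the gates:

```
raw_reads       316
unique_tags     112
mapped_tags     112
repeat_excluded_tags    18
candidate_tags  94
novel_candidates        17
novel_class_a   10
```

The 18 excluded tags are the 60-copy repeat family's multi-mapping reads
plus background reads that landed inside repeat copies.

The bundled reference tables (`mirseek fixtures --table table1|table2`)
carry a curated cucumber miRNA survey: 25 known families (19 conserved, 6
non-conserved) and 7 novel loci (3 Class A with sequenced stars, 4 Class B).

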