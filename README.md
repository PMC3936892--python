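# stemloop

Small-RNA sequencing miRNA discovery for plant genomes: from raw
adapter-ligated reads to named miRNA/miRNA* pairs, cross-library
expression calls and degradome-supported target identification.

The package targets the classic two-library study design — e.g. flower
buds of a male-sterile (A) and male-fertile (B) line of *Brassica
campestris* — where candidate miRNAs must be separated from the bulk of
degradation products, siRNAs and other small RNAs using only sequence,
structure and read evidence.

## What it computes

**Read cleanup with an exact ledger.** Raw reads are trimmed of the 3'
adapter, bounded to 15–30 nt, screened for low-complexity artifacts and
subtracted against Rfam-style ncRNA and Repbase-style repeat sets. The
categories are disjoint and applied in a fixed order, so the per-library
accounting table partitions the raw total exactly.

**Five-criterion hairpin screening.** Each genome-anchored candidate is
folded inside a ladder of precursor windows and its miRNA/miRNA* duplex
must satisfy: (1) the star sequence is itself sequenced; (2) fewer than
4 duplex mismatches and no run of 4; (3) at most one asymmetric bulge of
at most 2 nt; (4) opposite stem arms forming a duplex with 2-nt 3'
overhangs; (5) a minimal folding energy index

```
AMFE = |MFE| / L * 100          (kcal/mol per 100 nt)
MFEI = AMFE / GC%               must exceed 0.8
```

which separates miRNA precursors from other small RNAs whose folding
energy is explained by base composition alone. Mature sequences are
named in miRBase style (`-5p`/`-3p` arms, `-1`/`-2` sub-members for
identical matures from distinct loci, `P-` for a structurally predicted,
never-sequenced partner arm).

**Expression profiling.** Counts are normalized to reads per million
mappable reads (RPM); a miRNA is differentially expressed when the
larger/smaller RPM ratio strictly exceeds 2. qRT-PCR support follows
the 2^-ΔΔCt convention.

**Degradome (PARE) target calling.** Degradome read 5' ends are
anchored on the transcriptome (first 20 nt, exact, sense strand),
miRNAs are scanned with Allen-style penalties (mismatch 1, G:U 0.5,
doubled over miRNA positions 2–13, cutoff 4.5), and a target is called
when the degradome peak inside the binding region falls at the
canonical slice site (opposite miRNA nucleotides 9/10), with a t-plot
abundance category 0–4 attached.

**Synthetic studies.** `stemloop.simulate` generates the complete input
universe — toy genome with planted hairpins, two libraries with known
per-miRNA abundances and planted fold changes, contaminant/junk reads,
transcripts with planted cleavage sites — plus machine-readable truth
tables, including decoy hairpins that each violate exactly one
screening criterion and shuffled decoy transcripts. Every planted locus
is re-verified with the production screening code before the truth is
published.

## Worked example

`examples/03_expression_profiling.py` normalizes published read counts
across two libraries of 4,540,620 and 4,667,617 mappable reads:

```
      miR_name   rpm_A  rpm_B  fold_change direction  is_de
 bra-miR824-p3  114.52 831.69         7.26   up_in_B   True
bra-miR167b-p3 1334.84 805.98         1.66 unchanged  False
bra-miR172a-p5    1.76   1.71         1.03 unchanged  False
```

520 raw reads in library A are 114.52 RPM; 3,882 in library B are
831.69 RPM; the 7.26-fold ratio exceeds the two-fold rule, so
bra-miR824-p3 is called up-regulated in the fertile-line library. The
other examples (`examples/01_…` through `05_…`) walk through read
filtering, hairpin screening, degradome target calling and the full
end-to-end pipeline on synthetic data; each prints the numbers it
computes and what they mean.

A thin CLI mirrors the library for shell use:

```bash
stemloop simulate --config sim.yaml --out-dir sim/
stemloop preprocess --reads sim/libA.fastq --adapter TGGAATTCTCGGGTGCCAAGG \
    --rfam sim/rfam.fa --repbase sim/repbase.fa --out-dir out/
stemloop discover --genome sim/genome.fa --reads-a sim/libA.fastq \
    --reads-b sim/libB.fastq --plant-mirs sim/plant_mirnas.fa \
    --adapter TGGAATTCTCGGGTGCCAAGG --out-dir out/
stemloop targets --transcripts sim/transcripts.fa --degradome sim/degradome.fastq \
    --mirnas mirs.fa --homology sim/homology.tsv --out-dir out/
```

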