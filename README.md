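# mirpipe

Small RNA-seq miRNA discovery and two-library differential expression, built
as a fully testable pipeline around a ground-truth read simulator.

## What this is for

Classic two-library small RNA-seq studies (one pooled library per condition,
no replicates) identify miRNAs by a hierarchy of alignment steps, consolidate
sequence variants (isomiRs) into miRNA classes, and call differential
expression with exact count statistics rather than replicate-based models.
`mirpipe` implements that procedure end to end:

1. **Read processing** — 3' adapter trimming, collapsing to unique tags with
   per-library counts, then a filter cascade: length 14–27 nt; composition
   (no single nucleotide ≥ 80% of the read, at most two N); copy number
   (> 3 reads across both libraries); and removal of tags matching known
   contaminant RNA classes (rRNA/tRNA/snRNA/snoRNA/repeats). Survivors are
   the *high-quality* tags.
2. **Classification** — tags hitting a *known* precursor tier are known
   miRNAs; tags hitting an *other-mammal conserved* precursor that also
   occurs in the genome are conserved miRNAs; remaining tags longer than
   18 nt that map to the genome are clustered into loci, extended by 60 nt
   of flank on each side, folded, and accepted as putative novel (PPN)
   miRNAs when the fold is a genuine hairpin with the tag cluster on one
   arm. Folding is weighted base-pair maximisation (Nussinov dynamic
   programming; GC=3, AU=2, GU=1, minimum loop 3) with a deterministic
   traceback.
3. **isomiR consolidation** — tags from one precursor arm form a class; the
   most abundant member is the class reference sequence and class counts sum
   over members. The standard diagnostic (Spearman correlation of reference
   counts vs class totals) is built in.
4. **Differential expression** — for each miRNA with counts x, y against
   library totals N1, N2, three tests are computed: the Audic–Claverie
   exact test on the conditional distribution

   p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1+N2/N1)^(x+y+1) ),

   Fisher's exact test and the chi-squared test on the 2×2 table
   (x, N1−x; y, N2−y). Each p-value is Bonferroni-corrected across the m
   abundance-filtered miRNAs (> 1000 reads in either library by default),
   and a miRNA is called DE only when **all three** adjusted p-values fall
   below α = 0.001.
5. **Downstream** — two-of-three consensus of external target predictor
   lists, functional-category tallies of DE miRNAs, qBase-style qPCR
   normalization (relative quantities against the geometric mean of
   reference-gene quantities) and classic ΔΔCt fold changes, plus TSV
   report generation.

The synthetic-data module (`mirpipe.simdata`) generates the complete study
from scratch — a genome with embedded hairpin precursors in all three tiers,
contaminant references, and paired FASTQ libraries drawn as isomiR mixtures
with configurable differential abundance — together with a per-read truth
table, so every stage above can be scored against known ground truth without
any external downloads.

## Worked example

```python
from mirpipe import SimConfig
from mirpipe.pipeline import run_synthetic_experiment
from mirpipe.annotate import isomir_reference_correlation

cfg = SimConfig(seed=1, library_depth=50_000)
res = run_synthetic_experiment(cfg)
```

prints, via the summary fields:

```
high-quality reads: 84385 (84.39% of raw)
unique miRNAs: 51 (20 known, 10 conserved, 21 PPN)
isomiR reference vs class total, library A: Spearman r = 0.999
DE miRNAs (three-test consensus, Bonferroni, alpha=0.001): 10 of 51 tested (19.61%)
recovery vs simulation truth: sensitivity 1.00, false positive rate 0.000
```

84% of the simulated reads survive the filter cascade (the rest are junk,
out-of-range or contaminant reads — the simulator admixes 10% contaminant
and 5% junk reads); all 50 embedded loci are recovered in their correct
tiers plus one extra split record; the reference-isomiR diagnostic is
strongly positive; and the consensus caller finds exactly the loci simulated
with an 8-fold abundance difference, with no false positives.

The same stages are available as a shell pipeline:

```
mirpipe simulate --seed 1 --out-dir sim/
mirpipe process  --fastq-a sim/library_A.fastq --fastq-b sim/library_B.fastq \
                 --contaminants sim/contaminants.fa --out-dir proc/
mirpipe annotate --tags proc/tags.tsv --genome sim/genome.fa \
                 --known sim/known_precursors.fa --conserved sim/conserved_precursors.fa \
                 --out-dir annot/
mirpipe de       --counts annot/mirnas.tsv --out-dir de/
mirpipe report   --tags proc/tags.tsv --mirnas annot/mirnas.tsv --de de/de.tsv \
                 --out-dir report/
```

## Layout

- `src/mirpipe/simdata.py` — synthetic references, libraries, truth tables
- `src/mirpipe/readproc.py` — trimming, collapsing, filter cascade
- `src/mirpipe/annotate.py` — alignment, clustering, folding, classification
- `src/mirpipe/diffexpr.py` — the three count tests and consensus calling
- `src/mirpipe/downstream.py` — target consensus, qPCR, reports
- `src/mirpipe/pipeline.py` — one-call orchestration of a full experiment
- `docs/methods.md` — models, parameter choices, and limitations
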