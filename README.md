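# orfselect

Analysis toolkit for **open-reading-frame (ORF) selection of DNA fragment
libraries** built on split beta-lactamase protein-fragment complementation.

When a randomly sheared DNA fragment is cloned between the two halves of
TEM-1 beta-lactamase (Bla-Alpha, residues 24–195, and Bla-Omega, residues
196–286), the host survives ampicillin only if the fragment is translated
straight through to Bla-Omega — that is, if the insert is stop-free in the
reading frame imposed by the cloning cassette. Random fragmentation gives a
fragment 2 orientations × 3 junction phases × 3 length residues = 18 equally
likely cloning geometries, only one of which restores the native ORF
(1/18 ≈ 5.6%), so selection is essential and quantifying it matters.

`orfselect` implements the computational side of such a selection system:

| module | what it does |
|---|---|
| `orfselect.core` | cloning-context model, frame/stop-codon classifier, full-fusion translation |
| `orfselect.library` | sliding (1-bp-shift) in silico libraries, theoretical in-frame fractions, the 1-in-18 junction enumeration, the closed-form stop-free model (1 − p_stop)^⌊L/3⌋, random fragmentation |
| `orfselect.pipeline` | paired-end analysis: overlap merging → adapter trimming (edlib semi-global) → exhaustive mapping to the gene panel → frame classification with per-stage attrition |
| `orfselect.selection` | ampicillin-selection simulator with per-class survival, the adapter-deletion frame-correction leak, and colony sampling |
| `orfselect.simulate` | synthetic high-GC gene panels, adapter-ligated fragment libraries with ground-truth labels, and 2×250 paired-end reads |

## Worked example

Generate a synthetic 30-gene library at the study conditions (65% GC,
150–400 bp fragments, 10% 5'-adapter deletions), sequence it in silico, and
run the analysis pipeline:

```python
from orfselect import (SyntheticConfig, default_context, make_dataset,
                       run_pipeline)
from orfselect.io import write_fastq

ctx = default_context()
ds = make_dataset(SyntheticConfig(seed=1), ctx, out_dir="scratch/demo")
result = run_pipeline("scratch/demo/reads_R1.fastq",
                      "scratch/demo/reads_R2.fastq", ds.genes, ctx)
print(result.attrition)
print(round(result.open_fraction, 3))
```

prints

```
{'total_pairs': 10000, 'merged': 10000, 'trimmed': 9999, 'aligned': 9999, 'classified': 9999}
0.272
```

i.e. all 10,000 read pairs merged, adapters were located in all but one
read, every trimmed insert aligned to the panel, and 27.2% of aligned reads
are in-frame (stop-free in the cloning frame) — an *unselected* library,
far above the naive 5.6%
junction baseline because one forward phase of a stop-free coding sequence
is always open and high-GC sequence rarely hits a stop elsewhere. Simulating
ampicillin selection on the same clones and re-sequencing the survivors:

```python
from orfselect.simulate import make_reads, select_survivors
import numpy as np

survivors, _ = select_survivors(ds.constructs, ds.truth)
r1, r2 = make_reads(survivors, SyntheticConfig(seed=1), np.random.default_rng(2))
write_fastq(r1, "scratch/demo/sel_R1.fastq"); write_fastq(r2, "scratch/demo/sel_R2.fastq")
sel = run_pipeline("scratch/demo/sel_R1.fastq", "scratch/demo/sel_R2.fastq",
                   ds.genes, ctx)
print(round(sel.open_fraction, 3))   # -> 0.916
```

The selected library reads ~92% in-frame rather than 100% because clones
whose 5' adapter carries a 1–2 bp deletion can be frame-corrected in vivo
(they survive selection) yet are scored off-frame when re-sequenced against
the nominal adapter — the "frame-correction leak".

The same operations are exposed on the command line:

```bash
orfselect make-synthetic --out-dir syn --seed 5
orfselect insilico --ref syn/genes.fasta --length 100
orfselect pipeline --r1 syn/reads_R1.fastq --r2 syn/reads_R2.fastq \
    --ref syn/genes.fasta --out-dir out
orfselect select-sim --scenario scenario.json --replicates 10 --seed 2
```

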