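# Methods

## The frame model

A cloned fragment is *in-frame* (here: `cloning_frame_open`) when its
translation in the cloning frame — the reading frame imposed on the insert
by the upstream Bla-Alpha/adapter cassette, starting at codon position
`frame_offset` of the insert's first base — contains no stop codon
(TAA/TAG/TGA under the standard bacterial code; alternate NCBI tables are
accepted). The trailing partial codon is ignored: it cannot be a stop.

A second, stricter flag `fusion_viable` additionally requires the insert
length residue mod 3 to match `required_len_mod3`, the residue that keeps
the downstream Bla-Omega fragment in frame. The two are kept separate
because fixed-length in silico libraries (e.g. 100 bp, where 100 ≡ 1 mod 3)
have a nonzero in-frame fraction only under the stop-scan definition; the
stop-scan is therefore the default library metric, and the mod-3-aware flag
is reported alongside it. `native_frame` marks fragments that are
forward-strand *and* whose cloning frame coincides with the source gene's
codon frame — the 1-in-18 geometry.

Codons containing N are never counted as stops; instead the call is flagged
`ambiguous` and excluded from in-frame denominators by default, so
low-quality bases cannot bias fractions in either direction.

Coordinates are 0-based half-open on the reference forward strand
throughout; minus-strand fragments store their cloned (reverse-complemented)
sequence.

## Cloning context

The real cassette ligates a 34-mer TEV-site duplex at the 5' end and a
31-mer Gly-Ser-spacer duplex at the 3' end of each fragment; the published
material does not include the oligo sequences, and the vendor lengths
include ligation overhangs that are not retained in the reading frame. The
default `CloningContext` is therefore synthetic: a 33-nt 5' adapter encoding
Ser-Gly-Ser plus the TEV site ENLYFQG, a 30-nt (Gly4Ser)x2 3' adapter, and
short synthetic Alpha-tail / Omega-head flanks. All retained lengths are
multiples of 3, so the default cassette reads as a single contiguous frame
with `frame_offset = 0` and `required_len_mod3 = 0`. Every sequence is a
plain config field; real adapters can be supplied as JSON.

## Junction combinatorics and the stop-free model

`junction_configurations` enumerates the 2 × 3 × 3 = 18 equally likely
cloning geometries of a randomly sheared fragment (orientation, 5' phase,
length mod 3). Exactly one — forward, phase-matching, length ≡ 0 —
restores the native ORF: 1/18 ≈ 5.6%. The model deliberately ignores
internal stop codons; it is the naive geometric baseline.

The complementary sequence-composition model is
`analytic_stopfree_probability(L) = (1 − p_stop)^⌊L/3⌋`, with
`p_stop = Σ_stop Π p(base)` under i.i.d. bases. At 65% GC,
p_stop ≈ 0.025, so even a 300-bp fragment is stop-free in a fixed frame
with probability ≈ 0.08 — the reason high-GC fragment libraries contain far
more in-frame clones than 1/18.

## In silico libraries

Sliding libraries emit every window of a fixed length at a fixed shift
(default 1 bp) over every gene, on both strands by default (random
fragmentation clones both orientations; forward-only is a flag, since the
strand convention behind published theoretical values is not fixed).
Windows extending past a gene end are not emitted. Random fragmentation
draws a gene with probability proportional to its length, a length uniform
on the feasible part of the size window (default 150–400 bp, the
size-selection band), a uniform start, and a Bernoulli(1/2) strand.

## Sequencing pipeline

Stages, all pure functions with explicit thresholds (the original analysis
used third-party tools and published no thresholds; these defaults are
conservative substitutes and all configurable):

1. **Merge** (`min_overlap` 20 bp, `max_mismatch_rate` 0.1): mate 2 is
   reverse-complemented and every candidate overlap scored; the overlap
   maximizing matches wins (ties: lower mismatch rate, then longer
   overlap). Overlap disagreements take the higher-quality base, mate 1
   winning ties, which makes merging deterministic.
2. **Trim** (`adapter_max_errors` 3 per adapter): each adapter is located
   by semi-global (infix) edlib alignment; the leftmost optimal location is
   used for the 5' adapter and the rightmost for the 3'. 1–2 bp adapter
   deletions are absorbed and reported per read. If the 5' adapter is not
   found the reverse complement of the merged read is tried, making results
   independent of mate order.
3. **Map** (`min_identity` 0.85, `min_insert_len` 20): the insert is
   aligned against *every* panel gene on both strands (the panel is tens of
   genes, so the exhaustive search is exact and reproducible, unlike a
   heuristic mapper). Distance ties are broken by lexicographic gene id
   then lower start and flagged ambiguous.
4. **Classify**: the frame call is made on the trimmed insert from its
   first base (the cloning frame is a property of the construct, not of
   the alignment); the alignment contributes `native_frame`, per-gene
   counts and coverage breadth. The in-frame fraction is reported over
   aligned, unambiguous reads.

Attrition counts (pairs ≥ merged ≥ trimmed ≥ aligned ≥ classified) are part
of the result object.

## Selection simulator

`apply_selection` is binary per class: stop-free clones survive, off-frame
clones die, with probabilities configurable per class (the bench assay gives
growth/no-growth at an ampicillin step, not kinetics, so no dose–response
is modelled). Before survival draws, off-frame clones convert to the
`leak_corrected` class with probability `leak_rate` (default 0.10): clones
whose 5'-adapter deletion shifts the insert into an open frame. These
survive selection but are scored off-frame when re-sequenced against the
nominal adapter — both scoring views are reported, which is exactly the
mechanism that caps post-selection in-frame fractions below 100%. With
initial open fraction q and otherwise perfect selection the expected
post-selection open fraction is q / (q + (1 − q)·λ). `sample_colonies`
draws PCR-screen colonies multinomially (or hypergeometrically without
replacement).

## Synthetic data generator

The generator emulates the study conditions and its defaults are fixed at
them: 30 genes, 65% GC, 150–400 bp fragments, 2×250 reads, substitution
rate 10⁻³, 10% 5'-adapter 1–2 bp deletions (uniform position, length 1 or
2 equiprobable). Genes are built by *codon* sampling with stop codons
excluded — guaranteeing a stop-free native frame, like amplicons amplified
without their stop codon — with codons exponentially tilted by G+C count so
the expected base composition hits the GC target exactly (the tilt is
solved by root-finding). Gene lengths are multiples of 3 in 300–1500 bp.
Reads carry constant Q30 qualities: no downstream decision consumes
qualities except merge tie-breaking, so quality profiles are not modelled.
Ground-truth labels are computed on the pristine fragment before read
errors; `shifted_frame_open` additionally records openness in the
deletion-shifted frame, which is what decides leak survival in the
sequence-level selection (`select_survivors`).

What the generator does *not* emulate: real codon usage (frame-dependent
stop densities differ between genuine coding sequence and the tilted-codon
model, so synthetic theoretical fractions sit a few points below values
computed on real high-GC genes), PCR amplification bias, shearing physics,
indel sequencing errors, quality degradation, or chimeric inserts. Passing
tests therefore demonstrate correctness of the machinery and internal
consistency of the models, not agreement with any particular organism's
gene panel.

## Numerical and design choices

* Exhaustive edlib alignment replaces heuristic mapping; Biopython's
  PairwiseAligner is used in tests only, as an independent cross-check.
* Deterministic tie-breaks everywhere (merge: mate 1; map: gene id, then
  start; trim: leftmost/rightmost optimum) keep reruns bit-identical.
* All randomness flows through `numpy.random.Generator`; library
  generation, read simulation and selection draws take independent child
  seeds spawned from one seed.
* Problem sizes in the test suite and acceptance script (10,000-fragment
  libraries, 10⁵-draw Monte Carlo checks, shift-5 sliding libraries for the
  length-monotonicity sweep) were chosen to give sub-percent sampling error
  while keeping a full run to a couple of minutes on one CPU.

## Known limitations

* The adapter-deletion leak is modelled at the insert level: survival
  requires the deletion-shifted insert frame to be stop-free, ignoring the
  (GC-rich, stop-poor) shifted adapter/spacer codons and the downstream
  frame residue. This slightly overestimates leak survival.
* A deletion flush against the adapter–insert boundary is inherently
  ambiguous to any trimmer (the missing bases may be absorbed by matching
  insert bases); boundary calls can shift by 1–2 bp for such clones.
* Theoretical in-frame fractions on real gene panels require the real
  sequences as FASTA input (`orfselect insilico --ref ...`); the package
  ships none.
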