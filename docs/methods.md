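# Methods

## Model

The package models the α-globin cluster as a coordinate-addressed synthetic
reference (default: coordinates 158,001–184,600; 26,600 bp) carrying the
seven canonical cluster genes in order (ζ, ψζ1, ψα2, ψα1, α2, α1, θ) and the
three pairs of X/Y/Z homology boxes. All coordinates are 1-based inclusive
throughout the Python API; BED exports convert to 0-based half-open.

Structural alleles are lists of provenance segments — reference intervals or
undetected N runs — concatenated into a sequence. Unequal crossover between
a homology-box pair returns the reciprocal (deletion, triplication) product
pair: Z-box crossover gives -α3.7 / αααanti3.7, X-box crossover gives
-α4.2 / αααanti4.2. The HKαα allele is composed of three sections: the
αααanti4.2 junction segment, a special segment (an upstream region at
reference 171,116–171,235, a 22 bp undetected N run, and a downstream region
at 171,223–171,882, total 802 bp — the two published intervals overlap by
13 bp and are reproduced verbatim, not arbitrated), and the -α3.7 junction
segment. Functional α-gene counts per allele: αα 2, single deletions 1,
double deletions 0, triplications 3, HKαα 2.

## Generator realism and identifiability

The reference sequence is i.i.d. uniform A/C/G/T given a seed, with two
deliberate constraints:

1. **Paired homology boxes are byte-identical.** Crossover inside a perfect
   repeat is seamless, so the breakpoint within a box is unidentifiable —
   as in the real cluster. The breakpoint rule (box midpoint by default) is
   therefore a convention, and length conservation
   (|deletion| + |triplication| = 2·|αα|) holds for every offset.
2. **Splice points abutting unique sequence are microhomology-free.** The
   base just outside each special-segment edge is forced to differ from the
   base the neighbouring junction segment contributes at the same assembled
   position. With purely random sequence there is a 1/4 chance per edge of
   at least one base of chance microhomology, which makes the breakpoint
   genuinely ambiguous and the published coordinates unrecoverable for some
   seeds. Real assemblies report breakpoints up to microhomology; the
   synthetic generator instead makes the decomposition identifiable so
   coordinate recovery is exact for every seed.

Everything not published — gene and box intervals, --SEA/--THAI breakpoints,
all primers except the verbatim ZW-F/ZW-R pair — is synthetic and chosen
only so the published anchors (4.5 kb round-1 product; special-segment
coordinates and length) emerge from computation rather than being asserted.

## In-silico PCR

Primer binding allows at most one mismatch with an exact 3'-terminal
3-base match, on either strand; N never matches. Site search is vectorised
(numpy sliding windows) and verified in tests against a naive scanning
oracle. An amplicon is any convergent site pair on one template with product
length (5'-to-5' distance + 1) at most the assay cap (6,000 bp by default).
Allele specificity of gap-PCR is emergent from the cap: flanking primers are
too far apart on the intact allele and within range on the deleted one.
Gel observation merges products within 2 % relative size (comigration);
HKαα/αα and -α3.7/αα patterns then become indistinguishable, reproducing the
concealment phenomenon, and the caller treats such patterns as ambiguity
sets. The nested assay feeds round-1 amplicons — and only those — to round 2
and is positive iff both junction products arise from a single round-1
molecule, which is the cis proof; -α3.7 + αααanti4.2 in trans is negative.

## Calling and pedigree resolution

The screening library is the 7 alleles the study's assays can distinguish
(αα, -α3.7, -α4.2, --SEA, --THAI, αααanti4.2, HKαα; 28 unordered
genotypes). αααanti3.7 is constructible in the model and exercised in PCR
specificity tests but excluded from screening candidates, mirroring the
study's candidate space. Evidence integration is set intersection over
assays; ambiguity is preserved, never collapsed by priors. Pedigree
resolution is arc-consistency over (father, mother, child) triples with
atomic allele transmission (HKαα never splits); genotype sets shrink
monotonically to a fixed point. On tree-shaped pedigrees — including the
packaged study family — the result equals the brute-force joint-enumeration
closure, which is kept as a test oracle with explicit instance-size bounds.

## Decomposition and similarity

Local alignment is seed-and-extend: exact 15-mer seeds, ungapped X-drop
extension with match +1 / mismatch −2, N a hard stop. The noise model of
carrier sequences is substitutions plus undetected N runs, so gapped
alignment is unnecessary; the implementation is verified against Biopython's
`PairwiseAligner` local dynamic programming in tests. Segmentation anchors
on the two junction signatures (full homology box plus 50 bp unique flanks,
located with edlib infix alignment at ≤5 % divergence) and the principal N
run, then recovers each special-section boundary by anchored diagonal
extension from the gap edge, bridging an isolated substitution or interior N
run only when 12 exact diagonal matches follow. Identity is computed over
non-N columns only. Pairwise carrier similarity uses edlib global alignment
with N columns excluded from numerator and denominator; the shared-ancestor
flag is the minimum pairwise identity being at least 0.995.

## Numerical choices

- All randomness flows through `numpy.random.default_rng(seed)`; no global
  state. Identical seeds give identical references, carriers and hematology.
- Hematology simulation draws per-analyte Gaussians around class means
  anchored to the packaged family's records, with a default coefficient of
  variation of 0.04 (a modelling choice); zero CV returns the means exactly.
- Band merging averages comigrating product sizes and rounds to integers;
  pattern equality uses the same 2 % relative tolerance.

## Limitations

- The reference is random sequence, not GRCh38; --SEA/--THAI breakpoints and
  all primers except ZW-F/ZW-R are synthetic stand-ins, so band sizes other
  than the 4.5 kb round-1 product are internally consistent but not
  literature values.
- PCR is modelled combinatorially (binding + length cap); no thermodynamics,
  efficiency, or stochastic dropout. Hematology values are class-conditional
  draws, not a physiological model, and fetal records are absent by design.
- The severity predictor is a functional-gene-dose lookup with a β-trait
  overlay axis; it does not model nondeletional mutations or modifiers, and
  an HKαα homozygote prediction carries an explicit no-clinical-reports
  caveat.
- Arc-consistency is exact on tree pedigrees; on pedigrees with loops
  (e.g. consanguinity) the resolved sets are a sound over-approximation.
- Decomposition assumes the canonical section order and at least one
  detectable N run between the special sections; segmentation of sequences
  with two substitutions within 12 bp of each other near a section edge may
  truncate that section's recovered interval.
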