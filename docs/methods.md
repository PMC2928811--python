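# Methods

## The genetic design being emulated

The pipeline targets the classic livestock positional-cloning setting: a
monogenic recessive lethal mapped to a critical interval, an affected animal
homozygous for the mutant founder haplotype across the interval, and a
healthy, partially inbred carrier whose two interval copies descend from the
*same* ancestral chromosome — identical by descent — one copy ancestral,
one carrying the mutation. Re-sequencing the interval in the carrier should
show neutral founder-haplotype differences from the reference as homozygous
and exactly one heterozygous site: the causative mutation. The simulator
enforces this by construction (`simulate_haplotypes`): an ancestral
haplotype H with `n_neutral` variants, a mutant haplotype H\* = H + one
causal 1-bp coding insertion, case = H\*/H\*, carrier = H\*/H. The IBD
property (the carrier's haplotypes differ only at the causal site) is a
tested invariant.

## Synthetic-data model, and what it does not capture

**Reference and repeats.** The reference is i.i.d. random sequence at a
configurable GC fraction (default 0.42); repeats are random intervals with
exponential lengths placed until a target masked fraction is reached
(default 35%, trimmed to the target, merged). Real repeat families,
GC-coupled capture efficiency and assembly-quality structure are not
modelled; for the statistics the pipeline computes (masked/single-copy
totals, adjacency filtering) only the interval geometry matters.

**Genes.** `plant_genes` embeds intact ORFs — ATG start, stop end, no
internal stop, GT..AG introns, whole-exon CDS — into single-copy sequence,
writing the bases into the reference (the generated models must translate
cleanly in the reference frame, so the operation mutates the reference in
place). Gene bodies keep a 12 bp clearance from repeat edges so coding
calls cannot be consumed by the 10-nt repeat-adjacency filter. Gene 1
defaults to a fixed, constructed 545-codon CDS (`demo_frameshift_cds`) in
which a G inserted between CDS bases 363 and 364 leaves residues 122–123
unchanged under the shifted frame (Gly→Gly), changes residue 124 Ala→Gly,
and meets the first shifted-frame stop at mutant codon 165 — i.e.
`p.Ala124GlyfsX42`, a 164-residue truncated protein that keeps under 25% of
the 545-residue wild type. This is the worked frameshift example; the other
genes carry random ORFs (220–420 codons).

**Capture reads.** Depth is modelled as a per-1-kb-window lognormal
multiplier (σ = 0.3, unit mean) on the requested mean coverage, with
Poisson read starts per window and a `gap_fraction` of windows dropped
entirely — the simplest model that reproduces variable depth plus capture
dropout. Under the defaults this yields roughly 90% of bases at ≥4× for a
15× sample with 9% gap windows, matching the capture-performance regime the
pipeline is meant to exercise. Probe spacing and per-probe hybridisation
efficiency of real capture arrays are unknown and not modelled; the window
model is a stand-in. Reads carry their true haplotype and offset — there is
no alignment step (assembly/alignment is out of scope), so mapping error is
represented only by the optional duplication artifact: a 1%-diverged copy
of a chosen segment contributes an extra coverage-worth of reads there,
producing elevated depth and clusters of ~50% allele fractions (the
false-heterozygote phenomenon near segmental duplications). Sequencing
errors are i.i.d. substitutions (default 0.002/base); indel errors default
to zero so that indel pileup evidence stays interpretable. Base qualities
are not simulated.

**Pileup conventions.** A read supports an insertion at its anchor when it
covers the anchor base and at least one inserted base (then it counts once,
as the insertion allele); a read spanning a deleted base counts as a
deletion observation at that position. Allele counts therefore always sum
to depth. Columns above the 200× cap are subsampled to the cap with a
position-seeded hypergeometric draw, so capping is deterministic.

**Cohort.** The association cohort is genotype-level truth: affected
animals homozygous mutant, obligate carriers heterozygous except a
configurable number of phenocopy parents (wild type, flagged as having only
an unconfirmed affected-offspring record), unrelated animals heterozygous
with probability `carrier_rate` (default 0.032), other-breed controls wild
type. `table2_cohort()` is the fixed printed-structure screen
(16/36/309/75 animals, exactly 10 unrelated carriers); the default pipeline
report uses it so the association block is deterministic, while the sampled
generator is exercised separately.

Passing tests therefore show that the *method* — thresholds, cascade,
naming, association logic — behaves exactly as specified on data with the
study's structure; they cannot certify performance on real reads with
alignment artifacts, quality-dependent errors or reference bias.

## Caller decision rules and numerical choices

Decision order per column: depth 0 → no call; variant frequency ≥ 75% at
≥4× → homozygous variant; strictly between 25% and 75% at ≥15×
(genome-wide) or ≥10× (coding candidate evaluation) → heterozygous; variant
support at 1–3× → low-coverage flag; frequency ≤ 25% at ≥4× → homozygous
reference; otherwise no call (the uncertain 4–14× mid-frequency zone, which
the cascade sends to validation). The printed inequality directions are
followed literally: exactly 75% is homozygous, exactly 25% is reference.
The variant allele is the most frequent non-reference allele, ties broken
lexicographically (multi-allelic handling is otherwise undefined in this
calling style and this is a documented choice). Indel frequency uses reads
showing the event over depth at the anchor. The repeat-adjacency filter
excludes calls whose distance to a masked interval is ≤ 10 nt (boundary
inclusive, symmetric on both sides).

## Exclusion cascade

Case homozygous coding/splice calls are routed by control status:
identical strict homozygous call → excluded as shared; depth 0 → missing
coverage; 1–3× with the same variant → low-coverage support (counted with
the shared-homozygous exclusions in the printed-style summary, since the
supported genotype is homozygous mutant); relaxed-rule heterozygote →
candidate; anything else (homozygous-reference or uncertain control at a
case-homozygous site — a state that contradicts the IBD expectation) → a
separate `control_other` route. Every non-excluded route is re-genotyped by
the truth oracle (the Sanger stand-in): oracle-homozygous sites move to the
shared exclusion, oracle-heterozygous sites become confirmed candidates.
The five routes partition the case coding set at every stage (tested
invariant). Shared-homozygous exclusion uses the strict homozygous rule
(≥4×, ≥75%); whether a relaxed control threshold should apply there is
undefined in this calling style, and strict is the conservative choice.

## Association verdict

Perfect association is boolean exact concordance: all affected homozygous
mutant, no non-affected homozygous mutant, all obligate carriers
heterozygous — except that a wild-type obligate carrier whose only affected
offspring are flagged unconfirmed is recorded as a `phenocopy_suspect` and
does not break perfection (the phenocopy argument encoded as data). No
chi-square or exact test is computed: the claim under test is exact
concordance, so a p-value would be decoration. Allele frequency is reported
for the unrelated group at 1 decimal.

On frameshift arithmetic: `p.Ala124GlyfsX42` counts the stop at the 42nd
altered codon, i.e. 41 changed residues plus the stop; whether one says
"42 altered amino acids" (including the stop) or 41 (excluding it) is a
convention. The package reports the truncated length (164) and the fsX
index (42) and leaves both readings available rather than choosing.

## Pipeline and reproducibility

A master seed spawns one independent stream per stage
(reference, repeats, genes, haplotypes, reads per sample, pileup capping,
cohort), so toggling one stage never perturbs another's draws; identical
config + seed gives byte-identical outputs (no timestamps anywhere).
Configuration is a single schema-validated JSON document (unknown keys
rejected, seed mandatory). Default scale is a 120 kb interval — large
enough for ~50 neutral variants, five multi-exon genes and stable coverage
statistics, small enough that a full run takes well under a second — with
all sizes parameterised so interval-scale runs in the Mb range remain
possible. The end-to-end recovery suite runs 50 seeded full pipelines with
the control at 30× mean coverage (a round value at the scale of the ~27×
control coverage at a validated candidate site in the setting being
emulated) and requires the implanted causal insertion to be the sole final
candidate in every run; the corresponding failure mode — a heterozygous
site drifting above the 75% frequency bound in a low-depth window and being
excluded as shared — is a real property of threshold calling at modest
coverage, not of the implementation.

## Known limitations

- No alignment, so no reference bias, soft-clipping or mapping-quality
  effects; the duplication artifact is the only mis-mapping surrogate.
- Splice annotation is the ±2 nt canonical donor/acceptor window; no
  splice-strength scoring or NMD prediction.
- Insertion HGVS names are not 3'-normalised (the physical insertion point
  is reported); the parser accepts underscore and dash dialects.
- Single-base indels only in the default generator; the caller and
  annotator handle longer events but they are untested beyond that scale.
- The truth oracle is error-free; real validation assays are not.
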