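# Methods

This note documents the models, conventions and numerical choices behind
`pikkmap`, and what the synthetic generators do and do not emulate.

## Mutation catalog

Input tables are tab-separated mutation exports with one row per
(sample, mutation) call; cBioPortal header synonyms (`Hugo_Symbol`,
`Tumor_Sample_Barcode`, `Protein Change`, `HGVSp_Short`, …) are accepted.
Protein-change strings are classified by a deterministic grammar that
mirrors cBioPortal display categories:

* contains `*` or a frameshift marker `fs` → **truncation**;
* contains `del`/`ins`/`dup` without `fs` → **in-frame**;
* a single substitution `[A-Z][0-9]+[A-Z]` with two distinct standard
  residues → **missense**;
* anything else (splice notation, `X` targets, unknown grammars) →
  **other**, with no position assigned.

All positions are 1-based protein coordinates; genomic/transcript
coordinates are out of scope. Sample-level frequency counts a sample once
per gene regardless of how many mutations it carries, and the cohort size
is a required input because mutation exports omit unmutated samples.
Printed percentages use half-up rounding to one decimal. "Mutated residues"
default to missense records only — those are the positions mutated *to a
different residue*; the consequence filter is configurable because counts
including in-frame or other changes at a residue are a legitimate
alternative convention.

## Conservation

A residue is **conserved** when the identical amino acid occupies the
aligned column in at least one designated ortholog (strict identity; a
similarity mode based on positive substitution scores exists but is off by
default, matching the identity convention used when such calls are made by
manual inspection). Externally produced alignments (Clustal-Omega etc.) are
treated as authoritative when supplied; the built-in aligner is a global
pairwise Needleman–Wunsch/Gotoh with affine gaps for self-contained runs.

Aligner defaults: BLOSUM62, gap open 10, gap extend 1 (raw integer scale).
A gap run of length L costs `open + (L−1)·extend`. Traceback ties break
deterministically — diagonal, then gap-in-second-sequence, then
gap-in-first — so alignments are bit-reproducible. Percent identity is
reported under both conventions (identical columns over alignment columns,
and over the shorter ungapped sequence) because published "~X% identity"
figures rarely state their denominator; neither is treated as exact.

Residue correspondences are strictly monotonic position maps; mapping a
position aligned to a gap returns an explicit gap marker (`None`) rather
than silently skipping.

## Structure and solvent accessibility

PDB reading keeps the first MODEL only, drops HETATM/waters/hydrogens, and
for alternate locations keeps the highest-occupancy conformer (ties toward
altloc `A`). Unresolved (disordered) stretches are inferred from gaps in
author numbering and are first-class: position mapping reports them, burial
denominators exclude them. Author numbering is assumed to equal protein
numbering, with a per-chain integer offset for models where it does not;
no external residue-mapping service is consulted.

SASA is Shrake–Rupley with a 1.4 Å water probe and 960 sample points per
atom placed on a deterministic golden-spiral lattice — no RNG, so values
are bit-stable. Van der Waals radii (Å): C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80 (H 1.20, excluded by default); unknown elements raise unless a
fallback radius is passed. Relative SASA divides the residue sum by the
residue type's theoretical maximum (Gly-X-Gly-scale table shipped with the
package). A residue is **surface** when relative SASA ≥ 0.25 (configurable;
the underlying "visible on the surface" criterion is qualitative, so the
threshold is a modelling choice, and burial statements should be read as
robust to moderate threshold changes rather than as exact counts).

Distances default to Cα–Cα with a minimum-heavy-atom alternative, because
published distance figures rarely state the measured atom pair. Clusters
are single-linkage: connected components of the graph joining residue pairs
within the cutoff (default 24 Å, following the scale at which surface
residues mutated in one cancer type were described as clustering).
Dimer-aware analysis works per chain with SASA computed in the full
assembly, so interface residues correctly count as buried in the complex.

Bundled domain maps for ATM/ATR/Mec1 pre-fill only boundaries with a
published basis (ATM TRD3 2195–2475; the ~400-residue C-terminal kinase
domain of each protein); everything else is left to user-supplied
annotation files (TSV: name, start, end, 1-based inclusive). Domain lookup
returns the innermost (shortest) containing interval, so nested motifs
(TRD3 in FAT, PRD in kinase) behave naturally.

## Enrichment and overlap statistics

Fold enrichment of k of n tested residues in a domain occupying fraction
f of the protein is `(k/n)/f`. The headline p-value is the exact one-sided
binomial tail `P(X ≥ k)` with `X ~ Binomial(n, f)`; when integer domain and
protein lengths are given, the hypergeometric tail (drawing n residues
without replacement) is reported alongside. No multiple-testing correction
is applied by default — single-domain questions need none — but
Benjamini–Hochberg is available when scanning many domains. Tissue
specificity is reported descriptively (per-type residue sets and their
exact overlaps), not inferentially.

Fractions are printed to one decimal (139/336 = 41.4%); figures quoted
elsewhere as whole percentages (e.g. "42%") can therefore differ from the
package's output by up to half a point, and rhetorical roundings such as
"threefold" should be compared against the computed fold (2.76 in that
example), not asserted as exact values.

## Synthetic data: what it emulates, and what it does not

The generators produce the *shapes* of the real inputs with bookkept ground
truth; they are the basis of the end-to-end parameter-recovery tests.

* **Cohorts**: per-cancer-type strata with planted missense hotspot
  positions hit independently per sample, plus optional uniform background
  mutations drawn from a consequence mix. Defaults are the noiseless
  end-to-end condition: three strata of 70/70/60 samples (cohort 200), four
  hotspots each at per-sample probability 0.25 — enough that every planted
  hotspot is observed with overwhelming probability — and background rate 0,
  so recovered residue sets equal the planted sets exactly. Real exports
  differ in every distributional respect (mutational signatures, hotspot
  strength heterogeneity, multi-hit samples); passing recovery tests shows
  the bookkeeping and filters are correct, not that real hotspots are
  detectable at any given cohort size.
* **Orthologs**: substitutions are placed at unprotected sites until the
  realized identity (identical aligned positions over ancestral length) is
  within one percentage point of the target; protected cores are never
  substituted or deleted, and substitutions never reproduce the original
  residue. Optional indels write the true gapped alignment alongside. There
  is no substitution-rate matrix or phylogeny; the generator tests column
  bookkeeping, not evolutionary realism.
* **Toy structures**: Cα-only poly-alanine, so SASA truth reduces to
  geometry. The helix mode is an ideal α-helix trace (rise 1.5 Å, 100°
  per residue, radius 2.3 Å), all residues surface. The lattice-ball mode
  places Cα atoms on a cubic lattice filling a ball, with ground truth
  *buried iff all six axial neighbours are occupied*. The default 4.5 Å
  spacing was chosen analytically: with carbon + probe spheres of 3.1 Å,
  six axial neighbours occlude six disjoint caps totalling ≈82% of an
  interior atom's sphere (relative SASA ≈ 0.17 < 0.25), while a face
  residue with five neighbours keeps ≈31% exposed (≈ 0.29 ≥ 0.25), so the
  geometric truth and the 0.25 threshold agree with margin on every
  residue class; the ≥95% agreement requirement in the tests allows for
  sampling discretisation.

## Pipeline and problem sizes

The orchestrated run executes catalog → conservation → structure → stats,
writes one TSV per report plus `summary.json` (every summary number also
appears in a TSV), aborts with a stage-labelled error on failure, and skips
structure-dependent stages with a warning when no model is configured.
Re-running an identical configuration reproduces byte-identical outputs.

Test and verification problem sizes are chosen so the whole suite runs in
seconds while leaving the oracles meaningful: exhaustive alignment
enumeration up to length 8 (hundreds of thousands of paths), 100 random
clustering instances of ≤12 residues against graph-component oracles,
960-point SASA against closed-form sphere/cap formulas, and a 1200-residue
protein with a 250-residue toy structure for end-to-end recovery.

## Known limitations

* The aligner is pairwise only — no progressive MSA, profiles or HMMs;
  multi-species column logic relies on externally supplied alignments.
* No mmCIF parsing, superposition/RMSD, or electrostatics; no figure
  rendering.
* Quantities whose published values depend on external downloads or
  unstated measurement conventions (full-length ortholog identity
  percentages, specific inter-residue distances in deposited models,
  "visible on the surface" counts) are supported as operations with both
  conventions exposed, but are not asserted as exact values anywhere in the
  test suite.
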