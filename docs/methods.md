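# Methods

## Problem and scope

The package turns translated transcriptome sequences from several sea
anemone tissues (tentacles, column, mesenterial filaments, and their
combined assembly) into tiered, scaffold-classified, family-annotated toxin
candidates, compares their expression across tissues, and places the
peptide cohort on a neighbor-joining tree. External database searches,
read cleaning and assembly are out of scope: the inputs are amino-acid
FASTA files and a per-tissue count table, and the reference set for
annotation is a labelled FASTA supplied by the user (a synthetic exemplar
registry is bundled for self-contained runs).

## Screening

* **Tier cut.** `peptide` iff length ≤ 80 aa (inclusive), else `protein`.
  The cut is applied to the sequence as provided; no signal-peptide
  cleavage prediction is attempted, so precursor inputs are tiered as
  precursors.
* **Secreted-peptide flag.** length ≤ 200 aa and hydrophobic fraction
  ≥ 0.70, with the hydrophobic set H = {A,C,F,I,L,M,V}
  (Kyte–Doolittle-positive). The residue set and both thresholds are
  configurable; the fraction is evaluated over the whole sequence (a
  windowed variant was considered and rejected as under-specified — the
  whole-sequence form is the simplest consistent reading). `X` counts in
  the denominator, never the numerator. This is a *flag*, not a hard
  filter: it is one of several candidate-identification routes.
* **Peptide screen.** peptide tier and ≥ 4 cysteines — the
  disulfide-stabilised toxin candidate rule.
* **ORF finder.** Longest start-to-stop ORF over all six frames, standard
  code, ties broken by frame order (+1,+2,+3,−1,−2,−3) then position;
  ORFs under 30 nt (configurable) are ignored and an input with none
  yields an empty, flagged result.

## Cysteine scaffolds

The canonical pattern writes consecutive cysteines with spacer *s* as `CC`
(s=0), `CXC` (s=1), `CXsC` (2 ≤ s ≤ 3) and `C-C` (s > 3), merging shared
`C` glyphs left to right. The s > 3 ⇒ `-` threshold is the only assignment
consistent with the five classic family patterns (the Kunitz scaffold
shows `CX3C` next to `-` spacers). `X` is an ordinary spacer residue. Zero
cysteines give a distinct `no-scaffold` marker rather than an error.

Categories are the Roman numeral of the cysteine count; subcategories are
run-local 1-based lexicographic ranks of the distinct patterns within a
category (no external subcategory order exists, so the rank is defined per
cohort and stated as such). The census reports per-category counts and
percentages to two decimals.

Family templates (ShKT `C-C-C-CX3CX2C`, β-defensin `CXC-C-C-CC`,
Kunitz-type `C-C-C-C-CX3C`, EGF-like `C-C-C-CXC-C`, ICK `C-C-CC-C-C-C-C`)
match either exactly or *relaxed* — ignoring the lengths inside `CXnC`
tokens — because homologs vary short-loop lengths; exact matches always
rank first. Disulfide connectivity is returned verbatim from the template
(ShKT C1–C6/C2–C4/C3–C5; β-defensin C1–C5/C2–C4/C3–C6; Kunitz
C1–C6/C3–C5/C2–C4) and never invented: a cysteine-count mismatch or a
family without an established pattern yields "no prediction" with a
reason.

## Family annotation

Needleman–Wunsch global alignment under BLOSUM62 with affine gaps (open
−10, extend −1; a gap of length L costs −10 −(L−1)), delegated to
Biopython's `PairwiseAligner` with its deterministic first-optimal
traceback; an independently coded Gotoh DP serves as the scoring oracle in
the tests. Percent identity uses matches / columns with terminal gap
overhangs excluded from the denominator by default (`mode="core"`); the
all-columns denominator is available as `mode="all"`. The published
identity figures this models were produced by heterogeneous tools with
unstated conventions, so the denominator is an explicit, documented choice
here. `X` never counts as a match.

A query's best reference is the highest identity (ties: higher alignment
score, then lexicographic reference id). Identity ≥ 75 % transfers the
family label; below 75 % (strict) the call is "unknown". The bundled
reference registry is a *synthetic* exemplar set generated from the family
templates (one prototype per family, labelled `synthetic` in the filename
and headers); users annotating real data should supply real curated
references via `--reference`.

## Expression

TPM: `rate_i = count_i/(length_i/1000)`, `tpm_i = rate_i/Σrate × 10⁶` per
tissue; an all-zero tissue yields an all-zero column and is flagged.
Presence is strict `TPM > min_tpm` with `min_tpm = 0` by default (the
detection rule behind per-tissue presence lists is a configuration choice,
not a fact of the data). The sharing report decomposes 2–4 named sets into
exclusive Venn regions, pairwise overlaps and the common-to-all member
list. Top-N ranks by descending TPM with lexicographic tie-breaks; family
level sums member TPMs (sums, not means, to represent a family's overall
transcriptional output). The differential flag is
`|log2((a+1)/(b+1))| > 2` — base 2 with pseudocount 1 made explicit since
the bare "|LogFC| > 2" form underdetermines both.

## Phylogenetics

* **Distances.** p-distance on amino acids with *pairwise deletion*:
  columns with a gap or `X` in either member of a pair are removed for
  that pair; a pair with fewer than 50 % usable columns is undefined. A
  Poisson-corrected variant (−ln(1−p)) is available behind a config enum;
  p-distance is the default.
* **The 50 % figure** admits a second reading — a site-coverage cutoff
  applied alignment-wide before distances. Both are implemented:
  `p_distance` applies the per-pair rule, and `site_coverage_filter` drops
  columns with < 50 % residue coverage. The pipeline applies the site
  filter before distances because a star-shaped guide alignment of many
  dissimilar families otherwise accumulates enough gap columns to push
  *every* pair under the per-pair cutoff; taxa still undefined afterwards
  are pruned greedily and reported.
* **NJ.** Saitou–Nei: join the pair minimizing Q = (n−2)d_ij − r_i − r_j,
  ties broken by (smaller i, smaller j); branch lengths from the rate
  equations with negatives clamped to 0. Exact on additive matrices
  (property-tested against the generating topology on random additive
  trees, and cross-checked against dendropy's NJ on a generic matrix).
* **Bootstrap.** Column resampling with replacement, B = 1000 by default,
  seeded; each successful replicate's NJ bipartitions are tallied against
  the original tree's internal edges, and support = % of successful
  replicates. Replicates with an undefined pair are skipped and counted in
  a diagnostics field (counted + skipped = B).
* **Guide alignment.** Center-star over pairwise global alignments
  ("once a gap, always a gap"), with the center maximizing summed pairwise
  identity. It exists so the pipeline runs end to end without external
  aligners; for publication-grade trees supply a proper MSA via
  `--alignment`.

## Synthetic study generator

Defaults define the study conditions: five family cohorts (ShKT,
β-defensin, Kunitz-type, EGF-like, ICK) of 25 mature peptides each,
derived from one prototype per family by substituting non-cysteine
residues at rate 0.10 (cysteines fixed, substitutions never introduce
cysteines, so the scaffold is invariant); 20 % scaffold-free decoys
(uniform composition, < 4 cysteines, 30–70 aa); precursors = M-initial
hydrophobic-rich 20-aa signal + 0–30-aa pro-region + mature domain;
per-tissue presence masks (each tissue kept w.p. 2/3, at least one
tissue); negative-binomial counts with mean 50 and dispersion 5
(over-dispersion being the norm for RNA-seq counts — the choice of NB is a
modelling decision, no noise model being dictated by the data format).
`-` spacers draw uniformly from 4–12 residues, shrunk minimally (never
below 4) when needed to keep peptide-family matures ≤ 80 aa.

What the generator does *not* emulate: assembly artefacts (chimeras,
fragmentation), sequencing error, alignment-induced length variation
beyond substitutions (no indels within cohorts), phylogenetic structure
within a family beyond star-shaped divergence from one prototype, and
realistic family-size imbalance. Passing the recovery tests therefore
shows the pipeline's logic is correct under clean, well-separated
conditions; it does not certify recall on real assemblies, where
fragmented precursors and indel-rich homologs will lower identity scores.

## Numerical and design choices

* Tie-breaks are deterministic everywhere (alignment traceback, NJ pair
  choice, ranking by lexicographic id) so fixed-seed reruns are
  byte-identical.
* TPM conservation is exact to ≤ 0.5 per 10⁶ by construction; census
  percentages are rounded half-even to 2 decimals and sum to 100 ± 0.02.
* `mutate` with cysteine preservation draws substitutions from the 18
  non-identical, non-cysteine residues; without preservation, from the 19
  non-identical residues.
* The dataset tag `combine` is first-class (a combined assembly is its own
  dataset); a helper derives it as the union only when absent.
* Bootstrap support uses successful replicates as the denominator; the
  skip count is always reported alongside.
* Problem sizes in the acceptance script (156-sequence default fixture,
  200 additive-tree trials, 1000 bootstrap replicates) are the package's
  default study conditions and complete in seconds.

## Known limitations

* The center-star guide MSA inflates gaps on large, heterogeneous inputs;
  the pipeline's site-coverage filter mitigates but does not remove this.
* Template-based connectivity prediction is lookup only; no structural
  inference.
* The percent-identity denominator convention can shift identities by a
  few points relative to other tools on overhang-heavy pairs.
* The reproduction mode parses user-supplied supplementary tables
  defensively (sequence column sniffing, presence-column name matching);
  unusual layouts may still require manual column renaming.
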