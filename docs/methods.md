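# Methods

`rbprofiler` implements the computational side of host-range profiling for
lactococcal *Skunavirus* phages: classifying receptor-binding proteins (RBPs)
by their head domains, visualising the classification as a distance tree,
quantifying phage and RBP-group abundance from virome read mappings, and
scoring fluorescence binding assays of GFP-RBP fusions against lactococcal
strains of different cell-wall polysaccharide (CWPS) types.

## Head domains and pairwise comparison

A *Skunavirus* RBP has a conserved N-terminal shoulder/neck region and a
variable C-terminal head domain (~110 residues) that binds the host CWPS.
`extract_head_domain` takes the C-terminal `head_length` residues (default
exactly 110; sequences shorter than the window are used whole with a
warning).

Pairs of head domains are compared by affine-gap global (Needleman–Wunsch)
alignment using BLOSUM62 with gap open −11 and gap extend −1 (a gap run of
length L costs `open + (L−1)·extend`), backed by Biopython's
`PairwiseAligner`. Global alignment with identity/coverage thresholds is
used rather than local alignment with E-value cut-offs because head domains
are short, near-equal-length windows: E-value calibration depends on a
database size that has no meaning for thresholded pairwise comparison. The
unknown residue `X` scores 0 against everything and never counts as a
match.

From one optimal alignment we report

* **identity** = 100 · matches / aligned columns, where a column counts
  only when both sequences carry a residue (terminal and internal gap
  columns are excluded from the denominator);
* **coverage** of each sequence = 100 · aligned columns / ungapped length,
  and the pair-level coverage is the minimum of the two — a symmetric,
  conservative reading of "identity across 90% of the head domain".

Traceback is deterministic; the input pair is canonicalised by
(id, residues) before aligning so that identity and coverage are invariant
under argument swap.

## Groups and subgroups

The two-tier classification rule is:

* **group** — members share ≥ 50% identity across ≥ 90% of the head domain
  with at least one other member. Groups are the connected components
  (single linkage) of the thresholded graph; singleton components are
  reported as `ungrouped` rather than dropped. Single linkage is the
  default because observed groups combine a tight identity core (~82–95%)
  with pairs near the 50% floor, which a complete-linkage rule would split;
  complete linkage is available behind a flag for sensitivity analysis.
* **subgroup** — *all* members of a subgroup share ≥ 65% identity. That
  universally-quantified rule is exactly complete-linkage clustering on
  distance 100 − identity cut at 35. The all-pairs property is asserted on
  every run. Subgroup letters are assigned only when a group actually
  splits; cohesive groups carry no letters.

Labels are deterministic: groups are numbered I, II, … by descending size
with ties broken by the lexicographically smallest member id, and subgroup
letters follow the same convention, so relabelling is invariant under input
permutation.

`conserved_residue_report` aligns each head to a reference RBP and reports
the residue homologous to chosen reference positions (e.g. the
sugar-binding-crevice residues Trp 144, His 232, Asp 234 and Arg 256 of the
phage p2 RBP), flagging positions conserved across all heads.

## Distance tree

The tree is for visual grouping only. Distance = 100 − identity (a
p-distance analogue; no model correction, because the quantity the
classification thresholds is raw identity). Trees are built by canonical
neighbor joining with the Q-criterion; ties are broken on the
lexicographically smallest pair of node labels (a node is labelled by the
smallest leaf beneath it), making the topology independent of input order.
Negative branch-length estimates — an NJ artefact on non-additive input —
are clamped to 0 with a warning. On additive input the tree is exact (leaf
path lengths reproduce the input distances to ≈1e−15, verified against
trees with known branch lengths). Output is Newick with 6-decimal branch
lengths; no bootstrap support is computed, since a column bootstrap would
require a multiple-alignment stage that pairwise-distance NJ deliberately
avoids.

## Virome abundance

Alignment records come from plain SAM (one primary alignment per read;
secondary/supplementary records are skipped). Percent identity is derived
from the NM edit-distance tag as 100·(aligned − NM)/aligned; mapped records
without NM are rejected. Aligned read length counts CIGAR M/=/X/I
operations; reference span counts M/=/X/D.

Filters are inclusive at the threshold. Two presets mirror the profiling
workflow: genome mode (identity ≥ 80, aligned fraction ≥ 50) for relative
abundance per phage genus, and contig mode (identity ≥ 86, aligned ≥ 95,
covered fraction ≥ 55) for RPKM of representative RBP-group sequences.

Relative abundance uses a length-normalised read-count estimator:
`weight(category) = Σ_refs kept_reads/length`, category percentages are the
weight shares rescaled by the kept fraction, and unmapped-or-filtered reads
form an `unmapped` row so the table sums to exactly 100. This is a
documented simplification of coverage-based estimators whose internal
trimming rules are tool-specific; the filter semantics are reproduced
exactly. `RPKM = kept_reads / ((length/1000)·(total_kept/10⁶))`, with
references below the covered-fraction floor reported as 0 and flagged.
Covered fraction is computed by interval union (verified against a per-base
boolean-array recount).

## Binding assays

Raw plate fluorescence is normalised to fluorescence units (FU):

    FU = max(0, (raw − control_mean) / OD600)

where `control_mean` averages the RBP's protein-only control wells
(per-RBP controls assumed; a per-plate scheme reduces to the same
computation). Negative values are clamped to 0 and flagged — a reading
below the no-cell control is noise. FU is scale-invariant in the score
(multiplying all raw readings by a constant cancels) and homogeneous of
degree −1 in OD.

The **relative binding-affinity score** of a strain is
100 · mean FU(strain) / mean FU(optimal host), the optimal host being the
strain with the highest mean FU across replicates (ties to the smallest
strain id). An RBP whose means are all zero is reported as `no_binding`
with undefined scores rather than an error. Strain pairs are compared with
Welch's unequal-variance two-sample t-test on replicate FU (a standard
choice for small plate replicates with heterogeneous variance; no
multiple-testing correction by default, matching per-comparison reporting —
both configurable). Degenerate zero-variance pairs report p = 1 when the
vectors are identical and p = 0 with a flag otherwise.

## Synthetic data

The generators produce inputs with the structure each stage assumes, with
ground truth for recovery tests. They are pure functions of spec + seed.

* **Families** (`FamilySpec`): one random 110-mer ancestor per group;
  members derive by point substitutions (uniform over the 19 alternatives;
  no indels by default, since the classified statistic is identity and
  indels would only complicate coverage calibration). Substitution counts
  are calibrated to the target bands and every candidate group is
  *measured with the package's own aligner* and rejection-resampled (cap
  1000 attempts; exceeding the cap raises instead of silently violating a
  band). Defaults: within-group identity 85–95% (the observed typical
  band), between-group ≤ 35%, and cross-subgroup identity 53–62% — the
  cross-subgroup band must lie strictly between the 50% group floor and
  the 65% subgroup floor, since subgroups are only distinguishable when
  their cross identities fall below 65 while staying above 50.
* **Plates** (`PlateSpec`): sample wells read
  `background + od·gain·affinity + N(0, 0.05·signal)`; controls read
  `background + N(0, 0.05·background)`; OD uniform in 0.4–0.7 (mid-log
  harvest), 3 replicates, 3 controls. Defaults put peak FU near 3×10⁵,
  the magnitude observed in real assays. Truth scores are
  100·affinity/row-max.
* **Reads** (`ReadSimSpec`): category from the true weights, reference
  within a category proportional to length, start uniform; per-read
  identity and aligned fraction from a pass/fail mixture bracketing the
  filter thresholds with a 2-point margin (so integer rounding of edit
  distance and aligned length cannot flip a filter outcome). Records are
  written as plain headerful SAM so the real reader is exercised. The
  default layout uses equal-length references, under which the
  length-normalised estimator's expected category shares equal the
  generating weights exactly; with strongly unequal reference lengths
  inside a category the two notions of "abundance" diverge and the truth
  table's weights should be interpreted as per-reference abundance.

What the generators do **not** emulate: sequence-evolution realism (no
rate heterogeneity, codon structure or realistic indels), optics beyond
additive Gaussian noise, multi-mapping reads across near-identical
genomes, or dereplication of assembled RBP sets. Passing recovery tests
therefore demonstrates correctness of the computations under the stated
statistical assumptions, not robustness to every artefact of real viromes.

## Problem sizes and verification

The shipped verification (tests and `scripts/acceptance.py`) uses sizes
chosen to exercise every code path while staying desk-scale: 200 random
short pairs against exhaustive alignment enumeration; 100 random matrices
(n ≤ 12) against a depth-first component oracle; 20 family seeds of 5
groups × 8 members (one group split 4+4) for label recovery (ARI); 50
additive 5-leaf matrices for NJ; 20 seeds × 10,000 reads for abundance;
100 plate seeds for binding recovery; plus parameter-default and CLI
byte-determinism checks. All verification quantities are recomputed at run
time; none are stored.

## Known limitations

* The published group labels I–XI for the real 332-RBP dataset are not
  reproduced: that requires the deposited sequence archives and the
  historical label assignments, neither of which this package bundles.
* One optimal alignment is reported per pair; identity can differ by a
  fraction of a percent between co-optimal tracebacks. The grouping rule's
  thresholds are far from the identity bands the generator produces, so
  this does not affect recovery.
* The relative-abundance estimator is length-normalised read counting, not
  a trimmed-coverage estimator; see above.
* NJ emits no support values by design.
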