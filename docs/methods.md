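# Methods

This note records the models implemented in `covscan`, the conventions and
numerical choices they rest on, what the synthetic-data generators do and do
not emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Covariation statistics

All statistics operate on the *analyzed* columns of an alignment: those with
no gap character in any sequence. The gap policy is strict — a single gap
excludes the column — because a gap is an explicit statement that no
homologous residue exists for some family member, and every statistic below
assumes the column's residues are positionally homologous. Columns are
0-based internally; every user-facing report is in 1-based alignment
coordinates.

**Entropy and MI.** Column entropy is the plug-in (maximum-likelihood)
Shannon entropy in bits; base 2 is chosen so that a two-residue 50/50 column
scores exactly 1 bit. No pseudocounts and no sequence weighting are applied
anywhere. `MI(i,j) = H(i) + H(j) − H(i,j)`; tiny negative values from
floating-point cancellation are clamped to 0 (MI is analytically
nonnegative). Ambiguity codes (B, Z, X, ...) are kept and counted as extra
symbols rather than dropping sequences, which would silently change the
alignment depth; their presence is flagged with a warning.

**Product correction.** `MIp(i,j) = MI(i,j) − MIbar_i·MIbar_j / MIbar`
subtracts a per-pair estimate of the background MI contributed by shared
phylogeny, where `MIbar_i` is the mean MI of column *i* with all other
columns and `MIbar` the mean over the upper triangle (each pair counted
once). A fully conserved alignment has `MIbar = 0` and no signal to
correct; this raises a degenerate-alignment error rather than returning
zeros, because downstream standardization would otherwise divide by zero
silently.

**Zp.** MIp standardized over the upper triangle. The *sample* standard
deviation (ddof = 1) is used here and in every other standardization; the
choice is a convention and is mirrored exactly in the brute-force oracles
the tests compare against. Spread indistinguishable from zero at floating
precision (≤ 1e-12 relative to the data scale) is treated as degenerate.

**Position-wise Z and Zpx.** `Zx_i(j)` standardizes `MIp(i,·)` within row
*i* (off-diagonal entries). The pair statistic is the signed root of the
product: `Zpx = sqrt(Zx_i(j)·Zx_j(i))` when both factors are nonnegative,
else `−sqrt(|product|)`. The square root puts Zpx on the same scale as Zp;
the sign convention ensures a pair that is *below* both positions' means
(product positive, both factors negative) cannot rank as strong
covariation. A position whose MIp row is constant — typically a fully
conserved column, whose MI with everything is 0 — has no defined Zx. The
operation-level function raises a degenerate-position error naming the
column; the fitted model instead assigns NaN to that position's Zpx/ΔZp
scores and warns, so one conserved column does not abort a whole-family
analysis (Zp remains defined everywhere).

**ΔZp.** For each position *i*, its Zp values with all partners are sorted
descending (ties broken by ascending partner index, for determinism) into a
list `L_i`. The directional score of the pair ranked *k* is
`(L_i[k] − L_i[k+1]) / IQR_i`; the last-ranked pair, having no successor,
scores 0 (the minimal-evidence value — every pair must receive a score).
`IQR_i` is the 75th minus 25th percentile of `L_i` under the
linear-interpolation ("type 7") quantile definition, with no additional
scaling constant; this convention is fixed here, documented, and used
identically in the naive oracle the tests compare against exactly. The pair
score is the larger of its two directional scores, since either position's
list can provide the evidence that the pair stands clear.

**Residual cross-check.** The residual construction regresses `MI(i,j)` by
OLS on `(MIbar_i + MIbar_j)/2` across all pairs and feeds the residuals
through the same position-wise Z and signed-root product as Zpx. It is an
independent route to essentially the same quantity — both subtract a
background estimate that is (near-)linear in the positions' mean MI — and
the acceptance suite verifies the near-identity regression between the two
product statistics (slope within [0.99, 1.01], R² ≥ 0.999) on a deep
simulated background. The identity is regime-dependent: it is tight when
the background MI is dominated by shared phylogeny and the per-pair
finite-sample MI bias is homogeneous. At depth 150 the plug-in MI bias
(which grows with the number of residue types each column uses) varies
enough across pairs that the product and linear corrections separate
measurably (R² ≈ 0.98 with a 3-fold rate spread); at depth 300 with
homogeneous per-position rates the identity is recovered to R² ≈ 0.999.
The acceptance check therefore runs on a 300 × 120 simulation with rates
drawn from U(0.03, 0.07).

**Pair reports.** Significant-pair selection applies a score cutoff
(default 4.5) and a minimum sequence separation (default 10 positions,
measured in original alignment coordinates — close pairs are trivially in
contact and uninformative). Ties are broken by (smaller i, smaller j).

## Local covariation screen

The screen computes the mean pairwise Zp over sliding windows of `width`
(default 6) consecutive analyzed columns, together with the mean entropy of
the member columns. Windows never span an excluded (gapped) column: they
slide within maximal runs of consecutive ungapped columns, so a window
always covers a contiguous stretch of the original alignment and never
mixes the non-homologous contexts on either side of an indel. The window
start is reported at the original coordinate of its first member column.
Mean entropy is stored positive; plotting it negated below the Zp trace is
a rendering convention, not a storage one.

Thresholds: a window with mean Zp ≥ 2.5 warrants investigation; a family
with ≥ 5 such windows is flagged as probably containing a systematic
misalignment. Both values are exposed as parameters and as CLI flags.

## Shift injection

`inject_shift` emulates a registration error. Exactly
`round(fraction × depth)` sequences are chosen uniformly at random (a
deterministic count rather than per-sequence Bernoulli trials, so that a
given fraction always means the same number of rows); each moves its
segment residues one column left or right with equal probability. At the
segment boundary, the vacated cell is filled with the adjacent flanking
column's residue — mimicking a real registration error, where flanking
residues bleed into the misassigned region — and the residue pushed off the
other end leaves the segment. Because that terminal residue is genuinely
lost from the alignment, the manifest records it per shifted row, which
makes `revert_shift` an exact inverse. The segment must be gap-free and
must leave at least one flanking column on each side.

`build_block_experiment` prepends the two didactic constructions to a
background alignment. Unshifted: `block_width` identical conserved columns
plus an all-gap spacer column (the spacer is excluded by the gap policy;
the block columns are analyzed, carry zero entropy and hence zero
covariation). Shifted: a `block_width + 1`-column block where half the
rows carry the residues left-aligned with a trailing gap and half carry
them right-shifted with a leading gap; the middle `block_width − 1` columns
are gap-free, each holding two residue types at exactly 50/50 in perfect
lockstep — 1 bit of entropy and 1 bit of MI per pair, the worst-case
alignment artifact.

## In-silico evolution with group coevolution

A single root sequence (uniform over the 20 amino acids) evolves in
discrete steps. Per step: every position of every lineage substitutes with
its per-position probability; every lineage speciates (duplicates) with
probability 0.05; the run stops once the population reaches the target
depth and subsamples exactly that many lineages. Replacement residues are
uniform over the 19 alternatives. Within a designated group, a base
substitution in any member triggers each *other* member to substitute with
probability `p_co` in the same step; triggers do not cascade within a step
(the non-recursive reading — a triggered substitution does not itself
trigger).

Per-position substitution probabilities are drawn once per position from
U(0.01, 0.03). Calibration reasoning: with speciation at 0.05 a run to
depth 150 lasts on the order of 100 steps, so this interval puts roughly
one to three expected substitutions on each root-to-leaf path — columns
informative but not saturated. Wider intervals reaching 0.1 drive
high-rate columns to near-maximal entropy (every residue appearing, column
pairs carrying no phylogenetic structure) and make the finite-sample MI
bias strongly heterogeneous across pairs, which is not what curated protein
families look like. All constants are exposed as parameters, including
per-position `rate_overrides` (used to build conserved segments, e.g. a
catalytic core, by pinning rates to 0.001).

What the generator emulates: a range of per-column conservation, background
covariation from genuinely shared ancestry, and group-constrained
coevolution with a known truth table. What it does not emulate: realistic
substitution matrices (BLOSUM/WAG preferences), indels (output alignments
are gap-free unless a block construction adds gaps), rate variation over
time, or paralog contamination. Consequently, passing tests demonstrate
that the statistics behave as designed under phylogenetic background and
planted signal — not that their absolute scores on real families will match
the simulated ones. The group-coevolution sweep in particular reproduces
the qualitative structure robustly (pairwise groups outscore intermediate
groups of 4–5, which outscore groups of 10, for Zp, ΔZp and Zpx; the
rank-gap and position-relative statistics suppress intermediate groups far
more strongly than Zp), but the absolute mean Zp of intermediate groups is
sensitive to the simulator's unprinted constants: at `p_co = 0.95` a group
member's effective substitution rate scales roughly linearly with group
size, so intermediate-group columns saturate and their scores cap near 4
in this calibration regardless of how the remaining constants are set.

## Contact benchmarking

Contacts are defined on heavy atoms: two residues are in contact when any
pair of their non-hydrogen atoms lies within 6.0 Å (first PDB model, first
altloc conformer, waters and hetero groups excluded; chain selectable).
Alignment columns map to structure residues through the structure's own
sequence row in the alignment: its k-th non-gap character corresponds to
the chain's k-th residue, and columns whose aligned letter disagrees with
the structure's residue type are reported and dropped. Sequence separation
for benchmarking is measured in alignment coordinates, where the
statistics live.

Top-n accuracy reports, for n = 1..20, the fraction of the n highest-ranked
pairs in contact, after the 10-position separation filter; ranking ties are
resolved by the stable order of the input (pair index), and the convention
is documented because it can move a boundary pair in or out of a small n.
The accuracy-cutoff search returns the lowest score threshold whose
retained pairs reach the requested contact fraction (default 0.8), scanning
every distinct score; unattainable accuracy returns an explicit no-cutoff
sentinel rather than an arbitrary value. Overlap analysis partitions
per-method retained pair sets into all Venn regions with total and
in-contact counts.

Family curation criteria: a structure present; depth of at least 126
sequences (a literal reading of "more than 125"); at least 50 ungapped
positions; and the covariation-information check of at least L/10 pairs
with Zp ≥ 4.5, L being the alignment width.

## Problem sizes and determinism

Simulated experiments default to 150 sequences × 60 columns with 10
seeds/replicates — large enough for stable Zp fields (standardization over
~1,800 pairs), small enough that the whole acceptance script completes in
seconds. The residual-identity check uses 300 × 120 for the reasons above.
All randomness flows through explicit integer seeds (numpy
`default_rng`/`SeedSequence`); identical seeds give byte-identical outputs,
and the CLI writes a run manifest (inputs, parameters, seed, version)
alongside every result.

## Known limitations

- Plug-in MI is biased upward at finite depth, and the bias varies with
  how many residue types the columns use; none of the statistics correct
  for it (by design — the corrections target phylogenetic background, and
  standardization absorbs a homogeneous bias). Alignments below ~125
  sequences are flagged by the curation filter rather than rescued.
- No sequence weighting: heavily redundant families will overweight their
  dominant clade.
- The misalignment screen detects *systematic* shifts shared by a
  subpopulation; a shift in a single sequence is diluted by depth and
  generally invisible. Elevated local Zp can also reflect genuine
  secondary-structure covariation, which is why flagged windows warrant
  investigation, not automatic removal.
- Stockholm/FASTA only; mmCIF structures are out of scope, as is any
  automated repair of flagged regions.
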