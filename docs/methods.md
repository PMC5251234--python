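# Methods

## Model and assumptions

The package compares RNAs by their secondary structures without aligning
them. The representation is a deterministic, invertible encoding of
(sequence, pairing state): each base is annotated as paired or unpaired
(the 8-symbol characteristic alphabet), each symbol contributes three
vertical ±1 unit steps, and the cumulative sum of the 3N steps is the
TV-curve. Because the symbol → step-triple map is a bijection, no two
distinct (sequence, structure) pairs share a curve, and editing one base
changes exactly three consecutive steps — the encoding is local.

The underlying structural model is a single nested secondary structure per
RNA: pseudoknots, base triples and structure ensembles are out of scope.
When a structure is supplied it is taken at face value; otherwise a
folding backend predicts one.

### The C′ step triple

Published tabulations of the 8-symbol step map assign the same pattern
(+1, −1, −1) to both G and C′ while simultaneously asserting the map is
one-to-one. Seven symbols have unambiguous patterns; the eight sign
triples minus those seven leave exactly one unused pattern, (−1, −1, −1),
which this package assigns to C′. This is the unique resolution consistent
with bijectivity, and the encoding module asserts it at import time.

## Folding backends

* **rnafold** — shells out to Vienna `RNAfold` with tool defaults and
  returns the MFE structure (energy annotation discarded). Selected
  automatically when the executable is on PATH.
* **nussinov** — a maximum-base-pairing dynamic program over
  {AU, UA, GC, CG, GU, UG} with hairpin loops ≥ `min_loop` = 3 (the
  standard steric minimum). This is a combinatorial model, not a
  thermodynamic one; it is the deterministic, dependency-free default for
  the test surface, and its structures can differ from MFE structures.
  The traceback tie-break is fixed (prefer leaving the left end unpaired,
  else pair it with the smallest admissible partner), so output is unique.
  Verified against exhaustive enumeration of all nested pairings.

## Similarity parameters

| parameter | default | meaning |
|---|---|---|
| `levels` (L) | 4 | wavelet decomposition depth |
| `wavelet` | haar | family name (PyWavelets), periodized orthonormal transform |
| `weights` | uniform 1/(L+1) | per-level weights: approximation, then details d₁…d_L; auto-normalized |
| `signal_kind` | cumulative | curve ordinates y₁…y₃ₙ; `steps` selects the raw ±1 signal |

Choices made where the design was genuinely open:

* **Wavelet family.** Haar is the default: it is the natural basis for
  ±1 step signals, and on dyadic lengths its pyramid is exact rational
  algebra (coefficient counts len/2ʲ), which makes the oracle comparison
  and the round-trip bound (1e−9) sharp. Any PyWavelets family can be
  substituted by name.
* **Level weights.** Uniform over the L+1 levels, giving global and local
  scales equal say. Exposed as a configuration knob since applications may
  want to emphasize coarse topology or fine texture.
* **Length equalization.** Two RNAs of unequal length yield signals of
  unequal length; both are linearly interpolated onto the smallest power
  of two ≥ the longer signal. Upsampling both (rather than truncating or
  padding) preserves endpoints and curve shape and permits a full L-level
  pyramid without boundary effects.
* **Signal choice.** The cumulative curve is decomposed by default; the
  step signal is available as an alternative. The cumulative signal
  integrates composition drift along the molecule and is the
  representation the curve itself visualizes.

## Numerical conventions

* **Pearson per level, not concatenated:** correlations are computed
  separately for the approximation vector and each detail vector, then
  combined by the weights.
* **Zero-variance rule:** a constant coefficient vector has no defined
  correlation; if both vectors at a level are constant and identical the
  level contributes 1, otherwise (one or both constant) it contributes 0.
  This makes degenerate inputs (e.g. poly-A, whose detail levels vanish)
  well-defined.
* **Exactness guards:** identical coefficient vectors short-circuit to
  correlation 1.0, operands are ordered canonically before `corrcoef`, and
  the weighted sum uses compensated summation (`math.fsum`) — together
  these make self-similarity exactly 1.0 and similarity exactly symmetric
  at the bit level, not merely within rounding.
* Distances are reported to 6 decimal places in file outputs.

## Mutation scan

All 3N single-point mutants (three substitutions per position, ordered
A < C < G < U) are refolded with the same backend as the wild type —
mutants never inherit the wild-type structure, since a substitution can
rearrange the optimal fold. The wild-type structure, once obtained, is
fixed for the scan. Reported: the ranked mutant table (distance
descending), the deleteriousness profile (per-position maximum), a
20-bin histogram of all 3N distances on [0, max], and the maximal mutant
with ties broken by lowest position then A < C < G < U. When several
records are supplied to the CLI, only the first is scanned (logged).

## Phylogeny

Classical UPGMA: merge the minimum-distance pair at height d/2; distances
to the merged cluster are size-weighted means, keeping every
cluster-to-cluster distance equal to the mean of the raw leaf entries
(verified against a brute-force re-averaging oracle and SciPy's average
linkage). Ties are broken on the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest leaf), so trees are
reproducible. On ultrametric inputs the cophenetic distances reproduce the
input exactly. Newick export orders children by smallest descendant label
and quotes labels containing metacharacters. Tree cutting into k clusters
replays the merge history, stopping before the k−1 deepest merges.

## Synthetic data

The generator plants families: per family a uniform random ancestor of
the given length, members derived by independent per-site substitutions
(a hit always changes the base, so expected Hamming distance =
rate × length) and refolded individually. Defaults — 4 families × 20
members, length 60, rate 0.05 — define the family-recovery benchmark:
members stay close to their ancestor's fold while families are mutually
unrelated random sequences. What this emulates: clusters of homologous
structures at low divergence. What it does not: realistic covariation
(compensatory double substitutions), indels and length variation,
family-specific conserved motifs, or thermodynamic folding — so passing
family recovery demonstrates that the distance separates structurally
coherent groups, not that it reproduces curated-database phylogenies.
Problem sizes throughout the suite (records of length 10–64, 80-record
trees, length-20 mutation scans) were chosen as the smallest sets that
exercise every code path meaningfully.

## Degenerate inputs and limits

* Sequences shorter than 10 nt are rejected at every entry point; the
  encoding primitives themselves accept any length ≥ 1 for unit testing.
* All-unpairable sequences fold to all dots and compare via the
  zero-variance rule.
* A decomposition depth too large for the (resampled) signal is reduced
  to ⌊log₂ len⌋ with a logged warning.
* Trees need ≥ 3 records; query/target sets of the pairwise mode must
  have equal sizes. Each violation exits the CLI with a distinct code.

## Known limitations

Single structures only (no suboptimal ensembles or base-pair
probabilities); no pseudoknots; no multi-point mutation scanning; the
built-in folding model is not thermodynamic, so mutation-scan rankings
under `nussinov` and `rnafold` can differ; UPGMA assumes a roughly
clock-like divergence of the structural distance and can misplace taxa
when that fails.
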