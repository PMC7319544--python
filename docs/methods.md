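# Methods

## Structure model

A secondary structure is a set of base pairs (i, j), 1 ≤ i < j ≤ n, in
which every position pairs at most once, no two pairs cross (nested or
disjoint only — no pseudoknots), hairpin loops enclose at least h = 3
unpaired nucleotides, and only canonical pairs (AU/UA, CG/GC and the
GU/UG wobble) may form.  Lonely pairs are allowed.  The open chain has
energy exactly 0 under every model.

## Energy models

Full Turner-2004 parameterization (multiloop terms, dangles, special
loops) is deliberately out of scope; the point of the package is the
differential ensemble machinery, which is energy-model-agnostic.  Three
models ship, chosen so that every quantity the dynamic program produces
can be verified against exhaustive enumeration or closed forms:

| model | energy | RT (kcal/mol) | role |
|---|---|---|---|
| `toy-uniform` | −1.0 per pair | 1.0 | closed-form tests |
| `toy-pairtype` | GC/CG −3.0, AU/UA −2.0, GU/UG −1.0 | 1.0 | pair-type-sensitive tests |
| `stacking` | per-pair baseline + nearest-neighbour stack term | 0.6163 (37 °C) | realistic helix cooperativity |

The stacking parameter file (`src/mutfold/data/stacking.params`) holds
Turner-2004-style stack free energies for all 36 outer/inner pair
combinations (Watson–Crick steps from the published table, GU-involving
steps approximate), symmetric under strand reversal
(`STACK(XY,WZ) = STACK(ZW,YX)`), plus baselines of 0.0 for GC/CG and
+0.45 for AU/UA/GU/UG (a terminal-AU-penalty-style destabilization
applied per pair in this simplified model).  Dangling ends and coaxial
stacking are excluded.  Parameter files are plain `key = value` text
with `#` comments; loading validates completeness and round-trips.

## Partition function

`EnsembleFold` implements the inside/outside (McCaskill) recursions in
O(n³).  Inside: `Zb(i,j)` is the Boltzmann weight of structures on
[i, j] with (i, j) paired,

    Zb(i,j) = w(i,j) · [ Z(i+1,j−1) + (ws(i,j) − 1) · Zb(i+1,j−1) ]
    Z(i,j)  = Z(i+1,j) + Σ_k Zb(i,k) · Z(k+1,j)

where `w` is the pair's Boltzmann factor and `ws` the stack factor
coupling (i, j) to a directly nested (i+1, j−1) (ws ≡ 1 for the toy
models).  Outside: processing pairs by decreasing span, a pair's
probability is its exterior term plus a sum over innermost enclosing
pairs; the O(n⁴)-looking enclosure sum is reduced to O(n³) by
accumulating, per 5′ endpoint k, the quantity
`D(k, j) = Σ_l M(k,l) · Z(j+1, l−1)` (with `M = P·w/Zb`) as pairs are
processed, so each probability needs only one O(n) contraction.  The
stacking correction enters as an extra `(ws − 1)` term for the
immediately adjacent enclosing pair.  The same machinery exposes the
joint probability of directly stacked pairs (needed for energy-feature
expectations) and, via an allowed-pair mask, arbitrary restricted
ensembles.

Numerics: Boltzmann weights are rescaled per nucleotide (each position
carries a factor 1/σ) so partition functions of long sequences stay in
double-precision range; σ is estimated from a max-plus (best structure)
prepass for n > 250 and adjusted automatically on over-/underflow.  All
probabilities are ratios of identically scaled quantities and are exact
in the scale.  Negative round-off is clipped at 0; the test suite pins
DP-vs-enumeration agreement below 1e−9 (observed ~1e−15).

An exhaustive enumerator (`enumerate_structures`, guarded to n ≤ 25)
serves as the independent oracle throughout the tests and is exposed as
public API; it is never used by the analysis paths.

## Local folding and accessibility

Local mode computes, for every length-W window, the window-restricted
global probabilities (span cap L applied inside the window), and reports
each pair's unweighted mean over all windows fully containing it; edge
pairs are divided by their own covering-window count, not a constant.
W = L = n reproduces global folding to 1e−12.  Defaults: the global
preset is W = L = n with u = 1; the local preset W = 200, L = 150
follows common local-folding practice (the typical choice for long
mRNAs).  Accessibility: in global mode pu(i) = 1 − Σ_j P(i,j) exactly;
u-mer probabilities recompute the partition function with all pairs
touching the stretch forbidden and take `Z_constrained/Z` (naive
O(u·n³), chosen for oracle-verifiability over the optimized
exterior-loop recursion).  In local mode both quantities are averaged
over covering windows exactly like pairs.

## Differential representations

Pair-level delta is mutant − WT (red = strengthened by the mutation);
accessibility delta is WT − mutant (negative = more accessible mutant).
Both conventions are kept deliberately — each matches the way its plot
is conventionally read — and every output file documents its sign in a
header.  Differences are refused across unequal folding parameters.
Weakened/strengthened maps are the negative/positive parts of delta;
the combined matrix carries WT above and mutant below the diagonal,
losslessly.

## Relative entropy over the common structure space

The strict KL divergence D(p_wt ‖ p_mut) between Boltzmann ensembles is
infinite whenever the WT puts mass on structures containing a pair that
the mutation makes non-canonical.  `mutfold` therefore reports the
divergence of the *conditional* distributions over the common structure
space S′ (pairs canonical in both sequences), together with each
ensemble's coverage Z′/Z of that space and an `infinite_flag` set when
WT coverage < 1.  Using pair/stack-additive energies,

    D(q_wt ‖ q_mut) = ⟨E_mut − E_wt⟩_{q_wt} / RT + ln(Z′_mut / Z′_wt)

where the expectation decomposes into Σ p′_ij ΔE_pair(i,j) +
Σ p′_stack(i,j) ΔE_stack(i,j) over restricted-ensemble feature
probabilities — no enumeration, two masked folds per sequence.  The
result is clipped at 0 against round-off.  Within the analysis pipeline
the relative entropy always uses global folding with the span cap L
applied identically to both sequences (a windowed average has no
corresponding probability distribution over structures).

## Region scan and empirical p-values

For each window length ℓ (default {50}, clipped to n) and start position
(stride 5 by default, plus the final start so the 3′ tail is always
covered), the upper-triangle pair probabilities with both ends inside
the window are compared by Euclidean distance (maximized) and Pearson
correlation (minimized).  Degenerate windows: equal vectors give r = 1;
a zero-variance vector differing from the other gives r = 0.  Ties
resolve toward the smallest start, then the smallest length.  Windows
shorter than 4 nt admit no pair and are rejected.

The p-value background is the exhaustive set of all 3n single-nucleotide
substitutions of the input sequence, each refolded and rescanned under
the same configuration — fully deterministic and reproducible, in place
of any precomputed lookup table binned by GC content and length.
`p = (1 + #{background ≥ observed}) / (1 + 3n)` for distances (≤ for
correlations), so p > 0 always.  When the scored mutation is itself one
of the 3n background mutations, its own background entry is excluded
from the count (the denominator stays 3n + 1); this makes the p-values
of all 3n candidate mutations uniform on {1/(3n+1), …, 3n/(3n+1)} up to
ties, which the calibration test checks on a seeded 30-mer.  Multi-edit
mutations are scored against the unmodified background.

## Synthetic fixtures

`make_fixture_sequences(seed, count, length)` produces deterministic
random sequences with a planted complementary stem (two reverse-
complement arms around a ≥ 3 nt loop; ≥ 4 bp for length ≥ 11, the
longest stem that fits below that), guaranteeing non-trivial ensembles
at any size.  These fixtures emulate the *combinatorics* of structured
RNA — they carry no biological sequence composition, no conserved
motifs, and are paired with the simplified energy models above — so
green tests demonstrate the correctness of the ensemble algebra and the
differential machinery, not predictive accuracy on real transcripts
(which would additionally require a full nearest-neighbour
parameterization with loop entropies).

## Interop and pipeline

Dot plots are read and written in the ViennaRNA PostScript dialect
(`i j v ubox`, P = v²; `lbox` entries ignored with a warning); exported
probabilities below 1e−7 are dropped to bound file size (in-memory
values are never truncated).  The `dotplot-files` backend runs the
differential analysis and region scan directly on two externally
produced dot plots; relative entropy and empirical p-values require
refolding and are reported as null there.  Feeding the tool its own dot
plots reproduces the internal differential outputs within 1e−6 (the
round-trip precision of the 6-decimal v encoding).

Every run writes a bundle: figures, TSVs (sign conventions in headers),
`impact.json`, a run log with versions and parameters, the echoed
configuration, a manifest and a ZIP.  Renderers are deterministic
(fixed SVG hash salt, no timestamps); probability panels are grayscale
(0 → white), differential panels use a symmetric blue/white/red scale
whose limits are max(|Δ|) with a ±0.1 floor so near-null results are
not amplified; chords/arcs below |value| = 1e−3 are not drawn.

## Design choices and limitations

* Mutation codes accept identity edits (e.g. `A5A`) as null controls;
  duplicate positions are rejected; indels and genome coordinates are
  out of scope.
* Multi-record FASTA uses the first record with a warning; the default
  length cap is 2000 nt (cubic folding at desk scale).
* Sizes used in the shipped tests and acceptance script (oracle sweeps
  of 60–200 sequences at n ∈ [8, 15], a 30-mer p-value calibration,
  20–40-nt pipeline examples) were chosen so the whole suite verifies
  every contract in a few seconds on one core while staying well inside
  the enumeration guard.
* No numerical parity with ViennaRNA/RNAsnp/remuRNA binaries is
  attempted or promised: all measures are re-implemented over this
  package's own energy models.
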