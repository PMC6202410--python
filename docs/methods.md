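# Methods

## Observables and counting

A gapped pattern `X = (α, τ)` places symbol `α_j` at offset `Σ_{r≤j} τ_r`
from a window start; all `N′ = N − size(X) + 1` windows are scanned and
overlapping occurrences all count. Frequencies are stored as exact
`(count, windows)` integer pairs and divided only at reporting time, so
small worked examples are bit-exact (2/13, not 0.15384…). Windows never
wrap around the sequence end. A pattern that does not fit yields
`windows = 0` and an explicitly undefined frequency rather than zero.

The reverse complement of a pattern complements and reverses the symbols
and reverses the gap vector; it preserves the pattern size and is an
involution. This is the transform under which the extended Chargaff
symmetry `P(X) ≈ P(X̂)` is evaluated.

Counting is vectorized: a boolean conjunction over shifted code arrays for
a single pattern, and, for the bulk dinucleotide scan, one histogram of
`16·d(i) + d(i + offset)` per scale, where `d(i)` is the dinucleotide code
at position i. The naive per-window scanner is kept in the test suite as
the independent oracle; the two agree exactly on integer counts.

## Separation conventions

For `Y = (X_A, X_B; ℓ)` the flattened pattern's middle gap equals `ℓ`
under the default `formula` convention (the second dinucleotide starts
`ℓ + 1` positions after the first). The alternative `table1` convention
puts `ℓ` *free* positions between the two dinucleotides (middle gap
`ℓ + 1`); at `ℓ = 4` this is the 8-position layout `α₁α₂····α₇α₈` used in
reference tabulations of z at small scales. Both are exposed everywhere
(`--convention formula|table1`); the symmetry algebra is independent of the
choice because `ℓ` is carried opaquely. Which convention a given published
scan axis uses is not always stated; results at `ℓ ≫ 1` are insensitive to
the one-position difference.

Marginals `P(X_A)`, `P(X_B)` are computed over the whole sequence with
their own window counts (`N − 1` for dinucleotides), not restricted to
positions where the composite fits; the difference is O(ℓ/N).

## The symmetry algebra

`R` (swap) and `C` (reverse complement the first slot) are involutions and
do not commute; `CRC` maps `Y` to its full reverse complement. Symmetries
are generator sets over {R, C}; closures are computed by breadth-first
application with set semantics. Words apply right-to-left (operator
composition); for the four registered symmetries the closures are identical
under either order, so the choice is documented but immaterial. Generic
closure sizes are 2 (S1), 4 (S2, S4) and 8 (S3 — all combinations of
hatting each slot and swapping). Degenerate references (e.g. `X_B = X̂_A`,
or palindromic dinucleotides, which are their own reverse complement)
produce smaller closures; Eq.-level averages always use the deduplicated
closure size.

The S3 closure is taken as the full 8-element algebraic orbit of {R, C}.
One published listing of this set contains an element inconsistent with the
group closure; we follow the algebra.

## The index I_S(ℓ) and its calibration

`σ(ℓ)` is the population standard deviation of the 256 z values at scale ℓ
(population vs sample changes the result by < 0.2% at n = 256; undefined z
values are excluded with a logged count). `d_ℓ(Y_ref; S)` averages squared
z differences over the closure *including* the reference's zero term, and
`I_S(ℓ)` carries the literal `1/(2|A|)` prefactor with `A` the 256
*ordered* dinucleotide pairs (ordered is forced: R acts nontrivially).
If σ = 0 or a closure member's z is undefined at some scale, the index is
NaN there, never silently imputed.

Under the null of z drawn iid across pairs, the exact expectation is

    E[I_S] = (n/(n−1)) · (1/n) Σ_ref (|S(ref)|−1)/|S(ref)|,   n = 256,

because `Σ_{j≠k} (z_j − z_k)²/σ̂²  = 2n²` holds pointwise for any sample.
With the degenerate-closure census this gives 120/255 ≈ 0.471 (S1),
180/255 ≈ 0.706 (S2), 201/255 ≈ 0.788 (S3) and 156/255 ≈ 0.612 (S4);
restricted to non-degenerate closures the familiar `(|S_S|−1)/|S_S|`
values 1/2, 3/4, 7/8, 3/4 emerge. Note the informal reading "I = 1 when
the symmetry is absent" is only an upper-bound intuition: the literal
formulas give the values above, and we do not renormalize. The test suite
verifies both forms by Monte Carlo through the production code path.

## Scale detection and heatmap

A symmetry is *present* at ℓ when `0 ≤ I_S(ℓ) ≤ 0.025` (a fixed visual
threshold, not a significance test — significance testing is out of scope).
On the dyadic grid, `L_D` is the first scale at which S2 is present, `L_S`
the first at which S3 is present, and `L_M` the first scale at which S1 has
ceased to be present while S4 still is. These first-crossing estimates
carry a one-dyadic-step grid resolution; raising the threshold can only
decrease (never increase) `L_D` and `L_S`. Absent scales are reported as
absent with a reason, not as errors.

The heatmap intensity per sequence uses the band `[1.05·I_min, 6.5·I_min]`:
full color at or below the lower edge, white at or above the upper edge,
linear in between; `I_min = 0` degenerates the band (full color exactly at
I = 0, flagged in the log).

## The domain model

Defaults are the reference study conditions and are not tuning knobs:
transition matrices `M_I` and `M_II` (rows/columns ordered A, C, G, T)
whose stationary laws violate Chargaff (for `M_I`,
μ ≈ (0.174, 0.430, 0.163, 0.234)); chunk lengths uniform on [130, 170]
(mean 150); reverse-complement probability 1/2; macrostructure target
length 10⁶. The model's ground-truth scales are: `L_D` from the Markov
mixing time (the second-largest eigenvalue modulus is recorded as proxy,
with decay length −1/ln(slem) ≈ 10 bp); `L_S = 2 × 150 = 300` (independent
fair coins give geometric same-orientation runs of mean 2 chunks); and
`L_M` = the macrostructure length.

Design choices where the construction was genuinely open:

- **Chunk initialization.** Each chunk starts fresh from the stationary
  law (chunks are independent realizations); continuing the Markov state
  across chunk boundaries would contradict reverse complementing
  individual chunks.
- **Termination.** A macrostructure stops at the first chunk whose
  addition reaches the target, keeping whole chunks (final length in
  `[L_M, L_M + 170)`); truncating would bias the final chunk's length law.
- **Clustering.** Same-type clustering arises solely from the independent
  per-chunk coin (mean run 2); no extra run-length knob is enabled by
  default.
- **Mirroring scope.** Chunks are mirrored within their own
  macrostructure; the two macrostructures use different processes and are
  not cross-mirrored.
- **Draw order.** One seeded Generator drives everything; a macrostructure
  draws chunk lengths, then orientations, then one uniform matrix for all
  chunk symbols (chunks are generated column-parallel to the maximum
  length and trimmed). `generate_chunk` (single chunk) consumes draws
  sequentially; it is distributionally identical to, but not
  draw-for-draw interchangeable with, the batched path. Reproducibility is
  per-function: same config and seed, same genome, bit for bit.

## Statistical floors and problem sizes

The bulk scanner drops scales with fewer than 1000 composite windows
(logged) rather than reporting high-variance z values; z is double
precision in reports but every joint count is kept as an integer for exact
re-verification.

Validation problem sizes were chosen to make sampling error small relative
to the tested margins: 10⁶-symbol stationary Markov sequences (12
replicates) for the closed-form z check — where, because a per-cell t
statistic over 120 simultaneous cells has heavy small-sample tails, the
suite requires every |t| ≤ 5 and ≥ 95% of cells within 3 SE rather than a
simultaneous 3σ, which no correct implementation would pass reliably —
10⁴ replicates for the iid-null calibration, and five independent seeds of
the full 2×10⁶ bp default genome for the hierarchy reproduction.

## What the simulator does and does not emulate

The generator reproduces the statistical skeleton behind the symmetry
hierarchy: Chargaff-violating local composition, strand-symmetric domain
mirroring, geometric same-type clustering, and isochore-like macrostructure
heterogeneity. It does not emulate real genomes' repeat families, GC
gradients within isochores, assembly gaps, point-mutation dynamics, or the
length and sequence specificity of actual transposable elements. Passing
the synthetic hierarchy tests therefore demonstrates that the analysis
machinery detects the designed symmetry structure at the right scales — it
does not by itself certify behaviour on real chromosomes, for which the
optional integration test against a locally provided human chromosome 1
exists.

## Known limitations

- The bulk scanner is specialized to dinucleotide pairs (the general
  counter handles arbitrary gapped patterns one at a time).
- Marginals over the whole sequence introduce an O(ℓ/N) bias in z at
  scales approaching the sequence length; the window floor keeps this
  below the reported precision.
- `detect_scales` operationalizes what is otherwise a visual reading of
  curve crossings; on coarse grids the estimates inherit the grid step.
- IUPAC ambiguity codes are removed, not matched; amino-acid alphabets are
  out of scope.
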