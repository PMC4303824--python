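# Methods

This note documents the models, parameter choices and numerical
conventions behind `regen-evo`, and what the synthetic benchmark does and
does not establish.

## Conservation profiles

For a clade pair (A, B) and alignment column c, the raw score is the mean
of BLOSUM62(a, b) over all |A|·|B| residue pairs, with the population SD
kept as a dispersion track. Columns containing a gap, an `X` or a stop in
*any* row are removed globally before scoring ("any-gap" policy), so the
three clade-pair profiles share one x-axis; no further trimming of poorly
aligned termini is applied beyond this rule.

The smoother is the one-pole low-pass filter y_n = α·x_n + (1 − α)·y_{n−1}.
α ∈ (0, 1) trades resolution for noise: smaller α smooths more (the filter
memory is ≈ 1/α columns). The default α = 0.05 gives ≈ 20-column memory,
appropriate for domain-scale conservation trends. The recursion is seeded
with y₋₁ = x₀ rather than 0, avoiding an N-terminal startup transient.
Because the filter is directional, it is applied to the signal and to its
reversal, and the two outputs are averaged; the averaged signal of a
palindromic input is itself palindromic, and all smoothed values lie
within [min x, max x] (convexity).

The profile contrast reduces each family to one number, the margin
m = mean(fp smoothed) − mean(mf smoothed): m > δ ⇒ non-ToL, −m > δ ⇒
ToL-like, otherwise indeterminate. δ defaults to 0 — the decision
boundary is exposed as a parameter because conserved-region judgments in
practice are made visually and any scalar rule is a simplification.

## Trees

Point trees are neighbor joining (Saitou–Nei) on Kimura-corrected protein
distances d = −ln(1 − p − 0.2p²), p being the mismatch fraction over
pairwise gap-free columns. p beyond the formula's domain (p ≳ 0.854) is
capped at a configurable maximum (default 10) and flagged. Negative NJ
branch estimates are clamped to zero with the deficit moved to the sibling
edge, preserving their sum; on additive matrices NJ recovers topology and
branch lengths exactly (property-tested against path-summation oracles).
NJ on corrected distances is a deliberate desk-scale stand-in for a full
ML search: deterministic, fast, and sufficient for deciding which of three
coarse clade arrangements a family supports. Users with an externally
computed ML tree can pass it in; classification is identical from there.

Rooting is by midpoint with a deterministic tie-break (lexicographically
smallest leaf pair among longest paths), and children are re-ordered by
smallest descendant label so equal rootings serialize identically.
Classification then asks which clade-pair union is monophyletic on the
rooted tree. Note the interaction that drives the pipeline: the *generating*
topology is always ((metazoa, fungi), plant), but when the metazoan subtree
carries enough extra length, the midpoint of an inferred (unrooted) tree
moves onto the metazoan stem and the rooted tree shows fungi+plant as a
clade — exactly how rate acceleration masquerades as autotrophic paraphyly.

The mf/fp ratio is the mean metazoa×fungi patristic distance divided by the
mean fungi×plant one. Under a clock it sits below 1 (the mf split is more
recent); metazoan acceleration pushes it above 1. Alternative definitions
(e.g. stem-branch ratios) could be added behind the same interface.

Bootstrap supports resample alignment columns with replacement and report
the fraction of replicates containing each bipartition of the point tree
(default 100 replicates, seeded).

## Ka/Ks (NG86)

Synonymous site counts per codon follow Nei–Gojobori: each position
contributes one site split by the fraction of its non-stop single-base
mutants that are synonymous (site counts always sum to 3). Differences
between codons average the step classifications over all orderings of the
differing positions; orderings passing through stop codons are excluded
and the average renormalized (if every ordering is excluded — impossible
for ≤ 2 differences — all orderings are used with stop steps counted
non-synonymous). Proportions are Jukes–Cantor corrected; p ≥ 3/4 sets a
saturation flag instead of a number. Saturated Ks values are *excluded*
from clade-pair means and counted, never capped: at ~1 Gya clade depths
synonymous saturation is the norm, and a capped value would be an
arbitrary constant masquerading as data. All 61 site counts and 61×61
difference counts are precomputed, making whole-alignment tables pure
table lookups. An independent brute-force enumeration implementation is
kept in the test suite and must agree to 1e−12.

The clade contrast is deliberately coarse: metazoan-elevated iff
mean Ka(mf) > mean Ka(fp) and mean Ka(mp) > mean Ka(fp), strictly. A
branch-model likelihood-ratio test is out of scope; in its place a
nonparametric bootstrap (codon columns resampled, default 200 replicates)
gives a CI for Ka(mf) − Ka(fp). The CI is reported alongside the verdict
but does not enter the final classification, which uses only the three
primary signals.

## Synthetic families

The simulator's species tree is ultrametric in time units (leaf depth
1.0): crowns of 10 species are 0.5 deep; the metazoan and fungal stems are
0.3, the opisthokont stem 0.2, and the plant lineage splits at the root
(stem 0.5). A fungi–plant leaf path therefore spans 2.0 time units versus
1.6 for metazoa–fungi, giving a true mf/fp ratio of 0.8 under a clock and
1.6 at the default 3× metazoan acceleration. Crown topologies are random
(uniform joins at evenly spaced heights), so every family has its own
shape.

Sequences evolve by Poisson candidate point mutations
(rate × branch length × sites; base rate 0.3 per site per time unit),
with synonymous candidates always accepted, non-synonymous ones accepted
with probability ω = 0.2 (purifying selection typical of conserved
enzymes), and stop-creating candidates rejected. The non-ToL scenario
multiplies metazoan branch lengths by 3 (an accelerated clock); an
independent ω multiplier lets experiments separate "faster clock" from
"relaxed selection", which the two biological hypotheses conflate. At
these settings fungi–plant divergence is deep (~0.6 candidate
substitutions per site) but synonymous distances remain mostly below the
Jukes–Cantor boundary.

The canned **deep** configuration (rate 2.0, ω = 0.05) reproduces the
regime of real ~1 Gya enzyme orthologs: amino acids stay alignable while
synonymous positions randomize, so Ks saturates in the large majority of
fungi–plant pairs while Ka remains measurable (~0.2). A subtlety worth
recording: simply lengthening branches at moderate ω does *not* saturate
NG86's pS, because sustained amino-acid exchange drifts codon composition
toward high-degeneracy codons (synonymous flux is never rejected),
inflating the synonymous-site denominator until expected pS plateaus just
below 3/4. Strong purifying selection removes that drift, which is why
the deep preset lowers ω rather than raising the rate further.

No indels are simulated — families come out pre-aligned, sidestepping
aligner choice, which sits upstream of this pipeline in any case. No
transition/transversion or codon-frequency bias is modeled, no gene
duplication or loss, and clade sizes are balanced. Consequently the
benchmark demonstrates that the pipeline recovers rate-acceleration
signatures from clean three-clade families; it does not establish
robustness to alignment error, paralog contamination (the known
fungi-outgroup case caused by a two-gene family), unbalanced taxon
sampling, or base-composition artifacts.

## The final verdict

The three stage verdicts combine conjunctively: non-ToL requires
autotrophic paraphyly *and* a non-ToL conservation margin *and* elevated
metazoan Ka; ToL requires the full opposite agreement; everything else is
"mixed". Mixed is a real category, not a failure mode: families with a
ToL topology but elevated Ka, or a fungi-outgroup topology with ToL-like
conservation, land there and are reported with all three calls attached.

## Benchmark conditions and determinism

The default benchmark is 20 families per scenario at the defaults above
(10 species/clade, 300 codons, multiplier 3), master seed 7; per-family
seeds are derived from the master seed, and a repeated run serializes
byte-identically. Benchmark runs disable the two bootstrap layers since
neither enters the final classification. On this benchmark the expected
end-to-end recovery sits near 0.9: the binding constraint is the ToL-side
conservation margin, whose family-level distribution (mean ≈ −0.2, SD
≈ 0.15 BLOSUM units) is dominated by Poisson noise on the few deep stem
branches shared by every sequence pair — a small fraction of clock-like
families genuinely present a weak or inverted margin and are reported as
mixed. That long-tail behavior is a property of the simulated study
conditions themselves and is left visible rather than tuned away.
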