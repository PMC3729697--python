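# Methods

This note documents the models, conventions and numerical choices behind
`mitophylo`, and what the synthetic-data tests do and do not establish.

## Variant nomenclature and coordinates

All coordinates are 1-based rCRS positions (1..16569) throughout, including
when profiles are expressed against the RSRS ancestral root; the
rCRS↔RSRS relation is handled by the shipped translation table
(`data/rsrs_rcrs_diff.tsv`, the standard ~50-site difference set), and
`convert_reference` toggles membership of those sites. Token grammar: a
bare position is a transition, a base suffix a transversion with that
derived base, `d` a deletion, `.N<base>` a left-aligned insertion, a
trailing `@` a back mutation. Heteroplasmy and IUPAC ambiguity codes are
rejected rather than dropped — profiles are consensus calls, and silently
losing a site would corrupt distances.

The default site mask excludes exactly `16182C`, `16183C` and `16519` from
distances and dating. The mask is applied in distance/dating computations
only, not in classification motifs: the exclusion exists because these
length-variant-prone/hypermutable states distort mutation counts, not
because they carry no classification signal. How the poly-C tract around
16182–16194 (and 309.1C-style insertions elsewhere) should be normalised is
under-determined by convention; we left-align insertions and otherwise
leave tract variants to the mask.

## Haplogroup definitions and classification

The shipped definition tree covers the N1a1b/I and W clade system: branch
motifs that are published (e.g. I: `10034 16129`; I1a: `3447-8616T-16172`;
W against N2: `195@-204-207-1243-3505-5460-8251-8994-11947-15884C-16292`;
W3: `1406`; W6: `4093 8614 16325`; W7: `185`) are marked `printed`;
conventional control-region signatures (e.g. `16223` at N, `16391` at
N1a1b) are marked `standard`; everything else is a clearly marked
`placeholder` — the clade *name* is real, its defining site is a synthetic
stand-in chosen so every named clade is representable without external
downloads. Two subclades (W6a/W6b) carry the shared 16192 node variant plus
an HVS-I placeholder; I1c/I1c1 and W5a carry control-region sites inferred
from published ancient haplotypes (`inferred`). Classification results for
placeholder-defined clades are therefore structural, not biological.

Scoring is matched − missing over the cumulative motif restricted to the
profile's sequenced region (HVS-I, or explicit covered ranges for ancient
samples); private variants are never penalised. Back mutations cancel the
earlier event at the same position when accumulating motifs; an uncancelled
`@` is kept as evidence. Tie handling: among top-scoring clades, any clade
whose parent ties it is discarded (descending a chain whose added evidence
is invisible in the sequenced region is not an assignment), then the
deepest survivor wins, then the lexicographically smallest name. The
"discard zero-evidence descents" step is required for two behaviours the
rest of the design demands: an HVS-I-restricted profile must never be
assigned *deeper* than its full-genome counterpart, and a haplotype
matching a variant shared by several sibling subclades (the 16192 case)
must stay at their parent.

Survey tabulation counts a haplotype as a carrier of a clade when it
contains the clade's full HVS-I-restricted cumulative motif. A clade is
flagged non-assessable when that restricted motif is empty *or identical to
its parent's* — the latter refinement covers clades defined solely by
coding-region transitions (W3), whose carriers are indistinguishable from
their parent in control-region data.

## Parsimony tree construction

Construction is greedy and agglomerative: among unexplained variants
carried by ≥2 remaining samples, the one with the highest weighted sharing
count (carriers × site weight) founds the next clade; its carriers recurse,
with every variant common to all of them placed on the clade's stem edge.
Site weights default to 1 with a shipped down-weighting for known recurrent
sites (152, 185, 195, 16189, …): a hotspot must be shared proportionally
more broadly to define a clade, which is the deterministic surrogate for
hand-correcting trees against a reference phylogeny. Ties break by higher
weight, then lower position, then token string. A bottom-up refinement pass
pulls a variant above a node and plants `@` reversions on the non-carrying
branches when and only when that strictly lowers the total mutation count.

The well-formedness contract is the tip-replay invariant: accumulating edge
mutations root→tip (with `@` cancellation) reproduces each input masked
profile exactly. On homoplasy-free inputs with ≤6 tips the construction
attains the exhaustive-search parsimony optimum (verified against a Fitch
enumeration over all rooted binary topologies in the test suite); on
conflicting inputs it is a heuristic, and recurrent hits surface in
`homoplasy_scan` rather than being hidden. Samples identical to an internal
haplotype attach as zero-length tips (the paraphyletic "X*" situation);
duplicate haplotypes never change topology or score.

## Dating

ρ and σ follow the standard definitions (σ² = Σ n_e² m_e / n²); only
substitutions count (indels excluded, matching all-substitutions table
conventions), and reversion events count as mutations. The ML divergence
maximises the Poisson likelihood of per-edge counts with internal node
heights as free parameters under the clock constraint. Numerically the
heights are parameterised as h_root = exp(x₀) and h_child = h_parent ·
sigmoid(x_i), which makes the problem smooth and unconstrained (collapsed
zero-count subtrees are reached asymptotically); L-BFGS with ftol 1e-13.
The standard error comes from the profile-likelihood curvature with an
adaptive finite-difference stencil (initial half-width max(0.2, 0.1·T),
doubled until the curvature is negative). Single-tip clades return the tip
count with an undefined (NaN) standard error, flagged rather than guessed.

The 95% interval multiplier is fixed at 1.96. Interval endpoints are clock
images of distance ± 1.96·dispersion with **no flooring at zero**: a lower
bound below zero distance converts linearly through the origin and yields a
negative ky bound, the convention visible in published tables. Ages are
reported to 0.1 ky in rendered tables.

## The corrected molecular clock

The time dependence of the observable substitution rate (purifying
selection purges mildly deleterious variants over time) means distances
cannot be converted with a single rate. The package does not hard-code the
published calculator's coefficients; instead the default clock is
**anchor-calibrated** against the packaged whole-mtDNA age table
(`data/age_anchors.tsv`, 86 clades × {ML, ρ} pairs plus CI endpoints):

1. *Point anchors*: one (distance, age) knot per printed distance. Where
   several rows print the same distance with different ages (print-rounding
   scatter of ±0.05 substitutions ≈ ±0.14 ky), the row from the most deeply
   sampled clade wins (ρ column preferred on exact ties). Weighted isotonic
   regression (weights = Σn) enforces monotonicity; runs of equal fitted
   age merge into a single knot at the weighted mean distance.
2. *Interval anchors*: ρ-column CI endpoints (distance ρ ± 1.96σ, age = the
   printed bound) are inserted in descending-n order where they respect
   strict monotonicity; endpoints whose implied mean rate falls outside a
   plausible 2.2–3.2 ky-per-substitution envelope (print-rounding artefacts
   near the origin, where a bound of "0.1 ky" is compatible with almost any
   rate) are discarded. Only one CI column can be used: the two columns'
   endpoints contradict each other at several distances once rounded, and
   the ρ column's arguments (ρ, σ both printed) are the ones the package's
   own interval arithmetic reconstructs.
3. A monotone PCHIP interpolant through the knots, linear extrapolation
   beyond the last anchor and below zero (slope at the origin).

This reproduces the source table's conversions at print precision (±0.05 ky
on the headline rows; within the printed scatter everywhere), is strictly
increasing, and inverts to 1e-6 relative tolerance. The alternative
`ClockModel.selection_model()` fits ρ(t) = μ[(1−f)t + f(1−e^(−st))/s] — a
neutral fraction plus an exponentially purged deleterious fraction, the
structural form of selection-corrected clocks — to the same anchors by
weighted least squares; it is smooth but matches the table only to ~0.15 ky.
The `provenance` tag records which construction is active. Local secant
rates run ≈2.55–2.9 ky/substitution over the calibrated range (up to ~3.3
on short spans between CI-derived knots, which inherit rounding noise).

## Synthetic data: what it emulates, what it does not

`simulate_clade` draws a Kingman genealogy (msprime, haploid), optionally
rescaled to an exact TMRCA, and places mutations per edge as
Poisson(rate × duration) over the 16,569-site lattice, with hotspot
positions drawn at shipped rate multipliers, a 5% transversion fraction
(mtDNA substitution spectra are strongly transition-biased), and recurrent
hits on a lineage becoming reversions with probability ½. Default rate:
1/2600 per year, the reciprocal of the clock's near-origin slope — the
regime in which most simulated clades (≤20 ky) live. The root haplotype is
the reference, so profiles are exactly the surviving mutations; emitted
FASTA uses a fixed synthetic 16,569-nt reference (generated, mtDNA-like
base composition — a stand-in, not the real reference sequence).

Simulated data reproduces the statistical structure the dating assumes —
clock-like genealogies, Poisson counts, hotspot recurrence — and therefore
validates the estimators and the pipeline plumbing. It does not emulate
selection, population structure, sequencing error, ancient-DNA damage, or
real site-specific rate heterogeneity beyond the hotspot list, so passing
tests certify correctness of the computations, not robustness of ρ dating
to violations of its model on real data. Canonical test conditions: TMRCA
12 ky with n = 50 for interval-coverage checks (coverage ≈ 94% observed,
asserted ≥ 90% — the heuristic σ is approximately calibrated, not exact)
and n = 20 for ML parameter recovery on the known genealogy (≥ 90% of
estimates within 2 SE of truth).

## Known limitations

- Definition-table placeholders make classifications below the published
  motifs structural rather than biological (status column says which).
- The greedy parsimony construction is exact only on conflict-free inputs;
  with heavy homoplasy it can exceed the optimum, and reversion refinement
  only fires when strictly beneficial.
- ML standard errors are curvature-based and mildly anticonservative on
  reconstructed (rather than true) topologies.
- The anchor-calibrated clock interpolates print-rounded values; between
  anchors its local slope wiggles at the ±0.1 ky level. The parametric
  alternative smooths this at the cost of exact table reproduction.
- Bayesian skyline analyses and full-sequence substitution-model
  likelihoods (HKY+Γ) are out of scope; the Poisson count likelihood is the
  declared surrogate for divergence estimation.
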