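# Methods

`hydenseq` analyses strand-specific maps of ribonucleotides embedded in
genomic DNA during replication.  In a ribonucleotide-excision-repair (RER)
deficient background (*rnh201Δ*), each replicative polymerase leaves
ribonucleotides in the strands it synthesizes at a rate characteristic of
the enzyme; strains carrying a single promiscuous replicase variant
(*pol1-L868M* for Pol α, *pol3-L612M* for Pol δ, *pol2-M644G* for Pol ε)
turn that enzyme's footprint up and make the division of labor readable
from sequencing data.  Alkaline hydrolysis cleaves 3′ of each
ribonucleotide; paired-end sequencing of the resulting 5′ ends, shifted one
nucleotide upstream, maps ribonucleotide positions per strand.

## Pipeline model

**Coordinates.** 0-based, half-open throughout; per-strand dense count
arrays per chromosome; a semantics flag (`raw-5p-ends` → `implied-rnmp` →
`normalized`) prevents double-shifting or double-normalizing.

**Normalization.** SbfI digestion before library preparation plants 5′
ends at sequence-determined positions (forward end 6 nt, reverse end 2 nt
into the 8-bp palindromic site `CCTGCAGG`).  Because cleavage is a
per-genome-copy constant independent of genotype, counts at predicted site
ends act as internal standards.  Size factors are median-of-ratios:
per site–strand entry, each sample's count over the across-sample geometric
mean; entries with any zero are excluded; the factor is the median retained
ratio (mean of the central pair for an even count).  Division by the factor
puts every library on a common per-cell scale.  Site counts are taken from
the *unshifted* track — restriction ends are not ribonucleotide-derived —
and the two strand-ends of a site are separate entries.  A `window_bp`
option widens each predicted end for real libraries with end-repair slop
(default 0: exact position).

**Meta-profiles.** Origins are anchored at the 5′ end of the ACS on its
annotated strand and oriented so the ACS reads 5′→3′ from offset 0; bin *b*
covers `[b·w, (b+1)·w)` with w = 5 bp; counts are summed over origins for
the ACS ("same") and complementary ("opposite") strand, reversing the axis
and swapping strands for minus-strand origins.  A centered moving average
(10 bins, display only) matches the usual trend-line presentation.

**Strand bias r_b.** Per-bin RER−/RER+ ratios (pseudocount 0.5 guards
empty bins).  Bins are assigned nascent-leading or nascent-lagging by fork
direction: same strand at positive offsets is leading, at negative offsets
lagging, and the opposite strand mirrors.  r_b is the arithmetic mean of
ratios over lagging-assigned bins within ±10 kb flanks (excluding ±500 bp
around the anchor) divided by the mean over leading-assigned bins.  The
definition is symmetric, scale-invariant, and configurable (flank windows,
pseudocount); other reasonable definitions (geometric means, other windows)
shift the absolute value but not the direction of the bias.

**Background subtraction.** The RER+ partner of each genotype is dominated
by ribonucleotide-independent ends (nicks, shear, residual breakage).
Because size-factor normalization already places both libraries on a
per-cell scale — and background and restriction ends are per-cell constants
— the RER+ profile is subtracted from the RER− profile *directly*, bin by
bin.  Scaling each profile to its own total first (a plausible alternative)
would make the difference zero-sum over the window, i.e. it subtracts the
signal mean along with the background and destroys the leading-strand
component; we therefore do not do it.  Negative bins are clipped to zero
and the clipped mass logged.

**Deconvolution.** Each strain reports the same replication program
through its own rate vector ρ(g) = (ρ_α, ρ_δ, ρ_ε), the per-nucleotide
relative ribonucleotide-incorporation propensities with the strain's
variant enzyme elevated.  After anchoring each strain's scale on the distal
flanks (2–9.5 kb, where lagging strands are canonical Okazaki synthesis —
Pol α fraction ℓ/L̄ ≈ 15/165, rest Pol δ — and leading strands are Pol ε),
each bin and strand gives three equations

    d_g = ρ(g) · f,   Σ_p f_p = 1,   f ≥ 0,

solved exactly per bin: f_ε is eliminated through the sum constraint and
the remaining 2-D constrained least-squares problem is solved by convex
edge enumeration (unconstrained optimum if feasible, else the best of the
three clipped constraint edges).  Fractions are clipped and renormalized to
sum to one exactly; per-bin residual norms are reported.  Before the solve,
corrected densities are boxcar-smoothed over 9 bins: at the simulated study
conditions (4 origins, 10⁶ ends) the unsmoothed per-bin system is
noise-dominated and simplex clipping would bias the fractions; the width is
odd because an even centered boxcar is half a bin asymmetric and would
shift the strand-symmetry axis by ~2.5 bp.  The transfer fit applies the
identical kernel to its model curves so data and model are compared on the
same footing.

**Strand symmetry.** The two nascent strands are reflections of each other
through an axis slightly downstream of the ACS 5′ end (the effective
initiation center).  The axis is estimated by scanning candidates in
0.5-bp steps and minimizing the summed squared difference between the
same-strand profile and the reflected, linearly interpolated
opposite-strand profile, restricted to the central ±1 kb where the
asymmetric features live (distal flanks are symmetric on average and add
only noise); ties resolve to the smallest axis, and an override is
available.  The opposite strand is then reflected about the estimated axis
and averaged with the same strand.

**Origin Pol δ excess.** Canonical lagging synthesis contributes a flat
Pol δ fraction far from origins; its level is estimated as the mean
strand-averaged f_δ over the upstream distal flank and subtracted bin-wise
(negatives clipped).  The residual origin-proximal excess is summarized by
the midpoint of its contiguous full-width-at-half-maximum interval (the
apex is searched within ±1 kb).  A plateau-shaped excess makes an argmax
with tie-breaking unstable, which is why the FWHM midpoint is reported.

## Transfer-tract regression

The strand-averaged fractions are modeled generatively for one oriented
fork family.  Priming position X starts a Pol α primer of fixed length
ℓ_α; Pol δ extends for a tract L ~ Normal(μ_δ, σ_δ) truncated at 0; Pol ε
continues to the replicon boundary.  Offsets upstream of X belong to the
mirrored fork's lagging strand with fixed canonical fractions, giving

    f_α(x) = P(X > x)·c_α + P(X ≤ x < X+ℓ_α)
    f_δ(x) = P(X > x)·(1−c_α) + P(X+ℓ_α ≤ x < X+ℓ_α+L)
    f_ε(x) = P(x ≥ X+ℓ_α+L)

with c_α = ℓ_α/L̄_okazaki.  Two priming variants share the interface:
`gaussian_start` (X ~ Normal(μ_α, σ_α)) and `geometric` (X measured back
from an ssDNA exposure point with per-bp priming probability p_prime, so
the priming density decays geometrically upstream).  Curves are computed by
1-bp discrete quadrature (priming pmf × tract survival convolution) and
interpolated to the bin grid; the densities of X+ℓ_α and X+ℓ_α+L are the
α→δ and δ→ε transfer densities, whose grid argmax (ties → smallest offset)
gives the modal hand-off positions.

The fit is weighted least squares over the three curves jointly, weights
proportional to total corrected end density (count-derived fractions have
depth-dependent variance), box bounds, and five starts (one data-driven
heuristic plus four seeded random starts); the best converged start wins
and per-start costs are reported.  Budget-limited optimizer runs (status 0)
are accepted when their cost is finite — with a numerical Jacobian they are
routinely parameter-converged at a bound.  μ_δ at its lower bound is
flagged degenerate (no origin δ tract supported by the data).  The fit
consumes raw strand-averaged fractions: the model carries the canonical
lagging baseline explicitly, so pre-subtracting it would double-handle the
term; a `delta_is_excess` mode accepts pre-subtracted f_δ for comparison.

## Forward simulator

The simulator emulates the whole experiment so every stage is checkable
against planted truth: random genome with exactly `n_sbfi_sites` planted
(and accidental occurrences scrubbed), evenly spaced origins of alternating
orientation, per-copy replication, genotype-dependent incorporation, RER,
hydrolysis ends, restriction ends, uniform background, and multinomial
sampling to fixed depth.  All randomness flows from one seed; per-sample
substreams are derived by stable hashing of the sample id.

Geometry per fired origin (efficiency default 1.0 — the analysis anchors on
efficient, well-behaved origins): replicon boundaries at midpoints between
adjacent fired origins; the oriented-downstream fork's leading start is
drawn from the priming distribution and the upstream fork mirrors an
independent draw through the symmetry axis (default +45 bp).  Model 1
plants the leading strand as [α primer][δ tract][ε]; Model 2 plants an
ε-extended leading strand whose 5′ terminus is displaced by the converging
fork's first Okazaki fragment, nick-translated by Pol δ over the tract
length — so both models yield origin-proximal Pol δ synthesis on both
strands, differing in whether a leading α primer survives.  Lagging strands
are tiled by Okazaki fragments (Normal length, truncated), α primer at the
5′ end of each fragment.  Tracts tile every replicated strand exactly
(tested invariant).

End sampling: per nascent position the ribonucleotide weight is
coverage × ρ[p, allele] × `rate_scale` × retention; surviving
ribonucleotides at q yield ends at q+1 (forward) / q−1 (reverse), terminal
positions yielding none — the exact inverse of the pipeline shift.  A
uniform background of free ends (`background_rate` per bp per strand per
copy) is essential to the RER−/RER+ contrast: without it the per-bin ratio
is analytically flat (retention cancels bin-wise) and r_b ≡ 1; real RER+
libraries are background-dominated.  SbfI ends carry a per-copy constant
weight anchored on the background (`sbfi_end_fraction` = their share of a
signal-free library), so fixed-depth sampling naturally gives signal-rich
libraries proportionally fewer site and background reads, exactly the
regime in which SbfI size factors restore per-cell units.

The distal-flank r_b has a closed form used as an oracle: with per-bp
intensities I_lag = ρ_α c_α + ρ_δ (1−c_α) and I_lead = ρ_ε, retentions r∓
and background b,

    r_b = [(I_lag r− + b)(I_lead r+ + b)] / [(I_lag r+ + b)(I_lead r− + b)].

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| bin width | 5 | bp | standard presentation resolution |
| meta window | ±10 000 | bp | covers several Okazaki/tract scales, stays inside replicons |
| r_b flanks | 500–10 000 | bp | excludes the ambiguous core around the anchor |
| distal flank | 2 000–9 500 | bp | asymptotic division of labor for anchoring/canonical level |
| pseudocount | 0.5 | counts | finite ratios at low depth |
| density smoothing | 9 bins | — | variance reduction before the simplex solve; odd for symmetry |
| ρ wild-type α:δ:ε | 4:1:2 | relative | order-of-magnitude literature consistency; config values, not measured constants |
| variant folds α/δ/ε | 4/5/10 | × | elevations of the mapping variants; α = 4 keeps its closed-form bias above 1 (at 3 it is exactly 1) |
| rate_scale | 1e-4 | rNMP/nt per ρ-unit | ~1 ribonucleotide per few kb for the hottest enzyme |
| okazaki length | 165 ± 30 | bp | nucleosome-repeat-scale fragments |
| α primer length | 15 (10–20) | nt | primase+Pol α product |
| δ origin tract | 160 ± 8 | bp | inside the plausible 140–180 / 0–12 ranges |
| priming position | −60 ± 10 | bp | α synthesis peak just upstream of the ACS; tight priming keeps σ_δ identifiable |
| symmetry axis | +45 | bp | effective initiation center downstream of the ACS 5′ end |
| p_prime | 0.001 | per bp | geometric-variant priming probability |
| RER retention | 1.0 / 0.05 | — | RER− keeps all; RER+ a nominal residual (not quantified in vivo) |
| background_rate | 2e-5 | ends/bp/strand/copy | RER+ background-dominated, RER− signal-dominated |
| n_cells / depth | 200 / 1e6 | — | study conditions for the planted-recovery benchmarks |
| sbfi_end_fraction | 0.25 | — | site-end share of a signal-free library; keeps the anchor fed at 1e4-end depth |

All analysis ρ defaults are **implementer-chosen configuration**, not
measured constants; every benchmark is self-consistent because the
simulator and solver share the table, and real-data use requires
substituting measured propensities via `--rates-config`/`PolymeraseRates`.

## What the simulator does and does not emulate

It emulates the features the pipeline's correctness depends on: strand
assignment geometry, genotype-dependent incorporation, RER contrast,
hydrolysis end chemistry (including the off-by-one), restriction ends,
depth-limited multinomial sampling, and replicate/substream structure.  It
does **not** emulate sequence-dependent incorporation bias, replication
timing or variable origin firing time, fork-speed stochasticity,
termination-zone structure, mappability, PCR duplicates, nick-translation
removal of lagging primers (configurable retention is noted but defaults
to full retention), or mitochondrial DNA.  Passing tests therefore
demonstrate that the estimators invert the stated forward model at
realistic depths — not that real libraries satisfy that model.

Small known biases at study conditions: the fitted priming mean is pulled
a few bp downstream by Okazaki-phasing oscillations near the leading start
(a real structure the smooth lagging baseline does not model), with μ_δ
compensating so the δ→ε transition position is recovered to ~1 bp; σ_δ is
identifiable only to a few bp because it enters through the convolved
transition width.

## Numerical choices

Median of an even count = mean of the central pair.  Tract and priming
distributions are discretized to 1-bp cells; far tails are folded into the
last cell.  Axis scan: 0.5-bp grid, ties to the smallest candidate.
Degenerate σ = 0 handled as point masses; subnormal σ thresholded at 1e-6.
The per-bin QP enumeration is exact for this 2-variable geometry.  All
file outputs are plain text (bedGraph, BED6, TSV, JSON); byte-determinism
under a fixed seed is tested.
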