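# Methods

## Machines and their enumeration

The machines are deliberately minimal Turing machines: #Q states, one tape
over an alphabet Σ of #Σ symbols shared between input and tape, blank
symbol `0`, initial state 0, no accepting states (F = ∅). Each step reads
the symbol under the head, then writes, moves (left/stay/right), and
switches state according to the rule table δ. Runs are halted only by an
external iteration bound, so every machine yields a tape and no halting
analysis is needed or attempted (busy-beaver search and halting detection
are out of scope).

The total order over the (#Q, #Σ) space treats each of the #Q·#Σ cells as
one mixed-radix digit, `write·(3·#Q) + move·#Q + next_state`, radix
3·#Σ·#Q, with cells row-major over (state, read symbol) and the **last
cell least significant**. This makes the all-(0,0,0) table machine 0 and
the all-(#Σ−1, 2, #Q−1) table machine TNTM−1, with the successor wrapping
back to machine 0. The within-cell component order is a free choice —
any consistent digit layout yields a valid bijection — and is fixed as
above; machine ids are therefore comparable only within this package. Ids
are handled as exact Python integers (TNTM exceeds 64-bit already at seven
binary states); the compiled sweep loop is used whenever the id range fits
in int64 and a per-machine exact-arithmetic path covers the rest.

### Amplitude

The amplitude is the size of the contiguous span of cells the head
occupied when reading/writing, i.e. the cells whose content the run
actually (re)wrote. The cell the head merely rests on after its final move
is **not** counted, so the amplitude of an n-iteration run is between 1
and n, and the tape handed to the compressor is exactly the written span
(a machine that moves right writing `1` each step leaves, after n steps,
the tape 1ⁿ with amplitude n). The alternative convention — counting the
final resting cell — changes the amplitude of drifting machines by one;
the written-span reading is the one consistent with "characters written on
the tape" and is applied uniformly.

## The compression measure

Statistical complexity is estimated by an **adaptive finite-context
model**: order-k counts n(ctx, s) with additive (Laplace) smoothing
P(s|ctx) = (n(ctx,s) + α)/(n(ctx) + α|A|), α = 1 by default and exposed as
a parameter. One left-to-right pass both codes and learns: position i is
charged −log₂P, then its count is incremented. Positions with fewer than k
predecessors are charged the uniform log₂|A| bits; this start-up policy
costs O(k/|x|) of NC and makes sequences of length ≤ k score NC = 1
exactly, which is also the natural reading for one-cell tapes. Orders are
**pure**: no escape mechanism or blending across k. The best-order measure
runs each k in {2,…,9} with a fresh model and keeps the minimum NC,
breaking ties toward the smallest k.

Count tables are dense arrays while |A|ᵏ ≤ 4⁹ (covering every DNA and
small-tape configuration) and hash maps beyond that (e.g. rule-usage
alphabets of #Q·#Σ = 20 cells at order 9). Both paths implement the same
estimator and are cross-checked in the tests, along with a pure-Python
reference model.

With these choices the complete 2-state binary sweep at 50,000 iterations
gives mean amplitude 32,055 (std 20,836) and mean best-order NC 0.22849
(std 0.41925) — the amplitude statistics are estimator-independent, and
the NC mean sits within ~0.6% of the published reference value for this
experiment, so the default α = 1 is left untouched.

## Profiles

The normal profile is the per-position vector of normalized code lengths;
its unnormalized sum reproduces C(x) exactly (a conservation identity the
tests enforce at 1e−9 relative). The profile order defaults to the best
order found on the full sequence, since the per-position decomposition is
model-agnostic and this makes the profile sum match the global score.

The dynamic profile re-simulates nothing: the machine runs once, in bursts
of `sample_interval` iterations (default 100, configurable — the sampling
density is a presentation choice), and after each burst the current
written span is scored from scratch with fresh models. Incremental count
updates would be wrong, not merely stale: the model must code the tape as
it now reads, and the interior of the span changes between samples.

The low-pass filter used to smooth machine-space curves is a centered
moving average with edge truncation (window shrinks near the boundaries),
default window 501 points for full-space sweeps; the kernel shape is a
free choice and nothing downstream depends on it.

## Sweeps, summaries, regions

Sequential sweeps are deterministic and partition-invariant: splitting an
id range into jobs and merging the per-job record streams reproduces the
single-job records exactly (tested). Monte-Carlo sweeps draw every rule
component of every cell independently and uniformly from a seeded
generator. Summaries report arithmetic means with **population** standard
deviations (divide by n); at n ≥ 10⁴ the sample/population distinction is
below printed precision. The summary reports per-group standard
deviations; where a source table labels such columns "maximum standard
deviation" the per-group reading is used.

The high-NC regions of a machine space are supplied as id intervals rather
than hard-coded: such bands are identified visually on machine-space
plots, and the id order here is package-specific (see enumeration above). For the
(2,2) space the two bands used in the tests, (3200, 5400) and
(13900, 15350), were located on the 501-point low-pass-filtered NC curve
of the full 50,000-iteration sweep (contiguous runs above the 85th
percentile). Inside them the mean amplitude is ~11,200 vs ~36,500 outside,
mean NC 0.64 vs 0.14, mean bits 7.5 vs 16.6, and rule-usage sequences from
seeded 1,000-iteration re-simulations compress better inside — the
"short rule cycles rewriting a small span" signature.

## The hill climb (fixed algorithmic complexity)

The optimizer never changes the rule table's dimensions, so the machine's
description length is constant throughout; only the table's contents move.
A run rejection-samples an initial machine whose amplitude exceeds the
floor (default 100 cells; 10,000 draws before erroring), then repeatedly
replaces one uniformly chosen cell's entire triple with a fresh uniform
triple, re-simulates, and accepts only if the tape's best-order NC
strictly exceeds the running maximum while the amplitude stays above the
floor; rejected mutations are reverted (hill climbing, not a random walk).
Whole-triple replacement is the default reading of "change the value of
the rule"; single-component mutation is available behind a flag.
Acceptance uses strict inequality, so the accepted-NC sequence is strictly
monotone and replaying the final table reproduces the final score exactly.

The decrease variant flips the inequality. **Targeting** a desired NC
value switches acceptance to "strictly closer to the target" with an early
stop inside the tolerance band: pure monotone descent cannot implement
targeting, because initial machines frequently start below a low target
band and accepted steps can jump across it, so steering must be allowed
from both sides.

At desk scale (100 instances, 10 states, 2,000 tape iterations, 200 rule
iterations) the climb raises mean NC by ≈ +0.13 and mean bits by ≈ +9,
while mean amplitude falls ≈ 1,170 → 240 — the direction expected from
the full-scale experiments, which run orders of magnitude more instances
and rule iterations and are not reproduced numerically here.

## Robustness assessment and synthetic data

The assessment perturbs a sequence over a grid of substitution
probabilities × block-permutation counts and records the best-order NC per
cell. Within a cell, substitution is applied **before** permutation (the
two are conceptually simultaneous; a fixed order is required for
reproducibility). Uniform-mode substitution may redraw the original symbol
(so p = 1 is equivalent to an i.i.d. uniform string); fixed-mode always
writes one designated symbol (default `A` — the choice of nucleotide is
arbitrary). Block permutation cuts the sequence into contiguous blocks
whose sizes differ by at most one (longer blocks first) and shuffles their
order uniformly. Grid defaults: p ∈ {0, 0.05, …, 1} and block counts
{1, 2, 4, …, 512}; only the endpoints are fixed by the protocol, the
interior resolution is a choice. Every cell derives its own seed from
(master seed, probability index, block index), so cells are independent
and individually re-runnable.

The synthetic generators define the study inputs: the step string (500
zeros then 500 ones, NC ≈ 0.03 — the low-complexity fixture) and a seeded
order-k Markov DNA simulator whose `sharpness` parameter interpolates each
context's transition row between uniform (NC ≈ 1, the high-complexity
fixture) and a deterministic map (eventually periodic, NC < 0.05). The
simulator emulates only the complexity regime of real genomes — symbol
statistics under a stationary Markov source — not repeats, GC skew,
coding structure, or length distributions; passing the directional tests
on it shows the measure responds correctly to complexity and edits, not
that it captures any biological signal. Real FASTA input goes through
Biopython with A,C,G,T → 0..3; ambiguity codes either abort or are
resolved uniformly at random under a seed, per flag.

## Problem sizes and determinism

The headline experiments run at their native scales: the full 20,736-
machine enumeration and the 10,000-machine Monte-Carlo sample, both at
50,000 iterations (about one and a half minutes together on one CPU with
the compiled kernels). Directional and property tests use scaled-down
sizes — hundreds of machines, hundreds-to-thousands of iterations, ~100
optimizer instances — chosen so the full suite stays fast while each claim
retains a clear margin; the monotone/directional assertions were verified
to be stable across seeds at those sizes. All randomness flows through
seeded NumPy generators (the CLI derives named substreams from a single
master seed), sequential sweeps are bit-deterministic, and every CLI
output file carries a config sidecar sufficient to reproduce it.

## Known limitations

- NC with pure Markov orders is a statistical measure only; tapes with
  algorithmic but statistically opaque structure score as complex. This is
  by design (the object of study), not a defect, but it means NC is an
  upper-bound proxy, not an estimate of algorithmic complexity.
- Machine ids are package-specific (see enumeration); region intervals and
  top-machine lists transfer across implementations only qualitatively.
- The uniform start-up charge for the first k symbols slightly inflates NC
  on very short sequences (NC ≡ 1 for |x| ≤ k); alternatives (fallback
  contexts) would change third decimal places at tape scale.
- `best_order_nc` re-codes the sequence once per candidate order; for the
  9-order default this is an 8-pass cost, acceptable at tape lengths here.
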