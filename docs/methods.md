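# Methods

This note documents the models, conventions and numerical choices behind
`paleomito`, in the order the data flow through the package.

## Pileup model and coordinates

All coordinates are 0-based half-open internally; only the human-readable
call log is 1-based. The consensus is defined on reference coordinates: read
bases inserted relative to the reference contribute nowhere, and a reference
position deleted in a read simply receives no entry from that read (gapped
alignments are projected through their aligned pairs). Each pileup entry
carries its base, mapping orientation and the distances `dist5`/`dist3` from
the read's left and right alignment ends in reference orientation
(`dist5 + dist3 = read length − 1`).

Circularity is handled at pileup time: a read whose alignment extends past
the linear end of a circular reference wraps around the origin, contributing
to columns at both ends with end distances that follow the read. This is the
single-record convention produced by circular-aware realignment; a read
overhanging the end of a *linear* reference is rejected as evidence that the
upstream mapping was not circular-aware. Base qualities are not used in
calling; mapping-quality filtering is off by default (the data this targets
are typically already quality-filtered at mapping time) and available as an
option.

## Damage profile estimation

Single-stranded libraries show cytosine deamination as C→T on
forward-mapping reads and G→A on reverse-mapping reads, strongly end-biased.
The estimator computes, for each end distance `i < W` (window `W = 25` read
positions per end, the conventional display range, which also stabilizes
sparse tail cells):

* `ct5[i]`, `ct3[i]`: T-versus-reference-C mismatch rate of forward reads at
  distance `i` from the left / right alignment end;
* `ga5[i]`, `ga3[i]`: A-versus-reference-G rate of reverse reads, same
  indexing.

Entries with base `N` are excluded from numerators and denominators.
Baselines (`baseline_ct`, `baseline_ga`) are the mean over the innermost
five window cells of the corresponding array pair, restricted to cells with
nonzero denominators; positions beyond the window use the baseline, and
window cells with zero denominator inherit it rather than zero, so rarely
covered distances never look spuriously damage-free. Profile estimation is
reference-polarized even though two calling modes are not: the profile is a
per-sample damage *rate* summary, and only the flagging/calling step needs
to be reference-free.

Short fragments sit inside both end windows at once; such entries are
tallied in both the 5′- and 3′-anchored arrays, matching how per-end
misincorporation plots are conventionally accumulated.

## Per-base weights

A pileup entry's damage frequency `d` is looked up in the profile array
anchored at the **nearer** alignment end (`ct5[dist5]` if `dist5 ≤ dist3`,
else `ct3[dist3]`; the `ga` pair for reverse reads). The nearer-end rule is
the default because single-stranded libraries are deaminated at both
fragment ends; a 5′-only lookup is available (`lookup="five_prime"`) for
comparison with tools that anchor everything at the 5′ end. Weights are:
forward T → `1 − d`, forward C → `1 + d`, reverse A → `1 − d`, reverse G →
`1 + d`, everything else → 1. A balanced damaged/undamaged pair at the same
end distance therefore keeps total weight 2, preserving the column's mass
relative to raw counting. `d` is capped at 0.99 when forming weights so that
a saturated profile cell (a sparse cell estimating `d = 1`) cannot zero out
an observation; weights stay in `(0, 2]`.

## Calling modes and thresholds

A confident call requires coverage ≥ `min_cov` (default 3) and support ≥
`min_support` (default 0.65) for the most frequent base; both thresholds are
inclusive, so a 2-of-3 column (66.7%) is callable. Failing positions are
emitted as `N`. Entries with base `N` never count toward coverage or tallies
in any mode.

* **none** — raw counts; support = max count / total count.
* **pol_silence** — at positions where the reference shows C and at least
  one forward read shows T, forward-read Ts are treated as `N` (reverse-read
  As analogously at reference-G positions); calling then proceeds on the
  surviving entries. The coverage test applies to the post-silencing
  (effective) coverage: silenced entries are no longer observations. The
  pre-silencing alternative is available (`min_cov` against raw coverage
  would only require changing the gate), but post-silencing is the default
  because a silenced base carries no base identity.
* **free_silence** — identical silencing, but positions are flagged from the
  read stack alone: ≥ 1 forward-read T together with ≥ 1 C observed in any
  read regardless of orientation (G→A analogue for reverse-read As). The
  reference is never consulted.
* **free_weight** — every entry contributes its weight to its base's tally;
  nothing is discarded and flags are only reported. Support is the weighted
  majority fraction; the coverage gate uses the *unweighted* entry count,
  because weights encode base-identity confidence, not molecule existence.

Tie-breaks are never needed: a tied top pair has support ≤ 0.5 < 0.65
whenever coverage ≥ 2, and a single-entry column fails the coverage gate, so
ties always resolve to `N` (asserted by a property test). Mode `none` still
computes polarization-free flags for reporting parity, without affecting
calls. The per-result summary counts damaged positions as the union of CT-
and GA-flagged positions.

## Simulator

The generator emulates a deeply degraded single-stranded capture library on
a circular genome:

| parameter | default | meaning |
|---|---|---|
| `target_cov` | 10 | fold coverage; reads are drawn until the base count reaches it |
| `frag_mean` | 34 bp | mean mapped fragment length |
| `frag_shape` | 0.25 | lognormal sigma of the length model |
| `min_len` | 30 bp | truncation (post-filter fragment floor) |
| `damage_amp5` | 0.72 | terminal 5′ C→T probability (molecule strand) |
| `damage_amp3` | 0.40 | terminal 3′ C→T probability; no empirical anchor, freely configurable |
| `damage_decay` | 3.0 | exponential positional scale (read positions) |
| `damage_baseline` | 0.02 | interior damage probability |
| `seq_error` | 0.001 | uniform, strand-symmetric sequencing error |
| `p_forward` | 0.5 | probability a molecule maps forward |

Fragment lengths follow a lognormal truncated at `min_len`, whose location
parameter is calibrated numerically (Brent root-finding on the truncated
mean) so the realized mean equals `frag_mean`; this keeps "configured mean"
and "recovered mean" identical by construction. Each molecule-strand C at
distance `i` from the molecule's 5′ end and `j` from its 3′ end deaminates
with probability `min(1, amp5·e^(−i/decay) + amp3·e^(−j/decay) + baseline)`.
Reverse-mapping molecules are emitted reverse-complemented, so their
deamination appears as G→A in reference orientation. Sequencing error is
applied after damage, uniformly to a random different base, which makes the
damage channel the only strand-asymmetric mismatch source — a property the
tests exploit. Every deamination is logged (read, offset in reference
orientation, CT/GA class), making the simulator the oracle for
profile-recovery and consensus-accuracy tests.

Note one bookkeeping consequence: the *expected* mismatch rate at the
terminal profile cell is `amp5 + baseline` (≈ 0.74 at defaults), not `amp5`
alone, and recovery tests compare against the model's own expectation.

What the simulator does **not** emulate: capture/GC bias and the resulting
overdispersed coverage, PCR duplicates, contaminant or bacterial background
reads, per-cycle sequencer error profiles and quality scores, UDG-treated
libraries, and indels. Passing tests therefore demonstrate correctness of
the calling machinery under the stated generative model, not robustness to
every artefact of real capture data.

## Sex inference

`ratio = (X reads / X length) / (autosome reads / autosome length)`,
classified by band membership: male `[0.35, 0.65]`, female `[0.8, 1.2]`,
undetermined otherwise. The expectations are 0.5 and 1.0; the bands are
package policy, chosen symmetric and non-overlapping, and fully
configurable. `min_reads = 100` (total across both chromosomes) guards
against classifying shallow screening noise; zero autosomal reads yield an
explicit undetermined result rather than a division error. The comparison
autosome should be similar in length to X so assembly/mappability artefacts
roughly cancel.

## Problem sizes and test design

The synthetic study genome is 16,660 bp (the length scale of a horse
mitogenome) with uniform base composition. The test suite and acceptance
script use: ~20,000 reads for damage-profile recovery (terminal-cell
standard error ≈ 0.009); eight fixed-seed replicate libraries for the
weighting-versus-silencing comparison, because per-replicate N-counts at
damaged positions are small (tens) and only aggregates separate the modes
reliably; and exhaustive enumeration of all ≤ 4-entry pileup columns (plus
10⁵ sampled larger ones) against an independently written brute-force
calling oracle. The acceptance script emulates two capture libraries —
11.2× at 72% and 7× at 66% terminal damage — and pools them for the
reduction statistic; the shallow library dominates that statistic, since
silencing pushes marginal-coverage positions below the calling threshold
precisely where weighting can still call.

## Known limitations

* The consensus is haploid by construction; heteroplasmy and contamination
  mixtures are out of scope.
* Damage weights are frequency-based, not likelihood-based: they do not use
  base qualities, and a position covered only by terminal Ts from one strand
  remains genuinely ambiguous.
* Profile estimation needs a reference close enough for mismatch counting;
  grossly divergent references inflate the baseline.
* Indels are not called; the consensus always has the reference's length.
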