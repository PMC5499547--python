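# Methods

This note documents the models implemented in `cotshape`, their
parameters, the design decisions taken where the design was genuinely
open, and what the synthetic data can and cannot show.  All coordinates
are 1-based transcript coordinates with +1 the first transcribed
nucleotide; "d nt upstream of site X" means an RNA 3′-end length of
X − d.

## Template design

Random biotinylation is modelled at the level of the PCR stoichiometry.
For each base N, the biotin-11-dNTP amount is

    dNTP_bio(N) = m · dNTP_comb / (4 · N_count(N)),

where `N_count` counts occurrences of N across *both* strands of the
target-encoding region (reverse-primer span excluded, since that primer
is unmodified; equivalently `N_count(A) = #A + #T` on the nontemplate
strand) and `m` is the target number of biotins per template.  Each
eligible incorporation is then biotinylated independently with
probability `m / (4 · N_count)`, so the per-template biotin count is
binomial with mean `m` and, in practice, Poisson: the zero-biotin
fraction at `m = 1` is e⁻¹ ≈ 0.37.  PCR amplification bias and
polymerase preferences are deliberately ignored — only the count and
placement distribution matter downstream.  The promoter span (−45…−1) is
covered by the unmodified forward primer and is never biotinylated; a
terminal template-strand biotin is a flag, not a sampled site.

## TEC simulation

Single-round transcription (rifampicin) gives each template exactly one
TEC.  A TEC traverses candidate stall events in order of the RNA length
each would impose and resolves to the first success:

| parameter | default | basis |
|---|---|---|
| template-strand SAv stall probability | 0.85 | midpoint of the measured 80–87 % |
| nontemplate-strand SAv stall probability | 0.30 | measured ≈ 30 % |
| Gln111 stall probability | 0.95 | described only as "robust"; value is this package's choice |
| terminal SAv stall probability | 1.0 | run-off prevention |
| SAv stall offsets (nt upstream of the biotin) | {10: 0.75, 8: 0.125, 7: 0.125} | cluster spans 7–13 nt; ~25 % of TECs push 2–3 nt past the modal stop |
| Gln111 stall offset | 14 (fixed) | defined stop 14 nt upstream of the first GAATTC base |
| SAv backtrack depths | {2: 0.1, 3: 0.3, 4: 0.6} | ≤ 4 nt from the primary stop; pushed TECs add their push, ≤ 7 nt total |
| Gln111 backtrack depths | {0: 0.7, 1: 0.3} | never beyond 1 nt |
| termination window / probability | 80–82 nt; 0.99 (0 mM F), 0.01 (10 mM F) | terminated products accumulate at 80–82; antitermination ≈ 100 % with fluoride |
| pellet binding probability | 0.965 | 95–98 % of stalled-TEC RNAs pellet |

The nontemplate-strand stall offset is not characterised beyond "a more
defined stop"; we fix it at the modal 10 nt.  The terminal roadblock
reuses the SAv backtrack law.

Backtracking observables: GreB cleavage trims the nascent RNA to the
active-site register `L − b`; ExoIII protection of the template strand is
`f_DNA + b + δ` with `f_DNA = 14` and a uniform 0/1 nt digestion jitter,
reproducing 14–15 nt (Gln111) versus 17–19 nt (SAv) protections.

**Structure-capped backtracking.**  A folded hairpin immediately behind
RNAP blocks reverse translocation.  Elements marked `caps_backtracking`
cap `b` at 1 when the un-backtracked RNAP back edge sits within 4 nt of
the folded stem's 3′ end.  With the bundled pathway this engages only
for the wound terminator hairpin at 0 mM fluoride (lengths 76–80), which
is what limits the SAv terminator-transition displacement to a single
transcript length while aptamer-region transitions are displaced by the
full backtrack depth.

## Folding ground truth

The pathway is positional, not thermodynamic: a table of structural
elements, each switching the flexibility class (high / medium / low) of
listed positions once a threshold amount of RNA has **emerged** from the
polymerase.  Emergence is `L − (f_RNA + b)` with `f_RNA = 14` nt of RNA
held inside RNAP; backtracking therefore delays every apparent
transition by `b` lengths — the closed-form displacement law
`L_apparent = E + f_RNA + b` that the detection tests verify.

Thresholds for the bundled fluoride-riboswitch-like pathway are
calibrated by inverting observed Gln111 transition lengths with
`f_RNA = 14`: PK1 at E = 57 − 14 = 43, terminator winding (0 mM F) at
E = 76 − 14 = 62, partial terminator (10 mM F) at E = 88 − 14 = 74.
This inversion is the module's central modelling decision: the
experiment reports transcript lengths, the generator needs emergence
lengths.  Positions follow the crcB convention (P1 loop 11–16, PK1
partner 42–47, upper terminator stem 52–55); A10/A22 are single-position
aptamer signatures sharing the PK1 threshold.  The bundled target
*sequence* is synthetic (random, screened for unique 18-mers and absence
of GAATTC and the linker); only coordinates carry meaning.

Modification rates are 0.04 / 0.02 / 0.004 events·nt⁻¹·pulse⁻¹ for
high / medium / low, with a background RT-stop rate of 0.002 shared by
both channels — chosen once to give clear single-hit contrast at
desk-scale depth (≈ 10³ reads per length).  The condition-dependent
gradualness of the SAv PK1 transition reported for 0 mM fluoride has no
mechanistic parameter here and is not modelled.

## Probing and reads

Modification is an independent Bernoulli per unprotected position at its
class rate; the protected 3′-terminal `f_RNA + b` nt of a stalled TEC
are never modified, while released RNAs (terminated, run-off) are probed
in full.  The single-hit regime is enforced by rate magnitudes, not by
truncation: reverse transcription halts at the 3′-most stop it
encounters (modification or background), so extra hits are invisible, as
in the chemistry.  Population-scale stop sampling uses the exact
multinomial distribution `P(k) = h_k · Π_{j>k} (1 − h_j)` per molecule
group, which is equivalent to per-molecule simulation but fast.

Reads: the sequenced insert is `RNA[k+1..L] + linker` (a synthetic 9-mer
linker fixture; the real protocol's linker differs).  Read 1 reads the
insert in sense orientation from the RT stop, read 2 from the linker end
in reverse complement, so read 2 anchors the transcript length and
read 1 the stop.  Reads truncate pad-free on short inserts.  Sequencing
errors are off by default (a uniform substitution rate exists for
robustness tests).

Ligation bias is per-length multiplicative: each length draws a relative
ligation efficiency from a log-normal (median 1, σ = 0.5) clipped at 1,
and molecules are thinned accordingly.  The clip-at-1 form (rather than
dividing by the maximum draw) models lengths that ligate at the maximum
achievable efficiency and keeps usable depth; because reactivity
profiles are computed within each length, the bias distorts depth but —
as the invariance tests check — not the profiles.

## Demultiplexing and estimation

Read 2 must open with the reverse complement of the linker (Hamming
budget 1); its payload is matched exactly against target 3′ suffixes,
with a Hamming fallback, ties broken by fewest mismatches then longest
length.  Read 1 is matched within the assigned length, including the
insert/linker junction for short fragments.  Payloads shorter than 12 nt
(stops within the RNAP-protected span) are dropped as unmappable rather
than risk spurious length assignment; the drop is symmetric across
channels and those positions carry no structural signal.  In Gln111 mode
reads crossing into the EcoRI cassette — run-through products carrying
non-native sequence — fail to match and are tallied separately, exactly
the filtering the rigid roadblock affords.

Reactivities per length use the log-survival maximum-likelihood form:
positional stop hazards β̂_k = c⁺_k / (c⁺₀ + Σ_{j≤k} c⁺_j) (γ̂ from the
(−) channel), raw reactivity θ̃_k = max(0, ln(1−γ̂_k) − ln(1−β̂_k)),
normalised to Σθ = 1, and ρ = L·θ (mean 1).  Saturated hazards clamp
with a half-count pseudocount.  Lengths with under 40 reads in either
channel, or no differential signal, are flagged low-signal and excluded
from traces and comparisons (kept in matrices).  The estimator
reproduces −ln(1−r) of the generative rates on expected counts, hence
rate ratios within ~2 % at these magnitudes.

## Comparative statistics

* **Efficiency** = stalled / (stalled + run-off); terminated products
  are excluded, and terminal-roadblock stalls count as run-off
  equivalents since they passed every internal roadblock.
* **Δρ** is the elementwise difference over common lengths/positions.
* **Footprint stripe**: per length, the anchor is the last position
  where the reference (Gln111) ρ exceeds τ = 0.3 — its protected edge —
  and the width is the contiguous run of Δρ < −τ ending there.  Lengths
  with no qualifying run (the edge abuts an unreactive region, so no
  contrast is possible) carry no information and are excluded from the
  mean.  The reference matrix is an explicit argument because the anchor
  is a property of the less-backtracked dataset.
* **Transition detection**: the region-mean ρ trace is min-max
  normalised between medians of the first and last 5 defined lengths;
  onset is the first length past 0.5 toward the post-plateau sustained
  for 3 consecutive lengths, completion likewise at 0.9.  The 5/3
  windows match the 2–4-length sharpness of the transitions while
  resisting single-length noise.  `TRANSITION_PRESETS` records the trace
  windows used for the bundled pathway: traces start once the region has
  fully emerged for the relevant roadblock chemistry (region end +
  f_RNA + maximal backtrack), the 0 mM fluoride terminator window stops
  at length 85 before coverage collapses, and terminated lengths 80–82
  are excluded there because released RNAs are probed without an RNAP
  footprint.

## Problem sizes and numerics

Simulations use 10⁵ molecules per channel (≈ 10³ reads per length after
stalling, ligation thinning and alignment), 10⁵ draws for distribution
suprema, and 200 replicates for estimator-bias checks; at these sizes
every acceptance-level quantity is reproducible across seeds within its
stated tolerance and the full four-condition pipeline completes in well
under a minute.  All randomness flows through per-stage
`numpy.random.Generator` seeds recorded in the run manifest; identical
configs give byte-identical outputs.

## What the generator does not emulate

Real libraries add PCR duplicates, adapter dimers, quality decay,
sequence-dependent (not just length-dependent) ligation bias,
thermodynamic folding heterogeneity, pausing and NTP-dependent kinetics,
and imperfect single-hit chemistry.  Passing tests therefore demonstrate
that the analysis recovers the mechanistic signal structure — stall
registers, footprint shifts, transition displacement — under controlled
noise, not that it is robust to every artefact of real sequencing data.
Ligation-bias *correction* is out of scope (the bias is simulated and
profile invariance is tested); GreB kinetics are reduced to the
end-state backtrack register.
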