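# Methods

## Interaction probability

The central statistic is the per-pair interaction probability: the
percentage of trajectory frames in which the minimum atom–atom distance
between two residues is *strictly* below a threshold. Defaults and the
reasoning behind them:

- **Threshold 2 Å.** This is the conventional value for this analysis of
  the antibody–hemichannel interface. A 2 Å inter-residue distance is only
  physically attainable between an antigen and an antibody side chain when
  hydrogens participate, so the default atom selection is *all atoms*
  (hydrogens included when present); `heavy` and `calpha` modes are
  available where a coarser criterion is wanted. Whether the original
  analysis included hydrogens is not documented; both interpretations are
  supported and neither is asserted as canonical.
- **Strict inequality.** A distance exactly equal to the threshold is a
  non-contact. The generators exploit this to place boundary cases exactly.
- **Residue-level aggregation** is the frame-wise union (logical OR) over
  all pairs joining the residue to the partner entity. This is the only
  rule under which a residue's value can never fall below any of its pair
  values, which the published residue-level tables require.
- Probabilities are kept at one decimal internally; rendered tables round
  to integers, matching the published layout.
- **Candidate-pair enumeration** prefilters inter-entity residue pairs to
  those ever within threshold + 10 Å, using a KD-tree per frame (scipy's
  `cKDTree`); the same structure accelerates large minimum-distance
  queries. Exhaustive O(n·m) distance evaluation is retained as the oracle
  path and the two are asserted equal in the tests.

## Structures, trajectories, entities

Residues keep the author numbering of the coordinate file; no silent
renumbering. Multi-model PDB is the canonical trajectory dialect (biotite
does the parsing); plain XYZ frame series are also read. Neither format
carries time metadata, so frame times are model index × a user-supplied
stride in ns, and windows are closed intervals — the "last 10 ns of a
150 ns run" is `window=(140, 150)`. Chains are bound to semantic entities
(protomers P1…P6 in cyclic order, antibody heavy/light chains AB1-HC …)
and named regions (EC1, EC2, CDR1–3, constant) by a YAML config; a config
may describe a superset of the chains present, so the same file serves the
full complex and single-antibody pose structures.

## Epitope footprint and stoichiometry

Footprints use a strictly-greater 55% cutoff by default (inclusive mode by
flag). Residues are attributed to the antibody whose pairs produced the
contact; residues contacted by both antibodies appear in both footprints.
"Symmetric binding relative to the pore axis" is operationalized as
invariance under the half-turn of the ring: with two footprints, the
summary is symmetric iff rotating one protomer set by half the ring size
(3 positions for a hexamer) gives the other. This is a geometric
convention, not a fitted criterion.

## Pose filtering

No numeric definition of a CDR "facing" the EC1 loops exists for the
original (visually curated) pose selection, so the package uses a
reproducible surrogate: a pose's CDR faces EC1 iff (a) some CDR×EC1
residue pair is within 8 Å (configurable) and (b) the CDR centroid is
nearer the EC1 centroid than the whole antibody entity's centroid is. A
pose is retained when all three heavy-chain CDRs face (an any-CDR mode
exists). The surrogate is not claimed to reproduce the original manual
choice on the original (unavailable) pose ensemble; on generated pose sets
its verdicts coincide with the construction labels by design, which is
what the tests assert.

## Motif scanning and selectivity

Epitope positions (EC1 54–58, EC2 175–176 in hCx26 numbering) are
transferred to each family sequence by global pairwise alignment
(Biopython `PairwiseAligner`, BLOSUM62, gap open 10, gap extend 0.5 —
standard protein-alignment defaults, recorded in config for
reproducibility). Reference positions aligned to query gaps are reported
as unalignable, never silently dropped. Classification is position-wise
identity over the 7 motif residues: identical ⇒ predicted inhibited,
otherwise predicted not-or-weakly inhibited. The prediction is
deliberately binary; grading partial effects would need affinity modelling
outside this package's scope. The bundled motif table records, as an
annotation only, that hCx30's position 177 is a Leu whose antibody contact
is main-chain-mediated; position 177 is not part of the classifying motif.
The table also preserves two printed naming quirks (gene symbols "CJB7"
and "GJG3"); the conductance table's composite name hCx30.2/31.3 is joined
to the motif table's hCx30.2 through an explicit alias map rather than by
renaming either side.

## Conductance and concordance

Membrane conductance is Ohmic on the depolarizing-step window: mean
current (pA) over the window divided by the command voltage (mV), giving
nS; the command must be constant over the window and a zero-current
reversal potential is assumed (configurable). Tail-current analysis is not
implemented. Leak subtraction is optional and uses a blocked-condition
recording (channels blocked with divalent cations) under the same
protocol. Residual conductance is 100 × G_post / G_pre and is
scale-invariant by construction.

The inhibition cutoff for "measured inhibited" is 50%. The measured
residuals split bimodally (16–25% for inhibited isoforms versus 73–98% for
the rest), so any cutoff strictly between the modes yields the same
classification; 50% is the midpoint convention, and a test verifies the
insensitivity across (25, 73).

## Synthetic data

The generators define the study conditions; they emulate the *statistics*
of the real inputs, not their physics:

- **Toy complex**: six protomers on a 20 Å ring, EC1 (54–58) and EC2
  (172–179) residues as 3-pseudo-atom stacks, two antibodies whose
  designated CDR/light-chain residues sit exactly 1.5 Å above the EC1 apex
  of their mapped protomers (default map: AB1 → P1–P4, AB2 → P4, P5, P6,
  P1). Ground-truth contact sets are exact by construction and verified
  against brute-force geometry in the tests.
- **Contact trajectories**: each scheduled pair is placed at 1.5 Å (in
  contact) or 6 Å (apart) per frame according to a Bernoulli draw at the
  target fraction, or a two-state Markov chain with a prescribed mean
  dwell (stationary fraction preserved, variance inflated — the correlated
  case real trajectories resemble). Same seed ⇒ bit-identical frames.
- **Pose sets**: n poses with exactly n_correct correct orientations;
  incorrect kinds cover far displacement, flipped CDRs, and an "inverted"
  geometry that passes proximity but fails the orientation test.
- **Current traces**: Ohmic step-protocol currents (0 → +40 mV, 1 kHz,
  0.5 s) with additive Gaussian noise (default SD 5 pA on ~400 pA signals,
  a realistic whole-cell noise scale); post-antibody conductance is
  residual_fraction × control. At the default noise, residual fractions
  are recovered well within 1 percentage point.
- **Family sequences** are synthetic 220-residue scaffolds sharing a
  common seeded background, each carrying its isoform's bundled motif at
  the mapped positions, with isoform-specific substitutions away from the
  epitope and, for three isoforms, N-terminal extensions or an internal
  deletion to exercise alignment-based position transfer. They are *not*
  the true connexin sequences; conclusions about real sequences rest on
  the bundled motif table, not on these scaffolds.

What passing tests therefore show: the estimators and classifiers recover
known ground truth under controlled conditions, and the published-style
reference tables flow through the footprint/stoichiometry/concordance
stages to the expected qualitative results. What they do not show:
agreement with a re-run of the original MD or patch-clamp experiments —
the underlying raw trajectory and recordings are unavailable, so the
bundled interaction probabilities and residual conductances are inputs
here, covered by fixture-integrity and parameter-recovery checks rather
than recomputation.

## Problem sizes and numerical choices

Trajectory-based results in the tests and the acceptance script use 500-
to 5000-frame series on the toy complex (a few hundred atoms) — large
enough that binomial error at the reported rates is a fraction of a
percentage point, small enough for interactive runs. Stochastic assertions
use three binomial standard errors; exact assertions (100%, 0%,
frame-count recounts) use equality. Degenerate inputs (empty regions,
zero frames, zero driving voltage, empty joins) raise typed errors or are
reported as undefined rather than coerced to numbers.
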