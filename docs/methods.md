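# Methods

## The signal-concentration axis

A receiver colony reduces its 2-D surroundings to one number: the local
concentration `u` of the diffusible signal. Input `i`, when present,
contributes `c_i ≥ 0` (set by its distance to the receiver), and because
the diffusion equation is linear, contributions add: input state
`s ⊆ {1..n}` is seen as the subset sum `Σ_{i∈s} c_i`. The receiver's
activation function — highpass, lowpass, bandpass, bandstop — partitions
the axis into ON/OFF intervals with strictly positive thresholds and
strict inequalities, so at `u = 0` an activating receiver is OFF and an
inverting receiver is ON (this is what makes NOR from a lowpass possible).

**Degeneracy margin.** The induced truth table is only defined when no
state concentration falls within a margin ε of a threshold (default 1e-6
after normalizing the full subset sum to 1). Everything is scale-free:
multiplying contributions and thresholds by λ > 0 changes nothing, so the
margin convention carries no physical content.

**Admissible orderings.** Which gates one receiver can compute depends on
which strict orderings of the 2^n subset sums are achievable. The
all-absent state is always the minimum and supersets never sort below
subsets; beyond that, additivity imposes non-obvious constraints (if
`a < b` then `a + c < b + c`). Orderings are enumerated by depth-first
extension of the subset partial order; each prefix is checked by a small
linear program (maximize the minimal consecutive gap subject to `c ≥ 0`,
`Σc = 1`), with the parent node's feasible vector reused as a certificate
to skip most LP calls. This is exhaustive: 1, 2, 12 and 336 orderings for
n = 1..4. Ties between state concentrations are never needed — any gate
realizable with ties survives a generic perturbation — so restricting to
strict orders loses nothing.

**Enumeration.** For each ordering, highpass contributes ON-suffixes (never
containing rank 0), lowpass ON-prefixes (always containing rank 0),
bandpass contiguous ON-intervals excluding rank 0 (possibly empty), and
bandstop their complements. Collecting induced tables over all orderings ×
kinds × partitions gives the realizable set: 16/16 two-input gates with
{bandpass, bandstop}, 152/256 three-input gates with all four kinds. An
independent Monte-Carlo oracle (random exponential contribution vectors;
all threshold placements per observed ordering) reproduces the same sets
and is run as a cross-check in the tests and in `scripts/acceptance.py`.
Realizability is equivalent to the table having ≤ 3 blocks (maximal
same-output runs) along some admissible ordering, with the block pattern
matching an available kind; `min_blocks` computes the optimum, don't-care
states joining whichever neighbour minimizes the count.

## The Macchiato algorithm

Multi-receiver devices are read out by an **implicit OR**: the computation
is ON iff any receiver colony is ON. A valid design therefore needs every
receiver OFF in every target-OFF state, and every target-ON state covered
by at least one receiver; don't-cares are free. Minimizing the colony
count is a minimum set cover over the catalog of realizable sub-functions
that respect the target's OFF-set. The exact solver is branch-and-bound
(branching on the lowest uncovered state; bound = ceil(uncovered /
max coverage)); among equal-size covers the tie-break prefers fewer total
thresholds, then lexicographically smallest gate codes, making output
deterministic. A greedy coverage-maximizing variant is provided; at n = 3
with the full kind set it happens to match the exact optimum everywhere.
An explicit second-layer OR (one highpass receiver listening on a second
diffusible channel produced by all first-layer receivers) is emitted as a
structural description only — all shipped demonstrations use the implicit
form.

Receiver count is the only cost currently minimized; a cost hook
(thresholds-then-code tie-break) is the natural place to add preferences
such as "highpass over bandpass".

## Reaction-diffusion device model

The field obeys `∂u/∂t = D ∇²u (− k u) + sources`, solved with an explicit
finite-difference scheme (5-point Laplacian; no-flux or absorbing
boundaries; stability guard `dt ≤ h²/4D`; optional first-order decay,
default 0, i.e. the signal is conserved). A droplet deposits its dose at
t = 0 as a Gaussian one grid cell wide; a sender produces at constant rate
while induced. Against the free-space kernel `M/(4πDt)·exp(−r²/4Dt)` the
solver's RMSE is below 1 % of the peak at practically relevant times, and
mass is conserved to 1e-6 relative with no-flux boundaries. Linearity is
exploited throughout: each source is simulated once and input states are
sums of single-source fields (superposition is exact for this PDE and is
the physical basis of the additive axis model).

Colonies grow logistically (rate 0.7 /h, lag 2 h, OD-like capacity 1) and
**commit**: they read the local concentration at `commit_time` (default
6 h) and hold that expression state — the model counterpart of the
observation that expression rings stop moving early. Fluorescence
accumulates as biomass × committed expression rate, so with growth equal
across input states the fold change at read-out (20 h) reduces to the
ratio of committed dose-response rates. A continuous-integration mode is
available behind a flag on `ColonySpec`.

Dose-responses are Hill-type: activating Hill (highpass), repressing Hill
(lowpass), product of an activating and a repressing Hill (bandpass — an
activation cascade whose output is shut off by a repressor accumulating at
high dose), and its complement (bandstop). These functional forms and all
parameters below are *documented reconstructions*, not fitted values.

**Digital read-out.** A receiver's verdict follows its polarity: activating
strains read ON when fold change exceeds the decision ratio (default 1.5);
inverting strains, which are bright at zero input, read ON while fold
change stays above 1/1.5. *Normalized activity* = fold change / verdict
threshold makes > 1 mean ON for every strain, and the gate score is
computed on that scale: min over ON states / max over OFF states of the
per-state output (max over the receivers designated ON there). For designs
built purely from activating strains this equals the classic
least-fluorescent-ON over most-fluorescent-OFF fold-change ratio exactly.

## Default strain parameters and the distance ladder

On the 4.5 mm placement lattice, a droplet field at commitment time
(7.5 nmol ≙ 1 µL of 7.5 mM; D = 1.4 mm²/h, t = 6 h) offers a discrete
"ladder" of committed concentrations: ≈ 0.039, 0.021, 0.0064, 0.0037,
0.0006 … amount/mm² at 4.5, 6.4, 9, 10.1, 12.7 … mm. Strain thresholds
were placed once, by construction, so that the decision crossings
interleave this ladder (the experimental analogue is selecting strain
variants whose response range matches the device):

- highpass: basal 0.01, v_max 1, K 0.034, Hill 4 → crossing ≈ 0.0093,
  between one and two 9 mm contributions (enables AND) and far below one
  4.5 mm contribution (enables OR with large margin);
- bandpass: basal 0.01, v_max 1, K_act 0.005 (Hill 8), K_rep 0.0175
  (Hill 12) → ON between ≈ 0.0026 and ≈ 0.027, passing single 6.4 or 9 mm
  contributions and rejecting their doubles;
- narrow-band bandpass variant: v_max 0.05, K_act 0.0064, K_rep 0.0077
  (same Hill exponents). Lowering the dynamic range pulls the two
  fold-change crossings together (ON only over ≈ a factor 1.8 in
  concentration) — the knob a higher repressor dose turns in a
  T7/PhlF-style circuit;
- HSL (sender) highpass/lowpass: K 0.023, Hill 4, matched to the sender
  field (production 1.25 /h) — deliberately a matched pair, as the
  sender-based gates require.

The steep high-side exponents stand in for the ultrasensitivity of an
amplifying cascade; they are what lets a bandpass distinguish one input
from two (a factor-2 concentration step). With shallower slopes the
device reproduces the familiar weakness of spatial AND logic — moving from
"one input present" to "both present" only doubles the concentration, and
from n−1 to n inputs the step shrinks further — which is also why
simulated AND scores are systematically below OR scores (asserted in the
acceptance tests).

**Why a strain variant at all:** a receiver that must be ON for two-input
sums but OFF for both singles and the triple needs a band narrower than a
factor ~3 in concentration, while a gate whose ON set spans singles,
pairs and triples of the same inputs (the four-input example) needs one
wider than a factor 3. No single bandpass satisfies both, so the catalog's
Rule 110 entry uses the narrow variant with two colonies. This is a
physical-feasibility statement, not an abstract one — see limitations.

## Placement search

Positions live on the 384-well lattice (pitch 4.5 mm, 8×8 sites in a
35 mm well, minimum separation one pitch). Fitness is the gap, in log2
normalized activity, between the dimmest function-ON and brightest
function-OFF state, plus 0.2 × mean ON activity (a gradient out of the
all-quiet layout), minus a soft penalty (weight 2) for any receiver ON in
a *target*-OFF state. Log-activities are clipped at ±3 so saturation
cannot outweigh correctness. The EA is generational with tournament
selection (size 3), uniform per-node crossover, per-node 8-neighborhood
lattice-step mutation (rate 0.35), elitism 1, and deterministic repair
(clamp to lattice, displace collisions to the nearest free site); same
seed, same result, and the best-of-generation trace is non-decreasing.

Seeding matters on this lattice because feasible layouts can be isolated
points. For each receiver, every assignment of inputs to ladder rungs
(or "far") is scored through the actual dose-response — ON where the
receiver must cover, OFF where the target is OFF, free elsewhere — and the
best-margin assignments (far-preferred on near-ties) become target
distances; inputs are then placed greedily on lattice sites minimizing
log-concentration mismatch across all receivers, for several receiver
arrangements and scale variants. Seeds only initialize the population; the
simulator decides.

`geometric_feasibility_report` compares, per receiver, the achieved
contribution vector (single-input committed concentrations at its
position) with its designed sub-function and flags receivers whose
simulated verdicts deviate — the signature of conflicting distance
requirements when one input serves several receivers.

## Synthetic characterization data

`generate_characterization` produces titration tables around a known
dose-response with multiplicative log-normal noise (median-preserving;
CV-parameterized; seeded). It emulates endpoint fluorescence measurements
of a strain across inducer concentrations with replicate-level noise; it
does **not** emulate growth-phase artefacts, plate position effects,
autofluorescence backgrounds, or calibration-unit conversion, so passing
recovery tests show identifiability of the response model under clean
multiplicative noise, not robustness to real plate-reader pathologies.
Fitting is least squares on log fluorescence with data-driven starting
values and bounds; diagnostics report the log-scale RMSE and a
Wald–Wolfowitz runs test on concentration-ordered residual signs
(z < −1.96 flags systematic curvature, e.g. a highpass model forced onto
bandpass data). With CV 0.1 and 3 replicates over 8 log-spaced
concentrations, K is recovered within 20 % in ≥ 90 % of trials.

## Problem sizes and determinism

Exhaustive enumerations run at n ≤ 3 (full) and n = 4 (336 orderings,
~4000 realizable gates; cached per process). Placement searches use a
0.5 mm grid, population 32, 40 generations — enough for every catalog
gate with margin, and each single-gate search takes a couple of seconds
because committed fields are cached per source position. The Monte-Carlo
oracle uses 1e5 samples. All randomness flows through explicit integer
seeds (numpy default_rng); reruns are bit-identical.

## Known limitations

- **Count-minimal is not placement-feasible.** The exact minimizer's
  tie-break can select covers whose witnesses require concentration
  discriminations the lattice/strain library cannot produce (for 0x1B it
  prefers {highpass 0x01, bandpass 0x1A}, whose bandpass piece is not
  placeable with the default strains; the catalog pins the placeable
  {bandpass 0x0A, highpass 0x11} cover instead). Abstract realizability
  is exact; physical feasibility is checked by simulation, and the
  catalog records decompositions verified end to end.
- Cellular-automaton rules 30 and 110 admit *single-receiver* witnesses in
  the abstract model (their ON sets fit one admissible interval), but the
  required margins are tight; the shipped catalog realizes Rule 30 with
  one wide-band colony and Rule 110 with two narrow-band colonies.
- Three-input parity decomposes abstractly into {one-hot bandpass, AND3
  highpass}, but no lattice embedding satisfies both receivers under the
  default strains; the catalog entry is marked not placeable.
- The growth model ignores nutrient depletion, colony expansion and
  signal consumption; fold changes assume growth identical across input
  states.
- Two dimensions only; multi-molecule wiring beyond the single explicit
  OR layer is out of scope.
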