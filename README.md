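# macchiato

Design automation for **spatial bacterial computation**: digital logic built
not from gene-regulatory wiring but from the *positions* of bacterial
colonies on an agar plate.

Inputs are sources of a diffusible signal molecule — robotically dispensed
inducer droplets (IPTG) or biosensing *sender* colonies that secrete a
quorum-sensing molecule (3OC6-HSL) when an environmental stimulus is
present. Because diffusion is linear, overlapping gradients **add**: a
*receiver* colony at a given position sees the sum of per-input
contributions set by its distance to each source. Engineered receivers
convert that concentration into a digital fluorescence output through one
of four threshold response functions:

| kind | ON when |
|---|---|
| highpass | `u > θ` |
| lowpass | `u < θ` |
| bandpass | `θ_lo < u < θ_hi` |
| bandstop | `u < θ_lo` or `u > θ_hi` |

Moving a receiver relative to its inputs therefore reprograms its logic
without touching a single base pair. This package answers the four design
questions such devices pose:

1. **Realizability** (`macchiato.axis`) — which truth tables can a *single*
   receiver compute? Input states map to subset sums of a nonnegative
   contribution vector; the achievable orderings of those sums are
   enumerated exhaustively by depth-first extension of the subset partial
   order with linear-programming feasibility checks, and each activation
   function contributes its interval partitions. With bandpass + bandstop
   alone, all **16** two-input gates are single-receiver computable; with
   the full four-function set, **152 of the 256** three-input gates are.
2. **Minimization** (`macchiato.minimize`) — the *Macchiato algorithm*:
   for any truth table (don't-cares allowed), find the minimal set of
   receivers whose **implicit OR** (the device is ON if any receiver
   colony is ON) realizes it. Exact branch-and-bound set cover over the
   realizable sub-functions; every three-input gate needs at most two
   colonies, and an n-input gate whose output is OFF with no inputs
   present needs at most n − 1.
3. **Simulation** (`macchiato.simulator`) — a 2-D explicit finite-difference
   reaction-diffusion model with logistic colony growth, Hill-type
   dose-responses, and response commitment (colonies read their local
   concentration at a fixed time and hold the decision, matching the
   temporally static expression rings seen on plates). Produces
   concentration fields, per-pixel *gate maps*, per-colony fold changes,
   and the **gate score** — least-fluorescent ON state over
   most-fluorescent OFF state; score > 1 means the gate works.
4. **Placement** (`macchiato.placement`) — positions are restricted to a
   384-well-plate lattice (4.5 mm pitch). A seeded evolutionary algorithm
   (tournament selection, lattice-step mutation, uniform crossover,
   elitism) searches layouts maximizing the simulated ON/OFF separation,
   starting from witness-guided seeds that map each receiver's abstract
   design through the strain's decision thresholds onto target distances.

`macchiato.catalog` ships the demonstrated-gate catalog — OR/AND/XOR/NIMPLY,
the single-colony three-input set (0x7F, 0x37, Majority, one-hot), a
four-input gate, the two-colony set (the 0x1B multiplexer, cellular-automaton
rules 30 and 110, 0x6F), and the sender-based OR/NOR/NAND/IMPLY — each with
a pinned receiver decomposition that the whole pipeline reproduces end to end.

## Worked example: a 2-to-1 multiplexer in bacteria

Gate codes read the output column for state `00…0` first into the most
significant bit, so `IF C THEN B ELSE A` is `0x1B`: it decomposes into a
bandpass receiver computing `A AND NOT C` (`0x0A`) and a highpass receiver
computing `B AND C` (`0x11`).

```python
from macchiato import (EAConfig, SimGrid, optimize_layout, simulate_layout,
                       induced_truth_table)
from macchiato.catalog import paper_gate_catalog, pinned_design, device_for

gate = next(g for g in paper_gate_catalog() if g.code == 0x1B)
design = pinned_design(gate)
cfg = device_for(gate, grid=SimGrid(spacing=0.5, dt=0.04))
layout, trace = optimize_layout(
    design, EAConfig(population=32, generations=40, seed=1), cfg)
res = simulate_layout(layout, design, cfg)
```

prints (via the obvious loops):

```
bandpass  realizes 0xA
highpass  realizes 0x11
A   input     at (22.5, 22.5) mm
B   input     at (0.0, 18.0) mm
C   input     at (18.0, 22.5) mm
R0  receiver  at (18.0, 18.0) mm
R1  receiver  at (9.0, 22.5) mm
simulated truth table: 0x1B   gate score: 2.59
```

The evolved layout puts the bandpass receiver R0 close to A (in-band when A
is present, pushed over the band when C is also present) and the highpass
receiver R1 between B and C (firing only on their summed gradients); the
simulated device reproduces the multiplexer truth table with every ON state
at least 2.59-fold brighter than any OFF state. The same pipeline is
scriptable from the shell:

```sh
macchiato enumerate --n 3                      # -> 152 of 256 ... realizable
macchiato design 0x1B --n 3 --kinds highpass,bandpass --out design.json
macchiato place design.json --seed 1 --out-dir run/
macchiato simulate design.json run/layout.csv
```

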