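"""Truth tables for spatial logic gates.

A truth table over ``n`` diffusible inputs assigns an output in ``{0, 1, DC}``
to each of the ``2**n`` input states.  Input A is the most significant bit of
the state index, so for three inputs state ``0b110`` means "A and B present,
C absent".

Hex gate codes follow the convention used throughout this package: the output
for state ``0`` (no inputs present) is the most significant bit of the code,

    code = sum(output[i] * 2**(2**n - 1 - i) for i in range(2**n))

so for three inputs ``0x0A`` is ON exactly at states ``100`` and ``110``
(A AND NOT C) and ``0x11`` is ON at ``011`` and ``111`` (B AND C).  The
opposite bit order (state ``11...1`` in the least significant bit, as used
by Wolfram cellular-automaton rule numbers) is also common; helpers for
converting rule numbers are provided so the two are never mixed silently.
Don't-care entries have no hex encoding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "DC",
    "TruthTable",
    "GateScoreSample",
    "tt_from_hex",
    "tt_from_wolfram_rule",
    "tt_or",
    "enumerate_all_gates",
    "gate_score",
]

#: Sentinel for a "don't care" output entry.
DC: None = None

_MAX_ENUM_INPUTS = 4


def _validate_outputs(outputs: Sequence, n_inputs: int) -> tuple:
    if n_inputs < 1:
        raise ValueError(f"n_inputs must be >= 1, got {n_inputs}")
    out = tuple(outputs)
    if len(out) != 2**n_inputs:
        raise ValueError(
            f"expected {2**n_inputs} outputs for {n_inputs} inputs, got {len(out)}"
        )
    for o in out:
        if o not in (0, 1, DC):
            raise ValueError(f"outputs must be 0, 1 or DC (None); got {o!r}")
    return out


@dataclass(frozen=True)
class TruthTable:
    """An n-input single-output digital function over {0, 1, DC}.

    Parameters
    ----------
    n_inputs:
        Number of digital inputs (>= 1).
    outputs:
        One entry per input state, indexed with input A as the most
        significant bit.  ``None`` marks a don't-care state.
    label:
        Free-text name, e.g. ``"XOR"`` or ``"Rule 30"``.
    """

    n_inputs: int
    outputs: tuple = field(default=())
    label: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "outputs", _validate_outputs(self.outputs, self.n_inputs)
        )

    # -- basic queries -----------------------------------------------------

    @property
    def n_states(self) -> int:
        return 2**self.n_inputs

    @property
    def has_dc(self) -> bool:
        return any(o is DC for o in self.outputs)

    def on_states(self) -> tuple[int, ...]:
        """State indices with output 1."""
        return tuple(i for i, o in enumerate(self.outputs) if o == 1)

    def off_states(self) -> tuple[int, ...]:
        return tuple(i for i, o in enumerate(self.outputs) if o == 0)

    def state_bits(self, state: int) -> tuple[int, ...]:
        """Bit vector (A first) for a state index."""
        n = self.n_inputs
        return tuple((state >> (n - 1 - k)) & 1 for k in range(n))

    # -- encodings ---------------------------------------------------------

    def to_hex(self) -> int:
        """Gate code with state 0's output as the most significant bit."""
        if self.has_dc:
            raise ValueError("truth table with DC entries has no hex code")
        m = self.n_states
        return sum(o << (m - 1 - i) for i, o in enumerate(self.outputs))

    def bitstring(self, state: int) -> str:
        return "".join(str(b) for b in self.state_bits(state))

    def complement(self) -> "TruthTable":
        out = tuple(DC if o is DC else 1 - o for o in self.outputs)
        return TruthTable(self.n_inputs, out, label=f"NOT({self.label})" if self.label else "")

    def with_label(self, label: str) -> "TruthTable":
        return TruthTable(self.n_inputs, self.outputs, label=label)

    def __str__(self) -> str:
        rows = ", ".join(
            f"{self.bitstring(i)}->{'DC' if o is DC else o}"
            for i, o in enumerate(self.outputs)
        )
        name = self.label or (f"0x{self.to_hex():X}" if not self.has_dc else "table")
        return f"{name}[{rows}]"


def tt_from_hex(code: int, n_inputs: int, label: str = "") -> TruthTable:
    """Build the DC-free truth table encoded by a hex gate code.

    ``code`` must lie in ``[0, 2**(2**n_inputs))``; the most significant bit
    of the code is the output for the all-absent state.
    """
    m = 2**n_inputs
    if not 0 <= code < 2**m:
        raise ValueError(
            f"gate code 0x{code:X} out of range for {n_inputs} inputs "
            f"(must be 0 <= code < 2**{m})"
        )
    outputs = tuple((code >> (m - 1 - i)) & 1 for i in range(m))
    return TruthTable(n_inputs, outputs, label=label)


def tt_from_wolfram_rule(rule: int, n_inputs: int = 3, label: str = "") -> TruthTable:
    """Truth table of a Wolfram cellular-automaton rule number.

    Rule numbers put the output for state ``11...1`` in the most significant
    bit, i.e. the reverse of this package's gate-code bit order:
    Rule 30 is gate code 0x78 and Rule 110 is 0x76.
    """
    m = 2**n_inputs
    if not 0 <= rule < 2**m:
        raise ValueError(f"rule {rule} out of range for {n_inputs} inputs")
    outputs = tuple((rule >> i) & 1 for i in range(m))
    return TruthTable(n_inputs, outputs, label=label or f"Rule {rule}")


def tt_or(tables: Sequence[TruthTable], label: str = "") -> TruthTable:
    """Implicit-OR combination: ON wherever any table is ON.

    This is the read-out convention for multi-receiver gates: the computation
    is ON if any individual receiver colony is ON.  All tables must share
    ``n_inputs`` and be DC-free.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("tt_or requires at least one table")
    n = tables[0].n_inputs
    for t in tables:
        if t.n_inputs != n:
            raise ValueError(
                f"mismatched n_inputs: {t.n_inputs} != {n} (table {t.label or t})"
            )
        if t.has_dc:
            raise ValueError("tt_or is defined for DC-free tables only")
    outputs = tuple(
        1 if any(t.outputs[i] == 1 for t in tables) else 0 for i in range(2**n)
    )
    return TruthTable(n, outputs, label=label)


def enumerate_all_gates(n_inputs: int) -> list[TruthTable]:
    """All ``2**(2**n)`` DC-free truth tables on ``n_inputs`` inputs.

    Guarded at ``n_inputs <= 4``: beyond that the catalog is astronomically
    large and enumeration is never what you want.
    """
    if n_inputs > _MAX_ENUM_INPUTS:
        raise ValueError(
            f"enumeration supported for n_inputs <= {_MAX_ENUM_INPUTS} "
            f"(2**(2**{n_inputs}) tables is not enumerable)"
        )
    return [tt_from_hex(code, n_inputs) for code in range(2 ** (2**n_inputs))]


@dataclass(frozen=True)
class GateScoreSample:
    """Fold-change observations for the ON and OFF states of one gate.

    ``on_values`` / ``off_values`` are positive fold changes (fluorescence
    relative to the same colony with no inputs), one per input state in the
    respective class.
    """

    on_values: tuple[float, ...]
    off_values: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "on_values", tuple(float(v) for v in self.on_values))
        object.__setattr__(self, "off_values", tuple(float(v) for v in self.off_values))
        for v in self.on_values + self.off_values:
            if not v > 0:
                raise ValueError(f"fold changes must be positive, got {v}")
        if not self.on_values and not self.off_values:
            raise ValueError("at least one of on_values/off_values must be non-empty")


def gate_score(sample: GateScoreSample) -> float:
    """Least-fluorescent ON state divided by most-fluorescent OFF state.

    A score above 1 means every ON state outshines every OFF state, i.e. the
    gate separates digitally.  A constant-ON gate (no OFF states) scores
    ``+inf``; a constant-OFF gate scores 0 with a warning, so batch scoring
    over catalogs never aborts.
    """
    if not sample.off_values:
        return math.inf
    if not sample.on_values:
        warnings.warn("gate with no ON states scores 0", stacklevel=2)
        return 0.0
    return min(sample.on_values) / max(sample.off_values)
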