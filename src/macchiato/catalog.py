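"""Catalogs of demonstrated spatial logic gates.

`paper_gate_catalog` lists every gate demonstrated with droplet inputs:
the four non-trivial two-input gates a highpass/bandpass pair can compute
(OR, AND, XOR, NIMPLY), the single-colony three-input set (0x7F, 0x37,
Majority, one-hot "sum = 1"), the four-input (A OR C OR D) AND NOT B, and
the multi-colony set (the 0x1B multiplexer, cellular-automaton rules 30
and 110, and 0x6F).  `sender_gate_catalog` lists the four non-trivial
two-input gates achievable with highpass and lowpass receivers reading a
quorum-sensing molecule produced by biosensing sender colonies (OR, NOR,
NAND, IMPLY).

Each entry pins an explicit receiver decomposition (kind + sub-function
gate code), so the catalog doubles as a regression suite: the pinned OR
of sub-functions must equal the gate, the exact minimizer must need no
more receivers than the pinned design, and seeded placement + simulation
must reproduce the truth table.

"Sum = 1" is read as the one-hot function (ON iff exactly one input is
present); three-input parity is included under its own label.  Note the
exact minimizer realizes rules 30 and 110 with a single bandpass colony
(their ON states fit one admissible concentration interval), so those
entries pin one receiver; two-colony implementations trade this economy
for wider concentration margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .axis import ReceiverAxisSpec, is_realizable_single
from .device import DeviceConfig, hsl_strains, iptg_strains, narrow_bandpass
from .logic import TruthTable, tt_from_hex, tt_from_wolfram_rule, tt_or
from .minimize import MacchiatoDesign

__all__ = [
    "CatalogGate",
    "paper_gate_catalog",
    "sender_gate_catalog",
    "pinned_design",
    "device_for",
]


def device_for(gate: "CatalogGate", **overrides) -> DeviceConfig:
    """The device configuration a catalog gate was designed for."""
    if gate.source_kind == "sender":
        overrides.setdefault("strains", hsl_strains())
        overrides.setdefault("source_kind", "sender")
    else:
        strains = iptg_strains()
        if gate.strain_variant == "narrow-bandpass":
            strains["bandpass"] = narrow_bandpass()
        overrides.setdefault("strains", strains)
    return DeviceConfig(**overrides)


@dataclass(frozen=True)
class CatalogGate:
    """One demonstrated gate: truth table plus its pinned receiver set.

    ``strain_variant`` selects a non-default strain for the bandpass slot
    ("narrow-bandpass" = the low-gain narrow-band variant); ``placeable``
    is False for catalog extras with no physical layout under the default
    strain library and lattice.
    """

    label: str
    n_inputs: int
    code: int
    receivers: tuple[tuple[str, int], ...]  # (activation kind, sub-function code)
    source_kind: str = "droplet"  # droplet (inducer) or sender (biosensor colony)
    strain_variant: Optional[str] = None
    placeable: bool = True

    @property
    def expected_receivers(self) -> int:
        return len(self.receivers)

    @property
    def kinds(self) -> frozenset[str]:
        return frozenset(k for k, _ in self.receivers)

    def truth_table(self) -> TruthTable:
        return tt_from_hex(self.code, self.n_inputs, label=self.label)


def pinned_design(gate: CatalogGate) -> MacchiatoDesign:
    """Build the catalog's receiver design as a concrete MacchiatoDesign.

    Each pinned sub-function is converted to an axis witness restricted to
    its stated activation kind; the implicit OR of the witnesses must
    re-encode to the gate's code.
    """
    specs: list[ReceiverAxisSpec] = []
    for kind, sub in gate.receivers:
        res = is_realizable_single(tt_from_hex(sub, gate.n_inputs), {kind})
        if not res.realizable:
            raise ValueError(
                f"catalog gate {gate.label}: sub-function 0x{sub:X} is not "
                f"realizable with a {kind} receiver"
            )
        specs.append(res.witness)
    design = MacchiatoDesign(target=gate.truth_table(), receivers=tuple(specs))
    if design.output_table().to_hex() != gate.code:
        raise ValueError(f"catalog gate {gate.label}: pinned receivers do not OR to it")
    return design


def paper_gate_catalog() -> tuple[CatalogGate, ...]:
    """Droplet-input gates, Wolfram rules given as gate codes
    (Rule 30 = 0x78, Rule 110 = 0x76 in this package's bit order)."""
    rule30 = tt_from_wolfram_rule(30).to_hex()
    rule110 = tt_from_wolfram_rule(110).to_hex()
    return (
        CatalogGate("OR", 2, 0x7, (("highpass", 0x7),)),
        CatalogGate("AND", 2, 0x1, (("highpass", 0x1),)),
        CatalogGate("XOR", 2, 0x6, (("bandpass", 0x6),)),
        CatalogGate("NIMPLY", 2, 0x2, (("bandpass", 0x2),)),
        CatalogGate("0x7F", 3, 0x7F, (("highpass", 0x7F),)),
        CatalogGate("0x37", 3, 0x37, (("highpass", 0x37),)),
        CatalogGate("Majority", 3, 0x17, (("highpass", 0x17),)),
        CatalogGate("sum = 1", 3, 0x68, (("bandpass", 0x68),)),
        CatalogGate(
            "(A OR C OR D) AND NOT B", 4, 0x70F0, (("bandpass", 0x70F0),)
        ),
        CatalogGate(
            "0x1B (2-to-1 MUX)", 3, 0x1B,
            (("bandpass", 0x0A), ("highpass", 0x11)),
        ),
        CatalogGate("Rule 30", 3, rule30, (("bandpass", rule30),)),
        CatalogGate(
            "Rule 110", 3, rule110,
            (("bandpass", 0x16), ("bandpass", 0x60)),
            strain_variant="narrow-bandpass",
        ),
        CatalogGate("0x6F", 3, 0x6F, (("bandpass", 0x66), ("highpass", 0x0F))),
        CatalogGate(
            "XOR3 (parity)", 3, 0x69,
            (("bandpass", 0x68), ("highpass", 0x1)),
            placeable=False,
        ),
    )


def sender_gate_catalog() -> tuple[CatalogGate, ...]:
    """Sender-input gates: the four non-trivial two-input functions
    achievable with highpass and lowpass receivers.  NAND and IMPLY need
    two colonies, combined from NOT and IDENTITY sub-functions."""
    return (
        CatalogGate("OR", 2, 0x7, (("highpass", 0x7),), source_kind="sender"),
        CatalogGate("NOR", 2, 0x8, (("lowpass", 0x8),), source_kind="sender"),
        CatalogGate(
            "NAND", 2, 0xE,
            (("lowpass", 0xC), ("lowpass", 0xA)),
            source_kind="sender",
        ),
        CatalogGate(
            "IMPLY", 2, 0xD,
            (("lowpass", 0xC), ("highpass", 0x5)),
            source_kind="sender",
        ),
    )
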