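"""The Macchiato algorithm: minimal receiver-set decomposition.

A truth table that no single receiver can compute is decomposed into a small
set of receivers read out under implicit-OR semantics: the computation is ON
iff any receiver colony is ON.  Each receiver must therefore be OFF at every
state where the target is OFF (a hard constraint), and together the
receivers must cover every target-ON state; don't-care states are free.

This is a minimum set cover over the catalog of single-receiver-realizable
sub-functions of the target.  An exact branch-and-bound solver is the
default for n <= 4; a greedy coverage-maximizing heuristic is available for
quick answers and never beats the exact receiver count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .axis import (
    ACTIVATION_KINDS,
    ReceiverAxisSpec,
    enumerate_realizable,
    induced_truth_table,
)
from .logic import DC, TruthTable, tt_from_hex, tt_or

__all__ = [
    "MacchiatoDesign",
    "InfeasibleDesignError",
    "macchiato_minimize",
    "validate_design",
    "explicit_or_layer",
]


class InfeasibleDesignError(ValueError):
    """No receiver set can realize the target; carries an uncoverable state."""

    def __init__(self, message: str, uncoverable_state: int):
        super().__init__(message)
        self.uncoverable_state = uncoverable_state


@dataclass(frozen=True)
class MacchiatoDesign:
    """A receiver set realizing a target table under implicit-OR read-out."""

    target: TruthTable
    receivers: tuple[ReceiverAxisSpec, ...]
    or_mode: str = "implicit"

    def __post_init__(self):
        if self.or_mode not in ("implicit", "explicit_highpass"):
            raise ValueError(f"unknown or_mode {self.or_mode!r}")
        object.__setattr__(self, "receivers", tuple(self.receivers))

    @property
    def n_receivers(self) -> int:
        return len(self.receivers)

    def induced_tables(self) -> tuple[TruthTable, ...]:
        return tuple(induced_truth_table(r) for r in self.receivers)

    def output_table(self) -> TruthTable:
        """The implicit-OR of the receivers (constant FALSE if empty)."""
        if not self.receivers:
            return tt_from_hex(0, self.target.n_inputs, label="FALSE")
        return tt_or(self.induced_tables(), label=self.target.label)


def _masks(tt: TruthTable) -> tuple[int, int]:
    """(ON bitmask, OFF bitmask) over states; bit i set for state i."""
    on = sum(1 << i for i, o in enumerate(tt.outputs) if o == 1)
    off = sum(1 << i for i, o in enumerate(tt.outputs) if o == 0)
    return on, off


def _code_on_mask(code: int, m: int) -> int:
    """ON-state bitmask of a DC-free gate code (bit i = state i)."""
    on = 0
    for i in range(m):
        if (code >> (m - 1 - i)) & 1:
            on |= 1 << i
    return on


def _candidates(
    n: int, kinds: tuple[str, ...], off_mask: int
) -> list[tuple[int, int, ReceiverAxisSpec]]:
    """Realizable sub-functions never ON where the target is OFF.

    Returns (on_mask, cost-tiebreak key encoded separately, witness) tuples
    sorted by descending coverage, then fewer thresholds, then lower code.
    """
    m = 2**n
    cat = enumerate_realizable(n, kinds)
    cands = []
    for code, spec in cat.items():
        on = _code_on_mask(code, m)
        if on == 0 or on & off_mask:
            continue
        cands.append((on, code, spec))
    cands.sort(
        key=lambda t: (-bin(t[0]).count("1"), t[2].activation.n_thresholds, t[1])
    )
    return cands


def _greedy_cover(
    target_on: int, cands: Sequence[tuple[int, int, ReceiverAxisSpec]]
) -> Optional[list[int]]:
    chosen: list[int] = []
    uncovered = target_on
    while uncovered:
        best = None
        best_key = None
        for idx, (on, code, spec) in enumerate(cands):
            gain = bin(on & uncovered).count("1")
            if gain == 0:
                continue
            key = (-gain, spec.activation.n_thresholds, code)
            if best_key is None or key < best_key:
                best, best_key = idx, key
        if best is None:
            return None
        chosen.append(best)
        uncovered &= ~cands[best][0]
    return chosen


def _cover_key(
    cover: Sequence[int], cands: Sequence[tuple[int, int, ReceiverAxisSpec]]
) -> tuple:
    """Tie-break key: total thresholds, then sorted gate codes."""
    codes = sorted(cands[i][1] for i in cover)
    return (sum(cands[i][2].activation.n_thresholds for i in cover), tuple(codes))


def _exact_cover(
    target_on: int,
    cands: Sequence[tuple[int, int, ReceiverAxisSpec]],
    upper: int,
    node_cap: int = 200_000,
) -> Optional[list[int]]:
    """Branch-and-bound minimum cover with deterministic tie-breaking.

    Finds the minimal cover size, enumerating covers of that size and
    keeping the best by (total thresholds, sorted gate codes).  ``node_cap``
    bounds the enumeration; past it only strictly smaller covers are
    recorded, which keeps the result minimal and deterministic either way.
    The lower bound is ceil(|uncovered| / max single coverage).
    """
    if target_on == 0:
        return []
    best: list[Optional[list[int]]] = [None]
    best_size = [upper + 1]
    best_key: list = [None]
    nodes = [0]
    max_cov = max((bin(on).count("1") for on, _, _ in cands), default=0)
    if max_cov == 0:
        return None

    def record(chosen: list[int]) -> None:
        key = _cover_key(chosen, cands)
        if (
            len(chosen) < best_size[0]
            or best_key[0] is None
            or key < best_key[0]
        ):
            best[0] = list(chosen)
            best_size[0] = len(chosen)
            best_key[0] = key

    def search(uncovered: int, chosen: list[int]) -> None:
        nodes[0] += 1
        if not uncovered:
            record(chosen)
            return
        need = -(-bin(uncovered).count("1") // max_cov)
        limit = best_size[0] if nodes[0] > node_cap else best_size[0] + 1
        if len(chosen) + need >= limit:
            return
        # branch on the lowest uncovered state: some candidate must cover it
        pivot = (uncovered & -uncovered).bit_length() - 1
        for idx, (on, _, _) in enumerate(cands):
            if not (on >> pivot) & 1:
                continue
            chosen.append(idx)
            search(uncovered & ~on, chosen)
            chosen.pop()

    search(target_on, [])
    return best[0]


def macchiato_minimize(
    tt: TruthTable,
    available_kinds: Iterable[str] = ACTIVATION_KINDS,
    exact: bool = True,
) -> MacchiatoDesign:
    """Find a minimal receiver set whose implicit OR realizes ``tt``.

    With ``exact=True`` (default) the receiver count is globally minimal;
    ``exact=False`` runs a greedy set cover (same candidate catalog, never
    fewer receivers than the exact optimum).  Ties among minimal covers are
    broken toward fewer total thresholds, then lower gate codes, so output
    is deterministic.

    Raises :class:`InfeasibleDesignError` when some ON state cannot be
    covered at all — e.g. a target ON at the all-absent state when only
    highpass and bandpass receivers are available.
    """
    kinds = tuple(k for k in ACTIVATION_KINDS if k in set(available_kinds))
    if not kinds:
        raise ValueError("at least one activation kind required")
    if tt.n_inputs > 4:
        raise ValueError("macchiato_minimize supported for n_inputs <= 4")
    target_on, target_off = _masks(tt)
    cands = _candidates(tt.n_inputs, kinds, target_off)
    coverable = 0
    for on, _, _ in cands:
        coverable |= on
    missing = target_on & ~coverable
    if missing:
        state = (missing & -missing).bit_length() - 1
        bits = format(state, f"0{tt.n_inputs}b")
        raise InfeasibleDesignError(
            f"state {bits} is ON in the target but no available receiver "
            f"({', '.join(kinds)}) can be ON there while staying OFF on all "
            "target-OFF states",
            uncoverable_state=state,
        )
    greedy = _greedy_cover(target_on, cands)
    assert greedy is not None  # coverability established above
    if exact:
        chosen = _exact_cover(target_on, cands, upper=len(greedy))
        assert chosen is not None
    else:
        chosen = greedy
    receivers = tuple(cands[i][2] for i in sorted(chosen, key=lambda i: cands[i][1]))
    return MacchiatoDesign(target=tt, receivers=receivers)


@dataclass(frozen=True)
class StateReport:
    state: int
    bitstring: str
    target: object  # 0, 1 or DC (None)
    receiver_outputs: tuple[int, ...]
    or_output: int
    ok: bool


def validate_design(design: MacchiatoDesign) -> tuple[bool, list[StateReport]]:
    """Check the implicit OR of the receivers against the target, per state.

    Mismatches are reported, never raised; DC states always pass.
    """
    tt = design.target
    tables = design.induced_tables()
    for t in tables:
        if t.n_inputs != tt.n_inputs:
            raise ValueError("receiver/target input-count mismatch")
    reports = []
    ok_all = True
    for i in range(tt.n_states):
        outs = tuple(t.outputs[i] for t in tables)
        orv = 1 if any(o == 1 for o in outs) else 0
        tgt = tt.outputs[i]
        ok = tgt is DC or orv == tgt
        ok_all &= ok
        reports.append(StateReport(i, tt.bitstring(i), tgt, outs, orv, ok))
    return ok_all, reports


def explicit_or_layer(design: MacchiatoDesign) -> dict:
    """Second-layer OR read-out as a structural description.

    Instead of the implicit OR (reading every first-layer colony), a single
    highpass receiver listening on a *distinct* diffusible channel produced
    by all first-layer receivers reports the result.  This costs one extra
    signaling molecule and is purely structural — no new feasibility
    computation is involved.
    """
    nodes = [
        {
            "layer": 1,
            "index": i,
            "kind": r.activation.kind,
            "role": "term",
        }
        for i, r in enumerate(design.receivers)
    ]
    if not design.receivers:
        return {"nodes": [], "extra_molecules": 0, "redundant": False}
    redundant = len(design.receivers) == 1
    nodes.append(
        {
            "layer": 2,
            "index": 0,
            "kind": "highpass",
            "role": "or",
            "reads": "secondary diffusible channel produced by all layer-1 receivers",
        }
    )
    return {"nodes": nodes, "extra_molecules": 1, "redundant": redundant}
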