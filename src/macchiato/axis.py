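"""The signal-concentration axis: additive contributions and threshold logic.

A receiver colony reduces the 2-D geometry of its inputs to a single number:
the local signal concentration.  Each input source, when present, adds a
nonnegative contribution ``c_i`` (set by its distance to the receiver), and
contributions from overlapping diffusion fields are additive, so input state
``s`` is seen as the subset sum ``sum(c_i for i in s)``.  The receiver's
activation function — highpass, lowpass, bandpass or bandstop — partitions
the axis into ON and OFF intervals, and the induced digital function is the
activation applied to the 2**n subset sums.

Which digital functions a single receiver can compute therefore depends on
which *orderings* of the subset sums are achievable by some nonnegative
contribution vector.  The all-absent state always sits at concentration 0
(the axis minimum) and supersets never sit below subsets.  Admissible strict
orderings are found by depth-first extension of the subset partial order with
linear-programming feasibility checks; this is exhaustive for n <= 4.

Thresholds are strictly positive and inequalities strict, with an explicit
margin separating every state concentration from every threshold: at zero
concentration a highpass or bandpass receiver is OFF and a lowpass or
bandstop receiver is ON.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .logic import DC, TruthTable, tt_from_hex

__all__ = [
    "ACTIVATION_KINDS",
    "ActivationFunction",
    "ReceiverAxisSpec",
    "RealizabilityResult",
    "state_concentration",
    "apply_activation",
    "induced_truth_table",
    "admissible_orders",
    "is_realizable_single",
    "enumerate_realizable",
    "realizable_codes",
    "min_blocks",
    "random_witness_codes",
]

#: The four engineered response shapes, in canonical order.
ACTIVATION_KINDS = ("highpass", "lowpass", "bandpass", "bandstop")

#: Kinds needing two thresholds.
_TWO_THRESHOLD = frozenset({"bandpass", "bandstop"})

#: Default margin after normalizing the maximum subset sum to 1.
DEFAULT_MARGIN = 1e-6


@dataclass(frozen=True)
class ActivationFunction:
    """A threshold response shape.

    ``theta_lo`` is the single threshold for highpass/lowpass and the lower
    threshold for bandpass/bandstop; ``theta_hi`` applies only to the
    two-threshold kinds.  Thresholds are strictly positive (concentration
    units are arbitrary but shared with the contribution vector).
    """

    kind: str
    theta_lo: float
    theta_hi: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ACTIVATION_KINDS:
            raise ValueError(f"unknown activation kind {self.kind!r}")
        if not self.theta_lo > 0:
            raise ValueError("theta_lo must be > 0")
        if self.kind in _TWO_THRESHOLD:
            if self.theta_hi is None:
                raise ValueError(f"{self.kind} requires theta_hi")
            if not self.theta_lo < self.theta_hi:
                raise ValueError("theta_lo < theta_hi required")
        elif self.theta_hi is not None:
            raise ValueError(f"{self.kind} takes a single threshold")

    @property
    def n_thresholds(self) -> int:
        return 2 if self.kind in _TWO_THRESHOLD else 1

    def __call__(self, value: float) -> int:
        return apply_activation(self, value)

    def scaled(self, lam: float) -> "ActivationFunction":
        hi = None if self.theta_hi is None else self.theta_hi * lam
        return ActivationFunction(self.kind, self.theta_lo * lam, hi)


def apply_activation(act: ActivationFunction, value: float) -> int:
    """Digital output of an activation function at a concentration.

    All comparisons are strict; since thresholds are positive, zero
    concentration gives 0 for highpass/bandpass and 1 for lowpass/bandstop.
    """
    if value < 0:
        raise ValueError(f"concentration must be nonnegative, got {value}")
    if act.kind == "highpass":
        return int(value > act.theta_lo)
    if act.kind == "lowpass":
        return int(value < act.theta_lo)
    in_band = act.theta_lo < value < act.theta_hi
    if act.kind == "bandpass":
        return int(in_band)
    return int(not in_band)  # bandstop


def state_concentration(contributions: Sequence[float], state_bits: Sequence[int]) -> float:
    """Subset sum of the contributions over the inputs present in a state."""
    c = tuple(contributions)
    bits = tuple(state_bits)
    if len(bits) != len(c):
        raise ValueError(
            f"state has {len(bits)} bits but there are {len(c)} contributions"
        )
    return float(sum(ci for ci, b in zip(c, bits) if b))


@dataclass(frozen=True)
class ReceiverAxisSpec:
    """A receiver's abstract design: activation function + input contributions.

    ``margin`` is the minimum separation required between any state
    concentration and any threshold; the induced truth table is undefined
    (and an error) if a state lands within the margin of a threshold.
    """

    activation: ActivationFunction
    contributions: tuple[float, ...]
    margin: float = DEFAULT_MARGIN

    def __post_init__(self):
        c = tuple(float(x) for x in self.contributions)
        if not c:
            raise ValueError("at least one contribution required")
        if any(x < 0 for x in c):
            raise ValueError("contributions must be nonnegative")
        if not self.margin > 0:
            raise ValueError("margin must be positive")
        object.__setattr__(self, "contributions", c)

    @property
    def n_inputs(self) -> int:
        return len(self.contributions)

    def scaled(self, lam: float) -> "ReceiverAxisSpec":
        """Scale contributions and thresholds together; the induced table
        is invariant under this (the axis has no intrinsic unit)."""
        if not lam > 0:
            raise ValueError("scale factor must be positive")
        return ReceiverAxisSpec(
            self.activation.scaled(lam),
            tuple(x * lam for x in self.contributions),
            self.margin * lam,
        )


def induced_truth_table(spec: ReceiverAxisSpec, label: str = "") -> TruthTable:
    """The digital function a receiver computes, state by state."""
    n = spec.n_inputs
    act = spec.activation
    thresholds = [act.theta_lo] + ([act.theta_hi] if act.theta_hi is not None else [])
    outputs = []
    for state in range(2**n):
        bits = [(state >> (n - 1 - k)) & 1 for k in range(n)]
        v = state_concentration(spec.contributions, bits)
        for th in thresholds:
            if abs(v - th) < spec.margin:
                bs = "".join(str(b) for b in bits)
                raise ValueError(
                    f"degenerate spec: state {bs} at concentration {v:g} is "
                    f"within margin {spec.margin:g} of threshold {th:g}"
                )
        outputs.append(apply_activation(act, v))
    return TruthTable(n, tuple(outputs), label=label)


# ---------------------------------------------------------------------------
# Admissible orderings of the subset sums
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdmissibleOrder:
    """A strict ordering of all input states achievable by additive weights.

    ``order[k]`` is the state index at rank ``k`` (rank 0 is always the
    all-absent state).  ``contributions`` is a witness vector, normalized so
    the full subset sums to 1, with consecutive gaps maximized; ``sums[k]``
    is the witness concentration at rank ``k``.
    """

    order: tuple[int, ...]
    contributions: tuple[float, ...]
    sums: tuple[float, ...]

    @property
    def n_inputs(self) -> int:
        return len(self.contributions)

    def rank_of(self) -> dict[int, int]:
        return {s: k for k, s in enumerate(self.order)}


def _state_row(state: int, n: int) -> np.ndarray:
    return np.array([(state >> (n - 1 - k)) & 1 for k in range(n)], dtype=float)


def _chain_lp(prefix: Sequence[int], n: int) -> Optional[tuple[np.ndarray, float]]:
    """Maximize the minimum consecutive gap of the subset sums along a chain.

    Variables are the n contributions (>= 0, summing to 1) plus the margin m.
    Returns (contributions, margin) when feasible with positive margin.
    """
    m = len(prefix)
    if m < 2:
        return np.full(n, 1.0 / n), 1.0
    rows = [_state_row(s, n) for s in prefix]
    # -(S_{k+1} - S_k) + margin <= 0
    a_ub = np.zeros((m - 1, n + 1))
    for k in range(m - 1):
        a_ub[k, :n] = rows[k] - rows[k + 1]
        a_ub[k, n] = 1.0
    a_eq = np.zeros((1, n + 1))
    a_eq[0, :n] = 1.0
    cost = np.zeros(n + 1)
    cost[n] = -1.0  # maximize margin
    res = linprog(
        cost,
        A_ub=a_ub,
        b_ub=np.zeros(m - 1),
        A_eq=a_eq,
        b_eq=[1.0],
        bounds=[(0, 1)] * n + [(0, 1)],
        method="highs",
    )
    if not res.success or res.x[n] <= DEFAULT_MARGIN:
        return None
    return res.x[:n], float(res.x[n])


@lru_cache(maxsize=8)
def admissible_orders(n_inputs: int) -> tuple[AdmissibleOrder, ...]:
    """All strict orderings of the 2**n subset sums realizable by some
    nonnegative contribution vector (exhaustive, n <= 4).

    Depth-first extension of the subset partial order (a state may only be
    placed once all its subsets are placed), pruning branches whose partial
    chain is LP-infeasible.  For n = 2 there are 2 orders, for n = 3 there
    are 12, for n = 4 there are 336.
    """
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    if n_inputs > 4:
        raise ValueError(
            "admissible-order enumeration supported for n_inputs <= 4 "
            "(the chain count grows super-exponentially)"
        )
    n = n_inputs
    m = 2**n
    subsets_of = [
        tuple(t for t in range(m) if t != s and (t & s) == t) for s in range(m)
    ]
    supersets_of = [
        tuple(t for t in range(m) if t != s and (t & s) == s) for s in range(m)
    ]
    results: list[AdmissibleOrder] = []
    rows = [_state_row(s, n) for s in range(m)]

    def extend(prefix: list[int], placed: int, cert: np.ndarray) -> None:
        if len(prefix) == m:
            sol = _chain_lp(prefix, n)  # max-margin witness for the full chain
            if sol is not None:
                c, _ = sol
                sums = tuple(float(rows[s] @ c) for s in prefix)
                results.append(AdmissibleOrder(tuple(prefix), tuple(c), sums))
            return
        last = prefix[-1]
        for s in range(1, m):
            if placed >> s & 1:
                continue
            if any(not (placed >> t & 1) for t in subsets_of[s]):
                continue
            # a proper superset of s already placed makes S(s) > S(t) impossible
            if any(placed >> t & 1 for t in supersets_of[s]):
                continue
            prefix.append(s)
            # the parent's witness may already certify the extended chain;
            # fall back to an LP only when it does not
            if float((rows[s] - rows[last]) @ cert) > DEFAULT_MARGIN:
                extend(prefix, placed | (1 << s), cert)
            else:
                sol = _chain_lp(prefix, n)
                if sol is not None:
                    extend(prefix, placed | (1 << s), sol[0])
            prefix.pop()

    extend([0], 1, np.full(n, 1.0 / n))
    return tuple(results)


# ---------------------------------------------------------------------------
# Activation patterns along an ordering
# ---------------------------------------------------------------------------


def _interval_patterns(kind: str, m: int) -> Iterable[tuple[int, int]]:
    """ON-rank intervals (lo, hi) producible by a kind on an m-state chain.

    For highpass the ON set is a suffix never containing rank 0; for lowpass
    a prefix always containing rank 0; for bandpass any (possibly empty)
    contiguous interval excluding rank 0.  Bandstop intervals are the OFF
    sets (complement of a bandpass interval).
    """
    if kind == "highpass":
        for lo in range(1, m + 1):
            yield (lo, m)
    elif kind == "lowpass":
        for hi in range(1, m + 1):
            yield (0, hi)
    elif kind in ("bandpass", "bandstop"):
        yield (1, 1)  # empty band
        for lo in range(1, m):
            for hi in range(lo + 1, m + 1):
                yield (lo, hi)
    else:
        raise ValueError(f"unknown activation kind {kind!r}")


def _pattern_code(order: Sequence[int], lo: int, hi: int, invert: bool) -> int:
    """Gate code of the table whose ON ranks are [lo, hi) (or its complement)."""
    m = len(order)
    code = 0
    for rank, state in enumerate(order):
        on = lo <= rank < hi
        if invert:
            on = not on
        if on:
            code |= 1 << (m - 1 - state)
    return code


def _thresholds_for_interval(
    sums: Sequence[float], kind: str, lo: int, hi: int
) -> tuple[float, Optional[float]]:
    """Positive thresholds separating ranks [lo, hi) from the rest of a chain.

    For bandstop the interval is the OFF band (same thresholds as the
    bandpass it complements).
    """
    m = len(sums)

    def cut(k: int) -> float:
        # threshold between rank k-1 and rank k; above the top for k == m
        if k <= 0:
            raise ValueError("cut below rank 0 would need a nonpositive threshold")
        if k >= m:
            return sums[-1] * 1.5 + 0.5
        return 0.5 * (sums[k - 1] + sums[k])

    if kind == "highpass":
        return cut(lo), None
    if kind == "lowpass":
        return cut(hi), None
    if lo == hi:  # empty band: both thresholds inside the first gap
        g0, g1 = sums[0], sums[1]
        return g0 + (g1 - g0) / 3.0, g0 + 2.0 * (g1 - g0) / 3.0
    return cut(lo), cut(hi)


@dataclass(frozen=True)
class RealizabilityResult:
    """Outcome of a single-receiver realizability query."""

    realizable: bool
    witness: Optional[ReceiverAxisSpec] = None
    blocks: int = 0

    def __bool__(self) -> bool:
        return self.realizable


def _match_interval(
    order: Sequence[int], tt: TruthTable, kind: str
) -> Optional[tuple[int, int]]:
    """ON-rank interval realizing ``tt`` on this ordering with ``kind``,
    honouring DC wildcards; None if impossible."""
    if kind == "bandstop":
        inner = _match_interval(order, tt.complement(), "bandpass")
        return inner
    m = len(order)
    forced1 = [k for k, s in enumerate(order) if tt.outputs[s] == 1]
    forced0 = [k for k, s in enumerate(order) if tt.outputs[s] == 0]
    if kind == "highpass":
        if forced1 and forced1[0] == 0:
            return None  # zero state cannot exceed a positive threshold
        lo = forced1[0] if forced1 else m
        if forced0 and forced0[-1] >= lo:
            return None
        return (lo, m)
    if kind == "lowpass":
        if forced0 and forced0[0] == 0:
            return None  # zero state is always below a positive threshold
        hi = (forced1[-1] + 1) if forced1 else 1
        if forced0 and forced0[0] < hi:
            return None
        return (0, hi)
    if kind == "bandpass":
        if not forced1:
            return (1, 1)
        if forced1[0] == 0:
            return None
        lo, hi = forced1[0], forced1[-1] + 1
        if any(lo <= k < hi for k in forced0):
            return None
        return (lo, hi)
    raise ValueError(f"unknown activation kind {kind!r}")


def _witness_from_match(
    ao: AdmissibleOrder, kind: str, lo: int, hi: int
) -> ReceiverAxisSpec:
    two = kind in _TWO_THRESHOLD
    th_lo, th_hi = _thresholds_for_interval(ao.sums, kind, lo, hi)
    act = ActivationFunction(kind, th_lo, th_hi if two else None)
    # actual separation between every state sum and every threshold
    ths = [act.theta_lo] + ([act.theta_hi] if act.theta_hi is not None else [])
    sep = min(abs(s - t) for s in ao.sums for t in ths)
    return ReceiverAxisSpec(act, ao.contributions, margin=min(sep * 0.5, DEFAULT_MARGIN))


def _normalize_kinds(kinds: Iterable[str]) -> tuple[str, ...]:
    ks = tuple(k for k in ACTIVATION_KINDS if k in set(kinds))
    bad = set(kinds) - set(ACTIVATION_KINDS)
    if bad:
        raise ValueError(f"unknown activation kinds: {sorted(bad)}")
    if not ks:
        raise ValueError("at least one activation kind required")
    return ks


def is_realizable_single(
    tt: TruthTable, available_kinds: Iterable[str] = ACTIVATION_KINDS
) -> RealizabilityResult:
    """Can one receiver colony compute this table?

    Searches every admissible ordering of the subset sums combined with every
    available activation kind; DC states may fall on either side of a
    threshold.  The witness, when found, is a concrete contribution vector
    and threshold set whose induced table matches ``tt`` on all non-DC
    states; ``blocks`` is the number of maximal same-output runs along the
    witness ordering.
    """
    kinds = _normalize_kinds(available_kinds)
    if tt.n_inputs > 4:
        raise ValueError("realizability search supported for n_inputs <= 4")
    for ao in admissible_orders(tt.n_inputs):
        for kind in kinds:
            match = _match_interval(ao.order, tt, kind)
            if match is None:
                continue
            lo, hi = match
            witness = _witness_from_match(ao, kind, lo, hi)
            induced = induced_truth_table(witness)
            # sanity: the witness must reproduce the table on non-DC states
            assert all(
                tt.outputs[i] is DC or tt.outputs[i] == induced.outputs[i]
                for i in range(tt.n_states)
            ), "internal error: witness does not match its pattern"
            blocks = _count_blocks(ao.order, induced)
            return RealizabilityResult(True, witness, blocks)
    return RealizabilityResult(False, None, 0)


def _count_blocks(order: Sequence[int], tt: TruthTable) -> int:
    seq = [tt.outputs[s] for s in order if tt.outputs[s] is not DC]
    if not seq:
        return 1
    return 1 + sum(1 for a, b in zip(seq, seq[1:]) if a != b)


@lru_cache(maxsize=64)
def _realizable_catalog(
    n_inputs: int, kinds: tuple[str, ...]
) -> dict[int, tuple[int, str, int, int]]:
    """Map gate code -> (order index, kind, lo, hi) for every realizable code."""
    catalog: dict[int, tuple[int, str, int, int]] = {}
    orders = admissible_orders(n_inputs)
    m = 2**n_inputs
    for idx, ao in enumerate(orders):
        for kind in kinds:
            invert = kind == "bandstop"
            base = "bandpass" if invert else kind
            for lo, hi in _interval_patterns(base, m):
                code = _pattern_code(ao.order, lo, hi, invert)
                if code not in catalog:
                    catalog[code] = (idx, kind, lo, hi)
    return catalog


def realizable_codes(
    n_inputs: int, available_kinds: Iterable[str] = ACTIVATION_KINDS
) -> frozenset[int]:
    """Set of hex gate codes computable by a single receiver."""
    kinds = _normalize_kinds(available_kinds)
    return frozenset(_realizable_catalog(n_inputs, kinds))


def enumerate_realizable(
    n_inputs: int, available_kinds: Iterable[str] = ACTIVATION_KINDS
) -> dict[int, ReceiverAxisSpec]:
    """Every single-receiver-computable gate with a concrete witness design.

    Returns ``{gate code: ReceiverAxisSpec}``; the induced table of each
    witness re-encodes to its key.  Deterministic: the witness is the first
    found in canonical order (orderings as enumerated, kinds in
    ``ACTIVATION_KINDS`` order, intervals lexicographic).
    """
    kinds = _normalize_kinds(available_kinds)
    orders = admissible_orders(n_inputs)
    out: dict[int, ReceiverAxisSpec] = {}
    for code, (idx, kind, lo, hi) in sorted(
        _realizable_catalog(n_inputs, kinds).items()
    ):
        out[code] = _witness_from_match(orders[idx], kind, lo, hi)
    return out


def min_blocks(tt: TruthTable) -> int:
    """Minimum number of maximal same-output runs over admissible orderings.

    DC states join whichever neighbouring block minimizes the count (they are
    simply skipped when counting runs).  A single receiver with the full
    activation set exists iff the minimizing ordering has <= 3 blocks with a
    pattern matching an available kind.
    """
    if tt.n_inputs > 4:
        raise ValueError("min_blocks supported for n_inputs <= 4")
    return min(_count_blocks(ao.order, tt) for ao in admissible_orders(tt.n_inputs))


def random_witness_codes(
    n_inputs: int,
    available_kinds: Iterable[str] = ACTIVATION_KINDS,
    n_samples: int = 100_000,
    seed: int = 0,
) -> frozenset[int]:
    """Monte-Carlo oracle: accumulate gate codes from random witnesses.

    Draws random positive contribution vectors; for each, sorts the subset
    sums and applies every threshold placement in every inter-sum gap for
    every available kind, recording the induced gate code.  Independent of
    the linear-feasibility enumeration: with enough samples the accumulated
    set equals the exact realizable set (it is always a subset).
    """
    kinds = _normalize_kinds(available_kinds)
    rng = np.random.default_rng(seed)
    n = n_inputs
    m = 2**n
    states = np.arange(m)
    bits = ((states[:, None] >> np.arange(n - 1, -1, -1)[None, :]) & 1).astype(float)
    weights = 2 ** (m - 1 - states)
    # all sampled subset-sum vectors at once; threshold placements are then
    # enumerated once per distinct observed ordering (the induced code set
    # depends on the sums only through their order)
    cs = rng.exponential(1.0, size=(n_samples, n))
    all_sums = cs @ bits.T
    orderings = np.argsort(all_sums, axis=1, kind="stable")
    _, first_idx = np.unique(orderings, axis=0, return_index=True)
    codes: set[int] = set()
    for idx in first_idx:
        sums = all_sums[idx]
        ordered = np.sort(sums)
        # two candidate thresholds per inter-sum gap, plus above the top
        edges = np.concatenate([ordered, [ordered[-1] + 1.5]])
        cands = []
        for a, b in zip(edges[:-1], edges[1:]):
            cands.extend((a + (b - a) / 3.0, a + 2.0 * (b - a) / 3.0))
        cands = [t for t in cands if t > 0]
        for kind in kinds:
            if kind in ("highpass", "lowpass"):
                for th in cands:
                    on = sums > th if kind == "highpass" else sums < th
                    codes.add(int(weights[on].sum()))
            else:
                for i, tl in enumerate(cands):
                    for th in cands[i + 1 :]:
                        band = (sums > tl) & (sums < th)
                        on = band if kind == "bandpass" else ~band
                        codes.add(int(weights[on].sum()))
    return frozenset(codes)
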