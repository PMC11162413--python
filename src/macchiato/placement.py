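"""Evolutionary optimization of input and receiver positions.

Robotic dispensing constrains droplets and colonies to a 384-well-pitch
lattice (4.5 mm).  Given a receiver design, this module searches those
lattice positions for a layout whose simulated behavior realizes the
designed truth table, maximizing the separation between the dimmest
function-ON state and the brightest function-OFF state.

The search is a generational evolutionary algorithm: tournament selection,
uniform per-node crossover, single-lattice-step mutation in the
8-neighborhood, elitism of one, and deterministic repair of constraint
violations, all driven by a seeded generator so runs are reproducible.
The initial population mixes random layouts with witness-guided seeds:
each receiver's abstract contribution vector is mapped through the
strain's decision crossings and the simulated radial concentration
profile to target distances, and inputs are placed at lattice sites
approximating them.  Placement is the hard part of the design problem —
moving an input relative to one receiver moves it relative to all others
— so seeds only start the search and the simulator has the final word.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .device import DeviceConfig, decision_crossings, radial_concentration
from .logic import TruthTable
from .minimize import MacchiatoDesign
from .simulator import SimResult, activity_threshold, predict_gate

__all__ = [
    "LayoutSpec",
    "LayoutNode",
    "EAConfig",
    "fitness",
    "simulate_layout",
    "optimize_layout",
    "geometric_feasibility_report",
]

_INPUT_NAMES = "ABCDEFGH"


@dataclass(frozen=True)
class LayoutNode:
    role: str  # "input" | "receiver"
    id: str
    position: tuple[float, float]

    def __post_init__(self):
        if self.role not in ("input", "receiver"):
            raise ValueError(f"unknown node role {self.role!r}")


@dataclass(frozen=True)
class LayoutSpec:
    """Grid-constrained physical positions of inputs and receivers."""

    nodes: tuple[LayoutNode, ...]
    pitch: float = 4.5
    bounds: tuple[float, float] = (35.0, 35.0)
    min_separation: float = 4.5

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        for node in self.nodes:
            x, y = node.position
            if not (0 <= x <= self.bounds[0] and 0 <= y <= self.bounds[1]):
                raise ValueError(f"node {node.id} at {node.position} out of bounds")
            for c in (x, y):
                if abs(c / self.pitch - round(c / self.pitch)) > 1e-6:
                    raise ValueError(
                        f"node {node.id} at {node.position} off the "
                        f"{self.pitch} mm lattice"
                    )
        for a, b in itertools.combinations(self.nodes, 2):
            d = np.hypot(
                a.position[0] - b.position[0], a.position[1] - b.position[1]
            )
            if d < self.min_separation - 1e-6:
                raise ValueError(
                    f"nodes {a.id} and {b.id} are {d:.2f} mm apart "
                    f"(min {self.min_separation} mm)"
                )

    def inputs(self) -> tuple[LayoutNode, ...]:
        return tuple(n for n in self.nodes if n.role == "input")

    def receivers(self) -> tuple[LayoutNode, ...]:
        return tuple(n for n in self.nodes if n.role == "receiver")

    def position_of(self, node_id: str) -> tuple[float, float]:
        for n in self.nodes:
            if n.id == node_id:
                return n.position
        raise KeyError(node_id)


@dataclass(frozen=True)
class EAConfig:
    """Evolutionary-search hyperparameters (reconstructed defaults)."""

    population: int = 48
    generations: int = 60
    mutation_rate: float = 0.35
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 0
    penalty_weight: float = 2.0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Genotype: integer lattice coordinates, one row per node
# ---------------------------------------------------------------------------


def _lattice_size(cfg: DeviceConfig) -> int:
    return int(np.floor(min(cfg.grid.extent) / cfg.pitch)) + 1

def _sep_cells(cfg: DeviceConfig) -> float:
    return cfg.min_separation / cfg.pitch


def _valid(geno: np.ndarray, cfg: DeviceConfig) -> bool:
    nlat = _lattice_size(cfg)
    if geno.min() < 0 or geno.max() >= nlat:
        return False
    d2min = (_sep_cells(cfg) - 1e-9) ** 2
    for i in range(len(geno)):
        for j in range(i + 1, len(geno)):
            if ((geno[i] - geno[j]) ** 2).sum() < d2min:
                return False
    return True


def _repair(geno: np.ndarray, cfg: DeviceConfig, rng: np.random.Generator) -> np.ndarray:
    """Clamp to the lattice and displace colliding nodes to free sites."""
    nlat = _lattice_size(cfg)
    g = np.clip(geno, 0, nlat - 1)
    d2min = (_sep_cells(cfg) - 1e-9) ** 2
    for i in range(len(g)):
        ok = all(
            ((g[i] - g[j]) ** 2).sum() >= d2min for j in range(i) if True
        )
        if ok:
            continue
        # deterministic spiral over sites ordered by distance from g[i]
        sites = np.array(
            [(a, b) for a in range(nlat) for b in range(nlat)], dtype=int
        )
        order = np.argsort(((sites - g[i]) ** 2).sum(axis=1), kind="stable")
        for k in order:
            cand = sites[k]
            if all(((cand - g[j]) ** 2).sum() >= d2min for j in range(i)):
                g[i] = cand
                break
        else:
            raise ValueError("lattice too small for the requested node count")
    return g


def _to_layout(geno: np.ndarray, ids_roles: Sequence[tuple[str, str]], cfg: DeviceConfig) -> LayoutSpec:
    nodes = tuple(
        LayoutNode(role, nid, (float(g[0] * cfg.pitch), float(g[1] * cfg.pitch)))
        for (nid, role), g in zip(ids_roles, geno)
    )
    return LayoutSpec(
        nodes,
        pitch=cfg.pitch,
        bounds=cfg.grid.extent,
        min_separation=cfg.min_separation,
    )


def _design_ids_roles(design: MacchiatoDesign) -> list[tuple[str, str]]:
    n = design.target.n_inputs
    out = [(_INPUT_NAMES[k], "input") for k in range(n)]
    out += [(f"R{j}", "receiver") for j in range(design.n_receivers)]
    return out


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


def simulate_layout(
    layout: LayoutSpec,
    design: MacchiatoDesign,
    cfg: DeviceConfig,
    field_cache: Optional[dict] = None,
) -> SimResult:
    """Predict the behavior of a design placed at a layout."""
    n = design.target.n_inputs
    inputs = layout.inputs()
    receivers = layout.receivers()
    if len(inputs) != n or len(receivers) != design.n_receivers:
        raise ValueError(
            f"layout has {len(inputs)} inputs / {len(receivers)} receivers; "
            f"design needs {n} / {design.n_receivers}"
        )
    sources = [cfg.source(node.position) for node in sorted(inputs, key=lambda x: x.id)]
    cols = [
        cfg.colony(node.position, r.activation.kind)
        for node, r in zip(sorted(receivers, key=lambda x: x.id), design.receivers)
    ]
    return predict_gate(
        cfg.grid,
        sources,
        cols,
        designed_tables=design.induced_tables(),
        t_read=cfg.t_read,
        decision_ratio=cfg.decision_ratio,
        field_cache=field_cache,
    )


def fitness(
    layout: LayoutSpec,
    design: MacchiatoDesign,
    cfg: DeviceConfig,
    penalty_weight: float = 2.0,
    field_cache: Optional[dict] = None,
) -> float:
    """ON/OFF separation of the simulated layout, higher is better.

    The core term is the gap, in log2 normalized activity, between the
    dimmest function-ON state and the brightest function-OFF state, plus a
    small reward for the mean ON-state activity (which gives the search a
    gradient out of the all-quiet layout where every state reads equally
    dim).  Each receiver that turns ON in a state where the *target* is
    OFF incurs a soft penalty proportional to its excess activity — a hard
    rejection would stall the search on tight lattices.  (A receiver may
    turn ON in a target-ON state covered by another receiver: implicit-OR
    read-out makes that harmless.)  Deterministic for a given layout and
    configuration; fitness clearly above the shaping term implies correct
    digital behavior with margin.
    """
    res = simulate_layout(layout, design, cfg, field_cache=field_cache)
    tt = design.output_table()
    # clip at a factor 8 beyond/below threshold: once a state is safely ON
    # or OFF, further saturation must not outweigh correctness penalties
    lg = lambda v: float(np.clip(np.log2(v), -3.0, 3.0))
    on_out = [lg(res.output[s]) for s in range(tt.n_states) if tt.outputs[s] == 1]
    off_out = [lg(res.output[s]) for s in range(tt.n_states) if tt.outputs[s] == 0]
    core = (min(on_out) if on_out else 0.0) - (max(off_out) if off_out else 0.0)
    if on_out:
        core += 0.2 * float(np.mean(on_out))
    thr = [
        activity_threshold(r.activation.kind, cfg.decision_ratio)
        for r in design.receivers
    ]
    penalty = 0.0
    target = design.target
    for s in range(tt.n_states):
        if target.outputs[s] != 0:
            continue
        for j in range(design.n_receivers):
            a = res.fold_changes[s][j] / thr[j]
            if a > 1.0:
                penalty += np.log2(a)
    return float(core - penalty_weight * penalty)


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def _target_concentrations(
    design: MacchiatoDesign, cfg: DeviceConfig
) -> np.ndarray:
    """Threshold-aligned concentration targets (coarse fallback).

    Maps each receiver's abstract contribution vector onto the physical
    concentration axis by aligning its thresholds with the strain's
    decision crossings (geometric-mean alignment for two-threshold kinds).
    Zero contributions map to 0 (= "keep this input well below threshold").
    """
    n = design.target.n_inputs
    targets = np.zeros((design.n_receivers, n))
    for j, rec in enumerate(design.receivers):
        kind = rec.activation.kind
        crossings = decision_crossings(cfg.strains[kind], cfg.decision_ratio)
        if not crossings:
            continue
        act = rec.activation
        if act.theta_hi is not None and len(crossings) >= 2:
            scale = float(
                np.sqrt(
                    (crossings[0] * crossings[1]) / (act.theta_lo * act.theta_hi)
                )
            )
        else:
            scale = crossings[0] / act.theta_lo
        targets[j] = np.array(rec.contributions) * scale
    return targets


def _distance_ladder(cfg: DeviceConfig, radii: np.ndarray, prof: np.ndarray) -> list[
    tuple[float, float]
]:
    """Distinct lattice distances (mm) and their committed concentrations."""
    nlat = _lattice_size(cfg)
    ks = sorted({i**2 + j**2 for i in range(nlat) for j in range(nlat)} - {0})
    out = []
    for k in ks:
        d = cfg.pitch * float(np.sqrt(k))
        if d > radii[-1]:
            break
        out.append((d, float(np.interp(d, radii, prof))))
    return out


def _rung_targets(
    design: MacchiatoDesign,
    cfg: DeviceConfig,
    ladder: Sequence[tuple[float, float]],
) -> Optional[np.ndarray]:
    """Per-receiver target distances found by exhaustive rung assignment.

    For each receiver, every assignment of each input to a ladder rung (or
    to "far", contributing nothing) is scored through the strain's actual
    dose-response.  A matching assignment must read ON in every state the
    receiver is designated to cover and OFF in every state where the
    *target* is OFF; in target-ON states covered by other receivers the
    verdict is free (implicit OR).  Among matching assignments the one
    with the largest worst-state margin (|log activity| over constrained
    states) wins.  Returns a (receivers x inputs) array of distances,
    np.inf meaning "far", or None if some receiver has no match.
    """
    n = design.target.n_inputs
    tables = design.induced_tables()
    target = design.target
    far = (np.inf, 0.0)
    options = list(ladder) + [far]
    targets = np.zeros((design.n_receivers, n))
    for j, (rec, tab) in enumerate(zip(design.receivers, tables)):
        dr = cfg.strains[rec.activation.kind]
        thr = activity_threshold(rec.activation.kind, cfg.decision_ratio)
        r0 = float(dr.rate(0.0))
        best_key, best = None, None
        for combo in itertools.product(range(len(options)), repeat=n):
            us = [options[i][1] for i in combo]
            margin = np.inf
            ok = True
            for s in range(2**n):
                u = sum(us[k] for k in range(n) if (s >> (n - 1 - k)) & 1)
                a = float(dr.rate(u)) / r0 / thr
                must_on = tab.outputs[s] == 1
                must_off = target.outputs[s] == 0
                if (must_on and a <= 1.0) or (must_off and a >= 1.0):
                    ok = False
                    break
                if must_on or must_off:
                    margin = min(margin, abs(np.log(a)))
            if not ok:
                continue
            # on near-ties prefer "far" placements: an unconstrained input
            # is far easier to embed on the lattice
            n_far = sum(1 for i in combo if np.isinf(options[i][0]))
            key = (round(float(margin), 1), n_far, float(margin))
            if best_key is None or key > best_key:
                best_key, best = key, combo
        if best is None:
            return None
        targets[j] = [options[i][0] for i in best]
    return targets


def _seed_genotypes(
    design: MacchiatoDesign,
    cfg: DeviceConfig,
    rng: np.random.Generator,
    n_seeds: int,
) -> list[np.ndarray]:
    """Witness-guided starting layouts: receivers spread on the lattice,
    inputs greedily placed to match their target concentrations."""
    n = design.target.n_inputs
    nrec = design.n_receivers
    nlat = _lattice_size(cfg)
    radii, prof = radial_concentration(cfg)
    u_of = lambda d: float(np.interp(d, radii, prof))
    floor = max(prof.min(), 1e-12)
    sites = np.array([(a, b) for a in range(nlat) for b in range(nlat)], dtype=int)
    d2min = (_sep_cells(cfg) - 1e-9) ** 2
    safe_u = []
    for rec in design.receivers:
        cr = decision_crossings(
            cfg.strains[rec.activation.kind], cfg.decision_ratio
        )
        safe_u.append((cr[0] if cr else 1.0) * 0.3)

    def build(rec_cells: list[np.ndarray], targets_u: np.ndarray) -> Optional[np.ndarray]:
        """Greedy input placement against per-receiver concentration targets
        (np.inf target distance encoded as target_u = 0 -> one-sided)."""
        placed: list[np.ndarray] = [np.asarray(c) for c in rec_cells]
        input_cells: list[np.ndarray] = []
        for k in range(n):
            best, best_cost = None, np.inf
            for cand in sites:
                if any(((cand - p) ** 2).sum() < d2min for p in placed):
                    continue
                cost = 0.0
                for j in range(nrec):
                    d = float(np.hypot(*(cand - rec_cells[j]))) * cfg.pitch
                    u = max(u_of(d), floor)
                    t = targets_u[j, k]
                    if t > 0:
                        cost += (np.log(u) - np.log(max(t, floor))) ** 2
                    elif u > safe_u[j]:
                        cost += (np.log(u) - np.log(safe_u[j])) ** 2
                if cost < best_cost:
                    best, best_cost = cand.copy(), cost
            if best is None:
                return None
            placed.append(best)
            input_cells.append(best)
        return np.array(input_cells + rec_cells, dtype=int)

    center = nlat // 2
    rec_options: list[list[np.ndarray]] = []
    if nrec == 1:
        rec_options = [[np.array([center, center])]]
    else:
        for gap in (1, 2, 3, 4):
            for step in ((gap, 0), (0, gap), (gap, gap)):
                cells = [
                    np.array([center - step[0] * j, center - step[1] * j])
                    for j in range(nrec)
                ]
                if all(c.min() >= 0 for c in cells):
                    rec_options.append(cells)
    target_sets: list[np.ndarray] = []
    ladder = _distance_ladder(cfg, radii, prof)
    rungs = _rung_targets(design, cfg, ladder)
    if rungs is not None:
        # exact rung assignment: convert distances to concentrations
        tu = np.where(np.isinf(rungs), 0.0, rungs)
        target_sets.append(
            np.vectorize(lambda d: u_of(d) if d > 0 else 0.0)(tu)
        )
    base = _target_concentrations(design, cfg)
    for mult in (1.0, 1.75, 1.0 / 1.75):
        target_sets.append(base * mult)
    seeds = []
    for targets_u in target_sets:
        for cells in rec_options:
            g = build([c.copy() for c in cells], targets_u)
            if g is not None:
                seeds.append(g)
            if len(seeds) >= n_seeds:
                return seeds
    return seeds


# ---------------------------------------------------------------------------
# The evolutionary loop
# ---------------------------------------------------------------------------


def optimize_layout(
    design: MacchiatoDesign,
    ea: EAConfig = EAConfig(),
    cfg: DeviceConfig = DeviceConfig(),
) -> tuple[LayoutSpec, list[float]]:
    """Evolve a lattice layout for a design; returns (best layout, trace).

    The trace is the best fitness per generation; with elitism it is
    non-decreasing.  Identical seeds and configuration give bit-identical
    results.
    """
    ids_roles = _design_ids_roles(design)
    n_nodes = len(ids_roles)
    nlat = _lattice_size(cfg)
    if nlat**2 < n_nodes:
        raise ValueError(
            f"lattice has {nlat**2} sites but the design needs {n_nodes} nodes"
        )
    rng = np.random.default_rng(ea.seed)
    cache: dict = {}

    def evaluate(g: np.ndarray) -> float:
        return fitness(
            _to_layout(g, ids_roles, cfg),
            design,
            cfg,
            penalty_weight=ea.penalty_weight,
            field_cache=cache,
        )

    pop: list[np.ndarray] = []
    for g in _seed_genotypes(design, cfg, rng, n_seeds=max(4, ea.population // 6)):
        pop.append(_repair(g, cfg, rng))
    while len(pop) < ea.population:
        g = rng.integers(0, nlat, size=(n_nodes, 2))
        pop.append(_repair(g, cfg, rng))
    fits = [evaluate(g) for g in pop]
    trace: list[float] = []
    steps = np.array(
        [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    )
    for _ in range(ea.generations):
        order = np.argsort(fits, kind="stable")[::-1]
        elite = [pop[i].copy() for i in order[: ea.elitism]]
        new_pop: list[np.ndarray] = list(elite)
        while len(new_pop) < ea.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                idx = rng.integers(0, ea.population, size=ea.tournament_size)
                parents.append(pop[max(idx, key=lambda i: fits[i])])
            # uniform per-node crossover
            mask = rng.integers(0, 2, size=n_nodes).astype(bool)
            child = np.where(mask[:, None], parents[0], parents[1]).copy()
            # lattice-step mutation, 8-neighborhood
            for i in range(n_nodes):
                if rng.random() < ea.mutation_rate:
                    child[i] = child[i] + steps[rng.integers(0, len(steps))]
            new_pop.append(_repair(child, cfg, rng))
        pop = new_pop
        fits = [evaluate(g) for g in pop]
        trace.append(float(max(fits)))
    best = int(np.argmax(fits))
    return _to_layout(pop[best], ids_roles, cfg), trace


# ---------------------------------------------------------------------------
# Post-hoc geometric feasibility
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReceiverReport:
    receiver: str
    kind: str
    designed_code: int
    achieved_contributions: tuple[float, ...]
    matches_design: bool
    mismatched_states: tuple[str, ...]


def geometric_feasibility_report(
    design: MacchiatoDesign,
    layout: LayoutSpec,
    cfg: DeviceConfig = DeviceConfig(),
) -> list[ReceiverReport]:
    """Compare each receiver's achieved geometry against its axis witness.

    The achieved contribution of input k to receiver j is the committed
    concentration input k alone produces at j's position.  A receiver is
    flagged when its simulated per-state verdicts differ from its designed
    sub-function — the signature of conflicting distance requirements
    (moving an input relative to one receiver moves it relative to all).
    """
    if not design.receivers:
        return []
    res = simulate_layout(layout, design, cfg)
    tables = design.induced_tables()
    radii, prof = radial_concentration(cfg)
    reports = []
    for j, (rec, tab) in enumerate(zip(design.receivers, tables)):
        rnode = layout.position_of(f"R{j}")
        achieved = []
        for k in range(design.target.n_inputs):
            inode = layout.position_of(_INPUT_NAMES[k])
            d = float(np.hypot(rnode[0] - inode[0], rnode[1] - inode[1]))
            achieved.append(float(np.interp(d, radii, prof)))
        mism = tuple(
            tab.bitstring(s)
            for s in range(tab.n_states)
            if res.receiver_verdicts[s][j] != tab.outputs[s]
        )
        reports.append(
            ReceiverReport(
                receiver=f"R{j}",
                kind=rec.activation.kind,
                designed_code=tab.to_hex(),
                achieved_contributions=tuple(achieved),
                matches_design=not mism,
                mismatched_states=mism,
            )
        )
    return reports
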