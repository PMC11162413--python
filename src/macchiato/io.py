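"""File formats: truth-table CSV, design JSON, layout CSV, gate-map rasters.

Truth-table CSV has a ``state,output`` header, states as bitstrings with
input A first, outputs in {0,1,DC}.  Design JSON stores the target code
and, per receiver, the activation kind, thresholds, contributions and the
induced sub-function code, which is enough to rebuild the design exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .axis import ActivationFunction, ReceiverAxisSpec, induced_truth_table
from .device import DeviceConfig, hsl_strains, iptg_strains, narrow_bandpass
from .logic import DC, TruthTable, tt_from_hex
from .minimize import MacchiatoDesign
from .placement import LayoutNode, LayoutSpec
from .simulator import DoseResponse, SimGrid

__all__ = [
    "read_truth_table_csv",
    "write_truth_table_csv",
    "write_enumeration_csv",
    "design_to_json",
    "design_from_json",
    "layout_to_csv",
    "layout_from_csv",
    "trace_to_csv",
    "gate_map_to_csv",
    "gate_map_to_png",
    "load_device_config",
]


def read_truth_table_csv(path, label: str = "") -> TruthTable:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["state", "output"]:
        raise ValueError("truth-table CSV must have a 'state,output' header")
    states = [s.strip() for s in df["state"]]
    n = len(states[0])
    if sorted(states) != [format(i, f"0{n}b") for i in range(2**n)]:
        raise ValueError(f"expected all {2**n} states of {n} inputs exactly once")
    outputs: list = [0] * 2**n
    for s, o in zip(states, df["output"]):
        o = str(o).strip().upper()
        outputs[int(s, 2)] = DC if o == "DC" else int(o)
    return TruthTable(n, tuple(outputs), label=label)


def write_truth_table_csv(tt: TruthTable, path) -> None:
    rows = [
        {"state": tt.bitstring(i), "output": "DC" if o is DC else o}
        for i, o in enumerate(tt.outputs)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_enumeration_csv(path, n_inputs: int, kinds: Iterable[str]) -> None:
    """Realizability of every DC-free gate, with witnesses where they exist."""
    from .axis import enumerate_realizable, min_blocks

    witnesses = enumerate_realizable(n_inputs, kinds)
    rows = []
    for code in range(2 ** (2**n_inputs)):
        tt = tt_from_hex(code, n_inputs)
        spec = witnesses.get(code)
        rows.append(
            {
                "hex_code": f"0x{code:X}",
                "label": tt.label,
                "realizable": spec is not None,
                "kinds": spec.activation.kind if spec else "",
                "blocks": min_blocks(tt),
                "witness_contributions": (
                    ";".join(f"{c:.6g}" for c in spec.contributions) if spec else ""
                ),
                "witness_thresholds": (
                    ";".join(
                        f"{t:.6g}"
                        for t in (spec.activation.theta_lo, spec.activation.theta_hi)
                        if t is not None
                    )
                    if spec
                    else ""
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def design_to_json(design: MacchiatoDesign, path=None) -> str:
    payload = {
        "target_hex": f"0x{design.target.to_hex():X}" if not design.target.has_dc
        else None,
        "n_inputs": design.target.n_inputs,
        "label": design.target.label,
        "or_mode": design.or_mode,
        "receivers": [
            {
                "kind": r.activation.kind,
                "thresholds": [
                    t
                    for t in (r.activation.theta_lo, r.activation.theta_hi)
                    if t is not None
                ],
                "contributions": list(r.contributions),
                "margin": r.margin,
                "induced_hex": f"0x{induced_truth_table(r).to_hex():X}",
            }
            for r in design.receivers
        ],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def design_from_json(path) -> MacchiatoDesign:
    payload = json.loads(Path(path).read_text())
    n = payload["n_inputs"]
    target = tt_from_hex(
        int(payload["target_hex"], 16), n, label=payload.get("label", "")
    )
    receivers = []
    for r in payload["receivers"]:
        ths = r["thresholds"]
        act = ActivationFunction(
            r["kind"], ths[0], ths[1] if len(ths) > 1 else None
        )
        receivers.append(
            ReceiverAxisSpec(act, tuple(r["contributions"]), margin=r["margin"])
        )
    return MacchiatoDesign(
        target=target,
        receivers=tuple(receivers),
        or_mode=payload.get("or_mode", "implicit"),
    )


def layout_to_csv(layout: LayoutSpec, path) -> None:
    pd.DataFrame(
        [
            {"id": n.id, "role": n.role, "x_mm": n.position[0], "y_mm": n.position[1]}
            for n in layout.nodes
        ]
    ).to_csv(path, index=False)


def layout_from_csv(
    path, pitch: float = 4.5, bounds=(35.0, 35.0), min_separation: float = 4.5
) -> LayoutSpec:
    df = pd.read_csv(path)
    nodes = tuple(
        LayoutNode(row["role"], str(row["id"]), (float(row["x_mm"]), float(row["y_mm"])))
        for _, row in df.iterrows()
    )
    return LayoutSpec(nodes, pitch=pitch, bounds=bounds, min_separation=min_separation)


def trace_to_csv(trace: Sequence[float], path) -> None:
    pd.DataFrame(
        {"generation": np.arange(1, len(trace) + 1), "best_fitness": list(trace)}
    ).to_csv(path, index=False)


def gate_map_to_csv(codes: np.ndarray, grid: SimGrid, path) -> None:
    """Long-format per-pixel gate codes: x_mm, y_mm, hex_code."""
    ny, nx = codes.shape
    ys, xs = np.meshgrid(
        np.arange(ny) * grid.spacing, np.arange(nx) * grid.spacing, indexing="ij"
    )
    pd.DataFrame(
        {
            "x_mm": xs.ravel(),
            "y_mm": ys.ravel(),
            "hex_code": [f"0x{c:X}" for c in codes.ravel()],
        }
    ).to_csv(path, index=False)


def gate_map_to_png(codes: np.ndarray, path) -> None:
    """Raster of the gate map, one color per gate code (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    uniq = np.unique(codes)
    lut = {c: i for i, c in enumerate(uniq)}
    img = np.vectorize(lut.get)(codes)
    plt.imsave(path, img, cmap="tab20", origin="lower")


def load_device_config(path: Optional[str] = None, **overrides) -> DeviceConfig:
    """Device configuration from a YAML file plus keyword overrides.

    Recognized YAML keys: grid {extent, spacing, dt, D, boundary,
    decay_rate}, molecule ("IPTG" | "HSL"), bandpass_variant ("narrow"),
    strains {kind: {dose-response fields}}, and any scalar DeviceConfig
    field (dose, production_rate, commit_time, t_read, decision_ratio,
    pitch, min_separation, ...).
    """
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    grid_kw = data.pop("grid", {})
    if "extent" in grid_kw:
        grid_kw["extent"] = tuple(grid_kw["extent"])
    molecule = data.pop("molecule", "IPTG")
    strains = hsl_strains() if molecule.upper() == "HSL" else iptg_strains()
    if data.pop("bandpass_variant", None) == "narrow":
        strains["bandpass"] = narrow_bandpass()
    for kind, kw in (data.pop("strains", {}) or {}).items():
        strains[kind] = DoseResponse(kind, **kw)
    if molecule.upper() == "HSL":
        data.setdefault("source_kind", "sender")
    kwargs = {"grid": SimGrid(**grid_kw), "strains": strains, **data, **overrides}
    return DeviceConfig(**kwargs)
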