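"""Single-perturbation state diagrams (SPSDs).

An SPSD places one node per regulator state (0 .. 2**k - 1) and one edge per
single-regulator perturbation: a knock-down ``D_i`` clears bit ``i`` (moving
to a lower state number), an over-expression ``O_i`` sets it. Edge
*visibility* records whether the perturbation's effect on the target gene is
observable: from the transcriptome alone (the output differs across the
edge), through a PPI with a regulator whose effect is already visible from
the same source state, or optimistically from full cis-element knowledge.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

from grnlogic.boolean_space import (
    BooleanFunction,
    input_bit_mask,
    output_matrix,
    state_bits,
)

__all__ = [
    "Regime",
    "Integration",
    "Visibility",
    "StateNode",
    "TransitionEdge",
    "SPSD",
    "build_spsd",
    "export_spsd",
    "spsd_from_json",
    "visible_out_degree_matrix",
    "fully_visible_matrix",
]


class Regime(str, enum.Enum):
    """Which perturbations are available."""

    D = "D"  # knock-down only
    DO = "DO"  # knock-down and over-expression

    @classmethod
    def parse(cls, value) -> "Regime":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(f"unknown perturbation regime {value!r}; use D or DO")


class Integration(str, enum.Enum):
    """Which omics layers back the visibility call."""

    TX = "tx"  # transcriptome only
    TX_PPI = "ppi"  # transcriptome + protein-protein interactions
    TX_CIS_PPI = "cis-ppi"  # transcriptome + cis-elements (+ PPI)

    @classmethod
    def parse(cls, value) -> "Integration":
        if isinstance(value, cls):
            return value
        aliases = {
            "tx": cls.TX,
            "tx_ppi": cls.TX_PPI,
            "ppi": cls.TX_PPI,
            "+ppi": cls.TX_PPI,
            "tx_cis_ppi": cls.TX_CIS_PPI,
            "cis-ppi": cls.TX_CIS_PPI,
            "cis_ppi": cls.TX_CIS_PPI,
            "+cis(+ppi)": cls.TX_CIS_PPI,
        }
        key = str(value).lower()
        if key not in aliases:
            raise ValueError(
                f"unknown integration mode {value!r}; use tx, ppi or cis-ppi"
            )
        return aliases[key]


class Visibility(str, enum.Enum):
    R1_VISIBLE = "R1_VISIBLE"  # output changes across the edge
    PPI_VISIBLE = "PPI_VISIBLE"  # upgraded through a PPI anchor
    CIS_VISIBLE = "CIS_VISIBLE"  # optimistic full cis-element knowledge
    INVISIBLE = "INVISIBLE"

    @property
    def visible(self) -> bool:
        return self is not Visibility.INVISIBLE


@dataclass(frozen=True)
class StateNode:
    s: int
    bits: tuple[int, ...]
    output: int


@dataclass(frozen=True)
class TransitionEdge:
    source: int
    dest: int
    kind: str  # "D" or "O"
    rf: int  # 1-based regulator index
    visibility: Visibility

    @property
    def label(self) -> str:
        return f"{self.kind}{self.rf}"


@dataclass(frozen=True)
class SPSD:
    """The perturbation state diagram of one function under one setting."""

    function: BooleanFunction
    regime: Regime
    integration: Integration
    nodes: tuple[StateNode, ...]
    edges: tuple[TransitionEdge, ...]

    @property
    def k(self) -> int:
        return self.function.k

    def out_edges(self, s: int) -> tuple[TransitionEdge, ...]:
        return tuple(e for e in self.edges if e.source == s)

    def visible_out_degree(self, s: int) -> int:
        """N_{k,b,s}: solid-line edges leaving state ``s``."""
        return sum(1 for e in self.edges if e.source == s and e.visibility.visible)

    def visible_out_degrees(self) -> dict[int, int]:
        table = {node.s: 0 for node in self.nodes}
        for e in self.edges:
            if e.visibility.visible:
                table[e.source] += 1
        return table

    def invisible_edges(self) -> tuple[TransitionEdge, ...]:
        return tuple(e for e in self.edges if not e.visibility.visible)

    def is_fully_visible(self, s: int) -> bool:
        """Every regulator's effect evidenced at state ``s``.

        Under full cis-element (+PPI) knowledge this holds at every state;
        otherwise it requires k visible perturbation edges out of ``s``.
        """
        if self.integration is Integration.TX_CIS_PPI:
            return True
        return self.visible_out_degree(s) == self.k

    def __eq__(self, other) -> bool:  # noqa: D105
        if not isinstance(other, SPSD):
            return NotImplemented
        return (
            self.function.k == other.function.k
            and self.function.b == other.function.b
            and self.regime == other.regime
            and self.integration == other.integration
            and self.nodes == other.nodes
            and set(self.edges) == set(other.edges)
        )


def _edge_targets(s: int, k: int, regime: Regime) -> list[tuple[int, int, str]]:
    """(rf, dest, kind) for every perturbation available from state ``s``."""
    out = []
    for i in range(1, k + 1):
        mask = input_bit_mask(k, i)
        if s & mask:
            out.append((i, s ^ mask, "D"))
        elif regime is Regime.DO:
            out.append((i, s ^ mask, "O"))
    return out


def build_spsd(
    f: BooleanFunction,
    regime: Regime | str,
    integration: Integration | str,
) -> SPSD:
    """Build the SPSD of ``f`` with per-edge visibility.

    Transcriptome-only visibility marks an edge solid when the target output
    differs between its endpoints. The PPI upgrade (a single pass, anchored
    only on transcriptome-visible edges) and the optimistic cis-element mode
    are applied on top per the integration setting.
    """
    regime = Regime.parse(regime)
    integration = Integration.parse(integration)
    k = f.k
    nodes = tuple(
        StateNode(s=s, bits=state_bits(s, k), output=f.outputs[s])
        for s in range(1 << k)
    )
    edges: list[TransitionEdge] = []
    for s in range(1 << k):
        r1 = {
            i: f.outputs[s] != f.outputs[dest]
            for i, dest, _ in _edge_targets(s, k, regime)
        }
        for i, dest, kind in _edge_targets(s, k, regime):
            if integration is Integration.TX_CIS_PPI:
                vis = Visibility.CIS_VISIBLE
                if r1[i]:
                    vis = Visibility.R1_VISIBLE
            elif r1[i]:
                vis = Visibility.R1_VISIBLE
            elif integration is Integration.TX_PPI and _ppi_anchor(s, i, r1, k):
                vis = Visibility.PPI_VISIBLE
            else:
                vis = Visibility.INVISIBLE
            edges.append(
                TransitionEdge(source=s, dest=dest, kind=kind, rf=i, visibility=vis)
            )
    return SPSD(
        function=f,
        regime=regime,
        integration=integration,
        nodes=nodes,
        edges=tuple(edges),
    )


def _ppi_anchor(s: int, i: int, r1: dict[int, bool], k: int) -> bool:
    """PPI upgrade test for the RF_i edge out of state ``s``.

    Requires another RF_j whose own edge from ``s`` is transcriptome-visible
    and a pair of 1s for (i, j) in either endpoint of the RF_i edge. Since
    the endpoints differ only in bit i, the pair-of-1s condition reduces to
    bit j of the source being 1.
    """
    for j, visible in r1.items():
        if j != i and visible and s & input_bit_mask(k, j):
            return True
    return False


# ---------------------------------------------------------------------------
# Vectorized kernels shared by the exhaustive sweeps
# ---------------------------------------------------------------------------


def visible_out_degree_matrix(
    k: int,
    indices: np.ndarray,
    regime: Regime | str,
    integration: Integration | str,
) -> np.ndarray:
    """N_{k,b,s} for every function index in ``indices``: shape (n, 2**k)."""
    regime = Regime.parse(regime)
    integration = Integration.parse(integration)
    indices = np.asarray(indices, dtype=np.int64)
    n_states = 1 << k
    out = output_matrix(k, indices)  # (n, 2**k)
    states = np.arange(n_states)
    exists = np.empty((n_states, k), dtype=bool)  # (s, i-1)
    r1 = np.empty((indices.shape[0], n_states, k), dtype=bool)
    for i in range(1, k + 1):
        mask = input_bit_mask(k, i)
        bit_set = (states & mask) != 0
        exists[:, i - 1] = bit_set if regime is Regime.D else True
        r1[:, :, i - 1] = out != out[:, states ^ mask]
    if integration is Integration.TX_CIS_PPI:
        visible = np.broadcast_to(exists[None, :, :], r1.shape)
    elif integration is Integration.TX_PPI:
        # candidate anchors: R1-visible edges of RFs that are ON in the source
        # (the pair-of-1s condition collapses to "bit j of the source is 1")
        anchor_ok = np.empty((n_states, k), dtype=bool)
        for j in range(1, k + 1):
            anchor_ok[:, j - 1] = (states & input_bit_mask(k, j)) != 0
        anchored = r1 & anchor_ok[None, :, :]
        total = anchored.sum(axis=2, keepdims=True)
        has_other_anchor = (total - anchored.astype(np.int64)) > 0
        visible = (r1 | has_other_anchor) & exists[None, :, :]
    else:
        visible = r1 & exists[None, :, :]
    return visible.sum(axis=2).astype(np.int64)


def fully_visible_matrix(
    k: int,
    indices: np.ndarray,
    regime: Regime | str,
    integration: Integration | str,
) -> np.ndarray:
    """Indicator of full visibility for every (function, state).

    A state is fully visible when the effect of every regulator is
    evidenced. Under transcriptome-only and +PPI integration this requires k
    visible perturbation edges out of the state (so knock-down-only regimes
    qualify only at the all-ones state); full cis-element (+PPI) knowledge
    evidences every regulator without any perturbation, so every state of
    every function is fully visible regardless of the regime.
    """
    integration = Integration.parse(integration)
    indices = np.asarray(indices, dtype=np.int64)
    if integration is Integration.TX_CIS_PPI:
        return np.ones((indices.shape[0], 1 << k), dtype=bool)
    return visible_out_degree_matrix(k, indices, regime, integration) == np.int64(k)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def to_networkx(spsd: SPSD) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph(
        k=spsd.k,
        b=spsd.function.b,
        regime=spsd.regime.value,
        integration=spsd.integration.value,
    )
    for node in spsd.nodes:
        g.add_node(
            node.s, bits="".join(map(str, node.bits)), output=int(node.output)
        )
    for e in spsd.edges:
        g.add_edge(
            e.source,
            e.dest,
            key=e.label,
            kind=e.kind,
            rf=e.rf,
            visibility=e.visibility.value,
        )
    return g


def _to_dot(spsd: SPSD) -> str:
    lines = [
        "digraph SPSD {",
        f'  label="F_{spsd.function.b}^{spsd.k} '
        f'{spsd.regime.value} {spsd.integration.value}";',
        "  rankdir=TB;",
    ]
    for node in spsd.nodes:
        bits = "".join(map(str, node.bits))
        lines.append(
            f'  {node.s} [shape=circle, label="{node.s} ({bits})\\n{node.output}"];'
        )
    for e in sorted(spsd.edges, key=lambda e: (e.source, e.rf, e.kind)):
        style = "solid" if e.visibility.visible else "dashed"
        lines.append(
            f'  {e.source} -> {e.dest} [label="{e.label}", style={style}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def _to_json(spsd: SPSD) -> str:
    payload = {
        "function": spsd.function.to_record(),
        "regime": spsd.regime.value,
        "integration": spsd.integration.value,
        "nodes": [
            {"s": n.s, "bits": list(n.bits), "output": n.output} for n in spsd.nodes
        ],
        "edges": [
            {
                "source": e.source,
                "dest": e.dest,
                "kind": e.kind,
                "rf": e.rf,
                "visibility": e.visibility.value,
            }
            for e in sorted(spsd.edges, key=lambda e: (e.source, e.rf, e.kind))
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def _to_graphml(spsd: SPSD) -> str:
    g = to_networkx(spsd)
    return "\n".join(nx.generate_graphml(g)) + "\n"


def export_spsd(spsd: SPSD, format: str) -> str:
    """Serialize the SPSD; byte-stable for a fixed diagram.

    Formats: ``dot`` (graphviz, solid/dashed per visibility), ``graphml``,
    ``json``.
    """
    fmt = format.lower()
    if fmt == "dot":
        return _to_dot(spsd)
    if fmt == "json":
        return _to_json(spsd)
    if fmt == "graphml":
        return _to_graphml(spsd)
    raise ValueError(f"unknown export format {format!r}; use dot, graphml or json")


def spsd_from_json(text: str) -> SPSD:
    """Inverse of ``export_spsd(..., 'json')``."""
    payload = json.loads(text)
    f = BooleanFunction(k=payload["function"]["k"], b=payload["function"]["b"])
    nodes = tuple(
        StateNode(s=n["s"], bits=tuple(n["bits"]), output=n["output"])
        for n in payload["nodes"]
    )
    edges = tuple(
        TransitionEdge(
            source=e["source"],
            dest=e["dest"],
            kind=e["kind"],
            rf=e["rf"],
            visibility=Visibility(e["visibility"]),
        )
        for e in payload["edges"]
    )
    return SPSD(
        function=f,
        regime=Regime.parse(payload["regime"]),
        integration=Integration.parse(payload["integration"]),
        nodes=nodes,
        edges=edges,
    )
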