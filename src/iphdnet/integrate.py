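"""Assembly of the integrated phosphoprotein-histone-drug network.

The two edge layers — coefficient-weighted drug-histone edges from the
signature model and significant histone-phosphoprotein edges from the
PLSR model — are merged on exact histone-code ids into one tripartite
network.  Histones mediate everything: drug-phosphoprotein or intra-layer
edges are structural violations and rejected at construction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from .io_gct import LAYERS
from .plsr_net import HistonePhosphoEdge
from .signatures import DrugHistoneEdge

LAYER_PAIRS = ("drug-histone", "histone-phosphoprotein")


@dataclass
class TripartiteNetwork:
    """Typed tripartite network: drugs, histones, phosphoproteins.

    ``nodes`` holds (id, layer, module-or-None) triples; ``edges`` holds
    (source, target, layer_pair, weight, sign) tuples where the source is
    always the drug (drug-histone layer) or histone
    (histone-phosphoprotein layer).
    """

    nodes: set[tuple[str, str, str | None]] = field(default_factory=set)
    edges: set[tuple[str, str, str, float, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        layer_of: dict[str, str] = {}
        for nid, layer, _module in self.nodes:
            if layer not in LAYERS:
                raise ValueError(f"unknown layer {layer!r} for node {nid!r}")
            if nid in layer_of and layer_of[nid] != layer:
                raise ValueError(
                    f"node id {nid!r} tagged with two layers: "
                    f"{layer_of[nid]!r} and {layer!r}"
                )
            layer_of[nid] = layer
        for source, target, pair, weight, sign in self.edges:
            if source not in layer_of or target not in layer_of:
                raise ValueError(f"edge ({source}, {target}) has an endpoint not in nodes")
            if pair not in LAYER_PAIRS:
                raise ValueError(f"unknown layer pair {pair!r}")
            expected = {
                "drug-histone": ("drug", "histone"),
                "histone-phosphoprotein": ("histone", "phosphoprotein"),
            }[pair]
            if (layer_of[source], layer_of[target]) != expected:
                raise ValueError(
                    f"edge ({source}, {target}) tagged {pair!r} but endpoints are "
                    f"({layer_of[source]}, {layer_of[target]})"
                )
            if weight < 0:
                raise ValueError(f"negative weight on edge ({source}, {target})")
            if sign not in (-1, 1):
                raise ValueError(f"invalid sign on edge ({source}, {target})")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def layer_nodes(self, layer: str) -> set[str]:
        return {nid for nid, lay, _m in self.nodes if lay == layer}


def build_iphdnet(
    drug_histone_edges: Iterable[DrugHistoneEdge],
    histone_phospho_edges: Iterable[HistonePhosphoEdge],
    modules: dict[str, str] | None = None,
    rescale_weights: bool = False,
) -> TripartiteNetwork:
    """Merge the two edge layers into the tripartite iPhDNet.

    Histone nodes appearing in both layers are merged by exact id (a
    strict-match policy; unmatched histones are reported in a preflight
    warning because silent id drift would fragment the network).  Module
    labels from the signature model annotate drug and histone nodes.
    ``rescale_weights`` min-max rescales each layer's weights to [0, 1]
    for display exports; the default keeps native per-layer scales.
    """
    dh = list(drug_histone_edges)
    hp = list(histone_phospho_edges)
    modules = modules or {}

    dh_hist = {e.histone for e in dh}
    hp_hist = {e.histone for e in hp}
    if dh and hp:
        unmatched = dh_hist ^ hp_hist
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} histone ids appear in only one layer: "
                f"{sorted(unmatched)[:10]}{'...' if len(unmatched) > 10 else ''}",
                stacklevel=2,
            )

    drugs = {e.drug for e in dh}
    phosphos = {e.phosphoprotein for e in hp}
    collisions = (drugs & (dh_hist | hp_hist)) | (drugs & phosphos) | (
        phosphos & (dh_hist | hp_hist)
    )
    if collisions:
        raise ValueError(f"ids claimed by two layers: {sorted(collisions)}")

    def scaled(weights: list[float]) -> list[float]:
        if not rescale_weights or not weights:
            return weights
        lo, hi = min(weights), max(weights)
        if hi == lo:
            return [1.0] * len(weights)
        return [(w - lo) / (hi - lo) for w in weights]

    nodes: set[tuple[str, str, str | None]] = set()
    for d in drugs:
        nodes.add((d, "drug", modules.get(d)))
    for h in dh_hist | hp_hist:
        nodes.add((h, "histone", modules.get(h)))
    for p in phosphos:
        nodes.add((p, "phosphoprotein", modules.get(p)))

    edges: set[tuple[str, str, str, float, int]] = set()
    dh_w = scaled([e.weight for e in dh])
    for e, w in zip(dh, dh_w):
        edges.add((e.drug, e.histone, "drug-histone", float(w), e.sign))
    hp_w = scaled([e.weight for e in hp])
    for e, w in zip(hp, hp_w):
        edges.add((e.histone, e.phosphoprotein, "histone-phosphoprotein", float(w), e.sign))

    return TripartiteNetwork(nodes=nodes, edges=edges)


def neighborhood(
    net: TripartiteNetwork, node_id: str, layer: str | None = None
) -> list[tuple[str, str, float, int]]:
    """Adjacent nodes of ``node_id`` with (id, layer, weight, sign).

    Optionally restricted to one layer; ordered by weight descending then
    id so output is deterministic.
    """
    layer_of = {nid: lay for nid, lay, _m in net.nodes}
    if node_id not in layer_of:
        raise KeyError(f"unknown node {node_id!r}")
    if layer is not None and layer not in LAYERS:
        raise ValueError(f"unknown layer filter {layer!r}")
    out = []
    for source, target, _pair, weight, sign in net.edges:
        other = target if source == node_id else source if target == node_id else None
        if other is None:
            continue
        if layer is not None and layer_of[other] != layer:
            continue
        out.append((other, layer_of[other], weight, sign))
    out.sort(key=lambda t: (-t[2], t[0]))
    return out
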