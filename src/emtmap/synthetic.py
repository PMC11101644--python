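"""Seeded random signed regulatory maps and the packaged EMT-core fixture.

The generator emulates the statistical shape of curated disease maps:
signed, sparse, directed, with designated input nodes and optional planted
motifs (mutual inhibition, negative feedback, double-positive feedback).
Motif endpoints receive no random incoming edges, so a planted motif's
dynamics are governed by the motif alone — this is what lets the dynamics
stage recover planted structure (oscillation from negative feedback,
bistable settling from mutual inhibition).

The EMT-core fixture is a 21-node distillation of the TGFβ→EMT signalling
core of metastatic breast cancer (receptor activation, SMAD and PI3K/AKT
arms, the SNAIL/ZEB/TWIST programme, the guarding miRNA/GRHL2/OVOL2 loops
and the NF-kB–NKILA oscillator); every edge carries a provenance note in
the shipped JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .map_model import Interaction, RegulatoryMap, SpeciesNode

MOTIF_KINDS = ("mutual_inhibition", "negative_feedback", "double_positive_feedback")


class SpecError(ValueError):
    pass


class MotifConflictError(ValueError):
    """An existing edge carries the opposite sign of a motif edge."""


@dataclass(frozen=True)
class Motif:
    kind: str
    nodes: tuple[str, str]

    def __post_init__(self) -> None:
        if self.kind not in MOTIF_KINDS:
            raise SpecError(f"unknown motif kind {self.kind!r}")
        if len(self.nodes) != 2 or self.nodes[0] == self.nodes[1]:
            raise SpecError("motif needs two distinct node ids")

    def edges(self) -> list[tuple[str, str, str]]:
        a, b = self.nodes
        if self.kind == "mutual_inhibition":
            return [(a, b, "inhibition"), (b, a, "inhibition")]
        if self.kind == "negative_feedback":
            return [(a, b, "activation"), (b, a, "inhibition")]
        return [(a, b, "activation"), (b, a, "activation")]


@dataclass
class SyntheticMapSpec:
    n_nodes: int
    n_edges: int
    inhibition_fraction: float = 0.3
    motifs: list[Motif] = field(default_factory=list)
    input_nodes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise SpecError("n_nodes must be >= 1")
        if not 0.0 <= self.inhibition_fraction <= 1.0:
            raise SpecError("inhibition_fraction must lie in [0, 1]")
        if self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise SpecError("n_edges exceeds the number of distinct directed edges")
        if not 0 <= self.input_nodes <= self.n_nodes:
            raise SpecError("input_nodes out of range")
        node_ids = set(node_names(self.n_nodes))
        for m in self.motifs:
            for nid in m.nodes:
                if nid not in node_ids:
                    raise SpecError(f"motif node {nid!r} outside the generated id range")


def node_names(n: int) -> list[str]:
    width = max(2, len(str(n - 1)))
    return [f"n{i:0{width}d}" for i in range(n)]


def generate_random_map(spec: SyntheticMapSpec) -> RegulatoryMap:
    """Draw a random signed map; fully reproducible from ``spec.seed``.

    Exactly ``n_edges`` distinct directed edges (no self-loops), each
    inhibitory with probability ``inhibition_fraction``; edges never point
    into input nodes or motif endpoints; requested motifs are injected
    verbatim after the random wiring.
    """
    rng = np.random.default_rng(spec.seed)
    names = node_names(spec.n_nodes)
    inputs = set(names[: spec.input_nodes])
    reserved = {nid for m in spec.motifs for nid in m.nodes}
    candidates = [
        (u, v)
        for u in names
        for v in names
        if u != v and v not in inputs and v not in reserved
    ]
    if spec.n_edges > len(candidates):
        raise SpecError(
            f"n_edges={spec.n_edges} infeasible: only {len(candidates)} candidate edges "
            f"after excluding self-loops and edges into inputs/motif nodes"
        )
    chosen_idx = rng.choice(len(candidates), size=spec.n_edges, replace=False)
    species = [SpeciesNode(nid, nid) for nid in names]
    interactions = []
    for k, idx in enumerate(sorted(int(i) for i in chosen_idx)):
        u, v = candidates[idx]
        sign = "inhibition" if rng.random() < spec.inhibition_fraction else "activation"
        interactions.append(Interaction(id=f"e{k + 1:04d}", sources=(u,), target=v, sign=sign))
    map_ = RegulatoryMap(species, interactions, provenance=f"synthetic(seed={spec.seed})")
    for m in spec.motifs:
        map_ = inject_motif(map_, m)
    return map_


def inject_motif(map_: RegulatoryMap, motif: Motif, seed: int | None = None) -> RegulatoryMap:
    """Return a new map with the motif's edges added.

    Existing identical edges are not duplicated (injection is idempotent);
    an existing edge with the opposite sign raises
    :class:`MotifConflictError`.
    """
    new = map_.copy()
    known = {s.id for s in new.species}
    for nid in motif.nodes:
        if nid not in known:
            new.species.append(SpeciesNode(nid, nid))
            known.add(nid)
    existing = {}
    for inter in new.interactions:
        for src in inter.sources:
            existing[(src, inter.target)] = inter.sign
    for i, (u, v, sign) in enumerate(motif.edges(), start=1):
        prev = existing.get((u, v))
        if prev == sign:
            continue
        if prev is not None:
            raise MotifConflictError(
                f"edge {u}->{v} already present with sign {prev!r}, motif wants {sign!r}"
            )
        new.interactions.append(
            Interaction(
                id=f"m_{motif.kind}_{motif.nodes[0]}_{motif.nodes[1]}_{i}",
                sources=(u,),
                target=v,
                sign=sign,
                mechanism_note=f"injected {motif.kind} motif",
            )
        )
    return new


# ---------------------------------------------------------------------------
# packaged fixture


def _load_manifest() -> dict:
    with resources.files("emtmap.data").joinpath("emt_core_manifest.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


def emt_core_fixture() -> RegulatoryMap:
    """The packaged EMT-core map, built from the shipped JSON manifest."""
    manifest = _load_manifest()
    species = [
        SpeciesNode(s["id"], s["name"], s["kind"], s["compartment"])
        for s in manifest["species"]
    ]
    interactions = [
        Interaction(
            id=f"e{k + 1:02d}",
            sources=(e["source"],),
            target=e["target"],
            sign=e["sign"],
            mechanism_note=e["note"],
        )
        for k, e in enumerate(manifest["edges"])
    ]
    return RegulatoryMap(species, interactions, provenance="emt_core_fixture")


def emt_core_manifest() -> dict:
    """The fixture's manifest (species/edge lists with provenance notes)."""
    return _load_manifest()
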