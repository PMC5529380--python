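"""Generate the EB-PB neuron-type catalogue and type-level synaptic weights.

The circuit connects two neuropils of the fly central complex:

* the protocerebral bridge (PB), 18 glomeruli, nine per hemisphere
  (``R0``..``R8``, ``L0``..``L8``);
* the ellipsoid body (EB), a torus whose C and P rings are divided into 16
  wedges.  Around the torus the wedges run
  ``L1, R1, R2, .., R8, L8, L7, .., L2`` and each wedge subtends 22.5 deg of
  azimuth.  Adjacent wedge pairs form eight "dual regions"
  (``L1R1, R2R3, R4R5, R6R7, R8L8, L7L6, L5L4, L3L2``), the innervation unit
  of the PB->EB neurons.

Four neuron classes wire the two structures together:

* EIP: dendrites in three consecutive EB wedges, axon in one PB glomerulus
  (the two atypical types EIP0/EIP17 innervate the single wedge R8 / L8);
* PEI: dendrite in one PB glomerulus of R0-R7/L0-L7, axon in one EB dual
  region of the C ring — together with EIP a symmetric feedback loop;
* PEN: like PEI but dendrites in R1-R8/L1-L8 and axons in the P ring,
  forming an asymmetric "shifter" whose feedback lands one EB region over;
* ring neurons (R_EIP, R_PEI, R_PEN): GABAergic, from the lateral triangle,
  arborizing over all 16 wedges of their target ring; they supply the global
  inhibition that enforces a single activity bump and gate which ring
  circuit is in operation.

Synapses are inferred from region overlap: an axonal arbor in a region
contacts every dendritic arbor in the same region, and the maximal
conductance of the type-to-type connection is proportional to the number of
shared regions.  The two wrap-around connections onto the atypical types
(PEN8->EIP0 and PEN7->EIP17, one shared wedge each) are tripled so the bump
can cross the R8L8 seam without stalling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import networkx as nx

from ebpb.config import ModelConfig, default_config

EB_WEDGE_ORDER: Tuple[str, ...] = (
    "L1", "R1", "R2", "R3", "R4", "R5", "R6", "R7",
    "R8", "L8", "L7", "L6", "L5", "L4", "L3", "L2",
)
N_WEDGES = 16
N_DUALS = 8
WEDGE_POS: Dict[str, int] = {w: i for i, w in enumerate(EB_WEDGE_ORDER)}

EXCITATORY_CLASSES = ("EIP", "PEI", "PEN")
RING_CLASSES = ("R_EIP", "R_PEI", "R_PEN")
RING_TARGET = {"R_EIP": "EIP", "R_PEI": "PEI", "R_PEN": "PEN"}

# the two seam connections whose strength is tripled
TRIPLED_EDGES = ((("PEN", 8), ("EIP", 0)), (("PEN", 7), ("EIP", 17)))


@dataclass(frozen=True, order=True)
class RegionID:
    """A single anatomical region: a PB glomerulus or an EB wedge."""

    neuropil: str  # "EB" or "PB"
    label: str     # PB: R0..R8/L0..L8; EB wedge: R1..R8/L1..L8

    def __post_init__(self):
        if self.neuropil not in ("EB", "PB"):
            raise ValueError("neuropil must be EB or PB")
        side, idx = self.label[0], int(self.label[1:])
        if side not in "RL":
            raise ValueError("label side must be R or L")
        if self.neuropil == "PB" and not 0 <= idx <= 8:
            raise ValueError("PB glomeruli are numbered 0..8")
        if self.neuropil == "EB" and not 1 <= idx <= 8:
            raise ValueError("EB wedges are numbered 1..8")

    @property
    def position(self) -> int:
        """Circular position 0..15 of an EB wedge."""
        if self.neuropil != "EB":
            raise ValueError("position defined for EB wedges only")
        return WEDGE_POS[self.label]

    def __repr__(self):
        return f"{self.neuropil}:{self.label}"


def eb(label: str) -> RegionID:
    return RegionID("EB", label)


def pb(label: str) -> RegionID:
    return RegionID("PB", label)


def dual_regions(offset: int = 0) -> List[Tuple[RegionID, RegionID]]:
    """The eight dual regions as adjacent wedge pairs tiling the 16 wedges.

    ``offset`` rotates the tiling by one wedge; only ``offset=0`` reproduces
    the anatomically named duals (R2R3, L3L2 a.k.a. L23, and the R8L8 seam).
    """
    out = []
    for d in range(N_DUALS):
        a = (2 * d + offset) % N_WEDGES
        b = (2 * d + 1 + offset) % N_WEDGES
        out.append((eb(EB_WEDGE_ORDER[a]), eb(EB_WEDGE_ORDER[b])))
    return out


def dual_of_wedge(wedge: RegionID, offset: int = 0) -> int:
    """Index 0..7 of the dual region containing an EB wedge."""
    return ((wedge.position - offset) % N_WEDGES) // 2


@dataclass(frozen=True)
class NeuronTypeSpec:
    """One anatomical neuron type (regional innervation pattern)."""

    neuron_class: str
    type_index: int
    dendritic_regions: FrozenSet[RegionID]
    axonal_regions: FrozenSet[RegionID]
    transmitter: str  # "excitatory_NMDA" or "inhibitory_GABA_A"

    @property
    def name(self) -> str:
        return f"{self.neuron_class}{self.type_index}"

    def eb_dendrites(self) -> FrozenSet[RegionID]:
        return frozenset(r for r in self.dendritic_regions if r.neuropil == "EB")

    def eb_axons(self) -> FrozenSet[RegionID]:
        return frozenset(r for r in self.axonal_regions if r.neuropil == "EB")

    def __repr__(self):
        return f"<{self.name}>"


@dataclass(frozen=True)
class TypeSynapse:
    """A directed type-level connection with its overlap count and strength."""

    pre: NeuronTypeSpec
    post: NeuronTypeSpec
    overlap_count: int
    neuropil: str
    receptor: str       # NMDA / GABA_A / ACh
    G_max_nS: float = 0.0

    def key(self) -> Tuple[Tuple[str, int], Tuple[str, int]]:
        return ((self.pre.neuron_class, self.pre.type_index),
                (self.post.neuron_class, self.post.type_index))


@dataclass
class Connectome:
    types: List[NeuronTypeSpec]
    synapses: List[TypeSynapse]
    base_weights: Dict[Tuple[str, str], float] = field(default_factory=dict)
    dual_offset: int = 0

    def type_named(self, neuron_class: str, index: int) -> NeuronTypeSpec:
        for t in self.types:
            if t.neuron_class == neuron_class and t.type_index == index:
                return t
        raise KeyError(f"{neuron_class}{index}")

    def synapse(self, pre: Tuple[str, int], post: Tuple[str, int]) -> Optional[TypeSynapse]:
        for s in self.synapses:
            if s.key() == (pre, post):
                return s
        return None

    def subset(self, classes) -> "Connectome":
        """Connectome restricted to the given neuron classes (circuit variants)."""
        keep = set(classes)
        types = [t for t in self.types if t.neuron_class in keep]
        syn = [s for s in self.synapses
               if s.pre.neuron_class in keep and s.post.neuron_class in keep]
        return Connectome(types, syn, dict(self.base_weights), self.dual_offset)

    # -- export -----------------------------------------------------------
    def to_edge_table(self) -> List[dict]:
        return [dict(pre_class=s.pre.neuron_class, pre_index=s.pre.type_index,
                     post_class=s.post.neuron_class, post_index=s.post.type_index,
                     neuropil=s.neuropil, overlap_count=s.overlap_count,
                     receptor=s.receptor, G_max_nS=s.G_max_nS)
                for s in self.synapses]

    def write_edge_list(self, path, sep="\t") -> None:
        cols = ["pre_class", "pre_index", "post_class", "post_index",
                "neuropil", "overlap_count", "receptor", "G_max_nS"]
        with open(path, "w") as fh:
            fh.write(sep.join(cols) + "\n")
            for row in self.to_edge_table():
                fh.write(sep.join(str(row[c]) for c in cols) + "\n")

    def to_graph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for t in self.types:
            g.add_node(t.name, neuron_class=t.neuron_class,
                       transmitter=t.transmitter)
        for s in self.synapses:
            g.add_edge(s.pre.name, s.post.name, neuropil=s.neuropil,
                       overlap=s.overlap_count, receptor=s.receptor,
                       G_max_nS=s.G_max_nS)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)


class WiringError(ValueError):
    """Raised when the generated graph violates a circuit invariant."""


# ---------------------------------------------------------------------------
# catalogue construction
# ---------------------------------------------------------------------------

def _wedges(positions) -> FrozenSet[RegionID]:
    return frozenset(eb(EB_WEDGE_ORDER[p % N_WEDGES]) for p in positions)


def pei_dual_index(side: str, glom: int) -> int:
    """Dual region innervated by the PEI type with dendrite in PB side/glom.

    Anchored so that the EB dual R2R3 (index 1) receives PEI input from
    PB R5 and PB L3: this realises the visual-cue mapping in which a cue in
    wedge R2's receptive field is delivered to PB R5 and L3.
    """
    if side == "R":
        return (glom - 4) % N_DUALS
    return (4 - glom) % N_DUALS


def build_type_catalogue(config: Optional[ModelConfig] = None) -> List[NeuronTypeSpec]:
    """Deterministically construct all 53 neuron types.

    18 EIP + 16 PEI + 16 PEN + 3 ring-neuron types.  The regional assignment
    is generated algorithmically; the anchors it reproduces (worked shifter
    chains, PEI11 overlaps, cue mapping, seam connections) are asserted by
    the test-suite rather than hard-coded here.
    """
    cfg = config or default_config()
    off = cfg.dual_offset
    duals = dual_regions(off)
    types: List[NeuronTypeSpec] = []

    # EIP: dendrites 3 consecutive wedges, axon one PB glomerulus.
    # Right-block types 1..8 step clockwise (descending position), axon
    # R(8-k); left-block 9..16 similarly on the other hemisphere, axon
    # L(k-9).  The two atypical types innervate a single seam wedge and
    # project contralaterally, closing the opposite hemisphere's shifter
    # chain at R8L8.
    for k in range(18):
        if k == 0:
            dend, axon = _wedges([8]), pb("L8")
        elif k == 17:
            dend, axon = _wedges([9]), pb("R8")
        elif 1 <= k <= 8:
            dend = _wedges([8 - 2 * k, 9 - 2 * k, 10 - 2 * k])
            axon = pb(f"R{8 - k}")
        else:
            dend = _wedges([25 - 2 * k, 26 - 2 * k, 27 - 2 * k])
            axon = pb(f"L{k - 9}")
        types.append(NeuronTypeSpec("EIP", k, dend, frozenset([axon]),
                                    "excitatory_NMDA"))

    # PEI: dendrite one PB glomerulus of 0..7, axon one dual region (C ring).
    for k in range(16):
        side, glom = ("R", k) if k < 8 else ("L", k - 8)
        d = pei_dual_index(side, glom)
        types.append(NeuronTypeSpec(
            "PEI", k, frozenset([pb(f"{side}{glom}")]),
            frozenset(duals[d]), "excitatory_NMDA"))

    # PEN: copy of the PEI innervation with the PB site shifted one
    # glomerulus outward (dendrites 1..8), axon in the P ring.
    # PEN0..7 sit on the right hemisphere (numbered R8 down to R1),
    # PEN8..15 on the left (L1 up to L8).
    for k in range(16):
        if k < 8:
            side, glom = "R", 8 - k
        else:
            side, glom = "L", k - 7
        d = pei_dual_index(side, glom - 1)
        types.append(NeuronTypeSpec(
            "PEN", k, frozenset([pb(f"{side}{glom}")]),
            frozenset(duals[d]), "excitatory_NMDA"))

    # Ring neurons: axons blanket all 16 wedges of their target ring.
    all_wedges = _wedges(range(N_WEDGES))
    for name in RING_CLASSES:
        types.append(NeuronTypeSpec(name, 0, frozenset(), all_wedges,
                                    "inhibitory_GABA_A"))
    return types


# ---------------------------------------------------------------------------
# synapse inference
# ---------------------------------------------------------------------------

def infer_synapses(catalogue: List[NeuronTypeSpec],
                   validate: bool = True) -> List[TypeSynapse]:
    """Infer type-level synapses from region overlap.

    The rule: an axonal arbor contacts every dendritic arbor sharing a
    region, with overlap count = number of shared regions.  Ring neurons are
    wired by their functional rule: each ring type inhibits every type of
    its target class across the ring (overlap = wedges of the target's EB
    arbor), and R_EIP additionally receives direct excitation from every EIP
    type (a single-contact simplification of an indirect pathway).
    """
    syn: List[TypeSynapse] = []
    excit = [t for t in catalogue if t.neuron_class in EXCITATORY_CLASSES]
    rings = {t.neuron_class: t for t in catalogue if t.neuron_class in RING_CLASSES}

    for pre in excit:
        for post in excit:
            if pre is post:
                continue
            for neuropil in ("EB", "PB"):
                shared = {r for r in pre.axonal_regions if r.neuropil == neuropil} & \
                         {r for r in post.dendritic_regions if r.neuropil == neuropil}
                if shared:
                    syn.append(TypeSynapse(pre, post, len(shared), neuropil, "NMDA"))

    for ring_class, ring in rings.items():
        target_class = RING_TARGET[ring_class]
        for post in excit:
            if post.neuron_class != target_class:
                continue
            # EIP dendrites lie in the EB; PEI/PEN terminate there axonally
            arbor = post.eb_dendrites() if target_class == "EIP" else post.eb_axons()
            shared = ring.eb_axons() & arbor
            if shared:
                syn.append(TypeSynapse(ring, post, len(shared), "EB", "GABA_A"))

    r_eip = rings.get("R_EIP")
    if r_eip is not None:
        for pre in excit:
            if pre.neuron_class == "EIP":
                syn.append(TypeSynapse(pre, r_eip, 1, "EB", "NMDA"))

    if validate:
        validate_connectome(catalogue, syn)
    return syn


def assign_weights(synapses: List[TypeSynapse],
                   base_weights: Dict[Tuple[str, str], float]) -> List[TypeSynapse]:
    """Populate G_max = base_weight * overlap (3x for the two seam edges).

    Ring-neuron inhibition is uniform per target type (G_max = base weight):
    a ring neuron blankets the whole ring, and scaling its strength with the
    target's dendritic footprint would leave the single-wedge types EIP0 and
    EIP17 with a third of the typical inhibition while they already receive
    the tripled seam excitation — the seam would then capture every bump.
    """
    tripled = set(TRIPLED_EDGES)
    out = []
    for s in synapses:
        chan = (s.pre.neuron_class, s.post.neuron_class)
        if chan not in base_weights:
            raise KeyError(f"no base weight configured for channel {chan}")
        if s.pre.neuron_class in RING_CLASSES:
            w = base_weights[chan]
        else:
            w = base_weights[chan] * s.overlap_count
        if s.key() in tripled:
            w *= 3.0
        out.append(TypeSynapse(s.pre, s.post, s.overlap_count, s.neuropil,
                               s.receptor, w))
    return out


def build_connectome(config: Optional[ModelConfig] = None) -> Connectome:
    """Catalogue + inferred synapses + weights, as one validated object."""
    cfg = config or default_config()
    cat = build_type_catalogue(cfg)
    syn = assign_weights(infer_synapses(cat), cfg.base_weights)
    return Connectome(cat, syn, dict(cfg.base_weights), cfg.dual_offset)


# ---------------------------------------------------------------------------
# invariant validation
# ---------------------------------------------------------------------------

def validate_connectome(catalogue: List[NeuronTypeSpec],
                        synapses: List[TypeSynapse]) -> None:
    """Check the structural invariants of the generated graph.

    Raises :class:`WiringError` on violation — a failure signals a bug in the
    wiring rules, not bad user input.
    """
    by_key = {(s.pre.name, s.post.name): s for s in synapses}

    # overlap counts match the region sets
    for s in synapses:
        if s.pre.neuron_class in RING_CLASSES or s.post.neuron_class in RING_CLASSES:
            continue
        shared = {r for r in s.pre.axonal_regions if r.neuropil == s.neuropil} & \
                 {r for r in s.post.dendritic_regions if r.neuropil == s.neuropil}
        if len(shared) != s.overlap_count:
            raise WiringError(f"overlap mismatch on {s.pre.name}->{s.post.name}")

    # C-ring symmetry: every EIP->PEI edge is reciprocated
    for s in synapses:
        if s.pre.neuron_class == "EIP" and s.post.neuron_class == "PEI":
            if (s.post.name, s.pre.name) not in by_key:
                raise WiringError(
                    f"unreciprocated C-ring edge {s.pre.name}->{s.post.name}")

    # P-ring asymmetry: no EIP both projects to and receives from one PEN
    for s in synapses:
        if s.pre.neuron_class == "EIP" and s.post.neuron_class == "PEN":
            if (s.post.name, s.pre.name) in by_key:
                raise WiringError(
                    f"symmetric P-ring edge {s.pre.name}<->{s.post.name}")

    # seam edges exist with a single shared wedge
    for (pre_k, post_k) in TRIPLED_EDGES:
        s = by_key.get((f"{pre_k[0]}{pre_k[1]}", f"{post_k[0]}{post_k[1]}"))
        if s is None or s.overlap_count != 1:
            raise WiringError(f"seam edge {pre_k}->{post_k} missing or wrong overlap")


def shifter_chains(conn: Connectome) -> Dict[str, List[str]]:
    """Walk the two shifter cycles, following the strongest PEN->EIP edge.

    Returns the clockwise and counterclockwise cycles as alternating
    EIP/PEN name lists; each traverses all eight dual regions before
    returning to its start.
    """
    pen_dend_side = {}
    for t in conn.types:
        if t.neuron_class == "PEN":
            (r,) = [x for x in t.dendritic_regions]
            pen_dend_side[t.type_index] = r.label[0]

    def eip_target_pen(eip):
        for s in conn.synapses:
            if s.pre is eip and s.post.neuron_class == "PEN":
                return s.post
        return None

    def next_eip(pen, side):
        cands = []
        for s in conn.synapses:
            if s.pre is pen and s.post.neuron_class == "EIP":
                tgt = eip_target_pen(s.post)
                if tgt is not None and pen_dend_side[tgt.type_index] == side:
                    cands.append((s.G_max_nS if s.G_max_nS else s.overlap_count, s.post))
        if not cands:
            raise WiringError(f"shifter chain dead-ends at {pen.name}")
        return max(cands, key=lambda c: c[0])[1]

    chains = {}
    for label, start, side in (("CW", ("EIP", 17), "R"), ("CCW", ("EIP", 0), "L")):
        eip0 = conn.type_named(*start)
        node, names = eip0, [eip0.name]
        for _ in range(8):
            p = eip_target_pen(node)
            names.append(p.name)
            node = next_eip(p, side)
            names.append(node.name)
        if node is not eip0:
            raise WiringError(f"{label} chain does not close: {names}")
        chains[label] = names
    return chains
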