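"""Graph construction for the stacked two-U-Net ("W-Net") segmentation family.

The model family stacks two U-Nets end to end.  Four "paths" make up the
network: B1/B2 are the contracting (encoder) and expansion (decoder) halves of
the first U-Net, B3/B4 those of the second.  Besides the ordinary intra-U-Net
skip connections (B1 feeds B2, B3 feeds B4 at the same level), three families
of *bridge* connections carry first-U-Net feature maps into the second U-Net:

* ``B1->B4`` — encoder features of U-Net 1 into the decoder of U-Net 2,
* ``B2->B3`` — decoder features of U-Net 1 into the encoder of U-Net 2,
* ``B2->B4`` — decoder features of U-Net 1 into the decoder of U-Net 2.

The four named variants differ only in which bridge families are active; the
*compound* model activates all three, so every B4 block concatenates four
feature maps (its own up-convolved input plus same-level maps from B1, B2 and
B3).  All joins are channel-wise concatenations, never additions.

Networks are represented as an inspectable directed acyclic graph of
:class:`LayerNode` objects with exact output shapes and parameter counts, so
architecture arithmetic (filter schedules, spatial halving/doubling, concat
arities, capacity) can be checked without instantiating any weights.  The
numeric forward/backward executor in :mod:`wnetseg.nn` walks the same graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ShapeError",
    "GraphError",
    "BRIDGE_B1_B4",
    "BRIDGE_B2_B3",
    "BRIDGE_B2_B4",
    "ALL_BRIDGES",
    "VARIANT_BRIDGES",
    "FilterSchedule",
    "VariantSpec",
    "TensorShape",
    "LayerNode",
    "NetworkGraph",
    "make_filter_schedule",
    "contracting_block",
    "expansion_block",
    "assemble_network",
    "build_wnet",
    "trace_shapes",
    "count_parameters",
    "concat_arity",
]


class ShapeError(ValueError):
    """Raised when tensor shapes cannot be propagated consistently."""


class GraphError(ValueError):
    """Raised for structurally invalid network graphs (e.g. cycles)."""


BRIDGE_B1_B4 = "B1->B4"
BRIDGE_B2_B3 = "B2->B3"
BRIDGE_B2_B4 = "B2->B4"
ALL_BRIDGES = frozenset({BRIDGE_B1_B4, BRIDGE_B2_B3, BRIDGE_B2_B4})

#: Bridge families active in each named variant.
VARIANT_BRIDGES: Mapping[str, frozenset] = {
    "unet": frozenset(),
    "original_bridge": frozenset({BRIDGE_B1_B4, BRIDGE_B2_B3}),
    "modified_bridge": frozenset({BRIDGE_B2_B3, BRIDGE_B2_B4}),
    "compound": ALL_BRIDGES,
}

_VARIANT_ALIASES = {
    "original": "original_bridge",
    "modified": "modified_bridge",
    "wnet": "compound",
}


@dataclass(frozen=True)
class TensorShape:
    """Spatial/channel shape of one feature map (height, width, channels)."""

    height: int
    width: int
    channels: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0 or self.channels <= 0:
            raise ShapeError(f"all dimensions must be positive, got {self}")

    def spatial(self) -> tuple:
        return (self.height, self.width)

    def with_channels(self, channels: int) -> "TensorShape":
        return TensorShape(self.height, self.width, channels)

    def halved(self) -> "TensorShape":
        if self.height % 2 or self.width % 2:
            raise ShapeError(f"cannot halve odd spatial dims {self}")
        return TensorShape(self.height // 2, self.width // 2, self.channels)

    def doubled(self) -> "TensorShape":
        return TensorShape(self.height * 2, self.width * 2, self.channels)


@dataclass(frozen=True)
class FilterSchedule:
    """Doubling filter schedule: level *l* uses ``base_filters * 2**(l-1)``.

    The two full-scale versions start at 64 (reaching 1024 at level 5) or at
    32 (reaching 512); any positive base is accepted for scaled-down models.
    """

    base_filters: int
    levels: int
    per_level: tuple

    def __post_init__(self) -> None:
        if self.base_filters < 1 or self.levels < 1:
            raise ValueError("base_filters and levels must be >= 1")
        expected = tuple(self.base_filters * 2 ** l for l in range(self.levels))
        if tuple(self.per_level) != expected:
            raise ValueError(
                f"per_level {self.per_level} violates the doubling law {expected}"
            )

    def filters(self, level: int) -> int:
        return self.per_level[level - 1]


def make_filter_schedule(base_filters: int, levels: int) -> FilterSchedule:
    """Build the doubling schedule, e.g. ``(64, 5) -> [64,128,256,512,1024]``."""
    if base_filters < 1 or levels < 1:
        raise ValueError(
            f"base_filters and levels must be >= 1, got {base_filters}, {levels}"
        )
    return FilterSchedule(
        base_filters=base_filters,
        levels=levels,
        per_level=tuple(base_filters * 2 ** l for l in range(levels)),
    )


@dataclass(frozen=True)
class VariantSpec:
    """Which bridge families are active; defines the four model variants."""

    name: str
    bridges: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "bridges", frozenset(self.bridges))
        unknown = self.bridges - ALL_BRIDGES
        if unknown:
            raise ValueError(f"unknown bridge tags {sorted(unknown)}")
        if self.name in VARIANT_BRIDGES and self.bridges != VARIANT_BRIDGES[self.name]:
            raise ValueError(
                f"variant {self.name!r} requires bridges "
                f"{sorted(VARIANT_BRIDGES[self.name])}, got {sorted(self.bridges)}"
            )

    @property
    def two_unet(self) -> bool:
        """Whether paths B3/B4 exist (every named variant except plain U-Net)."""
        return self.name != "unet"

    @classmethod
    def resolve(cls, variant) -> "VariantSpec":
        if isinstance(variant, cls):
            return variant
        name = _VARIANT_ALIASES.get(str(variant), str(variant))
        if name not in VARIANT_BRIDGES:
            raise ValueError(
                f"unknown variant {variant!r}; expected one of "
                f"{sorted(VARIANT_BRIDGES)} (or a VariantSpec)"
            )
        return cls(name=name, bridges=VARIANT_BRIDGES[name])


@dataclass
class LayerNode:
    """One layer in the network graph.

    ``role`` is one of {input, conv3x3, activation, maxpool2x2, dropout,
    upsample, upconv2x2, concat, conv1x1_out}.  ``params`` counts trainable
    scalars (kernel + bias for convolutions, zero otherwise).  Extra
    role-specific attributes (activation kind, dropout rate, kernel size,
    in/out channels, block-feature flag) live in ``attrs``.
    """

    id: str
    role: str
    path: str
    level: int
    out_shape: TensorShape
    params: int = 0
    attrs: dict = field(default_factory=dict)


@dataclass
class NetworkGraph:
    """A DAG of :class:`LayerNode` with ordered edges.

    Edge order is meaningful for ``concat`` nodes (channel stacking order).
    """

    nodes: dict
    edges: list
    variant: VariantSpec | None
    schedule: FilterSchedule | None
    input_shape: TensorShape

    def __post_init__(self) -> None:
        self._preds: dict = {nid: [] for nid in self.nodes}
        self._succs: dict = {nid: [] for nid in self.nodes}
        for src, dst in self.edges:
            self._preds[dst].append(src)
            self._succs[src].append(dst)

    def predecessors(self, node_id: str) -> list:
        return list(self._preds[node_id])

    def successors(self, node_id: str) -> list:
        return list(self._succs[node_id])

    @property
    def input_id(self) -> str:
        (nid,) = [n.id for n in self.nodes.values() if n.role == "input"]
        return nid

    @property
    def output_id(self) -> str:
        sinks = [nid for nid in self.nodes if not self._succs[nid]]
        if len(sinks) != 1:
            raise GraphError(f"expected exactly one output node, found {sinks}")
        return sinks[0]

    def topological_order(self) -> list:
        indeg = {nid: len(self._preds[nid]) for nid in self.nodes}
        # insertion order of self.nodes keeps the traversal deterministic
        ready = [nid for nid in self.nodes if indeg[nid] == 0]
        order: list = []
        while ready:
            nid = ready.pop(0)
            order.append(nid)
            for succ in self._succs[nid]:
                indeg[succ] -= 1
                if indeg[succ] == 0:
                    ready.append(succ)
        if len(order) != len(self.nodes):
            raise GraphError("network graph contains a cycle")
        return order

    def feature_nodes(self) -> dict:
        """Map (path, level) -> id of the block-output feature node."""
        out = {}
        for node in self.nodes.values():
            if node.attrs.get("feature"):
                out[(node.path, node.level)] = node.id
        return out


class _Builder:
    """Accumulates nodes/edges; ids are '<path>.L<level>.<role><k>'."""

    def __init__(self) -> None:
        self.nodes: dict = {}
        self.edges: list = []

    def add(
        self,
        role: str,
        path: str,
        level: int,
        out_shape: TensorShape,
        inputs: Sequence[str] = (),
        params: int = 0,
        **attrs,
    ) -> str:
        k = sum(
            1
            for n in self.nodes.values()
            if n.role == role and n.path == path and n.level == level
        )
        nid = f"{path}.L{level}.{role}{k}" if k else f"{path}.L{level}.{role}"
        node = LayerNode(
            id=nid, role=role, path=path, level=level,
            out_shape=out_shape, params=params, attrs=dict(attrs),
        )
        self.nodes[nid] = node
        for src in inputs:
            self.edges.append((src, nid))
        return nid

    def shape(self, nid: str) -> TensorShape:
        return self.nodes[nid].out_shape

    def _conv(
        self, role: str, path: str, level: int, input_id: str,
        kernel: int, filters: int, out_shape: TensorShape, **attrs,
    ) -> str:
        cin = self.shape(input_id).channels
        params = kernel * kernel * cin * filters + filters
        return self.add(
            role, path, level, out_shape, inputs=[input_id], params=params,
            kernel=kernel, in_channels=cin, filters=filters, **attrs,
        )

    def concat(self, path: str, level: int, inputs: Sequence[str]) -> str:
        shapes = [self.shape(i) for i in inputs]
        spatial = {s.spatial() for s in shapes}
        if len(spatial) != 1:
            raise ShapeError(
                f"concat at ({path}, L{level}) mixes spatial sizes "
                f"{[s.spatial() for s in shapes]}"
            )
        out = shapes[0].with_channels(sum(s.channels for s in shapes))
        return self.add("concat", path, level, out, inputs=inputs)


def _default_activation(level: int, relu_levels: Iterable[int]) -> str:
    return "relu" if level in set(relu_levels) else "elu"


def _contracting(
    b: _Builder,
    inputs: Sequence[str],
    level: int,
    filters: int,
    dropout_rate: float,
    pool: bool,
    activation: str,
    path: str,
) -> tuple:
    """Append one encoder block; return (feature_id, carry_id).

    ``feature_id`` is the pre-pooling conv output (the level's feature map,
    used by skip/bridge connections); ``carry_id`` is what flows to the next
    block (after 2x2 max-pooling and dropout when ``pool``).
    """
    x = inputs[0] if len(inputs) == 1 else b.concat(path, level, list(inputs))
    shape = b.shape(x)
    if pool and (shape.height % 2 or shape.width % 2):
        raise ShapeError(
            f"({path}, L{level}): spatial dims {shape.spatial()} not divisible "
            "by 2 but pooling requested"
        )
    conv_shape = shape.with_channels(filters)
    x = b._conv("conv3x3", path, level, x, 3, filters, conv_shape)
    x = b.add("activation", path, level, conv_shape, inputs=[x], kind=activation)
    x = b._conv("conv3x3", path, level, x, 3, filters, conv_shape)
    feat = b.add(
        "activation", path, level, conv_shape, inputs=[x],
        kind=activation, feature=True,
    )
    carry = feat
    if pool:
        pooled = conv_shape.halved()
        carry = b.add("maxpool2x2", path, level, pooled, inputs=[carry])
        carry = b.add(
            "dropout", path, level, pooled, inputs=[carry], rate=dropout_rate
        )
    return feat, carry


def _expansion(
    b: _Builder,
    up_input: str,
    laterals: Sequence[str],
    level: int,
    filters: int,
    dropout_rate: float,
    activation: str,
    path: str,
) -> str:
    """Append one decoder block; return the block-output node id.

    upsample -> 2x2 up-convolution (channel-halving to ``filters``) ->
    concat with laterals -> (conv3x3 -> act) x2 -> dropout.
    """
    up_shape = b.shape(up_input).doubled()
    x = b.add("upsample", path, level, up_shape, inputs=[up_input])
    upconv_shape = up_shape.with_channels(filters)
    x = b._conv("upconv2x2", path, level, x, 2, filters, upconv_shape)
    for lat in laterals:
        if b.shape(lat).spatial() != upconv_shape.spatial():
            raise ShapeError(
                f"({path}, L{level}): lateral {lat} has spatial "
                f"{b.shape(lat).spatial()}, expected {upconv_shape.spatial()}"
            )
    if laterals:
        x = b.concat(path, level, [x, *laterals])
    conv_shape = upconv_shape
    x = b._conv("conv3x3", path, level, x, 3, filters, conv_shape)
    x = b.add("activation", path, level, conv_shape, inputs=[x], kind=activation)
    x = b._conv("conv3x3", path, level, x, 3, filters, conv_shape)
    x = b.add("activation", path, level, conv_shape, inputs=[x], kind=activation)
    out = b.add(
        "dropout", path, level, conv_shape, inputs=[x],
        rate=dropout_rate, feature=True,
    )
    return out


def contracting_block(
    level: int,
    in_shape: TensorShape,
    filters: int,
    dropout_rate: float = 0.5,
    pool: bool = True,
    activation: str | None = None,
) -> NetworkGraph:
    """Standalone encoder block as a graph fragment with its own input node."""
    if filters < 1:
        raise ValueError("filters must be >= 1")
    b = _Builder()
    inp = b.add("input", "B1", level, in_shape)
    act = activation or _default_activation(level, (4, 5))
    _contracting(b, [inp], level, filters, dropout_rate, pool, act, "B1")
    return NetworkGraph(b.nodes, b.edges, None, None, in_shape)


def expansion_block(
    level: int,
    up_input: TensorShape,
    lateral_inputs: Sequence[TensorShape],
    filters: int,
    dropout_rate: float = 0.4,
    activation: str | None = None,
) -> NetworkGraph:
    """Standalone decoder block fragment (input nodes for up + laterals)."""
    if filters < 1:
        raise ValueError("filters must be >= 1")
    b = _Builder()
    up = b.add("input", "B2", level + 1, up_input)
    lats = [b.add("input", "B1", level, s) for s in lateral_inputs]
    act = activation or _default_activation(level, (4, 5))
    _expansion(b, up, lats, level, filters, dropout_rate, act, "B2")
    return NetworkGraph(b.nodes, b.edges, None, None, up_input)


def assemble_network(
    variant,
    schedule: FilterSchedule,
    input_shape: TensorShape,
    *,
    dropout_contracting: float = 0.5,
    dropout_expanding: float = 0.4,
    relu_levels: Sequence[int] = (4, 5),
) -> NetworkGraph:
    """Assemble a full variant at the given filter schedule and input size.

    The first U-Net is B1 (encoder levels 1..L-1 pooled, unpooled bottleneck
    at level L) and B2 (decoder levels L-1..1 with the plain same-level skip
    from B1).  For two-U-Net variants, B3 re-encodes starting from B2's final
    feature map, each deeper block concatenating the pooled carry with the
    same-level B2 map when the B2->B3 bridge is active; B4 decodes with the
    intra-U-Net B3 skip plus B1 and/or B2 laterals per the active bridges.
    The head is a 1x1 convolution to a single sigmoid probability channel.
    """
    variant = VariantSpec.resolve(variant)
    if not isinstance(schedule, FilterSchedule):
        raise TypeError("schedule must be a FilterSchedule")
    L = schedule.levels
    if L < 2:
        raise ValueError("assembled networks need at least 2 levels")
    down = 2 ** (L - 1)
    if input_shape.height % down or input_shape.width % down:
        raise ShapeError(
            f"input spatial dims {input_shape.spatial()} must be divisible by "
            f"2^(levels-1) = {down}"
        )

    b = _Builder()
    act = lambda level: _default_activation(level, relu_levels)  # noqa: E731
    x = b.add("input", "B1", 1, input_shape)

    b1_feat: dict = {}
    for l in range(1, L):
        b1_feat[l], x = _contracting(
            b, [x], l, schedule.filters(l), dropout_contracting, True,
            act(l), "B1",
        )
    b1_feat[L], _ = _contracting(
        b, [x], L, schedule.filters(L), dropout_contracting, False, act(L), "B1"
    )

    b2_out: dict = {}
    prev = b1_feat[L]
    for l in range(L - 1, 0, -1):
        prev = _expansion(
            b, prev, [b1_feat[l]], l, schedule.filters(l), dropout_expanding,
            act(l), "B2",
        )
        b2_out[l] = prev

    if variant.two_unet:
        b3_feat: dict = {}
        x = b2_out[1]
        for l in range(1, L):
            inputs = [x]
            if l > 1 and BRIDGE_B2_B3 in variant.bridges:
                inputs.append(b2_out[l])
            b3_feat[l], x = _contracting(
                b, inputs, l, schedule.filters(l), dropout_contracting, True,
                act(l), "B3",
            )
        b3_feat[L], _ = _contracting(
            b, [x], L, schedule.filters(L), dropout_contracting, False,
            act(L), "B3",
        )

        prev = b3_feat[L]
        for l in range(L - 1, 0, -1):
            laterals = []
            if BRIDGE_B1_B4 in variant.bridges:
                laterals.append(b1_feat[l])
            if BRIDGE_B2_B4 in variant.bridges:
                laterals.append(b2_out[l])
            laterals.append(b3_feat[l])
            prev = _expansion(
                b, prev, laterals, l, schedule.filters(l), dropout_expanding,
                act(l), "B4",
            )
        head_in = prev
        head_path = "B4"
    else:
        head_in = b2_out[1]
        head_path = "B2"

    out_shape = TensorShape(input_shape.height, input_shape.width, 1)
    b._conv(
        "conv1x1_out", head_path, 1, head_in, 1, 1, out_shape,
        activation="sigmoid",
    )
    graph = NetworkGraph(b.nodes, b.edges, variant, schedule, input_shape)
    graph.topological_order()  # assert acyclic on construction
    return graph


def build_wnet(
    variant="compound",
    base_filters: int = 64,
    input_size: int = 256,
    levels: int = 5,
    **kwargs,
) -> NetworkGraph:
    """Convenience wrapper: square single-channel input, doubling schedule."""
    return assemble_network(
        variant,
        make_filter_schedule(base_filters, levels),
        TensorShape(input_size, input_size, 1),
        **kwargs,
    )


_SAME_SHAPE_ROLES = {"activation", "dropout"}


def _propagated_shape(node: LayerNode, in_shapes: Sequence[TensorShape],
                      graph: NetworkGraph) -> TensorShape:
    role = node.role
    if role == "input":
        return graph.input_shape
    if role in _SAME_SHAPE_ROLES:
        (s,) = in_shapes
        return s
    if role == "maxpool2x2":
        (s,) = in_shapes
        return s.halved()
    if role == "upsample":
        (s,) = in_shapes
        return s.doubled()
    if role == "concat":
        if len(in_shapes) < 2:
            raise ShapeError(f"concat node {node.id} has fewer than 2 inputs")
        if len({s.spatial() for s in in_shapes}) != 1:
            raise ShapeError(f"concat node {node.id} mixes spatial sizes")
        return in_shapes[0].with_channels(sum(s.channels for s in in_shapes))
    if role in {"conv3x3", "upconv2x2", "conv1x1_out"}:
        (s,) = in_shapes
        return s.with_channels(node.attrs["filters"])
    raise GraphError(f"unknown role {role!r} at node {node.id}")


def trace_shapes(graph: NetworkGraph) -> dict:
    """Re-propagate shapes through the graph and report per-(path, level) maps.

    Walks the DAG topologically, recomputes every node's output shape from
    its role and inputs, and checks it against the stored annotation; any
    inconsistency raises :class:`ShapeError` naming the offending node.
    Returns a mapping ``(path, level) -> TensorShape`` of block-output
    feature maps (plus the network output under ``("out", 0)``).
    """
    computed: dict = {}
    for nid in graph.topological_order():
        node = graph.nodes[nid]
        in_shapes = [computed[p] for p in graph.predecessors(nid)]
        shape = _propagated_shape(node, in_shapes, graph)
        if shape != node.out_shape:
            raise ShapeError(
                f"node {nid}: stored shape {node.out_shape} != propagated {shape}"
            )
        computed[nid] = shape
    table = {
        key: graph.nodes[nid].out_shape
        for key, nid in graph.feature_nodes().items()
    }
    table[("out", 0)] = graph.nodes[graph.output_id].out_shape
    return table


def count_parameters(graph: NetworkGraph) -> int:
    """Total trainable parameters: kh*kw*cin*cout + cout per convolution."""
    return sum(node.params for node in graph.nodes.values())


def concat_arity(graph: NetworkGraph, path: str, level: int) -> int:
    """Number of feature maps joined by the concat node at (path, level)."""
    hits = [
        n for n in graph.nodes.values()
        if n.role == "concat" and n.path == path and n.level == level
    ]
    if not hits:
        raise KeyError(f"no concat node at ({path}, level {level})")
    if len(hits) > 1:
        raise GraphError(f"multiple concat nodes at ({path}, level {level})")
    return len(graph.predecessors(hits[0].id))
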