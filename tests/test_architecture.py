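"""Architecture graph construction: schedules, blocks, wiring, shapes, capacity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wnetseg.architecture import (
    GraphError,
    ShapeError,
    TensorShape,
    VariantSpec,
    assemble_network,
    build_wnet,
    concat_arity,
    contracting_block,
    count_parameters,
    expansion_block,
    make_filter_schedule,
    trace_shapes,
)

ALL_VARIANTS = ("unet", "original_bridge", "modified_bridge", "compound")


class TestFilterSchedule:
    @pytest.mark.parametrize(
        "base,levels,expected",
        [
            (64, 5, (64, 128, 256, 512, 1024)),
            (32, 5, (32, 64, 128, 256, 512)),
            (1, 1, (1,)),
        ],
    )
    def test_doubling_law(self, base, levels, expected):
        assert make_filter_schedule(base, levels).per_level == expected

    @pytest.mark.parametrize("base,levels", [(0, 5), (-1, 5), (4, 0)])
    def test_rejects_nonpositive(self, base, levels):
        with pytest.raises(ValueError):
            make_filter_schedule(base, levels)


class TestVariantSpec:
    def test_bridge_sets(self):
        assert VariantSpec.resolve("unet").bridges == frozenset()
        assert VariantSpec.resolve("original_bridge").bridges == {
            "B1->B4", "B2->B3"}
        assert VariantSpec.resolve("modified_bridge").bridges == {
            "B2->B3", "B2->B4"}
        assert VariantSpec.resolve("compound").bridges == {
            "B1->B4", "B2->B3", "B2->B4"}

    def test_aliases_and_unknown(self):
        assert VariantSpec.resolve("original").name == "original_bridge"
        with pytest.raises(ValueError):
            VariantSpec.resolve("vnet")

    def test_inconsistent_bridges_rejected(self):
        with pytest.raises(ValueError):
            VariantSpec(name="unet", bridges=frozenset({"B1->B4"}))


class TestBlocks:
    @pytest.mark.parametrize(
        "level,shape,filters,pool,expected",
        [
            (1, (256, 256, 1), 64, True, (128, 128, 64)),
            (5, (16, 16, 512), 1024, False, (16, 16, 1024)),
            (1, (8, 8, 1), 2, True, (4, 4, 2)),
        ],
    )
    def test_contracting_output(self, level, shape, filters, pool, expected):
        frag = contracting_block(level, TensorShape(*shape), filters, pool=pool)
        sinks = [n for n in frag.nodes.values()
                 if not frag.successors(n.id)]
        (out,) = sinks
        assert (out.out_shape.height, out.out_shape.width,
                out.out_shape.channels) == expected

    def test_contracting_feature_precedes_pooling(self):
        frag = contracting_block(1, TensorShape(8, 8, 1), 4, pool=True)
        (feat,) = [n for n in frag.nodes.values() if n.attrs.get("feature")]
        assert feat.out_shape == TensorShape(8, 8, 4)

    def test_contracting_rejects_odd_pooling(self):
        with pytest.raises(ShapeError):
            contracting_block(1, TensorShape(7, 7, 1), 4, pool=True)

    @pytest.mark.parametrize(
        "up,laterals,filters,expected_concat_ch,expected_out",
        [
            ((16, 16, 1024), [(32, 32, 512)], 512, 1024, (32, 32, 512)),
            ((32, 32, 512), [(64, 64, 256)] * 3, 256, 1024, (64, 64, 256)),
            ((4, 4, 4), [], 2, None, (8, 8, 2)),
        ],
    )
    def test_expansion_output(self, up, laterals, filters,
                              expected_concat_ch, expected_out):
        frag = expansion_block(
            1, TensorShape(*up), [TensorShape(*s) for s in laterals], filters
        )
        concats = [n for n in frag.nodes.values() if n.role == "concat"]
        if expected_concat_ch is None:
            assert not concats
        else:
            assert concats[0].out_shape.channels == expected_concat_ch
        (out,) = [n for n in frag.nodes.values() if not frag.successors(n.id)]
        assert (out.out_shape.height, out.out_shape.width,
                out.out_shape.channels) == expected_out

    def test_expansion_rejects_lateral_mismatch(self):
        with pytest.raises(ShapeError):
            expansion_block(1, TensorShape(16, 16, 8), [TensorShape(16, 16, 4)], 4)


class TestAssembledNetworks:
    def test_compound_full_scale_shapes(self):
        graph = build_wnet("compound", base_filters=64, input_size=256)
        table = trace_shapes(graph)
        assert table[("B1", 5)] == TensorShape(16, 16, 1024)
        assert table[("out", 0)] == TensorShape(256, 256, 1)
        for level in range(1, 5):
            assert concat_arity(graph, "B4", level) == 4

    def test_unet_has_no_second_unet(self):
        graph = build_wnet("unet", base_filters=32, input_size=64)
        paths = {n.path for n in graph.nodes.values()}
        assert paths == {"B1", "B2"}
        for level in range(1, 5):
            assert concat_arity(graph, "B2", level) == 2

    def test_original_bridge_wiring(self):
        graph = build_wnet("original_bridge", base_filters=32, input_size=64)
        # B4 concatenates upconv + B1 + B3; B3 receives B2 at levels 2-4
        for level in range(1, 5):
            assert concat_arity(graph, "B4", level) == 3
        for level in range(2, 5):
            assert concat_arity(graph, "B3", level) == 2

    def test_modified_bridge_wiring(self):
        graph = build_wnet("modified_bridge", base_filters=32, input_size=64)
        for level in range(1, 5):
            assert concat_arity(graph, "B4", level) == 3
        # laterals are B2 and B3, not B1
        concat = next(n for n in graph.nodes.values()
                      if n.role == "concat" and n.path == "B4" and n.level == 1)
        pred_paths = [graph.nodes[p].path for p in graph.predecessors(concat.id)]
        assert pred_paths == ["B4", "B2", "B3"]

    def test_indivisible_input_rejected(self):
        with pytest.raises(ShapeError):
            build_wnet("compound", base_filters=4, input_size=100)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_wnet("bogus", base_filters=4, input_size=64)

    def test_hand_propagated_toy_shapes(self):
        # halving/doubling propagated by hand: 16 -> 8 -> 4 spatial,
        # channels 2 -> 4 -> 8 at levels 1..3
        graph = build_wnet("compound", base_filters=2, input_size=16)
        table = trace_shapes(graph)
        assert table[("B1", 3)] == TensorShape(4, 4, 8)

    def test_graph_is_acyclic_with_single_output(self):
        for variant in ALL_VARIANTS:
            graph = build_wnet(variant, base_filters=2, input_size=16)
            order = graph.topological_order()
            assert len(order) == len(graph.nodes)
            out = graph.nodes[graph.output_id]
            assert out.role == "conv1x1_out"
            assert out.out_shape.channels == 1

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    @pytest.mark.parametrize("size", [16, 32])
    def test_shape_conservation_across_paths(self, variant, size):
        graph = build_wnet(variant, base_filters=2, input_size=size, levels=4)
        table = trace_shapes(graph)
        for (path, level), shape in table.items():
            if path == "out":
                continue
            assert shape.height == shape.width == size // 2 ** (level - 1)

    def test_final_head_consumes_base_filters(self):
        graph = build_wnet("compound", base_filters=64, input_size=256)
        assert graph.nodes[graph.output_id].attrs["in_channels"] == 64

    def test_activation_policy(self):
        graph = build_wnet("compound", base_filters=2, input_size=16, levels=5)
        kinds = {
            (n.level, n.attrs["kind"])
            for n in graph.nodes.values() if n.role == "activation"
        }
        for level in (1, 2, 3):
            assert (level, "elu") in kinds and (level, "relu") not in kinds
        for level in (4, 5):
            assert (level, "relu") in kinds and (level, "elu") not in kinds


# Independent per-layer parameter oracle for the base-2, 3-level compound
# toy at 8x8: every convolution enumerated by hand as (k, cin, cout).
_COMPOUND_TOY_CONVS = [
    # B1: L1 two convs, L2 two convs, L3 bottleneck two convs
    (3, 1, 2), (3, 2, 2), (3, 2, 4), (3, 4, 4), (3, 4, 8), (3, 8, 8),
    # B2: L2 upconv + convs on concat(4 + 4 from B1), L1 likewise
    (2, 8, 4), (3, 8, 4), (3, 4, 4), (2, 4, 2), (3, 4, 2), (3, 2, 2),
    # B3: L1 on B2 output (2 ch), L2 on concat(pooled 2 + B2's 4), L3
    (3, 2, 2), (3, 2, 2), (3, 6, 4), (3, 4, 4), (3, 4, 8), (3, 8, 8),
    # B4: L2 upconv + convs on concat(4 + B1 4 + B2 4 + B3 4), L1 likewise
    (2, 8, 4), (3, 16, 4), (3, 4, 4), (2, 4, 2), (3, 8, 2), (3, 2, 2),
    # output head on 2 channels
    (1, 2, 1),
]


class TestParameterCounts:
    def test_single_conv_count(self):
        frag = contracting_block(1, TensorShape(8, 8, 1), 64, pool=False)
        conv1 = next(n for n in frag.nodes.values() if n.role == "conv3x3")
        assert conv1.params == (3 * 3 * 1 + 1) * 64  # 640

    def test_compound_toy_matches_hand_sum(self):
        expected = sum(k * k * cin * cout + cout
                       for k, cin, cout in _COMPOUND_TOY_CONVS)
        graph = build_wnet("compound", base_filters=2, input_size=8, levels=3)
        assert count_parameters(graph) == expected == 4285

    def test_unet_toy_matches_hand_sum(self):
        unet_convs = _COMPOUND_TOY_CONVS[:12] + [(1, 2, 1)]
        expected = sum(k * k * cin * cout + cout
                       for k, cin, cout in unet_convs)
        graph = build_wnet("unet", base_filters=2, input_size=8, levels=3)
        assert count_parameters(graph) == expected == 1883

    def test_monotone_in_base_filters(self):
        counts = [
            count_parameters(build_wnet("compound", bf, 64))
            for bf in (2, 4, 8, 16)
        ]
        assert counts == sorted(counts) and len(set(counts)) == 4

    def test_monotone_in_bridges(self):
        at = {
            v: count_parameters(build_wnet(v, 4, 64)) for v in ALL_VARIANTS
        }
        assert at["compound"] >= at["original_bridge"] >= at["unet"]
        assert at["compound"] > at["unet"]


class TestTraceShapes:
    def test_detects_corrupted_annotation(self):
        graph = build_wnet("unet", base_filters=2, input_size=16, levels=3)
        nid = next(n.id for n in graph.nodes.values() if n.role == "conv3x3")
        graph.nodes[nid].out_shape = TensorShape(3, 3, 3)
        with pytest.raises(ShapeError, match=nid.replace("(", "\\(")):
            trace_shapes(graph)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    base=st.integers(min_value=1, max_value=6),
    levels=st.integers(min_value=2, max_value=4),
    variant=st.sampled_from(ALL_VARIANTS),
)
def test_concat_arity_law(base, levels, variant):
    """B4 arity = 2 + active{B1->B4} + active{B2->B4}; B3 = 1 + active{B2->B3}."""
    size = 2 ** (levels + 1)
    graph = build_wnet(variant, base_filters=base, input_size=size,
                       levels=levels)
    spec = VariantSpec.resolve(variant)
    if spec.two_unet:
        expected_b4 = 2 + ("B1->B4" in spec.bridges) + ("B2->B4" in spec.bridges)
        for level in range(1, levels):
            assert concat_arity(graph, "B4", level) == expected_b4
        for level in range(2, levels):
            assert concat_arity(graph, "B3", level) == 1 + (
                "B2->B3" in spec.bridges)
    else:
        for level in range(1, levels):
            assert concat_arity(graph, "B2", level) == 2
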