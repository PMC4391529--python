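"""Treemap: hierarchy construction, layout geometry, colors, rendering."""

import re

import numpy as np
import pandas as pd
import pytest

from osmoomics import (
    ColorSpec,
    Rect,
    SimulationConfig,
    build_hierarchy,
    color_map,
    layout_treemap,
    min_leaf_aspect,
    render,
    simulate_annotation,
)


def annotation_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "main_role", "sub_role", "operon_id",
            "genome_order_index",
        ],
    )


SINGLE = annotation_frame([("g1", "Energy", "Glycolysis", "op1", 0)])

THREE_OPERON = annotation_frame(
    [
        ("g1", "Energy", "Glycolysis", "op1", 0),
        ("g2", "Energy", "Glycolysis", "op1", 1),
        ("g3", "Energy", "Glycolysis", "op1", 2),
        ("g4", "Transport", "Cations", "op2", 3),
    ]
)


class TestHierarchy:
    def test_single_gene_single_chain(self):
        root = build_hierarchy(SINGLE)
        assert root.weight == 1
        node = root
        for level in ("main_role", "sub_role", "operon", "leaf"):
            assert len(node.children) == 1
            node = node.children[0]
            assert node.level == level

    def test_operon_weight_is_member_count(self):
        root = build_hierarchy(THREE_OPERON)
        operons = [n for n in root.walk() if n.level == "operon"]
        weights = {n.label: n.weight for n in operons}
        assert weights == {"op1": 3.0, "op2": 1.0}
        assert root.weight == 4.0

    def test_duplicate_genome_index_rejected(self):
        bad = annotation_frame(
            [
                ("g1", "Energy", "x", "op1", 0),
                ("g2", "Energy", "x", "op1", 0),
            ]
        )
        with pytest.raises(ValueError):
            build_hierarchy(bad)

    def test_node_counts_match_annotation_truth(self, small_config):
        ann = simulate_annotation(small_config)
        root = build_hierarchy(ann)
        leaves = root.leaves()
        assert len(leaves) == len(ann)
        operons = [n for n in root.walk() if n.level == "operon"]
        assert len(operons) == ann.operon_id.nunique()
        mains = [n for n in root.walk() if n.level == "main_role"]
        assert len(mains) == ann.main_role.nunique()


class TestLayout:
    def test_two_equal_leaves_split_unit_square(self):
        ann = annotation_frame(
            [
                ("g1", "Energy", "x", "op1", 0),
                ("g2", "Energy", "x", "op2", 1),
            ]
        )
        root = build_hierarchy(ann)
        layout = layout_treemap(root, Rect(0, 0, 1, 1))
        areas = [layout[l].area for l in root.leaves()]
        assert areas == pytest.approx([0.5, 0.5])

    def test_area_conservation(self, small_config):
        ann = simulate_annotation(small_config)
        root = build_hierarchy(ann)
        canvas = Rect(0, 0, 640, 480)
        layout = layout_treemap(root, canvas)
        total = sum(layout[l].area for l in root.leaves())
        assert total == pytest.approx(canvas.area, rel=1e-6)

    @pytest.mark.parametrize("trial", range(10))
    def test_geometric_predicates_on_random_hierarchies(self, trial):
        cfg = SimulationConfig(seed=300 + trial,
                               n_genes=int(np.random.default_rng(trial)
                                           .integers(5, 51)))
        ann = simulate_annotation(cfg)
        root = build_hierarchy(ann)
        canvas = Rect(0, 0, 100, 80)
        layout = layout_treemap(root, canvas)

        # leaf area proportional to weight
        for leaf in root.leaves():
            expected = canvas.area * leaf.weight / root.weight
            assert layout[leaf].area == pytest.approx(expected, rel=5e-3)

        eps = 1e-9
        for node in root.walk():
            rect = layout[node]
            # children contained and mutually disjoint
            for child in node.children:
                c = layout[child]
                assert c.x >= rect.x - eps
                assert c.y >= rect.y - eps
                assert c.x + c.width <= rect.x + rect.width + eps
                assert c.y + c.height <= rect.y + rect.height + eps
            for a, b in zip(node.children, node.children[1:]):
                ra, rb = layout[a], layout[b]
                x_overlap = min(ra.x + ra.width, rb.x + rb.width) - max(
                    ra.x, rb.x
                )
                y_overlap = min(ra.y + ra.height, rb.y + rb.height) - max(
                    ra.y, rb.y
                )
                assert min(x_overlap, y_overlap) <= eps

        # genome-consecutive leaves within each operon are edge-adjacent
        for node in root.walk():
            if node.level != "operon":
                continue
            ordered = sorted(node.leaves(), key=lambda l: l.genome_order_index)
            for a, b in zip(ordered, ordered[1:]):
                ra, rb = layout[a], layout[b]
                shares_x = (
                    abs(ra.x + ra.width - rb.x) < 1e-6
                    or abs(rb.x + rb.width - ra.x) < 1e-6
                )
                shares_y = (
                    abs(ra.y + ra.height - rb.y) < 1e-6
                    or abs(rb.y + rb.height - ra.y) < 1e-6
                )
                assert shares_x or shares_y

    def test_leaf_aspect_ratio_sane(self, small_config):
        ann = simulate_annotation(small_config)
        root = build_hierarchy(ann)
        layout = layout_treemap(root, Rect(0, 0, 800, 800))
        assert min_leaf_aspect(layout) >= 0.001


class TestColorMap:
    def test_zero_maps_to_mid_grey(self):
        spec = ColorSpec()
        assert color_map(0.0, spec) == "#{:02x}{:02x}{:02x}".format(*spec.mid)

    def test_missing_maps_to_dark_grey(self):
        spec = ColorSpec()
        assert color_map(None, spec) == \
            "#{:02x}{:02x}{:02x}".format(*spec.missing)
        assert color_map(float("nan"), spec) == color_map(None, spec)

    def test_saturation_at_clip(self):
        spec = ColorSpec(clip=2.0)
        assert color_map(-2.0, spec) == \
            "#{:02x}{:02x}{:02x}".format(*spec.low)
        assert color_map(5.0, spec) == \
            "#{:02x}{:02x}{:02x}".format(*spec.high)

    def test_halfway_value_is_channelwise_midpoint(self):
        spec = ColorSpec(clip=2.0)
        got = color_map(1.0, spec)
        expected = tuple(
            int(round((a + b) / 2)) for a, b in zip(spec.mid, spec.high)
        )
        assert got == "#{:02x}{:02x}{:02x}".format(*expected)

    def test_monotone_along_value_axis(self):
        spec = ColorSpec()
        values = np.linspace(-3, 3, 25)
        channels = np.array(
            [
                [int(color_map(v, spec)[i:i + 2], 16) for i in (1, 3, 5)]
                for v in values
            ]
        )
        diffs = np.diff(channels, axis=0)
        for ch in range(3):
            col = diffs[:, ch]
            assert (col >= 0).all() or (col <= 0).all() or (
                # diverging ramps may change direction once, at zero
                (col[: len(col) // 2] >= 0).all()
                and (col[len(col) // 2:] <= 0).all()
            ) or (
                (col[: len(col) // 2] <= 0).all()
                and (col[len(col) // 2:] >= 0).all()
            )

    def test_clip_must_be_positive(self):
        with pytest.raises(ValueError):
            ColorSpec(clip=0)


class TestRender:
    def _counts(self, svg):
        return {
            cls: len(re.findall(f'class="{cls}"', svg))
            for cls in ("cell", "gene", "connector", "border")
        }

    def test_element_counts_match_counting_oracle(self, small_config):
        ann = simulate_annotation(small_config)
        root = build_hierarchy(ann)
        layout = layout_treemap(root, Rect(0, 0, 500, 500))
        svg = render(layout, root)
        counts = self._counts(svg)
        n_leaves = len(ann)
        operon_sizes = ann.groupby("operon_id").size()
        assert counts["cell"] == n_leaves
        assert counts["gene"] == n_leaves
        assert counts["connector"] == int((operon_sizes - 1).sum())
        internal = [n for n in root.walk() if n.level != "leaf"]
        assert counts["border"] == len(internal)

    def test_three_gene_operon_has_two_connectors(self):
        root = build_hierarchy(THREE_OPERON)
        layout = layout_treemap(root, Rect(0, 0, 10, 10))
        counts = self._counts(render(layout, root))
        assert counts["connector"] == 2

    def test_empty_overlay_renders_everything_dark_grey(self):
        root = build_hierarchy(THREE_OPERON)
        layout = layout_treemap(root, Rect(0, 0, 10, 10))
        spec = ColorSpec()
        svg = render(layout, root, overlay=None, spec=spec)
        dark = "#{:02x}{:02x}{:02x}".format(*spec.missing)
        for match in re.finditer(r'class="(?:cell|gene)"[^/]*fill="([^"]+)"',
                                 svg):
            assert match.group(1) == dark

    def test_overlay_colors_cells_and_circles_separately(self):
        root = build_hierarchy(SINGLE)
        layout = layout_treemap(root, Rect(0, 0, 10, 10))
        spec = ColorSpec()
        overlay = pd.DataFrame(
            {"gene_id": ["g1"], "mrna_log2": [2.0], "protein_log2": [-2.0]}
        )
        svg = render(layout, root, overlay, spec)
        cell_fill = re.search(r'class="cell"[^/]*fill="([^"]+)"', svg).group(1)
        gene_fill = re.search(r'class="gene"[^/]*fill="([^"]+)"', svg).group(1)
        assert cell_fill == "#{:02x}{:02x}{:02x}".format(*spec.low)
        assert gene_fill == "#{:02x}{:02x}{:02x}".format(*spec.high)

    def test_rendering_is_deterministic(self, small_config, tmp_path):
        ann = simulate_annotation(small_config)
        root = build_hierarchy(ann)
        layout = layout_treemap(root, Rect(0, 0, 300, 300))
        overlay = pd.DataFrame(
            {
                "gene_id": ann.gene_id,
                "mrna_log2": np.linspace(-3, 3, len(ann)),
                "protein_log2": np.linspace(3, -3, len(ann)),
            }
        )
        a = render(layout, root, overlay, path=tmp_path / "a.svg")
        b = render(layout, root, overlay, path=tmp_path / "b.svg")
        assert a == b
        assert (tmp_path / "a.svg").read_bytes() == \
            (tmp_path / "b.svg").read_bytes()

    def test_zero_weight_node_rejected(self):
        from osmoomics.treemap_viz import HierarchyNode

        root = HierarchyNode("root", "r", weight=0.0)
        with pytest.raises(ValueError):
            layout_treemap(root, Rect(0, 0, 1, 1))
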