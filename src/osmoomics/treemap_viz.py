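"""Genome-ordered hierarchical treemap of transcriptome + proteome signals.

Genes are grouped role → sub-role → operon → gene (TIGR two-level
functional categories, then predicted operons) and the 2D plane is
iteratively partitioned so that each gene is one treemap cell, with cells
of an operon kept consecutive in genome order.  Protein log2 ratios color
the cells, mRNA log2 ratios color a circle at each cell's centroid, and
connectors link the circles of genome-consecutive operon members.  Colors
run along a blue (down) – grey (no change) – orange (up) ramp saturating
at a configurable |log2| clip; genes with no assigned data are dark grey.

The partition is an ordered slice-and-dice layout: at each depth the
parent rectangle is split along one axis (alternating by level) into
strips proportional to child weights.  Cell area is therefore exactly
proportional to leaf weight, sibling cells are disjoint and tile their
parent, and leaves laid out along one axis in genome order are
edge-adjacent — the properties the rendering relies on.  Rendering is
deterministic: identical inputs give byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

LEVELS = ("root", "main_role", "sub_role", "operon", "leaf")


@dataclass(eq=False)
class HierarchyNode:
    level: str
    label: str
    children: list["HierarchyNode"] = field(default_factory=list)
    weight: float = 0.0
    genome_order_index: int | None = None

    def leaves(self) -> list["HierarchyNode"]:
        if self.level == "leaf":
            return [self]
        out: list[HierarchyNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass(frozen=True)
class Rect:
    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("Rect must have positive width and height")

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2, self.y + self.height / 2)


@dataclass
class ColorSpec:
    """Blue–grey–orange diverging ramp on the log2 scale.

    ``clip`` is the |log2 ratio| at which the ramp saturates (default 2.0,
    i.e. two-fold beyond the DE threshold); values are linearly
    interpolated channel-wise between the anchors.  Missing values map to
    a distinct dark grey.
    """

    low: tuple[int, int, int] = (0, 80, 220)  # blue, decreased expression
    mid: tuple[int, int, int] = (150, 150, 150)  # grey, no change
    high: tuple[int, int, int] = (235, 130, 0)  # orange, increased
    clip: float = 2.0
    missing: tuple[int, int, int] = (70, 70, 70)  # dark grey, no data

    def __post_init__(self) -> None:
        if self.clip <= 0:
            raise ValueError("clip must be > 0")


def build_hierarchy(annotation: pd.DataFrame) -> HierarchyNode:
    """Build the role → sub-role → operon → gene tree from an annotation.

    Each leaf is one gene with weight 1; internal weights are sums of
    their children.  Sibling order follows genome order (groups sorted by
    the smallest genome_order_index they contain, genes by their own
    index) so that consecutive genes end up in consecutive cells.
    """
    required = {"gene_id", "main_role", "sub_role", "operon_id",
                "genome_order_index"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns {sorted(missing)}")
    if annotation["genome_order_index"].duplicated().any():
        dupes = annotation.loc[
            annotation["genome_order_index"].duplicated(), "genome_order_index"
        ]
        raise ValueError(f"duplicate genome_order_index: {sorted(set(dupes))}")

    root = HierarchyNode("root", "genome")
    for main, main_df in _ordered_groups(annotation, "main_role"):
        main_node = HierarchyNode("main_role", main)
        for sub, sub_df in _ordered_groups(main_df, "sub_role"):
            sub_node = HierarchyNode("sub_role", sub)
            for operon, op_df in _ordered_groups(sub_df, "operon_id"):
                op_node = HierarchyNode("operon", operon)
                for _, gene in op_df.sort_values(
                    "genome_order_index"
                ).iterrows():
                    op_node.children.append(
                        HierarchyNode(
                            "leaf",
                            gene["gene_id"],
                            weight=1.0,
                            genome_order_index=int(
                                gene["genome_order_index"]
                            ),
                        )
                    )
                op_node.weight = sum(c.weight for c in op_node.children)
                sub_node.children.append(op_node)
            sub_node.weight = sum(c.weight for c in sub_node.children)
            main_node.children.append(sub_node)
        main_node.weight = sum(c.weight for c in main_node.children)
        root.children.append(main_node)
    root.weight = sum(c.weight for c in root.children)
    return root


def _ordered_groups(df: pd.DataFrame, column: str):
    order = (
        df.groupby(column)["genome_order_index"].min().sort_values().index
    )
    for key in order:
        yield key, df[df[column] == key]


def layout_treemap(
    tree: HierarchyNode, canvas: Rect
) -> dict[HierarchyNode, Rect]:
    """Recursive slice-and-dice partition of ``canvas`` by node weights.

    Children split their parent's rectangle along one axis, alternating
    horizontal/vertical with depth, each strip proportional to the child's
    weight; leaf area is therefore exactly weight/total of the canvas.
    """
    layout: dict[HierarchyNode, Rect] = {}

    def recurse(node: HierarchyNode, rect: Rect, depth: int) -> None:
        if node.weight <= 0:
            raise ValueError(f"zero-weight node {node.label!r} in layout")
        layout[node] = rect
        if not node.children:
            return
        horizontal = depth % 2 == 0  # split along x at even depths
        offset = 0.0
        extent = rect.width if horizontal else rect.height
        for child in node.children:
            frac = child.weight / node.weight
            span = frac * extent
            if horizontal:
                child_rect = Rect(rect.x + offset, rect.y, span, rect.height)
            else:
                child_rect = Rect(rect.x, rect.y + offset, rect.width, span)
            recurse(child, child_rect, depth + 1)
            offset += span

    recurse(tree, canvas, 0)
    return layout


def min_leaf_aspect(layout: dict[HierarchyNode, Rect]) -> float:
    """Smallest short/long side ratio over all leaf cells (layout sanity)."""
    ratios = [
        min(r.width, r.height) / max(r.width, r.height)
        for node, r in layout.items()
        if node.level == "leaf"
    ]
    return min(ratios) if ratios else 1.0


def color_map(value: float | None, spec: ColorSpec | None = None) -> str:
    """Map a log2 ratio (or missing) to a hex color on the diverging ramp.

    0 → mid grey; <= −clip → full blue; >= +clip → full orange; linear
    channel-wise interpolation in between; None/NaN → dark grey.
    """
    spec = spec or ColorSpec()
    if value is None or value != value:
        rgb = spec.missing
    else:
        t = max(-1.0, min(1.0, value / spec.clip))
        target = spec.low if t < 0 else spec.high
        frac = abs(t)
        rgb = tuple(
            int(round(m + frac * (c - m))) for m, c in zip(spec.mid, target)
        )
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def render(
    layout: dict[HierarchyNode, Rect],
    tree: HierarchyNode,
    overlay: pd.DataFrame | None = None,
    spec: ColorSpec | None = None,
    path: str | Path | None = None,
) -> str:
    """Render the treemap as SVG markup.

    ``overlay`` maps gene_id to optional mrna_log2 and protein_log2
    columns; protein values fill the cells, mRNA values the gene circles
    and connectors.  Emits, in paint order: leaf cells, operon connectors,
    gene circles, then hierarchy borders; element classes (cell,
    connector, gene, border) make the output machine-checkable.
    """
    spec = spec or ColorSpec()
    mrna: dict[str, float] = {}
    protein: dict[str, float] = {}
    if overlay is not None:
        idx = overlay.set_index("gene_id") if "gene_id" in overlay.columns \
            else overlay
        if "mrna_log2" in idx.columns:
            mrna = idx["mrna_log2"].dropna().to_dict()
        if "protein_log2" in idx.columns:
            protein = idx["protein_log2"].dropna().to_dict()

    canvas = layout[tree]
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{_f(canvas.width)}" height="{_f(canvas.height)}" '
        f'viewBox="{_f(canvas.x)} {_f(canvas.y)} '
        f'{_f(canvas.width)} {_f(canvas.height)}">'
    ]
    leaves = tree.leaves()
    for leaf in leaves:
        rect = layout[leaf]
        fill = color_map(protein.get(leaf.label), spec)
        parts.append(
            f'<rect class="cell" x="{_f(rect.x)}" y="{_f(rect.y)}" '
            f'width="{_f(rect.width)}" height="{_f(rect.height)}" '
            f'fill="{fill}"><title>{leaf.label}</title></rect>'
        )
    # connectors join genome-consecutive genes of the same operon,
    # drawn centroid-to-centroid beneath the circles
    for node in tree.walk():
        if node.level != "operon":
            continue
        ordered = sorted(
            node.leaves(), key=lambda l: l.genome_order_index
        )
        for a, b in zip(ordered, ordered[1:]):
            (x1, y1), (x2, y2) = layout[a].center, layout[b].center
            color = color_map(mrna.get(a.label), spec)
            parts.append(
                f'<line class="connector" x1="{_f(x1)}" y1="{_f(y1)}" '
                f'x2="{_f(x2)}" y2="{_f(y2)}" stroke="{color}" '
                f'stroke-width="1.5"/>'
            )
    for leaf in leaves:
        rect = layout[leaf]
        cx, cy = rect.center
        radius = 0.3 * min(rect.width, rect.height)
        fill = color_map(mrna.get(leaf.label), spec)
        parts.append(
            f'<circle class="gene" cx="{_f(cx)}" cy="{_f(cy)}" '
            f'r="{_f(radius)}" fill="{fill}" stroke="#222222" '
            f'stroke-width="0.3"/>'
        )
    # hierarchy borders: heavier strokes for shallower levels
    stroke_width = {"root": 2.0, "main_role": 1.5, "sub_role": 1.0,
                    "operon": 0.5}
    for node in tree.walk():
        if node.level == "leaf":
            continue
        rect = layout[node]
        parts.append(
            f'<rect class="border" x="{_f(rect.x)}" y="{_f(rect.y)}" '
            f'width="{_f(rect.width)}" height="{_f(rect.height)}" '
            f'fill="none" stroke="#000000" '
            f'stroke-width="{stroke_width[node.level]}"/>'
        )
    parts.append("</svg>")
    svg = "\n".join(parts)
    if path is not None:
        Path(path).write_text(svg)
    return svg


def _f(value: float) -> str:
    return f"{value:.4f}"


def read_overlay(path: str | Path) -> pd.DataFrame:
    """Overlay TSV: gene_id, mrna_log2, protein_log2 (blanks allowed)."""
    return pd.read_csv(path, sep="\t")
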