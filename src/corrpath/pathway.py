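"""Pathway-map styling: cluster projection and comparative mapping.

A metabolic map draws metabolites as nodes and reactions as edges labelled
with the gene symbols of their enzymes.  Two colouring schemes are
implemented:

* **Cluster projection** — nodes/edges take the colour of the heatmap
  cluster their entity fell in (orange for cluster A, light blue for B);
  entities absent from the analysis stay white (nodes) / grey (edges).

* **Comparative mapping** — for each entity, the Pearson correlation of
  its time course under one condition against another condition is placed
  in one of five display bins:

      strong_pos  r > 0.9        bold/big red
      pos         0.5 < r <= 0.9 red
      weak_pos    0 <= r <= 0.5  green
      neg         -0.5 <= r < 0  blue
      strong_neg  r < -0.5       bold/big blue

  The positive side is split at 0.9 and 0.5 but the negative side only at
  -0.5; this asymmetry is deliberate and preserved.  Boundary values attach
  to the weaker (inner) bin, and 0 joins weak_pos, so the bins partition
  [-1, 1] totally.  Undefined correlations (constant profiles) map to an
  "na" bin styled like absence.

Maps are rendered to SVG (own minimal serializer, deterministic output) and
GraphML (networkx) with the style attributes attached.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import GENE_AXIS, ClusterAssignment
from .correlation import DEFAULT_MIN_POINTS, common_grid, mean_profile, pearson
from .errors import InputError, LookupError_
from .io import Dataset, PathwayMap

logger = logging.getLogger(__name__)

PALETTE = {
    "orange": "#F5A623",
    "light_blue": "#9BD7E5",
    "red": "#D0021B",
    "green": "#2E9E3F",
    "blue": "#2257C4",
    "white": "#FFFFFF",
    "grey": "#BDBDBD",
}

#: base glyph geometry; "strong" bins scale these up
NODE_RADIUS = 14.0
EDGE_WIDTH = 2.0
STRONG_NODE_SCALE = 1.6
STRONG_EDGE_SCALE = 2.5

BIN_LABELS = ("strong_pos", "pos", "weak_pos", "neg", "strong_neg", "na")

#: bin -> colour word of the comparative legend (both "strong" bins share
#: their colour word with the plain bin; boldness/size carries the rest)
BIN_COLOR_WORD = {
    "strong_pos": "red",
    "pos": "red",
    "weak_pos": "green",
    "neg": "blue",
    "strong_neg": "blue",
    "na": "na",
}


def assign_bin(r: float) -> str:
    """Place a correlation value in one of the five display bins (or na).

    NaN -> ``"na"``; values outside [-1, 1] beyond float round-off are an
    input error.
    """
    if r is None or (isinstance(r, float) and math.isnan(r)) or np.isnan(r):
        return "na"
    r = float(r)
    if abs(r) > 1.0 + 1e-9:
        raise InputError(f"correlation {r} outside [-1, 1]")
    r = max(-1.0, min(1.0, r))
    if r > 0.9:
        return "strong_pos"
    if r > 0.5:
        return "pos"
    if r >= 0.0:
        return "weak_pos"
    if r >= -0.5:
        return "neg"
    return "strong_neg"


def bin_style(bin_label: str, kind: str) -> dict:
    """Fill/size (nodes) or stroke/width (edges) for a comparative bin."""
    color = {
        "strong_pos": PALETTE["red"], "pos": PALETTE["red"],
        "weak_pos": PALETTE["green"], "neg": PALETTE["blue"],
        "strong_neg": PALETTE["blue"],
        "na": PALETTE["white"] if kind == "node" else PALETTE["grey"],
    }[bin_label]
    strong = bin_label in ("strong_pos", "strong_neg")
    if kind == "node":
        return {"fill": color,
                "size": NODE_RADIUS * (STRONG_NODE_SCALE if strong else 1.0)}
    return {"stroke": color,
            "width": EDGE_WIDTH * (STRONG_EDGE_SCALE if strong else 1.0)}


@dataclass
class StyledMap:
    """A pathway map plus per-node/per-edge display styles."""

    base: PathwayMap
    node_styles: dict[str, dict] = field(default_factory=dict)
    edge_styles: dict[str, dict] = field(default_factory=dict)
    legend: str = ""

    def __post_init__(self) -> None:
        bad_n = set(self.node_styles) - set(self.base.nodes)
        bad_e = set(self.edge_styles) - set(self.base.edges)
        if bad_n or bad_e:
            raise InputError(f"styles for unknown ids: {sorted(bad_n | bad_e)}")


def _node_entity(node, known: set[str]) -> str | None:
    """Match a map node to a measured entity by display name, id or
    compound id."""
    for cand in (node.label, node.id, *node.compound_ids):
        if cand in known:
            return cand
    return None


def style_by_cluster(pmap: PathwayMap,
                     met_assign: ClusterAssignment,
                     gene_assign: ClusterAssignment) -> StyledMap:
    """Colour nodes/edges by heatmap cluster membership.

    Cluster A -> orange, cluster B -> light blue; unassigned or unmeasured
    -> white nodes / grey edges.  An edge whose gene labels fall in
    conflicting clusters is greyed with a logged conflict.
    """
    pmap.validate()
    met_labels = met_assign.labels
    gene_labels = gene_assign.labels
    cluster_color = {"A": PALETTE["orange"], "B": PALETTE["light_blue"]}

    node_styles = {}
    for nid, node in pmap.nodes.items():
        ent = _node_entity(node, set(met_labels))
        label = met_labels.get(ent) if ent else None
        node_styles[nid] = {
            "fill": cluster_color.get(label, PALETTE["white"]),
            "size": NODE_RADIUS,
        }

    edge_styles = {}
    for eid, edge in pmap.edges.items():
        found = {gene_labels[g] for g in edge.genes if g in gene_labels}
        found -= {"unassigned"}
        if len(found) == 1:
            color = cluster_color[found.pop()]
        else:
            if len(found) > 1:
                logger.warning(
                    "edge %s: genes %s span conflicting clusters; greyed",
                    eid, list(edge.genes))
            color = PALETTE["grey"]
        edge_styles[eid] = {"stroke": color, "width": EDGE_WIDTH}

    return StyledMap(base=pmap, node_styles=node_styles,
                     edge_styles=edge_styles,
                     legend="cluster projection: A=orange, B=light blue; "
                            "absent: white nodes / grey edges")


def between_condition_r(d: Dataset, entity_id: str, cond_a: str, cond_b: str,
                        min_points: int = DEFAULT_MIN_POINTS) -> float:
    """Pearson r of one entity's mean profile under two conditions, on the
    shared time grid.  NaN when either profile is constant on the grid."""
    try:
        pa = d.get(entity_id, cond_a)
        pb = d.get(entity_id, cond_b)
    except KeyError as exc:
        raise LookupError_(str(exc)) from exc
    grid = common_grid(pa, pb)
    if len(grid) < min_points:
        return float("nan")
    ma, _ = mean_profile(pa)
    mb, _ = mean_profile(pb)
    ia = [pa.times.index(t) for t in grid]
    ib = [pb.times.index(t) for t in grid]
    return pearson(ma[ia], mb[ib], min_points=min_points)


def comparative_map(pmap: PathwayMap, d: Dataset, cond_a: str, cond_b: str,
                    min_points: int = DEFAULT_MIN_POINTS,
                    ) -> tuple[StyledMap, pd.DataFrame]:
    """Style a map by between-condition correlation bins.

    Every mapped entity measured under both conditions gets a bin from
    :func:`assign_bin`; strong bins render enlarged/bold.  Unmeasured
    entities keep absence styling.  Returns the styled map and the bin
    table (``entity_id, kind, r, bin``) covering every mapped, measured
    entity.
    """
    pmap.validate()
    measured = {
        eid for eid in
        set(d.entities(condition=cond_a)) | set(d.entities("culture_metric", cond_a))
        if (eid, cond_b) in d
    }

    rows = []
    node_styles = {}
    for nid, node in pmap.nodes.items():
        ent = _node_entity(node, measured)
        if ent is None:
            node_styles[nid] = {"fill": PALETTE["white"], "size": NODE_RADIUS}
            continue
        r = between_condition_r(d, ent, cond_a, cond_b, min_points)
        b = assign_bin(r)
        node_styles[nid] = bin_style(b, "node")
        rows.append({"entity_id": ent, "kind": d.kind_of(ent),
                     "r": r, "bin": b})

    edge_styles = {}
    for eid, edge in pmap.edges.items():
        gene_rs = []
        for g in edge.genes:
            if g in measured:
                r = between_condition_r(d, g, cond_a, cond_b, min_points)
                gene_rs.append((g, r))
                rows.append({"entity_id": g, "kind": d.kind_of(g),
                             "r": r, "bin": assign_bin(r)})
        finite = [(g, r) for g, r in gene_rs if not math.isnan(r)]
        if finite:
            # multi-gene (isozyme) edges take the most extreme correlation
            _, r_ext = max(finite, key=lambda gr: (abs(gr[1]), gr[1]))
            edge_styles[eid] = bin_style(assign_bin(r_ext), "edge")
        elif gene_rs:  # measured but all NA
            edge_styles[eid] = bin_style("na", "edge")
        else:
            edge_styles[eid] = {"stroke": PALETTE["grey"], "width": EDGE_WIDTH}

    table = (pd.DataFrame(rows, columns=["entity_id", "kind", "r", "bin"])
             .drop_duplicates(subset="entity_id")
             .sort_values("entity_id").reset_index(drop=True))
    sm = StyledMap(base=pmap, node_styles=node_styles, edge_styles=edge_styles,
                   legend=f"between-condition correlation {cond_a} vs {cond_b}")
    return sm, table


def unmapped_entities(pmap: PathwayMap, d: Dataset) -> list[str]:
    """Measured entities (any condition) that no node or edge represents."""
    mapped: set[str] = set()
    for node in pmap.nodes.values():
        mapped.update((node.label, node.id, *node.compound_ids))
    for edge in pmap.edges.values():
        mapped.update(edge.genes)
    return sorted(set(d.entities()) - mapped)


def variation_table(bins_ab: pd.DataFrame, bins_ac: pd.DataFrame) -> pd.DataFrame:
    """Group entities by their colour variation between two comparisons.

    Each entity is labelled ``<colour in A/B>/<colour in A/C>`` using the
    legend colour words (red/green/blue, strong bins collapse onto their
    colour word).  Output columns: ``pattern, kind, entities`` with
    metabolite and gene sections separated, every input entity appearing
    exactly once.
    """
    a = bins_ab.set_index("entity_id")
    c = bins_ac.set_index("entity_id")
    if set(a.index) != set(c.index):
        raise InputError("bin tables cover different entity sets")
    recs = []
    for eid in a.index:
        pat = f"{BIN_COLOR_WORD[a.loc[eid, 'bin']]}/{BIN_COLOR_WORD[c.loc[eid, 'bin']]}"
        recs.append({"pattern": pat, "kind": a.loc[eid, "kind"], "entity_id": eid})
    df = pd.DataFrame(recs)
    grouped = (df.groupby(["pattern", "kind"], sort=True)["entity_id"]
               .apply(lambda s: ";".join(sorted(s))).reset_index()
               .rename(columns={"entity_id": "entities"}))
    # metabolites before genes within each pattern, like the published layout
    kind_rank = {"metabolite": 0, "gene": 1, "culture_metric": 2}
    grouped["_k"] = grouped["kind"].map(kind_rank)
    grouped = (grouped.sort_values(["pattern", "_k"]).drop(columns="_k")
               .reset_index(drop=True))
    return grouped


def export_cluster_gene_list(assign: ClusterAssignment, cluster: str,
                             out: str | Path) -> Path:
    """Write the sorted gene symbols of one gene-axis cluster, one per
    line — the format enrichment services ingest."""
    if assign.axis != GENE_AXIS:
        raise InputError("gene list export requires a gene-axis assignment")
    if cluster not in {"A", "B", "unassigned"}:
        raise InputError(f"unknown cluster label {cluster!r}")
    genes = assign.members(cluster)
    out = Path(out)
    out.write_text("".join(f"{g}\n" for g in genes))
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _layout(pmap: PathwayMap, seed: int) -> dict[str, tuple[float, float]]:
    if pmap.has_layout():
        return {nid: (float(n.x), float(n.y)) for nid, n in pmap.nodes.items()}
    g = nx.Graph()
    g.add_nodes_from(sorted(pmap.nodes))
    g.add_edges_from((e.source, e.target) for e in pmap.edges.values())
    pos = nx.spring_layout(g, seed=seed)
    return {nid: (60 + 400 * (xy[0] + 1) / 2, 60 + 400 * (xy[1] + 1) / 2)
            for nid, xy in pos.items()}


def render_map(sm: StyledMap, out_svg: str | Path,
               out_graphml: str | Path | None = None,
               seed: int = 0) -> Path:
    """Render a styled map as SVG 1.1 (and optionally GraphML).

    Node coordinates come from the map layout when present, otherwise from
    a seeded force-directed layout, so repeated renders are byte-identical.
    The SVG carries no timestamps.
    """
    pos = _layout(sm.base, seed)
    xs = [p[0] for p in pos.values()] or [0]
    ys = [p[1] for p in pos.values()] or [0]
    pad = NODE_RADIUS * STRONG_NODE_SCALE + 30
    w, h = max(xs) + pad, max(ys) + pad

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{w:.0f}" height="{h:.0f}">',
        f'<desc>{sm.legend}</desc>',
    ]
    for eid in sorted(sm.base.edges):
        e = sm.base.edges[eid]
        st = sm.edge_styles.get(eid, {"stroke": PALETTE["grey"], "width": EDGE_WIDTH})
        (x1, y1), (x2, y2) = pos[e.source], pos[e.target]
        title = ",".join(e.genes) or eid
        parts.append(
            f'<line id="edge-{eid}" x1="{x1:.1f}" y1="{y1:.1f}" '
            f'x2="{x2:.1f}" y2="{y2:.1f}" stroke="{st["stroke"]}" '
            f'stroke-width="{st["width"]:.2f}"><title>{title}</title></line>'
        )
        if e.genes:
            mx, my = (x1 + x2) / 2, (y1 + y2) / 2
            parts.append(
                f'<text x="{mx:.1f}" y="{my - 4:.1f}" font-size="9" '
                f'fill="#555555" text-anchor="middle">{",".join(e.genes)}</text>'
            )
    for nid in sorted(sm.base.nodes):
        n = sm.base.nodes[nid]
        st = sm.node_styles.get(nid, {"fill": PALETTE["white"], "size": NODE_RADIUS})
        x, y = pos[nid]
        parts.append(
            f'<circle id="node-{nid}" cx="{x:.1f}" cy="{y:.1f}" '
            f'r="{st["size"]:.2f}" fill="{st["fill"]}" stroke="#333333" '
            f'stroke-width="1"/>'
        )
        parts.append(
            f'<text x="{x:.1f}" y="{y + st["size"] + 11:.1f}" font-size="10" '
            f'text-anchor="middle">{n.display_name}</text>'
        )
    parts.append("</svg>")
    out_svg = Path(out_svg)
    out_svg.parent.mkdir(parents=True, exist_ok=True)
    out_svg.write_text("\n".join(parts) + "\n")

    if out_graphml is not None:
        write_graphml(sm, out_graphml)
    return out_svg


def to_networkx(sm: StyledMap) -> nx.DiGraph:
    """Styled map as a directed graph with style data attributes."""
    g = nx.DiGraph(name=sm.base.name, legend=sm.legend)
    for nid in sorted(sm.base.nodes):
        n = sm.base.nodes[nid]
        st = sm.node_styles.get(nid, {"fill": PALETTE["white"], "size": NODE_RADIUS})
        g.add_node(nid, label=n.display_name, fill=st["fill"],
                   size=float(st["size"]),
                   compound_ids=";".join(n.compound_ids))
    for eid in sorted(sm.base.edges):
        e = sm.base.edges[eid]
        st = sm.edge_styles.get(eid, {"stroke": PALETTE["grey"], "width": EDGE_WIDTH})
        g.add_edge(e.source, e.target, id=eid, genes=";".join(e.genes),
                   stroke=st["stroke"], width=float(st["width"]),
                   reversible=e.reversible)
    return g


def write_graphml(sm: StyledMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(to_networkx(sm), path)
    return path
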