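"""Core data model and file I/O.

The pipeline consumes three kinds of time-course measurements from batch
cell culture — intracellular metabolite concentrations (µM), gene expression
(FPKM) and culture metrics (cell counts, extracellular glucose/lactate in
mM) — under one or more culture conditions.  Profiles are stored replicate-
resolved on each entity's own day grid; metabolite/culture profiles and gene
profiles typically live on different grids (e.g. days 0–5 vs days 0–3) and
are never silently interpolated.

Profiles are read from / written to tidy long-format CSV (one row per
replicate measurement).  Pathway maps — metabolites as nodes, reactions as
gene-labelled edges — come from a small JSON schema or, best-effort, from
KGML (KEGG pathway XML).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from lxml import etree

from .errors import IntegrityError, MapValidationError, ParseError, SchemaError

ENTITY_KINDS = ("metabolite", "gene", "culture_metric")

#: canonical column -> default header name in profile CSV files
DEFAULT_SCHEMA: dict[str, str] = {
    "entity_id": "entity_id",
    "entity_kind": "entity_type",
    "condition": "condition",
    "time": "time_day",
    "replicate": "replicate",
    "value": "value",
    "units": "units",
}


@dataclass(frozen=True)
class TimeSeriesProfile:
    """One entity's replicate-resolved time course under one condition.

    Parameters
    ----------
    entity_id:
        Short name, e.g. ``"PYR"`` (metabolite), ``"Ldha"`` (gene) or
        ``"cell_number"`` (culture metric).
    entity_kind:
        One of ``metabolite``, ``gene``, ``culture_metric``.
    condition:
        Culture-condition label, e.g. ``"0mM"``.
    times:
        Strictly increasing day indices.
    replicates:
        Per-time tuples of >= 1 finite measurement values.
    units:
        Measurement unit, e.g. ``"uM"``, ``"FPKM"``, ``"mM"``, ``"cells"``.
    """

    entity_id: str
    entity_kind: str
    condition: str
    times: tuple[float, ...]
    replicates: tuple[tuple[float, ...], ...]
    units: str = ""

    def __post_init__(self) -> None:
        if self.entity_kind not in ENTITY_KINDS:
            raise IntegrityError(
                f"unknown entity_kind {self.entity_kind!r} for {self.entity_id!r}"
            )
        if len(self.times) != len(self.replicates):
            raise IntegrityError(
                f"{self.entity_id!r}: {len(self.times)} times but "
                f"{len(self.replicates)} replicate groups"
            )
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise IntegrityError(f"{self.entity_id!r}: times not strictly increasing")
        for t, reps in zip(self.times, self.replicates):
            if len(reps) < 1:
                raise IntegrityError(f"{self.entity_id!r}: no replicate at day {t}")
            if not all(math.isfinite(v) for v in reps):
                raise IntegrityError(f"{self.entity_id!r}: non-finite value at day {t}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.entity_id, self.condition)


def mean_profile(p: TimeSeriesProfile) -> tuple[np.ndarray, np.ndarray]:
    """Per-time replicate mean and SD of a profile.

    SD is the population standard deviation (ddof=0), so a single replicate
    yields SD 0 rather than NaN.
    """
    means = np.array([float(np.mean(r)) for r in p.replicates])
    sds = np.array([float(np.std(r)) for r in p.replicates])
    return means, sds


class Dataset:
    """Collection of :class:`TimeSeriesProfile` keyed by (entity_id, condition).

    Enforces key uniqueness and that all profiles of an entity share the
    same kind and units.
    """

    def __init__(self, profiles: Iterable[TimeSeriesProfile] = (),
                 metadata: Mapping[str, str] | None = None):
        self._profiles: dict[tuple[str, str], TimeSeriesProfile] = {}
        self.metadata: dict[str, str] = dict(metadata or {})
        for p in profiles:
            self.add(p)

    def add(self, p: TimeSeriesProfile) -> None:
        if p.key in self._profiles:
            raise IntegrityError(
                f"duplicate profile for entity {p.entity_id!r} under "
                f"condition {p.condition!r}"
            )
        for other in self._profiles.values():
            if other.entity_id == p.entity_id:
                if other.entity_kind != p.entity_kind or other.units != p.units:
                    raise IntegrityError(
                        f"entity {p.entity_id!r} has inconsistent kind/units "
                        f"across conditions"
                    )
                break
        self._profiles[p.key] = p

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self) -> Iterator[TimeSeriesProfile]:
        return iter(self._profiles.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return tuple(key) in self._profiles

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self._profiles == other._profiles

    def get(self, entity_id: str, condition: str) -> TimeSeriesProfile:
        try:
            return self._profiles[(entity_id, condition)]
        except KeyError:
            raise KeyError(
                f"no profile for entity {entity_id!r} under condition {condition!r}"
            ) from None

    def conditions(self) -> list[str]:
        return sorted({p.condition for p in self})

    def entities(self, kind: str | None = None,
                 condition: str | None = None) -> list[str]:
        """Sorted entity ids, optionally restricted by kind and condition."""
        out = {
            p.entity_id
            for p in self
            if (kind is None or p.entity_kind == kind)
            and (condition is None or p.condition == condition)
        }
        return sorted(out)

    def kind_of(self, entity_id: str) -> str:
        for p in self:
            if p.entity_id == entity_id:
                return p.entity_kind
        raise KeyError(f"unknown entity {entity_id!r}")


# ---------------------------------------------------------------------------
# profile CSV I/O
# ---------------------------------------------------------------------------

def read_profiles(path: str | Path,
                  schema: Mapping[str, str] | None = None) -> Dataset:
    """Read a tidy long-format profile table into a :class:`Dataset`.

    ``schema`` maps canonical column roles (``entity_id``, ``entity_kind``,
    ``condition``, ``time``, ``replicate``, ``value``, ``units``) to the
    header names actually present; defaults to :data:`DEFAULT_SCHEMA`.
    Tab-separated files are recognised by a ``.tsv`` suffix.
    """
    path = Path(path)
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    for role, name in cols.items():
        if name not in df.columns:
            raise SchemaError(
                f"{path.name}: missing column {name!r} (role {role!r})"
            )

    def numeric(role: str) -> pd.Series:
        # Python's float() parses exactly (pandas' fast parser can be off
        # by 1 ulp, breaking exact round trips)
        out = np.empty(len(df))
        for i, cell in enumerate(df[cols[role]]):
            try:
                v = float(cell)
            except (TypeError, ValueError):
                v = math.nan
            if math.isnan(v):
                # +2: header line and 1-based numbering
                raise ParseError(
                    f"{path.name}: non-numeric {role!r} value {cell!r} "
                    f"at row {i + 2}"
                )
            out[i] = v
        return pd.Series(out, index=df.index)

    values = numeric("value")
    times = numeric("time")

    keys = list(zip(df[cols["entity_id"]], df[cols["condition"]],
                    times, df[cols["replicate"]]))
    seen: set = set()
    for i, k in enumerate(keys):
        if k in seen:
            raise IntegrityError(
                f"{path.name}: duplicate measurement for entity {k[0]!r}, "
                f"condition {k[1]!r}, day {k[2]}, replicate {k[3]!r} "
                f"(row {i + 2})"
            )
        seen.add(k)

    work = pd.DataFrame({
        "entity_id": df[cols["entity_id"]],
        "entity_kind": df[cols["entity_kind"]],
        "condition": df[cols["condition"]],
        "time": times,
        "replicate": df[cols["replicate"]],
        "value": values,
        "units": df[cols["units"]],
    })

    ds = Dataset(metadata={"source": str(path)})
    for (eid, cond), grp in work.groupby(["entity_id", "condition"], sort=True):
        kinds = grp["entity_kind"].unique()
        units = grp["units"].unique()
        if len(kinds) > 1 or len(units) > 1:
            raise IntegrityError(
                f"{path.name}: entity {eid!r} condition {cond!r} mixes "
                f"kinds/units {list(kinds)}/{list(units)}"
            )
        ts: list[float] = []
        reps: list[tuple[float, ...]] = []
        for t, sub in grp.sort_values(["time", "replicate"]).groupby("time", sort=True):
            ts.append(float(t))
            reps.append(tuple(float(v) for v in sub["value"]))
        ds.add(TimeSeriesProfile(
            entity_id=str(eid), entity_kind=str(kinds[0]), condition=str(cond),
            times=tuple(ts), replicates=tuple(reps), units=str(units[0]),
        ))
    return ds


def write_dataset(d: Dataset, path: str | Path,
                  schema: Mapping[str, str] | None = None) -> Path:
    """Write a :class:`Dataset` as tidy long CSV; round-trips with
    :func:`read_profiles` (floats serialised with `repr`, hence exactly)."""
    path = Path(path)
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    rows = []
    for p in sorted(d, key=lambda p: p.key):
        for t, reps in zip(p.times, p.replicates):
            for j, v in enumerate(reps, start=1):
                rows.append({
                    cols["entity_id"]: p.entity_id,
                    cols["entity_kind"]: p.entity_kind,
                    cols["condition"]: p.condition,
                    cols["time"]: repr(float(t)),
                    cols["replicate"]: j,
                    cols["value"]: repr(float(v)),
                    cols["units"]: p.units,
                })
    header = [cols[k] for k in ("entity_id", "entity_kind", "condition",
                                "time", "replicate", "value", "units")]
    pd.DataFrame(rows, columns=header).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# pathway maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayNode:
    id: str
    compound_ids: tuple[str, ...] = ()
    label: str = ""
    x: float | None = None
    y: float | None = None

    @property
    def display_name(self) -> str:
        return self.label or self.id


@dataclass(frozen=True)
class PathwayEdge:
    id: str
    source: str
    target: str
    genes: tuple[str, ...] = ()
    reversible: bool = False


@dataclass
class PathwayMap:
    """Metabolic pathway map: metabolites are nodes, reactions are edges
    labelled with the gene symbols of their enzymes."""

    name: str = ""
    nodes: dict[str, PathwayNode] = field(default_factory=dict)
    edges: dict[str, PathwayEdge] = field(default_factory=dict)

    def validate(self) -> "PathwayMap":
        dangling = [
            e.id for e in self.edges.values()
            if e.source not in self.nodes or e.target not in self.nodes
        ]
        if dangling:
            raise MapValidationError(
                f"edges with endpoints missing from node set: {sorted(dangling)}"
            )
        return self

    def has_layout(self) -> bool:
        return all(n.x is not None and n.y is not None for n in self.nodes.values())


def _map_from_json(data: dict) -> PathwayMap:
    pmap = PathwayMap(name=data.get("name", ""))
    for n in data.get("nodes", []):
        node = PathwayNode(
            id=str(n["id"]),
            compound_ids=tuple(n.get("compound_ids", [])),
            label=str(n.get("label", "")),
            x=n.get("x"), y=n.get("y"),
        )
        if node.id in pmap.nodes:
            raise MapValidationError(f"duplicate node id {node.id!r}")
        pmap.nodes[node.id] = node
    for e in data.get("edges", []):
        edge = PathwayEdge(
            id=str(e["id"]), source=str(e["source"]), target=str(e["target"]),
            genes=tuple(e.get("genes", [])),
            reversible=bool(e.get("reversible", False)),
        )
        if edge.id in pmap.edges:
            raise MapValidationError(f"duplicate edge id {edge.id!r}")
        pmap.edges[edge.id] = edge
    return pmap.validate()


def _map_from_kgml(path: Path) -> PathwayMap:
    """Best-effort KGML import: compound entries become nodes; reactions
    become edges between their substrates and products, labelled with the
    gene symbols of the gene entries pointing at each reaction."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    pmap = PathwayMap(name=root.get("title") or root.get("name") or path.stem)

    by_kgml_name: dict[str, str] = {}  # e.g. "cpd:C00022" -> node id
    for entry in root.findall("entry"):
        if entry.get("type") != "compound":
            continue
        gfx = entry.find("graphics")
        names = tuple(entry.get("name", "").split())
        label = (gfx.get("name") or "").split(",")[0].strip() if gfx is not None else ""
        node = PathwayNode(
            id=entry.get("id"),
            compound_ids=names,
            label=label,
            x=float(gfx.get("x")) if gfx is not None and gfx.get("x") else None,
            y=float(gfx.get("y")) if gfx is not None and gfx.get("y") else None,
        )
        pmap.nodes[node.id] = node
        for nm in names:
            by_kgml_name[nm] = node.id

    genes_by_reaction: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        if entry.get("type") != "gene" or not entry.get("reaction"):
            continue
        gfx = entry.find("graphics")
        label = (gfx.get("name") or "").split(",")[0].strip() if gfx is not None else ""
        symbols = [label] if label else entry.get("name", "").split()
        for rxn in entry.get("reaction", "").split():
            genes_by_reaction.setdefault(rxn, []).extend(symbols)

    for i, rxn in enumerate(root.findall("reaction")):
        rxn_name = rxn.get("name", "")
        genes = tuple(genes_by_reaction.get(rxn_name, []))
        reversible = rxn.get("type") == "reversible"
        subs = [s.get("id") for s in rxn.findall("substrate")]
        prods = [p.get("id") for p in rxn.findall("product")]
        for s in subs:
            for p in prods:
                if s in pmap.nodes and p in pmap.nodes:
                    eid = f"{rxn_name or 'rxn'}:{s}->{p}"
                    pmap.edges[eid] = PathwayEdge(
                        id=eid, source=s, target=p,
                        genes=genes, reversible=reversible,
                    )
    return pmap.validate()


def load_pathway_map(path: str | Path, format: str | None = None) -> PathwayMap:
    """Load a pathway map from JSON (native schema) or KGML.

    ``format`` is ``"json"`` or ``"kgml"``; when None it is inferred from
    the file suffix (``.xml``/``.kgml`` -> KGML).
    """
    path = Path(path)
    if format is None:
        format = "kgml" if path.suffix.lower() in (".xml", ".kgml") else "json"
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path.name}: malformed JSON: {exc}") from exc
        return _map_from_json(data)
    if format == "kgml":
        try:
            return _map_from_kgml(path)
        except etree.XMLSyntaxError as exc:
            raise ParseError(f"{path.name}: malformed XML: {exc}") from exc
    raise SchemaError(f"unknown pathway map format {format!r}")


def save_pathway_map(pmap: PathwayMap, path: str | Path) -> Path:
    """Write a map in the native JSON schema (round-trips with
    :func:`load_pathway_map`)."""
    path = Path(path)
    data = {
        "name": pmap.name,
        "nodes": [
            {"id": n.id, "compound_ids": list(n.compound_ids), "label": n.label,
             "x": n.x, "y": n.y}
            for n in sorted(pmap.nodes.values(), key=lambda n: n.id)
        ],
        "edges": [
            {"id": e.id, "source": e.source, "target": e.target,
             "genes": list(e.genes), "reversible": e.reversible}
            for e in sorted(pmap.edges.values(), key=lambda e: e.id)
        ],
    }
    path.write_text(json.dumps(data, indent=1, sort_keys=True))
    return path
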