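
import pytest

from corrpath.io import Dataset, PathwayMap, TimeSeriesProfile


def make_profile(eid, kind="metabolite", cond="0mM", times=(0, 1, 2),
                 reps=((1.0,), (2.0,), (3.0,)), units="uM"):
    """Build a profile; scalar entries in ``reps`` are wrapped as
    single-replicate tuples."""
    wrapped = tuple(
        tuple(r) if isinstance(r, (tuple, list)) else (float(r),) for r in reps
    )
    return TimeSeriesProfile(entity_id=eid, entity_kind=kind, condition=cond,
                             times=tuple(float(t) for t in times),
                             replicates=wrapped, units=units)


@pytest.fixture
def toy_map():
    """5-node linear pathway with gene-labelled edges, fixed layout."""
    pmap = PathwayMap(name="toy")
    from corrpath.io import PathwayEdge, PathwayNode
    names = ["GLC", "G6P", "PYR", "LAC", "CIT"]
    for i, n in enumerate(names):
        pmap.nodes[n] = PathwayNode(id=n, label=n, compound_ids=(f"C{i:05d}",),
                                    x=50.0 + 80 * i, y=100.0)
    edges = [("e1", "GLC", "G6P", ("Hk1",)), ("e2", "G6P", "PYR", ("Pkm",)),
             ("e3", "PYR", "LAC", ("Ldha",)), ("e4", "PYR", "CIT", ("Cs",))]
    for eid, s, t, genes in edges:
        pmap.edges[eid] = PathwayEdge(id=eid, source=s, target=t, genes=genes)
    return pmap.validate()


@pytest.fixture
def toy_map_json(tmp_path, toy_map):
    from corrpath.io import save_pathway_map
    path = tmp_path / "toy_map.json"
    save_pathway_map(toy_map, path)
    return path


@pytest.fixture
def two_condition_dataset():
    """Three metabolites + one gene + one culture metric under two
    conditions; the second condition negates M2's trend."""
    ds = Dataset()
    for cond in ("0mM", "5mM"):
        ds.add(make_profile("M1", times=range(6), reps=[1, 2, 3, 4, 5, 6],
                            cond=cond))
        m2 = [6, 5, 4, 3, 2, 1] if cond == "5mM" else [1, 2, 3, 4, 5, 6]
        ds.add(make_profile("M2", times=range(6), reps=m2, cond=cond))
        ds.add(make_profile("M3", times=range(6), reps=[2, 2, 2, 2, 2, 2],
                            cond=cond))
        ds.add(make_profile("Ldha", kind="gene", times=range(4),
                            reps=[1, 3, 2, 5], units="FPKM", cond=cond))
        ds.add(make_profile("cell_number", kind="culture_metric",
                            times=range(6), reps=[1, 4, 9, 7, 3, 1],
                            units="cells", cond=cond))
    return ds


def pearson_oracle(x, y):
    """Definitional double-sum Pearson r in pure Python (independent of the
    package's vectorised implementation)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x)
    dy = sum((b - my) ** 2 for b in y)
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy) ** 0.5


MINIMAL_KGML = """<?xml version="1.0"?>
<pathway name="path:toy00010" org="toy" number="00010" title="Toy glycolysis">
  <entry id="11" name="cpd:C00022" type="compound">
    <graphics name="PYR" x="100" y="200" type="circle"/>
  </entry>
  <entry id="12" name="cpd:C00186" type="compound">
    <graphics name="LAC" x="180" y="200" type="circle"/>
  </entry>
  <entry id="21" name="toy:Ldha" type="gene" reaction="rn:R00703">
    <graphics name="Ldha" x="140" y="180" type="rectangle"/>
  </entry>
  <reaction id="31" name="rn:R00703" type="reversible">
    <substrate id="11" name="cpd:C00022"/>
    <product id="12" name="cpd:C00186"/>
  </reaction>
</pathway>
"""


@pytest.fixture
def kgml_file(tmp_path):
    path = tmp_path / "toy.xml"
    path.write_text(MINIMAL_KGML)
    return path
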