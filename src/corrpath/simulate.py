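"""Synthetic time-course generator with planted structure.

Emulates the statistical design of a lactate-dose CHO batch-culture study:
metabolites and culture metrics measured daily on days 0-5, gene expression
on days 0-3, three replicates, and a control plus perturbed conditions
(e.g. 0/5/10 mM lactate added to the medium).  The generator plants

* a temporal pattern class per entity (via its block's base shape),
* block-correlated entity groups: entities in one block share a base shape
  up to a per-entity amplitude, so their pairwise Pearson r is 1 before
  noise, while distinct block shapes are required to satisfy |r| <= 0.1 on
  every configured grid (the logistic ramp and the symmetric bump are
  exactly orthogonal on symmetric day grids),
* dose effects: each non-control condition blends affected entities'
  shapes toward an alternative shape with weight = perturbation_strength,
  so the between-condition correlation against control decreases
  monotonically with dose,

and writes the matching ground truth so every downstream stage can be
scored (pattern accuracy, cluster recovery ARI, comparative-bin agreement).

Replicate noise is multiplicative log-normal with mean 1 and relative SD
``noise_cv`` — concentrations and FPKM are positive, scale-proportional
quantities.  Everything is reproducible from the config seed.

The culture-metric triple (cell_number rise-then-fall, extracellular
glucose decrease, extracellular lactate increase) is generated alongside
the omics blocks but outside the block system: its monotone-decrease shape
would be perfectly anti-correlated with an increase block and so cannot
satisfy the cross-block orthogonality bound.  Ground truth records its
pattern classes but no block id, and cluster scoring covers omics blocks
only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .correlation import pearson
from .errors import InputError
from .io import Dataset, TimeSeriesProfile
from .pathway import assign_bin

SHAPE_KINDS = ("increase", "decrease", "variable", "constant")

#: amplitude range (log-uniform) for per-entity scaling
AMPLITUDE_RANGE = (10.0, 1000.0)

#: blend-target shape per base shape for dose perturbations; chosen so the
#: target is orthogonal to the base on symmetric grids
_ALT_SHAPE = {"increase": "variable", "decrease": "variable",
              "variable": "increase", "constant": "variable"}


def base_shape(kind: str, grid: Sequence[float]) -> np.ndarray:
    """Unit-amplitude temporal template on a day grid.

    increase: logistic ramp 0.1 -> 1.0; decrease: its mirror; variable:
    symmetric single-peak bump (rises to mid-course, returns to the start
    level); constant: all ones.
    """
    g = np.asarray(grid, dtype=float)
    if g.size < 3:
        raise InputError("grid must have >= 3 points")
    if kind == "constant":
        return np.ones_like(g)
    c = (g[0] + g[-1]) / 2.0
    span = (g[-1] - g[0]) / 2.0
    if kind in ("increase", "decrease"):
        raw = 1.0 / (1.0 + np.exp(-4.0 * (g - c) / span))
        raw = (raw - raw.min()) / (raw.max() - raw.min())
        shape = 0.1 + 0.9 * raw
        return shape if kind == "increase" else shape[::-1].copy()
    if kind == "variable":
        return 1.0 + np.exp(-((g - c) / (0.5 * span)) ** 2)
    raise InputError(f"unknown shape kind {kind!r}")


@dataclass
class Block:
    block_id: str
    members: list[str]
    base_shape: str


@dataclass
class Condition:
    label: str
    perturbation_strength: float = 0.0
    affected_entities: list[str] | None = None  # None -> all block entities


@dataclass
class SyntheticConfig:
    """Study design of a synthetic dataset.

    Defaults mirror the emulated experiment: 34 metabolites and 40 genes in
    two orthogonal-shape blocks, days 0-5 (metabolites/culture) vs 0-3
    (genes), triplicates, 5% replicate noise, and a control plus two dose
    conditions of increasing perturbation.
    """

    n_metabolites: int = 34
    n_genes: int = 40
    met_times: tuple[float, ...] = (0, 1, 2, 3, 4, 5)
    gene_times: tuple[float, ...] = (0, 1, 2, 3)
    n_replicates: int = 3
    noise_cv: float = 0.05
    blocks: list[Block] | None = None
    conditions: list[Condition] = field(default_factory=lambda: [
        Condition("0mM", 0.0),
        Condition("5mM", 0.3),
        Condition("10mM", 0.7),
    ])
    include_culture: bool = True
    seed: int = 0

    def entity_names(self) -> tuple[list[str], list[str]]:
        mets = [f"M{i:03d}" for i in range(self.n_metabolites)]
        genes = [f"G{i:03d}" for i in range(self.n_genes)]
        return mets, genes

    def resolved_blocks(self) -> list[Block]:
        """Default: two blocks (ramp / bump) interleaving metabolites and
        genes so both axes carry both blocks."""
        if self.blocks is not None:
            return self.blocks
        mets, genes = self.entity_names()
        b1 = [e for i, e in enumerate(mets) if i % 2 == 0] + \
             [e for i, e in enumerate(genes) if i % 2 == 0]
        b2 = [e for i, e in enumerate(mets) if i % 2 == 1] + \
             [e for i, e in enumerate(genes) if i % 2 == 1]
        return [Block("block1", b1, "increase"), Block("block2", b2, "variable")]


#: culture metrics: (shape, amplitude, units); shapes echo typical batch
#: culture: biomass rises then falls, glucose is consumed, lactate accumulates
CULTURE_METRICS = {
    "cell_number": ("variable", 1.0e6, "cells"),
    "glucose_ext": ("decrease", 20.0, "mM"),
    "lactate_ext": ("increase", 10.0, "mM"),
}


@dataclass
class GroundTruth:
    """Planted structure: per-entity pattern class, block id (None for
    culture metrics), and expected comparative bin vs control per
    condition at zero noise."""

    pattern: dict[str, str]
    block: dict[str, str | None]
    expected_bin: dict[str, dict[str, str]]  # condition -> entity -> bin

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "pattern": self.pattern,
            "block": self.block,
            "expected_bin": self.expected_bin,
        }, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(pattern=data["pattern"], block=data["block"],
                   expected_bin=data["expected_bin"])


def _check_block_orthogonality(blocks: list[Block],
                               grids: list[tuple[float, ...]]) -> None:
    shapes = {b.base_shape for b in blocks}
    for grid in grids:
        tmpl = {s: base_shape(s, grid) for s in shapes}
        for i, a in enumerate(sorted(shapes)):
            for b in sorted(shapes)[i + 1:]:
                if "constant" in (a, b):
                    continue  # zero variance: correlation undefined, no leak
                r = pearson(tmpl[a], tmpl[b])
                if abs(r) > 0.1:
                    raise InputError(
                        f"block shapes {a!r} and {b!r} have |r|={abs(r):.3f} "
                        f"> 0.1 on grid {list(grid)}; choose a different "
                        f"shape pairing (e.g. pair 'increase' or 'decrease' "
                        f"with 'variable', not with each other)"
                    )


def generate(cfg: SyntheticConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a dataset plus its ground truth from a study design."""
    rng = np.random.default_rng(cfg.seed)
    mets, genes = cfg.entity_names()
    blocks = cfg.resolved_blocks()
    grids = [tuple(cfg.met_times), tuple(cfg.gene_times)]
    _check_block_orthogonality(blocks, grids)

    block_of = {}
    for b in blocks:
        for e in b.members:
            if e in block_of:
                raise InputError(f"entity {e!r} in more than one block")
            block_of[e] = b
    missing = (set(mets) | set(genes)) - set(block_of)
    if missing:
        raise InputError(f"entities not covered by any block: {sorted(missing)}")

    kind_of = {**{m: "metabolite" for m in mets}, **{g: "gene" for g in genes}}
    units_of = {**{m: "uM" for m in mets}, **{g: "FPKM" for g in genes}}
    grid_of = {**{m: tuple(float(t) for t in cfg.met_times) for m in mets},
               **{g: tuple(float(t) for t in cfg.gene_times) for g in genes}}
    shape_of = {e: block_of[e].base_shape for e in block_of}

    entities = mets + genes
    if cfg.include_culture:
        for name, (shape, amp, unit) in CULTURE_METRICS.items():
            entities.append(name)
            kind_of[name] = "culture_metric"
            units_of[name] = unit
            grid_of[name] = tuple(float(t) for t in cfg.met_times)
            shape_of[name] = shape

    amplitude = {}
    for e in entities:
        if kind_of[e] == "culture_metric":
            amplitude[e] = CULTURE_METRICS[e][1]
        else:
            lo, hi = np.log10(AMPLITUDE_RANGE)
            amplitude[e] = float(10 ** rng.uniform(lo, hi))

    # noise sigma so that multiplicative factors have mean 1, SD noise_cv
    if cfg.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(cfg.noise_cv ** 2)))
    else:
        sigma = 0.0

    ds = Dataset(metadata={"generator": "corrpath.simulate",
                           "seed": str(cfg.seed)})
    truth_pattern: dict[str, str] = {}
    truth_block: dict[str, str | None] = {}
    expected_bin: dict[str, dict[str, str]] = {}

    clean_control: dict[str, np.ndarray] = {}
    for e in entities:
        grid = grid_of[e]
        clean_control[e] = amplitude[e] * base_shape(shape_of[e], grid)
        truth_pattern[e] = shape_of[e] if shape_of[e] != "constant" else "constant"
        truth_block[e] = (block_of[e].block_id
                          if kind_of[e] != "culture_metric" else None)

    for cond in cfg.conditions:
        p = float(cond.perturbation_strength)
        if not 0.0 <= p <= 1.0:
            raise InputError("perturbation_strength must be in [0, 1]")
        affected = (set(cond.affected_entities)
                    if cond.affected_entities is not None
                    else set(block_of))
        expected_bin[cond.label] = {}
        for e in entities:
            grid = grid_of[e]
            if p > 0 and e in affected and kind_of[e] != "culture_metric":
                alt = base_shape(_ALT_SHAPE[shape_of[e]], grid)
                unit = (1 - p) * base_shape(shape_of[e], grid) + p * alt
                clean = amplitude[e] * unit
            else:
                clean = clean_control[e]
            r0 = (pearson(clean_control[e], clean)
                  if np.std(clean) > 0 and np.std(clean_control[e]) > 0
                  else float("nan"))
            expected_bin[cond.label][e] = assign_bin(r0)

            reps = []
            for v in clean:
                if sigma > 0:
                    factors = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                                            size=cfg.n_replicates)
                else:
                    factors = np.ones(cfg.n_replicates)
                reps.append(tuple(float(v * f) for f in factors))
            ds.add(TimeSeriesProfile(
                entity_id=e, entity_kind=kind_of[e], condition=cond.label,
                times=grid, replicates=tuple(reps), units=units_of[e],
            ))

    gt = GroundTruth(pattern=truth_pattern, block=truth_block,
                     expected_bin=expected_bin)
    return ds, gt


# ---------------------------------------------------------------------------
# scoring against ground truth
# ---------------------------------------------------------------------------

@dataclass
class TruthScore:
    pattern_accuracy: float | None = None
    cluster_ari: float | None = None
    bin_agreement: float | None = None


def truth_check(gt: GroundTruth,
                pattern_table: pd.DataFrame | None = None,
                condition: str | None = None,
                cluster_labels: dict[str, str] | None = None,
                bin_table: pd.DataFrame | None = None) -> TruthScore:
    """Score recovered structure against the planted truth.

    pattern_table: ``classify_dataset`` output restricted via ``condition``
    (default: the table's only condition).  cluster_labels: entity ->
    cluster name; ARI is computed over entities with a planted block.
    bin_table: ``comparative_map`` output; requires ``condition`` naming
    the non-control condition being compared.
    """
    score = TruthScore()

    if pattern_table is not None:
        tbl = pattern_table
        if condition is not None:
            tbl = tbl[tbl["condition"] == condition]
        tbl = tbl[tbl["entity_id"].isin(gt.pattern)]
        if tbl.empty:
            raise InputError("pattern table shares no entities with truth")
        hits = sum(gt.pattern[e] == p
                   for e, p in zip(tbl["entity_id"], tbl["pattern"]))
        score.pattern_accuracy = hits / len(tbl)

    if cluster_labels is not None:
        common = sorted(e for e in cluster_labels
                        if gt.block.get(e) is not None)
        if not common:
            raise InputError("cluster labels share no block entities with truth")
        score.cluster_ari = float(adjusted_rand_score(
            [gt.block[e] for e in common],
            [cluster_labels[e] for e in common],
        ))

    if bin_table is not None:
        if condition is None or condition not in gt.expected_bin:
            raise InputError("bin scoring needs the compared condition label")
        exp = gt.expected_bin[condition]
        tbl = bin_table[bin_table["entity_id"].isin(exp)]
        if tbl.empty:
            raise InputError("bin table shares no entities with truth")
        hits = sum(exp[e] == b for e, b in zip(tbl["entity_id"], tbl["bin"]))
        score.bin_agreement = hits / len(tbl)

    return score
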