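"""Molecular-marker screening for horizontal gene transfer.

Two classic signals are computed per gene: (i) the gene-vs-genome GC
content ratio, flagged as compositionally anomalous outside (0.8, 1.2) —
transferred genes tend to retain the donor's base composition until
amelioration erases it; and (ii) the codon class at a conserved aligned
position (the Ser56-style marker), whose distribution over a phylogeny is
summarized by small parsimony.  Few, phylogenetically scattered anomalies
argue against systematic recent transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core_io import Alignment, CdsRecord, GAP_CHARS, translate_cds
from .tree_utils import Tree

__all__ = [
    "GcReport",
    "CodonMarkerConfig",
    "ParsimonyResult",
    "gc_content",
    "gc_ratio_flag",
    "codon_at_aligned_column",
    "classify_codon",
    "fitch_parsimony",
    "marker_report",
]

RATIO_HIGH = 1.2
RATIO_LOW = 0.8


@dataclass
class GcReport:
    """Per-gene GC evidence: gene GC, genome GC, their ratio, anomaly flag."""

    id: str
    gene_gc: float
    genome_gc: float
    ratio: float
    anomalous: bool

    def __post_init__(self) -> None:
        if abs(self.ratio - self.gene_gc / self.genome_gc) > 1e-9:
            raise ValueError("ratio inconsistent with gene_gc/genome_gc")
        expected = self.ratio > RATIO_HIGH or self.ratio < RATIO_LOW
        if self.anomalous != expected:
            raise ValueError("anomalous flag inconsistent with ratio")


@dataclass
class CodonMarkerConfig:
    """Configuration of the conserved-site codon marker.

    ``marker_column`` is a match-coordinate alignment column.  The default
    classes follow the published dichotomy verbatim — ACY = {ACC, ACT} vs
    TCN = {TCA, TCC, TCG, TCT} — and are fully configurable, e.g. AGY
    ({AGC, AGT}) can be substituted in one line.
    """

    marker_column: int = 0
    class_definitions: dict[str, frozenset[str]] = field(
        default_factory=lambda: {
            "ACY": frozenset({"ACC", "ACT"}),
            "TCN": frozenset({"TCA", "TCC", "TCG", "TCT"}),
        }
    )
    lost_label: str = "lost"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, codons in self.class_definitions.items():
            for codon in codons:
                if len(codon) != 3 or set(codon) - set("ACGT"):
                    raise ValueError(f"invalid codon {codon!r} in class {name}")
                if codon in seen:
                    raise ValueError(f"codon {codon} in more than one class")
                seen.add(codon)


@dataclass
class ParsimonyResult:
    """Small-parsimony summary of a discrete character on a tree."""

    min_changes: int
    node_state_sets: dict[str, frozenset[str]]
    one_optimal_labeling: dict[str, str]


def gc_content(dna: str) -> float:
    """GC fraction over unambiguous bases; N is excluded from both the
    numerator and the denominator."""
    dna = dna.upper()
    counts = {b: dna.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous bases")
    return (counts["G"] + counts["C"]) / total


def gc_ratio_flag(gene_gc: float, genome_gc: float,
                  gene_id: str = "") -> GcReport:
    """Flag a gene as compositionally anomalous when its GC ratio to the
    genome is strictly above 1.2 or strictly below 0.8."""
    if genome_gc <= 0:
        raise ValueError("genome_gc must be positive")
    ratio = gene_gc / genome_gc
    return GcReport(
        id=gene_id, gene_gc=gene_gc, genome_gc=genome_gc, ratio=ratio,
        anomalous=ratio > RATIO_HIGH or ratio < RATIO_LOW,
    )


def codon_at_aligned_column(
    cds_record: CdsRecord,
    aligned_row: str,
    column: int,
    lost_label: str = "lost",
) -> str:
    """The codon encoding the residue at an alignment column.

    A gap at the column means the site was lost in this sequence.  The
    codon index is the count of non-gap positions strictly before the
    column (0-based, half-open slice of the CDS).
    """
    if not 0 <= column < len(aligned_row):
        raise ValueError(f"column {column} outside row of length {len(aligned_row)}")
    degapped = "".join(c for c in aligned_row if c not in GAP_CHARS)
    protein = translate_cds(cds_record.cds)
    if len(degapped) != len(protein) or any(
        a != b for a, b in zip(degapped, protein) if "X" not in (a, b)
    ):
        raise ValueError(
            f"aligned row does not degap to the translation of cds "
            f"{cds_record.id!r}"
        )
    if aligned_row[column] in GAP_CHARS:
        return lost_label
    k = sum(1 for c in aligned_row[:column] if c not in GAP_CHARS)
    return cds_record.cds[3 * k: 3 * k + 3].upper()


def classify_codon(codon: str, config: CodonMarkerConfig) -> str:
    """Assign a codon to its marker class; unknown codons and lost sites
    get the lost label.  Case-insensitive."""
    if codon == config.lost_label:
        return config.lost_label
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    for name, codons in config.class_definitions.items():
        if codon in codons:
            return name
    return config.lost_label


# ---------------------------------------------------------------------------
# Small parsimony
# ---------------------------------------------------------------------------

def _node_key(node: dendropy.Node, index: int) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return f"_internal_{index}"


def fitch_parsimony(
    tree: Tree, tip_states: Mapping[str, str]
) -> ParsimonyResult:
    """Minimum number of state changes of a discrete character on a tree.

    Computed by unit-cost dynamic programming over the observed states
    (exact on binary trees and polytomies alike); ``node_state_sets`` lists,
    per internal node, every state attaining the minimum, and
    ``one_optimal_labeling`` is a concrete optimal assignment (ties resolve
    to the lexicographically smallest state).  A 'lost' label is an
    ordinary state, not missing data.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in tip_states]
    if missing:
        raise ValueError(f"no state for leaves: {missing}")
    states = sorted(set(tip_states.values()))
    s_index = {s: i for i, s in enumerate(states)}
    ns = len(states)
    inf = np.inf

    up: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            cost = np.full(ns, inf)
            cost[s_index[tip_states[node.taxon.label]]] = 0.0
        else:
            cost = np.zeros(ns)
            for child in node.child_nodes():
                u = up[child]
                cost += np.minimum(u.min() + 1.0, u)
        up[node] = cost

    root = tree.seed_node
    min_changes = int(up[root].min())

    down: dict[dendropy.Node, np.ndarray] = {root: np.zeros(ns)}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        for child in node.child_nodes():
            u = up[child]
            g = down[node] + up[node] - np.minimum(u.min() + 1.0, u)
            down[child] = np.minimum(g, g.min() + 1.0)

    keys: dict[dendropy.Node, str] = {}
    node_state_sets: dict[str, frozenset[str]] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        keys[node] = _node_key(node, i)
        if not node.is_leaf():
            total = up[node] + down[node]
            node_state_sets[keys[node]] = frozenset(
                states[k] for k in range(ns) if total[k] == min_changes
            )

    labeling: dict[str, str] = {}
    chosen: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            cost = up[node]
        else:
            parent_state = chosen[node.parent_node]
            cost = up[node] + (np.arange(ns) != parent_state)
        k = int(np.argmin(cost))  # argmin ties -> smallest index = lexicographic
        chosen[node] = k
        labeling[keys[node]] = states[k]

    result = ParsimonyResult(
        min_changes=min_changes,
        node_state_sets=node_state_sets,
        one_optimal_labeling=labeling,
    )
    # invariant: the concrete labeling realizes min_changes
    realized = sum(
        1 for node in tree.preorder_node_iter()
        if node is not root and chosen[node] != chosen[node.parent_node]
    )
    if realized != min_changes:
        raise AssertionError("optimal labeling does not realize min_changes")
    return result


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

def marker_report(
    cds_records: Sequence[CdsRecord],
    alignment: Alignment,
    tree: Optional[Tree],
    config: CodonMarkerConfig,
    clade_min_leaves: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene HGT marker table plus a parsimony/anomaly summary.

    Table columns: id, gene_gc, genome_gc, ratio, anomalous, marker_codon,
    marker_class.  The summary reports the parsimony minimum of the codon
    class on the tree, the anomalous-gene count, and a verdict:
    'systematic' when more than half the genes in any clade of at least
    ``clade_min_leaves`` leaves are anomalous, else 'non-systematic'.
    """
    rows_by_id = dict(alignment.rows)
    table_rows = []
    classes: dict[str, str] = {}
    for rec in cds_records:
        if rec.id not in rows_by_id:
            raise ValueError(f"no alignment row for gene {rec.id!r}")
        report = gc_ratio_flag(gc_content(rec.cds), rec.genome_gc, rec.id)
        codon = codon_at_aligned_column(
            rec, rows_by_id[rec.id], config.marker_column, config.lost_label
        )
        marker_class = classify_codon(codon, config)
        classes[rec.id] = marker_class
        table_rows.append({
            "id": rec.id,
            "gene_gc": report.gene_gc,
            "genome_gc": report.genome_gc,
            "ratio": report.ratio,
            "anomalous": report.anomalous,
            "marker_codon": codon,
            "marker_class": marker_class,
        })
    table = pd.DataFrame(table_rows)

    summary: dict = {"n_genes": len(table),
                     "n_anomalous": int(table["anomalous"].sum())}
    anomalous_by_id = dict(zip(table["id"], table["anomalous"]))
    verdict = "non-systematic"
    if tree is not None:
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        unknown = sorted(leaves - set(anomalous_by_id))
        if unknown:
            raise ValueError(f"tree leaves without gene records: {unknown}")
        parsimony = fitch_parsimony(tree, classes)
        summary["parsimony_min_changes"] = parsimony.min_changes
        for node in tree.preorder_internal_node_iter():
            clade = [lf.taxon.label for lf in node.leaf_iter()]
            if len(clade) < clade_min_leaves:
                continue
            frac = np.mean([anomalous_by_id[l] for l in clade])
            if frac > 0.5:
                verdict = "systematic"
                break
    summary["verdict"] = verdict
    return table, summary
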