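"""Seeded generators for every input the analysis consumes.

The toolkit's analyses are exercised end-to-end on synthetic data with the
statistical structure the real inputs are assumed to have: a clustered
protein superfamily evolved along a tree (within-family identity far above
between-family identity, with the true residue homology recorded), hinge
motifs implanted in a controlled subset, coding genes drawn from host
genomes of controlled GC content with a planted fraction of compositionally
anomalous (transferred) genes, discrete codon classes evolving on a tree,
and rigid-body-transformed/perturbed coordinate sets.  Every generator is
deterministic per seed and carries machine-readable ground truth.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .core_io import Alignment, CdsRecord, SequenceRecord, write_fasta
from .structure_compare import CoordSet
from .tree_utils import Tree, write_newick

__all__ = [
    "SyntheticSuperfamily",
    "SyntheticGenomeSet",
    "simulate_tree",
    "evolve_sequences",
    "plant_families",
    "implant_hinge",
    "generate_genomes",
    "evolve_codon_states",
    "perturb_coords",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class SyntheticSuperfamily:
    """A simulated superfamily with full ground truth.

    ``true_alignment`` columns are homology classes (ancestral or inserted
    sites); ``site_ids`` gives each column's site token and
    ``leaf_site_maps`` each record's ordered site tokens, so any later
    alignment can be scored against the true column assignments.
    """

    records: list[SequenceRecord]
    true_tree: Tree
    true_alignment: Alignment
    site_ids: list[int]
    leaf_site_maps: dict[str, list[int]]
    family_labels: dict[str, int] = field(default_factory=dict)
    motif_carriers: set[str] = field(default_factory=set)

    def truth_json(self) -> str:
        return json.dumps({
            "family_labels": self.family_labels,
            "motif_carriers": sorted(self.motif_carriers),
            "site_ids": self.site_ids,
            "leaf_site_maps": self.leaf_site_maps,
        }, indent=1)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, outdir / "records.fasta")
        from .core_io import write_alignment
        write_alignment(self.true_alignment, outdir / "true_alignment.fasta")
        (outdir / "true_tree.nwk").write_text(write_newick(self.true_tree) + "\n")
        (outdir / "truth.json").write_text(self.truth_json())


@dataclass
class SyntheticGenomeSet:
    """Simulated genomes and genes with planted transfer labels."""

    genomes: list[tuple[str, float]]
    genes: list[CdsRecord]
    transferred: set[str]
    donor_gc: float

    def truth_json(self) -> str:
        return json.dumps({
            "genomes": [{"organism": o, "genome_gc": gc}
                        for o, gc in self.genomes],
            "transferred": sorted(self.transferred),
            "donor_gc": self.donor_gc,
        }, indent=1)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with (outdir / "genes.fasta").open("w") as fh:
            for g in self.genes:
                fh.write(f">{g.id}\n{g.cds}\n")
        with (outdir / "genome_gc.tsv").open("w") as fh:
            fh.write("id\tgenome_gc\n")
            for g in self.genes:
                fh.write(f"{g.id}\t{g.genome_gc:.6f}\n")
        (outdir / "truth.json").write_text(self.truth_json())


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _yule_topology(
    n_leaves: int, birth_rate: float, rng: np.random.Generator
) -> dendropy.Node:
    """Grow a Yule subtree; waiting times are exponential with rate
    birth_rate x (current lineage count)."""
    root = dendropy.Node()
    root._pending = 0.0
    active = [root]
    while len(active) < n_leaves:
        k = len(active)
        dt = rng.exponential(1.0 / (birth_rate * k))
        for nd in active:
            nd._pending += dt
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent.edge.length = parent._pending
        for _ in range(2):
            child = dendropy.Node()
            child._pending = 0.0
            parent.add_child(child)
            active.append(child)
    dt = rng.exponential(1.0 / (birth_rate * n_leaves))
    for nd in active:
        nd.edge.length = nd._pending + dt
    root.edge.length = None
    return root


def simulate_tree(n_leaves: int, birth_rate: float = 1.0,
                  seed: int = 0) -> Tree:
    """A Yule (pure-birth) tree with ``n_leaves`` leaves labeled t1..tn."""
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    root = _yule_topology(n_leaves, birth_rate, rng)
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace, seed_node=root)
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxon_namespace.new_taxon(label=f"t{i}")
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution with homology bookkeeping
# ---------------------------------------------------------------------------

def _mutate_branch(
    sites: list[int],
    residues: list[str],
    length: float,
    subs_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    site_order: list[int],
    counter: list[int],
) -> tuple[list[int], list[str]]:
    sites = list(sites)
    residues = list(residues)
    L = len(sites)
    n_sub = rng.poisson(subs_rate * length * L)
    for _ in range(n_sub):
        pos = int(rng.integers(len(sites)))
        current = residues[pos]
        alternatives = [a for a in AMINO_ACIDS if a != current]
        residues[pos] = alternatives[int(rng.integers(19))]
    n_indel = rng.poisson(indel_rate * length * L)
    for _ in range(n_indel):
        g = int(rng.geometric(0.5))  # mean length 2
        if rng.random() < 0.5:  # insertion after position p (0 = front)
            p = int(rng.integers(len(sites) + 1))
            new_tokens = list(range(counter[0], counter[0] + g))
            counter[0] += g
            new_res = [AMINO_ACIDS[int(rng.integers(20))] for _ in range(g)]
            if p == 0:
                anchor = site_order.index(sites[0])
            else:
                anchor = site_order.index(sites[p - 1]) + 1
            site_order[anchor:anchor] = new_tokens
            sites[p:p] = new_tokens
            residues[p:p] = new_res
        else:  # deletion
            if len(sites) <= g:
                continue  # never empty a sequence
            start = int(rng.integers(len(sites) - g + 1))
            del sites[start:start + g]
            del residues[start:start + g]
    return sites, residues


def evolve_sequences(
    tree: Tree,
    root_seq: str,
    subs_rate: float,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> SyntheticSuperfamily:
    """Evolve a root sequence along a tree with Poisson substitutions
    (uniform over the 19 alternative residues) and geometric-length indels.

    Site tokens are threaded through the simulation so the returned
    ``true_alignment`` records residue homology exactly: two leaf residues
    share a column iff they descend from the same ancestral or inserted
    site.
    """
    if not root_seq:
        raise ValueError("root_seq must be nonempty")
    if subs_rate < 0 or indel_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    L = len(root_seq)
    site_order: list[int] = list(range(L))
    counter = [L]

    state: dict[dendropy.Node, tuple[list[int], list[str]]] = {}
    state[tree.seed_node] = (list(range(L)), list(root_seq))
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_sites, parent_res = state[node.parent_node]
        state[node] = _mutate_branch(
            parent_sites, parent_res, node.edge.length or 0.0,
            subs_rate, indel_rate, rng, site_order, counter,
        )

    records: list[SequenceRecord] = []
    leaf_site_maps: dict[str, list[int]] = {}
    leaf_res: dict[str, dict[int, str]] = {}
    for leaf in tree.leaf_node_iter():
        sites, residues = state[leaf]
        rid = leaf.taxon.label
        records.append(SequenceRecord(id=rid, sequence="".join(residues)))
        leaf_site_maps[rid] = list(sites)
        leaf_res[rid] = dict(zip(sites, residues))

    present = set().union(*leaf_site_maps.values())
    columns = [s for s in site_order if s in present]
    rows = [
        (rid, "".join(leaf_res[rid].get(s, "-") for s in columns))
        for rid in sorted(leaf_res)
    ]
    return SyntheticSuperfamily(
        records=records,
        true_tree=tree,
        true_alignment=Alignment(rows=rows),
        site_ids=columns,
        leaf_site_maps=leaf_site_maps,
    )


def plant_families(
    k: int,
    n_per_family: int,
    within_depth: float = 0.06,
    between_depth: float = 0.8,
    seed: int = 0,
    root_length: int = 200,
    indel_rate: float = 0.01,
    within_identity: float = 75.0,
    between_identity: float = 35.0,
    max_redraws: int = 10,
) -> SyntheticSuperfamily:
    """A superfamily of ``k`` distinct families joined by deep branches.

    Branch lengths are in expected substitutions per site (the substitution
    rate is folded into the lengths).  Realized identities are verified —
    every within-family pair at or above ``within_identity`` percent, every
    between-family pair at or below ``between_identity`` — and the draw is
    repeated (up to ``max_redraws``) until the constraints hold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    from .ssn import pairwise_identity  # local import to avoid a cycle

    last_violation = ""
    for attempt in range(max_redraws):
        rng = np.random.default_rng((seed + 7919 * attempt) % (2 ** 31))
        root_seq = "".join(AMINO_ACIDS[int(rng.integers(20))]
                           for _ in range(root_length))

        taxon_namespace = dendropy.TaxonNamespace()
        root = dendropy.Node()
        for fam in range(k):
            sub = _yule_topology(n_per_family, 1.0, rng) \
                if n_per_family > 1 else dendropy.Node()
            # normalize the family subtree to the requested within depth
            depths = []

            def _depth(nd, acc=0.0):
                if nd.is_leaf():
                    depths.append(acc)
                for c in nd.child_nodes():
                    _depth(c, acc + (c.edge.length or 0.0))

            _depth(sub)
            scale = within_depth / max(depths) if depths and max(depths) > 0 else 1.0
            for nd in sub.preorder_iter():
                if nd is not sub and nd.edge.length is not None:
                    nd.edge.length *= scale
            sub.edge.length = between_depth
            root.add_child(sub)
        tree = dendropy.Tree(taxon_namespace=taxon_namespace, seed_node=root)
        family_labels: dict[str, int] = {}
        fam_counters = [0] * k
        for leaf in tree.leaf_node_iter():
            fam = root.child_nodes().index(_family_ancestor(leaf, root))
            fam_counters[fam] += 1
            label = f"F{fam}_t{fam_counters[fam]}"
            leaf.taxon = taxon_namespace.new_taxon(label=label)
            family_labels[label] = fam

        sf = evolve_sequences(tree, root_seq, subs_rate=1.0,
                              indel_rate=indel_rate,
                              seed=(seed + 104729 * attempt) % (2 ** 31))
        sf.family_labels = family_labels

        ok = True
        seqs = {r.id: r.sequence for r in sf.records}
        ids = sorted(seqs)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ident = pairwise_identity(seqs[a], seqs[b])
                same = family_labels[a] == family_labels[b]
                if same and ident < within_identity:
                    ok = False
                    last_violation = f"within pair {a},{b} at {ident:.1f}%"
                elif not same and ident > between_identity:
                    ok = False
                    last_violation = f"between pair {a},{b} at {ident:.1f}%"
                if not ok:
                    break
            if not ok:
                break
        if ok:
            return sf
    raise RuntimeError(
        f"identity constraints unreachable after {max_redraws} redraws "
        f"(last violation: {last_violation}); decrease within_depth or "
        f"increase between_depth"
    )


def _family_ancestor(leaf: dendropy.Node, root: dendropy.Node) -> dendropy.Node:
    node = leaf
    while node.parent_node is not root:
        node = node.parent_node
    return node


def implant_hinge(
    records: Sequence[SequenceRecord],
    fraction: float,
    seed: int = 0,
    alignment: Optional[Alignment] = None,
    relative_position: float = 0.75,
) -> tuple[list[SequenceRecord], set[str], Optional[Alignment]]:
    """Overwrite a window of ceil(fraction x n) records with the hinge 9-mer
    E-x-G-T-E-A-A-A-A (x drawn from {E,K,R}).

    The window starts at a fixed relative position in each sequence
    (toward the C-terminus, where the RCL sits).  Sequences shorter than 9
    are skipped with a warning.  When the records' true alignment is
    passed, its rows are updated in step (the overwrite changes residues,
    not homology).
    """
    if not records:
        raise ValueError("records must be nonempty")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_carriers = math.ceil(fraction * len(records))
    eligible = [r.id for r in records if len(r.sequence) >= 9]
    skipped = len(records) - len(eligible)
    if skipped:
        warnings.warn(f"{skipped} sequences shorter than 9 skipped")
    if n_carriers > len(eligible):
        warnings.warn("fewer eligible sequences than requested carriers")
        n_carriers = len(eligible)
    chosen = set(
        map(str, rng.choice(sorted(eligible), size=n_carriers, replace=False))
    ) if n_carriers else set()

    out: list[SequenceRecord] = []
    aln_rows = dict(alignment.rows) if alignment is not None else None
    for rec in records:
        if rec.id not in chosen:
            out.append(rec)
            continue
        x = "EKR"[int(rng.integers(3))]
        motif = f"E{x}GTEAAAA"
        start = int(round(relative_position * (len(rec.sequence) - 9)))
        seq = rec.sequence[:start] + motif + rec.sequence[start + 9:]
        out.append(SequenceRecord(id=rec.id, sequence=seq,
                                  taxonomy=rec.taxonomy,
                                  annotations=rec.annotations,
                                  description=rec.description))
        if aln_rows is not None:
            row = aln_rows[rec.id]
            positions = [i for i, c in enumerate(row) if c != "-"]
            new_row = list(row)
            for off, res in enumerate(motif):
                new_row[positions[start + off]] = res
            aln_rows[rec.id] = "".join(new_row)
    new_alignment = None
    if alignment is not None:
        new_alignment = Alignment(
            rows=[(rid, aln_rows[rid]) for rid, _ in alignment.rows],
            column_annotations=dict(alignment.column_annotations),
        )
    return out, chosen, new_alignment


# ---------------------------------------------------------------------------
# Genomes and codon-state evolution
# ---------------------------------------------------------------------------

def _nonstop_adjusted_p(gc: float) -> float:
    """Base GC probability whose expectation *conditional on non-stop
    codons* equals the target.

    Stop codons (TAA, TAG, TGA) are AT-rich, so plain rejection sampling
    inflates gene GC; solving E[GC | non-stop](p) = gc removes the bias.
    """
    from scipy.optimize import brentq

    def cond_gc(p: float) -> float:
        q, g = (1 - p) / 2, p / 2  # per-base A/T and G/C probabilities
        p_stop = q * q * (q + 2 * g)
        e_gc_stop = 2 * q * q * g  # TAG and TGA each carry one G
        return (3 * p - e_gc_stop) / (3 * (1 - p_stop))

    return float(brentq(lambda p: cond_gc(p) - gc, 1e-6, 1 - 1e-6,
                        xtol=1e-12))


def _random_codons(n: int, gc: float, rng: np.random.Generator) -> str:
    """Codons with bases i.i.d. at the given GC fraction; internal stop
    codons are resampled, with the base composition pre-adjusted so the
    non-stop conditional GC expectation equals ``gc`` exactly."""
    p = _nonstop_adjusted_p(gc)
    probs = np.array([(1 - p) / 2, p / 2, p / 2, (1 - p) / 2])
    letters = np.array(["A", "G", "C", "T"])
    out = []
    for _ in range(n):
        while True:
            codon = "".join(letters[rng.choice(4, size=3, p=probs)])
            if codon not in _STOP_CODONS:
                out.append(codon)
                break
    return "".join(out)


def generate_genomes(
    n_genomes: int,
    gc_range: tuple[float, float] = (0.25, 0.65),
    genes_per_genome: int = 10,
    gene_length: int = 900,
    hgt_fraction: float = 0.1,
    donor_gc: float = 0.65,
    seed: int = 0,
) -> SyntheticGenomeSet:
    """Genomes of uniform-random GC with a planted fraction of transferred
    genes generated under the donor's GC content.

    Per genome, round(hgt_fraction x genes_per_genome) genes are planted as
    transfers; their bases are i.i.d. at ``donor_gc``, native genes at the
    genome's own GC.  Gene length must be divisible by 3.
    """
    lo, hi = gc_range
    if not (0 < lo < 1 and 0 < hi < 1):
        raise ValueError("gc_range values must be in (0, 1)")
    if not 0 < donor_gc < 1:
        raise ValueError("donor_gc must be in (0, 1)")
    if not 0 <= hgt_fraction <= 1:
        raise ValueError("hgt_fraction must be in [0, 1]")
    if gene_length % 3 != 0:
        raise ValueError("gene_length must be divisible by 3")
    rng = np.random.default_rng(seed)
    genomes: list[tuple[str, float]] = []
    genes: list[CdsRecord] = []
    transferred: set[str] = set()
    n_codons = gene_length // 3
    n_hgt = int(round(hgt_fraction * genes_per_genome))
    for gi in range(n_genomes):
        gc = float(rng.uniform(lo, hi))
        organism = f"g{gi}"
        genomes.append((organism, gc))
        hgt_idx = set(rng.choice(genes_per_genome, size=n_hgt, replace=False))
        for j in range(genes_per_genome):
            is_hgt = j in hgt_idx
            cds = _random_codons(n_codons, donor_gc if is_hgt else gc, rng)
            gene_id = f"{organism}_orf{j}"
            genes.append(CdsRecord(id=gene_id, cds=cds, genome_gc=gc))
            if is_hgt:
                transferred.add(gene_id)
    return SyntheticGenomeSet(genomes=genomes, genes=genes,
                              transferred=transferred, donor_gc=donor_gc)


def evolve_codon_states(
    tree: Tree,
    class_set: Sequence[str] = ("ACY", "TCN"),
    switch_prob_per_edge: float = 0.05,
    loss_prob_per_edge: float = 0.0,
    seed: int = 0,
    lost_label: str = "lost",
) -> tuple[dict[str, str], int]:
    """Evolve a discrete codon-class character along a tree.

    The root state is uniform over ``class_set``; on each edge the state is
    lost with ``loss_prob_per_edge`` (absorbing), else switched to another
    class with ``switch_prob_per_edge``.  Returns tip states and the true
    number of edges on which the state changed (an upper bound for the
    parsimony minimum).
    """
    for p in (switch_prob_per_edge, loss_prob_per_edge):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    classes = sorted(class_set)
    rng = np.random.default_rng(seed)
    states: dict[dendropy.Node, str] = {}
    states[tree.seed_node] = classes[int(rng.integers(len(classes)))]
    changes = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = states[node.parent_node]
        state = parent
        if parent != lost_label:
            if rng.random() < loss_prob_per_edge:
                state = lost_label
            elif rng.random() < switch_prob_per_edge and len(classes) > 1:
                others = [c for c in classes if c != parent]
                state = others[int(rng.integers(len(others)))]
        states[node] = state
        if state != parent:
            changes += 1
    tips = {lf.taxon.label: states[lf] for lf in tree.leaf_node_iter()}
    return tips, changes


# ---------------------------------------------------------------------------
# Evaluating a computed alignment against the recorded homology
# ---------------------------------------------------------------------------

def near_consensus_ids(
    superfamily: SyntheticSuperfamily, max_substitutions: int = 2
) -> list[str]:
    """Records within ``max_substitutions`` Hamming distance of their
    family's consensus (among members sharing the family's modal site
    layout, i.e. indel-free relative to the family)."""
    from collections import Counter, defaultdict

    by_family: dict[int, list[str]] = defaultdict(list)
    for rid, fam in superfamily.family_labels.items():
        by_family[fam].append(rid)
    eligible: list[str] = []
    seqs = {r.id: r.sequence for r in superfamily.records}
    for fam, ids in sorted(by_family.items()):
        layouts = Counter(tuple(superfamily.leaf_site_maps[i]) for i in ids)
        modal = layouts.most_common(1)[0][0]
        members = [i for i in ids
                   if tuple(superfamily.leaf_site_maps[i]) == modal]
        consensus = "".join(
            Counter(seqs[i][p] for i in members).most_common(1)[0][0]
            for p in range(len(modal))
        )
        for i in members:
            dist = sum(a != b for a, b in zip(seqs[i], consensus))
            if dist <= max_substitutions:
                eligible.append(i)
    return eligible


def column_homology_recovery(
    superfamily: SyntheticSuperfamily,
    result,
    seed_column_sites: Sequence[int],
    record_ids: Sequence[str],
) -> float:
    """Fraction of true column assignments recovered by a profile alignment.

    ``result`` is a :class:`~serpintools.profile_align.SuperfamilyAlignResult`
    whose seed columns carry the site tokens ``seed_column_sites``.  For
    each listed record and each final-alignment column whose underlying
    site the record truly possesses, the placement counts as recovered when
    the record's residue shown at that column is the residue that evolved
    at that site.
    """
    from .profile_align import align_to_profile, row_residue_indices

    col_sites = [seed_column_sites[j] for j in result.column_seed_indices()]
    by_id = {r.id: r for r in superfamily.records}
    total = correct = 0
    for rid in record_ids:
        rec = by_id[rid]
        row, ins = align_to_profile(result.enriched_profile, rec)
        qidx = row_residue_indices(row, ins)
        rsites = superfamily.leaf_site_maps[rid]
        rset = set(rsites)
        for c, s in enumerate(col_sites):
            if s not in rset:
                continue
            total += 1
            qi = qidx[c]
            if qi is not None and rsites[qi] == s:
                correct += 1
    if total == 0:
        raise ValueError("no scorable column assignments")
    return correct / total


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

def perturb_coords(
    coords: CoordSet,
    sigma: float,
    rigid_transform: bool = False,
    seed: int = 0,
) -> CoordSet:
    """Gaussian per-axis displacement (sigma, Angstrom), optionally followed
    by a random proper rotation and translation."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    pts = coords.points + rng.normal(0.0, sigma, size=coords.points.shape)
    if rigid_transform:
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.uniform(-20.0, 20.0, size=3)
        pts = pts @ rot.T + shift
    return CoordSet(label=f"{coords.label}_perturbed", points=pts,
                    residue_ids=coords.residue_ids)
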