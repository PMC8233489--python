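"""Independent reference implementations used only to cross-check results.

Each oracle recomputes a quantity by a different route than the library:
plain-Python full-matrix dynamic programming for alignment identity,
exhaustive path enumeration for profile Viterbi scores, exhaustive internal
labeling for small parsimony, the quaternion characteristic-polynomial
method for superposition RMSD, and naive window scanning for motifs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def identity_oracle(a: str, b: str, gap_open: float = 10.0,
                    gap_extend: float = 0.5) -> float:
    """Percent identity via a plain-Python Gotoh DP.

    Maximizes BLOSUM62 score, then identity count; per-cell ties prefer the
    diagonal state, then a gap in b, then a gap in a (opening preferred
    over extending on a full tie).  Identity = 100 x identities / columns,
    with the terminal runs of gap-containing columns excluded.
    """
    n, m = len(a), len(b)
    # cell value: (score, ident); pointer: predecessor state
    S = {}
    P = {}
    S[(0, 0, 0)] = (0.0, 0)
    for s in (1, 2):
        S[(s, 0, 0)] = (NEG, 0)
    for i in range(1, n + 1):
        S[(0, i, 0)] = (NEG, 0)
        S[(2, i, 0)] = (NEG, 0)
        S[(1, i, 0)] = (-gap_open - (i - 1) * gap_extend, 0)
        P[(1, i, 0)] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        S[(0, 0, j)] = (NEG, 0)
        S[(1, 0, j)] = (NEG, 0)
        S[(2, 0, j)] = (-gap_open - (j - 1) * gap_extend, 0)
        P[(2, 0, j)] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # diagonal
            best, ptr = (NEG, 0), None
            for s in (0, 1, 2):
                cand = S[(s, i - 1, j - 1)]
                if cand[0] > best[0] or (cand[0] == best[0]
                                         and cand[1] > best[1]):
                    best, ptr = cand, s
            match = _B62[a[i - 1], b[j - 1]]
            same = 1 if a[i - 1] == b[j - 1] else 0
            S[(0, i, j)] = (best[0] + match, best[1] + same)
            P[(0, i, j)] = ptr
            # gap in b (consume a)
            op = S[(0, i - 1, j)]
            ex = S[(1, i - 1, j)]
            open_score = (op[0] - gap_open, op[1])
            ext_score = (ex[0] - gap_extend, ex[1])
            if open_score[0] > ext_score[0] or (
                    open_score[0] == ext_score[0]
                    and open_score[1] >= ext_score[1]):
                S[(1, i, j)], P[(1, i, j)] = open_score, 0
            else:
                S[(1, i, j)], P[(1, i, j)] = ext_score, 1
            # gap in a (consume b)
            op = S[(0, i, j - 1)]
            ex = S[(2, i, j - 1)]
            open_score = (op[0] - gap_open, op[1])
            ext_score = (ex[0] - gap_extend, ex[1])
            if open_score[0] > ext_score[0] or (
                    open_score[0] == ext_score[0]
                    and open_score[1] >= ext_score[1]):
                S[(2, i, j)], P[(2, i, j)] = open_score, 0
            else:
                S[(2, i, j)], P[(2, i, j)] = ext_score, 2

    state, best = 0, S[(0, n, m)]
    for s in (1, 2):
        cand = S[(s, n, m)]
        if cand[0] > best[0] or (cand[0] == best[0] and cand[1] > best[1]):
            state, best = s, cand

    columns = []  # (char_a or None, char_b or None)
    i, j = n, m
    while i > 0 or j > 0:
        p = P[(state, i, j)]
        if state == 0:
            columns.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
        elif state == 1:
            columns.append((a[i - 1], None))
            i -= 1
        else:
            columns.append((None, b[j - 1]))
            j -= 1
        state = p
    columns.reverse()

    def is_gap(col):
        return col[0] is None or col[1] is None

    lead = 0
    while lead < len(columns) and is_gap(columns[lead]):
        lead += 1
    trail = 0
    while trail < len(columns) - lead and is_gap(columns[-1 - trail]):
        trail += 1
    core = columns[lead:len(columns) - trail]
    if not core:
        return 0.0
    ident = sum(1 for x, y in core if x is not None and x == y)
    return 100.0 * ident / len(core)


def viterbi_enumeration_oracle(profile, sequence: str) -> float:
    """Best log-odds over ALL legal state paths, by explicit enumeration.

    Mirrors the declared model: begin/end behave as match states, no I<->D
    transitions, free unaligned tails (transitions touching the flanking
    insert states cost nothing, their emissions score zero).
    """
    from serpintools.profile_align import PROFILE_ALPHABET

    k = len(profile)
    n = len(sequence)
    lo = np.log(profile.emissions) - np.log(profile.background)[None, :]
    t = {name: math.log(profile.transitions[name])
         for name in profile.transitions}
    aa = {c: i for i, c in enumerate(PROFILE_ALPHABET)}

    best = [NEG]

    def emit(i, j):  # residue i against match state j (1-based)
        c = sequence[i]
        return 0.0 if c == "X" else lo[j - 1, aa[c]]

    def rec(state, i, j, acc):
        # state in {"M","D","I"}; i residues consumed; j = current column
        if i == n and j == k:
            if state == "M":
                end = t["MM"]
            elif state == "D":
                end = t["DM"]
            else:
                end = 0.0 if j == k else t["IM"]  # I_k is free
            if acc + end > best[0]:
                best[0] = acc + end
        if j < k:
            if i < n:  # -> M_{j+1}
                if state == "M":
                    cost = t["MM"]
                elif state == "D":
                    cost = t["DM"]
                else:
                    cost = 0.0 if j in (0, k) else t["IM"]
                rec("M", i + 1, j + 1, acc + cost + emit(i, j + 1))
            if state != "I":  # -> D_{j+1}
                cost = t["MD"] if state == "M" else t["DD"]
                rec("D", i, j + 1, acc + cost)
        if i < n and state != "D":  # -> I_j
            free = j in (0, k)
            cost = (0.0 if free else (t["MI"] if state == "M" else t["II"]))
            rec("I", i + 1, j, acc + cost)

    rec("M", 0, 0, 0.0)
    return best[0]


def fitch_enumeration_oracle(tree, tip_states: dict[str, str]) -> int:
    """Minimum edge-change count by enumerating every internal labeling."""
    states = sorted(set(tip_states.values()))
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    edges = [(nd.parent_node, nd) for nd in tree.preorder_node_iter()
             if nd.parent_node is not None]
    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        label = {id(nd): s for nd, s in zip(internals, combo)}
        for nd in tree.leaf_node_iter():
            label[id(nd)] = tip_states[nd.taxon.label]
        changes = sum(1 for p, c in edges if label[id(p)] != label[id(c)])
        if best is None or changes < best:
            best = changes
    return best


def quaternion_rmsd_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal superposition RMSD via the quaternion eigenvalue method."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    ga = float(np.sum(a0 * a0))
    gb = float(np.sum(b0 * b0))
    m = b0.T @ a0
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = float(np.linalg.eigvalsh(key)[-1])
    msd = max(0.0, (ga + gb - 2.0 * lam)) / len(a)
    return math.sqrt(msd)


def hinge_scan_oracle(sequence: str) -> list[tuple[int, str]]:
    """All length-9 windows tested against the positional residue sets."""
    sets = [{"E"}, {"E", "K", "R"}, {"G"}, {"T"}, {"E"},
            {"A"}, {"A"}, {"A"}, {"A"}]
    hits = []
    for i in range(len(sequence) - 8):
        window = sequence[i:i + 9]
        if all(c in allowed for c, allowed in zip(window, sets)):
            hits.append((i, window))
    return hits


def patristic_oracle(tree) -> dict[tuple[str, str], float]:
    """All-pairs leaf path lengths via root paths and explicit LCAs."""
    paths = {}
    for lf in tree.leaf_node_iter():
        chain = []
        node = lf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        paths[lf.taxon.label] = chain
    out = {}
    labels = sorted(paths)
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            sx = {id(n) for n in paths[x]}
            lca = next(n for n in paths[y] if id(n) in sx)
            def dist_to(chain, target):
                d = 0.0
                for node in chain:
                    if node is target:
                        return d
                    d += node.edge.length or 0.0
                raise AssertionError
            out[(x, y)] = dist_to(paths[x], lca) + dist_to(paths[y], lca)
    return out
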