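"""Position-specific profile models and the structure-seeded alignment workflow.

A profile is built from a seed alignment: columns with at most a threshold
gap fraction (and, when a structural mask is given, resolved in the seed
crystal structures) become match states with pseudocounted residue emission
probabilities; a single shared set of match/insert/delete transition
probabilities is estimated from the seed rows' own state paths.  Sequences
are scored and aligned against a profile by Viterbi dynamic programming in
log-odds space, which also drives consensus-representative selection per
cluster and the iterative superfamily alignment:

    seed -> global profile -> per-cluster profiles & representatives
         -> representative alignment -> enriched profile -> final alignment

This replaces ensemble HMM tooling with a minimal, fully specified profile
implementation: plain pseudocounts, Viterbi (not forward) scoring, and free
unaligned tails.  Insert-state residues live in a side channel and are
excluded from match-coordinate alignments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _kernels
from .core_io import Alignment, GAP_CHARS, SequenceRecord, length_filter

__all__ = [
    "PROFILE_ALPHABET",
    "Profile",
    "ProfileScore",
    "SuperfamilyAlignResult",
    "build_profile",
    "score_sequence",
    "align_to_profile",
    "row_residue_indices",
    "select_representative",
    "mask_unresolved_columns",
    "superfamily_align",
    "superfamily_align_detailed",
]

logger = logging.getLogger(__name__)

PROFILE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(PROFILE_ALPHABET)}

#: Transition order used throughout: M->M, M->I, M->D, I->I, I->M, D->D, D->M
TRANSITION_NAMES = ("MM", "MI", "MD", "II", "IM", "DD", "DM")


@dataclass
class Profile:
    """Profile over match states with shared transition probabilities."""

    match_columns: list[int]
    emissions: np.ndarray            # (k, 20), rows sum to 1
    background: np.ndarray           # (20,), sums to 1
    transitions: dict[str, float]    # keys TRANSITION_NAMES
    pseudocount_weight: float = 1.0

    def __post_init__(self) -> None:
        k = len(self.match_columns)
        if k == 0:
            raise ValueError("profile has zero match states")
        if any(b >= a for a, b in zip(self.match_columns[1:],
                                      self.match_columns)):
            raise ValueError("match_columns must be strictly increasing")
        if self.emissions.shape != (k, 20):
            raise ValueError("emissions must be (n_match, 20)")
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("emission rows must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        for group in (("MM", "MI", "MD"), ("II", "IM"), ("DD", "DM")):
            total = sum(self.transitions[g] for g in group)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"transitions out of {group[0][0]} must sum to 1")

    def __len__(self) -> int:
        return len(self.match_columns)

    def _log_odds(self) -> np.ndarray:
        return np.log(self.emissions) - np.log(self.background)[None, :]

    def _log_transitions(self) -> np.ndarray:
        return np.log(np.array([self.transitions[t] for t in TRANSITION_NAMES]))

    # -- plain-text serialization (versioned) -------------------------------

    def to_text(self) -> str:
        lines = ["serpintools-profile v1",
                 f"alphabet {PROFILE_ALPHABET}",
                 f"pseudocount {float(self.pseudocount_weight)!r}",
                 "match_columns " + " ".join(str(int(c))
                                             for c in self.match_columns),
                 "transitions " + " ".join(
                     f"{t}={float(self.transitions[t])!r}"
                     for t in TRANSITION_NAMES),
                 "background " + " ".join(f"{float(v)!r}"
                                          for v in self.background)]
        for row in self.emissions:
            lines.append("emission " + " ".join(f"{float(v)!r}" for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Profile":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("serpintools-profile v1"):
            raise ValueError("unrecognized profile format/version")
        fields: dict[str, str] = {}
        emissions = []
        for ln in lines[1:]:
            key, _, rest = ln.partition(" ")
            if key == "emission":
                emissions.append([float(v) for v in rest.split()])
            else:
                fields[key] = rest
        transitions = dict(
            (kv.split("=")[0], float(kv.split("=")[1]))
            for kv in fields["transitions"].split()
        )
        return cls(
            match_columns=[int(v) for v in fields["match_columns"].split()],
            emissions=np.array(emissions),
            background=np.array([float(v) for v in fields["background"].split()]),
            transitions=transitions,
            pseudocount_weight=float(fields["pseudocount"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "Profile":
        return cls.from_text(Path(path).read_text())


@dataclass
class ProfileScore:
    """Viterbi log-odds score (nats) and optimal state path for one sequence."""

    id: str
    score: float
    path: str  # string over M/I/D

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError("profile score must be finite")


def build_profile(
    alignment: Alignment,
    gap_fraction_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    resolved_mask: Optional[Sequence[bool]] = None,
) -> Profile:
    """Estimate a profile from a (seed) alignment.

    A column becomes a match state iff its gap fraction is at most
    ``gap_fraction_threshold`` and, when ``resolved_mask`` is given, the
    column is marked resolved.  Emissions are pseudocounted toward the
    pooled background; transition probabilities are pooled over the seed
    rows' state paths with +1 smoothing.  The ambiguity letter X is ignored
    in all counts.
    """
    n_rows = len(alignment.rows)
    ncol = alignment.column_count
    if resolved_mask is not None and len(resolved_mask) != ncol:
        raise ValueError("resolved_mask length must equal column count")

    counts = np.zeros((ncol, 20))
    gaps = np.zeros(ncol)
    for _, seq in alignment.rows:
        for j, c in enumerate(seq):
            if c in GAP_CHARS:
                gaps[j] += 1
            elif c in _AA_INDEX:
                counts[j, _AA_INDEX[c]] += 1

    match_cols = [
        j for j in range(ncol)
        if gaps[j] / n_rows <= gap_fraction_threshold
        and (resolved_mask is None or resolved_mask[j])
    ]
    if not match_cols:
        raise ValueError("no columns qualify as match states")

    pooled = counts.sum(axis=0)
    background = (pooled + 1.0) / (pooled.sum() + 20.0)

    k = len(match_cols)
    emissions = np.empty((k, 20))
    for s, j in enumerate(match_cols):
        n_eff = counts[j].sum()
        emissions[s] = (counts[j] + pseudocount_weight * background) / (
            n_eff + pseudocount_weight
        )

    # transition counts from observed seed state paths (begin/end act as M)
    is_match = np.zeros(ncol, dtype=bool)
    is_match[match_cols] = True
    tcounts = {t: 1.0 for t in TRANSITION_NAMES}  # +1 smoothing
    for _, seq in alignment.rows:
        prev = "M"
        for j, c in enumerate(seq):
            gap = c in GAP_CHARS
            if is_match[j]:
                state = "D" if gap else "M"
            else:
                if gap:
                    continue
                state = "I"
            key = prev + state
            if key in tcounts:
                tcounts[key] += 1.0
            prev = state
        key = prev + "M"  # close into the end state
        if key in tcounts:
            tcounts[key] += 1.0

    transitions: dict[str, float] = {}
    for group in (("MM", "MI", "MD"), ("II", "IM"), ("DD", "DM")):
        total = sum(tcounts[g] for g in group)
        for g in group:
            transitions[g] = tcounts[g] / total

    return Profile(
        match_columns=match_cols,
        emissions=emissions,
        background=background,
        transitions=transitions,
        pseudocount_weight=pseudocount_weight,
    )


def _encode_query(sequence: str) -> np.ndarray:
    codes = np.empty(len(sequence), dtype=np.int64)
    for i, c in enumerate(sequence):
        if c == "X":
            codes[i] = -1  # background emission, log-odds 0
        elif c in _AA_INDEX:
            codes[i] = _AA_INDEX[c]
        else:
            raise ValueError(f"residue {c!r} outside the profile alphabet")
    return codes


def _viterbi(profile: Profile, record: SequenceRecord) -> tuple[float, np.ndarray]:
    if not record.sequence:
        raise ValueError("cannot score an empty sequence")
    score, path = _kernels.viterbi_profile(
        _encode_query(record.sequence),
        profile._log_odds(),
        profile._log_transitions(),
        True,
    )
    return float(score), path


def score_sequence(profile: Profile, record: SequenceRecord) -> ProfileScore:
    """Viterbi log-odds score of a sequence against the profile.

    The score is the log probability of the best state path, with match
    emissions expressed as log-odds against the profile background (so an
    uninformative sequence scores near the transition cost alone).  The
    traceback tie-break is match > delete > insert.
    """
    score, path = _viterbi(profile, record)
    letters = {_kernels.ST_M: "M", _kernels.ST_D: "D", _kernels.ST_I: "I"}
    return ProfileScore(
        id=record.id, score=score,
        path="".join(letters[int(s)] for s, _ in path),
    )


def align_to_profile(
    profile: Profile, record: SequenceRecord
) -> tuple[str, dict[int, str]]:
    """Align a sequence to the profile's match coordinates.

    Returns the gapped row over the match states (length = number of match
    states) and a side channel of insert-state residues keyed by the match
    state they follow (0 = before the first match state).
    """
    _, path = _viterbi(profile, record)
    row = ["-"] * len(profile)
    insertions: dict[int, str] = {}
    pos = 0
    for s, j in path:
        if s == _kernels.ST_M:
            row[j - 1] = record.sequence[pos]
            pos += 1
        elif s == _kernels.ST_I:
            insertions[int(j)] = insertions.get(int(j), "") + record.sequence[pos]
            pos += 1
        # delete states leave the gap in place
    return "".join(row), insertions


def row_residue_indices(row: str, insertions: dict[int, str]) -> list[Optional[int]]:
    """Map each match-coordinate column of an aligned row back to the index
    of the sequence residue it shows (None for delete columns).

    The residue order is: insertions after match state 0 (the unaligned
    head), match column 1, insertions after it, match column 2, ...
    """
    indices: list[Optional[int]] = []
    pos = len(insertions.get(0, ""))
    for j, c in enumerate(row, start=1):
        if c == "-":
            indices.append(None)
        else:
            indices.append(pos)
            pos += 1
        pos += len(insertions.get(j, ""))
    return indices


def select_representative(
    cluster_records: Sequence[SequenceRecord], cluster_profile: Profile
) -> SequenceRecord:
    """The most consensus-like member: maximal profile log-odds score,
    ties broken by smallest id."""
    if not cluster_records:
        raise ValueError("cannot select a representative from an empty cluster")
    best: Optional[tuple[float, SequenceRecord]] = None
    for rec in sorted(cluster_records, key=lambda r: r.id):
        s = score_sequence(cluster_profile, rec).score
        if best is None or s > best[0]:
            best = (s, rec)
    assert best is not None
    return best[1]


def mask_unresolved_columns(
    alignment: Alignment, resolved_mask: Sequence[bool]
) -> Alignment:
    """Keep exactly the columns marked resolved (e.g. present in the seed
    crystal structures), in order."""
    if len(resolved_mask) != alignment.column_count:
        raise ValueError(
            f"mask length {len(resolved_mask)} != column count "
            f"{alignment.column_count}"
        )
    keep = [j for j, ok in enumerate(resolved_mask) if ok]
    rows = [(rid, "".join(seq[j] for j in keep)) for rid, seq in alignment.rows]
    anns = {k: "".join(v[j] for j in keep)
            for k, v in alignment.column_annotations.items()}
    return Alignment(rows=rows, column_annotations=anns)


@dataclass
class SuperfamilyAlignResult:
    """Full output of the staged superfamily alignment."""

    alignment: Alignment
    global_profile: Profile
    enriched_profile: Profile
    representatives: list[SequenceRecord]

    def column_seed_indices(self) -> list[int]:
        """For each final-alignment column, the (masked) seed-alignment
        column it descends from."""
        return [self.global_profile.match_columns[j]
                for j in self.enriched_profile.match_columns]


def superfamily_align(
    seed_alignment: Alignment,
    resolved_mask: Optional[Sequence[bool]],
    clusters: Iterable[Sequence[str]],
    all_records: Sequence[SequenceRecord],
    gap_fraction_threshold: float = 0.5,
    pseudocount_weight: float = 5.0,
    length_tolerance: float = 0.25,
) -> Alignment:
    """Iterative structure-seeded superfamily alignment.

    Pipeline: (1) global profile from the (masked) seed alignment;
    (2) per cluster, align surviving members to the global profile, build a
    cluster profile, and pick the consensus-like representative;
    (3) align representatives to the global profile; (4) build the enriched
    profile from the representative alignment; (5) align every surviving
    record (post length filter) to the enriched profile.  Deterministic
    given its inputs; clusters with no surviving member are dropped with a
    logged warning.
    """
    return superfamily_align_detailed(
        seed_alignment, resolved_mask, clusters, all_records,
        gap_fraction_threshold, pseudocount_weight, length_tolerance,
    ).alignment


def superfamily_align_detailed(
    seed_alignment: Alignment,
    resolved_mask: Optional[Sequence[bool]],
    clusters: Iterable[Sequence[str]],
    all_records: Sequence[SequenceRecord],
    gap_fraction_threshold: float = 0.5,
    pseudocount_weight: float = 5.0,
    length_tolerance: float = 0.25,
) -> SuperfamilyAlignResult:
    """As :func:`superfamily_align` but returning the intermediate profiles
    and selected representatives alongside the final alignment."""
    seed = seed_alignment
    if resolved_mask is not None:
        seed = mask_unresolved_columns(seed, resolved_mask)
    global_profile = build_profile(
        seed, gap_fraction_threshold=gap_fraction_threshold,
        pseudocount_weight=pseudocount_weight,
    )

    survivors, _ = length_filter(all_records, tolerance=length_tolerance)
    by_id = {r.id: r for r in survivors}

    representatives: list[SequenceRecord] = []
    for k, cluster in enumerate(clusters):
        members = [by_id[i] for i in cluster if i in by_id]
        if not members:
            logger.warning("cluster %d has no surviving members; dropped", k)
            continue
        rows = [(m.id, align_to_profile(global_profile, m)[0])
                for m in members]
        cluster_aln = Alignment(rows=rows)
        cluster_profile = build_profile(
            cluster_aln, gap_fraction_threshold=gap_fraction_threshold,
            pseudocount_weight=pseudocount_weight,
        )
        representatives.append(select_representative(members, cluster_profile))

    if not representatives:
        raise ValueError("no cluster produced a representative")
    rep_rows = [(r.id, align_to_profile(global_profile, r)[0])
                for r in representatives]
    rep_alignment = Alignment(rows=rep_rows)
    enriched = build_profile(
        rep_alignment, gap_fraction_threshold=gap_fraction_threshold,
        pseudocount_weight=pseudocount_weight,
    )

    final_rows = [(r.id, align_to_profile(enriched, r)[0]) for r in survivors]
    return SuperfamilyAlignResult(
        alignment=Alignment(rows=final_rows),
        global_profile=global_profile,
        enriched_profile=enriched,
        representatives=representatives,
    )
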