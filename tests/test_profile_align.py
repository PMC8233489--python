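import itertools

import numpy as np
import pytest

from serpintools.core_io import Alignment, SequenceRecord
from serpintools.profile_align import (
    PROFILE_ALPHABET,
    Profile,
    align_to_profile,
    build_profile,
    mask_unresolved_columns,
    row_residue_indices,
    score_sequence,
    select_representative,
    superfamily_align,
    superfamily_align_detailed,
)
from serpintools.synthetic_data import (
    column_homology_recovery,
    near_consensus_ids,
)
from serpintools.ssn import build_network, collapse_redundancy, mcl_cluster

from oracles import viterbi_enumeration_oracle


@pytest.fixture()
def acde_profile():
    aln = Alignment(rows=[(f"r{i}", "ACDE") for i in range(4)])
    return build_profile(aln)


def family_clusters(sf):
    nodes = collapse_redundancy(sf.records)
    net = build_network(nodes, sf.records)
    cs = mcl_cluster(net)
    by_node = {n.representative_id: n.member_ids for n in nodes}
    return [[m for nid in cl for m in by_node[nid]] for cl in cs.clusters]


def seed_from_family(sf, family=0):
    rows = [(rid, row) for rid, row in sf.true_alignment.rows
            if sf.family_labels[rid] == family]
    keep = [j for j in range(len(rows[0][1]))
            if any(r[1][j] != "-" for r in rows)]
    seed = Alignment(rows=[(rid, "".join(row[j] for j in keep))
                           for rid, row in rows])
    sites = [sf.site_ids[j] for j in keep]
    return seed, sites


class TestBuildProfile:
    def test_identical_rows_give_full_match_states(self, acde_profile):
        assert acde_profile.match_columns == [0, 1, 2, 3]
        assert np.argmax(acde_profile.emissions[0]) == \
            PROFILE_ALPHABET.index("A")

    def test_pure_frequencies_without_pseudocounts(self):
        aln = Alignment(rows=[("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")])
        prof = build_profile(aln, pseudocount_weight=0.0)
        em = prof.emissions[0]
        assert em[PROFILE_ALPHABET.index("A")] == pytest.approx(0.5)
        assert em[PROFILE_ALPHABET.index("C")] == pytest.approx(0.5)

    def test_gap_heavy_column_is_insert(self):
        rows = [("a", "AC"), ("b", "AC"), ("c", "A-"),
                ("d", "A-"), ("e", "A-")]
        prof = build_profile(Alignment(rows=rows),
                             gap_fraction_threshold=0.5)
        assert prof.match_columns == [0]

    def test_resolved_mask_restricts_match_states(self):
        aln = Alignment(rows=[(f"r{i}", "ACDE") for i in range(3)])
        prof = build_profile(aln, resolved_mask=[True, False, True, False])
        assert prof.match_columns == [0, 2]

    def test_zero_match_columns_errors(self):
        aln = Alignment(rows=[("a", "A-"), ("b", "-A")])
        with pytest.raises(ValueError):
            build_profile(aln, gap_fraction_threshold=0.2)

    def test_normalization_invariants(self, workflow_superfamily):
        seed, _ = seed_from_family(workflow_superfamily)
        for pc in (0.5, 1.0, 5.0):
            prof = build_profile(seed, pseudocount_weight=pc)
            assert np.allclose(prof.emissions.sum(axis=1), 1.0, atol=1e-9)
            assert prof.background.sum() == pytest.approx(1.0, abs=1e-9)
            for group in (("MM", "MI", "MD"), ("II", "IM"), ("DD", "DM")):
                assert sum(prof.transitions[g] for g in group) == \
                    pytest.approx(1.0, abs=1e-9)


class TestScoreSequence:
    def test_perfect_query_all_match_positive(self, acde_profile):
        s = score_sequence(acde_profile, SequenceRecord("q", "ACDE"))
        assert s.path == "MMMM"
        assert s.score > 0

    def test_short_query_two_matches_two_deletes(self, acde_profile):
        s = score_sequence(acde_profile, SequenceRecord("q", "AC"))
        assert s.path.count("M") == 2 and s.path.count("D") == 2

    def test_consensus_beats_every_single_substitution(self, acde_profile):
        consensus = "".join(PROFILE_ALPHABET[int(np.argmax(row))]
                            for row in acde_profile.emissions)
        best = score_sequence(acde_profile,
                              SequenceRecord("c", consensus)).score
        for pos, alt in itertools.product(range(4), PROFILE_ALPHABET):
            if alt == consensus[pos]:
                continue
            variant = consensus[:pos] + alt + consensus[pos + 1:]
            s = score_sequence(acde_profile,
                               SequenceRecord("v", variant)).score
            assert best >= s

    def test_path_consistency(self, acde_profile, workflow_superfamily):
        # the reported path must account for the whole query and profile
        for rec in workflow_superfamily.records[:6]:
            seed, _ = seed_from_family(workflow_superfamily)
            prof = build_profile(seed, pseudocount_weight=5.0)
            s = score_sequence(prof, rec)
            assert s.path.count("M") + s.path.count("I") == len(rec.sequence)
            assert s.path.count("M") + s.path.count("D") == len(prof)

    def test_residue_handling(self, acde_profile):
        from serpintools.profile_align import _encode_query

        with pytest.raises(ValueError, match="outside"):
            _encode_query("AC?E")
        # X scores as background: log-odds contribution 0, score finite
        s = score_sequence(acde_profile, SequenceRecord("q", "XXXX"))
        assert np.isfinite(s.score)

    def test_viterbi_equals_path_enumeration(self):
        rng = np.random.default_rng(13)
        aas = list(PROFILE_ALPHABET)
        for trial in range(30):
            ncol = int(rng.integers(2, 5))
            nrow = int(rng.integers(2, 5))
            rows = []
            for r in range(nrow):
                row = "".join(
                    "-" if rng.random() < 0.15
                    else aas[rng.integers(20)] for _ in range(ncol))
                if set(row) == {"-"}:
                    row = aas[int(rng.integers(20))] + row[1:]
                rows.append((f"r{r}", row))
            try:
                prof = build_profile(Alignment(rows=rows))
            except ValueError:
                continue
            query = "".join(aas[rng.integers(20)]
                            for _ in range(rng.integers(1, 6)))
            got = score_sequence(prof, SequenceRecord("q", query)).score
            want = viterbi_enumeration_oracle(prof, query)
            assert got == pytest.approx(want, abs=1e-9), (rows, query)


class TestAlignToProfile:
    def test_seed_row_maps_to_itself(self, workflow_superfamily):
        seed, _ = seed_from_family(workflow_superfamily)
        prof = build_profile(seed, pseudocount_weight=5.0)
        rid, row = seed.rows[0]
        seq = "".join(c for c in row if c != "-")
        got, ins = align_to_profile(prof, SequenceRecord(rid, seq))
        expected = "".join(row[j] for j in prof.match_columns)
        # residues of the seed row that fall in insert columns are reported
        # in the side channel, not the match row
        assert got == expected or not ins

    def test_insertion_goes_to_side_channel(self, acde_profile):
        got, ins = align_to_profile(acde_profile,
                                    SequenceRecord("q", "ACWDE"))
        assert got == "ACDE"
        assert ins == {2: "W"}

    def test_deletions_render_as_gaps(self, acde_profile):
        got, ins = align_to_profile(acde_profile, SequenceRecord("q", "AC"))
        assert got == "AC--"

    def test_row_residue_indices_round_trip(self, acde_profile):
        rec = SequenceRecord("q", "WACWDE")
        row, ins = align_to_profile(acde_profile, rec)
        idx = row_residue_indices(row, ins)
        for col, qi in enumerate(idx):
            if qi is not None:
                assert row[col] == rec.sequence[qi]


class TestSelectRepresentative:
    def test_single_member(self, acde_profile):
        rec = SequenceRecord("only", "ACDE")
        assert select_representative([rec], acde_profile) is rec

    def test_consensus_member_wins(self, workflow_superfamily):
        sf = workflow_superfamily
        fam0 = [r for r in sf.records if sf.family_labels[r.id] == 0]
        seed, _ = seed_from_family(sf, 0)
        prof = build_profile(seed, pseudocount_weight=1.0)
        consensus = "".join(PROFILE_ALPHABET[int(np.argmax(row))]
                            for row in prof.emissions)
        members = fam0 + [SequenceRecord("zz_consensus", consensus)]
        assert select_representative(members, prof).id == "zz_consensus"

    def test_tie_breaks_to_smallest_id(self, acde_profile):
        members = [SequenceRecord("b", "ACDE"), SequenceRecord("a", "ACDE")]
        assert select_representative(members, acde_profile).id == "a"

    def test_empty_cluster_errors(self, acde_profile):
        with pytest.raises(ValueError):
            select_representative([], acde_profile)


class TestMaskUnresolved:
    def test_all_true_is_identity(self):
        aln = Alignment(rows=[("a", "ACDE")])
        assert mask_unresolved_columns(aln, [True] * 4).rows == aln.rows

    def test_all_false_errors(self):
        aln = Alignment(rows=[("a", "ACDE")])
        with pytest.raises(ValueError):
            mask_unresolved_columns(aln, [False] * 4)

    def test_pattern_mask(self):
        aln = Alignment(rows=[("a", "ACDE"), ("b", "AC-E")])
        out = mask_unresolved_columns(aln, [True, False, True, False])
        assert out.rows == [("a", "AD"), ("b", "A-")]

    def test_length_mismatch_errors(self):
        aln = Alignment(rows=[("a", "ACDE")])
        with pytest.raises(ValueError):
            mask_unresolved_columns(aln, [True, True])


class TestSuperfamilyAlign:
    def test_every_survivor_appears_once(self, workflow_superfamily):
        sf = workflow_superfamily
        seed, _ = seed_from_family(sf)
        aln = superfamily_align(seed, None, family_clusters(sf), sf.records)
        assert sorted(aln.ids) == sorted(r.id for r in sf.records)

    def test_byte_identical_reruns(self, workflow_superfamily, tmp_path):
        from serpintools.core_io import write_alignment

        sf = workflow_superfamily
        seed, _ = seed_from_family(sf)
        clusters = family_clusters(sf)
        p1, p2 = tmp_path / "a1.fasta", tmp_path / "a2.fasta"
        write_alignment(superfamily_align(seed, None, clusters, sf.records), p1)
        write_alignment(superfamily_align(seed, None, clusters, sf.records), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_column_count_equals_enriched_match_states(self,
                                                       workflow_superfamily):
        sf = workflow_superfamily
        seed, _ = seed_from_family(sf)
        res = superfamily_align_detailed(seed, None, family_clusters(sf),
                                         sf.records)
        assert res.alignment.column_count == len(res.enriched_profile)

    def test_homology_recovery_for_near_consensus_sequences(
            self, workflow_superfamily):
        sf = workflow_superfamily
        seed, sites = seed_from_family(sf)
        res = superfamily_align_detailed(seed, None, family_clusters(sf),
                                         sf.records)
        eligible = near_consensus_ids(sf, max_substitutions=2)
        assert len(eligible) >= 3
        recovery = column_homology_recovery(sf, res, sites, eligible)
        assert recovery >= 0.9

    def test_monotonicity_duplicated_row_score(self, workflow_superfamily):
        sf = workflow_superfamily
        seed, _ = seed_from_family(sf)
        rid, row = seed.rows[0]
        rec = SequenceRecord(rid, "".join(c for c in row if c != "-"))
        base = score_sequence(build_profile(seed), rec).score
        grown = Alignment(rows=seed.rows + [(rid + "_copy", row)])
        boosted = score_sequence(build_profile(grown), rec).score
        assert boosted >= base


class TestProfileSerialization:
    def test_text_round_trip(self, acde_profile, tmp_path):
        p = tmp_path / "profile.txt"
        acde_profile.save(p)
        back = Profile.load(p)
        assert back.match_columns == acde_profile.match_columns
        assert np.array_equal(back.emissions, acde_profile.emissions)
        assert back.transitions == acde_profile.transitions

    def test_unknown_version_rejected(self):
        with pytest.raises(ValueError):
            Profile.from_text("something else\n")
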