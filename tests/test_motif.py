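"""Motif grammar parsing, scanning, curation and redundancy clustering."""

import random

import pytest

from cglrkit.motif import (
    MotifError,
    MotifMatch,
    alignment_identity,
    curate,
    dedupe_cluster,
    parse_pattern,
    scan,
)
from cglrkit.synth import gen_motif_proteome

from oracles import regex_scan_oracle


class TestParse:
    def test_full_active_site_motif_tokenizes_to_13_elements(self, active_site):
        kinds = [e.kind for e in active_site.elements]
        assert kinds == [
            "class", "class", "fixed", "fixed", "gap",
            "class", "class", "class", "class", "gap",
            "class", "class", "class",
        ]
        gaps = [e for e in active_site.elements if e.kind == "gap"]
        assert [(g.min_len, g.max_len) for g in gaps] == [(8, 20), (50, 90)]
        assert active_site.elements[2].residue == "G"
        assert active_site.elements[1].members == frozenset("QT")

    def test_two_token_pattern(self):
        pat = parse_pattern("G[SG]")
        assert [e.kind for e in pat.elements] == ["fixed", "class"]
        assert pat.elements[1].members == frozenset("SG")

    def test_slash_class_and_unicode_dash(self):
        pat = parse_pattern("[E/D]h[E/D]X50–90[E/D]")
        assert pat.elements[0].members == frozenset("DE")
        assert (pat.elements[3].min_len, pat.elements[3].max_len) == (50, 90)

    def test_adjacent_gaps_merge_by_summing_bounds(self):
        pat = parse_pattern("A[X1-2][X3-4]C")
        assert len(pat.elements) == 3
        assert (pat.elements[1].min_len, pat.elements[1].max_len) == (4, 6)

    def test_round_trips_through_canonical_rendering(self, patterns):
        for pat in patterns.values():
            assert parse_pattern(pat.render(), name=pat.name) == pat

    @pytest.mark.parametrize(
        "bad", ["[X3-2]", "", "a", "[]", "h[QT", "G1S", "[X5-90"]
    )
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises((MotifError, ValueError)):
            parse_pattern(bad, class_definitions={"h": "ACFILMVWY"})


class TestScan:
    def test_overlapping_fixed_pattern_placements(self):
        spans = [m.full_span for m in scan("AGSGSA", parse_pattern("GS"))]
        assert spans == [(1, 3), (3, 5)]

    def test_variable_gap_enumerates_both_placements(self):
        matches = scan("AGCAGGC", parse_pattern("A[X1-2]C"))
        assert [m.full_span for m in matches] == [(0, 3), (3, 7)]
        assert matches[0].anchor_spans == ((0, 1), (2, 3))
        assert matches[1].anchor_spans == ((3, 4), (6, 7))

    def test_first_mode_returns_leftmost_only(self):
        matches = scan("AGCAGGC", parse_pattern("A[X1-2]C"), mode="first")
        assert len(matches) == 1 and matches[0].full_span == (0, 3)

    def test_nonstandard_residues_fail_anchors_but_fill_gaps(self):
        # X counts toward the spacer but never satisfies an anchor, even a
        # class anchor spanning all 20 standard residues
        assert [m.full_span for m in scan("AXC", parse_pattern("A[X1-1]C"))] == [(0, 3)]
        assert scan("AXC", parse_pattern("A[ACDEFGHIKLMNPQRSTVWY]C")) == []

    def test_no_match_returns_empty(self):
        assert scan("AAAA", parse_pattern("W")) == []

    def test_matches_regex_enumeration_oracle_on_random_cases(self):
        rng = random.Random(20_260_101)
        from conftest import random_pattern_and_sequence

        for _ in range(60):
            pattern, seq = random_pattern_and_sequence(rng)
            got = {m.anchor_spans for m in scan(seq, pattern)}
            assert got == regex_scan_oracle(seq, pattern)

    def test_position_shift_equivariance(self, active_site):
        proteome = gen_motif_proteome(3, 0, active_site, seed=11)
        for planted in proteome:
            base = {m.anchor_spans for m in scan(planted.sequence, active_site)}
            k = 7
            # a poly-proline prefix cannot start (or extend into) a match
            shifted = {
                m.anchor_spans for m in scan("P" * k + planted.sequence, active_site)
            }
            assert shifted == {
                tuple((s + k, e + k) for s, e in spans) for spans in base
            }

    def test_planted_motifs_recovered_exactly(self, active_site):
        proteome = gen_motif_proteome(20, 20, active_site, seed=3)
        for planted in proteome:
            hits = {m.anchor_spans for m in scan(planted.sequence, active_site)}
            if planted.label == "positive":
                assert planted.anchor_spans in hits
            else:
                assert not hits


class TestCurate:
    FLAGS = {"ntase_helix_bundle_homology": True, "structural_homology": True}

    def _planted_record(self, patterns, seed=0):
        # plant with the inner spacer capped so the catalytic-triad motif
        # (spacer 50-90 measured two residues earlier) is guaranteed too
        pat = parse_pattern(
            "h[QT]GS[X8-20][DE]h[DE]h[X50-88]h[DE]h", name="plant"
        )
        seq = gen_motif_proteome(1, 0, pat, seed=seed)[0].sequence
        return ("rec", "Crassostrea gigas", seq, dict(self.FLAGS))

    def test_planted_motif_with_flags_is_retained(self, patterns):
        [rec] = curate([self._planted_record(patterns)], patterns)
        assert rec.decision == "retained" and rec.reasons == []
        assert rec.matches and all(isinstance(m, MotifMatch) for m in rec.matches)

    def test_motif_free_sequence_lists_every_failed_criterion(self, patterns):
        [rec] = curate([("x", "sp", "PPPPPPPPPP" * 20, dict(self.FLAGS))], patterns)
        assert rec.decision == "excluded"
        assert "active site absent" in rec.reasons
        assert "catalytic triad absent" in rec.reasons

    def test_false_external_flag_excludes(self, patterns):
        rid, sp, seq, flags = self._planted_record(patterns)
        flags["structural_homology"] = False
        [rec] = curate([(rid, sp, seq, flags)], patterns)
        assert rec.decision == "excluded"
        assert rec.reasons == ["structural_homology flag false"]

    def test_missing_flag_raises_naming_the_record(self, patterns):
        with pytest.raises(MotifError, match="rec7"):
            curate([("rec7", "sp", "ACDEFGHIKL", {"structural_homology": True})],
                   patterns)

    def test_batch_decisions_match_construction_truth(self, patterns):
        rng = random.Random(5)
        records, truth = [], []
        for i in range(40):
            rid = f"r{i:03d}"
            planted = rng.random() < 0.5
            flags_ok = rng.random() < 0.7
            flags = {
                "ntase_helix_bundle_homology": flags_ok,
                "structural_homology": True,
            }
            if planted:
                _, _, seq, _ = self._planted_record(patterns, seed=1000 + i)
            else:
                seq = gen_motif_proteome(
                    0, 1, patterns["active_site"], seed=2000 + i
                )[0].sequence
            records.append((rid, "sp", seq, flags))
            truth.append(planted and flags_ok)
        decided = curate(records, patterns)
        got = [r.decision == "retained" for r in decided]
        assert got == truth
        # order independence: same decisions on reversed input
        rev = {r.sequence_id: r.decision for r in curate(records[::-1], patterns)}
        assert all(rev[r.sequence_id] == r.decision for r in decided)

    def test_relaxed_criterion_set(self, patterns):
        seq = gen_motif_proteome(1, 0, parse_pattern("G[SG]"), seed=1)[0].sequence
        [rec] = curate(
            [("r", "sp", seq, dict(self.FLAGS))],
            patterns,
            required_motifs=("activation_loop",),
        )
        assert rec.decision == "retained"


class TestDedupe:
    def test_identical_sequences_share_a_cluster(self):
        clusters = dedupe_cluster([("a", "MKVLW" * 20), ("b", "MKVLW" * 20)])
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == ["a", "b"]

    def test_ninety_percent_identity_splits_at_095(self):
        rng = random.Random(2)
        base = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(100))
        positions = rng.sample(range(100), 10)
        mutated = list(base)
        for p in positions:
            mutated[p] = "W" if base[p] != "W" else "Y"
        mutated = "".join(mutated)
        assert alignment_identity(base, mutated) == pytest.approx(0.90)
        assert len(dedupe_cluster([("a", base), ("b", mutated)], 0.95, 1.0)) == 2
        assert len(dedupe_cluster([("a", base), ("b", mutated)], 0.85, 1.0)) == 1

    def test_mutation_clouds_recovered_as_clusters(self):
        rng = random.Random(7)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        seqs = []
        for c in range(3):
            centroid = "".join(rng.choice(alphabet) for _ in range(200))
            for i in range(4):
                s = list(centroid)
                for p in rng.sample(range(200), 4):  # 2% divergence
                    s[p] = rng.choice(alphabet.replace(s[p], ""))
                seqs.append((f"c{c}_{i}", "".join(s)))
        clusters = dedupe_cluster(seqs, 0.95, 1.0)
        assert len(clusters) == 3
        for cluster in clusters:
            prefixes = {m.split("_")[0] for m in cluster.member_ids}
            assert len(prefixes) == 1

    def test_exact_threshold_partitions_into_duplicate_groups(self):
        seqs = [("a", "MKVL"), ("b", "MKVL"), ("c", "MKVI"), ("d", "MKVL")]
        clusters = dedupe_cluster(seqs, 1.0, 1.0)
        groups = {frozenset(c.member_ids) for c in clusters}
        assert groups == {frozenset({"a", "b", "d"}), frozenset({"c"})}

    def test_empty_input(self):
        assert dedupe_cluster([]) == []
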