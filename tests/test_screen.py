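"""Radiolabel/CIP/P1/mass signature prediction and product inference."""

from itertools import combinations

import pytest

from cglrkit.cdn import parse_name
from cglrkit.screen import (
    LOST,
    RETAINED,
    ObservationError,
    ScreenObservation,
    distinguishability_report,
    full_observation,
    infer_product,
    predict_signature,
    signature_partition,
)
from cglrkit.synth import gen_screen_observation


class TestPredictSignature:
    def test_canonical_cua_loses_both_labels(self):
        sig = predict_signature(parse_name("3'3'-cUA"))
        assert sig.labels == frozenset("AU")
        assert sig.cip_resistant
        assert sig.p1_retention == {"A": LOST, "U": LOST}

    def test_fully_protected_homodimer_retains(self):
        sig = predict_signature(parse_name("2'2'-c-di-AMP"))
        assert sig.p1_retention == {"A": RETAINED}

    def test_mixed_linkage_cua_retains_adenosine_only(self):
        # per the chemical name c[U(2',5')pA(3',5')p], A's alpha-phosphate
        # sits in the P1-protected 2'-5' bond donated by uridine
        sig = predict_signature(parse_name("2'3'-cUA"))
        assert sig.p1_retention == {"A": RETAINED, "U": LOST}

    def test_linkage_retention_classes(self, all_candidates):
        for cand in all_candidates:
            donors = sorted(u.donor for u in cand.units)
            states = set(predict_signature(cand).p1_retention.values())
            if donors == [3, 3]:
                assert states == {LOST}
            elif donors == [2, 2]:
                assert states == {RETAINED}
            elif not cand.is_homodimer:  # mixed heterodimer: exactly one kept
                assert states == {RETAINED, LOST}

    def test_labels_equal_base_set(self, all_candidates):
        for cand in all_candidates:
            sig = predict_signature(cand)
            assert sig.labels == cand.bases
            assert set(sig.p1_retention) == set(sig.labels)


class TestInferProduct:
    def test_sp_cglr1_style_observation_pins_canonical_cua(self, all_candidates):
        obs = ScreenObservation(
            labels_incorporated=frozenset("AU"),
            cip_resistant=True,
            p1_retention={"A": LOST, "U": LOST},
            observed_mz=[(634.0, "[M-H]-")],
        )
        assert infer_product(obs, all_candidates).names == ["3′3′-cUA"]

    def test_retention_pattern_alone_pins_mixed_cua(self, all_candidates):
        obs = ScreenObservation(
            labels_incorporated=frozenset("AU"),
            p1_retention={"A": RETAINED, "U": LOST},
        )
        assert infer_product(obs, all_candidates).names == ["2′3′-cUA"]

    def test_labels_only_observation_keeps_all_isomers(self, all_candidates):
        obs = ScreenObservation(labels_incorporated=frozenset("AU"))
        assert len(infer_product(obs, all_candidates)) == 4

    def test_empty_observation_returns_every_candidate(self, all_candidates):
        assert len(infer_product(ScreenObservation(), all_candidates)) == 36
        got = infer_product(
            ScreenObservation(labels_incorporated=frozenset("G")), all_candidates
        )
        assert len(got) == 3

    def test_substrate_dependency_consistency(self, all_candidates):
        obs = ScreenObservation(
            labels_incorporated=frozenset("AU"),
            substrate_dependency=frozenset(
                {frozenset("AU"), frozenset("AUG"), frozenset("ACGU")}
            ),
        )
        assert len(infer_product(obs, all_candidates)) == 4

    def test_impossible_observation_reports_closest_candidate(self, all_candidates):
        obs = ScreenObservation(
            labels_incorporated=frozenset("AU"),
            cip_resistant=False,  # no cyclic product is CIP-sensitive
        )
        result = infer_product(obs, all_candidates)
        assert len(result) == 0
        assert result.diagnostic is not None and "closest" in result.diagnostic

    def test_inconsistent_observation_raises(self):
        with pytest.raises(ObservationError):
            ScreenObservation(
                labels_incorporated=frozenset("A"),
                p1_retention={"G": RETAINED},
            )


class TestRoundTripAndMonotonicity:
    def test_full_signature_round_trip_and_degeneracy_consistency(
        self, all_candidates
    ):
        degenerate = {
            cand
            for group in distinguishability_report(all_candidates)
            for cand in group
        }
        for cand in all_candidates:
            result = infer_product(full_observation(cand), all_candidates)
            assert cand in result.consistent
            if cand in degenerate:
                assert len(result) > 1
            else:
                assert result.names == [cand.name]

    def test_adding_evidence_never_enlarges_consistent_set(self, all_candidates):
        fields = ("cip", "p1", "mass")
        for cand in all_candidates[::5]:
            sets = {}
            for r in range(len(fields) + 1):
                for chosen in combinations(fields, r):
                    obs = gen_screen_observation(cand, set(chosen) | {"labels"})
                    sets[chosen] = frozenset(
                        infer_product(obs, all_candidates).names
                    )
            for small, big_set in sets.items():
                for extra in set(fields) - set(small):
                    larger = tuple(f for f in fields if f in set(small) | {extra})
                    assert sets[larger] <= big_set


class TestDistinguishability:
    def test_mass_only_groups_by_molecular_formula(self, all_candidates):
        groups = distinguishability_report(all_candidates, assays=["mass"])
        assert len(groups) == 10
        assert sum(len(g) for g in groups) == 36

    def test_labels_only_groups_by_base_composition(self, all_candidates):
        groups = distinguishability_report(all_candidates, assays=["labels"])
        assert len(groups) == 10
        for group in groups:
            assert len({c.bases for c in group}) == 1

    def test_full_panel_leaves_only_mixed_homodimer_pairs(self, all_candidates):
        groups = distinguishability_report(all_candidates)
        assert [[c.name for c in g] for g in groups] == [
            ["2′2′-c-di-AMP", "2′3′-c-di-AMP"],
            ["2′2′-c-di-CMP", "2′3′-c-di-CMP"],
            ["2′2′-c-di-GMP", "2′3′-c-di-GMP"],
            ["2′2′-c-di-UMP", "2′3′-c-di-UMP"],
        ]
        # heterodimer linkage isomers are all fully resolved
        resolved = [
            g[0] for g in signature_partition(all_candidates) if len(g) == 1
        ]
        assert all(not c.is_homodimer or sorted(
            u.donor for u in c.units) == [3, 3] for c in resolved)

    def test_empty_assay_panel_rejected(self, all_candidates):
        with pytest.raises(ValueError):
            distinguishability_report(all_candidates, assays=[])
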