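"""Canonicalization, pair scoring (against a brute-force DP oracle), and
tiered matching against the bundled lexicon."""

import pytest
from hypothesis import given, settings, strategies as st

from drugnorm.fixtures import variant_frequency_table
from drugnorm.normalize import (
    AMBIGUOUS,
    MATCHED,
    UNMATCHED,
    MatchCandidate,
    MatchConfig,
    Matcher,
    canonicalize,
    map_batch,
    match_name,
    score_pair,
)


def levenshtein_oracle(a: str, b: str) -> int:
    """Independent dynamic-programming edit distance (unit costs)."""
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(
                min(previous[j] + 1, current[j - 1] + 1, previous[j - 1] + (ca != cb))
            )
        previous = current
    return previous[len(b)]


raw_names = st.text(
    alphabet=st.sampled_from("abcdefghij /-+?.()[]HCL"), min_size=0, max_size=40
)
canonical_tokens = st.lists(
    st.text(alphabet=st.sampled_from("abcdefgh"), min_size=1, max_size=8),
    min_size=0,
    max_size=5,
)


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("oxycodone-aspirin", "aspirin oxycodone"),
            ("aspirin/oxycodone", "aspirin oxycodone"),
            ("Methadone HCL", "hydrochloride methadone"),
            ("", ""),
            ("aspirin w/oxycodone", "aspirin oxycodone"),
            ("oxycodone with aspirin", "aspirin oxycodone"),
            ("aspirin + oxycodone", "aspirin oxycodone"),
            ("methadone hydrochloride.", "hydrochloride methadone"),
            ("methadone ap?hp", "ap hp methadone"),
            ("ketalgin (methadone)", "ketalgin"),
            ("methadone [methadone hydrochloride]", "methadone"),
            ("oxycodone and asa", "aspirin oxycodone"),
        ],
    )
    def test_rules(self, raw, expected):
        assert canonicalize(raw) == expected

    @settings(derandomize=True, max_examples=300)
    @given(raw_names)
    def test_idempotent(self, raw):
        once = canonicalize(raw)
        assert canonicalize(once) == once

    def test_all_tabled_aspirin_oxycodone_variants_share_one_canonical_form(self):
        names = variant_frequency_table(214256)["raw_name"]
        forms = {canonicalize(n) for n in names}
        # the numeric-code and truncated-stem variants keep distinct canonical
        # forms (they match via verbatim synonymy); everything else collapses
        assert forms == {
            "aspirin oxycodone",
            "00554201 aspirin oxycodone",
            "aspirin oxycod",
        }


class TestScorePair:
    @pytest.mark.parametrize("text", ["aspirin oxycodone", "x", "hydrochloride methadone"])
    def test_identity_scores_one(self, text):
        assert score_pair(text, text) == 1.0

    def test_both_empty_is_zero(self):
        assert score_pair("", "") == 0.0

    def test_single_edit_two_token_example(self):
        # J = 1/3, D = 1, maxlen = 23 -> 0.5/3 + 0.5 * 22/23
        score = score_pair("hydrochloride methadon", "hydrochloride methadone")
        assert score == pytest.approx(0.5 * (1 / 3) + 0.5 * (22 / 23))
        assert round(score, 3) == 0.645

    def test_disjoint_short_names(self):
        assert score_pair("codeine", "fentanyl") == pytest.approx(0.0625)

    @settings(derandomize=True, max_examples=200)
    @given(canonical_tokens, canonical_tokens)
    def test_symmetric_bounded_and_matches_dp_oracle(self, tokens_a, tokens_b):
        a, b = " ".join(sorted(tokens_a)), " ".join(sorted(tokens_b))
        score = score_pair(a, b)
        assert score == pytest.approx(score_pair(b, a))
        assert 0.0 <= score <= 1.0
        if a or b:
            set_a, set_b = set(a.split()), set(b.split())
            jaccard = len(set_a & set_b) / len(set_a | set_b)
            expected = 0.5 * jaccard + 0.5 * (
                1 - levenshtein_oracle(a, b) / max(len(a), len(b))
            )
            assert score == pytest.approx(expected)
            assert (score == 1.0) == (a == b)


class TestMatchName:
    def test_exact_tier_on_preferred_name(self, opioid_lexicon):
        result = match_name("belbuca", opioid_lexicon)
        assert result.status == MATCHED
        assert result.accepted == (1716058,)
        assert result.candidates[0].tier == "exact"
        assert result.candidates[0].score == 1.0

    def test_exact_tier_is_case_insensitive(self, opioid_matcher):
        result = opioid_matcher.match("BELBUCA")
        assert result.accepted == (1716058,)
        assert result.candidates[0].tier == "exact"

    def test_tabled_variant_matches_its_concept(self, opioid_matcher):
        result = opioid_matcher.match("methadone hcl")
        assert result.status == MATCHED
        assert result.accepted == (218337,)

    def test_canonical_tier_for_unseen_reordering(self, opioid_matcher):
        result = opioid_matcher.match("Naloxone/Buprenorphine")
        assert result.status == MATCHED
        assert result.accepted == (352364,)
        assert result.candidates[0].tier == "canonical"

    def test_approximate_tier_for_single_edit_misspelling(self, opioid_matcher):
        result = opioid_matcher.match("methadnne hcl")
        assert result.status == MATCHED
        assert result.accepted == (218337,)
        assert result.candidates[0].tier == "approximate"

    def test_gibberish_is_unmatched(self, opioid_matcher):
        result = opioid_matcher.match("zzzzqx")
        assert result.status == UNMATCHED
        assert result.accepted == ()
        assert result.candidates == ()

    def test_empty_name_is_unmatched(self, opioid_matcher):
        result = opioid_matcher.match("")
        assert result.status == UNMATCHED

    def test_whole_lexicon_closure_every_synonym_exact(self, opioid_lexicon, opioid_matcher):
        for term, _type, cid in opioid_lexicon.iter_terms():
            result = opioid_matcher.match(term)
            assert result.status == MATCHED
            assert result.accepted == (cid,)
            assert result.candidates[0].tier == "exact"
            assert result.candidates[0].score == 1.0

    def test_raising_min_score_never_adds_accepted_matches(self, opioid_lexicon):
        queries = ["methadnne hcl", "oxycodome", "zzzzqx", "belbuca", "fentanil"]
        thresholds = [0.2, 0.4, 0.6, 0.8, 1.0]
        for query in queries:
            accepted_sets = [
                set(match_name(query, opioid_lexicon, MatchConfig(min_score=t)).accepted)
                for t in thresholds
            ]
            for lower, higher in zip(accepted_sets, accepted_sets[1:]):
                assert higher <= lower

    def test_tie_between_distinct_concepts_is_ambiguous(self):
        import io
        from drugnorm.lexicon import read_lexicon

        lexicon = read_lexicon(io.StringIO("1|abcd xy|preferred\n2|abcd xz|preferred\n"))
        result = match_name("abcd xq", lexicon, MatchConfig(min_score=0.2))
        # equidistant from both synonyms -> both accepted, reported ambiguous
        assert result.status == AMBIGUOUS
        assert set(result.accepted) == {1, 2}


class TestMatchCandidate:
    def test_exact_tier_requires_score_one(self):
        with pytest.raises(ValueError):
            MatchCandidate(concept_id=1, score=0.9, tier="exact")

    def test_sort_order_tier_then_score_then_id(self):
        candidates = sorted(
            [
                MatchCandidate(concept_id=5, score=0.7, tier="approximate"),
                MatchCandidate(concept_id=2, score=0.9, tier="approximate"),
                MatchCandidate(concept_id=9, score=1.0, tier="exact"),
                MatchCandidate(concept_id=1, score=0.9, tier="approximate"),
            ]
        )
        assert [c.concept_id for c in candidates] == [9, 1, 2, 5]


class TestMapBatch:
    def test_all_tabled_names_map_to_aspirin_oxycodone(self, opioid_lexicon):
        names = list(variant_frequency_table(214256)["raw_name"])
        table = map_batch(names, opioid_lexicon)
        assert len(table) == 12
        assert (table["status"] == MATCHED).all()
        assert (table["concept_id"] == 214256).all()

    def test_empty_input_gives_empty_table(self, opioid_lexicon):
        table = map_batch([], opioid_lexicon)
        assert len(table) == 0
        assert list(table.columns) == [
            "raw_name", "concept_id", "preferred_name", "status", "score", "tier",
        ]

    def test_mixed_matched_and_unmatched(self, opioid_lexicon):
        table = map_batch(["belbuca", "zzzzqx"], opioid_lexicon)
        assert list(table["status"]) == [MATCHED, UNMATCHED]
        assert table["concept_id"].isna().tolist() == [False, True]

    def test_duplicates_collapse_to_one_row(self, opioid_lexicon):
        table = map_batch(["belbuca", "belbuca", "actiq"], opioid_lexicon)
        assert list(table["raw_name"]) == ["belbuca", "actiq"]

    def test_override_takes_precedence(self, opioid_lexicon):
        table = map_batch(["belbuca"], opioid_lexicon, overrides={"belbuca": 218337})
        assert table.loc[0, "concept_id"] == 218337
        assert table.loc[0, "tier"] == "override"

    def test_override_with_unknown_concept_rejected(self, opioid_lexicon):
        with pytest.raises(ValueError, match="not in lexicon"):
            map_batch(["belbuca"], opioid_lexicon, overrides={"belbuca": 999999999})
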