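"""Dynamic-programming alignment, decoys, and target-decoy FDR."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinseq import (
    AlignmentParams,
    ConfigurationError,
    Peptide,
    RSSummary,
    assign_and_fdr,
    build_reference_profile,
    expected_rs_sequence,
    make_decoys,
    score_alignment,
)
from kinseq.reference import ProfileStep, ReferenceProfile


def _rs(recognizer, mean_pd, index=0, aperture=0):
    return RSSummary(aperture_id=aperture, rs_index=index, dye=f"dye-{recognizer}",
                     recognizer=recognizer, n_pulses=10, mean_pd=mean_pd,
                     median_pd=mean_pd, rs_start=float(index))


def _profile(recognizers_pds, label="ref", is_decoy=False):
    """Profile from a list of (recognizer, expected_pd) recognition steps."""
    steps = tuple(
        ProfileStep(position=i + 1, residue="A", recognizer=rec,
                    expected_pd=pd, expected_binding_prob=0.9)
        for i, (rec, pd) in enumerate(recognizers_pds)
    )
    # sequence content is irrelevant to scoring; use a placeholder peptide
    pep = Peptide(sequence="A" * max(len(recognizers_pds), 1), label=label)
    return ReferenceProfile(peptide=pep, steps=steps, is_decoy=is_decoy)


def _read_matching(profile):
    return [
        _rs(step.recognizer, step.expected_pd, index=i)
        for i, step in enumerate(profile.recognition_steps())
    ]


def brute_force_score(rs_list, profile, params):
    """Independent enumeration oracle: maximum over all monotone pairings,
    penalizing unmatched items before the last matched index on each side
    (trailing unmatched items are free)."""
    steps = profile.recognition_steps()
    m, n = len(rs_list), len(steps)
    best = 0.0  # empty matching
    for k in range(1, min(m, n) + 1):
        for ri in itertools.combinations(range(m), k):
            for sj in itertools.combinations(range(n), k):
                s = 0.0
                for i, j in zip(ri, sj):
                    rs, step = rs_list[i], steps[j]
                    if rs.recognizer == step.recognizer:
                        s += params.match_bonus - params.pd_weight * abs(
                            math.log(rs.mean_pd / step.expected_pd)
                        )
                    else:
                        s += params.mismatch_penalty
                s += params.spurious_rs_penalty * (ri[-1] + 1 - k)
                s += params.missed_rs_penalty * (sj[-1] + 1 - k)
                best = max(best, s)
    return best


class TestScoring:
    def test_identity_alignment_scores_match_bonus_per_step(self, table, peptides):
        profile = build_reference_profile(peptides["ENALDRAEQAEADK"], table)
        read = _read_matching(profile)
        params = AlignmentParams()
        result = score_alignment(read, profile, params)
        n = len(profile.recognition_steps())
        assert result.score == pytest.approx(params.match_bonus * n)
        assert len(result.pairs) == n
        assert [p for _, p in result.pairs] == [
            s.position for s in profile.recognition_steps()
        ]

    def test_own_profile_beats_isobaric_sibling_via_pd_term(self, table, peptides):
        """A noiseless read from the Leu-bearing peptide outscores the
        Ile-bearing profile by exactly the position-4 kinetic term."""
        prof_l = build_reference_profile(peptides["ENALDRAEQAEADK"], table)
        prof_i = build_reference_profile(peptides["ENAIDRAEQAEADK"], table)
        read = _read_matching(prof_l)
        params = AlignmentParams()
        s_own = score_alignment(read, prof_l, params).score
        s_other = score_alignment(read, prof_i, params).score
        assert s_own > s_other
        assert s_own - s_other == pytest.approx(
            params.pd_weight * abs(math.log(0.35 / 0.23))
        )

    def test_empty_read_scores_zero(self, table, peptides):
        profile = build_reference_profile(peptides["VIESRAQK"], table)
        assert score_alignment([], profile).score == 0.0

    def test_truncated_read_pays_no_trailing_penalty(self, table, peptides):
        profile = build_reference_profile(peptides["ENALDRAEQAEADK"], table)
        params = AlignmentParams()
        full = _read_matching(profile)
        truncated = full[:4]
        s = score_alignment(truncated, profile, params).score
        assert s == pytest.approx(params.match_bonus * 4)

    @given(
        m=st.integers(0, 6),
        n=st.integers(1, 6),
        seed=st.integers(0, 10_000),
    )
    def test_dp_equals_bruteforce_enumeration(self, m, n, seed):
        rng = np.random.default_rng(seed)
        recognizers = ["LIV", "NQ", "E"]
        read = [
            _rs(recognizers[rng.integers(3)], float(rng.uniform(0.05, 2.0)), i)
            for i in range(m)
        ]
        profile = _profile([
            (recognizers[rng.integers(3)], float(rng.uniform(0.05, 2.0)))
            for _ in range(n)
        ])
        params = AlignmentParams(
            match_bonus=float(rng.uniform(0.5, 3.0)),
            mismatch_penalty=-float(rng.uniform(0.5, 4.0)),
            missed_rs_penalty=-float(rng.uniform(0.1, 2.0)),
            spurious_rs_penalty=-float(rng.uniform(0.1, 2.0)),
            pd_weight=float(rng.uniform(0.0, 2.0)),
        )
        dp = score_alignment(read, profile, params).score
        assert dp == pytest.approx(brute_force_score(read, profile, params))


class TestDecoys:
    def test_decoys_preserve_composition_and_terminal_lysine(self, table, peptides):
        refs = [build_reference_profile(peptides[l], table)
                for l in ("ENALDRAEQAEADK", "ENAIDRAEQAEADK")]
        decoys = make_decoys(refs, table, seed=1)
        assert len(decoys) == len(refs)
        target_rs = {tuple(expected_rs_sequence(r)) for r in refs}
        for ref, decoy in zip(refs, decoys):
            assert decoy.is_decoy
            assert decoy.peptide.sequence.endswith("K")
            assert sorted(decoy.peptide.sequence) == sorted(ref.peptide.sequence)
            assert decoy.peptide.sequence != ref.peptide.sequence
            assert tuple(expected_rs_sequence(decoy)) not in target_rs

    def test_decoy_of_phosphopeptide_keeps_its_ptm(self, table, peptides):
        refs = [build_reference_profile(peptides["TIDDLEDEVpYAQK"], table)]
        (decoy,) = make_decoys(refs, table, seed=2)
        assert len(decoy.peptide.ptms) == 1
        pos, name = decoy.peptide.ptms[0]
        assert name == "phospho" and decoy.peptide.sequence[pos - 1] == "Y"

    def test_too_short_peptide_raises(self, table):
        refs = [build_reference_profile(Peptide(sequence="LK"), table)]
        with pytest.raises(ConfigurationError, match="permutable"):
            make_decoys(refs, table, seed=0)


class TestAssignmentAndFDR:
    def test_decoy_free_run_has_zero_q_values(self, table, peptides):
        profile = build_reference_profile(peptides["VIESRAQK"], table)
        reads = {ap: _read_matching(profile) for ap in range(5)}
        results = assign_and_fdr(reads, [profile], [])
        assert all(r.q_value == 0.0 for r in results)
        assert all(r.best_reference == profile.label for r in results)

    def test_decoy_dominated_run_reaches_q_of_one(self, table):
        target = _profile([("LIV", 0.3), ("E", 0.2)], label="target")
        decoy = _profile([("NQ", 1.0), ("R", 0.2)], label="decoy", is_decoy=True)
        reads = {ap: _read_matching(decoy) for ap in range(5)}
        results = assign_and_fdr(reads, [target], [decoy])
        assert all(r.is_decoy for r in results)
        assert max(r.q_value for r in results) == 1.0

    def test_q_values_monotone_nonincreasing_in_score(self, table, peptides):
        rng = np.random.default_rng(21)
        prof_a = build_reference_profile(peptides["ENALDRAEQAEADK"], table)
        prof_b = build_reference_profile(peptides["ENAIDRAEQAEADK"], table)
        decoys = make_decoys([prof_a, prof_b], table, seed=3)
        reads = {}
        for ap in range(40):
            base = prof_a if ap % 2 else prof_b
            rs = [
                _rs(step.recognizer,
                    float(step.expected_pd * rng.lognormal(0, 0.4)), i, ap)
                for i, step in enumerate(base.recognition_steps())
                if rng.random() > 0.2
            ]
            if rs:
                reads[ap] = rs
        results = assign_and_fdr(reads, [prof_a, prof_b], decoys)
        ranked = sorted(results, key=lambda r: -r.score)
        qs = [r.q_value for r in ranked]
        assert all(q1 <= q2 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.score >= r.second_score for r in results)

    def test_assignment_invariant_to_candidate_order(self, table, peptides):
        rng = np.random.default_rng(22)
        prof_a = build_reference_profile(peptides["VIENRAMK"], table)
        prof_b = build_reference_profile(peptides["VIESRAQK"], table)
        reads = {}
        for ap in range(20):
            base = prof_a if ap % 2 else prof_b
            reads[ap] = [
                _rs(step.recognizer,
                    float(step.expected_pd * rng.lognormal(0, 0.3)), i, ap)
                for i, step in enumerate(base.recognition_steps())
            ]
        fwd = assign_and_fdr(reads, [prof_a, prof_b], [])
        rev = assign_and_fdr(reads, [prof_b, prof_a], [])
        assert [r.best_reference for r in fwd] == [r.best_reference for r in rev]

    def test_swapping_profiles_swaps_winners(self, table, peptides):
        """Discrimination is anti-symmetric: reads built from profile A win
        under A and the same construction from B wins under B."""
        prof_a = build_reference_profile(peptides["ENALDRAEQAEADK"], table)
        prof_b = build_reference_profile(peptides["ENAIDRAEQAEADK"], table)
        read_a, read_b = _read_matching(prof_a), _read_matching(prof_b)
        res = assign_and_fdr({0: read_a, 1: read_b}, [prof_a, prof_b], [])
        by_ap = {r.aperture_id: r.best_reference for r in res}
        assert by_ap == {0: prof_a.label, 1: prof_b.label}
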