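"""Kinetic-profile alignment and target-decoy FDR.

A read is an ordered list of recognition segments; a reference profile is the
ordered list of non-dark steps expected for a peptide.  The two are aligned
by global dynamic programming over monotone pairings: an aligned (RS, step)
pair scores ``match_bonus`` when the recognizers agree, minus
``pd_weight * |ln(observed mean PD / expected PD)|`` -- a scale-free,
symmetric kinetic agreement term -- or ``mismatch_penalty`` when they
disagree; an unmatched reference step costs ``missed_rs_penalty`` and an
unmatched read RS ``spurious_rs_penalty``.  Trailing unmatched items on
either side are free (reads truncate; segmentation can also fragment the
tail), leading/internal gaps are not.

Each read is assigned to the highest-scoring candidate among the target
profiles and one shuffled decoy per target; the decoy score distribution
estimates the false-match rate, and each read receives the standard
target-decoy q-value (#decoy matches at or above its score over #target
matches, monotonized).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .reference import (
    ConfigurationError,
    Peptide,
    RecognizerTable,
    ReferenceProfile,
    build_reference_profile,
    expected_rs_sequence,
)
from .primary import RSSummary


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring constants for the kinetic-profile DP."""

    match_bonus: float = 2.0
    mismatch_penalty: float = -3.0
    missed_rs_penalty: float = -1.0
    spurious_rs_penalty: float = -1.0
    pd_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.match_bonus < 0:
            raise ConfigurationError("match_bonus must be >= 0")
        for p in (self.mismatch_penalty, self.missed_rs_penalty,
                  self.spurious_rs_penalty):
            if p > 0:
                raise ConfigurationError("penalties must be <= 0")
        if self.pd_weight < 0:
            raise ConfigurationError("pd_weight must be >= 0")


@dataclass(frozen=True)
class AlignmentScore:
    """DP result: total score and the traceback as (rs_index, reference
    position) pairs in alignment order."""

    score: float
    pairs: tuple


@dataclass(frozen=True)
class AlignmentResult:
    """Best-reference assignment of one read with its target-decoy q-value."""

    aperture_id: int
    best_reference: str
    score: float
    second_score: float
    is_decoy: bool
    q_value: float
    pairs: tuple = ()


def _pair_score(rs: RSSummary, step, params: AlignmentParams) -> float:
    if rs.recognizer != step.recognizer:
        return params.mismatch_penalty
    return params.match_bonus - params.pd_weight * abs(
        math.log(rs.mean_pd / step.expected_pd)
    )


def score_alignment(rs_list: Sequence[RSSummary], profile: ReferenceProfile,
                    params: Optional[AlignmentParams] = None) -> AlignmentScore:
    """Align a read's RS sequence to a reference profile.

    Returns the optimal score over all monotone pairings (with free trailing
    gaps on both sides) and its traceback.  An empty read or an all-dark
    profile scores 0 with no pairs.
    """
    params = params or AlignmentParams()
    steps = profile.recognition_steps()
    m, n = len(rs_list), len(steps)
    if m == 0 or n == 0:
        return AlignmentScore(score=0.0, pairs=())

    # S[i][j]: best score consuming first i RSs and first j steps;
    # ptr: 0 diag, 1 up (spurious RS), 2 left (missed step)
    S = np.empty((m + 1, n + 1))
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    S[0, 0] = 0.0
    for i in range(1, m + 1):
        S[i, 0] = i * params.spurious_rs_penalty
        ptr[i, 0] = 1
    for j in range(1, n + 1):
        S[0, j] = j * params.missed_rs_penalty
        ptr[0, j] = 2
    for i in range(1, m + 1):
        rs = rs_list[i - 1]
        for j in range(1, n + 1):
            diag = S[i - 1, j - 1] + _pair_score(rs, steps[j - 1], params)
            up = S[i - 1, j] + params.spurious_rs_penalty
            left = S[i, j - 1] + params.missed_rs_penalty
            best = diag
            p = 0
            if up > best:
                best, p = up, 1
            if left > best:
                best, p = left, 2
            S[i, j] = best
            ptr[i, j] = p

    # free trailing gaps on both sides: end anywhere
    bi, bj = np.unravel_index(int(np.argmax(S)), S.shape)
    score = float(S[bi, bj])
    pairs: List[Tuple[int, int]] = []
    i, j = int(bi), int(bj)
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            pairs.append((i - 1, steps[j - 1].position))
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return AlignmentScore(score=score, pairs=tuple(pairs))


def _mergeable_pairs(sequence: str, table: RecognizerTable) -> int:
    """Number of consecutive same-recognizer residue pairs not separated by a
    dark residue.  Such pairs fuse into one recognition segment downstream
    (no silent cleavage gap splits them), so this count shapes how many RSs a
    peptide's reads actually show."""
    count = 0
    prev = None
    for aa in sequence:
        rec = table.recognizer_for(aa)
        if rec is None:
            prev = None  # the dark residue's silent gap splits the run
            continue
        if prev is not None and rec.name == prev:
            count += 1
        prev = rec.name
    return count


def make_decoys(references: Sequence[ReferenceProfile], table: RecognizerTable,
                seed: int, max_tries: int = 2000) -> List[ReferenceProfile]:
    """One shuffled decoy per target reference.

    Internal residues (everything except the anchored C-terminal residue,
    which the library chemistry fixes) are shuffled, carrying any PTM with
    its residue, and resampled until the decoy's expected RS sequence differs
    from every target's.  Decoys are sequence shuffles rather than reversals
    because recognizer content, not residue order alone, drives the score.

    Shuffles are additionally constrained to preserve the target's number of
    mergeable same-recognizer adjacencies: segmentation fuses such runs, so
    an unconstrained shuffle would show systematically fewer recognition
    segments than the target and its score distribution would no longer mimic
    false target matches (the target-decoy estimate would lose calibration).
    The constraint is dropped if no conforming shuffle is found.
    """
    rng = np.random.default_rng(seed)
    target_rs = {tuple(expected_rs_sequence(p)) for p in references}
    target_seqs = {p.peptide.sequence for p in references}
    decoys = []
    for ref in references:
        pep = ref.peptide
        ptm_by_pos = dict(pep.ptms)
        tokens = [(aa, ptm_by_pos.get(i + 1)) for i, aa in enumerate(pep.sequence)]
        head, tail = tokens[:-1], tokens[-1:]
        if len(head) < 2:
            raise ConfigurationError(
                f"peptide {pep.label!r} has fewer than 2 permutable residues"
            )
        target_pairs = _mergeable_pairs(pep.sequence, table)
        chosen = fallback = None
        for _ in range(max_tries):
            perm = [head[k] for k in rng.permutation(len(head))] + tail
            seq = "".join(aa for aa, _ in perm)
            ptms = tuple((i + 1, name) for i, (_, name) in enumerate(perm) if name)
            decoy_pep = Peptide(sequence=seq, ptms=ptms,
                                label=f"decoy_{pep.label}")
            profile = build_reference_profile(decoy_pep, table, is_decoy=True)
            if (tuple(expected_rs_sequence(profile)) in target_rs
                    or seq in target_seqs):
                continue
            if _mergeable_pairs(seq, table) == target_pairs:
                chosen = profile
                break
            fallback = fallback or profile
        chosen = chosen or fallback
        if chosen is None:
            raise ConfigurationError(
                f"could not build a decoy distinct from targets for {pep.label!r}"
            )
        decoys.append(chosen)
    return decoys


def assign_and_fdr(rs_by_read: Mapping[int, Sequence[RSSummary]],
                   references: Sequence[ReferenceProfile],
                   decoys: Sequence[ReferenceProfile],
                   params: Optional[AlignmentParams] = None) -> List[AlignmentResult]:
    """Assign each read to its best-scoring reference and compute q-values.

    Reads with no recognition segment are skipped.  Ties are broken toward a
    target (not a decoy), then lexicographically by label.  The q-value at
    score s is (#decoy best-matches with score >= s) /
    max(1, #target best-matches with score >= s), monotonized so that q is
    nonincreasing in score.  When the decoy set is larger than the target set
    (several shuffles per target sharpen the empirical null), the decoy count
    is scaled by the target/decoy profile ratio before forming the quotient.
    """
    params = params or AlignmentParams()
    profiles = list(references) + list(decoys)
    decoy_ratio = (len(decoys) / len(references)) if references and decoys else 1.0
    prelim = []
    for ap in sorted(rs_by_read):
        rs_list = rs_by_read[ap]
        if not rs_list:
            continue
        scored = [(score_alignment(rs_list, p, params), p) for p in profiles]
        scored.sort(key=lambda t: (-t[0].score, t[1].is_decoy, t[1].label))
        best_aln, best_profile = scored[0]
        second = scored[1][0].score if len(scored) > 1 else float("nan")
        prelim.append((ap, best_profile, best_aln, second))

    # target-decoy q-values over the whole run
    order = sorted(range(len(prelim)), key=lambda k: -prelim[k][2].score)
    n_decoy = n_target = 0
    fdr_at = np.empty(len(prelim))
    for rank, k in enumerate(order):
        if prelim[k][1].is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdr_at[rank] = n_decoy / decoy_ratio / max(1, n_target)
    q_at = np.minimum.accumulate(fdr_at[::-1])[::-1]

    q_by_read = {}
    for rank, k in enumerate(order):
        q_by_read[k] = float(min(q_at[rank], 1.0))

    return [
        AlignmentResult(
            aperture_id=ap,
            best_reference=profile.label,
            score=aln.score,
            second_score=second,
            is_decoy=profile.is_decoy,
            q_value=q_by_read[k],
            pairs=aln.pairs,
        )
        for k, (ap, profile, aln, second) in enumerate(prelim)
    ]


def alignment_results_to_dataframe(results: Sequence[AlignmentResult],
                                   flow_cell_id: str = ""):
    import pandas as pd

    rows = [{
        "flow_cell_id": flow_cell_id,
        "aperture_id": r.aperture_id,
        "best_reference": r.best_reference,
        "score": r.score,
        "second_score": r.second_score,
        "delta": r.score - r.second_score,
        "is_decoy": r.is_decoy,
        "q_value": r.q_value,
    } for r in results]
    return pd.DataFrame(rows, columns=[
        "flow_cell_id", "aperture_id", "best_reference", "score",
        "second_score", "delta", "is_decoy", "q_value",
    ])
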