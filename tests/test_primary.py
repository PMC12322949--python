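"""Dye calling (Gaussian mixture) and recognition-segment extraction."""

import numpy as np
import pytest

from kinseq import (
    ApertureRead,
    DyeModelFitError,
    Peptide,
    SimConfig,
    analyze_run,
    build_reference_profile,
    call_dyes,
    call_read,
    expected_rs_sequence,
    fit_dye_model,
    segment_rs,
    simulate_run,
)
from kinseq.primary import GAP_THRESHOLD_INTERPULSE_MULTIPLE


def _read_from_arrays(table, dyes, starts, durations, aperture_id=0, jitter=0.0,
                      seed=0):
    """Craft an ApertureRead whose pulses sit at (or near) the dye means."""
    rng = np.random.default_rng(seed)
    recs = {r.dye: r for r in table.recognizers}
    dye_names = tuple(table.dyes)
    intensity = np.array([recs[d].dye_intensity_mean for d in dyes])
    lifetime = np.array([recs[d].dye_lifetime_mean for d in dyes])
    if jitter:
        intensity = intensity + rng.normal(0, jitter, len(dyes))
        lifetime = lifetime + rng.normal(0, jitter, len(dyes))
    return ApertureRead(
        aperture_id=aperture_id,
        start=np.asarray(starts, dtype=float),
        duration=np.asarray(durations, dtype=float),
        intensity=intensity,
        lifetime=lifetime,
        true_dye=np.array([dye_names.index(d) for d in dyes], dtype=np.int16),
        true_position=np.zeros(len(dyes), dtype=np.int16),
        dye_names=dye_names,
    )


class TestDyeModel:
    def test_noiseless_pulses_called_with_posterior_one(self, table):
        dye_names = table.dyes
        dyes = [d for d in dye_names for _ in range(20)]
        n = len(dyes)
        read = _read_from_arrays(table, dyes, np.arange(n) * 2.0, np.full(n, 0.1))
        model = fit_dye_model([read], table)
        calls = call_read(model, read)
        assert all(c.dye == dyes[i] for i, c in enumerate(calls))
        assert all(c.posterior > 0.999 for c in calls)

    def test_well_separated_dyes_called_almost_perfectly(self, table):
        """Two dyes >= 6 SD apart on both axes: >= 99% of 1000 noisy pulses
        recover their hidden truth label."""
        rng = np.random.default_rng(11)
        dye_names = table.dyes
        truth = rng.choice([0, 4], size=1000)  # LIV vs E dyes, far apart
        dyes = [dye_names[t] for t in truth]
        read = _read_from_arrays(table, dyes, np.arange(1000) * 2.0,
                                 np.full(1000, 0.1), jitter=0.08, seed=11)
        model = fit_dye_model([read], table)
        labels, _ = call_dyes(model, read)
        assert np.mean(labels == truth) >= 0.99

    def test_single_dye_run_assigns_all_pulses_to_one_component(self, table):
        pep = Peptide(sequence="EG")
        config = SimConfig(library=[(pep, 1.0)], n_apertures=100,
                           loading_prob=1.0, dropout_prob=0.0, seed=12)
        run = simulate_run(config, table)
        model = fit_dye_model(run, table)
        e_dye_idx = table.dyes.index(table.recognizer_for("E").dye)
        for read in run.reads[:20]:
            labels, _ = call_dyes(model, read)
            assert np.all(labels == e_dye_idx)

    def test_too_few_pulses_rejected(self, table):
        read = _read_from_arrays(table, [table.dyes[0]] * 5,
                                 np.arange(5) * 1.0, np.full(5, 0.1))
        with pytest.raises(ValueError, match="at least"):
            fit_dye_model([read], table)

    def test_unidentifiable_clusters_raise_fit_error(self, table):
        """Pulse clusters far from every configured dye cannot be identified
        with the calibration and must fail loudly."""
        rng = np.random.default_rng(13)
        n = 600
        intensity = np.concatenate([rng.normal(40.0, 0.1, n // 2),
                                    rng.normal(80.0, 0.1, n // 2)])
        lifetime = np.concatenate([rng.normal(50.0, 0.1, n // 2),
                                   rng.normal(90.0, 0.1, n // 2)])
        with pytest.raises(DyeModelFitError):
            fit_dye_model((intensity, lifetime), table)


class TestSegmentation:
    def test_dye_change_opens_new_segment(self, table):
        d1, d2 = table.dyes[0], table.dyes[4]
        read = _read_from_arrays(table, [d1, d1, d1, d2, d2, d2],
                                 [0.0, 0.5, 1.0, 1.5, 2.0, 2.5],
                                 np.full(6, 0.2))
        rs = segment_rs(read, read.true_dye, table, gap_threshold=5.0,
                        min_pulses_per_rs=3)
        assert [s.dye for s in rs] == [d1, d2]
        assert [s.n_pulses for s in rs] == [3, 3]

    def test_large_gap_splits_same_dye_pulses(self, table):
        d1 = table.dyes[0]
        starts = [0.0, 0.5, 1.0, 100.0, 100.5, 101.0]
        read = _read_from_arrays(table, [d1] * 6, starts, np.full(6, 0.2))
        rs = segment_rs(read, read.true_dye, table, gap_threshold=5.0,
                        min_pulses_per_rs=3)
        assert [s.dye for s in rs] == [d1, d1]
        assert rs[0].rs_start == 0.0 and rs[1].rs_start == 100.0

    def test_short_segments_are_discarded(self, table):
        d1, d2 = table.dyes[0], table.dyes[4]
        read = _read_from_arrays(table, [d1, d1, d1, d2, d1, d1, d1],
                                 np.arange(7) * 0.5, np.full(7, 0.2))
        rs = segment_rs(read, read.true_dye, table, gap_threshold=5.0,
                        min_pulses_per_rs=3)
        assert [s.dye for s in rs] == [d1, d1]

    def test_summary_statistics_are_per_segment(self, table):
        d1 = table.dyes[0]
        durations = [0.1, 0.2, 0.3]
        read = _read_from_arrays(table, [d1] * 3, [0.0, 1.0, 2.0], durations)
        (rs,) = segment_rs(read, read.true_dye, table, gap_threshold=5.0)
        assert rs.mean_pd == pytest.approx(0.2)
        assert rs.median_pd == pytest.approx(0.2)
        assert rs.n_pulses == 3

    def test_segmentation_partitions_retained_pulses(self, table, peptides):
        pep = peptides["ENALDRAEQAEADK"]
        config = SimConfig(library=[(pep, 1.0)], n_apertures=20,
                           loading_prob=1.0, dropout_prob=0.0, seed=14)
        run = simulate_run(config, table)
        for read in run.reads:
            rs = segment_rs(read, read.true_dye, table, gap_threshold=12.0,
                            min_pulses_per_rs=1)
            # with min_pulses 1 every pulse is retained exactly once
            assert sum(s.n_pulses for s in rs) == read.n_pulses
            # segments are time-ordered and disjoint
            starts = [s.rs_start for s in rs]
            assert starts == sorted(starts)


class TestEndToEnd:
    def test_rs_order_recovers_reference_sequence(self, table_bp1, peptides):
        """With certain binding and default dye noise, the called RS dye order
        reproduces the expected recognizer sequence for nearly every read."""
        pep = peptides["ENALDRAEQAEADK"]
        config = SimConfig(library=[(pep, 1.0)], n_apertures=60,
                           loading_prob=1.0, dropout_prob=0.0, seed=15)
        run = simulate_run(config, table_bp1)
        rs_by_read, _ = analyze_run(run, table_bp1)
        expected = expected_rs_sequence(build_reference_profile(pep, table_bp1))
        observed = [tuple(s.recognizer for s in rs) for rs in rs_by_read.values()]
        matches = sum(1 for seq in observed if list(seq) == expected)
        # short segments (geometric pulse-count tail below min_pulses_per_rs)
        # drop an RS in a minority of reads; the modal signature is exact
        assert matches / len(observed) >= 0.7
        from collections import Counter

        assert list(Counter(observed).most_common(1)[0][0]) == expected

    def test_rs_grouping_matches_hidden_truth(self, table, peptides):
        """The multiset of (dye, pulse count) per read matches the hidden
        per-residue grouping (groups of >= 3 pulses) for >= 95% of reads."""
        pep = peptides["ENALDRAEQAEADK"]
        config = SimConfig(library=[(pep, 1.0)], n_apertures=100,
                           loading_prob=1.0, dropout_prob=0.01, seed=16)
        run = simulate_run(config, table)
        rs_by_read, _ = analyze_run(run, table)
        ok = 0
        for read in run.reads:
            truth = []
            for pos in np.unique(read.true_position):
                mask = read.true_position == pos
                if mask.sum() >= 3:
                    truth.append((int(read.true_dye[mask][0]), int(mask.sum())))
            got = [
                (table.dyes.index(s.dye), s.n_pulses)
                for s in rs_by_read[read.aperture_id]
            ]
            if sorted(truth) == sorted(got):
                ok += 1
        assert ok / len(run.reads) >= 0.95
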