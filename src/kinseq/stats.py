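"""Discrimination statistics: per-position PDs, fold changes, aperture fractions.

Downstream of alignment, the discriminating quantities are (i) the pulse
duration observed at a specific residue position, compared between two
peptides as a fold change with flow cells as the replicate unit, and (ii)
for PTM readout, the percentage of apertures containing at least one
recognition segment of a given recognizer, compared between conditions with
a Welch two-sample t-test.

The fold change is the geometric mean of the per-flow-cell ratios of mean
PDs; this makes fold(a, b) * fold(b, a) = 1 hold exactly and pairs naturally
with the two-tailed one-sample t-test of the log ratios against 0 (i.e.
against a fold change of 1).  Multiple positions are tested without
multiplicity correction by default, mirroring per-position reporting; a Holm
adjustment helper is provided but not applied automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .align import AlignmentResult
from .primary import RSSummary
from .reference import ReferenceProfile


@dataclass
class PositionPD:
    """Per-aperture mean pulse durations observed at one reference position."""

    peptide: str
    position: int
    recognizer: str
    pds: list
    flow_cell_id: str = ""

    def __post_init__(self) -> None:
        if any(pd <= 0 for pd in self.pds):
            raise ValueError("pulse durations must be > 0")


@dataclass(frozen=True)
class FoldChangeResult:
    """Fold change in mean PD between two peptides at one position.

    ``fold_change`` is the geometric mean of per-flow-cell ratios (a over b);
    ``sd`` the standard deviation of those ratios; ``p_value`` a two-tailed
    one-sample t-test of the log ratios against a fold change of 1, defined
    only with >= 2 replicate flow cells and nonzero variance.
    """

    position: int
    peptide_a: str
    peptide_b: str
    fold_change: float
    sd: float
    p_value: float
    n_replicates: int
    per_flow_cell: tuple = ()
    degenerate: bool = False


@dataclass(frozen=True)
class ApertureFractionResult:
    """Percent of apertures containing >= 1 RS of a recognizer, per condition."""

    recognizer: str
    condition: str
    percent: float
    per_flow_cell: tuple = ()
    p_value: Optional[float] = None


def collect_position_pds(results: Sequence[AlignmentResult],
                         rs_by_read: Mapping[int, Sequence[RSSummary]],
                         profile: ReferenceProfile,
                         flow_cell_id: str = "",
                         max_q: float = 0.05) -> List[PositionPD]:
    """Map aligned recognition segments back to reference positions.

    Only reads assigned to ``profile`` (non-decoy, q <= max_q) contribute.
    Each aligned RS is routed to its reference position through the alignment
    traceback; when several RSs land on one position in one read their mean
    PDs are averaged, so each aperture contributes at most one value per
    position.  Positions aligned in zero reads are absent from the output,
    not zero-filled -- dark positions can therefore never appear.
    """
    recognizer_at = {s.position: s.recognizer for s in profile.recognition_steps()}
    acc: Dict[int, List[float]] = {}
    for res in results:
        if res.is_decoy or res.best_reference != profile.label or res.q_value > max_q:
            continue
        rs_list = rs_by_read[res.aperture_id]
        per_pos: Dict[int, List[float]] = {}
        for rs_index, position in res.pairs:
            per_pos.setdefault(position, []).append(rs_list[rs_index].mean_pd)
        for position, values in per_pos.items():
            acc.setdefault(position, []).append(float(np.mean(values)))
    return [
        PositionPD(peptide=profile.label, position=pos,
                   recognizer=recognizer_at[pos], pds=acc[pos],
                   flow_cell_id=flow_cell_id)
        for pos in sorted(acc)
    ]


def _group_by_flow_cell(pds: Sequence[PositionPD], position: int) -> Dict[str, List[float]]:
    out: Dict[str, List[float]] = {}
    for p in pds:
        if p.position == position:
            out.setdefault(p.flow_cell_id, []).extend(p.pds)
    return out


def pd_fold_change(a: Sequence[PositionPD], b: Sequence[PositionPD],
                   position: int) -> FoldChangeResult:
    """Fold change of mean PD (peptide a over peptide b) at ``position``.

    ``a`` and ``b`` are PositionPD collections spanning one or more flow
    cells; the ratio of across-aperture mean PDs is formed per common flow
    cell and summarized as described in the module docstring.
    """
    ga, gb = _group_by_flow_cell(a, position), _group_by_flow_cell(b, position)
    common = sorted(set(ga) & set(gb))
    if not common:
        raise ValueError(f"no flow cell has data for position {position} in both groups")
    ratios = np.array([np.mean(ga[fc]) / np.mean(gb[fc]) for fc in common])
    fold = float(np.exp(np.mean(np.log(ratios))))
    label_a = a[0].peptide if a else ""
    label_b = b[0].peptide if b else ""
    n = len(ratios)
    if n < 2:
        return FoldChangeResult(position, label_a, label_b, fold,
                                float("nan"), float("nan"), n,
                                tuple(ratios), degenerate=True)
    sd = float(np.std(ratios, ddof=1))
    log_ratios = np.log(ratios)
    if np.allclose(log_ratios.var(ddof=1), 0.0):
        return FoldChangeResult(position, label_a, label_b, fold, sd,
                                float("nan"), n, tuple(ratios), degenerate=True)
    p = float(sps.ttest_1samp(log_ratios, 0.0).pvalue)
    return FoldChangeResult(position, label_a, label_b, fold, sd, p, n,
                            tuple(ratios))


def aperture_fraction_with_rs(rs_by_read_per_fc: Mapping[str, Mapping[int, Sequence[RSSummary]]],
                              recognizer: str, condition: str = "",
                              denominator: str = "any-rs",
                              n_loaded_per_fc: Optional[Mapping[str, int]] = None
                              ) -> ApertureFractionResult:
    """Percent of apertures containing >= 1 RS of ``recognizer``.

    ``rs_by_read_per_fc`` maps flow cell id -> {aperture -> RS list}.  With
    ``denominator='any-rs'`` (default) the baseline is apertures with at
    least one RS of any recognizer; ``denominator='loaded'`` divides by the
    supplied per-flow-cell loaded-aperture counts instead.
    """
    per_fc = []
    for fc in sorted(rs_by_read_per_fc):
        rs_by_read = rs_by_read_per_fc[fc]
        with_any = [ap for ap, rs in rs_by_read.items() if rs]
        hits = sum(
            1 for ap in with_any
            if any(rs.recognizer == recognizer for rs in rs_by_read[ap])
        )
        if denominator == "any-rs":
            denom = len(with_any)
        elif denominator == "loaded":
            if n_loaded_per_fc is None:
                raise ValueError("denominator='loaded' requires n_loaded_per_fc")
            denom = n_loaded_per_fc[fc]
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        per_fc.append(100.0 * hits / denom if denom else 0.0)
    return ApertureFractionResult(
        recognizer=recognizer, condition=condition,
        percent=float(np.mean(per_fc)) if per_fc else 0.0,
        per_flow_cell=tuple(per_fc),
    )


def compare_aperture_fractions(a: ApertureFractionResult,
                               b: ApertureFractionResult) -> float:
    """Welch two-sample t-test p-value between the per-flow-cell percentages
    of two conditions (the PTM-readout comparison)."""
    if len(a.per_flow_cell) < 2 or len(b.per_flow_cell) < 2:
        raise ValueError("need >= 2 flow cells per condition for a Welch test")
    return float(
        sps.ttest_ind(a.per_flow_cell, b.per_flow_cell, equal_var=False).pvalue
    )


def holm_adjust(p_values: Sequence[float]) -> List[float]:
    """Holm step-down adjustment (optional; off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()


def fold_changes_to_dataframe(results: Sequence[FoldChangeResult]):
    import pandas as pd

    rows = [{
        "position": r.position,
        "peptide_a": r.peptide_a,
        "peptide_b": r.peptide_b,
        "fold_change": r.fold_change,
        "sd": r.sd,
        "p_value": r.p_value,
        "n_replicates": r.n_replicates,
        "degenerate": r.degenerate,
    } for r in results]
    return pd.DataFrame(rows, columns=[
        "position", "peptide_a", "peptide_b", "fold_change", "sd",
        "p_value", "n_replicates", "degenerate",
    ])


def plot_fold_changes(results: Sequence[FoldChangeResult], path=None):
    """Bar plot of fold changes with SD error bars (one bar per position)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * max(len(results), 3), 3.2))
    xs = np.arange(len(results))
    ax.bar(xs, [r.fold_change for r in results],
           yerr=[0 if math.isnan(r.sd) else r.sd for r in results],
           capsize=3, color="#4878d0")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(xs)
    ax.set_xticklabels([str(r.position) for r in results])
    ax.set_xlabel("position")
    ax.set_ylabel("PD fold change")
    if results:
        ax.set_title(f"{results[0].peptide_a} / {results[0].peptide_b}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_aperture_fractions(results: Sequence[ApertureFractionResult], path=None):
    """Grouped bar plot of per-recognizer aperture percentages by condition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    recognizers = sorted({r.recognizer for r in results})
    conditions = sorted({r.condition for r in results})
    width = 0.8 / max(len(conditions), 1)
    fig, ax = plt.subplots(figsize=(1.4 * max(len(recognizers), 3), 3.2))
    for ci, cond in enumerate(conditions):
        vals = []
        for rec in recognizers:
            match = [r for r in results if r.recognizer == rec and r.condition == cond]
            vals.append(match[0].percent if match else 0.0)
        ax.bar(np.arange(len(recognizers)) + ci * width, vals, width, label=cond)
    ax.set_xticks(np.arange(len(recognizers)) + width * (len(conditions) - 1) / 2)
    ax.set_xticklabels(recognizers)
    ax.set_ylabel("% apertures with RS")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
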