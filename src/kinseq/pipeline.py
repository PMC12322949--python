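"""End-to-end experiment orchestration.

Mirrors the bench design: a peptide library loaded onto several independent
flow cells (three by default), each simulated, dye-called, segmented, and
aligned against the candidate references plus shuffled decoys.  All
randomness flows from one master seed through ``numpy.random.SeedSequence``
spawning, so a run is reproducible end to end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .align import (
    AlignmentParams,
    AlignmentResult,
    assign_and_fdr,
    make_decoys,
)
from .primary import DyeModel, analyze_run
from .reference import (
    Peptide,
    RecognizerTable,
    ReferenceProfile,
    build_reference_profile,
    default_table,
)
from .simulate import RunData, SimConfig, simulate_run
from .stats import (
    ApertureFractionResult,
    FoldChangeResult,
    PositionPD,
    aperture_fraction_with_rs,
    collect_position_pds,
    pd_fold_change,
)


@dataclass
class FlowCellAnalysis:
    """Analyzed state of one flow cell (pulse data dropped after analysis)."""

    flow_cell_id: str
    rs_by_read: dict
    results: list  # AlignmentResult; empty when alignment was skipped
    true_peptide_by_aperture: dict
    dye_model: Optional[DyeModel] = None


@dataclass
class ConditionResult:
    """One experimental condition: several flow cells of one library."""

    table: RecognizerTable
    references: list  # ReferenceProfile
    decoys: list
    flow_cells: list  # FlowCellAnalysis
    position_pds: dict  # peptide label -> list[PositionPD] across flow cells
    condition: str = ""

    def rs_by_read_per_fc(self) -> Dict[str, dict]:
        return {fc.flow_cell_id: fc.rs_by_read for fc in self.flow_cells}

    def aperture_fraction(self, recognizer: str,
                          denominator: str = "any-rs") -> ApertureFractionResult:
        n_loaded = {
            fc.flow_cell_id: len(fc.true_peptide_by_aperture)
            for fc in self.flow_cells
        }
        return aperture_fraction_with_rs(
            self.rs_by_read_per_fc(), recognizer, condition=self.condition,
            denominator=denominator, n_loaded_per_fc=n_loaded,
        )

    def fold_change(self, label_a: str, label_b: str,
                    position: int) -> FoldChangeResult:
        return pd_fold_change(
            self.position_pds[label_a], self.position_pds[label_b], position
        )

    def pooled_position_values(self, label: str, position: int) -> List[float]:
        """Per-aperture mean PDs at a position pooled across flow cells."""
        return [
            v
            for p in self.position_pds.get(label, [])
            if p.position == position
            for v in p.pds
        ]


def run_condition(library: Sequence[Tuple[Peptide, float]],
                  table: Optional[RecognizerTable] = None,
                  references: Optional[Sequence[Peptide]] = None,
                  *,
                  seed: int = 0,
                  n_flow_cells: int = 3,
                  n_apertures: int = 2000,
                  loading_prob: float = 0.3,
                  dropout_prob: float = 0.01,
                  run_duration: float = 36000.0,
                  align_params: Optional[AlignmentParams] = None,
                  max_q: float = 0.05,
                  condition: str = "",
                  decoys_per_target: int = 5,
                  keep_models: bool = False) -> ConditionResult:
    """Simulate and analyze one condition across independent flow cells.

    ``references`` defaults to the library peptides.  Pass ``references=[]``
    to skip alignment (aperture-fraction readouts need only the RS lists).
    Several shuffled decoys per target (``decoys_per_target``) are pooled so
    the empirical null has enough tail resolution for stable q-values; the
    target/decoy ratio is normalized away inside the FDR computation.
    """
    table = table or default_table()
    if references is None:
        references = [p for p, _ in library]
    ref_profiles = [build_reference_profile(p, table) for p in references]

    master = np.random.SeedSequence(seed)
    fc_seeds = master.spawn(n_flow_cells + 1)
    decoy_seed = int(fc_seeds[-1].generate_state(1)[0] % (2 ** 31))
    decoys = []
    if ref_profiles:
        for j in range(decoys_per_target):
            decoys.extend(
                make_decoys(ref_profiles, table, seed=decoy_seed + j)
            )

    flow_cells: List[FlowCellAnalysis] = []
    position_acc: Dict[str, List[PositionPD]] = {p.label: [] for p in ref_profiles}
    for i in range(n_flow_cells):
        fc_id = f"fc{i + 1}"
        rng = np.random.default_rng(fc_seeds[i])
        config = SimConfig(
            library=list(library),
            n_apertures=n_apertures,
            loading_prob=loading_prob,
            dropout_prob=dropout_prob,
            run_duration=run_duration,
            seed=int(fc_seeds[i].generate_state(1)[0] % (2 ** 31)),
        )
        run = simulate_run(config, table, flow_cell_id=fc_id, rng=rng)
        rs_by_read, model = analyze_run(run, table, random_state=i)
        results = (
            assign_and_fdr(rs_by_read, ref_profiles, decoys, align_params)
            if ref_profiles else []
        )
        truth = {read.aperture_id: read.true_peptide for read in run.reads}
        flow_cells.append(FlowCellAnalysis(
            flow_cell_id=fc_id,
            rs_by_read=rs_by_read,
            results=results,
            true_peptide_by_aperture=truth,
            dye_model=model if keep_models else None,
        ))
        for profile in ref_profiles:
            position_acc[profile.label].extend(
                collect_position_pds(results, rs_by_read, profile,
                                     flow_cell_id=fc_id, max_q=max_q)
            )
    return ConditionResult(
        table=table,
        references=ref_profiles,
        decoys=decoys,
        flow_cells=flow_cells,
        position_pds=position_acc,
        condition=condition,
    )


def run_pair_experiment(peptide_a: Peptide, peptide_b: Peptide,
                        table: Optional[RecognizerTable] = None,
                        *, seed: int = 0, **kwargs) -> ConditionResult:
    """Equimolar two-peptide library on shared flow cells (the paralogue /
    spliceform discrimination design)."""
    library = [(peptide_a, 0.5), (peptide_b, 0.5)]
    return run_condition(library, table, [peptide_a, peptide_b],
                         seed=seed, **kwargs)


def config_manifest(config: Mapping, seed: int) -> dict:
    """Run manifest: canonical config hash, seed, and software versions."""
    import sklearn

    canonical = json.dumps(config, sort_keys=True, default=str)
    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "kinseq_version": __version__,
        "numpy_version": np.__version__,
        "sklearn_version": sklearn.__version__,
    }


def write_manifest(outdir, config: Mapping, seed: int) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(config_manifest(config, seed), indent=1))
    return path
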