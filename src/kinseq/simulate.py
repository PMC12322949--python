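"""Single-aperture kinetic sequencing simulator.

Each loaded nanoaperture holds one peptide.  Residues are processed N→C: the
exposed N-terminal amino acid, if cognate to a recognizer and if a
Bernoulli(binding probability) trial succeeds, produces a recognition segment
-- a train of pulses with exponentially distributed durations (mean = the
table's PD for that (recognizer, residue), scaled by any PTM factor) separated
by exponential unbound gaps.  Aminopeptidase cleavage is a memoryless clock
that runs only while the recognizer is unbound (a bound recognizer shields
the terminus), so the number of pulses in a segment is geometric with mean
cleavage_time / interpulse.  Dark residues contribute only a silent
exponential cleavage gap.  Pulse intensity and lifetime are Gaussian around
the dye's photophysics, which is what makes dye calling a statistical problem
downstream.  A per-residue dropout probability subsumes all premature
termination causes (photobleaching, peptide loss); the run ends at
``run_duration``.

Hidden truth labels (peptide identity, per-pulse residue position and dye)
ride along on every read so tests can make exact conditional checks; the
serialization keeps them in a sidecar file the analysis path never reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .reference import (
    ConfigurationError,
    Peptide,
    RecognizerTable,
    ReferenceProfile,
    build_reference_profile,
)


@dataclass(frozen=True)
class Pulse:
    """One recognizer-bound interval (``duration`` is this pulse's PD)."""

    start: float
    duration: float
    intensity: float
    lifetime: float
    true_dye: Optional[str] = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.start < 0:
            raise ValueError("pulse requires duration > 0 and start >= 0")


@dataclass
class SimConfig:
    """Run-level simulation parameters.

    ``library`` is a list of (Peptide, mixing fraction) pairs whose fractions
    sum to 1.  ``mean_interpulse`` and ``cleavage_mean_time`` default to the
    recognizer table's values when left as None.  Defaults mirror a 10 h run
    with 2,000 apertures per flow cell and an equimolar library.
    """

    library: list
    n_apertures: int = 2000
    loading_prob: float = 0.3
    run_duration: float = 36000.0
    mean_interpulse: Optional[float] = None
    cleavage_mean_time: Optional[float] = None
    dropout_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.library:
            raise ConfigurationError("library must contain at least one peptide")
        total = sum(frac for _, frac in self.library)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"library fractions sum to {total}, not 1")
        for prob in (self.loading_prob, self.dropout_prob):
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError("probabilities must be in [0, 1]")
        if self.run_duration <= 0 or self.n_apertures <= 0:
            raise ConfigurationError("run_duration and n_apertures must be > 0")
        for t in (self.mean_interpulse, self.cleavage_mean_time):
            if t is not None and t <= 0:
                raise ConfigurationError("time scales must be > 0")

    def to_dict(self) -> dict:
        return {
            "library": [
                {"sequence": p.sequence, "ptms": list(p.ptms), "label": p.label,
                 "fraction": frac}
                for p, frac in self.library
            ],
            "n_apertures": self.n_apertures,
            "loading_prob": self.loading_prob,
            "run_duration": self.run_duration,
            "mean_interpulse": self.mean_interpulse,
            "cleavage_mean_time": self.cleavage_mean_time,
            "dropout_prob": self.dropout_prob,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        library = [
            (Peptide(sequence=e["sequence"], ptms=tuple(map(tuple, e["ptms"])),
                     label=e["label"]), e["fraction"])
            for e in data["library"]
        ]
        kwargs = {k: data[k] for k in
                  ("n_apertures", "loading_prob", "run_duration", "mean_interpulse",
                   "cleavage_mean_time", "dropout_prob", "seed") if k in data}
        return cls(library=library, **kwargs)


@dataclass
class ApertureRead:
    """Time-ordered pulses from one aperture, stored as parallel arrays.

    ``true_dye`` holds dye indices into ``dye_names``; ``true_position`` the
    1-based residue position each pulse came from.  ``pulses`` materializes
    the record view for small-data work.
    """

    aperture_id: int
    start: np.ndarray
    duration: np.ndarray
    intensity: np.ndarray
    lifetime: np.ndarray
    true_dye: np.ndarray
    true_position: np.ndarray
    true_peptide: str = ""
    truncated: bool = False
    dye_names: tuple = ()

    def __post_init__(self) -> None:
        n = len(self.start)
        if not all(len(a) == n for a in (self.duration, self.intensity,
                                         self.lifetime, self.true_dye,
                                         self.true_position)):
            raise ValueError("pulse arrays must have equal length")
        if n:
            if np.any(self.duration <= 0):
                raise ValueError("pulse durations must be > 0")
            ends = self.start[:-1] + self.duration[:-1]
            if np.any(self.start[1:] < ends - 1e-9):
                raise ValueError("pulses must be sorted and non-overlapping")

    @property
    def n_pulses(self) -> int:
        return len(self.start)

    @property
    def pulses(self) -> List[Pulse]:
        return [
            Pulse(
                start=float(self.start[i]),
                duration=float(self.duration[i]),
                intensity=float(self.intensity[i]),
                lifetime=float(self.lifetime[i]),
                true_dye=self.dye_names[self.true_dye[i]]
                if self.dye_names and self.true_dye[i] >= 0 else None,
            )
            for i in range(self.n_pulses)
        ]


@dataclass
class RunData:
    """One simulated flow cell: loaded apertures only (empty ones omitted)."""

    flow_cell_id: str
    config: SimConfig
    reads: list = field(default_factory=list)

    def all_pulse_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        """Concatenated (intensity, lifetime) across reads, for dye-model fitting."""
        if not self.reads:
            return np.empty(0), np.empty(0)
        return (
            np.concatenate([r.intensity for r in self.reads]),
            np.concatenate([r.lifetime for r in self.reads]),
        )


def _simulate_from_profile(profile: ReferenceProfile, table: RecognizerTable,
                           config: SimConfig, rng: np.random.Generator,
                           aperture_id: int = 0) -> ApertureRead:
    interpulse = config.mean_interpulse or table.kinetics.mean_interpulse
    dye_names = tuple(table.dyes)
    dye_index = {d: i for i, d in enumerate(dye_names)}

    t = 0.0
    truncated = False
    starts: list = []
    durations: list = []
    intensities: list = []
    lifetimes: list = []
    dyes: list = []
    positions: list = []

    for step in profile.steps:
        if t >= config.run_duration:
            break
        if config.dropout_prob and rng.random() < config.dropout_prob:
            truncated = True
            break
        cleave = config.cleavage_mean_time or table.cleavage_mean_for(step.residue)
        if step.is_dark or rng.random() >= step.expected_binding_prob:
            # silent residue: the cleavage clock runs uninterrupted
            t += rng.exponential(cleave)
            continue
        rec = table.recognizer_for(step.residue)
        # during each unbound interval, binding (rate 1/interpulse) races
        # cleavage (rate 1/cleave); pulses before cleavage are geometric
        p_cleave = interpulse / (interpulse + cleave)
        n = int(rng.geometric(p_cleave)) - 1
        gap_scale = interpulse * cleave / (interpulse + cleave)
        if n > 0:
            gaps = rng.exponential(gap_scale, n)
            pds = rng.exponential(step.expected_pd, n)
            pulse_starts = t + np.cumsum(gaps) + np.concatenate(
                ([0.0], np.cumsum(pds[:-1]))
            )
            t = float(pulse_starts[-1] + pds[-1])
            keep = pulse_starts < config.run_duration
            k = int(keep.sum())
            if k:
                starts.append(pulse_starts[:k])
                durations.append(pds[:k])
                intensities.append(
                    rng.normal(rec.dye_intensity_mean, rec.dye_intensity_sd, k)
                )
                lifetimes.append(
                    rng.normal(rec.dye_lifetime_mean, rec.dye_lifetime_sd, k)
                )
                dyes.append(np.full(k, dye_index[rec.dye], dtype=np.int16))
                positions.append(np.full(k, step.position, dtype=np.int16))
        t += rng.exponential(gap_scale)  # final unbound interval ends in cleavage

    def _cat(parts, dtype):
        return np.concatenate(parts) if parts else np.empty(0, dtype=dtype)

    return ApertureRead(
        aperture_id=aperture_id,
        start=_cat(starts, float),
        duration=_cat(durations, float),
        intensity=_cat(intensities, float),
        lifetime=_cat(lifetimes, float),
        true_dye=_cat(dyes, np.int16),
        true_position=_cat(positions, np.int16),
        true_peptide=profile.label,
        truncated=truncated,
        dye_names=dye_names,
    )


def simulate_aperture(peptide: Peptide, table: RecognizerTable, config: SimConfig,
                      rng: np.random.Generator, aperture_id: int = 0) -> ApertureRead:
    """Simulate one loaded aperture holding ``peptide``."""
    profile = build_reference_profile(peptide, table)
    return _simulate_from_profile(profile, table, config, rng, aperture_id)


def simulate_run(config: SimConfig, table: RecognizerTable,
                 flow_cell_id: str = "fc1",
                 rng: Optional[np.random.Generator] = None) -> RunData:
    """Simulate one flow cell.

    Each of ``n_apertures`` apertures is independently empty (probability
    1 - loading_prob) or loaded with a single peptide drawn from the library
    mixing fractions.  Reproducible: the same config (seed included) yields an
    identical run; pass ``rng`` to control seeding externally.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    profiles = [build_reference_profile(p, table) for p, _ in config.library]
    fractions = np.array([frac for _, frac in config.library])

    loaded = rng.random(config.n_apertures) < config.loading_prob
    choices = rng.choice(len(profiles), size=config.n_apertures, p=fractions)
    reads = []
    for ap in np.flatnonzero(loaded):
        reads.append(
            _simulate_from_profile(
                profiles[choices[ap]], table, config, rng, aperture_id=int(ap)
            )
        )
    return RunData(flow_cell_id=flow_cell_id, config=config, reads=reads)


# ---------------------------------------------------------------------------
# Serialization: JSON-lines runs, flat pulse CSV, truth sidecar
# ---------------------------------------------------------------------------


def write_run(run: RunData, path, truth_path=None) -> None:
    """Write a run as JSON-lines (header line, then one aperture per line).

    Truth labels go to ``truth_path`` (default: path + '.truth.jsonl') so the
    analysis path can be pointed at the run file alone.
    """
    path = Path(path)
    truth_path = Path(truth_path) if truth_path else path.with_suffix(
        path.suffix + ".truth.jsonl"
    )
    with path.open("w") as fh:
        header = {
            "flow_cell_id": run.flow_cell_id,
            "config": run.config.to_dict(),
            "dye_names": list(run.reads[0].dye_names) if run.reads else [],
        }
        fh.write(json.dumps(header) + "\n")
        for read in run.reads:
            fh.write(json.dumps({
                "aperture_id": read.aperture_id,
                "start": read.start.tolist(),
                "duration": read.duration.tolist(),
                "intensity": read.intensity.tolist(),
                "lifetime": read.lifetime.tolist(),
            }) + "\n")
    with truth_path.open("w") as fh:
        for read in run.reads:
            fh.write(json.dumps({
                "aperture_id": read.aperture_id,
                "peptide": read.true_peptide,
                "truncated": read.truncated,
                "dye": read.true_dye.tolist(),
                "position": read.true_position.tolist(),
            }) + "\n")


def read_run(path, truth_path=None) -> RunData:
    """Read a JSON-lines run; truth arrays are restored when the sidecar exists."""
    path = Path(path)
    truth_path = Path(truth_path) if truth_path else path.with_suffix(
        path.suffix + ".truth.jsonl"
    )
    truth: dict = {}
    if truth_path.exists():
        with truth_path.open() as fh:
            for line in fh:
                rec = json.loads(line)
                truth[rec["aperture_id"]] = rec
    with path.open() as fh:
        header = json.loads(fh.readline())
        dye_names = tuple(header["dye_names"])
        reads = []
        for line in fh:
            rec = json.loads(line)
            n = len(rec["start"])
            tr = truth.get(rec["aperture_id"], {})
            reads.append(ApertureRead(
                aperture_id=rec["aperture_id"],
                start=np.asarray(rec["start"], dtype=float),
                duration=np.asarray(rec["duration"], dtype=float),
                intensity=np.asarray(rec["intensity"], dtype=float),
                lifetime=np.asarray(rec["lifetime"], dtype=float),
                true_dye=np.asarray(tr.get("dye", [-1] * n), dtype=np.int16),
                true_position=np.asarray(tr.get("position", [-1] * n), dtype=np.int16),
                true_peptide=tr.get("peptide", ""),
                truncated=tr.get("truncated", False),
                dye_names=dye_names,
            ))
    return RunData(
        flow_cell_id=header["flow_cell_id"],
        config=SimConfig.from_dict(header["config"]),
        reads=reads,
    )


def run_to_pulse_csv(run: RunData, path) -> None:
    """Flat CSV of pulses: aperture_id, start_s, duration_s, intensity, lifetime."""
    frames = [
        pd.DataFrame({
            "aperture_id": read.aperture_id,
            "start_s": read.start,
            "duration_s": read.duration,
            "intensity": read.intensity,
            "lifetime": read.lifetime,
        })
        for read in run.reads
    ]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["aperture_id", "start_s", "duration_s",
                                     "intensity", "lifetime"]))
    df.to_csv(path, index=False)
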