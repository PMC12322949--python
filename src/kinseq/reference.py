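"""Recognizer calibration and kinetic reference profiles.

The sequencing chemistry exposes one N-terminal amino acid (NAA) at a time;
fluorophore-labeled recognizers reversibly and repeatedly bind their cognate
NAAs, so each recognized residue produces a train of fluorescence pulses whose
duration distribution is characteristic of the (recognizer, NAA) pair.  This
module holds that calibration -- which recognizer sees which residue, the dye
photophysics used for dye calling, and the per-residue mean pulse durations --
and turns a peptide (optionally carrying PTMs) into the kinetic reference
profile that the aligner matches reads against.

Residues with no cognate recognizer are "dark": they yield no pulses and
appear in a read only as a silent gap while the aminopeptidase works.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ConfigurationError(ValueError):
    """Raised when a recognizer table or peptide definition is invalid."""


def _check_residues(residues: Iterable[str], what: str) -> None:
    bad = sorted(set(residues) - CANONICAL_AA)
    if bad:
        raise ConfigurationError(f"{what}: non-canonical residue(s) {bad!r}")


@dataclass(frozen=True)
class Recognizer:
    """One NAA recognizer and the photophysics of its fluorophore.

    ``dye_intensity_*`` are in arbitrary fluorescence units,
    ``dye_lifetime_*`` in nanoseconds.
    """

    name: str
    cognates: frozenset
    dye: str
    dye_intensity_mean: float
    dye_intensity_sd: float
    dye_lifetime_mean: float
    dye_lifetime_sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "cognates", frozenset(self.cognates))
        if not self.cognates:
            raise ConfigurationError(f"recognizer {self.name!r}: empty cognate set")
        _check_residues(self.cognates, f"recognizer {self.name!r}")
        if self.dye_intensity_sd <= 0 or self.dye_lifetime_sd <= 0:
            raise ConfigurationError(
                f"recognizer {self.name!r}: dye SDs must be > 0"
            )


@dataclass(frozen=True)
class PTMModifier:
    """Multiplicative perturbation of binding kinetics by a modification.

    ``binding_prob_factor`` in [0, 1] scales the probability that an exposed
    modified residue yields a recognition segment at all; ``pd_factor`` > 0
    scales its mean pulse duration.
    """

    residue: str
    ptm: str
    binding_prob_factor: float
    pd_factor: float

    def __post_init__(self) -> None:
        _check_residues([self.residue], f"PTM modifier {self.ptm!r}")
        if not 0.0 <= self.binding_prob_factor <= 1.0:
            raise ConfigurationError(
                f"PTM {self.ptm!r} on {self.residue}: binding_prob_factor "
                f"{self.binding_prob_factor} outside [0, 1]"
            )
        if self.pd_factor <= 0:
            raise ConfigurationError(
                f"PTM {self.ptm!r} on {self.residue}: pd_factor must be > 0"
            )


@dataclass
class KineticParams:
    """Per-(recognizer, residue) binding kinetics.

    ``mean_pd`` maps (recognizer name, residue) to the mean pulse duration in
    seconds; ``binding_prob`` to the probability an exposed cognate residue
    produces a recognition segment at all; ``mean_interpulse`` (seconds) is
    the mean unbound interval between pulses within a segment.
    """

    mean_pd: dict
    binding_prob: dict = field(default_factory=dict)
    mean_interpulse: float = 1.0

    DEFAULT_BINDING_PROB = 0.9

    def __post_init__(self) -> None:
        for key, pd in self.mean_pd.items():
            if pd <= 0:
                raise ConfigurationError(f"mean_pd for {key} must be > 0, got {pd}")
        for key, bp in self.binding_prob.items():
            if not 0.0 < bp <= 1.0:
                raise ConfigurationError(
                    f"binding_prob for {key} must be in (0, 1], got {bp}"
                )
        if self.mean_interpulse <= 0:
            raise ConfigurationError("mean_interpulse must be > 0")

    def pd_for(self, recognizer: str, residue: str) -> float:
        return self.mean_pd[(recognizer, residue)]

    def binding_prob_for(self, recognizer: str, residue: str) -> float:
        return self.binding_prob.get((recognizer, residue), self.DEFAULT_BINDING_PROB)


@dataclass
class RecognizerTable:
    """The system calibration: recognizers, kinetics, PTM modifiers.

    Invariants enforced at construction: cognate sets are pairwise disjoint
    (no residue may be claimed by two recognizers), their union covers at most
    the 20 canonical residues, every cognate has a kinetic entry, and dyes are
    unique so a dye call identifies a recognizer.
    """

    recognizers: list
    kinetics: KineticParams
    ptm_modifiers: list = field(default_factory=list)
    cleavage_mean_time: float = 120.0
    cleavage_class_times: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict = {}
        for rec in self.recognizers:
            for aa in rec.cognates:
                if aa in seen:
                    raise ConfigurationError(
                        f"residue {aa!r} is cognate to both "
                        f"{seen[aa]!r} and {rec.name!r}"
                    )
                seen[aa] = rec.name
        if len(seen) > 20:
            raise ConfigurationError("cognate union exceeds 20 canonical residues")
        dyes = [rec.dye for rec in self.recognizers]
        if len(set(dyes)) != len(dyes):
            raise ConfigurationError("recognizers must carry distinct dyes")
        for rec in self.recognizers:
            for aa in rec.cognates:
                if (rec.name, aa) not in self.kinetics.mean_pd:
                    raise ConfigurationError(
                        f"missing kinetic entry for ({rec.name}, {aa})"
                    )
        if self.cleavage_mean_time <= 0:
            raise ConfigurationError("cleavage_mean_time must be > 0")
        self._by_residue = {
            aa: rec for rec in self.recognizers for aa in rec.cognates
        }
        self._by_dye = {rec.dye: rec for rec in self.recognizers}

    # -- lookups ---------------------------------------------------------

    def recognizer_for(self, residue: str) -> Optional[Recognizer]:
        """The recognizer whose cognate set contains ``residue``, else None (dark)."""
        return self._by_residue.get(residue)

    def recognizer_for_dye(self, dye: str) -> Recognizer:
        return self._by_dye[dye]

    def modifier_for(self, residue: str, ptm: str) -> PTMModifier:
        for mod in self.ptm_modifiers:
            if mod.residue == residue and mod.ptm == ptm:
                return mod
        raise ConfigurationError(f"no PTM modifier for {ptm!r} on residue {residue!r}")

    @property
    def cognate_union(self) -> frozenset:
        return frozenset(self._by_residue)

    @property
    def dyes(self) -> list:
        """Dye names in recognizer order (the canonical dye-index order)."""
        return [rec.dye for rec in self.recognizers]

    def cleavage_mean_for(self, residue: str) -> float:
        return self.cleavage_class_times.get(residue, self.cleavage_mean_time)

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "recognizers": [
                {
                    "name": r.name,
                    "cognates": sorted(r.cognates),
                    "dye": r.dye,
                    "dye_intensity_mean": r.dye_intensity_mean,
                    "dye_intensity_sd": r.dye_intensity_sd,
                    "dye_lifetime_mean": r.dye_lifetime_mean,
                    "dye_lifetime_sd": r.dye_lifetime_sd,
                }
                for r in self.recognizers
            ],
            "kinetics": {
                "mean_interpulse": self.kinetics.mean_interpulse,
                "entries": [
                    {
                        "recognizer": rec,
                        "residue": aa,
                        "mean_pd_s": pd,
                        "binding_prob": self.kinetics.binding_prob_for(rec, aa),
                    }
                    for (rec, aa), pd in sorted(self.kinetics.mean_pd.items())
                ],
            },
            "ptm_modifiers": [
                {
                    "residue": m.residue,
                    "ptm": m.ptm,
                    "binding_prob_factor": m.binding_prob_factor,
                    "pd_factor": m.pd_factor,
                }
                for m in self.ptm_modifiers
            ],
            "cleavage_mean_time_s": self.cleavage_mean_time,
            "cleavage_class_times_s": dict(self.cleavage_class_times),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RecognizerTable":
        recognizers = [
            Recognizer(
                name=r["name"],
                cognates=frozenset(r["cognates"]),
                dye=r["dye"],
                dye_intensity_mean=float(r["dye_intensity_mean"]),
                dye_intensity_sd=float(r["dye_intensity_sd"]),
                dye_lifetime_mean=float(r["dye_lifetime_mean"]),
                dye_lifetime_sd=float(r["dye_lifetime_sd"]),
            )
            for r in data["recognizers"]
        ]
        kin = data["kinetics"]
        mean_pd, binding_prob = {}, {}
        for e in kin["entries"]:
            key = (e["recognizer"], e["residue"])
            mean_pd[key] = float(e["mean_pd_s"])
            if "binding_prob" in e:
                binding_prob[key] = float(e["binding_prob"])
        kinetics = KineticParams(
            mean_pd=mean_pd,
            binding_prob=binding_prob,
            mean_interpulse=float(kin.get("mean_interpulse", 1.0)),
        )
        mods = [
            PTMModifier(
                residue=m["residue"],
                ptm=m["ptm"],
                binding_prob_factor=float(m["binding_prob_factor"]),
                pd_factor=float(m["pd_factor"]),
            )
            for m in data.get("ptm_modifiers", [])
        ]
        return cls(
            recognizers=recognizers,
            kinetics=kinetics,
            ptm_modifiers=mods,
            cleavage_mean_time=float(data.get("cleavage_mean_time_s", 120.0)),
            cleavage_class_times={
                k: float(v)
                for k, v in data.get("cleavage_class_times_s", {}).items()
            },
        )

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def save_tsv(self, directory) -> None:
        """Write the three-file TSV form (recognizers, kinetics, ptm_modifiers)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        lines = ["recognizer\tcognates\tdye\tintensity_mean\tintensity_sd\tlifetime_mean\tlifetime_sd"]
        for r in self.recognizers:
            lines.append(
                f"{r.name}\t{','.join(sorted(r.cognates))}\t{r.dye}"
                f"\t{r.dye_intensity_mean}\t{r.dye_intensity_sd}"
                f"\t{r.dye_lifetime_mean}\t{r.dye_lifetime_sd}"
            )
        (directory / "recognizers.tsv").write_text("\n".join(lines) + "\n")
        lines = ["recognizer\tresidue\tmean_pd_s\tbinding_prob"]
        for (rec, aa), pd in sorted(self.kinetics.mean_pd.items()):
            lines.append(f"{rec}\t{aa}\t{pd}\t{self.kinetics.binding_prob_for(rec, aa)}")
        (directory / "kinetics.tsv").write_text("\n".join(lines) + "\n")
        lines = ["residue\tptm\tbinding_prob_factor\tpd_factor"]
        for m in self.ptm_modifiers:
            lines.append(f"{m.residue}\t{m.ptm}\t{m.binding_prob_factor}\t{m.pd_factor}")
        (directory / "ptm_modifiers.tsv").write_text("\n".join(lines) + "\n")


def _load_table_tsv(directory: Path) -> RecognizerTable:
    import pandas as pd

    rec_df = pd.read_csv(directory / "recognizers.tsv", sep="\t")
    recognizers = [
        Recognizer(
            name=row.recognizer,
            cognates=frozenset(str(row.cognates).split(",")),
            dye=row.dye,
            dye_intensity_mean=row.intensity_mean,
            dye_intensity_sd=row.intensity_sd,
            dye_lifetime_mean=row.lifetime_mean,
            dye_lifetime_sd=row.lifetime_sd,
        )
        for row in rec_df.itertuples()
    ]
    kin_df = pd.read_csv(directory / "kinetics.tsv", sep="\t")
    mean_pd = {
        (row.recognizer, row.residue): row.mean_pd_s for row in kin_df.itertuples()
    }
    binding_prob = (
        {(row.recognizer, row.residue): row.binding_prob for row in kin_df.itertuples()}
        if "binding_prob" in kin_df.columns
        else {}
    )
    kinetics = KineticParams(mean_pd=mean_pd, binding_prob=binding_prob)
    ptm_path = directory / "ptm_modifiers.tsv"
    mods = []
    if ptm_path.exists():
        ptm_df = pd.read_csv(ptm_path, sep="\t")
        mods = [
            PTMModifier(
                residue=row.residue,
                ptm=row.ptm,
                binding_prob_factor=row.binding_prob_factor,
                pd_factor=row.pd_factor,
            )
            for row in ptm_df.itertuples()
        ]
    return RecognizerTable(recognizers=recognizers, kinetics=kinetics, ptm_modifiers=mods)


def load_recognizer_table(path) -> RecognizerTable:
    """Load a recognizer table from a JSON file or a directory of TSVs.

    Accepts a single JSON document (see ``RecognizerTable.to_dict`` for the
    schema), a directory containing ``recognizers.tsv``, ``kinetics.tsv`` and
    optionally ``ptm_modifiers.tsv``, or a path to ``recognizers.tsv`` whose
    siblings are looked up in the same directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recognizer table not found: {path}")
    if path.is_dir():
        return _load_table_tsv(path)
    if path.suffix.lower() == ".json":
        return RecognizerTable.from_dict(json.loads(path.read_text()))
    return _load_table_tsv(path.parent)


def default_table() -> RecognizerTable:
    """The shipped six-recognizer, 12-residue default calibration."""
    with resources.files("kinseq.data").joinpath("default_table.json").open() as fh:
        return RecognizerTable.from_dict(json.load(fh))


def table_with_de_recognizer() -> RecognizerTable:
    """Alternate calibration with a combined Asp/Glu recognizer (13 residues)."""
    with resources.files("kinseq.data").joinpath("table_de.json").open() as fh:
        return RecognizerTable.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Peptides and reference profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence (N→C, 1-letter codes) with optional PTMs.

    PTM positions are 1-based from the N-terminus.
    """

    sequence: str
    ptms: tuple = ()
    label: str = ""
    source_proteoform: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ConfigurationError("empty peptide sequence")
        _check_residues(self.sequence, f"peptide {self.sequence!r}")
        object.__setattr__(self, "ptms", tuple((int(p), str(n)) for p, n in self.ptms))
        for pos, name in self.ptms:
            if not 1 <= pos <= len(self.sequence):
                raise ConfigurationError(
                    f"PTM position {pos} outside peptide of length {len(self.sequence)}"
                )
        if not self.label:
            suffix = "".join(f"[{p}:{n}]" for p, n in self.ptms)
            object.__setattr__(self, "label", self.sequence + suffix)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProfileStep:
    """Expected behaviour of one residue position: its recognizer (or dark),
    expected mean pulse duration and binding probability after PTM scaling."""

    position: int
    residue: str
    recognizer: Optional[str]
    expected_pd: Optional[float]
    expected_binding_prob: Optional[float]

    @property
    def is_dark(self) -> bool:
        return self.recognizer is None


@dataclass(frozen=True)
class ReferenceProfile:
    """The kinetic signature expected for a peptide: one step per residue."""

    peptide: Peptide
    steps: tuple
    is_decoy: bool = False

    @property
    def label(self) -> str:
        return self.peptide.label

    def recognition_steps(self) -> list:
        """The non-dark steps, in order (what an ideal read would show)."""
        return [s for s in self.steps if not s.is_dark]


def build_reference_profile(peptide: Peptide, table: RecognizerTable,
                            is_decoy: bool = False) -> ReferenceProfile:
    """Predict the expected recognition-segment profile of a peptide.

    Each residue becomes one step; residues outside the cognate union are
    dark.  PTM-bearing residues have their expected PD and binding probability
    multiplied by the table's matching modifier factors; an unknown PTM name
    raises ``ConfigurationError``.
    """
    mods = {}
    for pos, name in peptide.ptms:
        mods[pos] = table.modifier_for(peptide.sequence[pos - 1], name)
    steps = []
    for i, aa in enumerate(peptide.sequence, start=1):
        rec = table.recognizer_for(aa)
        if rec is None:
            steps.append(ProfileStep(i, aa, None, None, None))
            continue
        pd = table.kinetics.pd_for(rec.name, aa)
        bp = table.kinetics.binding_prob_for(rec.name, aa)
        if i in mods:
            pd *= mods[i].pd_factor
            bp *= mods[i].binding_prob_factor
        steps.append(ProfileStep(i, aa, rec.name, pd, bp))
    return ReferenceProfile(peptide=peptide, steps=tuple(steps), is_decoy=is_decoy)


def expected_rs_sequence(profile: ReferenceProfile) -> list:
    """Ordered recognizer names of the profile's non-dark steps."""
    return [s.recognizer for s in profile.recognition_steps()]


# ---------------------------------------------------------------------------
# Peptide input
# ---------------------------------------------------------------------------


def _parse_ptm_spec(spec: str) -> tuple:
    ptms = []
    for item in spec.split(","):
        item = item.strip()
        if not item:
            continue
        pos, _, name = item.partition(":")
        if not name:
            raise ConfigurationError(f"malformed PTM spec {item!r} (want pos:name)")
        ptms.append((int(pos), name))
    return tuple(ptms)


def read_peptides_fasta(path) -> list:
    """Read peptides from FASTA.  PTMs are encoded in the description line as
    ``ptm=10:phospho`` (comma-separated for several); the record id is the label."""
    from Bio import SeqIO

    peptides = []
    for record in SeqIO.parse(str(path), "fasta"):
        ptms: tuple = ()
        source = ""
        for token in record.description.split()[1:]:
            key, _, value = token.partition("=")
            if key == "ptm":
                ptms = _parse_ptm_spec(value)
            elif key == "gene":
                source = value
        peptides.append(
            Peptide(sequence=str(record.seq).upper(), ptms=ptms,
                    label=record.id, source_proteoform=source)
        )
    return peptides


def packaged_peptides() -> dict:
    """The shipped tropomyosin peptide fixtures, keyed by label."""
    path = resources.files("kinseq.data").joinpath("tpm_peptides.fasta")
    with resources.as_file(path) as p:
        return {pep.label: pep for pep in read_peptides_fasta(p)}
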