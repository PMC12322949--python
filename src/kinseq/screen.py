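"""In-silico Lys-C digestion and proteoform-informative peptide screening.

Proteoforms of the same gene family (paralogues, spliceforms) can differ by a
single residue, so the first step of a targeted sequencing experiment is to
find digest peptides that are unique to one proteoform or gene.  Specificity
is decided by substring search over the proteoform protein sequences: a
peptide found in exactly one proteoform is proteoform-specific; found in
several proteoforms of a single gene it is gene-specific (equivalently,
shared within that gene's spliceforms); otherwise non-specific.

Candidate peptides are then screened with four sequenceability criteria:
a C-terminal lysine (required by the library chemistry, which conjugates
through the terminal Lys), at least 3 residues cognate to the recognizer set,
at least 3 distinct recognizers hit, and a length of 5-25 residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .reference import CANONICAL_AA, ConfigurationError, RecognizerTable, _check_residues

PROTEOFORM_SPECIFIC = "proteoform-specific"
GENE_SPECIFIC = "gene-specific"
#: spliceforms of one gene share gene-specific peptides; alias kept for clarity
SHARED_WITHIN_GENE = GENE_SPECIFIC
NON_SPECIFIC = "non-specific"

#: labels used to report which selection criteria a peptide failed
FAIL_CTERM_K = "no-cterm-K"
FAIL_COGNATES = "too-few-cognate-aa"
FAIL_RECOGNIZERS = "too-few-recognizers"
FAIL_LENGTH = "length-out-of-range"


@dataclass(frozen=True)
class Proteoform:
    """One protein product: accession, parent gene, amino-acid sequence."""

    id: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ConfigurationError(f"proteoform {self.id!r}: empty sequence")
        _check_residues(self.sequence, f"proteoform {self.id!r}")


@dataclass
class DigestPeptide:
    """A digest product, its parent proteoforms and specificity class."""

    sequence: str
    parent_ids: set = field(default_factory=set)
    start_positions: dict = field(default_factory=dict)  # proteoform id -> 1-based
    specificity: Optional[str] = None


@dataclass(frozen=True)
class SelectionCriteria:
    """The four sequenceability checks, with the shipped defaults."""

    require_cterm_k: bool = True
    min_cognate_aa: int = 3
    min_distinct_recognizers: int = 3
    min_length: int = 5
    max_length: int = 25

    def __post_init__(self) -> None:
        if self.min_length <= 0 or self.max_length < self.min_length:
            raise ConfigurationError("invalid length bounds")


def digest_lysc(proteoform: Proteoform, missed_cleavages: int = 0,
                cleave_before_proline: bool = True) -> List[DigestPeptide]:
    """Digest a proteoform with Lys-C: cleavage strictly after every K.

    Unlike trypsin, Lys-C cleaves Lys-Pro bonds; set
    ``cleave_before_proline=False`` for the trypsin-like rule.  With
    ``missed_cleavages=m`` every concatenation of up to m+1 adjacent fragments
    is returned, ordered N→C.  Every occurrence is kept (a repeated fragment
    such as successive lysines appears once per site), so the fully cleaved
    products concatenate back to the input.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    seq = proteoform.sequence
    # fully cleaved fragment boundaries
    bounds = []
    start = 0
    for i, aa in enumerate(seq):
        if aa == "K" and (cleave_before_proline or i + 1 >= len(seq) or seq[i + 1] != "P"):
            bounds.append((start, i + 1))
            start = i + 1
    if start < len(seq):
        bounds.append((start, len(seq)))

    out = []
    for i in range(len(bounds)):
        for j in range(i, min(i + missed_cleavages + 1, len(bounds))):
            s, e = bounds[i][0], bounds[j][1]
            out.append(DigestPeptide(
                sequence=seq[s:e],
                parent_ids={proteoform.id},
                start_positions={proteoform.id: s + 1},
            ))
    return out


def classify_specificity(peptides: Sequence[DigestPeptide],
                         proteome: Sequence[Proteoform]) -> List[DigestPeptide]:
    """Assign each peptide's specificity by substring search over ``proteome``.

    Parents and start positions are recomputed from the hits, so the result is
    independent of how the peptides were produced and of proteome ordering.
    """
    result = []
    for pep in peptides:
        hits = [pf for pf in proteome if pep.sequence in pf.sequence]
        if not hits:
            raise ValueError(
                f"peptide {pep.sequence!r} not found in any supplied proteoform"
            )
        genes = {pf.gene for pf in hits}
        if len(hits) == 1:
            spec = PROTEOFORM_SPECIFIC
        elif len(genes) == 1:
            spec = GENE_SPECIFIC
        else:
            spec = NON_SPECIFIC
        result.append(
            DigestPeptide(
                sequence=pep.sequence,
                parent_ids={pf.id for pf in hits},
                start_positions={
                    pf.id: pf.sequence.index(pep.sequence) + 1 for pf in hits
                },
                specificity=spec,
            )
        )
    return result


def passes_selection(peptide, table: RecognizerTable,
                     criteria: Optional[SelectionCriteria] = None):
    """Evaluate the four sequenceability criteria.

    ``peptide`` may be a sequence string, a ``DigestPeptide`` or anything with
    a ``sequence`` attribute.  Returns ``(passed, failed_labels)`` where
    ``failed_labels`` lists every criterion that failed (empty on a pass).
    Cognate residues are counted with multiplicity; recognizers are counted as
    distinct recognizer names hit.
    """
    criteria = criteria or SelectionCriteria()
    seq = peptide if isinstance(peptide, str) else peptide.sequence
    failed = []
    if criteria.require_cterm_k and not seq.endswith("K"):
        failed.append(FAIL_CTERM_K)
    cognate_count = sum(1 for aa in seq if aa in table.cognate_union)
    if cognate_count < criteria.min_cognate_aa:
        failed.append(FAIL_COGNATES)
    recognizers = {
        table.recognizer_for(aa).name for aa in seq if aa in table.cognate_union
    }
    if len(recognizers) < criteria.min_distinct_recognizers:
        failed.append(FAIL_RECOGNIZERS)
    if not criteria.min_length <= len(seq) <= criteria.max_length:
        failed.append(FAIL_LENGTH)
    return (not failed), failed


def screen_proteome(proteome: Sequence[Proteoform], table: RecognizerTable,
                    criteria: Optional[SelectionCriteria] = None,
                    missed_cleavages: int = 0) -> pd.DataFrame:
    """Digest every proteoform, classify specificity and apply the selection
    criteria; returns one tidy row per distinct digest peptide."""
    seen: dict = {}
    for pf in proteome:
        for pep in digest_lysc(pf, missed_cleavages=missed_cleavages):
            seen.setdefault(pep.sequence, pep)
    classified = classify_specificity(list(seen.values()), proteome)
    rows = []
    for pep in sorted(classified, key=lambda p: p.sequence):
        ok, failed = passes_selection(pep, table, criteria)
        rows.append(
            {
                "peptide": pep.sequence,
                "parents": ";".join(sorted(pep.parent_ids)),
                "specificity": pep.specificity,
                "passes": ok,
                "failed_criteria": ";".join(failed),
            }
        )
    return pd.DataFrame(rows)


def read_proteome_fasta(path) -> List[Proteoform]:
    """Read proteoforms from FASTA with ``id|gene`` headers (gene defaults to
    the id when no ``|`` is present)."""
    from Bio import SeqIO

    proteome = []
    for record in SeqIO.parse(str(path), "fasta"):
        pid, _, gene = record.id.partition("|")
        proteome.append(
            Proteoform(id=pid, gene=gene or pid, sequence=str(record.seq).upper())
        )
    return proteome
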