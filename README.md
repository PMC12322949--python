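# kinseq

Simulation and analysis of **recognizer-based single-molecule protein
sequencing kinetics**, built around the problem of telling apart
proteoforms — protein variants of one gene family — whose peptides differ
by as little as a single isobaric residue (Leu/Ile) or one phosphate group.

In this sequencing modality a peptide sits alone in a nanoaperture while
aminopeptidases remove residues one at a time and fluorophore-labeled
recognizers bind each exposed N-terminal amino acid (NAA) reversibly. Every
recognized residue produces a *recognition segment* (RS): a train of light
pulses whose **pulse duration** (PD) distribution is characteristic of the
(recognizer, NAA) pair. The ordered RS series with its PD statistics — the
*kinetic signature* — carries both residue identity and position, which is
exactly what mass spectrometry struggles to provide for isobaric or highly
similar peptides. Tropomyosin (TPM1/TPM2) peptides are the shipped model
system: paralogue pairs ENALDRAEQAEADK/ENAIDRAEQAEADK and
VIESRAQK/VIENRAMK, spliceform peptides SLMASEEEYSTK, TIDDLEETLASAK and
TIDDLEDEVYAQK, and the phosphotyrosine form of the latter.

The package is for computational proteomics researchers who want a tested,
fully synthetic testbed for this data type: every stage is replaceable, and
simulated runs carry hidden truth labels so analysis claims can be checked
exactly.

## What it implements

| Stage | Module | Core idea |
|---|---|---|
| Peptide screening | `kinseq.screen` | in-silico Lys-C digestion, proteoform-specificity by substring search, four sequenceability criteria (C-terminal K, ≥3 cognate residues, ≥3 recognizers, length 5–25) |
| Reference model | `kinseq.reference` | recognizer/dye/kinetics calibration table; expected kinetic profile of a peptide, with multiplicative PTM perturbations |
| Simulation | `kinseq.simulate` | per-aperture pulse lists: exponential PDs with mean μ(recognizer, NAA), geometric pulse counts per RS (binding races cleavage), dark residues, dye photophysics, dropout |
| Primary analysis | `kinseq.primary` | Gaussian-mixture dye calling on (intensity, lifetime); RS segmentation by dye change / gap threshold |
| Alignment | `kinseq.align` | dynamic programming over (RS, reference step) pairs scoring recognizer agreement plus a `−|ln(PD_obs/PD_exp)|` kinetic term; shuffled-decoy q-values |
| Statistics | `kinseq.stats` | per-position PD collection via traceback, PD fold changes with flow-cell replicates and t-tests, aperture-fraction PTM readout with Welch tests |

The discriminating statistic for a residue substitution at position *p* is
the PD fold change

&nbsp;&nbsp;&nbsp;&nbsp;FC(p) = geomean over flow cells of ⟨PD⟩ₐ(p) / ⟨PD⟩ᵦ(p),

tested against FC = 1 with a two-tailed t-test of the log ratios (flow
cells are the replicate unit). PTM detection uses the percentage of
apertures containing ≥1 RS of a recognizer, compared between conditions
with a Welch two-sample t-test: phosphorylation of Tyr weakens binding by
the aromatic-residue recognizer, so the Tyr RS rate collapses while
unaffected recognizers stay put.

## Worked example

Discriminate the Asn/Ser substitution at position 4 of the paralogue pair
VIENRAMK/VIESRAQK from a simulated equimolar run (three flow cells of 400
apertures):

```python
import numpy as np
from kinseq import packaged_peptides, run_pair_experiment

peptides = packaged_peptides()
result = run_pair_experiment(
    peptides["VIENRAMK"], peptides["VIESRAQK"],
    seed=1, n_flow_cells=3, n_apertures=400,
)
fc = result.fold_change("VIENRAMK", "VIESRAQK", 4)
asn = result.pooled_position_values("VIENRAMK", 4)
ser = result.pooled_position_values("VIESRAQK", 4)
print(f"position-4 mean PD  Asn: {np.mean(asn):.3f} s  (n={len(asn)} apertures)")
print(f"position-4 mean PD  Ser: {np.mean(ser):.3f} s  (n={len(ser)} apertures)")
print(f"PD fold change (Asn/Ser): {fc.fold_change:.2f}  "
      f"(sd {fc.sd:.2f}, p = {fc.p_value:.1e}, {fc.n_replicates} flow cells)")
```

Output:

```
position-4 mean PD  Asn: 1.005 s  (n=154 apertures)
position-4 mean PD  Ser: 0.205 s  (n=142 apertures)
PD fold change (Asn/Ser): 4.90  (sd 0.12, p = 7.4e-05, 3 flow cells)
```

Reads were simulated, dye-called, segmented into RSs, aligned against both
reference profiles plus shuffled decoys, and retained at q ≤ 0.05; each
retained aperture contributes its position-4 RS mean PD. The ~5× fold
change is the Asn-vs-Ser kinetic contrast in the shipped calibration
(N: 1.0 s, S: 0.2 s), recovered end to end from pulse-level data.

The same machinery is available from the shell:

```bash
kinseq digest  --fasta proteome.fasta -o peptides.csv
kinseq screen  --fasta proteome.fasta -o screen.csv
kinseq all     --config experiment.yaml     # simulate→analyze→align→compare
```

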