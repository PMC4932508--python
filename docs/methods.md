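# Methods

## Problem setting and model

A 2S albumin is modelled as a single mature chain with three annotations:
a disulphide topology (unordered Cys position pairs, each Cys in at most
one bond), a set of hydroxyproline positions, and a list of natural
terminal-processing variants `(n_trim, c_trim)` treated as alternative
parent sequences rather than as cleavage events. Coordinates are 1-based;
a cleavage site at position *i* cuts the bond between residues *i* and
*i+1*, matching the residue-subscript convention used in the allergen
literature (Arg59, Arg123, ...).

Partial digestion is a subset of the permitted cleavage sites. The chain
fragments of a state tile the sequence (k cuts → k+1 fragments); the
observable species are the connected components of the graph whose nodes
are fragments and whose edges are disulphide bonds joining two fragments.
A singleton fragment without a bonded cysteine is *released* and no
longer co-purifies with the digestion-resistant core.

## Cleavage rules

The default trypsin rule cleaves after Lys/Arg unless the next residue is
Pro. The fuller Keil exception table (no cleavage in CKD, DKD, CKH, CKY,
KKR, CRK, RRH, RRR contexts; WKP and MRP cleave despite the proline
block) is available as an alternative ruleset because published
site-location tools differ in whether they apply it; the minimal rule is
the default. Structural accessibility (a buried Arg next to a disulphide)
is deliberately *not* a sequence rule — it is what the flexibility
classifier measures.

## Masses

Neutral chain mass = Σ residue masses + water, with residue masses taken
from elemental compositions (monoisotopic by default; an average-mass
mode exists because some reported species tables print integer-Da values
of unstated convention). Modification bookkeeping:

| quantity | monoisotopic | average |
|---|---|---|
| water | 18.010565 | 18.0153 |
| proton | 1.007276 | 1.007276 |
| per disulphide | −2.015650 | −2.0159 |
| hydroxyproline | +15.994915 | +15.9994 |
| alkylated Cys | +57.021464 | +57.0513 |

Intact species mass = Σ chain masses + n_SS·(−2 H); alkylation is only
possible after reduction, so an intact species never carries +57.
Hydroxyproline occupancy is treated as binary per annotated site,
producing a +16-spaced sub-ladder (site-specific but not necessarily
stoichiometric hydroxylation); partial alkylation of a reduced chain with
n cysteines gives the n+1-member +57 ladder.

Theoretical pI solves Σ charges(pH) = 0 by Brent bisection on pH 0–14
using the EMBOSS pKa table (N-term 8.6, C-term 3.6, K 10.8, R 12.5,
H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1). Different published pKa sets shift
absolute pI by roughly ±0.3 pH units, so pI is used as a verification
direction, not a hard filter. All cysteines are treated as titratable;
for disulphide-bonded species this slightly underestimates pI.

## Deconvolution

Every (peak, z) interpretation back-calculates a neutral-mass candidate
M = z·(m/z − 1.007276). Candidates are sorted and clustered greedily
within the ppm tolerance (default 10 ppm, the instrument's stated
precursor tolerance); a cluster is an envelope when at least two distinct
peaks at consecutive charges agree. Envelopes are accepted greedily by
decreasing support, consuming their peaks; remaining peaks explainable by
an accepted mass at any charge within twice the tolerance are absorbed.
The absorption step is essential: with ppm-level noise an envelope can
split, and its leftover even-charge peaks would otherwise form a
perfectly consistent consensus at M/2 (wrong-charge back-calculations of
one mass give exactly M·c/z — the proton term cancels). The consensus
mass is the mean of the contributing back-calculations; intensities are
reported but never scored. When the charge range is pinned
(z_min = z_max) leftover peaks are reported individually with support 1
and flagged.

## Joint inference

For every terminal variant and every cleavage subset up to `max_cuts`
(default 6; the recovery experiments use 3, matching their ≤3 planted
cuts), species are assembled and two theoretical mass sets are built: the
intact species masses with their hydroxylation sub-ladders, and the
per-chain hydroxylation × alkylation ladders for the reduced sample.
States whose theoretical masses cannot come within ±0.5% of any observed
mass are pruned before ladder expansion. Candidates are ranked by

1. number of distinct experimental masses explained (both samples),
2. joint consistency — every matched intact species must have each chain
   matched in the reduced sample with hydroxylation counts that can sum
   to the intact assignment (the −2 H/+57 algebra then reconstructs the
   intact mass exactly, by construction of the theoretical sets),
3. lower mean |ppm error|,
4. fewer cuts (parsimony last, favouring minimal-hydrolysis readings),

with the cut tuple as a final deterministic tie-break. An empty ranking
is reported with diagnostics rather than an exception at the library
level; the CLI maps it to exit code 4.

## Flexibility analysis

RMSF uses sliding windows (default 20 frames, stride 1) with the
window-local mean as reference: per atom, the RMS displacement from the
window mean; per residue, the mean over selected atoms (backbone = N, CA,
C, O); per profile, the mean over windows. Stride and reference are
configurable since conventions differ between analysis tools; a window
equal to the trajectory length reproduces the whole-trajectory RMSF. Rg
is mass-weighted; RMSD optionally applies a Kabsch SVD superposition
(with determinant correction) before averaging.

A site is predicted susceptible when its RMSF is **strictly greater**
than the cutoff (default 0.65 Å, the threshold at which observed
susceptible and resistant site populations separate); a site exactly at
the cutoff is resistant. Evaluation reports TP/FP/TN/FN with
susceptibility as the positive class; "PPV for resistance" is TN/(TN+FN),
i.e. the PPV of the mirrored classifier — numerically identical to the
NPV of the susceptibility classifier, and reported to the nearest
integer percent.

## Synthetic data: what it emulates, what it does not

`gen_isoform` builds the eight-cysteine skeleton with randomized spacer
lengths (the largest spacer is the unstructured loop between the second
and third cysteine), K/R guaranteed in the termini and loop, prolines
seeded into the loop for hydroxylation sites, and a nested disulphide
pairing (C1–C6, C2–C5, C3–C7, C4–C8) that keeps the core cross-linked.
Defaults — 140 residues, 4 bonds, 3 hydroxyprolines — are at the scale of
the peanut conglutin mature chains.

`gen_flex_profile` draws correlated Gaussian noise (correlation length 6
residues) around a 0.80 Å baseline, raises the termini, and multiplies in
dips at bonded cysteines and short inter-cysteine (helical core)
segments; labels apply the production 0.65 Å rule and are then flipped
with `label_flip_prob`. `simulate_true_digestion` samples planted cuts
with probability ∝ RMSF⁶, concentrating them in termini and loop as
observed for real conglutins. `gen_peaklists` emits charge-state
envelopes (+8..+17 preferred for intact, +4..+12 for reduced, clipped to
the 300–3000 m/z window) with seeded Gaussian ppm noise (default 5 ppm)
and log-normal intensities; a mass with fewer than two observable charges
in the window is skipped and recorded as unobservable in the manifest,
as it would be invisible to envelope-based deconvolution on such a scan.

Passing the recovery experiments therefore shows that the joint
intact/reduced ranking identifies planted states under ppm-accurate,
full-ladder, single-protein conditions. It does not exercise co-eluting
isoform mixtures, isotopic fine structure, adducts, missing ladder
members, or real MD trajectories — the RMSF layer is validated against
numerical oracles and constructed profiles, not against simulation data.

## Numerical choices and limitations

- Matching tolerance 10 ppm (monoisotopic) or 1.0 Da (average mode);
  deconvolution clustering uses the same ppm tolerance, absorption 2×.
- Bisection tolerance for pI: 1e-6 pH; net charge at the solution is
  below 1e-3 by construction of the monotone charge function.
- RMSF windows require ≥2 frames and frame count ≥ window.
- Enumeration is exhaustive; with ~15–20 tryptic sites and max_cuts 6 the
  state count stays below ~40k, and the ±0.5% guard band prunes most
  states before ladder expansion. Recovery experiments use 200 datasets,
  140-residue isoforms and max_cuts 3 — sizes chosen so the whole
  experiment completes in a few minutes on one core.
- Ambiguities among competing assignments of one experimental mass are
  all reported, in the documented tie-break order. The ~5% of synthetic
  datasets where the planted state is not top-ranked are cases where an
  extra planted cut sits within a few residues of a terminus or of
  another cut: the released mini-peptide is unobservable in the scan
  window, both states explain exactly the same masses, and the parsimony
  tie-break prefers the state with fewer cuts. The planted state still
  appears in the ranking (top-3 in every seeded run measured); no
  mass-only method can separate such pairs.
- mzML ingestion and binary MD formats (DCD/XTC) are out of scope;
  `drpcore.io` is the documented adapter seam.
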