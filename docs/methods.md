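# Methods

## Problem and scope

`fentaqsar` predicts the μ-opioid receptor (μOR) binding affinity, as
pKi = −log₁₀(Ki [M]), of fentanyl-like molecules from structure alone,
and uses that predictive machinery for two downstream analyses: mining
activity cliffs in an assayed analog set, and ranking large enumerated
libraries of hypothetical analogs by a consensus of three models. The
intended users are forensic/regulatory chemists triaging novel synthetic
opioids and medicinal chemists exploring the 4-anilidopiperidine series.

## The three affinity models

**Field-based 3D-QSAR.** Each molecule receives a single conformer from
ETKDG distance geometry with the atoms of its maximum common substructure
(MCS) with a fentanyl template pinned to the template's coordinates,
optionally refined with MMFF94, then rigidly superposed onto the template
by a Kabsch least-squares fit over the MCS atoms. Molecules sharing fewer
than 6 heavy atoms of complete-ring MCS with the template are excluded
(logged). Molecular interaction fields are sampled on a regular grid
(1.0 Å spacing, 4.0 Å margin around the training set) with two classical
probes per point:

- steric: Σᵢ (r_min,i / rᵢ)¹², with r_min,i the atom's van der Waals
  radius plus a 1.7 Å sp³-carbon probe radius, truncated at +30;
- electrostatic: Σᵢ qᵢ·q_probe/(ε·rᵢ) with q_probe = +1 and a
  distance-dependent dielectric ε = r (hence qᵢ/rᵢ²), truncated at ±30.

Contributions vanish beyond an 8 Å per-atom cutoff; distances are floored
at 0.1 Å so a grid point inside an atom reports the cap, not a pole.
Charges are Gasteiger charges with hydrogen charges absorbed into their
heavy atoms; descriptors use heavy-atom coordinates only. The piperidine
amine is protonated (the pH-7 form) for the field model, because the key
positive-field feature near the basic nitrogen — the salt bridge to the
conserved aspartate of the μOR binding pocket — requires the cation. The
proprietary "field point" descriptors of the commercial lineage this
workflow mirrors are deliberately replaced by these open CoMFA-style
probes; the hydrophobic/shape channel is approximated by the steric probe
alone.

The descriptor matrix (zero-variance columns dropped) is regressed on
pKi with an explicit SIMPLS partial-least-squares fit: weight vectors are
extracted directly from the deflated covariance s = XᶜᵀYᶜ, scores are
unit-normalized and mutually orthogonal, and the regression vector is
B = R·qᵀ. The component count (≤ 10 by default) maximizes leave-one-out
q²; ties go to the smaller count. A single LOO pass per fold evaluates
the whole component path, which is numerically identical to refitting
per count (property-tested).

**Fingerprint kNN models.** Two k-nearest-neighbour regressors over
Tanimoto distances of hashed circular fingerprints of diameter 6:
connectivity invariants (ECFP6-like) and pharmacophoric feature
invariants in the six-feature Rogers–Hahn convention (FCFP6-like), both
folded to 2048 bits. A query's pKi is the inverse-distance-weighted mean
of its k = 5 nearest training compounds (ties broken by training order);
exact structural matches (distance < 1e−9) short-circuit to the plain
mean of the matching compounds. k is a documented substitute default —
the workflow this re-implements does not state one — and `select_k`
chooses it by LOO q² when asked. Predictions are bounded by the
neighbours' activity range by construction.

**Consensus.** A molecule's consensus prediction is the median of the
per-model predictions that fall inside each model's applicability domain
(median of two = their mean; absent if no model is in-domain). Domains:
kNN models require a maximum training-set Tanimoto similarity ≥ 0.40
(inclusive); the field model requires a leverage below 3(A+1)/n. Leverage
is computed in the A-dimensional PLS score space (the Williams-plot
convention): with thousands of grid descriptors and ~100 training rows,
raw-descriptor leverage saturates near 1 for every compound — including
the training set — so the classic cutoff is only meaningful on the
scores. Both thresholds are configurable.

## Validation

r² is reported as the squared Pearson correlation (with 1 − SSE/SST
additionally exposed as `r2_fit`), q² as 1 − PRESS/TSS under strict
leave-one-out refitting, and the error metrics are MSE, MAE and MAPE in
percent on the pKi scale. No ordering between test-set r² and q² is
assumed (the Kubinyi paradox). Every metric and the LOO loop are checked
against naive reimplementations; SIMPLS is checked against an
independent NIPALS oracle and, at full rank, against the least-squares
solution.

## Activity-cliff mining

All molecule pairs are scored by disparity = Δactivity / distance (the
SALI idea), with the more-active molecule first so Δ and disparity are
≤ 0. The default landscape metric is 1 − Tanimoto(ECFP6); a 3D mode uses
the cosine distance of field-descriptor rows under the same template
alignment. Pairs closer than `min_distance` (default 0.01) are excluded
as near-duplicates and counted, preventing division blow-up. Ranking is
by |disparity|, ties by |Δ|, then ids.

## Scaffold-hopping screen

Six series each vary one region of fentanyl and hold the rest: the N-tail,
the anilide N-aryl, a piperidine C3 decoration, the acyl substituent, a
para position of the anilide phenyl, and the phenethyl aryl. The region
boundaries are graphical in the source material; the shipped scaffolds
are this package's documented interpretation. Every fragment of a
single-attachment library (dummy atom, map number 1) is welded onto each
scaffold, products are valence-checked, restricted to single fragments
≤ 700 Da, deduplicated by canonical SMILES, sorted canonically and
capped (default 500 per series, after deduplication). Duplicates across
series are retained: identity is series-scoped. With the default
six series × cap 500 over a ≥ 600-fragment library, exactly 3000
consensus predictions are attempted.

For screening throughput the field model embeds products with the series
scaffold as a precomputed alignment core (skipping the per-molecule MCS
search) and uses distance-geometry conformers without MMFF refinement;
training conformers are always MMFF-refined. The constrained embedding
pins the shared core to the template coordinates, so the unrefined
geometries differ from refined ones mainly in the varied region; the
residual descriptor noise there is accepted in exchange for a screen that
runs in minutes on one CPU. Per-molecule embedding seeds derive from a
CRC of the canonical SMILES XOR the run seed, so results are independent
of enumeration order.

## Synthetic study set

The assayed compound set behind the original μOR models is a curated
ChEMBL subset that is not redistributable compound-by-compound, so the
package generates a stand-in with known ground truth: 115 analogs
decorated at five positions of the 4-anilidopiperidine scaffold (N-tail
R1, piperidine-4 R2, acyl R3, piperidine-3 R4, N-aryl R5), sampled so
each site keeps its fentanyl-native group with high probability — giving
the congeneric, single/double-point-variation structure of real SAR
series. pKi = 7.1 + Σ site contributions + N(0, σ²), clipped to the
experimental range [5.3, 10.1]; σ defaults to 0.2 pKi units, a typical
inter-assay Ki spread. The contribution table is fixed package data
chosen once to emulate the qualitative landscape of fentanyl SAR:
acyl removal (R3 = H, contribution −1.9) collapses potency, acyl chains
longer than propionyl erode it, aromatic R5 is favourable and its
removal costs ~1 log unit. Fentanyl itself and its acyl-removal partner
are always included, so cliff mining on the noise-free set recovers
acyl-removal cliffs.

What passing recovery tests shows: the pipeline can learn an additive,
locally smooth structure–activity landscape from 94 compounds and
generalize to 21 held-out analogs (external r² ≥ 0.6 for all three
models under the default seeds). What it does not show: performance on
real assay data, whose SAR is neither exactly additive nor noise-free in
a Gaussian way, and whose conformational ensembles are richer than one
embedded conformer. The generated pKi values carry no claim about real
compounds.

## Numerical choices and degenerate inputs

- SIMPLS truncates (with a warning) when the requested component count
  exceeds the rank of centered X; a zero-variance response is an error.
- LOO never skips a failing fold — the whole computation errors.
- Fingerprints of every parsable molecule are non-empty by construction;
  flavor/length mismatches are errors, not coercions.
- kNN tie-breaks at the k-th neighbour use stable training order.
- Distance-geometry embedding retries once with a shifted seed, then
  falls back to unconstrained embedding plus Kabsch alignment before
  declaring an alignment failure; failed molecules are excluded from
  training (logged) or predicted as NaN/out-of-domain.
- Ki ≤ 0, empty training tables, k outside [1, n], caps < 1 and
  metrics outside [0, 1] are rejected loudly.

## Known limitations

- One conformer per molecule; no ensembles and no flexible alignment.
- Gasteiger charges and a two-probe grid are a coarse stand-in for
  semi-empirical charges and richer field descriptors; absolute field
  energies are in arbitrary capped units.
- The scaffold-welding enumeration does not score synthetic
  accessibility or ADMET, and the fragment library is combinatorial
  rather than curated.
- Template alignment assumes the 4-anilidopiperidine (or a ≥ 6-atom
  common core) is present; the field model cannot score genuinely
  dissimilar chemotypes, which the applicability domain is designed to
  flag rather than fix.
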