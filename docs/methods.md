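# Methods

This note documents the models, conventions and numerical choices behind
`ifscreen`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Structure model and superposition

Coordinates live in a flat `(n_models, n_atoms, 3)` array over one shared
topology; multi-model PDB files are read and written through gemmi with
author residue numbering and insertion codes preserved verbatim (the
binding-site residue lists and contact rules are stated in author
numbering, so renumbering would corrupt them). Units are Å everywhere;
values quoted in nm (clustering cutoffs) are converted once at the
configuration boundary.

Superposition is the Kabsch least-squares fit (SVD with a determinant
correction, so the rotation is always proper). Fewer than three atoms or
a collinear set is an error rather than a silently unstable fit.

Ensemble RMSD supports two conventions, because published "ensemble RMSD
over N structures" figures rarely say which was used:

- `mean_pairwise` (default): the mean of all N(N−1)/2 pairwise
  superposed RMSDs, each pair superposed on the selection itself;
- `to_mean`: models aligned iteratively to their mean structure (5
  rounds), then the mean of per-model RMSDs to that mean. This is
  systematically smaller (roughly by √2 for Gaussian scatter).

Both are exposed on the API and the CLI; the deposited-ensemble check
script reports both, together with N,CA,C vs N,CA,C,O backbone atom sets.
RMSF uses the Cα convention after the same iterative alignment.

## Interface descriptors

The four pose-filter quantities and their conventions. The filter
thresholds themselves (BSA ≥ 2750 Å², MHP ≥ 0.5, ≥ 6 ionic, ≥ 7 H-bonds)
are data, not geometry: they are kept verbatim and inclusive.

**SASA / BSA.** Shrake–Rupley with a deterministic Fibonacci sphere
lattice, probe 1.4 Å, 960 points per atom (total area stable to ±2 %
under point doubling), Bondi vdW radii with a 1.70 Å fallback for unknown
elements. BSA is computed per partner as the area accessible alone but
occluded in the complex, then summed — algebraically identical to
SASA(A) + SASA(B) − SASA(AB) but exactly symmetric in the partner order.
Inter-partner atom distances below 1.0 Å are treated as a steric clash
and refused rather than silently producing a huge BSA.

**Hydrogen bonds.** Donor/acceptor heavy-atom typing per residue
(backbone N/O plus standard side chains; MAN/NAG/BMA glycan hydroxyls
and NAG N2/O7 are included so receptor glycans can bond). Criterion:
donor–acceptor distance ≤ 3.5 Å; when the donor carries explicit
hydrogens the D–H···A angle must be ≥ 120°, otherwise the distance
criterion alone applies (docking poses usually lack hydrogens; the
criteria degrade gracefully). One bond per unordered atom pair
(hydroxyl–hydroxyl pairs are not double-counted for the two donor
directions). The filter counts H-bonds at atom-pair level.

**Ionic bridges.** Arg NE/NH1/NH2 and Lys NZ vs Asp OD1/OD2, Glu
OE1/OE2 and C-terminal OXT within 4.0 Å; His is neutral unless
`his_charged` is set. Deduplicated to one bridge per residue pair — a
bidentate Arg–Asp pair is one bridge, matching how named salt-bridge
pairs are tabulated. Note a 3 Å N–O bridge also satisfies the H-bond
criterion; contact records carry both kinds, as interaction tables in
this field do ("I, H").

**Stacking.** Ring centroids (SVD plane fit) of Phe/Tyr/His/Trp within
5.5 Å and interplanar angle in the parallel (0–30°) or T-shaped (60–90°)
band, both enabled by default.

**MHP complementarity.** The molecular hydrophobicity potential at a
surface point p is Σᵢ fᵢ·exp(−d(p,i)/λ) with λ = 2.0 Å and atomic
constants fᵢ from a simplified Ghose–Crippen-style table (apolar atoms
positive, polar negative; per-residue/atom overrides available). The
score is the fraction of buried surface points — points accessible on a
partner alone but occluded in the complex, pooled over both partners —
where the two partners' fields share a sign. It is 1 for hydrophobic-on-
hydrophobic, 0 for hydrophobic-on-polar, and undefined (None, with a
warning) when nothing is buried; the filter rejects poses with an
undefined score. The exact functional form of the original
complementarity score is not published, so this form is declared,
configurable, and validated by its own constructions; the 0.5 threshold
is kept as given.

## gromos clustering

Daura neighbor-count clustering: the conformer with the most neighbors
within the RMSD cutoff becomes a representative, it and its neighbors
are removed, repeat. Two conventions are fixed for determinism and
documented: the neighbor relation is inclusive (≤ cutoff), and ties in
neighbor count go to the lowest conformer index. Clusters are returned
in descending size (stable within equal sizes). The original ensembles'
cluster counts (93/53/54/57) require the original trajectories and are
shipped only as narrative presets, not asserted.

## Two-stage post-scoring

`plan_runs` is exact integer bookkeeping over the conformer grid.
The non-specific stage keeps a pose iff all four descriptors meet their
inclusive thresholds; per-criterion rejection tallies let one see which
criterion does the work (a pose can count in several).

The specific stage imposes contact rules of the form "at least one
receptor residue from {left set} contacts at least one ligand residue
from {right set}", with a qualifying contact being ionic or hydrogen-
bonded (configurable). The default mode requires **every** rule
simultaneously — the stringent reading; `any_rule` is available. The
shipped rule sets are the β2(+)/β2(−) and α4(+)/β2(−) lists of the
original screening.

The original pipeline's final step picked one pose per interface by
visual inspection; `composite_rank` replaces that with a deterministic
sum of descriptor z-scores (a documented departure — it reproduces the
spirit, not the judgement). The original funnel counts (5483/4075/1671;
14/19) require the original half-million-pose ensembles and are not
reproducible at desk scale; the funnel logic is instead verified exactly
on planted synthetic ensembles of 200 poses.

## Contact persistence

Frames before the equilibration cut (default 30 ns) are discarded; the
lifetime of a (residue pair, kind) is present-frames / retained-frames,
held as an exact rational (`fractions.Fraction`), so the ≥ 20 %
reporting and ≥ 50 % highlight comparisons are exact at the boundary —
float thresholds are parsed via their decimal string to avoid binary
representation artifacts. The "simulation time" denominator is the
retained window (a 500 ns run with 30 ns discarded has a 470 ns
denominator). `window_split` reproduces per-segment tables (e.g. before
and after a rearrangement). The rearrangement detector is a deliberately
minimal step heuristic — flag the first frame whose RMSD exceeds the
running pre-step median by a jump threshold (default 1.5 Å) for a
sustained run of frames (default 5) — because the original event was
identified visually; no formal changepoint statistics are implied.

## Hill dose–response model

`response(D) = bottom + (top − bottom)/(1 + (D/IC50)^nH)` on the
normalized-current scale, top fixed at 100 %. The "maximal inhibition"
level of the receptor panel is interpreted as the shared bottom plateau
(31 % of control at the study conditions), shared because the highest
attainable dose does not define the plateau for every subtype; the
orientation is configurable. Fitting is multi-start trust-region least
squares (`scipy.optimize.least_squares`) over per-dataset (log IC50, nH)
plus the shared bottom, with IC50 starts log-spaced over the pooled dose
range; the log parameterization keeps IC50 positive and makes the nM/μM
rescaling property exact. Standard errors come from the asymptotic
covariance (IC50 SE delta-propagated from the log scale); a seeded
percentile bootstrap over replicates is available. Non-convergence is a
flagged result with diagnostics, not an exception.

At the study conditions (doses 3/10/30/100 μM, 6 replicates per point —
the experimental n was 5–8 — and σ = 5 points), the IC50 of the shallow
low-sensitivity dataset is intrinsically poorly determined: its median
absolute error is ~10–20 % regardless of estimator. The estimator is,
however, nearly median-unbiased: the median signed relative error of the
IC50s stays under 5 % and the median bottom error under 3 points over
100 seeds, which is what the acceptance suite asserts.

## Sequence properties

Average (not monoisotopic) masses from the IUPAC atomic-weight residue
table; disulfide oxidation removes 2 × 1.00794 Da per bridge; [M+zH]ᶻ⁺
adds one average H mass per charge; ε₂₈₀ = 5500·nTrp + 1490·nTyr +
125·ncystine. Rounding to printed precision happens only in reports,
never internally. The ws-PSCA constant is the N-terminal Met plus the
mature Ly6 domain of human PSCA (UniProt O43653, Leu12–Ser86), 76
residues, five disulfides; it reproduces the published 8350 Da reduced
mass, 4171.2 Da oxidized [M+2H]²⁺ and ε₂₈₀ = 10,595 M⁻¹cm⁻¹.

## NMR dynamics flags

All thresholds are strict inequalities, per their published wording:
boundary values (S² = 0.8, Rex = 3 s⁻¹, R1·R2 = 16 s⁻², intensity ratio
= 0.2, Δδ¹Hᴺ/ΔT = −4.5 ppb/K, t½ = 20 min) fall on the non-flagged
side. The three slow-exchange indicators combine by OR. The HNCO
broadening ratio is referenced to the mean intensity over the stable
residue set (Rex < 3 and S² > 0.8), computed by a helper and passed in;
an invisible peak is encoded as ratio 0. Missing observables give an
indeterminate (None/NA) flag, never a silent False. Full Lipari–Szabo
model-free fitting is out of scope — only the downstream classification
of its outputs is implemented.

## Synthetic data: what it emulates, and what it does not

The generators stand in for a docking engine and an MD engine. Planted
interactions sit ≥ 10 % inside the default detector cutoffs and planted
negatives ≥ 25 % outside, so label recovery is exact under reasonable
cutoff perturbations; burial units are isolated carbon pairs whose BSA
is known in closed form (spherical caps), so the BSA target is analytic,
not fitted. Pose-ensemble labels drive descriptor values and contact
lists directly. Everything is deterministic under its seed.

None of this is physically realistic: no Ramachandran validity, no
packing, no force field, no solvent. Passing tests therefore demonstrate
that the *logic* — detectors, filters, bookkeeping, fractions, fits,
flags — is correct on inputs with known answers; they say nothing about
whether the geometric cutoffs are optimal for real structures, and the
persistence analysis of real MD output will not bit-match tables
produced with other contact definitions.

## Problem sizes in the automated suite

The suite and the acceptance script run at desk scale by design: 200-pose
ensembles, 100-frame pseudo-trajectories, ≤ 50-atom SASA toys with a
20,000-sample oracle, 200 clustering cases at n ≤ 8, and 100 seeded Hill
fits. These sizes exercise every code path and keep the full run under a
minute on one CPU.

## Known limitations

- No trajectory-format (XTC/DCD) parsing; frames enter as multi-model
  PDB. An adapter hook is the natural extension point.
- No electrostatics solver, pKa prediction or binding-energy estimate;
  the descriptors are geometric.
- The MHP functional form is this package's own declared choice (the
  cited method's exact score is unpublished).
- Glycan chemistry is limited to H-bond donor/acceptor typing of
  MAN/NAG/BMA; no torsions, no branching logic beyond a parent-residue
  annotation.
- Pentamer reconstruction from per-interface solutions and the docking/
  MD engines themselves are out of scope; the pipeline consumes their
  outputs.
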