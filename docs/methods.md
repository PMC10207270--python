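# Methods

## Scientific background

Backbone carbonyl groups in peptides interact with one another: the lone
pair of a carbonyl oxygen O(i) can donate into the π* orbital of the next
carbonyl carbon C(i+1) (an n→π* interaction, equivalently a C=O···C=O
*tetrel bond*, since the carbonyl carbon exposes a π-hole). In α-helices the
O(i)···C(i+1) geometry is close to the Bürgi–Dunitz approach of a
nucleophile to a carbonyl, with O···C separations of roughly 2.7–3.4 Å.
These contacts are a secondary source of helical stability beyond the
canonical i→i+4 hydrogen bonds, and their distance distributions across a
conformational ensemble distinguish well-structured helical peptides from
intrinsically disordered ones.

`tetrelscan` implements the analysis chain around these contacts: geometric
detection, a density→energy calibration transferred from small bimolecular
model complexes, ensemble distance statistics with RMSD clustering, and a
synthetic backbone generator that provides controlled ordered/disordered
ensembles for testing.

## Contact detection

A contact is an ordered (donor, acceptor) pair of backbone carbonyls
satisfying:

- d(O_donor, C_acceptor) ≤ cutoff, default **3.6 Å** — slightly above the
  largest tabulated tetrel-bond distance in the packaged peptide records
  (3.376 Å) and near the O···C van-der-Waals sum;
- approach angle θ = ∠(O_donor···C_acceptor=O_acceptor) inside a window,
  default **[95°, 125°]**, centered near the Bürgi–Dunitz trajectory
  (~107°). No experimental angle criterion is tabulated for these systems,
  so the window is configuration, and θ is reported per contact so users can
  re-filter;
- |residue separation| ≥ min_separation (default 1) for same-chain pairs.
  The sign of the separation records direction; O(i)→C(i+1) is the canonical
  helical direction. Inter-chain pairs carry no separation and are not
  separation-filtered.

Colinear or degenerate geometries get θ = 0°/180° through the arccos limit
(cosines clipped to [−1, 1]); no division by zero can occur for physically
valid carbonyls, whose C=O bond length is validated to (1.0, 1.6) Å at
construction.

## Density→energy calibration

The electron density ρ at the bond critical point (or the NCI isosurface
between the carbonyls), reported as ρ×100 in atomic units, tracks the
strength of a noncovalent interaction. The package ships a reference table
of ten bimolecular model complexes — a cyclic amide paired with CO, CH₃CN,
CH₂O and O(CH₃)₂ donors, with and without a pre-formed bifurcated hydrogen
bond on the amide — carrying counterpoise-corrected interaction energies
ΔE_BSSE (kcal/mol), equilibrium O···C distances, and ρ×100 for both the
tetrel bond and the co-occurring ancillary contacts. These energies and
densities are *fixtures*: they come from wavefunction calculations the
package never performs.

The calibration is an ordinary least-squares fit of ΔE_BSSE on ρ×100 over
complexes **2–6** only. The hydrogen-bond-reinforced complexes 8–12 are held
out as a qualitative check (each binds more tightly than its plain
counterpart), and complex 12 in particular has a large ρ/ρ_ancillary
disparity that breaks the partition assumption below. On the packaged
values the fit gives

    ΔE = −5.4651 · (ρ×100) + 1.7919   (kcal/mol),  r = −0.964, n = 5.

Because the model complexes are co-stabilised by ancillary lone-pair–π,
π–π and CH–π contacts whose critical-point densities are comparable to the
tetrel bond's, predicting a tetrel-bond energy from ρ alone would
overestimate it. The package therefore partitions the predicted energy
multiplicatively: dE_ttb = f · (slope·ρ×100 + intercept) with ancillary
fraction f = 0.5 by default (half tetrel bond, half ancillary). The factor
multiplies the *output*, not the inputs — this choice reproduces the
packaged peptide-record energies at 1-decimal precision (all 30 records
agree within ±0.1 kcal/mol, and the seven headline contacts agree exactly
at one decimal). Report rounding is 1 decimal, halves away from zero,
matching table conventions. Pearson r is reported exactly as computed from
the packaged (rounded) table values; it is not adjusted toward correlation
values quoted for unrounded data.

Predictions at ρ×100 outside [0.2, 3.0] emit an `ExtrapolationWarning` but
still return a value.

### Geometry-only density surrogates

When no quantum-chemical density is available, two routes produce one from
geometry:

- **Distance→density model**: ρ×100 = A·exp(−B·d), fitted by nonlinear
  least squares to the 30 packaged (d, ρ×100) peptide records. An
  exponential is the standard near-field decay form for density with
  internuclear distance; the fitted model's Spearman rank correlation
  against the tabulated densities (0.94 on the packaged records) is stored
  on the model as a self-check. This surrogate feeds the `scan` command's
  per-contact energy estimates.
- **Promolecular density**: the minimum along the O···C segment of a sum of
  single-exponential atomic densities ρ_el(r) = A_el·exp(−r/B_el) over a
  supplied neighbourhood (H, C, N, O, S). The A/B constants are synthetic
  fixture values tuned to the density *tail* (1.4–2 Å from a nucleus), the
  only regime probed between two carbonyls; absolute magnitudes are
  approximate and only rank behaviour (denser at shorter contacts) is
  asserted or relied upon.

## Ensemble analysis

`distance_distributions` collects the O(i)···C(i+1) distance of every
consecutive residue pair across frames, each frame with identical weight
(no ensemble reweighting). Pairs are taken over the union roster; a frame
missing either residue contributes to that pair's absence count rather
than a zero. Summary statistics are the median, the IQR, and "narrowness"
(IQR/median); narrow distributions centered at short distances indicate a
persistently formed contact.

`cluster_frames` groups frames by pairwise best-fit Cα RMSD using
agglomerative **average-linkage** clustering with an ε distance stop
(default ε = 2 Å): merging halts once the smallest average inter-cluster
RMSD exceeds ε. Hierarchical-with-epsilon clustering of trajectory frames
is implemented in several variants across MD toolchains; average linkage is
the choice here and the linkage is exposed in `ClusterConfig`. Clusters are
reported largest-first (cluster 0 = most populated) and each cluster's
centroid is the member minimising the summed RMSD to its co-members. The
"CA+CB" atom selection degrades to Cα-only with a warning when Cβ atoms are
absent (the carbonyl frame model carries none).

`superpose_rmsd` solves the orthogonal Procrustes problem after centering
(Kabsch-type, proper rotations only — the reflection guard handles planar/
colinear sets), then applies the fitted rotation and measures residuals
directly; this keeps exact rigid copies at RMSD 0 to machine precision,
where the solver's own residual estimate loses accuracy near zero.

## Synthetic peptide generator

`synthetic_peptides` builds backbones in internal coordinates (NeRF-style
placement from bond length / bond angle / dihedral) with fixed standard
geometry: N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; angles
N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°, CA–C–O 120.8°; the carbonyl O
is placed anti-planar to the next amide nitrogen (dihedral N–CA–C–O =
ψ+180°). With the default dihedrals (φ = −57°, ψ = −47°, ω = 180°) the
chain is an ideal α-helix: measured rise 1.56 Å per residue, 3.67 residues
per turn, and all O(i)···C(i+1) distances at 2.888 Å — inside the
tetrel-bonding range. An alternative helical parameterisation (−60, −45)
is available by passing those dihedrals.

Disorder is modelled as independent per-residue Gaussian noise on φ and ψ
(ω stays planar): σ = 5° gives a tight helical ensemble, σ = 40° a
coil-like one. This is deliberately non-physical — real disordered peptides
sample discrete Ramachandran basins with correlated neighbours, excluded
volume and solvent effects, none of which the generator has — so passing
ensemble tests demonstrates that the analysis separates narrow from broad
distance distributions, not that it reproduces real MD ensembles. Bond
lengths and angles are exact regardless of noise, which the test suite
checks to 1e-6.

Determinism: frame i of an ensemble uses a sub-seed derived from the
ensemble seed and i via a splitmix64-style mixing function (masked to 31
bits), so ensembles are reproducible and extensible without re-generating
earlier frames.

## Problem sizes and numerical choices

Ensemble comparisons use 10-residue chains with 200 frames per condition
(σ = 5° vs 40°), a size at which the ordered/disordered IQR contrast is
unambiguous for every consecutive pair; clustering tests use 10–15 frames.
Calibration parameter-recovery simulations use 20 points per replicate with
Gaussian energy noise of sd 0.15 kcal/mol over 200 replicates. The
exponential surrogate fit starts from a log-linear estimate before the
nonlinear solve; degenerate inputs (zero density variance, constant
distances, < 2 calibration points, < 5 surrogate points, < 3 RMSD atoms)
raise typed errors rather than returning garbage. Histogram reporting for
distributions defaults to 0.1 Å bins over [2.5, 8.0] Å.

## Known limitations

- Energies are transferred from bimolecular model complexes to
  intramolecular peptide contacts through a single linear map plus a global
  0.5 ancillary factor; the factor is configurable but there is no
  per-contact decomposition.
- The detector considers backbone carbonyls only by default; side-chain
  carbonyls (ASN/GLN/GLU) can form the same contacts and are simply not
  extracted by `parse_structure` (which keys on atom names "C"/"O").
- The promolecular constants are tail-regime fixtures, not fitted atomic
  densities; absolute ρ values from that route should not be compared to
  quantum-chemical ones, only ranked.
- No mmCIF input, no binary trajectory formats, no symmetry expansion, no
  hydrogen handling.
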