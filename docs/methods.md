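# Methods

This note documents the models implemented in `caspfold`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Residue-interaction networks

**Contacts.** For each frame, all heavy-atom pairs within a distance cutoff
(default 4.0 Å) are contacts, excluding pairs from residues adjacent in the
chain (|i − j| ≤ 1 on the same chain), so covalent geometry never counts as
a non-covalent interaction. Hydrogens are excluded because their presence
and placement vary across structure sources. Each contact is typed by rules
that are deliberately simple and fully specified (they are this package's
operational definitions, not imported from any particular network tool, and
the atom sets are module constants that can be overridden):

- *electrostatic* — one atom is a sidechain carboxylate oxygen of Asp/Glu
  (OD1/OD2, OE1/OE2) and the other a sidechain nitrogen of Lys (NZ), Arg
  (NE/NH1/NH2) or His (ND1/NE2);
- *hydrophobic* — both atoms are sidechain carbons of apolar residues (Ala,
  Val, Leu, Ile, Pro, Phe, Met, Trp);
- *van der Waals* — any other heavy-atom pair within the cutoff.

**Aggregation.** Per frame and residue pair, the edge weight is the count of
contacting atom pairs (the "sum"); the stored edge weight is its mean over
frames (the "average") and the occupancy is the fraction of frames with at
least one contact. Edges with zero total contact are omitted.

**Centralities.** Degree centrality is the weighted degree, with contact
types pooled: DC(v) = Σ incident mean weights. This reads "number of
non-covalent interactions" as a contact count rather than a neighbor count;
an unweighted variant (distinct neighbors) is available behind a flag.
Betweenness is unnormalized node betweenness (Brandes, via networkx) on the
graph with edge length 1/mean_weight, so stronger contacts give shorter
paths; the conventional hub threshold of BC > 1000 is only meaningful on
unnormalized values, which is why normalization is not applied. An
unweighted BC is also available.

**Conservation bins.** ConSurf grades map 8–9 → high, 6–7 → intermediate,
1–5 → variable. Grade 5 is grouped with variable (the bin definitions leave
it unassigned between "6–7" and "below 5"; this choice is applied
consistently and documented here).

**Hubs.** A residue is a hub iff DC > dc_threshold AND BC > bc_threshold
(defaults 20 and 1000, both configurable); the quadrant counts of the
DC/BC scatter are reported alongside.

**Family averaging.** Per-residue metrics from several homologs are averaged
per master-alignment column; gap positions are excluded from numerator and
denominator, and each protein's ungapped alignment row must match its
residue count (and sequence, when given) or the offending protein is named
in the error.

## Essential dynamics and free-energy landscapes

Frames are superposed on a reference (default frame 0) by the Kabsch
algorithm over a selection (default Cα; selections "CA"/"heavy"/"all");
collinear selections are rejected as degenerate. PCA then eigendecomposes
the covariance of the mean-centered coordinates over its own selection
(default all heavy atoms) via thin SVD; eigenvalues are in Å² with the
n−1 denominator, eigenvector signs are fixed by making each mode's
largest-magnitude component positive (signs are arbitrary; determinism is
required), and mass weighting (√m per coordinate) is available behind a
flag but off by default.

The landscape is G = −RT ln(P/P_max) over a 2D histogram of (PC1, PC2)
projections, default 32×32 bins, T = 298.15 K (RT = 0.593 kcal/mol; the
temperature is a parameter). Empty bins are masked rather than assigned the
maximum energy, so the landscape is bounded by what was actually sampled.

**Basins.** Metastable states are persistent local minima on the
8-neighborhood grid. Plain local-minimum detection on a masked histogram is
dominated by sampling artifacts — every isolated occupied bin in the sparse
outskirts is a "minimum" — so minima are merged by topographic persistence:
bins are swept in order of increasing G (empty bins passable just above the
highest occupied level), components are merged union-find style, and a
minimum whose component joins a deeper one at a saddle less than
`min_prominence` above its own depth is absorbed. The default prominence is
2RT: a reported state must be at least e² ≈ 7.4-fold more populated than
the saddle connecting it to a deeper state, which removes single-bin
artifacts (an isolated bin of count c has persistence RT ln c) while
keeping genuinely separated clusters. Surviving minima closer than
`min_separation` bins (default 2) merge keeping the deeper; exact ties
break toward the lowest (row, col) index. Each basin's representative frame
is the frame projecting nearest its minimum-bin center (lowest index on
ties). Landscape breadth (occupied bin count × bin area, and PC1 span)
supports condition comparisons such as water vs denaturant.

## Equilibrium-unfolding thermodynamics

Linear extrapolation method with ΔG_i(urea) = ΔG°_i − m_i·[urea] and
K_i = exp(−ΔG_i/RT), R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹, T = 298.15 K by
default. Positive ΔG° means the more folded species is stable in water.
Fractions: two-state fU = K₁/(1+K₁); three-state monomer
fN = 1/(1+K₁+K₁K₂), fI = K₁fN, fU = K₁K₂fN (normalized Boltzmann weights;
they sum to 1 exactly). The observed signal is the population-weighted sum
of per-probe baselines: linear in urea for N and U, a urea-independent
constant for I (the standard identifiability choice; a slope can be
enabled).

**Global fitting.** ΔG° and m are shared across all datasets; baselines are
shared per probe across concentrations and directions. Residuals are
weighted per probe by the inverse of a successive-difference noise estimate
(median over that probe's datasets of sd(Δsignal)/√2), so probes recorded
in different units — fluorescence intensity versus CD ellipticity —
contribute comparable statistical information instead of the largest-range
probe dominating. Because baselines enter linearly, the multistart search
uses variable projection: only (ΔG°, m) are optimized nonlinearly
(bounds ΔG° ∈ [0, 15] kcal/mol, m ∈ (0, 3] kcal·mol⁻¹·M⁻¹, default 25
Latin-hypercube starts sampled as transition midpoints over the observed
urea window with ordered midpoints), with baselines profiled out by linear
least squares per probe. The best projected solution is polished over all
parameters (trf, tolerances 10⁻¹²) to supply the covariance-based standard
errors; AIC = n ln(RSS/n) + 2k on the weighted residuals supports two- vs
three-state comparison.

**Native baseline slope.** By default the native baseline is fit as
urea-independent. With a marginally stable native state (ΔG°₁ ≈ 1 kcal/mol
the native species never dominates over an extended pre-transition region,
so a native slope cannot be estimated from the data; leaving it free makes
ΔG°₁ practically unidentifiable (its Fisher-information bound degrades by
roughly an order of magnitude). `native_slope=True` restores the fully
general model for data with a well-resolved native plateau.

**Concentration dependence.** A monomeric mechanism predicts that
min–max-normalized curves at different protein concentrations superimpose.
The statistic is the maximum over probes and urea points of the range of
mean normalized signal across concentrations; the default threshold is 3×
the pooled successive-difference noise sd. Curves under the threshold are
flagged concentration-independent.

**Proteolysis kinetics.** Band intensities are fit to
I(t) = A·exp(−k_app·t) + C by bounded least squares (k_app ≥ 0, several
rate seeds); non-decaying data return k_app ≈ 0 with a degeneracy flag and
a warning.

## Synthetic data: what it emulates, and what it does not

**Ensembles.** Toy ensembles are Gaussian fluctuations along a small number
of planted orthonormal modes plus isotropic noise around a deterministic
base geometry, optionally with per-frame rigid-body jitter. Mode amplitudes
are drawn standard-normal and then standardized, so the planted sample
variance equals sd² exactly — the planted values are the ground truth that
recovery tests compare against, with no RNG sampling slack. The base
geometry is a compressed idealized helix (100° turn, radius 1.8 Å, rise
0.9 Å, one pseudo-sidechain atom 1 Å outward per residue): a canonical
α-helix trace with only two atoms per residue has no non-adjacent heavy-atom
pairs inside a 4 Å cutoff, so the compression stands in for the packing
density that full sidechains provide and yields residue contacts at
separations i ± 2…4. The residue palette cycles acidic/basic/apolar types
with opposite charges three apart, so generated networks carry
electrostatic, hydrophobic and vdW edges. "Denaturant" conditions are
emulated purely as broader mode variances — there is no force field, no
solvent and no urea chemistry, so passing tests demonstrate the analysis
machinery (contact counting, PCA, landscape construction), not anything
about real caspase energetics.

**Unfolding presets.** The registry ships `"21M"` (three-state;
ΔG°₁ = 1.0, ΔG°₂ = 2.7 kcal/mol, the published fitted values for the
subunit-swap variants) and `"hub_mutant"` (two-state; ΔG° = 2.3 kcal/mol,
the published value for the phenylalanine-quadruple core mutant). The
m-values (0.5 and 0.7; 0.6 for the two-state preset) and all baselines are
stand-ins chosen by this package, since the source supplementary tables are
not available: the m-values put the second transition's midpoint near 4 M
urea, and the baselines make the three probes rank the species differently
(total-aromatic 280 nm emission quenched most in I, Trp-only 295 nm
emission enhanced on partial exposure, CD ellipticity monotonic) — the
classic multi-probe signature that renders a partially folded intermediate
resolvable — with urea-independent native baselines, consistent with the
fitting default above. Noise is homoscedastic Gaussian per probe with sd
expressed as a fraction of that probe's noiseless signal range. Default
design: urea 0–9 M in 25 steps, probes {280 nm, 295 nm, CD 222 nm},
protein at 2/6/8 µM. The monomer models are concentration-independent by
construction; an adversarial `cm_shift_per_doubling` option injects a
dimer-like midpoint shift for testing the concentration-dependence check.

**Conservation/regions.** Grades are uniform over 1–9 except designated hub
positions drawn from {8, 9}; region classes follow a fixed block pattern
(helix/top_loop/beta/bottom_loop/short_beta). Real region classes are
consumed from annotation files, never computed — the caspase notion of
"top" (active-site) versus "bottom" loops is anatomical, not derivable from
geometry alone.

## Problem sizes and determinism

Recovery experiments use 10 replicate datasets per condition with 25
multistarts per fit; toy ensembles for PCA checks use 1000 frames with
2 Å / 1 Å planted modes; the betweenness oracle check enumerates all simple
paths on 200 random graphs of 4–8 nodes. Every generator and fit is a pure
function of its seed; the pipeline manifest hashes all artifacts so a rerun
with the same config and seed is verifiably identical.

## Known limitations

- Contact typing ignores hydrogen-bond geometry, π-stacking and
  backbone-mediated electrostatics; a contact is a distance, not an energy.
- The FEL is a 2D histogram estimate: basin count and depth depend on bin
  width and sampling; the persistence threshold trades false basins against
  merging genuinely shallow states.
- Only monomeric folding models are implemented; dimeric (concentration-
  dependent) mechanisms are detected by the overlay check but not fit.
- The toy generator produces Gaussian, harmonic ensembles; anharmonic or
  multi-well ensembles occur only through explicitly planted structure.
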