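# Methods

`actraj` analyses trajectories of the adenylyl-cyclase (AC) catalytic core —
the pseudo-symmetric C1/C2 domain pair — bound to G-protein α subunits, the
system in which inhibitory (Gαi) and stimulatory (Gsα) regulation is studied
by molecular dynamics. This note records the models and procedures the
package implements, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices that matter.

## Data model

A `Structure` is an ordered atom list with author residue numbering used
verbatim (mixed numbering schemes across references are a configuration
concern, not a code concern; no renumbering is performed). Van der Waals
radii are assigned at load time from a Chothia-style united-atom table
(C 1.87, N 1.65, O 1.40, S 1.85, P 1.90, H 1.00 Å, default 1.80 Å for
unknown elements), overridable per call. A `Trajectory` stacks coordinate
frames over one topology with an explicit frame interval `dt_ns` — multi-model
PDB carries no time axis, so time is metadata supplied by the caller, which
keeps the dwell-time filter well defined. `t0_ns` holds the time of the first
analysed frame, implementing the equilibration offset. Insertion codes are
rejected on input: they do not occur in this problem domain, and silently
accepting them would corrupt the (chain, residue, name) identity key.

Selections are declarative (chains × inclusive residue ranges × atom class)
with the field's vocabulary: `backbone` = {N, CA, C, O}, `heavy` = element ≠ H,
`calpha`, or an explicit name list. Resolution is deterministic and
order-stable (file order).

## Superposition, RMSD, RMSF

Rigid fits use the Kabsch SVD construction with reflection correction; the
reported RMSD is evaluated on the transformed coordinates rather than through
the singular-value identity, which cancels catastrophically near zero.
Mass weighting is off (plain coordinate RMSD) — nothing in the analysed
observables calls for it. Fit and measure selections are independent, so a
domain's RMSD can be measured after fitting on that domain only (the
per-domain convention); the default is fit = measure.

The average structure is iterative: all frames are fitted to the running mean
until the mean moves less than 1e-4 Å RMS (below PDB coordinate precision) or
50 iterations, with a warning on non-convergence. RMSD series default to the
average structure as reference. RMSF is the per-atom RMS fluctuation about
the mean of the fitted frames, grouped to residues by averaging the backbone
atoms (all atoms of a residue as fallback for residues without backbone,
e.g. ions). Flexibility *differences* between systems are plain per-residue
subtractions and may be negative.

## Conformational clustering

The greedy scheme: the frame with the most neighbours within the RMSD cutoff
(inclusive, `rmsd <= cutoff`) seeds a cluster; it and its neighbours are
removed; repeat. Ties in neighbour count go to the lowest frame index so
results are reproducible. Defaults: cutoff 1.5 Å on backbone atoms; clusters
with dwell time (member count × `dt_ns`) strictly below 100 ns are discarded
— a dwell exactly at the threshold is retained, matching the strict
"less than" discard rule. Two readings of a cluster "centre" are kept: the
medoid (member minimising summed RMSD to co-members; the default
representative, being the stricter geometric reading) and the greedy
most-neighbours centre (`method="center"`).

The full pairwise matrix is held in memory; the contract caps trajectories at
20 000 frames with a documented error above.

Known property: the pre-filter cluster *count* is not monotone in the cutoff
for arbitrary dissimilarity matrices — seeded random search finds matrices
where raising the cutoff splits differently and yields more clusters, and a
brute-force reimplementation reproduces the same partitions, so this is
intrinsic to the greedy scheme. With well-separated substates (the regime the
method is used in) the count does fall monotonically, and the tests assert it
there.

## Surface area and interface complementarity

Solvent-accessible surface area uses the slice construction: each atom's
solvent-expanded sphere (vdW + probe, probe default 1.4 Å) is cut into z
slices (default 0.1 Å); at each slice, the angular intervals of the atom's
circle covered by neighbouring circles are merged exactly, and by the hat-box
theorem the slice contributes `R · h · θ_accessible`. The angular direction is
therefore exact; the only discretisation error is axial, and an isolated
sphere integrates exactly to `4πR²`. At the 0.1 Å default, totals agree with
a 10 000-point quadrature reference to ~0.1% at ~10× lower cost; coarser
slices trade accuracy linearly for speed. Hydrogens are excluded throughout
(united-atom radii already account for them); exact duplicate positions are
collapsed to one atom with a warning.

Interface statistics follow the buried-surface convention:
ΔASA = ASA(A) + ASA(B) − ASA(AB), interface area = ΔASA/2 (single-sided, the
convention under which gap indices land in the 2–5 Å range typical of
protein–protein interfaces), and gap index = gap volume / interface area.
When the chains make no contact the interface area is zero and the gap index
is reported as undefined (None / empty field), never as a number.

The gap volume is a union of "gap spheres": for every cross-interface atom
pair, a sphere is seeded midway between the vdW surfaces with radius
`(d − r_a − r_b)/2`; seeds above `r_max` (5.0 Å) are skipped; each sphere is
shrunk in 0.1 Å steps, recentred half a step away from the most-penetrating
atom each time (max 50 iterations), until it touches no atom; spheres ending
below `r_min` (1.0 Å) are discarded. The published descriptions of
grid-based gap analysis leave the exact shrink rule open; the rule above is
this package's own deterministic choice. The union volume is integrated by
counting cubic-grid cell centres (default spacing 0.5 Å); refining 0.5 → 0.25 Å
moves values by under 3% on the fixtures tested. Only inter-chain gaps are
counted — rim cavities within one chain are out of scope.

One geometric fact constrains testing: with probe radius p, ΔASA is
identically zero once all surface–surface separations exceed 2p, for any
geometry. The monotonicity checks that pull a synthetic interface from 1 to
3 Å therefore run with a coarse 2.0 Å probe so the buried area (and hence the
gap index) stays defined across the whole range; all defaults elsewhere keep
the 1.4 Å water probe.

## Helix geometry

The binding-groove observables are the crossing angle and centroid separation
of two helix pairs — α1/α2 on C1 (defaults residues 408–420 and 468–475) and
α3/α4 on C2 (910–918 and 978–988). The default axis fit ("bisector") averages
cross products of successive second differences of the C-alpha trace: for an
ideal helix every second difference is exactly perpendicular to the axis, so
the estimate is exact regardless of twist or turn count, and it degrades
gracefully under noise (a 0.15 Å coordinate jitter moves an 18-residue axis
by under 3°). A plain SVD principal direction is available (`method="svd"`)
but carries a systematic bias of a degree or two whenever the residue range
spans a non-integer number of turns, because the axial coordinate then
correlates with helical phase — measurable against constructions and
documented here rather than silently absorbed. Axes are oriented N→C so
antiparallel pairs read as ~180°, not 0°; reported shifts of a few degrees
depend on this. The helix "centre" is the C-alpha centroid of the range
(also the axis anchor); per-frame values are computed and the series mean/SD
reported, rather than measuring once on an average structure.

## Contacts, persistence, monitors

A contact is residue-level: any heavy-atom pair across the interface
partition within the cutoff (default 5 Å, boundary inclusive); atom-level
maps are available behind a flag. Sides may be chain sets or arbitrary
pseudo-chain selections, so inter-domain (C1/C2) interfaces use the same
machinery as inter-molecular ones. Searches run through a KD-tree and are
exactly equal to brute-force enumeration (asserted, not assumed). The
conserved-contact fraction of frame t is |C_t ∩ C_ref| / |C_ref| with the
first production frame as default reference (the docked pose after
equilibration). Persistence fractions are per-pair and per-residue presence
frequencies; the persistent-residue list uses a strict `> 0.8` threshold —
a residue present in exactly 80% of frames does not qualify. Distance
monitors name single atoms (`A:LYS:1065:NZ -- B:ATP:1:O2G`) and must resolve
uniquely; ambiguity is an error, not a guess.

## Synthetic data

The generators stand in for undeposited microsecond trajectories; every
planted parameter is recoverable by the corresponding analysis module, and
that recovery battery *is* the module's test surface. Ideal helices use the
canonical lattice (rise 1.5 Å, twist 100°, C-alpha radius 2.3 Å) with N, C, O
stubs on companion helical lattices — sufficient for every implemented
observable; side chains are omitted. Helix pairs subtend exactly the
requested angle. Two-chain slab complexes share grid jitter between chains so
the nearest-surface separation equals the requested gap exactly, making
contacts, ΔASA and gap volume monotone in the gap. Multi-state trajectories
visit states in contiguous blocks (so the dwell-time filter is genuinely
exercised, unlike i.i.d. frame labels) with isotropic Gaussian coordinate
noise; the default test conditions are two states ~3 Å apart in fitted
backbone RMSD under 0.1 Å noise, which the 1.5 Å cutoff separates cleanly.
Substates are generated by scaling a random displacement field to an exact
fitted-RMSD target.

What the generators do *not* emulate: force-field energetics, correlated
(non-isotropic) fluctuations, side-chain packing, ATP/Mg²⁺ chemistry, or
realistic interface topography. Passing tests therefore demonstrate that the
*measurements* are correct on data with known answers — not that any
particular biological conclusion transfers.

The composite pipeline fixture is a two-domain/G-protein miniature: chains A
and B are helix pairs in contact (the "C1/C2" interface), chain G a flat slab
touching chain A (the "G-protein" interface). Its trajectory spends the
equilibration window in a third, clearly distinct conformation so that
equilibration skipping is observable: analysing without the skip yields three
retained clusters, with it exactly the two planted production substates.

## Pipeline

Configuration is YAML with these defaults: equilibration 400 ns (frames
skipped = floor(equilibration_ns / dt_ns)), clustering cutoff 1.5 Å /
min-dwell 100 ns on the C2-domain backbone, contact cutoff 5 Å, persistence
threshold 0.8, probe 1.4 Å, gap parameters (1.0, 5.0, 0.5) Å, interface
evaluation every 10th frame (SASA + gap volume dominate the cost; the
evaluation frequency is an explicit choice, reported in the manifest).
Validation is fail-fast and aggregated: every selection and monitor is
resolved against the topology before any output directory is created.
Stages are isolated — a failing observable does not suppress independent ones
— and stages whose preconditions are unmet (clustering a single frame) are
skipped with a recorded reason. All tables are CSV with fixed float
formatting, and the manifest (config echo, package version, seed, frame
counts, stage statuses — no timestamps) makes a run bit-reproducible;
identical config + input + seed yields byte-identical bundles. Between-system
comparisons report mean helix-angle/distance shifts, interface-statistic
shifts, the per-residue flexibility difference profile, and persistence
changes, as means over frames ± SD where applicable (single-number summaries
without a stated estimator are avoided).

Problem sizes in the shipped tests and the acceptance script are desk-scale
by design: fixtures of tens of frames and a few hundred atoms for end-to-end
runs, 200–2000 frames where closed-form statistics need the sample size
(average-structure convergence, RMSF), and 50-atom structures for the
surface-area oracle battery. These sizes make every check exact or
statistically sharp while keeping the whole battery a few minutes of compute.

## Known limitations

- PDB only (plus multi-model PDB trajectories); no binary trajectory formats,
  no mmCIF, no insertion codes.
- SASA is accessible-surface only (no molecular/Connolly surface); gap
  analysis counts inter-chain gaps only.
- No secondary-structure assignment: helix residue ranges are configuration,
  taken from ranges that stay helical.
- Greedy cluster counts are not monotone in the cutoff on arbitrary inputs
  (see above).
- The contact criterion is geometric; hydrogen-bond and salt-bridge
  classification are out of scope.
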