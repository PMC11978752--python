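# Methods

This note documents the models behind `ctsdyn`, the defaults that
matter, what the synthetic data does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Sequence arm

### CTS extraction

Group-I chaperonin tails are anchored at a highly conserved proline near
the C terminus (GroEL position 525). For unaligned input the anchor is
the **last proline within the C-terminal window** (default 40 residues,
excluding the final position, so a tail always exists); when an
alignment column for the conserved proline is known it can be passed as
a 1-based `anchor_hint` and takes precedence. Sequences without a
proline in the window are excluded and logged rather than guessed.
Ambiguity codes (B/Z/X) are tolerated in sequences — they are removed
pairwise in distance computation — but a tail containing them gets no
GRAVY/pI (logged; classification still runs on composition fractions).

### Physicochemistry

GRAVY is the arithmetic mean of Kyte–Doolittle hydropathies (table
shipped with Biopython). The isoelectric point is the root of the
Henderson–Hasselbalch net-charge function with the Bjellqvist pKa set
(terminal pKas residue-specific at the N terminus), found by bisection
on pH ∈ [0, 14] to 10⁻⁴ pH. The charge function is strictly decreasing
in pH, so the root exists and is unique; a peptide charged at both ends
of the interval returns the boundary.

### Composition classes

No quantitative boundary for the three observed CTS families
(gly-met-rich, charged/His-rich, pattern-free) exists in the
literature, so the classifier uses composition fractions with
configurable thresholds chosen a priori:

* `gly_met_rich` — (G+M)/length ≥ 0.6 **and** at least one M. The
  canonical `(GGM)₄M` scores 1.0; up to two point substitutions in a
  `(GGM)₂M` still pass.
* `charged_his_rich` — H fraction ≥ 0.25 **or** (D,E,K,R,H) fraction
  ≥ 0.4.
* `pattern_free` — everything else.

The labels partition all inputs. On 300 synthetic tails the planted
labels are recovered at ≥ 95 % (the generator's pattern-free tails are
drawn uniformly but re-drawn if their composition crosses into the
other two families — "pattern-free" is a composition statement, not
merely "random").

### Distances, trees, conservation

Pairwise distances use the proportion of differing sites after
**pairwise deletion** of columns where either sequence has a gap or
ambiguity code, corrected as d = a·[(1−p)^(−1/a) − 1] — the Poisson
correction with gamma-distributed site rates of shape *a* (default 1;
a→∞ recovers −ln(1−p)). Saturated pairs (p → 1) become `inf` with a
warning, or a configurable cap (10 substitutions/site in the pipeline)
— never a silent clip.

Neighbour joining is the classic Q-criterion/Saitou–Nei algorithm, made
deterministic by lexicographic label sorting and a lowest-(i,j)
tie-break; negative branch lengths are clamped to zero with the total
deficit recorded on the tree. On additive matrices the reconstruction
is exact (verified against brute-force path sums and scikit-bio's NJ).
Bootstrap supports resample columns with replacement; replicate *r*
draws from the *r*-th child of `SeedSequence(seed)`, so supports are
independent of taxon order. Failed replicates (no comparable sites,
saturation) are dropped and logged.

Substitution counts default to **Fitch parsimony** on the NJ topology
summed over columns (a tree-aware reading of "observed substitutions");
a consensus-mismatch counter is available via `method="consensus"`
since the two readings are not distinguishable from the original
description. Gap/ambiguity leaves are parsimony wildcards.

The conservation profile is an in-house stand-in for a Rate4Site-style
estimator: per-column Fitch change counts c on the NJ tree are treated
as Poisson observations with exposure T (total tree length) of a site
rate with a gamma(shape 1) prior whose mean is set empirically to the
overall mean rate; the posterior-mean rate (1+c)/(b+T) is mapped onto
the ungapped reference positions and z-normalized (mean 0, sd 1, lower
= conserved). A flat profile (all columns equal) raises an explicit
error instead of dividing by zero. This matches the gamma-1 modelling
choice of the distance correction and the mean-0/sd-1 presentation
convention, but it is not the ML Rate4Site algorithm; absolute rates
should not be compared across alignments.

## Structure arm

### Structures, superposition, tail building

PDB I/O goes through biotite; coordinates are Å, author numbering and
insertion codes preserved, multi-MODEL files round-trip as frame lists.
Superposition is closed-form Kabsch (proper rotation enforced by the
determinant sign correction); collinear selections are rejected. The
rotation angle comes from the matrix trace, the axis from the rotation
vector.

Missing tails are appended with **ideal backbone geometry** — N–CA
1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles 111°/116.2°/121.7°; extended
conformation φ = −120°, ψ = +120°, ω = 180° — by natural-extension
internal-coordinate placement, then relaxed on a soft-sphere clash
penalty (heavy-atom pairs < 2.6 Å, 1-2/1-3 neighbours excluded) with
stiff bond restraints, moving only the new atoms. Side chains and
carbonyl oxygens are deliberately omitted: the downstream network model
is Cα-only, so backbone-level geometry is all that survives. Ring
assemblies are built by placing one protomer copy per reference chain
via Kabsch on a shared selection (all-CA by default), preserving the
copy's internal geometry exactly and reporting per-chain placement
RMSDs.

### Elastic network model

Standard Cα ANM: nodes within a 12 Å cutoff joined by Hookean springs
with equilibrium length equal to the reference distance; reference
Hessian from 3×3 blocks −γᵢⱼ r̂r̂ᵀ. Two spring laws: uniform γ = 1
(default) and a distance-weighted inverse-sixth power law
γᵢⱼ = γ·(r/3.8 Å)⁻⁶ of the Hinsen Cα family. Dense eigensolve up to
3N = 3000 degrees of freedom, shift-invert Lanczos beyond (agreement
verified to 10⁻⁶ on 50-node instances); zero modes flagged at
|λ| < 10⁻⁸·λ_max (six for a connected, non-collinear assembly —
disconnection triggers a warning, not an error). Derived quantities use
the lowest 50 non-zero modes by default; MSF and cross-correlations are
mode sums in kT/γ units, overlaps are computed after projecting the
displacement out of the rigid-body space, so the cumulative squared
overlap over all internal modes is exactly 1.

### Mixed two-basin potential and the transition path

The two endpoint ENMs (equal node sets; R″ pre-superposed onto T so
rigid motion cannot masquerade as transition) are mixed by log-sum-exp:

    V_mix(x) = −(1/β)·ln[exp(−β·V_T(x)) + exp(−β·(V_R(x) + ε))]

*β* controls how sharply the surface follows the lower basin; the
default is calibrated in two stages so that the smoothing (ln 2/β)
removes at most 5 % of the barrier height — first against the
linear-interpolation barrier, then against the barrier of a coarsely
relaxed string, because the linear estimate badly overestimates
barriers for large motions. *ε* is iterated until the two relaxed basin
minima have equal mixed energy (|ΔV| < 10⁻⁶).

The saddle search relaxes a 21-image string (perpendicular steepest
descent with equal-arc-length reparametrization), runs a
**climbing-image** phase from the maximum-energy image (tangent from
the flanking images, adaptive step), and polishes with trust-region
eigenvector following on the analytic mixed Hessian, with rigid-body
null directions projected out. Toy systems converge to gradient norms
< 10⁻⁶ with exactly one negative curvature direction (verified against
a scalar root-finding oracle on the two-spring dimer). Symmetric ring
assemblies can present degenerate (index > 1) stationary points; a
bounded number of symmetry-breaking kicks attempts to reduce the index,
and the result reports its curvature signature honestly.

ENM pair energies are quadratic in bond length, not in coordinates, so
a large conformational change (the default planted 70°/45 Å tail
motion) can carve **metastable intermediates** into the mixed surface —
the toy analogue of the chaperonin's R/R′ intermediate states. The
path builder therefore connects the basins recursively: steepest
descent from each saddle into both sides, with legs glued rigidly
(basin identity is judged by superposed RMSD, since descents drift
rigidly) and further saddles sought between unconnected minima. When
the cascade cannot connect the basins within a few legs — rough
surfaces make high-dimensional saddle polishing unreliable — the
builder falls back to a densely relaxed string with a climbing-image
transition state, which is robust and deterministic. The returned path
reports its frame energies, arc-length progress, the index of the
highest-energy frame, and the number of interior metastable minima
(`n_intermediates = 0` means a clean two-basin transition with a
unimodal energy profile). Identical endpoints short-circuit to a
two-frame "no barrier" path.

### Motion metrics

All metrics superpose frames onto the T reference first (all nodes by
default; a selection such as the equatorial core can be passed where
displacement should be measured in the frame of the static base).
Backbone φ/ψ follow the IUPAC convention and are absent (not zero) at
termini or missing atoms; the "α" torsion is the virtual dihedral
Cα(i−1)–Cα(i)–Cα(i+1)–Cα(i+2) assigned to residue i, with chains split
at Cα–Cα gaps > 4.5 Å (the pseudo-bond-angle reading is computable from
the same trace but the dihedral is the default). Angle differences are
wrapped to (−180°, 180°] before chain-averaging and frame-RMS.

Segment motion is the Kabsch transform of the segment between endpoint
states after whole-ring pre-superposition on a configurable selection
(non-CTS nodes in the pipeline): rotation from the trace, translation
as the centroid-shift magnitude, averaged over chains. Recovery of a
planted noise-free motion is exact to < 10⁻⁴ degrees/Å, and within
1°/0.2 Å at 0.1 Å coordinate noise.

The ring axis is the normal of the best-fit plane of chain centroids;
the aperture is the minimum distance from that axis to any selected
atom, per frame. Chain-pairwise CTS correlations are Pearson
correlations of per-chain mean CTS displacement series over the
non-reference frames (the reference frame is identically zero for
every chain and would only dilute anti-correlation); zero-variance
series produce NaN entries, never a silent 0. Segment coupling
correlates two segments' chain-averaged radial centroid coordinates —
−1 is the anti-phase signature of apical-versus-CTS motion.

## Synthetic data: what it emulates, what it does not

The MSA evolver implements Poisson substitution with uniform
replacement over the other 19 residues (the process the Poisson+gamma
distance corrects for), gamma(shape) site rates, and a tail region with
a rate multiplier (default ×5) emulating the faster-diverging CTS. It
does not model indels, exchangeability structure (no BLOSUM-like
matrix), compositional bias, or alignment error — so passing tests show
the estimators are correct under their own model, not that real
chaperonin alignments satisfy that model.

The toy ring is a Cₙ-symmetric assembly (default 7 subunits) of three
stacked pseudo-domain slabs — labelled equatorial, intermediate and
apical so domain-resolved metrics are meaningful — forming a tall
cavity wall, with a pendant tail descending toward the axis base. The
geometry was designed so that (i) the assembly is connected at the
default 12 Å cutoff, (ii) the tails are the nodes nearest the axis
(they define the aperture), and (iii) a tail translated 45 Å up the
cavity remains within the cutoff of the apical wall, keeping both
endpoint networks connected. The two-state generator rotates each
chain's tail about its own radial axis and translates it along the
ring axis — identical per chain up to ring symmetry, so the planted
motion is Cₙ-synchronous; defaults are 70° and 45 Å, the reported CTS
motion between the T and R″ states. Real GroEL is ~10× larger
(~3 800 Cα in a tail-completed heptamer versus 203 nodes here), its
tails interact with nucleotide-dependent cavity walls, and its T→R″
motion is not a single rigid transform — the toy tests the machinery
and the qualitative claims (tail floppiness, ring damping, synchrony),
not GroEL's absolute energetics.

All generators are pure functions of their seed (NumPy
`default_rng`/`SeedSequence` throughout) and return their ground truth
alongside the data.

## Problem sizes and determinism

Default analysis sizes were chosen at desk scale: 203-node rings
(609 degrees of freedom, dense eigensolves), 30-taxon × 1000-site
alignments for topology recovery, 20 seeded replicates for the
CTS-divergence comparison, 300 tails for classifier recovery. The
acceptance script (`scripts/acceptance.py`) recomputes everything from
scratch from a single `--seed` in a few minutes on one CPU; all
randomness is routed through `SeedSequence` children of that seed.

## Known limitations

* The conservation estimator is empirical-Bayes over parsimony counts,
  not ML Rate4Site; ranks are comparable, absolute rates are not.
* The mixed-ENM surface for very large motions is multi-basin; the
  single-saddle/unimodal-energy picture holds only for modest
  conformational changes, and the string fallback (not the cascade) is
  what large planted motions exercise in practice.
* Composition-class thresholds are package conventions, not inferred
  boundaries; tune them per dataset via the keyword arguments.
* The tail builder produces backbone-only extended geometry with clash
  relief — adequate for Cα network models, not for all-atom work.
* `count_substitutions` depends on the inferred topology; on saturated
  alignments the capped distances make the NJ topology, and hence the
  count, cap-dependent.
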