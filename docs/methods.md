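# Methods

`hpsforge` builds two interchangeable computational representations of the
His–Purkinje system (HPS) on an idealized biventricular anatomy, couples
either one to the working myocardium through a first-arrival (eikonal)
activation solver, and renders 12-lead pseudo-ECGs so the two
representations can be compared under sinus rhythm and right-ventricular
(RV) apical pacing.

## Synthetic anatomy and ventricular coordinates

The anatomy is two truncated thick-walled ellipsoidal shells: an LV centred
at the origin (long axis along z, apex down, basal plane above the
equator) and a thinner RV shell offset laterally so that its cavity
swallows part of the LV epicardium — that shared wall is the septum.
Points are sampled on structured shell levels of the analytic surfaces,
tetrahedralized with Delaunay, and tetrahedra whose centroid lies inside
the two-wall solid are retained (largest connected component).  Boundary
triangles are tagged LV endocardium, RV endocardium (free wall **plus** the
RV-facing septal face), epicardium, or base, by nearest analytic surface.

Universal ventricular coordinates are assigned analytically:

* `z` (apicobasal) — 0 at the apex of the owning wall's endocardial shell,
  1 at the basal plane, interpolated per transmural level so the
  endocardial apex is exactly `z = 0`;
* `rho` (transmural) — radial interpolation between the endo and epi
  shells of the owning wall.  The septum belongs to the LV coordinate
  system (`nu = -1`) and its RV-facing surface has `rho = 1`, matching the
  published root coordinate `b_rv,sf = (0.73, 1.0, -0.04, -1)`;
* `phi` (rotational) — azimuth about the LV long axis, zero toward
  mid-septum (+x, the RV side), counter-clockwise seen from the base;
* `nu` — -1 for LV + septum, +1 for the RV free wall.

Because `rho = 1` on the septal endocardium, all sub-endocardial logic uses
a normalized endocardial depth `d_endo = d_endo_surf / (d_endo_surf +
d_outer_surf)` (0 on any endocardium, 1 on the epicardium/base) instead of
raw `rho`.

The UVC → Cartesian mapping returns the mesh node minimizing a
lexicographic metric: exact `nu` match, then Euclidean distance in
`(z, rho, phi/pi)` with circular `phi`; ties break to the lowest node
index.  Cartesian → UVC is the Euclidean nearest node, flagged beyond
twice the target edge length.  The literature delegates this mapping to a
k-d-tree tool without stating a metric, so the metric here is the package's
own documented choice.

Default dimensions (mm): LV endo semi-axes 45/22, wall 9; RV endo semi-axes
40/24, wall 4, lateral offset 24; basal plane at 0.3 of the LV long axis;
target edge length 4.  At these sizes the mesh has ≈2 800 nodes and
≈11 000 tetrahedra — deliberately desk-scale; the published subject mesh
(~1 mm resolution, MRI-derived) is out of scope, so all quantities that
depend on anatomy (activation spans, EAS timings, network node counts) are
scaled-down analogues, not reproductions.

## Fascicle-based HPS

The sub-endocardial (SE) layer is every node with `z ∈ [s_z,min, s_z,max] =
[0.15, 0.9]` and `d_endo ≤ s_rho = 0.1` — at the default resolution about a
one-node-deep endocardial shell.  Each of the five fascicular roots
(published baseline coordinates) becomes a disc: the SE nodes within geodesic distance
`delta_rad · L_ab` of the mapped root on the SE surface graph, where
`L_ab` is the apicobasal endocardial arc length of the owning ventricle
(the units of the published `delta_rad = 0.05` are unstated; an
anatomy-relative fraction keeps disc size proportional to heart size).
Discs fire at the prescribed timings `t_his`; fast conduction (3.70 m/s) is
assigned to the SE layer.

Fast SE edges are built per endocardial surface: the surface-triangle edges
of one tag (both endpoints in the SE set) plus that surface graph's own
2-ring diagonals.  Building them from volumetric adjacency instead would
let diagonals tunnel straight through the septal wall at Purkinje speed —
an unphysical shortcut the thin-layer model must not contain.

## Purkinje-based HPS

**His bundle.**  Bifurcation points are given in UVC (published baseline):
`b_h0` (atrio-ventricular exit, the unique network root) → `b_h1` →
{`b_h,lv` → three LV roots; `b_h,rv` → `b_h,rv,mid` → two RV roots}.  Each
leg walks from waypoint to waypoint one edge length at a time, snapping
every intermediate sample to the nearest SE node (error if none lies within
two edge lengths), so paths hug the endocardium rather than chording
through the cavity; the polyline is then discretized at the cable
resolution (500 µm).  Where a bifurcation node would exceed two offspring
(three LV fascicles leave `b_h,lv`), the extra departure cascades one node
downstream, preserving the two-parent/two-offspring cap everywhere.

**Fractal growth.**  Each fascicle grows an independent recombinant network
on its endocardial surface (LV tag for LV fascicles; RV tag — septal face
plus free wall — for RV fascicles).  Per generation every active tip
spawns up to two branches at ±psi (20°) about its heading in the local
tangent plane.  Branch lengths are Normal(mu, sigma·mu) with mu = 2100 µm
and sigma = 0.4 (sigma is printed unitless beside mu, hence relative),
truncated to [0.25·mu, 4·mu].  Branches advance in 500 µm sub-steps; each
sub-step direction is `normalize((1-r)·d + r·d_rep)` with repulsion r =
0.25 away from the nearest established node (excluding the branch's own
last three nodes), then the new point is re-projected onto the surface.  A
sub-step passing within half a resolution of an existing same-network node
connects to it if the degree caps allow (collision; otherwise the branch
ends free); tips leaving the z-band are truncated.  All branches of a
generation advance in lockstep; collision and repulsion queries see a
k-d-tree snapshot taken at each sub-step, so two branches meeting within
one sub-step connect on the next.

Growth stops when the coverage estimate — the fraction of the ventricle's
SE territory nodes within mu of the network, updated incrementally as a
union of balls — reaches `delta_cov` (0.6 at baseline; the published configuration lists this
value under a sizing radius, identified here with the coverage fraction), or at a
generation cap (40).  `delta_cov = 0` means no growth.  The published
mapping from coverage to growth steps is not given; coverage-based
stopping is the package's own choice.

**PVJs.**  A linear junction density `lambda = delta_cov / mu` (per µm)
drives a renewal process along a depth-first traversal of each network:
at every node the junction probability is `min(1, lambda·d)` with `d` the
arc distance since the last junction (reset on success).  The published
text states a distance-dependent probability from a linear density without
a functional form; the linear hazard is the simplest rule consistent with
it.  An accepted junction splits its host segment at the midpoint and
hangs a transmurally oriented stem there (initially one resolution long).

**Transmural extension.**  Each stem base casts a ray along the inward
endocardial normal; the first intersection with any other boundary surface
gives the paired wall distance D.  The stem is extended to
`clamp(s_rho · D · max(0.25, g), 0, 0.95·D)` with `g ~ Normal(1, sigma)`,
so junctions sit at a heterogeneous ~10 % wall depth and never cross the
wall.  Rays that find no pairing surface drop their junction (counted).
Finally each junction couples to its nearest tissue node.

All randomness flows through named substreams (one per fascicle, one for
junction placement, one for extension) spawned from the master seed, so
every artifact is bit-reproducible.

## Activation solver

One directed weighted graph covers tissue and network.  Tissue edges are
tetrahedral element edges plus 2-ring diagonals (the classic mitigation of
graph-metric anisotropy; on a rod the far-end arrival converges to
length/velocity within a few percent), weighted length/0.70 m/s.  Network
edges are bidirectional at 3.70 m/s, so orthodromic and antidromic
propagation both occur.  Each junction contributes one network→tissue edge
weighted by the anterograde delay (8 ms) and one tissue→network edge by
the retrograde delay (3 ms); a single multi-source Dijkstra solve then
captures the full anterograde/retrograde interplay — behaviourally
equivalent, for first arrivals, to the reaction-eikonal solver the full
model would use.  An optional transversely isotropic myocardium (rule-based
transmural fiber rotation ±60°, velocity ratio `anisotropy_ratio`) is
provided but off by default (ratio 1): the published anisotropy values
belong to an out-of-scope reference, and keeping both representations
isotropic keeps their comparison clean.

Pacing sources are Dirichlet data: after the solve every source vertex is
reset to its prescribed time even if propagation from another source
arrives earlier — a timed stimulus fires when told to, and the tissue
around it simply keeps its earlier arrival.  (This matters on the
synthetic anatomy: the fast SE layer can carry the LV wavefront to an RV
root before that root's own prescribed firing time.)  Consequently the
1-Lipschitz property of arrival times holds along every edge whose head is
not a source.

Scenarios: sinus fires `b_h0` at t = 0 (Purkinje) or the five discs at
`t_his` (fascicle); RV apical pacing fires the mapped `b_pace =
(0.3, 0, 0, +1)` at t = 0 — the fascicle model then keeps its fast SE
layer but fires no timed sources, so the layer is activated retrogradely.
Each run reports the activation times at the five root nodes; for the
Purkinje model these are the simulated analogues of `t_his`.

## Pseudo-ECG

Transmembrane voltage is the travelling template `v(x,t) = V(t - ta(x))`,
with V integrated from the two-variable Mitchell–Schaeffer model
(tau_in 0.3, tau_out 6, tau_open 120, tau_close 150, v_gate 0.13 ms;
explicit Euler with a step-halving stability check; the stimulus default
drives the normalized upstroke to ~1).  Electrode potentials use the
infinite-homogeneous-conductor dipole sum with linear tetrahedral
gradients — the full torso lead-field computation is out of scope, and
relative QRS-morphology comparisons between the two HPS representations
survive this simplification.  Standard limb/augmented/precordial leads
derive from the Wilson central terminal, which makes `I - II + III = 0`
and `aVR + aVL + aVF = 0` exact.  Electrodes sit on a torso-scale bounding
sphere in anatomically plausible directions; their exact placement is
synthetic plumbing shared by both representations.

Post-processing is a zero-phase 60 Hz low-pass (zero-phase so alignment is
not biased by group delay), then — against a reference — one global
integer-sample shift maximizing the summed cross-correlation over all
twelve leads and one uniform amplitude factor minimizing total squared
error, both logged.  The clinical measured-data chain (50 Hz notch, 0.5 Hz
high-pass, 60 Hz low-pass) is available as a separate preset.  The
alignment criterion is unspecified in the source description;
cross-correlation is the package's documented choice.

## The equivalence study

`run_all` mirrors the two-stage workflow: the Purkinje model is simulated
under sinus rhythm, its five simulated root timings are handed to the
fascicle model as `t_his` (exactly how the published timings were
produced), and both representations are then compared under sinus rhythm
and RV apical pacing via per-lead Pearson correlation after
alignment/uniform scaling.  At baseline on the synthetic anatomy the sinus
traces agree closely (per-lead r ≳ 0.9) while RV pacing agrees less — the
expected signature, since pacing exercises retrograde/antidromic physics
that the continuum SE layer only approximates.

## What the synthetic setting does and does not show

The generator reproduces the *structural* conditions of the workflow
(bounded SE layer, five fascicles, septal coordinate conventions,
wall-thickness-scaled junction depths) but not patient anatomy: no
trabeculation or papillary structure, idealized wall thickness, a crude
basal truncation, and a coarse 4 mm resolution against the published
~1 mm.  Passing tests therefore demonstrate correctness of the
construction and solvers and the qualitative fascicle/Purkinje
relationship, not quantitative agreement with any measured ECG.  Network
size (~70 k nodes / ~77 k branches at baseline) happens to be of the same
order as the published network because the coarser anatomy is offset by
full coverage of a smaller endocardium; this is incidental.

## Numerical choices and degenerate inputs

* Nearest-node queries tie-break to the lowest index; all stochastic
  stages consume named `SeedSequence` substreams.
* Closest-point queries certify k-d-tree candidate sets against the
  maximum face reach and fall back to exhaustive search when uncertain;
  ray casting is vectorized Möller–Trumbore over the tagged boundary.
* Degenerate geometry (non-positive thickness, RV not intersecting the
  LV, edge length exceeding a wall) is rejected at validation with a
  diagnostic; an SE band that excludes the whole mesh, a root outside the
  SE layer, a His sample with no snappable SE node, an unreachable pacing
  site, and an electrode inside the myocardium all raise errors naming
  the offending entity.
* Stage wall times are logged to stderr only, so repeated runs of the
  pipeline produce byte-identical artifacts.

## Known limitations

* The eikonal surrogate has no refractoriness, no rate dependence and no
  repolarization; T waves are out of scope.
* PVJ electrotonic microstructure and inter-fascicle anastomoses are not
  modelled; junction delays are fixed constants.
* The infinite-conductor pseudo-ECG ignores torso inhomogeneity; absolute
  amplitudes are arbitrary (hence the uniform-scaling comparison).
* Analytic UVC is only available for the package's own synthetic
  geometry; externally supplied meshes must bring their own coordinates.
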