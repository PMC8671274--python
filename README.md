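# hpsforge

Automated construction of a His–Purkinje system (HPS) for biventricular
cardiac electrophysiology models, in two interchangeable representations,
with a coupled activation solver and a 12-lead pseudo-ECG pipeline.

Personalizing ventricular activation to a patient's ECG is much cheaper
with a *phenomenological* HPS — five timed earliest-activation sites (EAS)
over a fast-conducting sub-endocardial (SE) layer — than with an anatomical
Purkinje network.  But only a *topologically realistic* network behaves
correctly beyond sinus rhythm, when junctions conduct retrogradely and the
network antidromically.  `hpsforge` implements the two-stage idea: fit (or
prescribe) the fascicle-based model, then automatically replace it with a
fractal Purkinje network that reproduces the same earliest-activation
pattern, and verify the swap by comparing simulated 12-lead ECGs.

Everything runs on the package's own idealized biventricular anatomy,
addressed through universal ventricular coordinates (UVC)
`b = (z, ρ, φ, ν)` — apicobasal, transmural, rotational, ventricular — so
every model entity (EAS roots, His-bundle bifurcations, SE-layer bounds,
pacing sites) is specified anatomy-relative.

The core pieces:

* **Fascicle model** — SE layer `z ∈ [s_z,min, s_z,max]`, `d_endo ≤ s_ρ`
  conducting at 3.70 m/s, with five geodesic discs of radius
  `δ_rad · L_ab` fired at timings `t_his`.
* **Purkinje model** — a His bundle laid out between UVC bifurcation
  points; per fascicle, a recombinant fractal network grown on the
  endocardium (branch length ~ N(μ, σμ), branching angle ±ψ, repulsion r,
  ≤2 parents and ≤2 offspring per node, collisions allowed) until a
  fraction `δ_cov` of the SE territory is covered; Purkinje–ventricular
  junctions (PVJs) placed by a renewal process with hazard
  `min(1, λd)`, `λ = δ_cov/μ`; each junction extended transmurally by
  ray-tracing to `s_ρ` of the local wall thickness.
* **Activation** — one multi-source Dijkstra solve on a directed graph
  (tissue edges + 2-ring diagonals at 0.70 m/s, cable edges at 3.70 m/s,
  asymmetric PVJ delays 8 ms anterograde / 3 ms retrograde) capturing
  orthodromic/antidromic and anterograde/retrograde interplay at once.
* **Pseudo-ECG** — Mitchell–Schaeffer action-potential template,
  infinite-conductor dipole summation, Wilson central terminal leads,
  zero-phase filtering, global alignment and uniform amplitude scaling.

See `docs/methods.md` for the model details and assumptions.

## Worked example

```sh
hpsforge all -w run --seed 1
```

builds the geometry, both HPS representations, all four simulations and
the ECG comparison, logging:

```
geometry: 2780 nodes, 11177 tets, SE layer 699 nodes
purkinje HPS: 71824 nodes, 77106 segments, 12875 PVJs (0 dropped)
purkinje sinus EAS timings (ms): lv_af=19.29, lv_sf=13.11, lv_pf=22.43, rv_sf=26.70, rv_mod=31.26
ECG agreement: sinus mean r=0.953, rv_apical mean r=0.894
```

Reading the output: the fractal networks discretized at 500 µm comprise
~72 k cable nodes with ~13 k junctions.  The five EAS timings are the
*simulated* arrival times of the His wavefront at the fascicular roots —
the Purkinje model's analogue of the fascicle model's prescribed `t_his`
(LV fascicles activate first, the RV moderator-band fascicle last, as in
normal conduction).  Handing exactly these timings to the fascicle model
and comparing 12-lead pseudo-ECGs gives a mean per-lead Pearson r of 0.95
under sinus rhythm; under RV apical pacing — where the fast-SE continuum
only approximates retrograde network physics — agreement drops to 0.89,
the expected signature of the representation swap.

Artifacts land in `run/`: the labelled mesh (`biv.vtu`, CARP text
triplet), the network (`hps.vtp`, plain-text `hps.cable`,
`pvj_couplings.txt`), per-node activation maps (`act_*.dat`), ECGs
(`ecg_*.csv`) and `comparison.json`.  Each stage is also available as its
own subcommand (`make-geometry`, `build-fascicle`, `grow-purkinje`,
`simulate`, `ecg`, `compare`) sharing the work directory, and every config
scalar can be overridden on the command line (`--delta-cov`, `--cv-purk`,
`--delay-antero`, ...).  A fixed `--seed` reproduces every artifact
byte-for-byte.

The same workflow is available as a library:

```python
from hpsforge.pipeline import run_all
result = run_all(seed=1)
result["eas_timings"]["purkinje"]     # simulated root timings (ms)
result["comparisons"]["sinus"]        # per-lead r / RMSE
```

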