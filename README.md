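# tndyn

Post-simulation analysis of cardiac troponin molecular-dynamics
trajectories: interdomain hinge-angle and interhelical-angle metrics,
RMSF/pairwise-RMSD fluctuation analysis with medoid (representative
structure) selection, per-frame atomistic interaction profiling aggregated
to residue-pair contact frequencies, and distribution statistics
(KDE mode, FWHM, open-state fractions, Cohen's *d*, ΔΔG arithmetic) for
comparing phosphorylation states and mutants.

## Who this is for

Groups running long multi-replica MD of the troponin core (cTnC/cTnI/cTnT)
— or any two-domain articulated protein — who need the standard
domain-motion observables and contact-frequency comparisons between
conditions (e.g. unphosphorylated vs Ser22/Ser23-bisphosphorylated cTnI,
wild type vs the DCM-linked cTnC-G159D mutant) as reproducible, scriptable
quantities rather than one-off notebook code.

## The quantities

* **Interdomain hinge angle** θ = ∠(head − fulcrum, arm − fulcrum), where
  the three anchors are Cα centroids: head = TnC 3–85 (NcTnC), fulcrum =
  TnC 94–157 (CcTnC), IT-arm end = pooled TnT 241–251 ∪ TnI 69–76. The
  principal slow motion of Ca²⁺-saturated troponin is this hinge.
* **A/B interhelical angle** = 180° − ∠(â_A, â_B), the supplement of the
  angle between the N→C axes of TnC helix A (14–25) and helix B (38–47);
  each axis endpoint is the average of a window of Cα positions from each
  helix end. Angles above 110° are conventionally the "open" hydrophobic
  patch.
* **NcTnC–CcTnC distance** between the TnC 3–85 and TnC 94–157 Cα
  centroids.
* **RMSF** per residue about an iterated mean structure; **RMSD2d**, the
  all-against-all heavy-atom RMSD matrix after optimal (Kabsch)
  superposition; the **representative structure** is the frame with the
  lowest summed RMSD to all others (the medoid).
* **Interaction frequencies**: per frame, residue pairs are classified as
  hydrogen-bonded, ionic, aromatic and/or van der Waals from atom typing
  (20 amino acids + phosphoserine with its physiological −2 phosphate) and
  geometric cutoffs; presence is boolean per pair per type per frame, and
  occupancy = 100·count/N_frames. State comparisons are percentage-point
  deltas.
* **Distribution statistics** per metric series: mean, sample std, the
  mode of a Gaussian-kernel KDE (Scott bandwidth), the full width at
  half-maximum of that density, threshold fractions, Cohen's
  *d* = (μ_B − μ_A)/s_pooled, and ΔΔG = ⟨ΔG⟩_B − ⟨ΔG⟩_A for externally
  computed binding-energy tables.

A synthetic-trajectory generator (`tndyn.synthetic`) builds toy two-domain
systems with *planted* hinge-angle distributions, helix crossing angles,
positional jitter and contact occupancies, and records every draw as ground
truth — so the entire pipeline is testable without MD output.

## Worked example

```python
from tndyn import geometry, stats, synthetic

spec = synthetic.SyntheticSpec(
    n_runs=5, frames_per_run=1000, seed=0,
    hinge_distribution=synthetic.GaussianAngles(121.6, 7.2),
)
traj, truth = synthetic.generate_trajectory(spec)
hinge = geometry.hinge_series(traj)
summary = stats.summarize(hinge.values)
print(f"frames: {traj.n_frames} over {traj.n_runs} runs")
print(f"hinge mean (std): {summary.mean:.2f} ({summary.std:.2f}) deg")
print(f"KDE mode: {summary.kde_mode:.1f} deg   FWHM: {summary.fwhm:.1f} deg")
```

```
frames: 5000 over 5 runs
hinge mean (std): 121.57 (7.17) deg
KDE mode: 120.0 deg   FWHM: 17.8 deg
```

The recovered mean and width match the planted N(121.6°, 7.2°) hinge
distribution; the FWHM is the KDE-smoothed width
2.355·√(σ² + h²) ≈ 17.1° at this sample size. Planted contacts are
likewise recovered by the interaction profiler:

```python
from tndyn import interactions
table = interactions.profile_trajectory(traj)
table.lookup(("TnC", 95), ("TnC", 98), "ionic")   # planted at 80%
```

```
TnC:95-TnC:98:ionic          planted   80%  measured  81.6%
TnC:105-TnC:108:hbond        planted   60%  measured  60.4%
TnC:115-TnC:118:aromatic     planted   25%  measured  28.6%
TnC:39-TnI:23:ionic          planted   80%  measured  79.6%
```

(each measured occupancy equals the realised Bernoulli draws of its
500-frame run exactly; the deviation from the planted rate is sampling
noise).

The same analyses run from the shell:

```sh
tndyn synth --spec spec.json --out-dir runs/
tndyn hinge --topology runs/topology.pdb --traj runs/run_00.pdb --out hinge.csv
tndyn stats hinge.csv --threshold 110 --out summary.json
tndyn run --config system.json          # full per-system bundle
tndyn compare-systems A_out/ B_out/ --out report/
```

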