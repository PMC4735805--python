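# idisc

Nanoscale analysis of adhesion/excitability nodes at the **cardiac
intercalated disc (ID)** — the end-to-end contact region between
cardiomyocytes where the adhesion molecule N-cadherin and the sodium
channel Nav1.5 form interleaved clusters that couple mechanical junctions
to electrical excitability.

The package is a tested, reusable implementation of the quantitative
pipeline such studies rely on, for researchers analysing two-channel
super-resolution (SMLM) data of membrane protein clusters:

- **Cluster metrics** — binarization, connected-component detection (2D
  and 3D), restriction to a ±500 nm band around the ID membrane line,
  and nearest-neighbour distance statistics (contact = edge-to-edge ≤ 0,
  100-nm-binned histograms).
- **CLEM registration** — least-squares affine mapping between
  fluorescence and EM frames from fiducial pairs, with a 20 nm QC gate.
- **Placement Monte Carlo** — ellipse clusters placed in membrane boxes
  under a random model or an attraction model: a parameter *f* ≥ 1 sets
  the ratio between the placement probability overlapping a reference
  cluster and not; for reference coverage *p* the accepted contact
  probability is the closed form *pf*/(*pf* + 1 − *p*).
- **Lattice binding walk** — a regulator diffusing on a 33-nm lattice in
  a 1,066 × 1,066 × 528 nm cuboid (2,127 molecules ≙ 6 µM), binding 44
  immobilized channels arranged clustered vs. distributed; the
  dissociation constant is read out as
  K_d = [L_free]·(R_free)/(RL), and channel clustering lowers the
  measured K_d through local rebinding.
- **Particle averaging** — two-stage (reference channel, then secondary)
  cross-correlation alignment of 100 × 100 px particle boxes with a
  provably monotone alignment score.
- **Surface topology** — triangulated surface-area amplification of
  height maps, peak detection, 3D/projected peak spacing, and FFT
  periodicity of the projected peak arrangement.
- **Current model** — channels per cluster from area at 33 nm pore
  pitch, expected clusters under a patch pipette, and the ensemble peak
  current I = n_clusters · n_channels · g · V.
- **Synthetic data** — generators with exact ground truth for every
  stage (the package ships no experimental data and needs none to be
  fully testable).

## Worked example

```python
>>> from idisc.current import predicted_patch_current, clusters_under_patch, CurrentModelParams
>>> clusters_under_patch(CurrentModelParams())   # 2 um pipette, 6.5x amplification, 1 um spacing
(20.420352248333657, 20)
>>> predicted_patch_current(19, 44, 10, 60)      # clusters x channels x pS x mV
501.59999999999997
```

A 2-µm patch pipette over membrane amplified 6.5× by ID folding samples
about 20 clusters at ~1 µm spacing; 19 clusters of 44 channels at 10 pS
unitary conductance and 60 mV driving force carry ≈ 502 pA of peak sodium
current — the order of magnitude measured directly in cell-attached
macropatch recordings at the ID.

The same pipeline runs from the shell:

```bash
idisc synth --box-length 6000 --n-ref 4 --n-query 8 --f 4 --seed 2 --outdir demo
idisc analyze-clusters --image demo/image.tif --membrane demo/membrane.csv --outdir demo_analysis
idisc predict-current
```

`analyze-clusters` writes `clusters.csv`, `distances.csv` and a
`summary.json` whose `contact_fraction` and `bin_fractions` sum to 1;
every subcommand records a manifest (parameters, seed, output checksums).

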