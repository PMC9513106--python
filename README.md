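# synthflow

Synthesis and reconstruction of multipoint 4D flow MRI of turbulent flow.

Starting from gridded ground-truth fields — mean velocity and Reynolds
stress tensor (RST) per voxel per cardiac frame, either produced by the
built-in analytic stenotic-jet phantom or loaded from gridded CFD
exports — the package:

1. **band-limits** the fields to a prescribed MR resolution by k-space
   apodization with a truncated Gaussian modulation transfer function
   (`synthflow.sampling`), including the partial-volume term that makes
   unresolved shear masquerade as turbulence;
2. **synthesizes** complex multipoint (multi-VENC, six-direction)
   phase-contrast MR signals with a scan-time-budget noise model
   `SNR = alpha * V * sqrt(dt)` (`synthflow.mrsignal`);
3. **reconstructs** directional velocities and intra-voxel standard
   deviations by multipoint MAP estimation, then assembles Cartesian
   velocity, RST, TKE and KE maps by pseudoinverse least squares
   (`synthflow.recon`);
4. **quantifies** errors against ground truth: ROI-integrated totals,
   signed percent errors, peak-TKE timing relative to peak flow and
   voxel-wise peak statistics (`synthflow.analysis`).

`synthflow.phantom` provides the analytic eccentric cosine-stenosis
phantom (Hagen-Poiseuille inlet, pulsatile waveform, parametric
post-stenotic turbulence), ensemble/temporal-window RST statistics and
HDF5 I/O; `synthflow.cli` orchestrates everything reproducibly.

## Command line

All stages run through a single entry point:

```sh
synthflow phantom    --config cfg.json --out field.h5
synthflow downsample --in field.h5 --out ds.h5 --delta-l 2.5
synthflow encode     --config cfg.json --in ds.h5 --out sig.h5 --seed 7
synthflow recon      --in sig.h5 --out recon.h5 [--psd-project]
synthflow run        --config cfg.json --out reports/   # full pipeline
synthflow fixtures   --size tiny --out fixture.h5
```

The config is a single JSON file; `examples/demo_config.json` runs a
75 % eccentric stenosis at 1.5 and 2.5 mm with 5 ms time averaging. Every `(delta_l, delta_t)` condition in
`conditions` is validated before any compute, all randomness derives
from the single `seed`, and reports (JSON + CSV per condition) record
the config hash.

## Conventions

* Grid spacing/origin in mm, voxel-center sampling, flow axis = z.
* Velocity in m/s, RST in Pa, TKE/KE densities in J/m^3, totals in mJ.
* Symmetric tensors are stored with 6 components, order
  `xx, yy, zz, xy, xz, yz`.
* HDF5 containers: `/u_mean (frames, 3, nx, ny, nz)`,
  `/rst (frames, 6, nx, ny, nz)`, `/mask`, attributes `spacing_mm`,
  `origin_mm`, `time_ms`, `rho`, `mu`.
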