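# txpet

Desk-scale simulation of **transmission-source attenuation correction (AC)
for non-time-of-flight PET/MRI**, with a quantitative comparison against the
standard clinical alternatives.

## The problem

PET quantification requires correcting emission data for photon attenuation
with a map of linear attenuation coefficients (a μ-map, cm⁻¹ at 511 keV).
A PET/MRI system has no transmission or CT hardware, so clinical μ-maps are
derived from MR images: Dixon-based segmentation (which contains no bone and
no internal air) or UTE-based segmentation (which resolves bone but
mis-segments tissue classes).  Both bias the reconstructed activity,
especially for bone-avid tracers such as ¹⁸F-NaF.  An orbiting 511 keV
transmission (TX) source integrated in the MR coil measures attenuation
directly — even *post-injection*, by interleaving transmission frames with
emission-only frames and windowing the sinogram to the source position.

`txpet` reproduces this study design end-to-end on a synthetic 2D body
slice (soft tissue, cortical-bone shells, an air-filled trachea, bone-avid
hot lesions, a coil hardware ring):

1. **phantom** — tissue labels, true μ-map, true activity, pseudo-CT (HU),
   hardware μ component, plus Dixon-like and UTE-like degraded μ-maps;
2. **acquisition** — Poisson simulation of a 30 min blank scan, 12 × 1 min
   post-injection transmission frames interleaved with 1 min emission-only
   frames (orbiting point source, per-bin window duty cycle), and a 30 min
   emission scan;
3. **attenuation** — μ-map variants: `TX` = OSEM reconstruction of
   p = ln(B/T) (blank over contamination-subtracted transmission), `CT` =
   bilinear HU→LAC scaling (μ = μ_w·(HU+1000)/1000 below a breakpoint, a
   second slope above it) down-sampled to the PET grid, `REF` = a 5.15 mm
   FWHM resolution-degraded reference, `DIXON`/`UTE` surrogates, and the
   hardware component merged into every map;
4. **recon** — attenuation-weighted OSEM (attenuation factors
   exp(−∫μ dl) inside the system model), calibrated to kBq/ml;
5. **evaluation** — two hot ROIs (27 px each, grown around the two
   strongest uptake maxima) and one cold ROI (198 px in the trachea);
   mean ± SD per method and relative difference to the reference, rounded
   half-away-from-zero to integer percent.

The forward/back projector is a ray-driven (Joseph-style) parallel-beam
pair materialised as one sparse matrix, so back projection is the exact
adjoint of forward projection.

## Worked example

```sh
txpet run --seed 1 --out results/run1
```

runs the full stochastic study (≈10 s) and prints:

```
Reference method: REF
ROI        Method     Activity [kBq/ml]  Rel. diff
HOT_LEFT   TRUE          59.7 ± 2.9            -2%
HOT_LEFT   TX            60.7 ± 2.9            +0%
HOT_LEFT   REF           60.9 ± 2.9              -
HOT_LEFT   CT            64.2 ± 2.5            +5%
HOT_LEFT   DIXON         58.5 ± 2.9            -4%
HOT_LEFT   UTE           60.0 ± 4.3            -1%
HOT_RIGHT  TRUE          59.7 ± 3.0            -2%
HOT_RIGHT  TX            61.2 ± 3.1            +1%
HOT_RIGHT  REF           60.9 ± 3.0              -
HOT_RIGHT  CT            64.2 ± 2.7            +5%
HOT_RIGHT  DIXON         58.5 ± 3.1            -4%
HOT_RIGHT  UTE           58.5 ± 4.0            -4%
COLD       TRUE           0.5 ± 0.1           -12%
COLD       TX             0.7 ± 0.2           +34%
COLD       REF            0.5 ± 0.2              -
COLD       CT             0.4 ± 0.1           -16%
COLD       DIXON          3.7 ± 0.4          +616%
COLD       UTE            0.3 ± 0.0           -47%
```

Reading the table: the transmission system (`TX`) agrees with the reference
reconstruction to ≈1% in the hot (bone-adjacent lesion) ROIs; the bone-free
Dixon-like map underestimates them (−4%); the bilinear-scaled CT map
overestimates them (+5%, the known dense-bone bias of bilinear scaling);
in the cold trachea ROI the Dixon map (trachea filled with soft tissue)
grossly overcorrects while the UTE map (trachea enlarged) undercorrects.
All intermediates (NIfTI images, HDF5 sinograms, CSV report, difference
images, JSON provenance) are written under `results/run1/`; the same seed
reproduces them byte-for-byte.

The stages are also available individually (`txpet phantom`, `simulate`,
`recon-mu`, `recon-activity`, `evaluate`) sharing one output directory, and
everything is scriptable through the library API
(`txpet.pipeline.full_pipeline`, `txpet.PipelineConfig`).

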