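# mfaquant

Quantification workflow for the **molecular force assay (MFA)** — a
massively parallel, force-based measurement of protein–DNA binding
strength. Each protein–DNA *sample bond* is loaded in series with its own
DNA-duplex *reference bond* between two separating surfaces; the weaker
bond ruptures, and a Cy5 label reports where the reference broke. The
read-out of one experiment is a pair of 16-bit fluorescence images of the
same surface: a *transfer* image taken right after separation and a
*saturation* image taken after labelling every functional surface protein.

The package is for people who analyse (or want to prototype analysis of)
such image pairs: it implements the complete analysis chain together with
a physics-based synthetic-data generator, so every stage can be validated
against known ground truth.

## What it computes

**Normalized Fluorescence.** After subtracting the camera background from
both channels, the images are divided pixel by pixel:

    NF = F_transfer / F_intact protein

NF at a pixel is the fraction of constructs there whose reference bond
ruptured; because both channels image the same immobilized proteins,
surface-density inhomogeneities cancel in the ratio. Histograms of each
pad (one pad = one motif × reference-length condition on the 4×4 stamp)
are fitted with a Gaussian to give the pad's NF mean ± SD. Pads whose
transfer signal does not rise above background carry no ratio information
and are assigned NF = 0 (the zero rule).

**Rupture competition.** Synthetic transfer fractions come from a
serial-bond competition model: each bond has a Bell off-rate
k(F) = k₀·exp(F/F_β), force ramps linearly at rate r, and

    P(reference first) = ∫₀^∞ (k_ref(F)/r) · exp(−∫₀^F [k_ref+k_sample]/r dF′) dF

evaluated both by adaptive quadrature and by kinetic Monte Carlo.
Identical bonds give P = 1/2 — the NF = 0.5 point at which a reference
duplex matches the sample bond's stability.

**Base-pair calibration.** Mean NF falls linearly with reference duplex
length (in shear geometry, over 20–40 bp), so strength differences can be
stated in DNA base pairs: either from the reference length solving
NF = 0.5 per motif (`linear_model`), or directly when one motif at length
L₁ is *equal within errors* (|ΔNF| ≤ σ₁+σ₂) to another at L₂ — the
strength gap is then |L₁−L₂| base pairs (`matched_pair`).

## Worked example

Simulate a default 4×4 pad experiment (three motifs × 20/40 bp shear
references), quantify it and calibrate, all from one seed:

```sh
mfa run-all --seed 3 --outdir demo
```

prints

```
matched_pair: delta = 20.0 bp
linear_model: delta = 20.8 bp
outputs in demo
```

and writes `demo/pads.csv` with one row per pad, e.g.

```
pad_row,pad_col,motif_label,reference_n_bp,nf_mean,nf_sd,n_pixels,status
1,0,low_affinity,20,0.388783,0.149409,1936,fitted
1,1,low_affinity,40,0.198905,0.0220961,1936,fitted
2,0,high_affinity,20,0.645445,0.0721924,1936,fitted
2,1,high_affinity,40,0.32035,0.0157856,1936,fitted
0,0,no_binding,20,0,,1936,zeroed
...
```

Reading the numbers: the high-affinity motif keeps 65% of its labels
against a 20 bp reference but only 32% against 40 bp; the low-affinity
motif gives 0.39 and 0.20; the no-binding motif never exceeds background
and is zeroed. Because the low-affinity/20 bp condition (0.39 ± 0.15) and
the high-affinity/40 bp condition (0.32 ± 0.02) agree within errors, the
strength difference between the two motifs equals the stability of a
20 bp duplex (`matched_pair: delta = 20.0 bp`); solving each motif's
linear NF-length model for NF = 0.5 gives the consistent 20.8 bp.
`demo/calibration.json` holds the full report (per-condition NF, both
methods, fitted lines, extrapolation flags).

The stages are also available separately (`mfa simulate`, `mfa quantify
transfer.tif saturation.tif`, `mfa calibrate pads.csv`) and as library
functions (`render_image_set`, `quantify_image_set`,
`equivalent_bp_difference`, …). Runs are byte-reproducible for a fixed
seed, and every run archives its resolved YAML config next to its outputs.

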