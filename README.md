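# ms2quant

Quantification of nascent transcription in live-imaged early *Drosophila*
embryos using the MS2-MCP reporter system, together with consensus
binding-site analysis and in-silico mutagenesis of the enhancer driving the
reporter.

In an MS2-MCP movie, each actively transcribing nucleus shows a single
sub-nuclear fluorescent dot (MCP-GFP bound to MS2 stem-loops in the nascent
transcript) while the nuclear envelopes are marked in a second channel
(Nup-RFP). From two-channel time-lapse stacks the package measures, per
nuclear-cycle window (nc9 … nc14c):

- the **number of active nuclei** — dots are segmented by smoothing
  (Gaussian filter, σ = 0.55), thresholding the MCP channel at a fraction
  *BTH* = 0.30 of maximum intensity, clustering suprathreshold pixels with
  4-connectivity (≥ 4 pixels per callable dot), and discarding dots outside
  Nup-labeled nuclei; counts are averaged over the frames in each ~10-min
  window;
- the **dot size** (transcription-rate proxy) in 4-pixel units,
  `size = pixel_count / 4`;
- the **expression-domain width and ventral boundary** along the
  dorsoventral axis: dot positions are reduced to a relative embryo-width
  coordinate EW ∈ [0, 100] (0 = ventral extreme, 100 = dorsal extreme),
  binned (4-pixel bins) and smoothed by a Gaussian-kernel density estimate
  with robust Silverman bandwidth *h* = 0.9·min(sd, IQR/1.34)·n^(−1/5); the
  width is the EW distance between the outermost crossings of the KDE curve
  at *TH* = 0.3 of its maximum, and the ventral boundary is the ventral-most
  crossing;
- **initiation timing** — the first frame at which each nucleus shows a dot;
- replicate alignment (EW cross-correlation shift) and two-group Student's
  *t* comparisons.

Because suitable public movies do not exist, the package ships a synthetic
embryo-movie generator with exact ground truth (elliptical embryo, a
peripheral monolayer of ring-shaped nuclei, at most one dot per nucleus,
a ventrolaterally restricted activity stripe whose count and extent change
across nuclear cycles, background noise). Every pipeline stage is validated
end-to-end against that ground truth.

The motif component scans degenerate IUPAC consensus patterns — Su(H)
`RTGRGAR`, Run core `ACCGCA`, extended Run `AACCRCA` — on both strands of
the packaged 658-bp *sog_Distal* enhancer sequence and rebuilds the
classical mutant reporter constructs (ΔSu(H), Δrun, the double mutant, and
an added-Run-site variant) by exact substring substitution.

## Worked example

Run the full pipeline on the default synthetic movie (512×512, 8 windows of
10 frames, seed 1) and print the per-window readouts:

```python
from ms2quant import synthetic
from ms2quant.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(synthetic=True,
                     simulation=synthetic.default_config(seed=1),
                     static_nuclei=True, seed=1)
res = run_pipeline(cfg, "runs/demo")
print(res.activity.to_string(index=False))
```

```
window  mean_active  n_frames
   nc9          0.0        10
  nc10          4.0        10
  nc11          8.0        10
  nc12         14.0        10
  nc13         22.0        10
 nc14a         18.0        10
 nc14b         14.0        10
 nc14c         10.0        10
```

The recovered activity trace equals the generator's ground truth exactly:
onset at nc10 with 4 nuclei, a nc13 peak, decline through nc14a–c. The
width table for the same run reads, e.g. for nc13, `width = 44.2 EW` with
`ventral_boundary = 17.7 EW` for a true activity stripe spanning EW
[20, 60] — the ~2 EW overshoot per side is the expected kernel blur
(≈ 0.52·*h* per side at *h* ≈ 3.8), and the window dot-size column sits at
`2.01` in 4-pixel units for a true mean dot area of ~8 pixels.

The same pipeline is available from the shell:

```sh
ms2quant run --synthetic --seed 1 --out runs/demo
ms2quant profile runs/demo            # overlay plot of the EW profiles
ms2quant motifs --out runs/motifs     # consensus scan + mutant constructs
```

`ms2quant motifs` prints, for the wild-type enhancer, 3 Su(H) hits and a
single Run hit (and, for the mutants, 0 hits after ΔSu(H)/Δrun and 2
extended-Run hits after the add-run edit):

```
    construct  pattern  n_hits                            hits  length_bp
   sog_Distal      SuH       3  56-63(-);151-158(+);456-463(+)        658
   sog_Distal      Run       1                      190-196(-)        658
    sogD_dSuH      SuH       0                                        657
    sogD_drun      Run       0                                        658
 sogD_add_run  Run_ext       2           142-149(-);190-197(-)        658
```

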