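# Methods

## The selection model

The package treats tumor ROI selection as a scoring problem over candidate
axis-aligned boxes given an edge map of the image. The edge map is assumed
to respond strongly along the tumor boundary and weakly elsewhere; nothing
about how it was produced is used beyond its being an 8-bit single-channel
image. Two indicators are computed per candidate box:

* **Edge mass `S`** — the sum of normalized edge intensities inside the box.
  Monotone under box enlargement; saturates once the box covers the whole
  boundary response.
* **Edge density `D`** — the fraction of box pixels above a per-image
  binarization threshold. Maximal for a tight box around the boundary;
  diluted by background as the box grows.

Their product `SD` peaks for boxes that cover the boundary (high `S`) while
staying tight (high `D`); the candidate with maximal `SD` is selected. The
rule assumes a single lesion per image and candidates that all lie within
the image frame (detector outputs from a differently-sized model input are
first mapped through `rescale_box`).

### Coordinate conventions

Boxes are integer rectangles with 0-based, inclusive corners; `x` indexes
columns, `y` rows, origin top-left. Width and height therefore carry a `+1`,
and two boxes touching at a corner share one pixel — which is also the
detection criterion (any overlap with the gold box counts as detected).
Rescaling between frames multiplies corners by the axis scale factors,
rounds half away from zero, and clamps into the target frame; a rescale and
its inverse move corners by at most one pixel.

### Intermode binarization

The threshold is computed once per image on the full edge map (before the
candidate loop), on the 256-bin histogram of the ×255-rescaled intensities:
the histogram is smoothed repeatedly with a 3-bin moving average (edges
replicated) until exactly two strict local maxima remain, and the threshold
is the midpoint of the two mode bins, mapped back to `[0,1]`. Binarization
uses a strict `>` comparison so an all-zero map stays all-zero under any
threshold. Degenerate inputs (unimodal or constant histograms, or failure to
reach bimodality within `max_iterations = 10 000` passes) fall back to the
histogram mean with a logged warning, and the pipeline counts these
fallbacks in its report. Ties in `SD` between candidates are broken by the
configured model order, making every run deterministic.

## Baseline combiners and evaluation

The three baseline fusions of the candidate set are: **average** (mean of
upper-left and of lower-right corners, rounded half away from zero),
**union** (smallest enclosing box — the rectangular reading of "union",
since downstream metrics need a single box), and **intersection** (iterated
box intersection; empty result = detection failure). Models that produced no
box are excluded before combining.

Evaluation is pixel-overlap precision/recall/F1 between single boxes, with
`F1 = 0` when the boxes are disjoint. Summaries report the detection rate
over all images of a group (benign / malignant / pooled) and mean ± sample
standard deviation (n−1; defined as 0 for a single image) of P/R/F1 over
detected images only — undetected images lower the rate but never enter the
means. Detection rates are reported at full precision together with a
rounded integer-percent field.

## Preprocessing

`to_artificial_rgb` stacks (original, sharpened, contrast-enhanced) versions
of a grayscale image into three channels for RGB-pretrained detectors.
Sharpening is unsharp masking (default radius 2 px, amount 1) and contrast
enhancement is clip-limited adaptive histogram equalization (default clip
0.01, image split into ~8×8 tiles), both via scikit-image and both
config-overridable; the exact filters behind "sharpened" and
"contrast-enhanced" are a design choice here, as standard realizations of
those operations. Channel 1 is always the bit-exact input. Resizing to
detector input sizes (e.g. 640×640, 512×512) is bilinear.

## The synthetic phantom generator

A phantom emulates what a learned edge detector returns for a BUS image with
one lesion:

* an **elliptical boundary band** with a soft Gaussian cross-profile —
  peak intensity 210/255, full width at half maximum 7 px, truncated below
  half maximum so the band has finite support (learned edge detectors emit
  thick soft edges, not hairlines);
* **sparse background clutter** (i.i.d. speckle, density 0.015, intensity
  140/255) standing in for off-lesion tissue edges;
* additive Gaussian pixel noise (SD 6/255), clipped to [0,255].

The gold-standard box is the bounding box of the band, mirroring the
convention that the gold ROI is the smallest rectangle enclosing the tumor
outline. Benchmark images (default frame 256×256) draw semi-axes uniformly
from [25, 65] px and centers uniformly subject to the band fitting in the
frame; the synthetic benign/malignant label is assigned by lesion elongation
(malignant iff max/min semi-axis ≥ 1.3), so both groups are populated for
aggregation testing.

Simulated detectors perturb the gold box: with a per-model failure
probability the box is absent; otherwise the box is scaled about its center
by a per-model bias with independent Gaussian jitter (per-model SD) on all
four corner coordinates, rounded and clamped to the frame. The default
ensemble — jitter 8 px for all four models; biases 1.12 / 0.90 / 1.15 /
1.00; failure probabilities 0.19 / 0.13 / 0.11 / 0.17 — was calibrated so
each simulated detector's operating point (detection rate ~80–90%, mean F1
~0.82–0.87, with over- and under-sizing directions distributed across the
ensemble and no single model dominant on every image) matches the regime
reported for fine-tuned BUS detectors. All randomness descends from one
integer seed with documented stream splitting per image and per model, so
benchmarks are bit-reproducible and order-independent.

**What passing on phantoms does and does not show.** The phantom captures
the contrasts the selection math depends on — a bright closed boundary,
empty lesion interior, weak background — and the failure/bias structure of a
detector ensemble. It does not capture structured clutter (ribs, fascia,
posterior shadowing), multiple lesions, broken or faint boundary segments,
or difficulty-correlated detector failure; results on phantoms therefore
validate the machinery and its qualitative ordering (selection ≥ best single
detector; intersection = precision extreme, union = recall extreme), not
clinical performance.

### Hypothetical illustration ROIs

`make_hypothetical_rois` builds the three illustrative boxes around a gold
box: a concentric sub-box with ~50% of its area and concentric super-boxes
with ~125% / ~175%. Integer side lengths are found by exhaustive search over
feasible widths minimizing the absolute area error (ties: aspect ratio
closest to gold's, then smaller width), which recovers exact factorizations
when they exist — for a 120×80 gold box: 80×60, 120×100, 160×105 — so the
percentage offsets round exactly to 50 / 25 / 75. Super-boxes are
constrained to contain the gold box inside the frame; if no placement gets
within 2% of the area target, the construction raises.

## Problem sizes and runtime

The shipped benchmark configuration is 200 phantoms of 256×256 px with four
simulated detectors (a few seconds end to end); oracle-equivalence tests use
1000 random boxes per operation on 24×24 grids, and the intermode
thresholder is cross-checked against an independent loop-based
reimplementation on 100 random bimodal histograms. These sizes give stable
estimates (binomial SE on a detection rate at n=200 is ~2–3 points) while
keeping the full suite under a minute.

## Known limitations

* "Union" and "intersection" are rectangular (enclosing box / common box);
  metrics on the non-rectangular pixel union would differ slightly.
* Whether printed `S` values in the method's original presentation were
  computed on the normalized or raw map cannot be confirmed from the
  presentation itself; this implementation normalizes first, as stated, and
  the selection rule is invariant to that global scale anyway.
* Candidate confidence scores are ignored by design; the selection rule is
  purely geometric/photometric.
* The intermode thresholder assumes an approximately bimodal intensity
  histogram; heavily textured edge maps may trigger the histogram-mean
  fallback (logged and counted).
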