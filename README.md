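# segfuse

Consensus fusion of multiple 2D binary segmentations of a single object.

## The problem

Delineating one object in an image — a tumor region in a histological
slide, a cell in a microscopy section, an organ in an MR slice — is
subjective. Different annotators draw different boundaries for the same
object (inter-rater variability), and the same annotator draws different
boundaries at different times (intra-rater variability). When N ≥ 2 binary
masks of the same object are available, a *fusion* algorithm combines them
into a single consensus contour: a closed, 1-pixel-wide loop delineating
the agreed boundary. `segfuse` implements eight such algorithms behind one
API and a small CLI, plus the evaluation and simulation machinery needed to
compare them.

## Algorithms

Write the filled region of rater *j* as *D<sub>j</sub>*.

| name | consensus region / contour |
|---|---|
| `largest` | boundary of ⋃<sub>j</sub> *D<sub>j</sub>* (union) |
| `smallest` | boundary of ⋂<sub>j</sub> *D<sub>j</sub>* (common area) |
| `avg_smallest_largest` | 1-pixel midline of the band between Smallest and Largest |
| `avg_target_largest/smallest/input` | walk a target contour; replace each pixel by the consensus (midpoint / collinear-extreme midpoint / centroid) of its group of nearest pixels on the other contours; close the cloud |
| `middle` | drop the smallest- and largest-area mask ⌊(N−1)/2⌋ times; odd N keeps the survivor, even N fuses the last two by a configurable tiebreak |
| `staple` | EM estimate of the hidden truth, weighting each rater by estimated sensitivity *p<sub>j</sub>* and specificity *q<sub>j</sub>* |

The averaging algorithms emit sparse pixel clouds, which are closed by one
of four methods: straight chords between polar-ordered points (`linear`),
shape-preserving monotone cubic interpolation of r(θ) (`pchip`, default),
or a morphological active contour (`chan_vese`, `geodesic`).

Agreement is scored with the Jaccard index
JI(A, B) = |A ∩ B| / |A ∪ B| on filled regions, and
`rank_algorithms` / `segfuse rank` produce a per-case JI table with row
means and a final ranking.

## Worked example

`examples/staple_rater_accuracy.py` simulates five raters who corrupt a
known disk per-pixel with sensitivity 0.90 and specificity 0.98, then lets
STAPLE recover both the consensus and each rater's accuracy from the masks
alone:

```
true sensitivity p = 0.9, true specificity q = 0.98

rater 1: estimated p = 0.9143, q = 0.9771
rater 2: estimated p = 0.8957, q = 0.9804
rater 3: estimated p = 0.9021, q = 0.9787
rater 4: estimated p = 0.9053, q = 0.9790
rater 5: estimated p = 0.9028, q = 0.9815

EM iterations: 1, converged: True
consensus JI vs hidden truth: 0.9979
mean single-rater JI:         0.9888
```

The estimates sit within about 0.01 of the simulation truth, and the fused
contour (JI 0.998) is closer to the hidden disk than any individual rater.
The other examples fuse boundary-noise annotators
(`fuse_synthetic_annotators.py`), close sparse contours
(`closing_sparse_contours.py`), and rank algorithms across cases
(`rank_algorithms_on_synthetic_cases.py`).

## Command line

```sh
segfuse simulate --shape disk --radius 20 --raters 5 --amplitude 2 --seed 7 --outdir fixtures/
segfuse fuse --algorithm middle --middle-tiebreak average fixtures/rater_*.png -o consensus.png
segfuse jaccard consensus.png fixtures/truth.png
segfuse rank --cases cases.txt --algorithms largest,smallest,middle-average,staple -o ranking.csv
```

Every output is accompanied by a `.manifest.json` recording the resolved
configuration, inputs, version and warnings. An INI config file
(`--config`) can set any option and register plugin algorithms; flags
override the file.

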