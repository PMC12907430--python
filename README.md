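# imlen — intramural length estimation for anomalous coronary arteries

Anomalous aortic origin of a coronary artery (AAOCA) is a congenital
anomaly associated with myocardial ischemia and sudden cardiac death in
the young. A key risk and surgical-planning parameter is the **intramural
(IM) length**: the distance over which the anomalous coronary travels
embedded within the aortic wall before exiting into the mediastinum.
Radiologic estimates of IM length from coronary CT angiography show
variable agreement with the surgical reference measurement.

`imlen` implements a semi-automatic, geometry-based estimator for users
who already have (from any segmentation/centerline tool):

* a triangulated surface of the aortic root / ascending aorta (STL or
  PLY, coordinates in mm, edge length ≈ 0.4 mm), and
* an ordered centerline of the anomalous coronary (CSV with columns
  `x,y,z` in mm, proximal → distal, first point proximal to the ostium).

## Method

For each centerline point the signed distance to the closest surface
**vertex** is computed (negative inside the aorta). Arc length `s` is
re-origined so `s = 0` at the **ostium**, the interpolated
inside-to-outside zero crossing of the signed distance. The distance
curve `d(s)` is resampled to a uniform grid (0.001 mm) and
differentiated; a continuous two-piece linear model is fit to the
derivative over the first 20 mm,

```
y(x) = a + b·x,              x < k
y(x) = a + b·k + c·(x − k),  x ≥ k        (k ≥ 0)
```

by profile least squares: for each candidate `k` the model is linear in
`(a, b, c)`, so an ordinary least-squares solve is run on a coarse `k`
grid followed by golden-section refinement — a deterministic, globally
scanned search. While the vessel is intramural it hugs the wall, so the
derivative is small; when it exits and curves away the derivative rises.
The transition point `k` is the IM length estimate.

The package also ships a synthetic **phantom** generator (capped-cylinder
aorta + planar coronary centerline with analytically known ostium and
exit arc lengths) for end-to-end validation, and a 58-patient surgical
cohort table with **agreement statistics** (RMSE against surgery, mean
error ± SD, exact/approximate Wilcoxon signed-rank comparison of the
computational and radiologic methods).

## Worked example

Generate a phantom with a designed IM length of 8 mm and estimate it:

```sh
$ imlen phantom --im-length 8 --out demo/phantom
$ imlen -v estimate --mesh demo/phantom/mesh.stl \
        --centerline demo/phantom/centerline.csv --out demo/est
INFO imlen: IM length estimate: 8.08 mm
```

`demo/est/result.json` then contains

```json
{
  "im_length_mm": 8.07674042112333,
  "a": 0.03426117262384602,
  "b": 0.002496066810503312,
  "c": 0.05028728979554405,
  "k": 8.07674042112333,
  "window_mm": 20.0,
  "spacing_mm": 0.001,
  "sse": 16.28719753719224,
  "ostium_offset_mm": 2.5999999999999996,
  "warnings": []
}
```

The ostium was located 2.6 mm along the raw centerline (the phantom's
exact design value, recorded in `demo/phantom/truth.json`), and the
fitted transition `k = 8.08 mm` recovers the designed 8 mm intramural
length to within 0.08 mm — well inside the ~0.4 mm geometric resolution
of the inputs. The small `b` and the rising `c` are the intramural and
departing distance slopes of the derivative fit.

Cohort statistics on the packaged table:

```sh
$ imlen cohort-stats --out demo/stats
Cohort: 58 patients (49 R-AAOCA, 9 L-AAOCA)

overall (n = 58)
  RMSE vs surgical:  computational 3.4 mm, radiologic 3.2 mm
  ...
L-AAOCA (n = 9)
  RMSE vs surgical:  computational 3.6 mm, radiologic 4.7 mm
  Wilcoxon comp vs rad: W = 8.0, p = 0.0977 (exact, n = 9)
R-AAOCA (n = 49)
  RMSE vs surgical:  computational 3.4 mm, radiologic 2.8 mm
  Wilcoxon comp vs rad: W = 594.5, p = 0.862 (approx, n = 49)
```

Other subcommands: `imlen profile-dump` writes the distance/derivative
profile as CSV; `imlen estimate --origin first-point` keeps the arc
origin at the first centerline point instead of the ostium. See
`imlen --help`.

## Library use

```python
from imlen import read_mesh, read_centerline, estimate_im_length

mesh = read_mesh("aorta.stl")
centerline = read_centerline("coronary.csv")
result = estimate_im_length(mesh, centerline)
print(result.im_length_mm)
```

Mesh and centerline must share one Cartesian frame in millimetres; no
unit or orientation metadata is read from the files.
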