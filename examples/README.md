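# Example input files

Minimal fixtures showing the three delimited-text formats the package reads:

* `design.csv` — one row per camera site: its array and 0/1 activity flags
  per survey occasion (`active_1..active_J`; 0 means the camera was not
  operating, and those cells become *missing*, not zero).
* `detections.csv` — long format, one row per (species, site, occasion) with
  `detected` in {0,1}. Active cells absent from the file default to 0.
* `covariates.csv` — one row per site; columns whose values are all 0/1 are
  treated as binary trail attributes, the rest as continuous covariates to be
  standardized (mean 0, sd 0.5) before fitting.

Load with:

```python
from interocc import read_detection_data, read_covariates, standardize_covariates
data = read_detection_data("detections.csv", "design.csv")
covs = standardize_covariates(read_covariates("covariates.csv"))
```
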