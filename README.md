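# aviary-transect

A toolkit for **whole-flock welfare assessment of loose-housed laying hens**
in multitiered aviary systems, built for welfare scientists, farm advisors
and auditors who need quantitative, repeatable prevalence estimates from
commercial houses of thousands of birds.

An aviary house consists of 1–3 rows of tiered structures separated by
littered aisles. A *transect* is one aisle-length walking path; the assessed
strip is the aisle plus half of each adjacent structure row, over all
vertical levels. Walking every transect screens the entire flock for 12
binary welfare indicators (feather loss on head/back/breast/tail, wounds on
head/back/tail/feet, dirty plumage, enlarged crop, sick, dead). Because each
transect spans the full house length, the flock of size $N$ in a house of
width $W$ is apportioned to transect $i$ of width $w_i$ as

$$\hat n_i = \operatorname{round}\!\left(N \, w_i / W\right),$$

under the assumption of homogeneous bird distribution, and the prevalence of
indicator $j$ in transect $i$ is $\hat p_{ij} = 100\, k_{ij} / \hat n_i$ per
cent. Wall transects absorb half of one structure row
($w = \text{aisle} + s/2$), central transects half of each flanking row
($w = \text{aisle} + s$), with the structure width derived as
$s = (W - \sum \text{aisles})/(\#\text{rows})$.

The package also implements:

* two graded fixed-sample schemes (0/1/2 severity scores on 50 random birds,
  one of them recording each bird's transect and vertical level), with
  prevalence $p = 100k/n$ and $\mathrm{SE} = 100\sqrt{\hat p(1-\hat p)/(n-1)}$;
* the comparison statistics used in the field: fixed-factor **binomial GLMs**
  (logit link, IRLS) with likelihood-ratio tests of flock, observer,
  transect-type and vertical-level effects, **Tukey-adjusted** pairwise
  comparisons of least-squares means with a compact letter display, and
  tie-aware **Spearman correlations** between methods;
* a **flock simulator** (known true prevalences, wall-placement bias,
  observer sensitivity and false positives) for estimator-recovery checks
  and paired power comparisons of whole-flock transect counting versus
  fixed-n bird sampling;
* a CLI (`aviary-transect validate | assess | compare | correlate |
  simulate | power`) over CSV/YAML inputs.

## Worked example

```python
from aviary_transect import (HouseGeometry, estimate_birds_per_transect,
                             derive_structure_width, animal_density)

house = HouseGeometry(
    house_id="flock1", house_width=14.0,
    aisle_widths=(1.75, 1.75, 1.75, 1.75),   # left wall -> right wall, m
    n_structures=3, flock_size=7500, usable_area=1850.0,
)
print(f"structure width: {derive_structure_width(house):.3f} m")
for t in estimate_birds_per_transect(house):
    print(f"T{t.index} ({t.kind:7s}) width {t.width:.3f} m -> {t.estimated_birds} birds")
print(f"stocking density: {animal_density(7500, 1850.0)} birds/m2")
```

prints

```
structure width: 2.333 m
T1 (wall   ) width 2.917 m -> 1563 birds
T2 (central) width 4.083 m -> 2188 birds
T3 (central) width 4.083 m -> 2188 birds
T4 (wall   ) width 2.917 m -> 1563 birds
stocking density: 4.05 birds/m2
```

i.e. a 14 m house with four 1.75 m aisles has 2.33 m structure rows; its
wall transects are credited 1,563 of the 7,500 hens and its central
transects 2,188 (the rounding is half-away-from-zero: 1562.5 → 1563).
An observer who counted 13 hens with severe head feather loss on transect 1
would record

```python
from aviary_transect import TransectCountRecord, transect_prevalence
layout = estimate_birds_per_transect(house)
rec = TransectCountRecord("flock1", "obs1", 1, "wall", {"fl_head": 13, "dirty": 2})
for est in transect_prevalence(rec, layout):
    print(f"{est.indicator}: {est.p:.3f}% of {est.n_basis} birds")
# fl_head: 0.832% of 1563 birds
# dirty: 0.128% of 1563 birds
```

a head-feather-loss prevalence of 0.83 % — the kind of sub-percent signal a
50-bird sample would usually miss entirely.

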