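# sizedist

Gamma-distribution analysis of Coulter-counter cell-size distributions in
budding yeast.

## What this package does

In a proliferating population of *Saccharomyces cerevisiae*, single-cell
volumes (measured in femtoliters with a Coulter-type channelyzer) are not
normally distributed: they are positively skewed, and among the common
right-skewed candidates — lognormal, Weibull, gamma — they are best
described by a **gamma distribution** with shape α and rate β (mean α/β).
This holds for haploid and diploid wild-type cells across carbon sources;
only the parameters move (e.g. α ≈ 6.3–7.9 in 2% dextrose, dropping to
α ≈ 4.1–4.9 under carbon restriction, tracking the smaller cell size).

That regularity turns goodness of fit into a screening metric: mutants
whose size distributions *cannot* be fitted by a gamma — negatively
skewed, multimodal, or otherwise deranged — point at genes required to
maintain the stereotypical size pattern, independently of whether the
cells are merely bigger or smaller than wild type.

`sizedist` implements that analysis as a reusable pipeline, for
biologists and statisticians working with binned size-frequency data:

1. **histogram_io** — read/validate wide or long size-frequency tables
   (bin centers in fL + per-strain frequencies), resample n cells per
   strain by seeded multinomial draws (default n = 1000), weighted
   medians, screen-table output.
2. **distfit** — maximum-likelihood fits of gamma (Newton iteration on
   the profile score ln α − ψ(α) = ln x̄ − mean(ln x), Minka
   initialization),
   lognormal (closed form), Weibull (profile Newton), and the
   three-parameter generalized gamma (nested 1-D power search); AIC/BIC
   model selection.
3. **gof** — Shapiro-Wilk normality screening (raw and log scale), the
   EDF statistics A² (Anderson-Darling), D (Kolmogorov-Smirnov) and W²
   (Cramér-von Mises), a parametric-bootstrap-calibrated composite gamma
   test, and a fixed-null AD test with the classical asymptotic p-value.
4. **screen** — the cohort pipeline: per-strain resampling → testing →
   fitting → ranking by departure from a fixed wild-type reference null
   (the average of wild-type gamma fits, shape 3.8277, rate 0.078949 for
   the haploid deletion-collection background), replicate collapsing,
   and `lge`/`whi` size-class annotation (top/bottom 5% of medians).
5. **groupstats** — Wilcoxon rank-sum (exact and normal approximation),
   Kruskal-Wallis, and Nemenyi post-hoc comparisons.
6. **synthetic** — Coulter-style synthetic cohorts with known ground
   truth (wild-type gamma, size-shifted, left-skewed, multimodal and
   debris-spiked classes) so every stage is testable without downloads.

## Worked example

```python
import sizedist as sd

# a wild-type-like histogram (20,000 cells binned on a 5-250 fL grid),
# resampled to n = 1000 cells and fitted
h = sd.simulate_wildtype(shape=6.624628, rate=0.060432, cells=20_000, seed=1)
s = sd.resample_cells(h, n=1000, seed=2)
fit = sd.fit_gamma(s)
sel = sd.model_select(s, families=("gamma", "lognormal", "weibull"))
res = sd.ad_test_fitted_gamma(s, B=999, seed=3)
```

This prints (via the obvious `print` calls):

```
gamma fit: shape=6.652  rate=0.0607  mean=109.6 fL
   family     ad     ks    cvm        bic
    gamma 0.4965 0.0264 0.0892 10245.9406
lognormal 2.5905 0.0484 0.4283 10271.4861
  weibull 3.2117 0.0430 0.4185 10291.5981
composite gamma AD: A2=0.497  p=0.229
normality (Shapiro-Wilk): p=5.42e-13
```

Reading: the refitted shape/rate recover the generating parameters within
resampling error and the fitted mean α̂/β̂ equals the sample mean (109.6
fL) exactly; the gamma has the lowest A², D and W² of the three families
and the lowest BIC; the bootstrap-calibrated composite test does not
reject the gamma (p = 0.229); normality is decisively rejected.

The same flow from the command line, with a synthetic 100-strain cohort
carrying 10 multimodal spike-ins:

```bash
sizedist simulate --out cohort.tsv --labels labels.tsv --seed 7
sizedist screen --input cohort.tsv --shape 3.8277 --rate 0.078949 \
    --bootstrap 199 --seed 42 --out screen.tsv
```

The ranked screen table puts all ten injected mutants in the worst ten
ranks, far above the null strains (fixed-null A² ≈ 1000 vs ≈ 1-7):

```
           strain  gamma_shape  fixed_null_ad  fixed_null_p  median_fl size_class  deviant_rank
    MULTIMODAL000       4.0795      1165.6942        0.0000    96.2745        lge             1
    MULTIMODAL005       4.0259      1151.5854        0.0000    95.3137     normal             2
    ...
WILDTYPE_GAMMA066       4.3647         6.9239        0.0004    44.3922     normal            11
```

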