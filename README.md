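# qpcrkit

Quality assessment, relative quantification and significance testing of
real-time quantitative PCR (qPCR) data, working from raw cycle-threshold
(CT) values in CSV tables.

Most small-scale gene-expression experiments report qPCR results as the
expression of a target gene normalized by a reference (housekeeping)
gene and relative to a calibrator condition. `qpcrkit` implements that
workflow for bench scientists and analysts in three steps:

1. **Assess** (`qpcrkit.assess`) — from a serial-dilution experiment,
   fit per-gene standard curves CT = b + m·log₁₀(amount) and check the
   comparative method's assumption: the amplification efficiency
   E = 10^(−1/m) should be close to 2, and the trend of
   ΔCT = CT(target) − CT(reference) against log₁₀(amount) should have a
   slope near 0.
2. **Analyze** (`qpcrkit.quantify`) — relative expression by either
   * the **comparative ΔΔCT model**: ΔΔCT = ΔCT(group) − ΔCT(calibrator),
     relative expression 2^(−ΔΔCT), SDs combined as s = √(s₁² + s₂²); or
   * the **relative standard-curve model**: each CT is inverted through
     its gene's curve, amount = 10^((CT − b)/m), and expression is a
     ratio of amounts with errors combined on the CV scale,
     cv = √(cv₁² + cv₂²), s = cv·X̄.
3. **Test** (`qpcrkit.sigtest`) — the ΔΔCT is exactly the difference in
   mean per-sample ΔCT between a condition and the control group, so it
   can be tested with a two-sample t-test, a Wilcoxon rank-sum test
   (with Hodges–Lehmann estimate and rank-sum-inverted interval), or a
   linear model of ΔCT on group indicators (any number of conditions).

`qpcrkit.synthetic` generates CT datasets with known ground truth, and
`qpcrkit.datasets` ships the classic human brain/kidney c-myc/GAPDH
experiments used throughout the documentation.

## Worked example

```python
>>> from qpcrkit import standard_curve, assess_efficiency, delta_delta_ct, relative_curve
>>> from qpcrkit.datasets import ct1, ct3

>>> dilution = ct3()                    # 7 dilutions x 3 replicates, 2 genes
>>> for c in standard_curve(dilution):
...     print(f"{c.gene}: slope {c.slope:.3f}, R2 {c.r_squared:.3f}, E {c.efficiency:.2f}")
c_myc: slope -3.387, R2 0.998, E 1.97
GAPDH: slope -3.434, R2 0.999, E 1.96

>>> assess_efficiency(dilution, "GAPDH").trends[0].slope   # dCT trend, ~0 is good
0.0471209986883112

>>> expression = ct1()                  # 6 brain + 6 kidney replicates
>>> for r in delta_delta_ct(expression, "GAPDH", reference_group="brain"):
...     print(f"{r.group}: dCT {r.normalized:.2f}+/-{r.error:.2f}, "
...           f"fold {r.fold_change:.1f} ({r.lower:.1f}-{r.upper:.1f})")
brain: dCT 6.86+/-0.17, fold 1.0 (0.9-1.1)
kidney: dCT 4.37+/-0.10, fold 5.6 (5.3-6.0)
```

Both slopes are close to the perfect-doubling value −3.32 (E ≈ 2) and
the ΔCT trend is nearly flat, so the comparative model is justified:
c-myc is about 5.6-fold higher in kidney than in brain relative to
GAPDH, with a ±1 SD interval of 5.3–6.0. The standard-curve model
agrees without assuming perfect efficiency:

```python
>>> curves = {c.gene: (c.slope, c.intercept) for c in standard_curve(dilution)}
>>> for r in relative_curve(expression, "GAPDH", "brain", curves):
...     print(f"{r.group}: normalized {r.normalized:.2f}, "
...           f"relative {r.fold_change:.1f} +/- {r.error:.2f}")
brain: normalized 0.07, relative 1.0 +/- 0.12
kidney: normalized 0.40, relative 5.5 +/- 0.35
```

The same steps are available from the shell:

```sh
qpcrkit assess  --input ct3.csv --amount amount --method standard_curve --output curves.csv
qpcrkit analyze --input ct1.csv --group-var group --reference-gene GAPDH \
                --reference-group brain --output result.csv
qpcrkit test    --input ct4.csv --group-var group --reference-gene ref \
                --reference-group control --method wilcoxon --output test.csv
```

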