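# cryoslice

Optimal slice-thickness modelling for fluorescent cell and microsphere
detection in block-face cryo-imaging.

Slice-and-image (cryo-imaging) systems alternately cut a frozen specimen
and photograph the freshly exposed block-face. Choosing the section
thickness `X` is a real trade-off: thin slices give exact counts but days
of scan time; thick slices are fast but silently drop the dimmest cells.
`cryoslice` implements a quantitative detection model for this choice,
aimed at cryo-imaging operators and anyone doing absolute quantification
of fluorescent cells or microspheres from block-face stacks.

## The model

A fluorophore at depth `x` (µm) below the block-face is seen through the
overlying tissue with intensity

    I(x) = I_fluo · exp(−µ_T · x)

where `I_fluo` is the unattenuated cell intensity (gray levels) and `µ_T`
the effective tissue attenuation coefficient (cm⁻¹), and it is detected
when `I(x) ≥ T` for a detector threshold `T`. Everything follows from
this:

* **Optimal slice thickness** — the largest loss-free section:
  `X_optimal = −ln(T / I_fluo) / µ_T`.
* **Optimal cell intensity** at a fixed thickness: `I_optimal = T·exp(µ_T X)`.
* **Sensitivity law** — under uniform cell placement,
  `Sens(X) = 1` for `X ≤ X_optimal` and `X_optimal / X` beyond
  (a −45° line on log-log axes).
* **Under-sampling correction** — `Count(X_optimal) = Count(X) / Sens(X)`,
  letting deliberately thick scans be corrected afterwards.
* Generalisations to mixed cell brightnesses (discrete intensity groups)
  and non-uniform depth distributions (quadrature over a density `p(x)`).

The package also contains the machinery to *test* these relationships end
to end on synthetic data: virtual tissue volumes (compliant, perturbed,
and overlapping placements), a digital sectioning simulator, a synthetic
block-face stack renderer, and the slice-skipping calibration pipeline
(threshold + 3-D connected-component counting) that one would run on a
thin-slice calibration scan.

## Worked example

The dimmer of the two characterised microsphere populations has
`I_fluo ≈ 87`, `µ_T ≈ 372 cm⁻¹`, `T = 10`. Planning a scan at 100 µm:

```text
$ cryoslice optimal -I 87 --mu 372 -T 10 -X 100
Optimal slice thickness X_optimal: 58.15 um
At X = 100 um:
  minimum loss-free intensity I_optimal: 412.64 gray
  expected sensitivity: 58.15%
  count correction factor 1/Sens: 1.7196
```

Reading: every microsphere is counted when sectioning at 58 µm or less;
at 100 µm only ~58% are seen, so an observed count should be multiplied
by 1.72 — or the spheres would need to be ~413 gray to survive 100 µm
sections. The same numbers fall out of simulation rather than the closed
form:

```text
$ cryoslice sweep --mode thickness -I 30 --mu 314 -T 10 -S 150 \
      --x-min 5 --x-max 150 --x-step 1 --out demo_sweep
$ python -c "import json; print(json.load(open('demo_sweep/summary.json'))['breakpoint_um'])"
35.0
```

i.e. a simulated volume of 30-gray cells keeps 100% sensitivity up to
35 µm sections, matching `X_optimal = 34.99` µm from the formula. Other
subcommands: `correct` (apply the correction factor), `render` (write a
synthetic block-face TIFF stack with ground truth), and `stack` (run the
slice-skipping calibration on a thin-slice stack, estimating `µ_T` and
`I_fluo` and recommending a thickness).

In the library, the same example is three calls:

```python
from cryoslice import OpticalParams, optimal_thickness, sensitivity_piecewise

params = OpticalParams(cell_intensity=87, attenuation=372, threshold=10)
x_opt = optimal_thickness(params)        # 58.15 um
sens = sensitivity_piecewise(100, x_opt) # 0.5815
```

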