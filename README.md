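# eqdx

Equieffective-dose calculations for radiopharmaceutical therapy (RPT)
dosimetry: the Lea–Catcheside dose-protraction factor *G*, relative
effectiveness RE, biologically effective dose BED, and EQDX, computed by
three interchangeable engines from sparse region-level time–dose-rate
measurements.

## Who this is for

Medical physicists and dosimetry researchers converting post-injection
absorbed dose-rate measurements (e.g. 3–4 SPECT/CT scans after a
[¹⁷⁷Lu]Lu-DOTATATE administration) into radiobiologically motivated dose
metrics. In RPT the irradiation is continuous and decaying, so sublethal
DNA-damage repair happens *during* delivery: the absorbed dose D alone
underestimates how schedule-dependent the biological effect is, and the
conversion to BED/EQDX must account for the dose-rate history.

## The model

Under the linear-quadratic model with a single-phase exponential repair
kernel ψ(t) = e^(−μt), μ = ln2/T_rep:

    G  = [ ∫₀^∞ dt Ḋ(t) ∫₀^t dt′ Ḋ(t′) e^(−μ(t−t′)) ] / (D²/2) ∈ (0, 1]
    RE = 1 + G·D/(α/β),   BED = D·RE,   EQDX = BED / (1 + X/(α/β))

Engines for G (all units h, Gy, Gy/h, 1/h):

* **analytic** — for a biexponential dose rate Ḋ(t) = r₀(e^(−λ_e1 t) −
  e^(−λ_e2 t)) the double integral has the closed form
  G = λ_e1 λ_e2 (λ_e1+λ_e2+μ) / [(λ_e1+λ_e2)(λ_e1+μ)(λ_e2+μ)],
  with D = r₀(1/λ_e1 − 1/λ_e2).
* **hybrid** — for a piecewise-linear dose rate up to an anchor time t_x
  with an exponential tail (rate λ_e estimated from the last 2–3 scans),
  the trapezoid recursion supplies N = ∫∫ on [0, t_x] and
  M = ∫₀^{t_x} Ḋ e^(μt′) dt′, and the tail closes analytically:
  R = N + M·Ḋ(t_x)e^(−μt_x)/(λ_e+μ) + Ḋ²(t_x)/(2λ_e(λ_e+μ)), G = 2R/D².
  No stopping time, no overflow.
* **numerical** — the classic dynamic-programming trapezoid recursion run
  to a finite stopping time. Faithful to the published algorithm,
  including its weakness: the interim weight e^(μt) overflows float64 once
  μ·t ≳ 709 (for T_rep = 0.5 h it passes 10¹⁰⁰ within a week), so a guard
  aborts cleanly with a flagged partial result.

A brute-force nested-quadrature oracle of the defining integral backs the
validation suite.

## Worked example

`python examples/01_biexponential_eqd2.py` fits four noiseless samples at
1, 4, 24, 72 h drawn from a known curve and prints:

```
fitted: r0=2.000000 Gy/h, lambda_e1=0.020000 /h, lambda_e2=0.500000 /h
D    = 96.000 Gy   (total absorbed dose)
G    = 0.04072     (dose-protraction factor, repair T_rep=1.5 h)
RE   = 1.39090     (relative effectiveness)
BED  = 133.527 Gy  (biologically effective dose)
EQD2 = 111.272 Gy  (equieffective dose in 2 Gy fractions)
```

The fit recovers the generating parameters exactly; G ≈ 0.041 means only
~4% of sublesion pairs survive repair at this dose rate, inflating the
96 Gy absorbed dose to a 111 Gy 2-Gy-fraction equivalent at α/β = 10 Gy.
The other examples profile numerical-engine convergence against stopping
time (`03`), reproduce the omit-last-scan comparison (`04`: analytic
−0.00%, hybrid +0.05%, numerical −20.3% for a slow-clearance curve
truncated at 250 h), and benchmark the engines (`05`).

There is also a thin CLI (`eqdx fit|gfactor|eqd2|simulate|converge|omit-study`)
over CSV sample tables with columns `region_id,time_h,dose_rate_gy_per_h`:

```
eqdx simulate --kind biexponential --out sim.csv
eqdx eqd2 sim.csv --engine hybrid --alpha-beta 10 --trep 1.5 --out results.csv
```

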