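# cyclicomp

Cyclic competition ("rock–paper–scissors"-type) ecosystems with
**species-dependent intraspecific competition**, studied with three
coupled solver layers over a single model definition:

* **mean-field rate equations** — exact fixed-point enumeration,
  analytic Jacobians, heteroclinic-cycle attractiveness, and
  one-parameter bifurcation scans;
* **stochastic lattice Monte Carlo** — individuals on a periodic
  square lattice with invasion, reproduction, intraspecific killing and
  mobility, with integer-exact event accounting;
* **spectral reaction–diffusion PDEs** — integrating-factor RK4 on the
  periodic unit square.

## The science

In the classic cyclic games (three-species RPS, the five-species single
cycle, and rock–paper–scissors–lizard–Spock) all species are on equal
footing, and that symmetry restricts which coexistence states can occur:
three or one species for RPS, five, three or one for RPSLS.  Giving each
species its own intraspecific competition rate `p_i` breaks the symmetry
and opens up *every* coexistence cardinality.  The mean-field equations
for densities `a_i` are

    da_i/dt = a_i [ mu (1 - rho) - sigma * sum_{j in predators(i)} a_j - (p_i / 2) a_i ]

with `rho = sum_i a_i`, reproduction rate `mu`, invasion rate `sigma`
(both fixed to 1 by convention) and intraspecific rate `p_i`.  On a
fixed support the equilibrium conditions are linear, so every fixed
point of every support subset is found exactly; stability comes from the
analytic Jacobian, and the attractiveness of the boundary heteroclinic
cycle (the "extinction by fluctuation" regime) from the product of
saddle eigenvalue ratios.  For the three-species game the closed forms
are exposed: single-species points `2/(2+p_i)`, pair points such as
`w1 (p_b, p_a - 2, 0)` with `w1 = 2/(p_a p_b + 2(p_a+p_b) - 4)`, and the
interior point `(a*, b*, c*)` with denominator
`Gamma = p_a p_b p_c + 8 + 2[p_a p_b + p_b p_c + p_c p_a - 2(p_a+p_b+p_c) + 12]`.

The lattice model realizes the same rates microscopically,

    XY -> X0 (sigma),   X0 -> XX (mu),   XX -> X0 (p),   XZ -> ZX (eps = 2MN),

with mobility `M`, and the PDE layer adds `M * laplacian` to the
reaction terms.  Scanning one `p_i` sweeps the system through extinction
/ full coexistence / partial coexistence phases whose boundaries the
three layers agree on.

## Worked example

Fixed points of the RPS game at `p = (2.5, 1, 0.5)`:

```python
from cyclicomp import make_model, find_fixed_points, integrate

model = make_model("rps", p=(2.5, 1.0, 0.5))
for fp in find_fixed_points(model):
    print(sorted(fp.support), fp.kind, fp.densities.round(5), fp.stability)
```

prints

```
[] empty [0. 0. 0.] unstable
[0] single [0.44444 0.      0.     ] saddle
[1] single [0.      0.66667 0.     ] saddle
[2] single [0.  0.  0.8] saddle
[0, 1] pair [0.36364 0.18182 0.     ] saddle
[0, 1, 2] full [0.19417 0.3301  0.1165 ] stable
```

The single-species states are saddles, the two-species point exists but
is unstable, and the interior point (densities 0.194, 0.330, 0.117) is
the stable attractor — all three species coexist.  Integrating
`integrate(model, (0.3, 0.3, 0.3), 2000)` converges to exactly that
point.  Raising `p_a` above 4 hands stability to the pair point
(two-species coexistence, a state the symmetric game cannot produce);
below 1.5 the boundary heteroclinic cycle becomes attracting and
fluctuations drive all but one species extinct.

The same sweep from the command line:

```sh
cyclicomp ode-scan --model rps --fix pa=1,pb=1,pc=0.5 --vary pa \
    --range 0.5:6:0.05 --out scan.csv
# {"thresholds": [1.5004, 4.0], "phase_changes": [[0, 3], [3, 2]]}
```

Lattice and PDE runs, and the named parameter presets:

```sh
cyclicomp lattice-run --model rps --p 5.2,1,0.5 --L 100 --M 1e-3 \
    --gens 400 --seed 3 --snap-at 400 --out run/
cyclicomp pde-run --model rps --p 5.2,1,0.5 --M 1e-3 --grid 64 \
    --tmax 200 --seed 1 --out pde/
cyclicomp presets    # rps_pa2.5, erps_pc5.65, rpsls_pe9.3, ...
```

## Layout

| module | contents |
| --- | --- |
| `cyclicomp.models` | `InteractionModel`, presets (rps / erps / rpsls), `RunConfig` |
| `cyclicomp.meanfield` | ODE right-hand side, integration, fixed points, stability, scans |
| `cyclicomp.lattice` | numba Monte Carlo kernel, event logs, survival probability |
| `cyclicomp.pde` | spectral reaction–diffusion solver |
| `cyclicomp.diagnostics` | balance indicators H/S/P, MSD exponent, coexistence classes |
| `cyclicomp.config`, `cyclicomp.render`, `cyclicomp.cli` | presets, config files, PNG snapshots, CLI |

See `docs/methods.md` for modeling assumptions, numerical choices and
known limitations.
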