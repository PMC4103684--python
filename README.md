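# twoscale

Simulation and analysis of a macroscopic **two-scale patterning model** of
mid-hindbrain boundary (MHB) formation: cell-bound Hill-type gene-regulation
ODEs for the six isthmic-organizer genes (*Otx2*, *Gbx2*, *Fgf8*, *Wnt1*,
*En*, *Pax*) coupled to reaction–diffusion PDEs for the secreted Fgf8 and
Wnt1 morphogens, plus a post-transcriptional miRNA extension that sharpens
the *Wnt1* expression boundary.

The package is for modellers of morphogen-based tissue patterning who want
to (i) simulate stiff reaction–diffusion gene-network models with
developing expression-domain discontinuities, (ii) enumerate and classify
the stable steady-state expression patterns, (iii) test under which spatial
miRNA production profiles a miRNA–mRNA titration mechanism sharpens a
target's expression boundary, (iv) fit the sigmoidal production profile to
1-D grayscale intensity traces from in-situ images, and (v) post-process
miRNA target predictions by consensus voting and developmental ON/OFF
logic filtering.

## Model

On the interval `x ∈ [-L, L]` (anterior left, MHB at `x* = 0`):

```
∂u_i/∂t = α_i B_i(u, v) - β_i u_i                     i = 1..6   (cell-bound)
∂v_j/∂t = α_j u_src(j) - β_j v_j + d_j ∂²v_j/∂x²      j = 1, 2   (morphogens)
v_j(±L, t) = 0
```

The `B_i ∈ [0,1]` are HillCube continuizations of the Boolean regulatory
logic (Hill inputs `x^n/(k^n + x^n)`, AND = product, OR =
inclusion–exclusion); defaults `n = 2`, `k = 0.1`, all rates 1,
`d = 0.001`. The miRNA extension adds free miRNA `m`, complex `c` and a
binding sink on the *Wnt1* mRNA `u₄`:

```
∂u₄/∂t = α₄ B₄ - β₄ u₄ - κ m u₄
∂m/∂t  = α_m(x) - β_m m - κ m u₄ + λ ξ c + d_m ∂²m/∂x²
∂c/∂t  = κ m u₄ - λ c
```

with the production profile `α_m(s) = p1 (tanh((l - s)/p2) + p4)` in the
normalised MHR coordinate `s` and regulation scenarios i (transient
binding, full recycling), ii (complex co-degradation) and iii (ii plus
miRNA transport). See `docs/methods.md` for the full model description,
parameter table and numerical scheme.

## Worked example

Compute the narrow ("steady state 2") expression pattern and scan the
miRNA production-profile offset `l` for boundary sharpening in scenario ii:

```python
from twoscale import (Grid, build_mhb_model, find_steady_state,
                      make_initial_conditions, overlap_scan)
from twoscale.mhb import MHBParams
from twoscale.mirna import MiRNAParams

grid = Grid(L=2.0, N=250)
model = build_mhb_model()
ss2 = find_steady_state(
    model, grid,
    make_initial_conditions("unimodal", 0.0, grid, widths=0.18, amplitudes=0.7),
    t_max=160.0,
)
print(f"converged={ss2.converged} at t={ss2.t_reached}")
scan = overlap_scan("ii", [0.2, 0.4, 0.5, 0.7], MHBParams(), MiRNAParams(),
                    grid, ss2.profile, t_final=50.0)
print(scan[["l", "sharpened", "mhb_change", "flank_reduction", "score"]]
      .round(3).to_string(index=False))
```

prints

```
converged=True at t=77.0
  l  sharpened  mhb_change  flank_reduction  score
0.2      False       0.026            0.032  0.548
0.4       True       0.074            0.079  1.907
0.5       True       0.109            0.104  2.906
0.7      False       0.171            0.138  4.681
```

Reading: at `l = 0.2` the miRNA domain barely overlaps the *Wnt1* domain
(3% mean flank reduction — no effect); at `l ∈ {0.4, 0.5}` the production
front sits on the *Wnt1* anterior flank, which is selectively reduced
(8–10%) while the boundary peak is nearly untouched (<12% change) and the
flank curvature increases — a sharpening; at `l = 0.7` the miRNA overruns
the boundary peak itself (17% erosion), an overall reduction rather than a
sharpening.

Enumerating attractors from 24 space-filling unimodal initial conditions
(`twoscale steady-states --config configs/reference.yaml`) yields exactly
two stable non-zero patterns: `SS1-wide` (En/Pax domain width ≈ 2.1) and
`SS2-narrow` (width ≈ 0.41, with the steeper posterior *Fgf8* edge); their
Otx2, Gbx2 and *Wnt1* profiles coincide.

## Command line

```
twoscale simulate      --config configs/reference.yaml --out runs/sim
twoscale steady-states --config configs/reference.yaml --out runs/steady
twoscale mirna-scan    --scenario ii --out runs/scan
twoscale fit-profile   trace.csv --out runs/fit
twoscale filter-mirna  predictions.csv states.csv --out runs/filter
```

A small synthetic prediction/state fixture for the filtering workflow is
bundled under `examples/` (`toy_predictions.csv`, `toy_states.csv`; four
miRNAs pass the filter, the top two by score are selected).

Each run writes delimited result tables plus a `provenance.json` with the
resolved configuration, seeds and package version.

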