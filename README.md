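# notchwnt

Coupled-cell ODE model of Notch–Wnt crosstalk at the Hes1 promoter in the
intestinal crypt.

Cells in the crypt epithelium choose between absorptive and secretory
fates through Delta–Notch lateral inhibition, while the canonical Wnt
pathway controls their proliferative state through β-catenin. The two
pathways talk to each other at the *Hes1* promoter: the NICD:β-catenin
complex drives the Notch-mediated transcription route, β-catenin binds the
promoter directly in the Wnt-mediated route, and Dishevelled represses the
promoter when the extracellular Wnt stimulus is high. This package
implements that crosstalk model for pairs (or arbitrary contact graphs) of
cells and the analysis around it, for modellers studying how promoter
control and the Wnt gradient shape cell-fate dynamics.

Each cell carries twelve species — Notch receptor `N`, Delta `D`, NICD
`F`, NICD:β-catenin `I1`, Hes1 `H1`, Hath1 `H2`, Ngn3 `P`, β-catenin `B`,
Axin `A`, free GSK3β `G`, destruction complex `C` and complex-bound
β-catenin `I2` — with dynamics of the form

```
dN/dt  = α_N·hill(D̄; κ₁, n) − k_cl·N − μ_N·N
dH1/dt = α_H1·[θ₂·hill(I1; κ₄, n) + (1−θ₂)·hill(B; κ₇, n)]·Ψ_W(W)·inh(H1; κ₅, m) − μ_H1·H1
dB/dt  = α₃ + α₄·W − k₃·F·B − k_CB·C·B − μ_B·B
...
```

where `hill(x; κ, n) = xⁿ/(κⁿ + xⁿ)`, `inh` is its complement, `D̄` is the
mean Delta over graph neighbours, `θ₂ ∈ [0, 1]` is the proportion of
Notch-mediated promoter control, `W` the local Wnt stimulus (1 ≡
100 ng/ml) and `ρ_APC ∈ [0, 1]` scales destruction-complex formation (APC
knockouts). The full system, parameters and calibration are described in
`docs/methods.md`.

## What it provides

- deterministic stiff integration of cell pairs / graphs with timed
  mutation events (APC single/double hits, Wnt hyperstimulation);
- a stochastic Hes1 extension (additive production noise, Euler scheme
  with Wiener or literal per-step scaling);
- steady states, Jacobian spectra, oscillation-period measurement with an
  amplitude filter, and (θ₂, W) regime sweeps;
- reaction-network structure: stoichiometry, conservativity, weak
  reversibility, export in a concordance-toolbox dialect, and a numerical
  multistability probe;
- the sensitivity-ranked sequential 1D calibration procedure that
  produced the shipped parameter set.

## Worked example

```python
import notchwnt as nw

params = nw.default_params()

# decoupled beta-catenin steady states
for W in (0.0, 1.0, 2.0):
    print(f"B*(W={W:.0f}) = {nw.bstar_decoupled(params, W):.2f} nM")

# homogeneous pair: Hes1 period
traj = nw.run_notch_pair(params, ic=(0.5, 0.5), W=1.0, horizon_h=16.0)
m = nw.measure_period(traj)
print(f"Hes1 period = {m.period_h:.2f} h (amplitude {m.amplitude:.3f} nM)")

# heterogeneous pair at the standard promoter mix: patterned state
scen = nw.build_scenario("healthy_pair", theta2=0.75, W=0.0, params=params,
                         horizon_h=24.0)
tr = nw.run_deterministic(scen, params)
print(f"Hes1 at 24 h: cell1 = {tr.series('cell1', 'H1')[-1]:.2f} nM, "
      f"cell2 = {tr.series('cell2', 'H1')[-1]:.2f} nM")
```

prints

```
B*(W=0) = 6.63 nM
B*(W=1) = 25.00 nM
B*(W=2) = 55.00 nM
Hes1 period = 2.19 h (amplitude 0.275 nM)
Hes1 at 24 h: cell1 = 6.74 nM, cell2 = 1.70 nM
```

β-catenin rises with the Wnt stimulus (2.2-fold from `W=1` to `W=2`,
8.3-fold from `W=0`); a homogeneous pair oscillates with a ~2.2 h Hes1
period (within 10% of the 2 h calibration benchmark); and a slightly asymmetric pair at low Wnt resolves into the
laterally inhibited pattern — one high-Hes1 (absorptive-like) and one
low-Hes1 (secretory-like) cell.

The same experiments are available from a shell:

```bash
notchwnt simulate --scenario wnt_hyper_pair -W 0 --hours 30 --out traj.csv
notchwnt sweep --theta2 0:1:5 --w 0,1,2 --out regimes.csv
notchwnt network --variant full --coupling step4_only --wnt off \
    --export toolbox.txt --probe --draws 50 --out verdict.json
notchwnt sensitivity --output period --out sens.csv
```

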