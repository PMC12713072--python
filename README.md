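# lyosim

Mechanistic simulation of **continuous lyophilization (freeze drying) of
suspended vials** for biopharmaceutical drug products.

In the suspended-vial configuration, vials hang from a carrier and move
continuously through dedicated freezing and drying chambers without ever
touching a shelf; every vial sees the same heat-transfer history, so a
single-vial model characterizes the whole line.  `lyosim` implements the
full cycle for process design, optimization and what-if analysis:

* **Freezing** — an event-driven lumped model covering preconditioning,
  vacuum-induced surface freezing (VISF), ice nucleation (controlled at a
  set temperature, or stochastic as a Poisson process with intensity
  λ = k_n (T_f,l − T)^b_n V_l sampled exactly via its survival
  probability), solidification with the growing ice shell as a series
  heat-transfer resistance and the liquid slaved to molal freezing-point
  depression, and final cooling.
* **Primary drying** — a one-dimensional Stefan (moving-boundary)
  problem: conduction in the frozen layer, side-wall radiation, a
  receding sublimation front with flux
  N_w = (p_sat,ice(T) − p_w,c)/R_p(S) against a thickness-dependent cake
  resistance, solved by the method of lines on a Landau-transformed grid
  ξ = (z − S)/(H − S) with a stiff integrator and front-arrival event.
* **Secondary drying** — conduction in the dried cake coupled to
  linear-driving-force desorption of bound water,
  ∂c_w/∂t = −f_a e^(−E_a/RT) c_w, terminated at a residual-moisture
  target.
* **Chamber/condenser balance** — the chamber water pressure as a
  dynamic state for condenser-failure and choked-flow studies, coupled
  two-way with primary drying.

See `docs/methods.md` for the model equations, assumptions, numerical
treatment and limitations.

## Worked example

```python
from lyosim import make_case, run_full_cycle

case = make_case("default")          # 3 mL of 5 wt% sucrose, 10R vial,
res = run_full_cycle(case)           # VISF-controlled nucleation at 268 K
s = res.summary
print(f"VISF start          : {s['t_f1']/3600:.2f} h")
print(f"nucleation          : {s['t_f3']/3600:.2f} h")
print(f"freezing done       : {s['t_f5']/3600:.2f} h")
print(f"primary drying      : {s['t_d1']/3600:.2f} h")
print(f"secondary drying    : {s['t_d2']/3600:.2f} h")
print(f"total cycle         : {s['cycle_time']/3600:.2f} h")
print(f"VISF mass loss      : {s['evaporated_mass_visf']:.2e} kg")
print(f"final residual water: {s['final_c_w_mean']:.3f} kg/kg")
```

prints

```
VISF start          : 0.25 h
nucleation          : 0.31 h
freezing done       : 1.23 h
primary drying      : 5.70 h
secondary drying    : 5.87 h
total cycle         : 12.80 h
VISF mass loss      : 2.29e-05 kg
final residual water: 0.010 kg/kg
```

i.e., the vial supercools, nucleates four minutes after the chamber is
evacuated, finishes freezing in ~1.2 h, sublimates its ~3 g of ice in
~5.7 h, and desorbs bound water down to the 1% residual-moisture target
in a further ~5.9 h — with only ~0.8% of the water lost to VISF
evaporation.

The same scenarios are available from the shell:

```bash
lyosim cycle --case default --out runs/cycle
lyosim freeze --case visf-study --out runs/visf
lyosim condenser-failure --out runs/failure
lyosim montecarlo --case visf-study --n 1000 --seed 1 \
    --k-n 1e-7 --b-n 10 --out runs/mc
lyosim make-config --case 2b --out case2b.yaml   # editable YAML scenario
```

Each run writes CSV trajectories, a `summary.json` and a manifest with
the configuration hash and seed.

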