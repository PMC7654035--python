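# magnetoferm

Digital twin and analytics for oxystat batch fermentation of the
magnetotactic bacterium *Magnetospirillum gryphiswaldense*, which
biomineralizes chains of membrane-enveloped magnetite (Fe₃O₄) nanocrystals —
magnetosomes.  Magnetosome yield and crystal size depend sharply on dissolved
oxygen: growth is fastest around 1% of air saturation, biomineralization is
maximal in anoxia with nitrate as the sole electron acceptor, and is
abolished at high dO₂.  Stable microoxic control in a stirred tank therefore
requires an automated cascade, and quantifying the product requires particle
statistics beyond bulk proxies.

This package is aimed at bioprocess and biomineralization researchers who
want to study that control problem and the associated quantification
pipeline *in silico*:

- **`magnetoferm.controller`** — PI controller with a split-range cascade:
  the 0–100 % controller output first ramps agitation (100–300 rpm,
  quantized 10 rpm steps), then airflow (0–10 SLPM of air, 0.1 SLPM steps);
  anti-windup by integral clamping; an O₂-probe model with Gaussian noise,
  a 6 ppb detection floor (0.075 % air saturation) and ±1 % span.
- **`magnetoferm.bioreactor`** — the synthetic-data generator / plant: a
  seven-state ODE for biomass X (OD₅₆₅), lactate S, nitrate N, dissolved
  oxygen C, cellular iron and magnetosome size, with

  μ = μ_max · S/(K_S+S) · min[C/(K_O₂+C) + η·K_fnr/(K_fnr+C) · N/(K_N+N), 1] · (1−s·C),

  dC/dt = k_La(rpm, airflow)·(C* − C) − q_O₂·X·C/(K_O₂+C),

  growth-coupled lactate uptake (single yield Y), Fnr-type oxygen repression
  of nitrate respiration, and first-order relaxation of iron content and
  particle size toward dO₂-dependent asymptotes.  Presets `oxic95`,
  `microoxic1`, `anoxic0` encode the three study regimes (4/4/10 mM
  nitrate; anoxic runs are open-loop under 0.2 SLPM N₂).  A TEM emulator
  draws per-particle diameters and per-cell counts from the measured
  trajectories.
- **`magnetoferm.growth`** — log-linear growth-rate fits, doubling times,
  window-slope consumption rates (mM h⁻¹ OD⁻¹), yields Y_x/s, C_mag, and
  volumetric magnetite productivity via M(Fe₃O₄)/(3 M(Fe)).
- **`magnetoferm.particles`** — pooled size summaries (mean, sd, median,
  IQR, fraction > 30 nm), per-cell magnetosome densities, and a Wilcoxon
  rank-sum test (exact enumeration for n ≤ 12, tie-corrected normal
  approximation otherwise).
- **`magnetoferm.saxs`** — SAXS curve reduction, the sphere form factor
  P(qR) = [3(sin x − x cos x)/x³]² with Gaussian diameter polydispersity,
  Guinier fits (R = √(5/3)·R_g for solid spheres), flake/platelet Guinier
  decomposition, and the membrane/core split
  2R_core = 2R − 2·R_membrane.
- **`magnetoferm.io` / `magnetoferm.cli`** — CSV/`.dat` readers and writers
  and the `magnetoferm` command-line interface.

## Worked example

```python
import numpy as np
from magnetoferm.bioreactor import run_preset, observe
from magnetoferm import growth

record = run_preset("microoxic1", seed=1)           # 35 h closed loop at 1% dO2
print(f"median dO2: {np.median(record.frame['dO2_pct']):.2f} %")

obs = observe(record, 0.5, 0.02, seed=2)            # 30-min, 2%-noise sampling
mu = growth.fit_growth_rate(obs.frame["time_h"].to_numpy(),
                            obs.frame["od565"].to_numpy(), (10, 17))
print(f"growth rate: {mu.value:.3f} 1/h, "
      f"doubling time: {growth.doubling_time(mu.value):.2f} h")
```

prints

```
median dO2: 0.85 %
growth rate: 0.145 1/h, doubling time: 4.79 h
```

i.e. the cascade holds the 1% set point (trace median 0.85 % over 35 h) and
log-linear regression over the 10–17 h main-growth window recovers the
microoxic specific growth rate (0.145 h⁻¹ here, ±0.002 across replicate
seeds) from noisy at-line observations.

From the shell:

```bash
magnetoferm simulate --preset anoxic0 --seed 1 --out runs/
magnetoferm analyze --records runs/anoxic0_seed1.csv --window 17 23 --out runs/
magnetoferm particles --regime anoxic --timepoint 34 --out runs/
```

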