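# invafront

Individual-based lattice simulation of population invasion through a
degradable environmental barrier, with the statistical machinery to
characterize the invasion front: Langevin drift/diffusion estimation and
kinetic-roughening (dynamic scaling) analysis.

## The problem

Invading populations — tumour clones pushing into the extracellular matrix
are the motivating example — rarely advance into empty space: every new
site resists occupation until the invaders have degraded its barrier.  When
the invading population comprises interacting subpopulations, the front's
speed, its fluctuations and its geometry all depend on whether those
subpopulations help or hinder each other's barrier degradation.

The model: species live on lattice units (a half-infinite 1D array seeded
at unit 0, or a 2D strip of transverse width `L`, periodic sideways, seeded
with a full first row).  A randomly selected occupied unit attempts one
duplication (into a nearest neighbour empty of that species) and one
migration (a uniformly drawn lattice direction) per occupant species.  A
target unit with barrier intensity `N` rejects entry until its trial
counter satisfies, for a single species,

    n >= N

and for two species, whose failed trials are counted separately as
`n1`, `n2`,

    zeta * n1 + n2 > N   or   n1 + zeta * n2 > N,

where the interaction parameter `zeta` weights the rival's contribution:
`zeta > 0` cooperation, `zeta < 0` competition, `zeta = 0` indifference.
Each failed entry attempt increments the acting species' counter by one.
The two species may co-occupy a unit; the barrier is their only coupling.
One time step = as many counted unit selections as there are lattice units.

Analysis: the front coordinate (`X` in 1D; the mean height `H` of the
per-column front profile `X_i` in 2D) behaves as drift plus diffusion,
`dX/dt = V + sqrt(D) eta(t)`, and the package estimates `V`, `D` and their
power-law dependence on `N`, `zeta` and `L` (`V ~ N^-gamma_V`,
`D ~ N^-gamma_D`, `D_H ~ L^-gamma_L`).  The 2D front's interface width
`W^2 = (1/L) sum_i (X_i - H)^2` is analysed in the Family–Vicsek frame
`W ~ L^alpha f(t / L^z)`: growth exponent `beta`, saturated width `W_sat`,
roughness exponents `alpha_L` and `alpha_N`.

## Worked example

```python
from invafront import run_ensemble, ensemble_stats, fit_langevin, fit_power_law

Ns = [5, 10, 20, 40, 80]
Vs, Ds = [], []
for N in Ns:
    trajs = run_ensemble(1, N, 2000, 300, record_every=4,
                         base_seed=1, cell_key=("demo", N))
    lv = fit_langevin(ensemble_stats(trajs), method="endpoints")
    Vs.append(lv.V); Ds.append(lv.D)
    print(f"N={N:3d}  V={lv.V:.4f}  D={lv.D:.5f}")

gv = fit_power_law(Ns, Vs, fit_range=(20, 80), convention="decay")
gd = fit_power_law(Ns, Ds, fit_range=(20, 80), convention="decay")
print(f"gamma_V = {gv.exponent:.3f} +/- {gv.stderr:.3f}")
print(f"gamma_D = {gd.exponent:.3f} +/- {gd.stderr:.3f}")
```

Output (seed 1):

```
N=  5  V=0.2373  D=0.06452
N= 10  V=0.1341  D=0.01877
N= 20  V=0.0721  D=0.00571
N= 40  V=0.0373  D=0.00161
N= 80  V=0.0190  D=0.00042
gamma_V = 0.961 +/- 0.006
gamma_D = 1.891 +/- 0.036
```

Doubling the barrier roughly halves the invasion speed (`gamma_V ~ 1`) and
quarters the front's diffusive fluctuation (`gamma_D ~ 2`): a unit opens
after ~N trials, so the advance rate scales as 1/N and the variance of the
advance count as 1/N².

The same workflow is available from a shell:

```bash
invafront simulate --n 10 --replicates 200 --steps 2000 --seed 1 --out traj.csv
invafront analyze --traj traj.csv --out summary.json
invafront sweep --config my_sweep.yaml          # YAML/JSON SweepConfig mirror
invafront reproduce --experiment fig2 --scale 0.5 --seed 1 --out sweep_out/
invafront validate
```

`reproduce` runs one of four preset experiment families (1D single-species
N-sweep; 1D interaction sweep; 2D Langevin sweeps; 2D roughening study),
writes per-cell trajectory CSVs plus a JSON manifest sufficient to
regenerate every trajectory bit-exactly, and summarizes all fitted
exponents in `summary.json`.

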