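# viralsir

Sharing-plus-advertising SIR dynamics for viral-video spread.

When a video spreads on a platform, two forces recruit viewers: people
sharing it with each other, and the advertising the owner pays for.  Because
both act at once, their contributions are hard to disentangle from view
counts alone — yet that split is exactly what a marketing budget decision
needs.  `viralsir` implements a compartmental model that makes the split
explicit, for modellers and analysts working on information diffusion,
viral marketing, or epidemiology-style models of online content.

## The model

The potential audience is divided into susceptibles $S$ (unaware of the
video), infecteds $I$ (active sharers) and recovereds $R$ (watched it,
stopped sharing):

$$
\begin{aligned}
S' &= -\beta IS/N - \gamma N^2/(N+I) + bN,\\
I' &= \beta_1 IS/N + \gamma N^2/(N+I) - \alpha I,\\
R' &= (\beta-\beta_1) IS/N + \alpha I,
\end{aligned}
$$

with contact rate $\beta$, sharer-conversion rate $\beta_1 < \beta$ (a
contact that does not create a sharer still produces a viewer, who goes
straight to $R$), recovery rate $\alpha$, new-user inflow $bN$, and the
*advertising function* $\gamma N^2/(N+I)$ — strongest ($\gamma N$) when
nobody is sharing, fading as sharers take over.  $N$ is held at the initial
total population.

On top of the ODE core the package provides:

- **Equilibrium theory** — the unique interior fixed point $(S^*, I^*)$ from
  the closed-form quadratic $f(I)=\alpha I^2 + (\alpha - \tfrac{\beta_1}{\beta}b)NI
  - (1-\tfrac{\beta_1}{\beta})\gamma N^2 - \tfrac{\beta_1}{\beta}bN^2$, its
  bracket $(b-\gamma/2)N/\beta < S^* < (\alpha-\gamma/2)N/\beta_1$, and the
  Jacobian-based stability certificate (valid for $\alpha > b > \gamma$).
- **Attribution** — the cumulative conversion integrals
  $n_S(T)=\int_0^T \beta IS/N\,dt$ (sharing) and
  $n_A(T)=\int_0^T \gamma N^2/(N+I)\,dt$ (direct advertising), and a
  lineage-tracking agent-based simulator whose Type A / Type B labels
  attribute every viewer to a sharing-seeded or advertising-seeded
  transmission chain.
- **Calibration** — normalized least squares of the model's $R(t)$ against
  cumulative daily views, minimized by multi-start Nelder–Mead
  (`ViewCountModel(...).fit()` in the Model/Results style).
- **Synthetic data** — seeded view-count series with mean-preserving
  multiplicative noise, so the whole pipeline is testable offline.

## Worked example

With the reference configuration ($N=10^4$, $S_0=9900$, $I_0=100$,
$\beta=0.4$, $\beta_1=0.1$, $\alpha=0.03$, $b=0.02$, $\gamma=0.002$):

```sh
$ viralsir equilibrium
S_star=2204.273314255519
I_star=2080.5549379971044
S_lower=475.0
S_upper=2900.0
B_bar=0.09254989238648818
C_bar=0.002582203448445296
stable=True
```

The spread settles at about 2204 unaware users and 2081 active sharers
(inside the theoretical bracket 475–2900), and the negative-real-part
eigenvalues certify the point is stable — every start converges there.

```python
>>> import viralsir as v
>>> traj = v.integrate(v.DEMO_PARAMS, v.ModelState.initial(9900, 100),
...                    t_end=100, output_grid=0.1)
>>> v.cumulative_fluxes(traj, T=100.0)
(26229.419859733996, 1669.71822834637)
```

Over the first 100 days roughly 26 229 users convert through sharing but only
1 670 through advertising directly — yet the agent-based lineage count
(`viralsir abm` + `viralsir attribute`) shows most viewers trace back to an
advertising-recruited root: advertising works mostly *indirectly*, by seeding
chains that sharing then amplifies.

Fitting a synthetic 200-day series (5% daily observation noise) recovers the
generating rates:

```python
>>> noisy, truth = v.generate_view_series(v.SynthConfig(
...     true_params=v.DEMO_PARAMS, S0=1e6, I0=100, n_days=200,
...     noise_sigma=0.05, seed=0))
>>> res = v.ViewCountModel(noisy, s0=1e6, i0=100,
...                        theta0=v.DEMO_PARAMS.replace(beta=0.3, alpha=0.05)).fit(seed=0)
>>> print(res.summary())
Sharing-plus-advertising SIR fit to daily views
================================================
observations: 201 days (t_max = 200)
S0 = 1e+06, I0 = 100, N = 1.0001e+06
free parameters: beta, beta1, alpha, gamma, b
------------------------------------------------
  beta   = 0.434074
  beta1  = 0.0931979
  alpha  = 0.0283888
  gamma  = 0.00185014
  b      = 0.0199797
  beta1/beta = 0.2147
------------------------------------------------
Er = 2.60053e-07   converged = True   iterations = 3840   restarts = 5
```

All five rates come back within ~9% of the truth
(β=0.4, β₁=0.1, α=0.03, γ=0.002, b=0.02) despite the noise; `Er` is the
normalized least-squares cost.

The same operations are available from the shell: `viralsir simulate | equilibrium | abm | attribute | fit | synth`
(see `viralsir --help`), all reading/writing plain CSV and writing a
manifest of every resolved parameter and seed.

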