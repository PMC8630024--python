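# hostcycle

Many host-associated microbes live a **biphasic life cycle**: they
alternate between a host-associated phase and a free-living environmental
phase, replicating in both habitats and migrating between them.  For such
a lineage, fitness is not a single replication rate — it integrates
replication in *each* compartment together with the transmission rates
between them.  `hostcycle` is a simulation and sensitivity-analysis
toolkit for the minimal model of this situation, aimed at theoretical
ecologists and microbiome researchers who want to reason about which
life-history trait selection will act on first.

## The model

A lineage with host abundance $n_H(t)$ and environment abundance $n_E(t)$
follows

$$
\begin{aligned}
\dot n_H &= r_H n_H + m_H n_E - m_E n_H - k_{HE} n_H n_E - k_{HH} n_H^2,\\
\dot n_E &= r_E n_E + m_E n_H - m_H n_E - k_{EH} n_E n_H - k_{EE} n_E^2,
\end{aligned}
$$

with net replication rates $r_H, r_E$ (possibly negative), migration rates
$m_E$ (host → environment) and $m_H$ (environment → host), and
intraspecific competition intensities $k_{ij}$.  Time is measured in units
of $1/r_E$ (the presets set $r_E = 1$).

**Without competition** ($k_{ij}=0$) the dynamics are linear with
projection matrix $A = \begin{pmatrix} r_H - m_E & m_H \\ m_E & r_E - m_H
\end{pmatrix}$, whose dominant eigenvalue $\lambda$ is the asymptotic
overall growth rate — the fitness measure.  The selection gradient is the
vector of sensitivities $s_i = \partial\lambda/\partial x_i$, one per
trait, computed in closed form.

**With competition** the asymptotic rate is uninformative (growth
saturates), so fitness becomes the finite-horizon effective growth rate

$$\Lambda = \frac{1}{t_{max}}\log\frac{n_E(t_{max})+n_H(t_{max})}{n_E(0)+n_H(0)},$$

whose sensitivities $S_i$ are measured by forward trait perturbations.
$\Lambda$ depends on the probing time $t_{max}$, the initial distribution
of microbes across compartments, and the competition pattern — all part of
the measurement protocol (`ProbeSpec`).

**Optimal strategies.**  If the lineage can tune one trait at a time, the
locally optimal move follows the largest $|s_i|$.  Excluding $r_E$ (the
lineage is assumed already adapted to the environment), the recurring
strategies are: **I** increase $r_H$, **II** decrease $m_H$, **III**
increase $m_E$, **IV** increase $m_H$.  `hostcycle` maps these regions
over trait space, extracts the contour lines between them, and quantifies
how the contours move with $t_{max}$ and competition intensity, including
the long-time limits given by the sensitivities of the equilibrium
abundance $N^* = n_H^* + n_E^*$ (closed-form for one-compartment and
global competition).

## Worked example

The running example is a source–sink phenotype: fast environment
($r_E = 1$), slow host ($r_H = 0.1$), symmetric migration $m = 0.5$.

```bash
$ hostcycle lambda --r-h 0.1 --m 0.5
{ ... "lambda": 0.7226812023536856 }
```

The lineage grows at 72% of the pure-environment rate: migration drags it
through the slow host.  Where should adaptation act?

```bash
$ hostcycle sensitivity --r-h 0.1 --m 0.5
{
  "method": "analytic",
  "s_rE": 0.8344823658112248,
  "s_rH": 0.1655176341887752,
  "s_mE": 0.20612943893480795,
  "s_mH": -0.46283529268764173
}
```

Ignoring $s_{r_E}$, the largest magnitude is $|s_{m_H}| = 0.463$ with a
negative sign: the optimal single-trait move is to *decrease* migration
into the host (strategy II) — staying longer in the fast compartment beats
replicating faster inside the host at this point of trait space.

With global competition ($k = 1$) and a short probing window the measured
rate drops:

```bash
$ hostcycle effective-growth --r-h 0.1 --m 0.5 --scenario global --k 1 --t-max 3
{ ... "Lambda": -0.10638841012604498 }
```

$\Lambda < 0$ here only because the population is already near its
carrying capacity $N^* = \lambda/k \approx 0.72$ over most of the window.

Equilibria and strategy maps:

```bash
$ hostcycle equilibrium --scenario host_only --r-h 0.1 --m-e 0.5 --m-h 1.2 --k 1
{ ... "n_H": 2.6000000000000005, "n_E": 6.500000000000003, "stable": true }

$ hostcycle strategy-map --preset fig1c --out fig1c.csv
# 101 x 100 grid over r_H in [-1, 1], m in (0, 2]; labels I/II plus the
# contour polyline (m = 1 - r_H) in fig1c.csv.contours.json
```

Python API mirrors the CLI: see `hostcycle.integrate`,
`hostcycle.dominant_growth_rate`, `hostcycle.analytic_sensitivities`,
`hostcycle.effective_growth_rate`, `hostcycle.equilibrium`,
`hostcycle.strategy_grid`.  Full model documentation in
[docs/methods.md](docs/methods.md).

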