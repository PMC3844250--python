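# Methods

## 1. The mechanistic contractile element (`ce_core`)

The contractile element (CE) is a one-dimensional assembly of three
components between the origin y = 0 and the load attachment y2:

* **AE** (active element): an ideal force source, `F_AE = A_AE · F_AE_max`,
  with activation `A_AE ∈ [0, 1]`.  No activation dynamics: the virtual
  protocols switch `A_AE` from 0 to 1 at t = 0, as the hardware protocol
  did.
* **PDE** (parallel damping element): a damper across the AE whose
  coefficient is linear in the transmitted force,
  `d_PDE(F_SE) = D_PDE · ((1 − R_PDE) F_SE / F_AE_max + R_PDE)`.
  `R_PDE ∈ [0, 1]` is the fraction of the maximum damping left at zero
  force; `D_PDE` [N s/m] is the maximum coefficient.
* **SE** (serial element): a unilateral linear spring (stiffness `k_SE`,
  default 2401 N/m as in the hardware rig; force ≥ 0, slack flag exposed),
  optionally rigid.

The AE/PDE node is massless, so the force balance
`F_CE = F_SE = F_AE + F_PDE` holds identically and yields the node's
shortening speed algebraically, `v1 = (F_AE − F_SE)/d_PDE(F_SE)`.  The
kinematic identity `l_AE = l_PDE = l_CE − l_SE` holds by construction of
the coordinates (l_AE = y1, l_CE = y2).

**Why a hyperbola.**  At a steady operating point under constant force F,
`v(F) = (F_max − F) / (D_eff · ((1 − R) F/F_max + R))` with
`D_eff = (1 − κ_v) D_PDE`, where κ_v is the fraction of the CE velocity
taken up by the serial element (κ_v = 0 at constant SE tension).  This is
exactly Hill's `(F + a) v = b (P0 − F)` with `a = F_max R/(1 − R)`,
`b = F_max/(D_eff (1 − R))`, `P0 = F_max`.  `steady_state_fv` evaluates
this closed form and serves as the analytic oracle for every simulated
experiment; `hill_to_design`/`design_to_hill` are the exact algebraic
conversions.

**Degenerate input**: `R_PDE = 0` with a slack spring makes the damping
coefficient zero and the node rate singular; this raises a dedicated error
advising `R_PDE > 0` rather than returning infinity.

## 2. Virtual protocols (`experiments`)

*Isometric*: the far end is clamped; the force rises against the serial
spring with local time constant `d_PDE/k_SE`.  The plateau is declared when
the node speed stays below 1e-5 m/s for 50 ms (the protocol source states
no criterion; this one is documented and configurable in code).  Because
the plateau time constant is `D_PDE/k_SE` (≈ 0.92 s for the piglet design),
full convergence takes ~6–7 s; `run_isometric` therefore has its own time
budget `t_isom_max` (default 10 s), while quick-release experiments release
at the fixed protocol time `t_QR = 3 s` whether or not the plateau has
fully converged — exactly as a hardware rig with a fixed release schedule
behaves.  The measured `F_CE(t_QR)` then exceeds every load in the sweep.

*Isotonic quick release*: clamp until `t_QR = 3 s`, then a constant
external force; the operating point `(F_CE, v_CE)` is read at
`t_eval = 3.5 s`, velocity by centred finite difference of the CE length.
Released loads greater than the held force are flagged (`no_shortening`),
not raised.

**Released boundary.**  Two models are provided:

* `ideal` (default): a massless, force-controlled boundary — the SE tension
  equals the external force from the instant of release.  This is the
  faithful idealisation of the force-controlled motor that loaded the
  hardware CE, and it makes the isotonic phase exactly isotonic.
* `inertial`: a point mass `m_load` carries the external force.  This mode
  exists to study the physics of releasing a real mass: the load/spring
  mode is strongly underdamped (its decay rate `k_SE/(2 d_PDE)` ≈ 1 1/s is
  independent of the mass), so the force at `t_eval` still rings by tens of
  percent around the nominal load.  It is deliberately **not** the default:
  the protocol's isotonicity requirement (force within 1% of the load at
  evaluation) is unattainable with any point-mass load on this rig's
  timescales.

*Sweep*: 19 load levels uniform in [0.02, 0.95] of the measured isometric
maximum (the level count matches the published protocol; the hardware's
exact levels are unpublished), 10 repetitions each.  Without measurement
noise the repetitions are identical replicas of one simulation per level;
with noise, independent Gaussian draws per repetition from a seeded
generator (the seed is mandatory whenever noise is on).

*κ_v*: computed as `v_SE/v_CE` by centred differences at the evaluation
instant; exactly 0 for a rigid SE and ≈ 0 during an isotonic phase
(constant SE tension ⇒ constant SE length).  During the clamped phase
`v_CE = 0` and the ratio is undefined (raised as an error).

## 3. Hyperbola fitting and the catalogue (`hill_param`)

`fit_hyperbola` does nonlinear least squares of `P(v)` (scipy `curve_fit`,
positivity bounds, initialisation `a0 = 0.25 P0`, `b0 = 0.25 v_max`).  R²
is computed **on force residuals** — the protocol extracts forces at fixed
evaluation times — so users can reproduce hardware-style ".97" numbers.
`P0` can be fixed to the isometrically measured maximum, which improves the
identifiability of `a` considerably on noisy data.

The packaged catalogue carries six literature muscles verbatim (name, A, B,
F_max, optimal CE length, and the published design-parameter columns).
Integrity is enforced by a SHA-256 checksum plus physical validation (six
rows, positive entries, slope-matching consistency of the effective-damping
column to 2%).  Notes:

* The published `R_PDE` column is reproduced by `A/(A + F_max)` only for
  the rat gastrocnemius (0.167); the other five printed values follow from
  no inversion of the printed (A, B, F_max) that we could identify.  The
  catalogue keeps the printed values verbatim; `design_params_for` uses the
  closed-form inversion so that the resulting construct reproduces the
  published hyperbola exactly.
* The rat tibialis anterior row has A = F_max (a_rel = 1.0), which is
  physiologically implausible but kept as printed.
* κ_v and D_PDE are not separable from force-velocity data alone; the
  public design parameter is `D_eff = (1 − κ_v) D_PDE`.

## 4. The muscle-tendon unit (`mtu`)

The pendulum actuator is a standard macroscopic MTU with the human tibialis
anterior parameter set (l_CE_opt = 0.1 m, F_max = 10 kN, ΔW = 0.57,
ν_CE = 4, A_rel0 = 0.25, B_rel0 = 2.25 1/s, l_SEE0 = 0.23 m,
ΔU_SEE,nll = 0.1825, ΔU_SEE,l = 0.073, ΔF_SEE0 = 10 kN, D_SE = 0.3,
R_SE = 0.01):

* active force-length `exp(−|(l/l_opt − 1)/ΔW|^ν)`;
* Hill force-velocity, concentric per Hill with `a = A_rel0 F_max`,
  `b = B_rel0 l_opt`; eccentric as the standard continuous extension (slope
  ratio 2 at v = 0, asymptote 1.5 × isometric; both configurable — the
  source parameter set specifies no eccentric branch, but pendulum
  perturbations stretch the antagonist, so one is required);
* SEE: zero below rest length, power-law toe up to strain ΔU_SEE,nll where
  the force reaches ΔF_SEE0, linear beyond with stiffness
  `ΔF_SEE0/(ΔU_SEE,l · l_SEE0)` ≈ 595.6 kN/m.  The toe exponent
  `ΔU_SEE,nll/ΔU_SEE,l = 2.5` follows from C¹ continuity at the junction
  rather than being hard-coded;
* serial damping `d_SE = d_SE,max ((1 − R_SE)(F_CE + F_PEE)/F_max + R_SE)`
  with `d_SE,max = D_SE F_max A_rel0/(l_opt B_rel0)` ≈ 3333 N s/m;
* PEE: the parameter set lists none, so a quadratic spring engaging at
  0.95 l_opt and reaching 2 F_max at l_opt (1 + ΔW) is the documented,
  configurable default;
* activation: first-order filter `dq/dt = (u − q)/τ_act`, τ_act = 30 ms
  default, optional instantaneous mode (whether the original pendulum
  muscles had activation dynamics is unstated; both are provided).

The single mechanical state is l_CE.  Its rate solves the series force
equilibrium; on each force-velocity branch the balance is a quadratic in
the rate (the Hill branch is linear-fractional, the damping coefficient
linear in the force), solved in closed form with residual verification to
1e-6 F_max and branch selection by the sign of the residual at zero rate.
With zero activation the active force vanishes identically and the balance
degenerates to a linear equation, handled explicitly.

## 5. The inverted pendulum (`pendulum_control`)

One rigid segment (m = 50 kg, J = 45.125 kg m² about the hinge — exactly
m h² — h_COG = 0.95 m) on a hinge above a massless foot whose angle α(t) is
kinematically prescribed: a 1°/s ramp saturating at 1°, or 1° sinusoids at
1 Hz / 0.1 Hz.  The only dynamic degree of freedom is the segment angle β;
`J β̈ = m g h sin β + τ_actuator`.

* **Torque generator**: commands `−(Kp e + Ki ∫e + Kd ė)` directly, with
  `e` the β signal delayed by 0.1 s.  Published gain sets: P 500;
  PID 500/50/500.  Note the prescribed foot rotation has no mechanical path
  into this actuator (the hinge lies on the foot's rotation axis and the
  generator has no passive elasticity), so torque-mode runs are seeded by a
  small initial offset β(0) = 0.1° — applied to muscle runs too, for a fair
  comparison.
* **Antagonistic muscles**: path lengths `l = l_ref ∓ r_m (β − α)` — ground
  motion perturbs the muscles mechanically with zero delay (the preflex) —
  and stimulations `clamp(q0 ± PID(e), 0, 1)` around a co-activation
  baseline q0.  Published gain sets: P 1; PID 1/0.3/0.3 (per radian of
  delayed error).

**Muscle geometry** (open in the source; fixed here by linearised analysis
and logged in every result): moment arm r_m = 0.15 m; both CEs at
1.05 l_CE_opt at β = α = 0; q0 = 0.1.  Rationale:

1. *Static preflex stability* requires the antagonistic pair's joint
   stiffness `2 r_m² k_muscle` to exceed the gravitational destabilising
   stiffness `m g h = 466 N·m/rad`.  On the ascending limb near the
   force-length optimum the exp-bell slope is far too small (≈ 3.8 kN/m per
   unit q0 at 0.9 l_opt ⇒ ≲ 19 N·m/rad for any plausible geometry): an
   ascending-limb operating point cannot hold the pendulum.  Slightly past
   optimum the **parallel elastic elements** are engaged and dominate the
   stiffness; at 1.05 l_opt the static joint stiffness (PEE + active slope,
   in series with the SEE) is ≈ 3 kN·m/rad ≈ 6.5 × m g h.
2. *Delayed-feedback damping margin*: delayed P feedback injects negative
   damping ≈ Kp r_m F_max sin(ω Δt)/ω near the co-activated pair's
   resonance.  The muscles' intrinsic force-velocity damping scales with
   r_m² while the feedback scales with r_m, so a larger moment arm both
   detunes the resonance away from the 1 Hz perturbation and keeps the net
   modal damping positive with the published muscle gain Kp = 1.

The anti-windup clamp bounds the integral term at the actuator's output
scale (1 in stimulation units; 1000 N m for the torque generator).
"Topple" is declared at |β| > 30° (the benchmark never defines it; the
threshold is configurable and results are insensitive to it — runs either
stay within ~2° or diverge).

## 6. Numerics

All simulations use fixed-step 5th-order Dormand-Prince integration
(1 ms default), the classic fixed-step "ODE5" configuration: fixed stepping
keeps the 0.1 s feedback dead time an exact integer number of steps and
makes every run bit-for-bit reproducible.  The controller is discrete with
a zero-order hold over each step.  The passive pendulum conserves energy to
O(dt⁵) per step, and its simulated exponential growth rate matches the
analytic eigenvalue `sqrt(g/h_COG) = 3.214 1/s` to ≲ 0.1%, which validates
the integrator against a closed form.

## 7. Synthetic data

The `fv_noisy` fixture emulates a measured force-velocity table from the
quick-release rig: the full 19 × 10 sweep with additive Gaussian noise,
σ_F = 1% of F_max (load-cell scale) and σ_v = 1e-4 m/s (the optical
encoder's ~6e-5 m position resolution differentiated over the evaluation
window).  It does *not* emulate sensor quantisation, motor-control-loop
artefacts, 1 kHz DAQ aliasing, or trial-to-trial parameter drift — so a
green fitter test establishes statistical parameter recovery under
idealised noise, not robustness to structured hardware error.  Fixtures
are deterministic by seed (identical bytes on repeat).

## 8. Known limitations

* The CE reproduces concentric dynamics only; its eccentric behaviour is
  undefined (the MTU module owns the eccentric branch).
* No history-dependent muscle effects (force enhancement/depression), no
  pennation, no calcium-kinetics activation model.
* The pendulum foot is massless and purely kinematic; no double-pendulum,
  no sensory noise, no gain optimisation.
* The quick-release inertial-load mode is physically honest but cannot
  satisfy the 1% isotonicity requirement at 0.5 s after release (see §2);
  quantitative force-velocity work should use the ideal boundary.
* Torque-mode pendulum runs respond to the initial offset only, since the
  prescribed foot rotation cannot reach a pure torque source mechanically.
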