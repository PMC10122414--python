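# Model description and methods

`erwbox` quantifies the long-term permanence of carbon dioxide removal
(CDR) through enhanced rock weathering (ERW) with a deliberately reduced
coupled carbon-cycle model. This note records the model equations and
assumptions, the parameter choices that matter (with defaults and why),
what the synthetic forcing and ensemble machinery do and do not emulate,
and the numerical decisions a maintainer would want written down.

## 1. Seawater carbonate system

State: dissolved inorganic carbon (DIC) and total alkalinity (TA) per
box, with temperature, salinity and pressure. Speciation solves

TA = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] − [H⁺]

for total-scale pH by a safeguarded Newton iteration bracketed in
pH ∈ [2, 12] (bisection fallback), converged to 1e-10 pH units.
Phosphate and silicate alkalinity are omitted: at open-ocean
concentrations they contribute <1% of TA, far below the differences the
box model resolves. Constants: K0 Weiss (1974); K1/K2 Lueker et
al. (2000); K_B Dickson (1990); K_w Millero (1995); calcite/aragonite
solubility Mucci (1983); Millero (1995) pressure corrections. All on
the total hydrogen-ion scale, so no scale conversions arise. The
formulation set is a config key (`"lueker2000"`); the unit tests pin the
implementation to published check values (pK1 = 5.8472, pK2 = 8.9660,
log₁₀K_sp = −6.3693/−6.1883 at 25 °C, S = 35) and to an independent
bisection solver over a 1000-state grid. Calcium is conservative with
salinity, Ca = 0.01028·S/35 mol/kg.

## 2. Box ocean

Four boxes: low-latitude surface (85% of ocean area, 100 m), high-
latitude surface (15%, 250 m), intermediate (2.9e17 m³), deep
(remainder of 1.33e18 m³). This is the minimum structure separating
fast mixed-layer re-equilibration with the atmosphere from slow
interior storage — the mechanism that controls how much ERW-delivered
DIC escapes back to the air. Temperatures are fixed preindustrial
values (21, 3, 9, 2.5 °C) plus a per-box fraction (1.0, 0.7, 0.25,
0.05) of the global-mean anomaly; interior warming lag is not otherwise
resolved.

**Transport.** A 20 Sv overturning loop (low-lat surface → high-lat
surface → deep → intermediate → return) plus pairwise mixing of
60 / 55 / 35 Sv (surface–intermediate, high-lat–deep,
intermediate–deep). Transport is one fixed linear operator; explicit
Euler conserves each tracer to round-off, with a stability bound
dt < min(V/outflow) ≈ 8 yr, enforced at every call.

**Gas exchange.** flux = k_w·K0·(pCO₂_ocean − pCO₂_atm)·area with a
piston velocity of 1800 m/yr (≈ 20 cm/hr). Piston velocity and the
mixing rates were calibrated once so that the control run's cumulative
historical (to 2020) ocean uptake is ~30% of diagnosed emissions
(measured 29.9%), then frozen.

**Biological pump.** Surface phosphate is drawn down on restoring
timescales of 1 yr (low-lat) and 8 yr (high-lat; the long timescale
emulates light/iron limitation), converted to organic carbon at
C:P = 106, remineralized 75%/25% (intermediate/deep) from the low-lat
box and wholly in the deep box from the high-lat box. CaCO₃ export is a
rain ratio of 0.07 times organic export, removing 1 DIC + 2 ALK from
the surface and redissolving in the deep box. Uptake is clipped to the
available nutrient. These closures yield a realistic preindustrial
state: DIC 2024/2190/2279/2320 µmol/kg by box, surface PO₄ depleted,
surface Ω_arg ≈ 3.3–3.6.

**Burial and weathering.** CaCO₃ burial = b₀·max(Ω_cal − 1, 0)ⁿ
(b₀ = 1.6e13 mol/yr per saturation unit, n = 1) with deep-box chemistry
evaluated at an effective shelf/slope sediment pressure of 120 bar
(the box mid-depth is below the calcite saturation horizon; preserved
burial happens shallower). Background weathering delivers dissolved
CaCO₃ (1 DIC + 2 eq ALK per mol, DIC tagged rock-derived) to the
surface at the rate diagnosed at spinup (0.118 GtC/yr), a plausible
deep-sea CaCO₃ burial magnitude. Delivering the dissolved rock directly
— rather than debiting atmospheric CO₂ and re-outgassing it — makes
weathering = burial an exact fixed point and keeps the carbon audit
closed; at steady state the two formulations are equivalent.

## 3. Climate

Radiative forcing: 5.35·ln(C/278) W/m² for CO₂ plus the Myhre et
al. (1998) square-root fits with band overlap for CH₄ (ref 722 ppb) and
N₂O (ref 273 ppb — the same preindustrial value the shipped pathways
use; any mismatch here injects a spurious startup forcing). Temperature:
two-layer energy balance with Geoffroy et al. (2013) median parameters
(λ = 1.13 W m⁻² K⁻¹ → ECS ≈ 3.3 K, γ = 0.73, C = 7.3, C₀ = 106 W yr
m⁻² K⁻¹). Land anomaly = 1.4 × global anomaly (configurable); this
amplified anomaly drives the slab biosphere, consistent with treating
T₀ as the preindustrial land temperature.

## 4. Slab biosphere

dV/dt = N − L and dS/dt = L − R with N = N₀[1 + B ln(C/C₀)],
L = V/(Λ_veg V + Λ₀), R = Γ S Q₁₀^((T−T₀)/10); C₀ = 278 ppm and T₀ is
carried as a land-temperature anomaly of zero (neither value is pinned
by observation; both are package assumptions). Closed-form steady
states V* = N₀Λ₀/(1 − N₀Λ_veg) (requiring N₀Λ_veg < 1) and S* = N₀/Γ
anchor both the initial condition and the integrator tests (recovered
to 1e-6 by RK4 at dt = 0.1 yr). NPP is clipped at zero with a log
record if extreme parameters drive it negative; land–atmosphere
exchange is booked as −(ΔV + ΔS) per step, so it is conservative
independent of integrator error.

## 5. Forcing scenarios and emission inversion

Three idealized concentration families (1765–2300, annual, monotone
PCHIP through anchor points) emulate the standard scenario shapes:
**low** (peak ≈ 450 ppm mid-century, ≈ 421 ppm by 2100), **mid**
(≈ 538 ppm at 2100, stabilizing ≈ 543), **high** (≈ 936 ppm at 2100,
stabilizing ≈ 1960 by 2250), each with matching CH₄/N₂O anchors. The
anchors are idealized approximations, not the published tables; a CSV
reader accepts real tables. CH₄/N₂O are always imposed; they enter only
through radiative forcing.

Scenario CO₂ is emission-driven. A prescribed-CO₂ run diagnoses the net
emission each step as the atmospheric increment not supplied by the
ocean and land fluxes; the step-resolution series is retained, so the
emission-driven rerun reproduces the prescribed trajectory to round-off
(the <1 ppm contract holds with enormous margin), while the exported
CSV is annual. Diagnosed emissions are plausible: ~35 GtCO₂/yr in the
2010s on the mid pathway.

## 6. Spinup

Stage 1 integrates the ocean closed (no weathering/burial, atmosphere
fixed at 278 ppm) for up to 2500 yr; the burial implied by the final
deep saturation state becomes the imposed weathering flux. Stage 2
opens the system for 500 yr, then finishes with a direct Newton solve
for the tracer fixed point of the 50-yr map (total phosphate
constrained, since it is conserved and would otherwise make the
Jacobian singular). The solve replaces the literal multi-millennial
integration of the carbonate-compensation adjustment at an identical
fixed point. The restart state is stationary to solver precision:
diagnosed steady-state emissions ~2e-10 GtCO₂/yr (contract: < 0.05) and
atmospheric drift ~1e-9 ppm over a free 535-yr control (contract:
< 1 ppm).

## 7. Interventions and accounting

Both modes deploy at a constant rate (default 10 GtCO₂/yr) from 2030.
Baseline subtracts the rate from control emissions (they may go
negative — that is the point). ERW removes the same CO₂ from the
well-mixed atmosphere and instantaneously delivers DIC + ALK to the
surface ocean at the feedstock stoichiometry — silicate (1, 1),
carbonate (2, 2, one mol rock-derived) per mol CO₂ — routed by
configurable surface-box weights (default: all to the low-latitude box,
the reduced analogue of river delivery; there is no coastline to
concentrate into). Weathering kinetics, soil transit, and
transport-path losses are out of scope. Every run audits whole-system
carbon and alkalinity budgets to 1e-6 relative (they close to
round-off) and aborts on breach.

Metrics integrate annual-mean fluxes from the start year through the
stated year inclusive ("end of the century" = through 2100); η, p,
p_leak and storage efficiency are as defined in the README. The
saturation co-benefit is the area-weighted mean surface Ω_arg change of
the ERW and baseline runs versus control (evaluated at 2070 in the
reference analysis). Ensemble results are summarized by the median with
a central-68% envelope and the standard deviation (reported side by
side, since "±" conventions differ).

## 8. Ensemble construction

The six slab parameters are drawn from broad priors — N₀ ∈ [30, 80]
GtC/yr, B ∈ [0.2, 1.0], Λ_veg ∈ [0, 0.012] yr/GtC, Λ₀ ∈ [3, 45] yr,
Γ ∈ [0.008, 0.12] yr⁻¹ (log-uniform), Q₁₀ ∈ [1.3, 4.5] — and filtered
in two stages. Stage 1 (offline, standalone slab driven by
concentration-forced climate): the modern (2005–2015 mean) soil stock
must lie in 1200–2000 GtC, NPP in 45–65 GtC/yr, vegetation turnover in
8–25 yr (textbook modern windows), and the 2015→2100 changes under the
low and high scenarios must fall in ΔV ∈ [−25, 400] and
ΔS ∈ [−250, 150] GtC, envelopes spanning CMIP5-class projections under
strong forcing. Stage 2 re-applies the same windows to the coupled
control run of each survivor. The joint stage-1 acceptance fraction is
~3.6e-3 with these defaults. Desk-scale reference sizes: 3e4 prior
draws, ≤130 coupled members (~109 survive); ensemble medians of the
leakage metrics are stable to ~0.1 pp at this size, the baseline
backflux median to ~1 pp. Seeds fix membership bit-reproducibly.

## 9. What the reduced model does and does not show

The reference analysis (seed 1) yields: baseline backflux ≈ 43% (low
scenario) and 25% (high) through 2100 at 10 GtCO₂/yr; silicate ERW
leakage ≈ 9.1% (carbonate ≈ 18.2%, ratio ≈ 2.0); silicate storage
efficiency ≈ 91%; surface Ω_arg co-benefit ratio (ERW vs direct
removal) ≈ 2.3. Storage efficiency evolves smoothly from ~87% early in
deployment to its ~91% plateau as delivered DIC is subducted below the
mixed layer — cumulative leakage stabilizes rapidly.

Known limitations:

* **Ω co-benefit magnitude.** The ERW-vs-control increase in global-mean
  surface Ω_arg is ~10% here. A spatially resolved ocean concentrates
  river-routed alkalinity in coastal surface waters and yields roughly
  double that; a single low-latitude box dilutes the same delivery over
  85% of the ocean surface and flushes it to depth on a ~12-yr
  residence time. The *relative* statement (ERW impact more than twice
  direct removal's) is robust; the absolute global-mean increase is
  structurally understated.
* Backflux at very large mitigation rates on low/mid pathways leaves
  the regime where responses scale linearly (a 40 GtCO₂/yr sweep is
  meaningful only against high-emission controls).
* No sea ice, salinity dynamics, regional fields, nutrient co-limitation,
  land use, or sediment diagenesis beyond the first-order burial closure;
  the biological pump and remineralization partition are fixed closures
  calibrated for a realistic preindustrial state, not emergent.
* The synthetic pathways are idealized: results are properties of the
  scenario *shapes* (peak-decline / stabilization / rise), not of any
  specific published table.

## 10. Numerical choices

dt = 0.1 yr throughout (transport bound ≈ 8 yr; mixed-layer gas
exchange, the fastest process, has an e-folding of ~1.5 yr; the slab's
fastest timescale is Λ₀ ≥ 3 yr). Carbonate solves warm-start from the
previous step's pH (1–2 Newton iterations each). Ledger convention:
fluxes are annual means (positive into the atmosphere), states are
start-of-year snapshots; time integrals are cumulative sums of annual
means from the start year through the end year inclusive. Degenerate
inputs: zero-DIC speciation returns zero carbon species; nutrient
uptake and slab pools clip at zero with a log record; unknown
feedstocks, minerals, modes and non-bracketed alkalinity raise typed
errors carrying the offending inputs.
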