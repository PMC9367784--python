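# Methods

## Scope and system boundary

The package computes the annual CO₂, CH₄ and N₂O emissions (aggregated
to CO₂-equivalent with 100-year GWPs) of a beef-cattle herd together
with the corn-planting system that feeds it, for two breeding models:

* **EC (ecological cycle)**: whole-plant silage corn is grown and
  processed into feed on-farm, all manure returns to the field, straw is
  fully utilized (no open burning). Processes: corn planting,
  N-fertilizer application, manure application, feed production, enteric
  fermentation, manure management.
* **non-EC (conventional)**: common corn grain is fed, 45% of manure
  re-enters the planting system, and 85.75% of corn straw is open-burned
  (9.88% is feed; the remaining ~4% of minor fates is neglected).
  Processes: as above, with straw burning replacing feed production.

Irrigation, transport, energy use, upstream fertilizer manufacture,
soil-carbon stock change and liming/urea CO₂ are outside the boundary.
Every process is a Tier-1 product of activity data and an emission
factor; there is no cohort structure and no feed-dependent (gross-energy)
enteric model.

## Units and conventions

The canonical internal unit is **kg·a⁻¹** for every mass. The reporting
unit 10⁷ t·a⁻¹ (= 10¹⁰ kg·a⁻¹) and the 2-decimal display rounding
(half away from zero) exist only in the report writer; computation is
never rounded. The N₂O-N → N₂O conversion is the exact ratio 44/28,
kept as a division, never a decimal approximation. Default factors
(coefficient table): corn planting 1.50 t CO₂·t⁻¹; feed processing
0.0102 t·t⁻¹; soil N₂O-N direct 0.0105, deposition-indirect 0.01,
leaching-indirect 0.0075 t·t⁻¹ with loss fractions F_GAS = 0.1 (fertilizer)
/ 0.2 (applied manure) and F_L = 0.25; burning factors 1.39 / 2.19×10⁻³ /
7×10⁻⁵ kg·kg⁻¹ with combustion factor G = 0.1; enteric CH₄
65 kg·head⁻¹·a⁻¹; VS rates 6.8 / 10.8 and managed shares 0.28 / 0.29
with CH₄ factors 1.05 / 2.05 kg·kg⁻¹ VS and direct N₂O factors 0.005 /
0.01 (EC / non-EC); N excretion 0.41 kg·(1000 kg)⁻¹·d⁻¹ at 319 kg live
weight; GWP CH₄ = 28, N₂O = 265.

## Straw balance: two totals

The conventional scenario's total straw can be read two ways from the
published mass balance, and both are needed:

* the **normalized total** rescales the two retained fates to sum to 1:
  `feed_demand × (0.0988 + 0.8575)/0.0988 = 31.80 × 10¹⁰ kg` — this is
  the printed total straw requirement and drives corn-planting CO₂;
* the **feed-share total** `feed_demand / 0.0988 = 33.25 × 10¹⁰ kg` is
  the gross straw production — the printed straw-burning cells are
  reproducible only from this one.

`StrawBalance` carries both, and each consumer names which it uses; the
inconsistency is inherent to the source tables, not resolvable from the
inputs.

## Replication vs corrected mode

The published tables contain two cells that cannot be derived from the
published inputs; the package exposes both readings instead of hiding
the gap:

1. **EC N-fertilizer N₂O**: the coefficient-table inputs give
   0.158 × 10⁷ t·a⁻¹, the table prints 0.21 × 10⁷ t·a⁻¹. No tested
   parameter combination reconciles them. The EC fixture therefore
   carries an *as-printed override* (0.21 × 10⁷ t = 2.1 × 10⁹ kg);
   replication mode reports the override (flagged `overridden` in every
   output), corrected mode reports the formula value.
2. **Manure application N₂O**: the printed cells (49.53 t EC, 22.29 t
   non-EC) are reproducible only when the applied "N" is the per-head
   annual manure mass (8030 kg — not herd-scaled, and a manure mass
   rather than an N mass) times the return rate, converted with a 273
   N₂O potential rather than the stated 265. Replication mode encodes
   exactly that; corrected mode uses herd-scale N excretion
   (10⁷ × 47.74 kg N × return rate) with GWP 265, giving ~0.29 × 10⁷ t
   for EC — four orders of magnitude above the printed cell. An empty
   herd yields zero in both modes.

Related data notes: the coefficient table prints a daily manure mass of
22.67 kg·d⁻¹ whose annual equivalent (8274.55 kg) contradicts the same
source's annual figure 8030.00 kg; the fixtures set 22.0 kg·d⁻¹ so the
annual mass — the only quantity used downstream — is exact. The
planting areas (9.01 × 10⁵ and 70.66 × 10⁵ hm²) are scenario inputs:
the published per-area straw yields do not reconcile with them under
any unit reading, so no attempt is made to derive one from the other.
The N-fertilizer nitrogen input has no published defining equation and
is reconstructed as `area × application_rate × (straight-N share +
compound share × compound N content)`, which reproduces the printed
non-EC cell to 3 significant figures. The straw-burning CH₄ cell prints
0.18 × 10⁷ t where the formula gives 0.175; the package keeps the
arithmetic value and treats the print as rounding.

The published industry percentages treat straw burning as a category
outside both industries; this package assigns it to the planting
industry so that industry subtotals conserve the total.

## Sensitivity and uncertainty

The inventory is a sum of products, so each output is linear in every
single parameter; the one-at-a-time central-difference elasticity
(ΔE/E)/(Δp/p) then equals the perturbed term's share of the output,
which the tests verify against the report's own shares. Monte Carlo
uses plain independent sampling (no Latin hypercube, for auditability)
with a seeded generator; identical inputs give bit-identical summaries
(mean, SD, 2.5/50/97.5 percentiles). The default perturbation set puts
±20% uniform bands on every emission factor — the source names factor
choice and GWP vintage as its uncertainty drivers but gives no
distributions, so a symmetric band of the typical Tier-1 factor spread
is used — plus the published roughage-intake range 8–10 kg·head⁻¹·d⁻¹
for conventional scenarios. The silage intake (20 kg·head⁻¹·d⁻¹) and
the concentrate ration (2.5–6.5 kg·head⁻¹·d⁻¹) have no corresponding
perturbable parameter: the former has no published range, the latter is
excluded from the scenario difference by construction. GWPs are
perturbable parameters like any other (`gwp.gwp_ch4`, `gwp.gwp_n2o`).

## Synthetic scenarios

The generator samples structurally valid scenarios from closed
intervals anchored at the published values (±20% bands; published
ranges where they exist; herd size log-uniform between 10⁴ and 10⁷ so
linearity is exercised across scales). It starts from the published
fixture and replaces only sampled fields, so pinning every interval to
a point reproduces the fixture — and its inventory — exactly; the
generator is a strict superset of the fixtures. Generated non-EC
scenarios keep the two retained straw fates summing to 0.9563 unless
the burn fraction is sampled explicitly. What the generator does *not*
emulate: covariance between parameters (intake vs weight, factor
correlations), seasonal or cohort structure, and measurement noise in
activity data — passing tests therefore demonstrate arithmetic and
structural correctness of the pipeline, not calibration to any real
region's statistics.

## Numerical choices and problem sizes

All arithmetic is double precision on quantities ≤ 10¹² kg, far from
any loss of significance; no tolerance tuning is needed beyond the
display-rounding bounds used when comparing to printed values (a
printed 2-decimal cell carries ±0.005 × 10⁷ t of rounding; printed
per-gas rows were computed in the source from already-rounded cells and
accumulate k × 0.005 for k components). Degenerate scenarios (herd 0,
area 0) are legal and produce all-zero inventories. Monte-Carlo checks
use n = 2000 draws (standard error ≈ 0.06% of the mean for a ±10%
uniform band), property suites use 100 seeded draws; the deterministic
inventory itself is microseconds, so the full suite runs in seconds.

## Known limitations

Tier-1 throughout; no per-kg-beef functional unit (absolute annual
totals only); no spatial disaggregation; both scenarios share one
enteric factor even though silage diets plausibly lower enteric CH₄ —
the source's own discussion argues this but its method applies equal
factors, and the package follows the method.
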