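# Methods

## Problem and model

Administrative hospital-insurance claims do not map one-to-one onto disease
events. Under the Korean National Health Insurance (NHI) system, hospitals
bill inpatient care monthly, so one long acute-myocardial-infarction (AMI)
hospitalization generates several claims; transfers between hospitals and
early readmissions fragment an episode further. Counting claims therefore
overstates admissions. This package implements the standard
claims-to-episodes reduction for AMI:

1. **Case definition.** A claim qualifies when its primary or any secondary
   ICD-10 diagnosis starts with `I21`. Codes `I22`–`I25` (subsequent MI,
   post-MI complications, other ischaemic heart disease) do not qualify a
   claim. Prefix matching is dot- and case-insensitive (`I210` ≡ `I21.0`),
   since both dialects occur in claims extracts.
2. **Episode merging.** Per patient, qualifying claims are sorted by
   (admission date, discharge date, claim id) and scanned; a claim joins the
   current episode when, against the anchor claim, at least one of three
   conditions holds:
   - **C1** — its admission is within `admission_window_days` (default 28)
     of the anchor's admission;
   - **C2** — its admission is within `discharge_window_days` (default 3)
     of the anchor's discharge;
   - **C3** — its own length of stay is under `short_stay_days` (default 3).
3. **Attribution.** Each episode takes year, sex, age and (by default) the
   emergency-department flag from its index claim; the invasive-procedure
   flag (coronary angiography, angioplasty or bypass) is true when any
   member claim carries a configured procedure code.
4. **Tabulation.** Episode counts by calendar year, sex and ten-year age
   band, with ED and invasive proportions and binomial 95% confidence
   intervals, plus yearly trend series.

## Decisions where the algorithm statement is open

The three-condition rule leaves several details unstated; each is a
configurable decision with the following defaults:

- **Anchor.** "Adjacent claims" is read as *consecutive in sorted order*
  (rolling anchor), so merges chain transitively: claims 28 days apart in a
  long chain stay one episode. `MergeRule(anchor="index")` re-anchors C1 to
  the episode's first claim, which caps episode growth.
- **Inclusivity.** "Within N days" is read inclusively (a gap of exactly 28
  days fires C1; exactly 3 days fires C2).
- **Negative gaps.** C2 accepts a second admission *before* the first
  discharge, so overlapping claims from two hospitals (a transfer) merge.
- **LOS convention.** Length of stay is discharge − admission in whole days
  (same-day discharge = 0), so "LOS < 3" means stays of 0–2 nights.
  `los_counts_both_ends=True` switches to discharge − admission + 1.
- **C3 is literal.** A short second claim merges *regardless of the time
  gap*, because the rule is a disjunction. This is the rule's sharpest edge:
  it can merge a 1-day admission six months after the previous one into the
  same episode. The stress generator quantifies this.
- **Mixed code sets.** A claim carrying both `I21` and `I22`–`I25` codes is
  included by default — the exclusion list is read as "these codes do not
  qualify a claim", not "their presence disqualifies one", since those codes
  mark sequelae that can legitimately co-occur with an acute code.
  `CaseDefinition(strict_exclusion=True)` drops such claims instead.
- **Ties and conflicts.** Identical admission dates break by earlier
  discharge, then claim id. Sex/age conflicts within an episode resolve to
  the index claim with a warning log line. Episodes spanning a year
  boundary belong to the index admission's year.

## Confidence intervals

The published year-by-sex table prints "% (95% CI)" without naming a
method. The Wald normal approximation, p ± z·sqrt(p(1−p)/n) with
z = Φ⁻¹(0.975) ≈ 1.959964, reproduces **all 30** printed triples exactly
after rounding, so it is the default engine; Wilson score intervals
(via statsmodels) are available with `method="wilson"`. Display values are
percentages rounded **half-up** to one decimal; a 9-decimal pre-quantize
absorbs binary float error at exact midpoints. Bounds are clipped to
[0, 1], so degenerate proportions (0/n, n/n) give zero-width Wald
intervals. Internally all proportions are kept at full precision. Episodes
with an unknown admission route (≈2.4% of admissions in the source data)
stay in every denominator and count as non-ED, matching how the published
totals retain them.

## Synthetic claims generator

Real NHI claims are not public, so the generator plants episodes with known
labels and fragments them by the three documented mechanisms:

- `monthly_split` — a stay crossing a calendar-month boundary is cut at
  month ends into claims abutting within the discharge window (billing is
  monthly; the inter-claim gap defaults to 1 day);
- `transfer` — two overlapping claims from distinct provider ids, the
  second admitted on the first's discharge day;
- `early_readmission` — a second claim admitted within the 28-day window of
  the first admission;
- `none` — a single claim.

Defaults emulate the published study's marginals: study window 2007-01-01
to 2011-12-31; 56.3% male; age bands drawn from the published pooled
age distribution of episodes; ED probability 56.7% (male) / 49.2% (female);
invasive probability 35.1% / 17.9%; 2.4% of routes missing. Values the
source tables do not determine were fixed once at structurally plausible
levels: episodes per patient categorical {1: 0.70, 2: 0.22, 3: 0.08}
(most patients contribute one episode over five years), a total-stay
distribution over 0–60 days with median ~5 days and a long-stay tail that
exercises the monthly split, and a fragmentation mix of 55% none / 20%
monthly split / 10% transfer / 15% early readmission.

**Separation guarantee.** With `guarantee_separation=True`, consecutive
planted episodes of a patient are placed so that *no* condition can fire
across the boundary: the next index admission is more than 28 days past the
previous episode's last admission (defeats C1) and more than 3 days past
its final discharge (defeats C2), and the next episode's index claim stays
at least `short_stay_days` (defeats C3 — if fragmentation would produce a
shorter index fragment, that episode is kept as a single claim). Under
these constraints the builder provably returns the planted partition, and
the recovery tests confirm it exactly over many seeds. `stress_generate`
relaxes the constraints with probability `p_separation_violation` per
boundary, which the sensitivity analysis uses to show the undercount bias
when true episodes fall inside the windows. The route intent applies to the
index claim and the planted ED label is recorded *after* missingness, so
planted labels always equal what a correct builder attributes.

What the generator does **not** emulate: non-AMI claims mixed into the
stream (selection is tested on hand-built claims instead), miscoded
patient ids, real Korean incidence or seasonality, provider-level billing
idiosyncrasies, and age/sex-dependent lengths of stay. Passing recovery
tests therefore validate the algorithm's logic, not the clinical accuracy
of the 28/3/3 windows on real data — the latter would need chart review.

## Verification design

- **Oracle equivalence.** An independent union-find implementation builds
  episodes as connected components over consecutive-pair merge edges. The
  scan and the oracle are compared on an exhaustive grid of 3-claim
  configurations — inter-claim admission gaps {0, 1, 2, 3, 4, 27, 28, 29,
  50} × stays {0, 1, 2, 3, 4, 10}, chosen to cover both sides of every
  inequality boundary of C1–C3 (17,496 configurations) — and on 1,000
  random patients with up to 6 claims, plus a derandomized property test.
- **Published-table replay.** The printed tables are inputs: the CI engine
  must recover every printed "% (95% CI)" triple from its printed counts,
  the overall proportions (53.4% ED, 27.6% invasive of 295,001 episodes)
  are recomputed through the tabulation path on count-expanded frames, and
  the claims-to-episodes identity 180,597 + 114,404 = 295,001 is checked.
- **Invariants.** Conservation (every claim in exactly one episode), order
  invariance, idempotent selection, monotonicity of the episode count in
  each window threshold, and CI width monotone in the denominator.

Problem sizes (3,000 patients in the analysis drivers, 200 patients × 50
seeds for recovery, 1,000 random oracle patients) keep every driver and the
full test suite in the seconds range while leaving all code paths covered.

## Known limitations

- Episodes truncated by the study window edges are kept as observed; no
  boundary correction.
- Patient identifiers are assumed exact; no probabilistic linkage.
- Diagnosis codes are matched by prefix only, with no validation against an
  official ICD-10 code list.
- The generator's procedure codes (`CAG01`, `PCI01`, `CABG1`) are synthetic
  placeholders; real extracts require configuring the local fee-code lists.
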