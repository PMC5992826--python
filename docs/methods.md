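# Methods

`crcscreen` implements a deterministic Markov cohort model of colorectal
cancer (CRC) natural history, screening, and treatment in a
lower-middle-income setting, and the cost-effectiveness machinery around
it. This note records the model, the conventions the package fixes where
several were defensible, and what the shipped synthetic inputs do and do
not represent.

## The cohort model

A closed cohort of average-risk 50-year-olds is followed in 1-year cycles
to age 100. Public health states: normal mucosa; low-risk adenomatous
polyp (< 1 cm); high-risk polyp (> 1 cm); preclinical (undiagnosed) cancer
in localized, regional, or disseminated stage; clinical (diagnosed) cancer
in the same three stages; post-treatment surveillance; death from CRC;
death from other causes.

Disease progresses along the adenoma–carcinoma sequence. Annual
probabilities (base case): normal → low-risk polyp is age-interpolated
(0.00836 at 50 rising to 0.01521 at 70, linear between anchors, constant
outside); low → high 0.036; high → preclinical-localized 0.042;
preclinical localized → regional 0.17 and → clinical 0.17; preclinical
regional → distant 0.10 and → clinical 0.21; preclinical disseminated
surfaces clinically with probability 1. Where a preclinical state has two
simultaneous exits they are treated as independent competing events with
joint occurrence resolved in favor of clinical presentation, so e.g.
preclinical-localized moves to clinical with probability 0.17 and silently
to regional with 0.17 × (1 − 0.17).

The cohort enters at 50 with prevalent disease: 20 % low-risk polyps, 5 %
high-risk polyps, and 0.24 / 0.12 / 0.04 % preclinical cancer by stage.

**Cancer mortality.** Treated 5-year mortality is 0.10 / 0.35 / 0.92 by
stage, converted to an annual probability under a constant hazard
(1 − (1 − p₅)^(1/5)) and applied for five cycles after diagnosis — the
diagnosis year plus four aged "tunnel" sub-states — after which
local/regional survivors carry no excess cancer mortality in long-term
surveillance. Disseminated patients stay in the clinical disseminated
state until death. Patients who do not receive treatment (relevant only
when treatment receipt < 1) are assigned the annualized mortality of the
next-worse stage; untreated disseminated disease compresses its 5-year
mortality into 4 years. Internally the diagnosed compartments are split
by detection route (clinical presentation vs screen detection): by default
screen-detected patients are always treated — a screening program carries
its cases into care — so reduced treatment receipt acts on clinically
presenting disease. With full receipt the routes are identical, and the
base case is unaffected by the split.

**Background mortality** competes with everything: the life-table qx for
the current age is applied first and the disease kernel acts on the
surviving fraction. Accounting is cycle-start with no half-cycle
correction; at the terminal age the residual cohort is closed out to
death from other causes. These conventions are fixed so that results are
reproducible bit for bit.

## Screening

Three programs run from age 50 through 75: FOBT annually; FOBT annually
plus flexible sigmoidoscopy every 5 years; colonoscopy every 10 years
(offers at 50/60/70). Screening happens at cycle start, before that
cycle's transitions, so it finds prevalent lesions.

Test positivity: FOBT sensitivity 0.03 / 0.34 / 0.72 for low-risk polyps,
high-risk polyps, and cancer, specificity 0.91 (so 9 % of healthy
attenders test false-positive each round); colonoscopy sensitivity
0.92 / 0.97 / 0.93 with perfect specificity; sigmoidoscopy uses the
colonoscopy sensitivities times (1 − 0.21), the probability that a
neoplasm lies within reach of the scope. A positive FOBT or sigmoidoscopy
leads to confirmatory colonoscopy with probability 0.84. Only colonoscopy
removes polyps (returning the individual to normal mucosa) or diagnoses
preclinical cancer, which enters the clinical state at its current stage —
early detection is a stage freeze, the model's entire benefit mechanism,
along with cancer prevention through polypectomy. Each colonoscopy
carries a 0.0008 perforation risk (treated at $500) and a 0.012 death
risk given perforation; perforation deaths are booked as other-cause
deaths. In years where FOBT and sigmoidoscopy coincide they form one
combined visit with a single participation draw; either test positive
triggers confirmation.

**Adherence** is a persistent attender/never-attender split: the
modality's adherence (0.75 FOBT, 0.75 sigmoidoscopy+FOBT, 0.80
colonoscopy) is the fraction of the population that participates in every
offered round, and the remainder is never screened. The strategy outcome
is the mixture of an always-attending cohort and the no-screening cohort.
This choice is load-bearing. Under the alternative — an independent
participation draw at every offer — everyone is eventually screened, and
26 annual FOBT rounds at 45 % per-round detection inevitably out-detect
three colonoscopies, which inverts the ranking of the programs: an annual
stool test would beat a 10-yearly colonoscopy on mortality simply by
attrition. The persistent split reflects how screening programs behave
(a stable unreached fraction) and caps each program's mortality reduction
near its adherence, which is the regime in which a 10-yearly colonoscopy
at 80 % adherence beats annual FOBT at 75 %. The per-event convention
remains available via `adherence.adherence_mode = "per_event"`.
Confirmatory colonoscopy (0.84) is always per-event.

## Economics

Costs (2012 US$): colonoscopy 100, FOBT 8, sigmoidoscopy 20, perforation
treatment 500; treatment on entry into a clinical state — 500 localized
(surgery-only), 9,000 regional, 20,000 disseminated — charged once at
diagnosis, scaled by the treatment-receipt probability for clinically
presenting patients; surveillance 200/year during the post-diagnosis
tunnel years and long-term surveillance. Utilities: 1.0 for
healthy/polyp/preclinical states, 0.7 during clinical and tunnel years
for local/regional disease, 0.25 every year with clinical disseminated
disease, and 0.9 in long-term surveillance — the last has no published
value; 0.9 is this package's default and is configurable. Costs and
QALYs are discounted at 3 %/year to age 50. The willingness-to-pay
threshold is 3 × per-capita GDP ($3,900), i.e. $11,700/QALY.

The comparison applies strict dominance, then extended dominance (the
frontier is the lower-left convex hull of the cost–QALY scatter; a
strategy is extendedly dominated when its segment ICER exceeds the next
segment's), then ICERs against the next-best non-dominated comparator.
The preferred strategy at a WTP is the frontier strategy with the highest
ICER not exceeding it. Incremental columns are reported both against the
best strategy and sequentially along the frontier.

## Sensitivity machinery

Every parameter with a declared range can be swept one-way on an even
grid; age-indexed schedules are swept by one multiplicative factor on all
anchors, with the factor interval chosen as the intersection of the
per-anchor relative ranges so any admissible factor keeps every anchor
inside its printed range. The tornado evaluates each parameter at its
range endpoints (others at base case) and ranks by the span of the
net-monetary-benefit margin of 10-yearly colonoscopy over the best
alternative at the WTP threshold (an ICER metric is also available).
Threshold search bisects until the preferred strategy flips, to $1 for
costs and 0.005 for probabilities, and reports the bracket midpoint.
Multi-way analysis evaluates a full factorial grid (capped at 2,000
cells). The decreased-treatment-adherence scenario sets treatment
receipt to 0.75 — a quarter of clinically presenting patients go
untreated — and leaves everything else unchanged.

## Synthetic inputs

**Life table.** The model's background mortality is a national life
table, supplied as CSV (`age,qx`). The shipped default is synthetic: a
Gompertz–Makeham hazard μ(x) = a + b·e^(cx) discretized exactly
(qx = 1 − exp(−∫ μ over the year), so discrete survival equals the
continuous survival function at integer ages), with a = 7.98e-4,
b = 5.13e-5, c = 0.095 solved so that period life expectancy is ≈ 71
years at birth *and* ≈ 25 years at age 50 — the two published anchors for
the modeled population in 2013. The second anchor matters: this
population's adult survival is poor relative to its infant survival, and
calibrating to e0 alone leaves e50 near 27–32 years, far too optimistic.
The synthetic table reproduces those two moments only; it has no
age-specific structure beyond the Makeham form (no excess young-adult
male mortality, no sex stratification, no cohort effects).

**What passing tests show, and what they don't.** All structural results
— dominance of 10-yearly colonoscopy, the ordering and approximate size
of the mortality reductions, the adherence breakpoint near 0.66–0.69 —
are stable features of the model on any plausible life table, and the
test suite verifies them on the synthetic default. Absolute discounted
quantities are not: discounted QALYs are essentially discounted life
expectancy at 50 (17.3 years here), and the discounted cost of the
FOBT-containing programs scales with the number of screening years the
cohort lives to collect, so these quantities shift with the life table.
The published figures these checks compare against imply a discounted
life expectancy near 14.3 years — a markedly shorter-lived cohort than
the two demographic anchors produce. The replication checks on absolute
costs and QALYs (and the colonoscopy-cost breakpoint, which inherits the
FOBT-arm cost level) therefore fail on the synthetic table and are left
failing rather than re-tuning the table toward the outputs; the checks on
structure, mortality reductions, and the adherence breakpoint pass.

**Parameter sampling.** `sample_parameter_set` draws each ranged
parameter uniformly and independently within its interval, seeded and
reproducible — a utility for robustness harnesses, not a probabilistic
sensitivity analysis (no distributions beyond uniform, no correlation).

**Toy oracle.** A well → sick → dead chain with constant rates has
geometric-series closed forms for discounted occupancy; the engine's
accumulator is verified against them to 1e-9, and a 100,000-individual
Monte-Carlo microsimulation of the exact cohort kernel checks occupancy
and incidence within 3 binomial standard errors.

## Numerical conventions and degenerate inputs

Row stochasticity is enforced to 1e-12 on every kernel and 1e-9 along
traces; screening conserves probability mass except perforation deaths,
which move to other-cause death explicitly. Probabilities are validated
to [0, 1] on construction and after every override, with the offending
key named. Division-by-zero guards: mortality-reduction and WTP require
positive baselines; equal-effect ICERs are reported as cost comparisons,
never ratios; coincident strategies on the cost–QALY plane are co-optimal
rather than mutually dominating. The incidence denominator is the living
cohort at cycle start, scaled to 100,000 — the registry convention. The
first modeled year carries a pulse of prevalent preclinical cancer
(initial-prevalence artifact), so the incidence curve is guaranteed
nondecreasing only from age 51.

## Known limitations

No sex or risk-group stratification; no FIT/CT-colonography; no
post-polypectomy shortened surveillance intervals; adherence is binary
persistent rather than behaviorally modeled; untreated-cancer survival is
a policy assumption (next-worse-stage), not data; no probabilistic
sensitivity analysis; program set-up costs and indirect (societal) costs
are out of scope. Treatment costs are charged at diagnosis rather than
spread over therapy, which slightly overweights them under discounting.
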