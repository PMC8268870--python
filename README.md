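# parpsense

Rule-based prediction of PARP-inhibitor sensitivity for tumors carrying
**variants of unknown significance (VUS)** in homologous-recombination (HR)
genes (*BRCA1*, *BRCA2*, *PALB2*, *ATM*, *RAD51C*, *BRIP1*, ...).

PARP inhibitors (olaparib, niraparib, rucaparib) exploit synthetic lethality
with HR deficiency, but roughly 40% of HR-gene variants found by clinical
sequencing are VUS, which currently block prescription. `parpsense`
implements a desk-scale algorithm that classifies VUS-carrying patients as
PARP-inhibitor **Sensitive (S)**, **Resistant (R)** or **Uncertain (U)**
from data already present in a routine NGS report, and validates such
predictions against progression-free survival (PFS).

## The algorithm

**Second-hit (LOH) score.** HR genes are tumor suppressors: both alleles
must be lost. With tumor purity *p* (pathologist estimate) and a diploid
model, a heterozygous somatic variant has expected allele frequency
VAF = *p*/2, so the score

> *s* = VAF / *p*

equals 0.5 when the wild-type allele is retained and rises toward
1/(2−*p*) ≥ 0.7 (for *p* ≳ 0.57) when it is lost. Scores ≥ 0.7 fall in the
*green* zone — putative loss of the wild-type allele, call **D**; scores
below are *red*, call **B**; missing inputs give **U**.

**Per-variant verdict (two evidence models).** A VUS is *deleterious*
under a model as soon as either the second-hit call or the model's
in-silico call (PROVEAN ≤ −2.5 → D, or DANN ≥ 0.96 → D, when only raw
scores are available) is D; *benign* when both are B; *unknown* otherwise.

**Patient label and consensus.** Under each model a patient is S when any
of their VUS is deleterious — unless ECOG Performance Status ≥ 3, which
forces R (PS 3 patients progress before the drug can act). The final label
is the consensus of the PROVEAN-based and DANN-based models; disagreement
gives U. A decision tree routes non-VUS patients directly: known
pathogenic → treat; benign only → do not expect an HRD-type response.

**Validation.** Kaplan–Meier PFS curves and Mantel–Cox log-rank tests,
with clinical benefit defined as PFS strictly greater than 120 days.

The two published study cohorts ship as packaged fixtures: the 41-patient
olaparib cohort (`table2`, of which the 12 VUS-only patients form
`table3`) and the 8-patient niraparib VUS cohort (`table5`).

## Worked example

```sh
parpsense classify --fixture table3
```

```
patient_id            provean_model  dann_model  final  decision
Ovarian #2            S              S           S      treat_parpi_sensitive
Ovarian #6            S              S           S      treat_parpi_sensitive
Ovarian #20           S              S           S      treat_parpi_sensitive
Ovarian #23           S              R           U      treat_uncertain
Breast #6             S              S           S      treat_parpi_sensitive
Breast #8             S              S           S      treat_parpi_sensitive
Digestive tract #1    R              R           R      do_not_expect_hrd_response
Digestive tract #2    R              R           R      do_not_expect_hrd_response
Digestive tract #5    R              R           R      do_not_expect_hrd_response
Digestive tract #6    R              R           R      do_not_expect_hrd_response
Digestive tract #7    R              R           R      do_not_expect_hrd_response
Skin #1               S              S           S      treat_parpi_sensitive
```

Six patients are Sensitive, five Resistant, one Uncertain (the two models
disagree on Ovarian #23). Every Sensitive patient's PFS exceeds 120 days
and every Resistant patient's falls short of it, which the survival
subcommand confirms:

```sh
parpsense survival --fixture table3 --group-by-benefit
```

```json
{"n": 12, "events": 12, "median_days": 93.0,
 "logrank": {"chi_square": 12.23, "p_value": 0.00047}}
```

i.e. splitting the 12 patients at the 120-day benefit threshold separates
the PFS curves (log-rank p ≈ 5 × 10⁻⁴); the cohort's overall median PFS is
93 days.

The same API is available from Python:

```python
from parpsense import load_fixture, classify_consensus, expected_het_vaf

expected_het_vaf(0.60)          # 0.30 — het VAF expected at 60% purity
cohort = load_fixture("table3")
res = classify_consensus(cohort.cases[0])
res.final_label                 # 'S'
res.rationale                   # per-variant evidence trace
```

Other subcommands: `parpsense loh-table` (the green/red LOH decision grid
as TSV), `parpsense simulate --seed N` (synthetic cohort with ground
truth), `parpsense fixtures table2` (dump a packaged cohort), and
`parpsense classify --patients your_patients.tsv --variants your_variants.tsv`
for your own data (TSV schema documented in `parpsense.io`; VAFs can also
be pulled from a VCF with `--vcf`).

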