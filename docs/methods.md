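# Methods

## Problem setting

Clinical panel/exome sequencing of tumors reports, per variant, a gene, an
HGVS description, a curated pathogenicity class, a variant allele
frequency (VAF), and — from the pathology report — the tumor cell content
(purity) of the specimen. For homologous-recombination (HR) genes, a large
fraction of observed variants are of unknown significance (VUS), which
blocks PARP-inhibitor prescription. `parpsense` turns those quantities,
plus two in-silico pathogenicity predictors, into a patient-level
Sensitive / Resistant / Uncertain call, and provides the survival
machinery to validate such calls against progression-free survival (PFS).

## Second-hit model

Assumptions: the specimen is a two-population mixture of diploid tumor
cells (fraction *p*, the purity) and diploid normal cells; the variant is
heterozygous where present; copy number at the locus is 2 except for the
single event of interest, loss of the remaining wild-type allele in tumor
cells (which leaves one allele per tumor cell).

Counting alleles over the mixture gives the expected VAF per state:

| state                   | VAF        | score = VAF/p |
|-------------------------|------------|---------------|
| somatic het, no loss    | p/2        | 0.5           |
| somatic het, WT loss    | p/(2−p)    | 1/(2−p)       |
| germline het, no loss   | 1/2        | 1/(2p)        |
| germline het, WT loss   | 1/(2−p)    | 1/((2−p)p)    |

The score `second_hit_score(vaf, purity) = vaf / purity` is therefore 0.5
at the heterozygous-no-loss baseline independent of purity, and the loss
states exceed 0.7 once p ≥ 2 − 1/0.7 ≈ 0.571. The published per-variant
scores this package reproduces are consistent with exactly this ratio
(all ten red-zone scores ≤ 0.66, all six green-zone scores ≥ 0.72, values
above 1 arising naturally from germline loss states), but the original
computation was never printed; the formula is a reconstruction and is
documented as such in `second_hit.py`.

**Threshold.** The printed scores leave the gap (0.66, 0.72]. The default
boundary is 0.7, ties resolved upward (score ≥ 0.7 → green/D). It is
exposed as a parameter (`RunConfig.second_hit_threshold`, CLI
`--second-hit-threshold`). Scores above 2 cannot arise under any diploid
state and are flagged implausible in the rendered grid. Missing VAF or
purity yields the call U. Purity inputs above 1 are interpreted as
percentages with a warning.

**Known confounders.** The ratio cannot distinguish wild-type loss from
amplification of the variant allele, and an *unlost* germline
heterozygote already scores 1/(2p) > 0.7 whenever p < 0.71. Zygosity is
treated as unknown; copy-number-aware LOH calling is out of scope.

## In-silico evidence

PROVEAN (alignment-based; more negative = more damaging) and DANN (neural
network; [0,1], higher = more damaging) are consumed, never computed. A
categorical B/D/U call from an annotation front-end always takes
precedence; raw scores are thresholded at PROVEAN ≤ −2.5 and DANN ≥ 0.96
(the tools' customary operating points; both configurable — the packaged
cohorts carry categorical calls, so nothing downstream depends on these
defaults). Variants the tools cannot score (start-loss, frameshift,
splice) resolve to U, as do stray out-of-vocabulary symbols that
occasionally appear in annotation exports (carried verbatim on the
record, treated as U at resolution).

## Classification rules

Per model (PROVEAN-based or DANN-based), per VUS: **deleterious** iff
second-hit = D or the in-silico call = D; **benign** iff both = B;
**unknown** otherwise. Unknown evidence never argues for sensitivity —
this is the conservative direction for a treatment recommendation.

Per patient: any-variant-deleterious aggregation (a single inactivated HR
gene suffices for PARP-inhibitor synthetic lethality), gated by ECOG
Performance Status: PS ≥ 3 forces Resistant in both models, reflecting
that poor-PS patients progress before the drug can act. The gate applies
only within the VUS algorithm; routing of known-pathogenic patients
ignores PS unless `gate_known_pathogenic` is set. When PS was never
recorded the gate cannot fire (PS is optional in the data model precisely
because historical cohorts often lack it for non-VUS patients).

Final label: consensus of the two models — agreement gives S or R,
disagreement gives U. U is deliberately preserved rather than forced to
either side; the decision tree maps S/R/U to
treat / do-not-expect-HRD-response / uncertain, with known pathogenic and
benign-only patients routed before the VUS algorithm runs.

## Survival analysis

Kaplan–Meier estimation and the two-sample Mantel–Cox log-rank test are
delegated to `lifelines`; the module adds the package's conventions:
median = smallest event time with S(t) ≤ 0.5 (undefined when the curve
never falls that far); events precede censorings at tied times; clinical
benefit = PFS **strictly** greater than 120 days (a PFS of exactly 120
days is not benefit). The concordance report cross-tabulates predicted
labels against the benefit flag and lists discordant patients; U
predictions are tallied as "uncertain", never as hits or misses.

The packaged olaparib cohort encodes censoring as: treatment-ongoing
annotations → censored; the day-1 stop for an allergic reaction →
censored (toxicity, not progression); every other row → event. Published
*group-level* median-PFS figures for that cohort are internally
inconsistent with the published per-patient PFS values under any standard
convention, so no test or target anchors on them; per-patient values are
used throughout.

## Synthetic-cohort generator

`simulate_cohort` emulates the cohort structure the classifier assumes,
with every patient carrying one variant: true class drawn from
benign / VUS-benign / VUS-deleterious / pathogenic; purity uniform on a
range; loss of the wild-type allele with a set probability for truly
deleterious variants; true VAF from the allele-count table above;
observed VAF ~ Binomial(depth, VAF)/depth; in-silico calls correct for
the true class except for an independent per-tool flip; PFS exponential
with a class-dependent median, shortened for PS ≥ 3, with random
censoring. A single seeded NumPy generator drives everything; identical
configs give identical cohorts.

Defaults describe the study conditions: 60 patients (the pooled
ovarian-cancer PARP-inhibitor cohort size), class mix
0.10/0.15/0.15/0.60 (the 3:12:26 olaparib census, with the VUS split
evenly between truly benign and truly deleterious, matching the 6/6
outcome split), purity 0.6–0.9 (typical FFPE specimens), read depth 100
(panel coverage of 80–100×), PS distribution 0.10/0.55/0.15/0.20/0
(the VUS cohort's 1/7/2/2), PFS medians 81 days for benign-behaving and
190 days for deleterious-behaving classes (the published group medians),
10% censoring, somatic zygosity, loss probability 0.8, flip rate 0.1.

What the generator does *not* emulate: multi-variant patients, subclonal
variants, copy-number change beyond single-allele loss, non-exponential
PFS, informative censoring, and correlated tool errors. Passing recovery
tests therefore demonstrate the pipeline's internal consistency — e.g.
sensitivity = specificity = 1 in the noiseless limit, and ≈ 0.25 each
when both tools are coin flips and there is no LOH signal (consensus then
requires two independent coins to agree) — not clinical performance.

`recovery_experiment` reports sensitivity/specificity of the final label
against the simulated truth (U counts as a miss) and the S-vs-R log-rank
p-value. Problem sizes in the test suite (cohorts of 60–1000, read depths
up to 10⁶, 20 log-rank replicates, 1500–3000 permutation draws) were
chosen to keep Monte-Carlo error well inside the asserted tolerances
while the full suite runs in about two minutes.

## Numerical and interface choices

- TSV cohort schema: UTF-8, header row, two files (patients, variants);
  HGVS strings verbatim, never normalized or validated. VCF ingestion
  (per-sample AF, else AD) overlays VAFs onto the variant table.
- Re-treatment episodes are distinct cases with distinct ids; variants
  are kept as an ordered list, never deduplicated; all patient-level
  outputs are invariant to variant order (tested).
- `second_hit_call` on exactly the threshold returns D; the permutation
  log-rank reference uses ≥ observed − 1e−12 to avoid float-tie
  undercounting; KM curves store censor times separately so an
  all-censored cohort yields S ≡ 1 with undefined median.
- The CLI is a thin wrapper over the library; outputs carry a version +
  parameter header and are byte-identical across repeated runs on the
  same inputs (no timestamps).

## Limitations

The clinical evidence base is 20 patients across both VUS cohorts; the
algorithm is a hypothesis-generating rule set, not a validated clinical
device. The second-hit formula is a reconstruction (see above). Cutoffs
(0.7, −2.5, 0.96, PS 3, 120 days) are study-derived operating points, all
configurable. The package never recommends a specific PARP inhibitor.
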