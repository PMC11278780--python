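# Methods

## The inference problem

*Epichloë* endophytes of cool-season grasses synthesise four classes of
bioactive alkaloids — ergot alkaloids (EAS cluster), indole-diterpenes
(IDT/LTM cluster), peramine/pyrrolopyrazines (the multi-domain `ppzA`
NRPS) and lolines (LOL cluster). Which end products and intermediates a
strain can make is determined, to first order, by which biosynthesis genes
it carries, and gene carriage is routinely assayed by PCR as a
presence/absence profile. `endochem` turns such profiles into predicted
chemotypes: the set of producible metabolites per pathway, a `ppzA` allele
call, a mating-type call, a per-cluster pattern code, a chemotype label
(types 1–4) and a livestock-safety category (I/II).

## Pathway model and producibility

Each pathway is a small DAG of metabolites. A step produces one metabolite
and is gated by an all-of set of gene markers plus an optional precursor
metabolite. The producibility rule is boolean reachability:

> a metabolite is producible iff every gene in its step's gate is present
> **and** its precursor (if any) is itself producible.

The engine evaluates steps once in topological order of the precursor DAG;
an independent fixed-point oracle (start from the empty set, repeatedly add
any satisfiable step until closure) is kept in `endochem.simulate` and the
two are cross-checked on thousands of random profiles in the test suite.
Two consequences of the boolean model are tested as properties: flipping a
gene absent→present never removes a metabolite (monotonicity), and knocking
out a gate gene removes exactly the gated metabolites plus everything
downstream of them through precursor chains (knockout soundness).

Default gating (bundled YAML under `endochem/data/models/`, overridable by
user files validated against `pathway_model.schema.json`):

- **EAS**: chanoclavine I (CC) ← {dmaW, easF, easC, easE}; D-lysergic acid
  (D-LC) ← CC + {easD, easA, easG, cloA}; ergovaline (ERV) ← D-LC +
  {lpsA, lpsB, easH}; ergonovine (EN) ← D-LC + {lpsC}; lysergic acid
  α-hydroxyacetamide (LAH) ← EN + {easO, easP}. This is the coarsest
  assignment consistent with the knockout literature; whether easH is
  strictly required for ERV cannot be decided from presence/absence data in
  which every ERV-competent strain carries it, so it is kept required but
  configurable.
- **IDT**: paspaline (PAS) ← {idtG, idtB, idtM, idtC, idtS}; paxilline
  (PAX) ← PAS + {idtP, idtQ}; terpendole K (TDK) ← PAX + {idtF, idtK};
  lolitrem B (LTM-B) ← TDK + {idtE, idtJ}.
- **PPZ**: peramine (PER) ← all seven ppzA domain segments plus the
  reductase domain R (allele ppzA-1); pyrrolopyrazine-1,4-diones
  (PPZ-dione) ← the seven segments plus the ΔR deletion marker (allele
  ppzA-2), which stalls the final reductive release step.
- **LOL**: 1-acetamidopyrrolizidine (AcAP) ← the five-gene all-of gate
  {lolC, lolF, lolD, lolT, lolU}; N-formylloline and N-acetylloline ← AcAP
  plus the remaining six cluster genes as one block. Finer downstream
  granularity would not change any call on data where the AcAP gate fails,
  and can be supplied in a model file.

Toxicity: every EAS and IDT product is flagged toxic to grazing livestock;
peramine, the pyrrolopyrazinediones and all loline products are
insect-active but livestock-safe. Safety category I is defined as an empty
intersection between the producible set and the toxic set; II otherwise.

## Calls, codes and chemotype labels

- **ppzA allele**: R present & ΔR absent → ppzA-1; ΔR present & R absent →
  ppzA-2; neither → none; both → conflict (warned, producibility then
  follows the raw domain gates, so a conflicted profile can show both
  branches).
- **Mating type**: mtAC only → A; mtBA only → B; neither → undetermined;
  both → conflict.
- **Pattern codes** are one-letter per-cluster summaries derived from raw
  calls: PPZ A/B = full vs ΔR allele; EAS A = 11-gene core present, B =
  whole cluster absent; IDT A = cluster absent, B = core + idtP/idtQ/idtF/
  idtK present, C = same without idtP; LOL A = lolC present. Profiles
  matching no letter code X with a warning. Codes are reported for
  readability only.
- **Chemotype labels** are defined over producible sets, not pattern
  codes, because published code letters can disagree with the underlying
  marker table (an idtP-negative strain is B by one published summary but C
  by the code definitions; the producible set {PAS} is unambiguous).
  Type 1 = peramine only; 2 = peramine + {CC, D-LC, ERV} + {PAS, PAX,
  TDK}; 3 = {CC, D-LC, ERV} + {PAS}, no peramine; 4 = {CC, D-LC, ERV} +
  {PAS, PAX, TDK}, no peramine. Anything else is `unclassified` with a
  warning — the labels describe the combinations observed in the field
  survey the defaults were built for, not all combinatorially possible
  profiles.

## Unknown calls

Profiles are tri-state: present / absent / unknown. Unknown is distinct
from absent (an unassayed marker is not a clean negative). The engine
resolves unknowns by policy: `strict` (default) treats them as absent —
conservative for producibility claims, though note that for *safety
screening* a missing toxin gene call resolved to absent is the permissive
direction, which is why every resolved unknown is attached to the result as
a warning; `optimistic` treats them as present and exists for sensitivity
analysis. Strict results are always a subset of optimistic results, and
masking calls to unknown can only shrink strict producible sets — both are
property-tested.

## Survey arithmetic

Infection frequency is 100·n_infected/n_samples rounded half-up to two
decimals (half-up, not banker's, matches printed survey tables: 36/44 →
81.82, 2/12 → 16.67). Aggregation is exact integer summation with per-host
and per-location rollups; a location sampled for two hosts counts once in
the location tally. Zero-sample records are accepted but their frequency is
undefined (error from `infection_frequency`, empty cell in reports).

## Synthetic data generator

Field collections show two modes of gene loss: whole clusters missing and
single genes missing inside an intact cluster. The generator mirrors this:
per strain and cluster, retain the cluster with probability π, then drop
each gene of a retained cluster independently with probability δ; the two
ppzA allele segments are mutually exclusive (R with probability
`allele_R_prob`), as are the mating-type idiomorphs. Defaults are fixed at
the structure of the reference field survey: π = 1.0 (PPZ), 0.8 (EAS, IDT,
LOL); δ = 0.2 (≈ per-gene absence rate inside retained clusters there);
allele_R_prob = 0.5; mating_type_a_prob = 1.0; unknown_prob = 0. One seeded
`numpy` generator per simulate call; no global state.

Ground truth (producible sets, type, category) is computed at generation
time with the fixed-point oracle and a definitional restatement of the
type/category rules, deliberately independent of the engine module, so
round-trip tests are a genuine dual-route check. What the generator does
*not* emulate: PCR false positives/negatives, primer cross-reactivity,
linkage between dropout events, or any sequence-level signal — passing
round-trip tests shows the inference is correct for the assumed loss model,
not that PCR profiling itself is error-free.

## Numerical and formatting choices

- Cell tokens: `+`/`1`/`present` → present; `-`, Unicode minus `−`, `0`,
  `absent` → absent; empty, `?`, `NA` → unknown. Delimiter sniffing is
  limited to tab vs comma. Strain ids are whitespace-stripped and
  case-sensitive; duplicates are errors.
- Marker aliases: bare ppzA segment names (A1…R, ΔR/∆R/dR) and the idtO →
  idtQ naming variant are accepted on input; idtO triggers a warning
  because it reflects a known published inconsistency.
- Reports have a fixed column order and are byte-identical across reruns;
  producible metabolites are listed pathway-by-pathway in pathway order.
- Reported "terminal products" are producible metabolites with no
  producible successor; they are informational and play no role in
  classification.
- CLI exit codes: 0 success, 2 input/validation error, 3 internal error;
  outputs are never overwritten without `--force`.

## Problem sizes used in tests

The bundled field tables are 20 strains × 46 markers and 6 survey rows;
property suites use 300 hypothesis examples and 1000 seeded random profiles
per pathway model; round-trip recovery uses 300–500 simulated strains. The
full suite runs in well under a minute.

## Known limitations

Gene presence is treated as function: a present-but-broken allele, copy
number, expression level and alkaloid quantities are all outside the model
(a strain carrying a toxin pathway may still accumulate sub-threshold
amounts in planta). The chemotype labels 1–4 are survey-specific summaries;
novel gene combinations fall out as `unclassified` rather than being forced
into a label.
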