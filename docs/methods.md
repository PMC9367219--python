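# Methods

## Problem and measurement model

`cadval` measures a deployed binary CXR abnormality classifier against the
hospital's own radiology reports, treated as ground truth.  Two record
streams must be joined: AI results derived from PACS DICOM studies, and
reports exported from HIS as per-session XML.  With no shared accession
number, linkage relies on patient identity and time: a pair is eligible
iff the patient IDs agree, the study time lies inside the report's session
window `[CHECK_IN_TIME, CHECK_OUT_TIME]`, and the report follows the study
by at most 24 hours (the hospital's reporting protocol).  Matched pairs
are scored as a 2×2 diagnostic table with abnormal as the positive class;
the headline statistic is `F1 = TP / (TP + (FP + FN)/2)`, the harmonic
mean of precision and recall, with a percentile-bootstrap 95% CI.

The assumption doing the real work is that the report label is correct:
the template rule is a proxy for the radiologist's verdict, and its
error rate is not modeled.

## Matching conventions

* **Window direction.** "Within 24 h" is read one-sided
  (`0 ≤ report_time − study_time ≤ 24 h`): in the hospital workflow a
  report never precedes its study.  `window_mode="absolute"` keeps the
  two-sided reading available.
* **Boundaries** are inclusive at both session-window ends and at exactly
  24 h, so legitimate boundary records are never dropped.
* **Assignment.** Eligibility can be many-to-many (a patient with two
  same-day studies).  Assignment is one-to-one and greedy by smallest
  report delay, with ties broken lexicographically by study UID then
  session ID — deterministic for a fixed input.  The count of records with
  multiple eligible candidates is logged.  `brute_force_match` enumerates
  the eligible set exhaustively and is kept as an independent oracle: the
  greedy output must always be a one-to-one subset of it, and equals it
  whenever eligibility is unambiguous.

## Report labeling conventions

A report is normal iff each of the four thoracic regions (chest wall,
pleura, lung, mediastinum) is matched by one of its canonical
normal-description templates as a contiguous substring of the
DESCRIPTION.  "Verbatim" requires an equality convention for free text;
the default is Unicode NFC composition, case folding (re-composed after
folding), whitespace runs collapsed to single spaces, and surrounding
whitespace stripped.  Diacritics are preserved — the rule is
Vietnamese-specific and diacritics are contrastive.  `normalize=False`
(CLI `--no-normalize`) gives raw byte-for-byte substring matching.

The shipped template file (`cadval/data/templates_vi.yaml`) reproduces
the published template table as-is, including its apparent typographical
variants; a site deploying against a real HIS export should verify the
templates against its own reporting conventions and drop in a corrected
file.  There is deliberately no sentence segmentation, negation
detection, or fuzzy matching: the rule's value is that it is auditable.

## Evaluation conventions

* **Undefined metrics** (zero denominator) are flagged (`None`/NaN),
  never silently zero.
* **Bootstrap.** Each replicate resamples all matched pairs with
  replacement and recomputes F1; the default 10,000 replicates give a
  Monte-Carlo error on the CI endpoints well under ±0.003 at n ≈ 6,000.
  Percentiles use numpy's linear interpolation.  Replicates with an
  undefined F1 (no positive truths and no positive calls) are excluded
  from the mean and percentiles and reported in `n_degenerate`; at any
  realistic prevalence they cannot occur.  The RNG is
  `numpy.random.default_rng(seed)`; the seed is part of the result object
  so published runs are repeatable.
* **Summary reconstruction.** `reconstruct_from_summary(n_pos, n_neg,
  sensitivity, specificity)` uses nearest-integer rounding (half away
  from zero): `TP = round(sens·n_pos)`, `TN = round(spec·n_neg)`, with FN
  and FP as class complements.  For the reference deployment population
  (1,756 abnormal / 4,529 normal, sens 0.686, spec 0.839) this yields
  (TP, FP, FN, TN) = (1205, 729, 551, 3800), and the reconstruction is
  validated by all four printed statistics at once: accuracy re-emerges
  as 79.6% rather than being imposed.

## Synthetic-data generator

The generator emulates the statistical structure of a two-month
provincial-hospital deployment so the whole pipeline is testable offline.
Defaults (all overridable in `GeneratorConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 5,989 | patients over the simulated period |
| `studies_per_patient_mean` | 6285/5989 ≈ 1.049 | 1 + Poisson(mean−1) studies each |
| `prevalence` | 0.279 | P(truth = abnormal) per study |
| `sensitivity` / `specificity` | 0.686 / 0.839 | AI prediction Bernoulli rates given truth |
| `cxr_service_id` | `"CXR-MOH"` | stand-in for the reserved national CXR service code |
| `report_delay_max_hours` | 24 | report delay drawn uniformly on (0, max] |
| `unmatched_study_rate` | 0.046 | study whose report never reaches HIS |
| `unmatched_report_rate` | 0.060 | orphan HIS report with no PACS study |
| `nuisance_modality_rate` | 0.05 | CT/MR/US studies of ABDOMEN/SKULL injected |
| `out_of_window_rate` | 0.010 | report delayed past the 24 h window |

The deployment-scale defaults give ≈6,285 CXR studies and a few percent
of unlinkable records on each side, matching the record counts of the
reference deployment.  Timestamps are timezone-naive local ISO 8601 at
whole-second resolution.  Normal reports concatenate one template per
region with benign formatting noise (case, separators, whitespace, an
occasional header) that the labeler's normalization must absorb; abnormal
reports replace one or more region sentences with region-specific
abnormal phrases (an artifact convention — real abnormal wording is
free).  Orphan reports belong to extra patient IDs, so they can never
link by construction; one session is emitted per study with disjoint
windows within a patient, so a clean corpus (all noise rates zero) has
exactly one eligible report per study and the downstream pipeline must
recover the hidden truth table *exactly* — the strongest end-to-end test
the generator supports.

What the generator does **not** emulate: real free-text variation beyond
template concatenation (no typos inside templates, no negated findings),
pixel data, DICOM tag inconsistencies beyond the nuisance
modality/body-part values, label noise in the reports, and
patient-level correlation of abnormality across repeat studies.  Passing
on synthetic corpora therefore demonstrates the plumbing and the
statistics, not robustness to messy site-specific text.

## Problem sizes used in the test suite

Unit and property tests run on corpora of 50–400 patients; the
operating-point recovery checks generate one deployment-scale corpus
(~6,285 studies) and compare empirical sensitivity/specificity within 3
binomial standard errors; the matcher oracle property runs on 1,000
random small linkage problems; bootstrap checks use 10,000 replicates on
the 6,285-pair reconstructed fixture.  The full suite completes in well
under a minute on one CPU.

## Known limitations

* The greedy nearest-delay assignment is an artifact decision; a deployed
  system could have resolved same-session multiplicities differently.
* The reserved CXR `SERVICE_ID` of the national health system is not
  public; it is required site configuration with no default (the
  generator's `CXR-MOH` is a placeholder token).
* Bootstrap CI endpoints are Monte-Carlo quantities: third-decimal
  agreement across seeds or percentile conventions is expected only
  within ±0.001–0.003.
* The labeler is meaningful only for report corpora that actually use the
  template sentences; it does not generalize across languages or sites.
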