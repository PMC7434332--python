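# Methods

This note documents the scoring model, the extraction and generation
machinery, the synthetic-data generator, and the numerical and design
choices behind `imaudit`.

## The reporting-quality rubric

The rubric audits *presence* of acquisition parameters, not their
scientific adequacy. It is deliberately low-stringency: passing means "a
reader could begin to evaluate and replicate the image", not "reporting
is exemplary".

Sections and their rules:

| section | applies to | pass condition |
|---|---|---|
| objective | optical microscopy (not whole-animal, EM, MRI, X-ray) | magnification **and** NA reported |
| digitization | everything except MRI/X-ray | one planar route — pixel size, or total magnification + camera model, or frame size + scan zoom — and, if 3-D, the Z step |
| spectral | fluorescence records | excitation **and** emission for the fluorochromes used |
| EM | TEM/SEM | all configured required settings (default: accelerating voltage, magnification, spot size) |

Global grade: for optical microscopy, objective **plus** one of
digitization/spectral. The rule is treated as necessary *and sufficient*
at the record level, which is exactly how the graded worked examples
behave (a passage with objective + digitization but no wavelengths earns
a global pass). Whole-animal optical imaging is graded on digitization
plus (where fluorescent) spectral; EM records on the EM section alone;
MRI and X-ray records are ineligible and never scored. A record that
asserts fluorescence but documents zero channels fails spectral: the
technique is claimed but entirely undescribed.

Article aggregation defaults to `all_records_pass`: one undocumented
experiment fails the article even when another is fully described. This
matches the failing worked example, where a single well-described
super-resolution panel could not rescue an article whose confocal imaging
was undescribed. `any_record_passes` is available for sensitivity
analyses. Section outcomes at article level are worst-case across
records. How a mixed EM + optical article should combine into one global
value is genuinely underdetermined; with the default aggregation every
eligible record must pass its own modality's rule, and both readings of
edge cases can be recovered from the per-section outcomes, which are
always reported.

Spectral completeness defaults to *all* channels
(`require_all_channels_spectral = True`): multichannel experiments are
where channel discrimination matters most. EM required settings are
configurable because EM reporting has historically been judged
case-by-case; EM *sample-preparation* adequacy (fixation quality and the
like) is expert visual judgment and is surfaced only as informational
checklist fields, never scored.

### Sampling adequacy (advisory)

Lateral Rayleigh resolution r = 0.61·λ/NA, Nyquist pixel r/2, with λ the
shortest reported emission wavelength. Annotations compare the reported
pixel size with the Nyquist pixel and are rounded to the nearest integer
ratio ("finer than Nyquist (≈4×)"). They never affect pass/fail — the
rubric audits reporting, and a *reported* undersampled acquisition is
still a reported one.

## Domain model

All reportable parameters are `Optional`; absence always means "not
reported". Construction validates types only; `validate_record` reports
domain-rule violations (positivity; NA ∈ (0, 1.7], admitting high-NA oil
immersion; wavelengths in 300–900 nm; modality consistency) as *data* and
never raises, so erroneous source values can be held and audited rather
than rejected. Wavelengths are center/width bands in nm; a laser line is
a width-0 band. Units are fixed internally: µm for lengths, nm for
wavelengths, s for exposure, kV for EM voltage.

## OME metadata layer

Only the OME 2016-06 data model is targeted; vendor dialects (ND2, CZI,
LIF) are out of scope because they are neither standardized nor reliably
documented. Reads accept standalone OME-XML or a TIFF whose
ImageDescription holds OME-XML; one record is produced per `Image`
element, with no merging. Unit attributes are honored and normalized
(lengths to µm, wavelengths to nm); absent unit attributes assume the OME
defaults. Extraction never invents values: absent elements yield absent
fields. Modality is not inferred beyond
`is_fluorescence := any channel has a wavelength`, because OME does not
encode modality reliably; callers supply it.

The *OME-mapped subset* — the fields this layer reads and writes — is
instrument model, objective magnification/NA/immersion/correction, pixel
size, Z step, camera (detector) model, and per-channel name, excitation
and emission centers and exposure time. Frame size, scan zoom, pinhole
(in Airy units), total magnification, EM settings and band widths have no
faithful counterpart in this slice and travel only in fixture manifests;
round-trip guarantees are stated on the subset. The `silicone` immersion
value maps to OME `Other` and therefore cannot round-trip; the generator
avoids it in round-trip corpora. Written fixtures embed a 16×16 pixel
payload (TIFF) or a `MetadataOnly` element (XML); for TIFF the XML is
serialized with character references so the ImageDescription stays 7-bit
ASCII, as the TIFF tag type requires.

## Text mining

Word counts are maximal non-whitespace runs — the simplest rule
consistent with the one passage whose published word-processor count (79)
is reproduced exactly. The other two packaged passages count 123 and 139
tokens against published counts of 121 and 136; citation formatting
altered in typesetting makes those counts unreproducible under any fixed
tokenizer, so they are not used as anchors. The imaging-text fraction is
100 × (words starting inside an imaging span) / (all words).

Parameter extraction is deterministic regular-expression matching — no
language model — so audits are reproducible and every populated field
carries the span it came from (`ExtractionHit`). Notable policies:

* Numbers adjacent to x/X are magnifications only when integral, ≤ 400,
  and with objective-context vocabulary within ±80 characters; this
  rejects "2X integration" and "4X binning". The `60XO`-style Olympus
  suffix is accepted.
* "µm", "um" and "micron(s)" are equivalent; nm values are converted.
  Decimal commas are not supported (the corpus is English-language).
* Camera models are vendor word + following model-like tokens (containing
  an uppercase letter or digit), stopping at plain-lowercase words — so
  "Andor iXon EM-CCD camera" → `Andor iXon EM-CCD` but "Andor Xyla 4.2
  scientific CMOS camera" → `Andor Xyla 4.2`.
* Multi-setup passages keep all magnification/NA/camera hits; the record
  draft takes the first complete pairing, and the rubric passes if any
  complete pair exists (this is how a two-microscope passage passes).
* A stated objective magnification is taken at face value as the total
  magnification, so magnification + camera model satisfies the
  digitization planar route — again matching the graded examples.
* Overlapping same-parameter matches are collapsed to one hit, so two
  phrasings of one laser line cannot create a phantom second channel.
* `is_fluorescence` is asserted by the modality hint, by any extracted
  channel, or by fluorescence vocabulary (confocal, laser, fluorophore
  names); `is_3d` by a Z step or z-stack vocabulary.

`audit_text` = extraction + `score_record`, returning the verdict together
with the hit list for auditability.

## Methods-text generation

Two built-in template profiles (wide-field fluorescence; laser-scanning
confocal) cover the two most common fluorescence experiment types; others
are derivable by constructing a `TemplateProfile`. Missing required
parameters render as visible `[NOT RECORDED: field]` markers plus
warnings rather than being silently dropped — the artifact's purpose is
exposing gaps, so generated text must never hide one. Z step is required
exactly when the record is 3-D. Output is deterministic; phrasing is
American English with SI units and wavelengths as "488 nm" / "520/35 nm".
The original example-output supplement of the tool this emulates is not
available, so template wording is a reconstruction; the tested contract
is semantic: for every record the rubric passes, the rendered paragraph
re-audited by `audit_text` passes too.

The checklist profiles (`render_checklist`) are likewise reconstructed
from the scoring rules, as the minimal reportable parameter set for each
profile; they are not a verbatim copy of any published checklist.

## Corpus statistics

Percentages are computed from pooled counts (never means of per-article
percentages) with half-up rounding: 0 decimals for count-ratio
percentages, 1 decimal for the methods-text and pass-rate columns. The
methods-text fraction pools words over imaging-containing articles only;
pass rates use eligible articles (imaging present, not exclusively
MRI/X-ray) as denominator. Pooling makes summaries invariant under any
partition of the corpus, which is property-tested. Known source-data
artifacts in printed tables (a row whose printed percentage does not
follow from its own printed counts) are documented in the README and not
modeled.

## Synthetic-data generator

`imaudit.simulate` draws records a core facility would recognise:
magnifications from {10, 20, 25, 40, 60, 63, 100}; NA uniform on
0.25–1.45 (2 decimals); pixel size uniform on 0.03–0.4 µm (4 decimals);
Z step 0.1–1.0 µm; 1–3 channels with excitation 350–650 nm, a Stokes
shift of 20–80 nm, filter widths {0, 25, 35, 50} nm; exposures
0.01–2 s; real instrument/camera/software names. `random_record` drops
each reportable parameter independently (default p = 0.4), emulating the
incomplete methods sections the rubric exists to catch.

What the generator does *not* emulate: correlated omission patterns
(real articles omit whole sections, not independent fields), vendor
metadata dialects, OCR/typesetting noise in text, and multi-experiment
articles mixing modalities. Passing the randomized suites therefore shows
the machinery is self-consistent under realistic parameter values, not
that extraction recall on arbitrary published prose is complete; the
three packaged real passages are the external anchors for that.

## Numerical and degenerate-input choices

* Rounding of percentages: decimal half-up (not banker's), matching every
  printed count-ratio checked.
* NA violations above 1.7 are reported, not raised, so erroneous source
  text can be audited.
* `score_article([])`, `pct(n, 0)`, empty methods text, and missing panel
  counts are usage/domain errors; malformed XML raises a parse error with
  line/column offsets; a non-OME namespace raises an unsupported-format
  error.
* Fixture manifests are JSON with sorted keys; outputs are byte-identical
  under a fixed seed.

## Problem sizes

The test and acceptance suites use 2 × 2 × 2¹⁰ = 4096 truth-table cases,
1000 records for monotonicity, and 100 records each for the OME
round-trip and generator–auditor loops — sizes at which every suite is
exhaustive or statistically redundant for rule-based (noise-free) checks,
and the whole battery completes in seconds.

## Known limitations

* Extraction patterns target English methods prose of the kind shown in
  the packaged passages; recall on heavily abbreviated or tabular methods
  is untested.
* The OME layer does not read vendor-proprietary containers, and pixel
  data are never inspected — figure/panel classification is curator data
  entry by design.
* Modality cannot be inferred from OME metadata or (reliably) from text;
  audits are most precise when the caller supplies a modality hint.
* The rubric encodes one published reading of "minimal reporting";
  stricter community standards would need additional sections, which the
  configurable `RubricConfig` and profile machinery accommodate but do
  not ship.
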