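# imaudit

**Audit, extract and generate the reporting of microscopy image-acquisition
methods.**

Most published biomedical articles that rely on microscopy do not state the
acquisition parameters a reader would need to evaluate or replicate the
imaging experiment — often not even the objective lens NA or the pixel
size. `imaudit` is a toolkit for people who care about that gap: imaging
core-facility staff vetting manuscripts, journal staff checking reporting
checklists, and meta-researchers quantifying reporting quality across a
literature corpus.

## What it does

* **Models** every reportable acquisition parameter
  (`AcquisitionRecord`): modality, objective lens (magnification *M*,
  numerical aperture *NA*, immersion, correction class), digitization
  (pixel size *dx*, Z step *dz*, frame size, scan zoom, camera, pinhole),
  per-channel spectral settings (λ_ex, λ_em as center/width bands,
  exposure), and EM settings (accelerating voltage, gun bias,
  magnification, spot size). "Not reported" is absence, never a sentinel.
* **Scores** a record with a low-stringency pass/fail rubric in three
  optical sections plus one EM section:
  - *objective*: pass iff **both** *M* and *NA* are reported;
  - *digitization*: pass iff any planar-sampling route is reported —
    *dx*, or total magnification + camera model, or frame size + scan
    zoom — and, for 3-D acquisitions, additionally *dz*;
  - *spectral* (fluorescence only): pass iff excitation **and** emission
    are documented for the fluorochromes used;
  - *EM* (TEM/SEM only): pass iff the configured acquisition settings
    (default: voltage, magnification, spot size) are present.

  **Global pass** = objective **plus** at least one of
  digitization/spectral (EM records are graded on the EM section;
  whole-animal optical imaging on digitization + spectral; MRI/X-ray are
  outside the rubric and ineligible). Article-level scores aggregate
  record scores (default: every record must pass).
* **Extracts** records from OME-XML / OME-TIFF metadata
  (`read_metadata`), and writes synthetic OME fixtures with controlled
  per-field completeness plus a ground-truth manifest (`write_fixture`).
* **Mines** free methods text for parameters with deterministic,
  span-tracked patterns (`extract_parameters`, `audit_text`), counts words
  and the imaging fraction of a methods section (`count_words`,
  `imaging_text_fraction`).
* **Generates** a publication-ready methods paragraph from a record
  (`render_methods`), with visible `[NOT RECORDED: …]` markers for every
  gap, and a per-parameter checklist (`render_checklist`).
* **Aggregates** curated per-article audits into journal / group / total
  summary tables with pooled-count percentages (`summarize`,
  `panel_audit_compare`).
* **Advises** on sampling adequacy via the Rayleigh resolution
  *r* = 0.61·λ/NA and the Nyquist pixel *r*/2 (`sampling_annotation`);
  advisory only, never part of a verdict.

## Worked example

The packaged fixture `passage2.txt` is a real 79-word confocal/wide-field
methods passage. Auditing it:

```bash
imaudit audit-text src/imaudit/fixtures/passage2.txt --modality confocal_laser_scanning
```

prints the extraction evidence and the verdict:

```
instrument_model                    'Nikon Eclipse Ti-E'     'Nikon Eclipse Ti-E microscope'
objective.magnification             100.0                    '100x'
objective.correction_class          'Plan Apochromat'        'Plan Apochromat'
objective.numerical_aperture        1.45                     'NA 1.45'
digitization.camera_model           'Andor iXon EM-CCD'      'Andor iXon EM-CCD camera'
objective.magnification             100.0                    '100x'
objective.numerical_aperture        1.4                      'NA 1.40'
digitization.camera_model           'Andor Xyla 4.2'         'Andor Xyla 4.2 scientific CMOS camera'
{
  "objective_section": "pass",
  "digitization_section": "pass",
  "spectral_section": "fail",
  "em_section": "not_applicable",
  "global_pass": true,
  ...
}
```

Reading: both objectives are fully specified (100×/1.45 and 100×/1.40),
planar sampling is derivable from the total magnification plus the named
cameras, but no excitation or emission wavelengths are given — so the
spectral section fails while the passage still earns a (minimal) global
pass. Exit code 0 signals the pass; a failing text exits 3.

The generator runs the other way — from a complete record it drafts, for
example:

> Images were acquired on a Olympus IX83 laser-scanning confocal
> microscope using MetaMorph software. A 20x Plan Fluor objective lens
> (NA 1.02, glycerol immersion) was used. Images were acquired at a pixel
> size of 0.3116 µm, a scan zoom of 1.4 and a 1.2 AU pinhole. Z-stacks
> were acquired with a Z step of 0.81 µm. Channel 1 (Alexa 568) was
> excited at 376 nm and its emission was collected at 422/50 nm, with an
> exposure time of 1.719 s. …

and `audit_text` on that output grades a global pass — the
generator–auditor loop is closed and tested.

## Notes on the packaged corpus counts

The per-journal counts shipped in `imaudit.datasets` are printed aggregate
inputs; only the with-imaging/without-imaging split per journal is
published, so figure- and word-level columns of a summary built from them
are placeholders. One printed source row ("Developmental Biology 29/30,
99%") is inconsistent with its own counts (29/30 rounds to 97%); the
toolkit reproduces the arithmetic from counts and does not model such
source-data artifacts. The minimal-reporting checklist profiles are
reconstructed from the scoring rules; the original checklist supplement is
not reproduced verbatim.

See `docs/methods.md` for the full account of the rubric, the extraction
patterns, the synthetic-data generator and known limitations.
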