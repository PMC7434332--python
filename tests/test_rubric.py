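"""Rubric scoring: section rules, global grade, oracle equivalence,
monotonicity, and sampling-adequacy arithmetic."""

import itertools

import pytest

from imaudit.records import (
    AcquisitionRecord,
    Band,
    ChannelSpec,
    DigitizationSpec,
    EMSpec,
    Modality,
    ObjectiveSpec,
    SectionOutcome,
)
from imaudit.rubric import (
    DEFAULT_CONFIG,
    RubricConfig,
    lateral_resolution_um,
    nyquist_pixel_um,
    sampling_annotation,
    score_article,
    score_digitization,
    score_em,
    score_objective,
    score_record,
    score_spectral,
)
from imaudit.simulate import random_record

PASS, FAIL, NA = SectionOutcome.PASS, SectionOutcome.FAIL, SectionOutcome.NOT_APPLICABLE


def _optical(modality=Modality.CONFOCAL_LASER_SCANNING, **kwargs):
    kwargs.setdefault("is_fluorescence", True)
    return AcquisitionRecord(modality=modality, **kwargs)


class TestObjectiveSection:
    def test_magnification_and_na_together_pass(self):
        rec = _optical(objective=ObjectiveSpec(magnification=100, numerical_aperture=1.45))
        assert score_objective(rec).outcome is PASS

    def test_missing_na_fails_and_is_named(self):
        rec = _optical(objective=ObjectiveSpec(magnification=100))
        out = score_objective(rec)
        assert out.outcome is FAIL
        assert out.missing == ("objective.numerical_aperture",)

    @pytest.mark.parametrize(
        "modality",
        [Modality.WHOLE_ANIMAL_OPTICAL, Modality.TEM, Modality.SEM, Modality.MRI],
    )
    def test_not_applicable_modalities(self, modality):
        rec = AcquisitionRecord(modality=modality)
        assert score_objective(rec).outcome is NA


class TestDigitizationSection:
    def test_total_magnification_plus_camera_is_a_valid_planar_route(self):
        rec = _optical(
            digitization=DigitizationSpec(
                camera_model="Andor iXon EM-CCD", total_magnification=100
            )
        )
        assert score_digitization(rec).outcome is PASS

    def test_pixel_and_z_pass_in_3d(self):
        rec = _optical(
            is_3d=True,
            digitization=DigitizationSpec(pixel_size_xy_um=0.2666, z_step_um=0.5),
        )
        assert score_digitization(rec).outcome is PASS

    def test_3d_without_z_step_fails_on_axial_sampling(self):
        rec = _optical(is_3d=True, digitization=DigitizationSpec(pixel_size_xy_um=0.1))
        out = score_digitization(rec)
        assert out.outcome is FAIL
        assert "z_step_um" in out.missing

    def test_frame_size_plus_zoom_is_a_valid_planar_route(self):
        rec = _optical(
            digitization=DigitizationSpec(frame_size_px=(512, 512), scan_zoom=2.0)
        )
        assert score_digitization(rec).outcome is PASS


class TestSpectralSection:
    def test_excitation_line_plus_emission_band_pass(self):
        rec = _optical(
            channels=[
                ChannelSpec(
                    excitation_nm=Band(center_nm=488),
                    emission_nm=Band(center_nm=520, width_nm=35),
                )
            ]
        )
        assert score_spectral(rec).outcome is PASS

    def test_fluorescence_with_no_channel_information_fails(self):
        assert score_spectral(_optical(channels=[])).outcome is FAIL

    def test_not_applicable_without_fluorescence(self):
        rec = AcquisitionRecord(modality=Modality.BRIGHTFIELD, is_fluorescence=False)
        assert score_spectral(rec).outcome is NA

    def test_any_channel_policy_relaxes_the_all_channel_default(self):
        complete = ChannelSpec(
            excitation_nm=Band(center_nm=488), emission_nm=Band(center_nm=520)
        )
        bare = ChannelSpec()
        rec = _optical(channels=[complete, bare])
        assert score_spectral(rec, DEFAULT_CONFIG).outcome is FAIL
        relaxed = RubricConfig(require_all_channels_spectral=False)
        assert score_spectral(rec, relaxed).outcome is PASS


class TestEMSection:
    def test_required_settings_present_pass(self):
        rec = AcquisitionRecord(
            modality=Modality.TEM,
            em=EMSpec(accelerating_voltage_kv=120, magnification=30000, spot_size=3),
        )
        assert score_em(rec).outcome is PASS

    def test_missing_voltage_fails(self):
        rec = AcquisitionRecord(
            modality=Modality.TEM, em=EMSpec(magnification=30000, spot_size=3)
        )
        out = score_em(rec)
        assert out.outcome is FAIL
        assert "em.accelerating_voltage_kv" in out.missing

    def test_not_applicable_for_optical_records(self):
        assert score_em(_optical()).outcome is NA


class TestGlobalGrade:
    def test_objective_plus_digitization_passes_despite_spectral_fail(self):
        rec = _optical(
            objective=ObjectiveSpec(magnification=100, numerical_aperture=1.45),
            digitization=DigitizationSpec(
                camera_model="Andor iXon EM-CCD", total_magnification=100
            ),
            channels=[],
        )
        score = score_record(rec)
        assert score.spectral_section is FAIL
        assert score.global_pass

    def test_all_three_sections_pass(self, confocal_record):
        score = score_record(confocal_record)
        assert (
            score.objective_section,
            score.digitization_section,
            score.spectral_section,
        ) == (PASS, PASS, PASS)
        assert score.global_pass and score.eligible

    def test_all_sections_failing_fail_globally(self):
        score = score_record(_optical())
        assert not score.global_pass
        assert score.missing_items  # every gap is named

    def test_whole_animal_graded_on_digitization_and_spectral_only(self):
        rec = AcquisitionRecord(
            modality=Modality.WHOLE_ANIMAL_OPTICAL,
            is_fluorescence=False,
            digitization=DigitizationSpec(pixel_size_xy_um=25.0),
        )
        score = score_record(rec)
        assert score.objective_section is NA
        assert score.global_pass

    def test_mri_records_are_ineligible(self):
        score = score_record(AcquisitionRecord(modality=Modality.MRI))
        assert not score.eligible and not score.global_pass


class TestArticleAggregation:
    def test_one_failing_record_fails_the_article(self, confocal_record):
        failing = _optical()
        score = score_article([failing, confocal_record])
        assert not score.global_pass and score.eligible

    def test_mri_only_article_is_ineligible(self):
        score = score_article([AcquisitionRecord(modality=Modality.MRI)])
        assert not score.eligible

    def test_singleton_passing_article_passes(self, confocal_record):
        assert score_article([confocal_record]).global_pass

    def test_mixed_mri_and_optical_scores_the_optical_record(self, confocal_record):
        score = score_article(
            [AcquisitionRecord(modality=Modality.MRI), confocal_record]
        )
        assert score.eligible and score.global_pass

    def test_empty_article_is_a_usage_error(self):
        with pytest.raises(ValueError):
            score_article([])


# ---------------------------------------------------------------------------
# exhaustive oracle equivalence

_FIELDS = ("mag", "na", "pixel", "totmag", "camera", "frame", "zoom", "z", "ex", "em")


def _truth_table_oracle(p: dict, is_3d: bool) -> dict:
    """Independent restatement of the scoring prose for a single-channel
    fluorescence record: objective needs NA and magnification; any one
    planar route passes digitization, plus Z when 3-D; spectral needs both
    wavelengths; global = objective plus one other section."""
    objective = p["mag"] and p["na"]
    planar = p["pixel"] or (p["totmag"] and p["camera"]) or (p["frame"] and p["zoom"])
    digitization = planar and (p["z"] if is_3d else True)
    spectral = p["ex"] and p["em"]
    return {
        "objective": objective,
        "digitization": digitization,
        "spectral": spectral,
        "global": objective and (digitization or spectral),
    }


def _record_from_presence(p: dict, modality: Modality, is_3d: bool) -> AcquisitionRecord:
    return AcquisitionRecord(
        modality=modality,
        is_3d=is_3d,
        is_fluorescence=True,
        objective=ObjectiveSpec(
            magnification=60 if p["mag"] else None,
            numerical_aperture=1.4 if p["na"] else None,
        ),
        digitization=DigitizationSpec(
            pixel_size_xy_um=0.1 if p["pixel"] else None,
            total_magnification=60 if p["totmag"] else None,
            camera_model="Andor Zyla 4.2" if p["camera"] else None,
            frame_size_px=(512, 512) if p["frame"] else None,
            scan_zoom=2.0 if p["zoom"] else None,
            z_step_um=0.3 if p["z"] else None,
        ),
        channels=[
            ChannelSpec(
                excitation_nm=Band(center_nm=488) if p["ex"] else None,
                emission_nm=Band(center_nm=520) if p["em"] else None,
            )
        ],
    )


@pytest.mark.timeout(10)
@pytest.mark.parametrize(
    "modality", [Modality.CONFOCAL_LASER_SCANNING, Modality.WIDEFIELD_FLUORESCENCE]
)
@pytest.mark.parametrize("is_3d", [False, True])
def test_score_record_matches_exhaustive_truth_table(modality, is_3d):
    """All 2^10 presence/absence combinations agree with the independently
    enumerated truth table."""
    for bits in itertools.product([False, True], repeat=len(_FIELDS)):
        p = dict(zip(_FIELDS, bits))
        expected = _truth_table_oracle(p, is_3d)
        score = score_record(_record_from_presence(p, modality, is_3d))
        got = {
            "objective": score.objective_section is PASS,
            "digitization": score.digitization_section is PASS,
            "spectral": score.spectral_section is PASS,
            "global": score.global_pass,
        }
        assert got == expected, f"{p} ({modality}, is_3d={is_3d})"


# ---------------------------------------------------------------------------
# monotonicity

_ADDITIONS = {
    "objective.magnification": 60.0,
    "objective.numerical_aperture": 1.4,
    "digitization.pixel_size_xy_um": 0.1,
    "digitization.total_magnification": 60.0,
    "digitization.camera_model": "Andor Zyla 4.2",
    "digitization.frame_size_px": (512, 512),
    "digitization.scan_zoom": 2.0,
    "digitization.z_step_um": 0.3,
}
_RANK = {FAIL: 0, PASS: 1}


def _degrades(before: SectionOutcome, after: SectionOutcome) -> bool:
    return before in _RANK and after in _RANK and _RANK[after] < _RANK[before]


def _add_field(rec: AcquisitionRecord, path: str, value) -> AcquisitionRecord:
    rec = rec.model_copy(deep=True)
    head, _, leaf = path.partition(".")
    if head == "channels":
        for ch in rec.channels:
            if getattr(ch, leaf) is None:
                setattr(ch, leaf, value)
    elif leaf:
        if getattr(rec, head) is None:
            setattr(
                rec,
                head,
                ObjectiveSpec() if head == "objective" else DigitizationSpec(),
            )
        setattr(getattr(rec, head), leaf, value)
    else:
        setattr(rec, head, value)
    return rec


@pytest.mark.timeout(30)
def test_adding_a_parameter_never_degrades_any_verdict(rng):
    """Over 1000 randomized incomplete records, reporting one more
    parameter never flips a section or the global grade from pass to fail."""
    additions = dict(_ADDITIONS)
    additions["channels.excitation_nm"] = Band(center_nm=488)
    additions["channels.emission_nm"] = Band(center_nm=520)
    for _ in range(1000):
        rec = random_record(rng)
        before = score_record(rec)
        for path, value in additions.items():
            after = score_record(_add_field(rec, path, value))
            for section in (
                "objective_section",
                "digitization_section",
                "spectral_section",
                "em_section",
            ):
                assert not _degrades(getattr(before, section), getattr(after, section)), (
                    path,
                    rec,
                )
            assert not (before.global_pass and not after.global_pass), (path, rec)


# ---------------------------------------------------------------------------
# sampling adequacy

def test_rayleigh_resolution_and_nyquist_pixel():
    assert lateral_resolution_um(520, 1.3) == pytest.approx(0.244, abs=1e-3)
    assert nyquist_pixel_um(520, 1.3) == pytest.approx(0.122, abs=1e-3)


def test_doubling_na_halves_resolution():
    assert lateral_resolution_um(520, 1.4) == pytest.approx(
        lateral_resolution_um(520, 0.7) / 2
    )


def test_fourfold_oversampling_annotation():
    # 0.61*520/1.45/2 ≈ 0.109 µm Nyquist pixel vs 0.03 µm reported
    assert sampling_annotation(0.03, 520, 1.45) == "finer than Nyquist (≈4×)"


def test_nonpositive_na_is_a_domain_error():
    with pytest.raises(ValueError):
        lateral_resolution_um(520, 0)
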