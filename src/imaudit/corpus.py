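"""Corpus-level aggregation of per-article imaging audits.

Curators supply one :class:`ArticleRecord` per article — figure counts,
methods-section word counts, imaging modalities and (optionally) a rubric
:class:`~imaudit.records.QualityScore`.  This module pools them into
per-journal, per-group and grand-total summary rows:

* the share of articles containing original images,
* the share of figures (main plus supplemental) that are imaging figures,
* the share of methods-section text devoted to image acquisition
  (pooled over imaging-containing articles only),
* and the rubric pass rate over eligible articles (articles whose imaging
  is exclusively MRI/X-ray are not eligible).

Percentages are always recomputed from pooled counts, never averaged over
per-article percentages, so summarising a corpus equals summarising the
concatenation of any partition of it.  Figure and panel classification is
data entry by a curator, not computation: western blots, gels and
schematics are excluded upstream.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .records import EXCLUDED_MODALITIES, Modality, QualityScore

#: journal-group definition: group name -> member journal names
JournalGroup = dict[str, list[str]]


class UnknownJournalError(KeyError):
    """A group references a journal absent from the corpus."""


class ArticleRecord(BaseModel):
    """Curated per-article counts and verdicts."""

    model_config = ConfigDict(extra="forbid")

    journal: str
    source_id: str = ""
    n_figures_total: int
    n_figures_imaging: int
    n_panels_total: Optional[int] = None
    n_panels_imaging: Optional[int] = None
    mm_words_total: int = 0
    mm_words_imaging: int = 0
    modalities: list[Modality] = []
    quality: Optional[QualityScore] = None
    exclusion_note: str = ""

    @model_validator(mode="after")
    def _ordered(self) -> "ArticleRecord":
        if self.n_figures_imaging > self.n_figures_total:
            raise ValueError("imaging figures cannot exceed total figures")
        if self.mm_words_imaging > self.mm_words_total:
            raise ValueError("imaging words cannot exceed total words")
        if (self.n_panels_total is None) != (self.n_panels_imaging is None):
            raise ValueError("panel counts must be given together")
        if (
            self.n_panels_total is not None
            and self.n_panels_imaging > self.n_panels_total
        ):
            raise ValueError("imaging panels cannot exceed total panels")
        return self

    @property
    def has_imaging(self) -> bool:
        return self.n_figures_imaging > 0

    @property
    def eligible(self) -> bool:
        """In the quality denominator: has imaging, not exclusively MRI/X-ray."""
        if not self.has_imaging:
            return False
        if self.quality is not None:
            return self.quality.eligible
        if self.modalities and all(m in EXCLUDED_MODALITIES for m in self.modalities):
            return False
        return True

    @property
    def passes(self) -> bool:
        return self.quality is not None and self.quality.global_pass


def pct(numerator: int, denominator: int, decimals: int = 0) -> float:
    """100*n/d rounded half-up to *decimals* (the convention of printed
    count-ratio percentages)."""
    if denominator <= 0:
        raise ValueError("pct requires a positive denominator")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


_SUMMARY_COLUMNS = [
    "row",
    "n_articles",
    "n_with_imaging",
    "pct_with_imaging",
    "pct_imaging_figures",
    "pct_imaging_methods_text",
    "n_eligible",
    "n_pass",
    "pct_pass",
]


class CorpusSummary(BaseModel):
    """Per-journal, per-group and total aggregate rows."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    table: pd.DataFrame

    def row(self, name: str) -> dict:
        df = self.table
        match = df[df["row"] == name]
        if match.empty:
            raise KeyError(name)
        return match.iloc[0].to_dict()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CorpusSummary) and self.table.equals(other.table)


def _aggregate(name: str, articles: list[ArticleRecord]) -> dict:
    n = len(articles)
    n_img = sum(a.has_imaging for a in articles)
    fig_total = sum(a.n_figures_total for a in articles)
    fig_img = sum(a.n_figures_imaging for a in articles)
    imaging_articles = [a for a in articles if a.has_imaging]
    words_total = sum(a.mm_words_total for a in imaging_articles)
    words_img = sum(a.mm_words_imaging for a in imaging_articles)
    n_eligible = sum(a.eligible for a in articles)
    n_pass = sum(a.passes and a.eligible for a in articles)
    return {
        "row": name,
        "n_articles": n,
        "n_with_imaging": n_img,
        "pct_with_imaging": pct(n_img, n, 0) if n else None,
        "pct_imaging_figures": pct(fig_img, fig_total, 0) if fig_total else None,
        "pct_imaging_methods_text": (
            pct(words_img, words_total, 1) if words_total else None
        ),
        "n_eligible": n_eligible,
        "n_pass": n_pass,
        "pct_pass": pct(n_pass, n_eligible, 1) if n_eligible else None,
    }


def summarize(
    articles: list[ArticleRecord], groups: Optional[JournalGroup] = None
) -> CorpusSummary:
    """Pool *articles* into per-journal rows, group rows and a total row.

    Word-count percentages pool over imaging-containing articles only;
    pass rates use eligible articles as denominator.  Raises
    :class:`UnknownJournalError` if a group names an absent journal.
    """
    if not articles:
        raise ValueError("summarize requires at least one article")
    journals: list[str] = []
    for a in articles:
        if a.journal not in journals:
            journals.append(a.journal)
    rows = [
        _aggregate(j, [a for a in articles if a.journal == j]) for j in journals
    ]
    for group, members in (groups or {}).items():
        unknown = set(members) - set(journals)
        if unknown:
            raise UnknownJournalError(
                f"group {group!r} references unknown journals {sorted(unknown)}"
            )
        rows.append(
            _aggregate(group, [a for a in articles if a.journal in members])
        )
    rows.append(_aggregate("Total", list(articles)))
    return CorpusSummary(table=pd.DataFrame(rows, columns=_SUMMARY_COLUMNS))


def panel_audit_compare(articles: list[ArticleRecord]) -> tuple[float, float]:
    """Pooled figure-level and panel-level imaging percentages.

    Requires panel counts on every input article (the panel-by-panel
    control audit); percentages are whole numbers, half-up.
    """
    if not articles:
        raise ValueError("panel_audit_compare requires at least one article")
    if any(a.n_panels_total is None for a in articles):
        raise ValueError("panel counts are required on every article")
    fig = pct(
        sum(a.n_figures_imaging for a in articles),
        sum(a.n_figures_total for a in articles),
        0,
    )
    panel = pct(
        sum(a.n_panels_imaging for a in articles),
        sum(a.n_panels_total for a in articles),
        0,
    )
    return fig, panel


# ---------------------------------------------------------------------------
# CSV interchange

_SECTION_COLS = (
    "objective_section",
    "digitization_section",
    "spectral_section",
    "em_section",
)


def articles_to_csv(articles: list[ArticleRecord], path) -> None:
    rows = []
    for a in articles:
        row = a.model_dump(exclude={"modalities", "quality"})
        row["modalities"] = ";".join(m.value for m in a.modalities)
        for col in _SECTION_COLS:
            row[col] = getattr(a.quality, col).value if a.quality else None
        row["global_pass"] = a.quality.global_pass if a.quality else None
        row["eligible"] = a.quality.eligible if a.quality else None
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def articles_from_csv(path) -> list[ArticleRecord]:
    df = pd.read_csv(path)
    out = []
    for row in df.to_dict(orient="records"):
        def clean(v):
            return None if v is None or (isinstance(v, float) and pd.isna(v)) else v

        quality = None
        if clean(row.get("objective_section")) is not None:
            quality = QualityScore(
                objective_section=row["objective_section"],
                digitization_section=row["digitization_section"],
                spectral_section=row["spectral_section"],
                em_section=row["em_section"],
                global_pass=bool(row["global_pass"]),
                eligible=bool(row["eligible"]),
            )
        mods = clean(row.get("modalities"))
        out.append(
            ArticleRecord(
                journal=row["journal"],
                source_id=str(clean(row.get("source_id")) or ""),
                n_figures_total=int(row["n_figures_total"]),
                n_figures_imaging=int(row["n_figures_imaging"]),
                n_panels_total=(
                    int(v) if (v := clean(row.get("n_panels_total"))) is not None else None
                ),
                n_panels_imaging=(
                    int(v) if (v := clean(row.get("n_panels_imaging"))) is not None else None
                ),
                mm_words_total=int(clean(row.get("mm_words_total")) or 0),
                mm_words_imaging=int(clean(row.get("mm_words_imaging")) or 0),
                modalities=(
                    [Modality(m) for m in mods.split(";")] if mods else []
                ),
                quality=quality,
                exclusion_note=str(clean(row.get("exclusion_note")) or ""),
            )
        )
    return out
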