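"""Packaged reference data: worked-example passages and published corpus counts.

The three methods passages are real published image-acquisition
descriptions used as graded worked examples of failing, minimally passing,
and good reporting; each ships with a sidecar JSON stating the expected
rubric verdicts.  The corpus constants are the printed per-journal and
pooled counts of a 240-article audit of eight biomedical journals; they
serve as inputs for the aggregation arithmetic, not as computed outputs.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any

from .corpus import ArticleRecord, JournalGroup
from .records import Modality


def _fixture_text(name: str) -> str:
    return (resources.files("imaudit.fixtures") / name).read_text(encoding="utf-8")


def worked_example(n: int) -> str:
    """Methods passage *n* (1 = failing, 2 = passing-but-incomplete, 3 = good)."""
    if n not in (1, 2, 3):
        raise ValueError("worked examples are numbered 1-3")
    return _fixture_text(f"passage{n}.txt")


def worked_example_expected(n: int) -> dict[str, Any]:
    """Sidecar with the expected rubric verdicts for passage *n*."""
    if n not in (1, 2, 3):
        raise ValueError("worked examples are numbered 1-3")
    return json.loads(_fixture_text(f"passage{n}.expected.json"))


# ---------------------------------------------------------------------------
# Published corpus counts (inputs to the aggregation arithmetic)

#: (journal, articles with imaging, articles evaluated) for the eight-journal
#: 240-article audit.
JOURNAL_ARTICLE_COUNTS: list[tuple[str, int, int]] = [
    ("Developmental Biology", 29, 30),
    ("Development", 28, 28),
    ("Developmental Cell", 32, 32),
    ("J Cell Biology", 29, 30),
    ("Nature Immunology", 18, 29),
    ("J Immunology", 17, 31),
    ("J Neuroscience", 18, 30),
    ("Biophysical Journal", 14, 30),
]

#: journal groups used in the summary table
DEFAULT_GROUPS: JournalGroup = {
    "Total developmental biology": [
        "Developmental Biology",
        "Development",
        "Developmental Cell",
    ],
    "Total immunology": ["Nature Immunology", "J Immunology"],
}

#: pooled figure counts over the whole corpus: (imaging figures, all figures)
CORPUS_FIGURE_COUNTS: tuple[int, int] = (1439, 2780)

#: the 12-article panel-by-panel control audit:
#: (imaging figures, figures, imaging panels, panels)
PANEL_AUDIT_COUNTS: tuple[int, int, int, int] = (85, 94, 558, 641)


def journal_count_articles() -> list[ArticleRecord]:
    """Expand the per-journal article counts into a minimal article corpus.

    Only the with-imaging/without-imaging split per journal is published,
    so each article carries a single placeholder figure whose imaging flag
    encodes that split; figure-level and word-level columns of a summary
    built from this corpus are placeholders, the article-level percentages
    are the published ones.
    """
    articles = []
    for journal, n_imaging, n_total in JOURNAL_ARTICLE_COUNTS:
        for i in range(n_total):
            has = i < n_imaging
            articles.append(
                ArticleRecord(
                    journal=journal,
                    source_id=f"{journal}:{i + 1}",
                    n_figures_total=1,
                    n_figures_imaging=1 if has else 0,
                    modalities=(
                        [Modality.CONFOCAL_LASER_SCANNING] if has else []
                    ),
                )
            )
    return articles


def panel_audit_articles() -> list[ArticleRecord]:
    """The panel-by-panel control audit as one pooled article record
    (per-article splits were not published)."""
    fig_img, fig_total, panel_img, panel_total = PANEL_AUDIT_COUNTS
    return [
        ArticleRecord(
            journal="Development",
            source_id="panel-audit-pooled",
            n_figures_total=fig_total,
            n_figures_imaging=fig_img,
            n_panels_total=panel_total,
            n_panels_imaging=panel_img,
        )
    ]
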