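"""Corpus aggregation: printed-count arithmetic, pooled percentages,
partition invariance, ordering invariants, and CSV round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imaudit.corpus import (
    ArticleRecord,
    UnknownJournalError,
    articles_from_csv,
    articles_to_csv,
    panel_audit_compare,
    pct,
    summarize,
)
from imaudit.datasets import (
    CORPUS_FIGURE_COUNTS,
    DEFAULT_GROUPS,
    PANEL_AUDIT_COUNTS,
    journal_count_articles,
    panel_audit_articles,
)


class TestPct:
    @pytest.mark.parametrize(
        "n, d, decimals, expected",
        [
            (185, 240, 0, 77),
            (0, 10, 0, 0),
            (85, 94, 0, 90),
            (558, 641, 0, 87),
            (1439, 2780, 0, 52),
            (1, 8, 1, 12.5),
            (1, 16, 1, 6.3),  # half-up at the rounding boundary
        ],
    )
    def test_half_up_rounding(self, n, d, decimals, expected):
        assert pct(n, d, decimals) == expected

    def test_zero_denominator_is_a_domain_error(self):
        with pytest.raises(ValueError):
            pct(1, 0)


def _article(journal, total=10, imaging=5, words=(100, 10), **kwargs):
    return ArticleRecord(
        journal=journal,
        n_figures_total=total,
        n_figures_imaging=imaging,
        mm_words_total=words[0],
        mm_words_imaging=words[1],
        **kwargs,
    )


class TestSummarize:
    def test_published_journal_counts_reproduce_printed_percentages(self):
        summary = summarize(journal_count_articles(), DEFAULT_GROUPS)
        total = summary.row("Total")
        assert (total["n_with_imaging"], total["n_articles"]) == (185, 240)
        assert total["pct_with_imaging"] == 77
        assert summary.row("Nature Immunology")["pct_with_imaging"] == 62
        assert summary.row("Total immunology")["pct_with_imaging"] == 58
        assert summary.row("Total developmental biology")["pct_with_imaging"] == 99

    def test_single_all_imaging_article(self):
        summary = summarize([_article("J", total=4, imaging=4)])
        assert summary.row("Total")["pct_imaging_figures"] == 100

    def test_pooled_percentages_match_a_brute_force_recount(self, rng):
        journals = ["A", "B", "C"]
        articles = []
        for i in range(20):
            total = int(rng.integers(1, 15))
            imaging = int(rng.integers(0, total + 1))
            wt = int(rng.integers(50, 3000))
            wi = int(rng.integers(0, wt + 1))
            articles.append(
                _article(journals[i % 3], total, imaging, (wt, wi))
            )
        summary = summarize(articles)
        # independent pooling by plain sums
        fig_pct = pct(
            sum(a.n_figures_imaging for a in articles),
            sum(a.n_figures_total for a in articles),
            0,
        )
        imaging_arts = [a for a in articles if a.n_figures_imaging > 0]
        word_pct = pct(
            sum(a.mm_words_imaging for a in imaging_arts),
            sum(a.mm_words_total for a in imaging_arts),
            1,
        )
        total = summary.row("Total")
        assert total["pct_imaging_figures"] == fig_pct
        assert total["pct_imaging_methods_text"] == word_pct

    def test_partition_invariance(self, rng):
        articles = [
            _article("A" if i % 2 else "B", 8, int(rng.integers(0, 9)))
            for i in range(30)
        ]
        whole = summarize(articles)
        order = rng.permutation(len(articles))
        shuffled = [articles[i] for i in order]  # same multiset, any order
        assert summarize(shuffled).row("Total") == whole.row("Total")

    def test_ordering_invariants_hold_on_random_corpora(self, rng):
        for _ in range(25):
            articles = []
            for i in range(int(rng.integers(1, 12))):
                total = int(rng.integers(1, 10))
                articles.append(
                    _article("J%d" % rng.integers(3), total, int(rng.integers(0, total + 1)))
                )
            for _, row in summarize(articles).table.iterrows():
                assert row["n_pass"] <= row["n_eligible"]
                assert row["n_eligible"] <= row["n_with_imaging"]
                assert row["n_with_imaging"] <= row["n_articles"]
                for col in ("pct_with_imaging", "pct_imaging_figures", "pct_pass"):
                    value = row[col]
                    if value is not None and not (isinstance(value, float) and np.isnan(value)):
                        assert 0 <= value <= 100

    def test_unknown_group_journal_is_a_configuration_error(self):
        with pytest.raises(UnknownJournalError):
            summarize([_article("A")], {"group": ["A", "Nonexistent"]})

    def test_empty_corpus_is_a_usage_error(self):
        with pytest.raises(ValueError):
            summarize([])


class TestPanelAudit:
    def test_printed_panel_audit_counts_give_90_and_87(self):
        assert panel_audit_compare(panel_audit_articles()) == (90, 87)

    def test_all_imaging_fixture_is_100_100(self):
        art = ArticleRecord(
            journal="J",
            n_figures_total=5,
            n_figures_imaging=5,
            n_panels_total=40,
            n_panels_imaging=40,
        )
        assert panel_audit_compare([art]) == (100, 100)

    def test_randomized_fixture_equals_brute_force_recount(self, rng):
        articles = []
        for _ in range(12):
            nf = int(rng.integers(1, 10))
            npan = int(rng.integers(nf, 60))
            articles.append(
                ArticleRecord(
                    journal="Development",
                    n_figures_total=nf,
                    n_figures_imaging=int(rng.integers(0, nf + 1)),
                    n_panels_total=npan,
                    n_panels_imaging=int(rng.integers(0, npan + 1)),
                )
            )
        fig, panel = panel_audit_compare(articles)
        assert fig == pct(
            sum(a.n_figures_imaging for a in articles),
            sum(a.n_figures_total for a in articles),
        )
        assert panel == pct(
            sum(a.n_panels_imaging for a in articles),
            sum(a.n_panels_total for a in articles),
        )

    def test_missing_panel_counts_are_a_usage_error(self):
        with pytest.raises(ValueError):
            panel_audit_compare([_article("J")])


def test_corpus_figure_totals_are_self_consistent():
    imaging, total = CORPUS_FIGURE_COUNTS
    assert imaging <= total
    fig_img, fig_total, panel_img, panel_total = PANEL_AUDIT_COUNTS
    assert fig_img <= fig_total and panel_img <= panel_total


def test_csv_round_trip_reproduces_identical_summaries(tmp_path):
    articles = journal_count_articles()
    path = tmp_path / "articles.csv"
    articles_to_csv(articles, path)
    back = articles_from_csv(path)
    assert back == articles
    assert summarize(back, DEFAULT_GROUPS) == summarize(articles, DEFAULT_GROUPS)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["A", "B"]),
            st.integers(0, 8),
            st.integers(0, 8),
        ),
        min_size=1,
        max_size=12,
    )
)
def test_article_invariants_enforced_and_summaries_bounded(entries):
    articles = []
    for journal, total, imaging in entries:
        total = max(total, 1)
        imaging = min(imaging, total)
        articles.append(_article(journal, total, imaging, (50, 25)))
    summary = summarize(articles)
    total_row = summary.row("Total")
    assert 0 <= total_row["pct_imaging_figures"] <= 100
    assert total_row["n_with_imaging"] <= total_row["n_articles"]
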