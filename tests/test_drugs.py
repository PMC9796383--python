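"""Drug scoring, top-quantile enrichment, repurposing triage."""

import math

import numpy as np
import pytest

from seizekit.datasets import ge_reference_bundle, load_repurposing_reference
from seizekit.drugs import (
    DrugProfile,
    DrugRank,
    drug_scores,
    load_drug_profiles,
    rank_enrichment,
    repurposing_candidates,
    write_drug_profiles,
)
from seizekit.evidence import EvidenceDatabase
from .conftest import record


def profile(name, targets=(), used=True, asd=False, studies=0, models=0, indications=("pain",)):
    return DrugProfile(
        drug_name=name, targets=frozenset(targets), used_in_humans=used,
        antiseizure_approved=asd, indications=tuple(indications),
        n_animal_studies=studies, n_animal_models=models,
    )


class TestDrugScores:
    def test_score_sums_target_citations(self):
        db, _ = ge_reference_bundle()  # SCN1A 290, GABRA2 9 citations
        ranks = drug_scores(db, [profile("d1", {"SCN1A", "GABRA2"}), profile("d2", {"PCDH7"})])
        by_name = {r.drug_name: r for r in ranks}
        assert by_name["d1"].score == 299
        assert by_name["d1"].rank == 1
        assert by_name["d2"].score == 1

    def test_no_db_targets_scores_zero_but_stays_ranked(self, tiny_db):
        ranks = drug_scores(tiny_db, [profile("d1", {"NOTINDB"}), profile("d2", {"GENEA"})])
        by_name = {r.drug_name: r for r in ranks}
        assert by_name["d1"].score == 0
        assert by_name["d1"].rank == 2
        assert by_name["d1"].percentile == 1.0

    def test_equal_scores_ordered_by_name(self, tiny_db):
        ranks = drug_scores(tiny_db, [profile("zeta", {"GENEB"}), profile("alpha", {"GENEB"})])
        assert [r.drug_name for r in ranks] == ["alpha", "zeta"]
        assert [r.rank for r in ranks] == [1, 2]

    def test_duplicate_names_rejected(self, tiny_db):
        with pytest.raises(ValueError, match="duplicate"):
            drug_scores(tiny_db, [profile("d"), profile("d")])

    def test_added_citation_never_worsens_rank(self, tiny_db):
        profiles = [profile("a", {"GENEA"}), profile("b", {"GENEB"}), profile("c", {"GENEB"})]
        before = {r.drug_name: r for r in drug_scores(tiny_db, profiles)}
        boosted = EvidenceDatabase(list(tiny_db.records) + [record("GENEA", "fly", "99")])
        after = {r.drug_name: r for r in drug_scores(boosted, profiles)}
        assert after["a"].score >= before["a"].score
        assert after["a"].rank <= before["a"].rank


class TestRankEnrichment:
    @staticmethod
    def ranking(n):
        return [DrugRank(f"d{i:03d}", score=n - i, rank=i, percentile=i / n) for i in range(1, n + 1)]

    def test_all_labels_in_top_fifth_forces_fold_five(self):
        ranks = self.ranking(100)
        labels = {r.drug_name: r.rank <= 12 for r in ranks}
        res = rank_enrichment(ranks, labels, top_fraction=0.2)
        assert res.fold == pytest.approx(5.0)
        assert (res.k_labeled_in_bin, res.K_labeled, res.m_top_bin) == (12, 12, 20)

    def test_exact_p_value_from_binomial_ratio(self):
        # k=K=10 of N=100 in bin m=20: p = C(20,10)/C(100,10)
        ranks = self.ranking(100)
        labels = {r.drug_name: r.rank <= 10 for r in ranks}
        res = rank_enrichment(ranks, labels, top_fraction=0.2)
        expected = math.comb(20, 10) / math.comb(100, 10)
        assert res.p_value == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(1.067e-8, rel=1e-3)

    def test_bin_size_is_ceiling(self):
        ranks = self.ranking(11)
        labels = {r.drug_name: r.rank == 1 for r in ranks}
        res = rank_enrichment(ranks, labels, top_fraction=0.2)
        assert res.m_top_bin == 3  # ceil(0.2 * 11)

    def test_no_labels_rejected(self):
        ranks = self.ranking(10)
        with pytest.raises(ValueError, match="labeled"):
            rank_enrichment(ranks, {r.drug_name: False for r in ranks})

    def test_invariant_to_relabeling_unlabeled_drugs(self):
        """fold and p depend only on which drugs are labeled, not on any
        permutation of the unlabeled drugs among themselves."""
        rng = np.random.default_rng(8)
        n = 50
        scores = rng.integers(0, 100, size=n)
        order = np.argsort(-scores, kind="stable")
        names = [f"d{i:02d}" for i in range(n)]
        ranks = [DrugRank(names[j], int(scores[j]), r + 1, (r + 1) / n) for r, j in enumerate(order)]
        labels = {nm: i < 8 for i, nm in enumerate(names)}
        base = rank_enrichment(ranks, labels)
        # swap two unlabeled drugs' identities in the ranking
        unlabeled = [r for r in ranks if not labels[r.drug_name]]
        a, b = unlabeled[0], unlabeled[-1]
        swapped = [
            DrugRank(b.drug_name if r is a else a.drug_name if r is b else r.drug_name,
                     r.score, r.rank, r.percentile)
            for r in ranks
        ]
        res = rank_enrichment(swapped, labels)
        assert (res.fold, res.p_value) == (base.fold, base.p_value)

    def test_mean_fold_near_one_under_random_labels(self):
        """Uniformly random labels over seeded replicates: mean fold within
        3 SE of 1.0 (the null of the ranking hypothesis)."""
        rng = np.random.default_rng(17)
        ranks = self.ranking(60)
        folds = []
        for _ in range(500):
            chosen = rng.choice(60, size=9, replace=False)
            labels = {r.drug_name: i in set(chosen.tolist()) for i, r in enumerate(ranks)}
            folds.append(rank_enrichment(ranks, labels).fold)
        folds = np.asarray(folds)
        se = folds.std(ddof=1) / np.sqrt(len(folds))
        assert abs(folds.mean() - 1.0) <= 3 * se


class TestRepurposing:
    def test_reference_style_row_retained(self):
        # a Riluzole-like profile: used in humans, not antiseizure-approved,
        # one database target, 4 studies in 4 models
        db, _ = ge_reference_bundle()
        profiles = [profile("Riluzole", {"SCN1A"}, studies=4, models=4,
                            indications=("Amyotrophic lateral sclerosis",))]
        ranks = drug_scores(db, profiles)
        out = repurposing_candidates(ranks, profiles, db)
        assert len(out) == 1
        row = out[0]
        assert (row.drug_name, row.n_animal_studies, row.n_animal_models) == ("Riluzole", 4, 4)
        assert row.score == 290

    def test_antiseizure_approved_excluded(self, tiny_db):
        profiles = [profile("d1", {"GENEA"}, asd=True, studies=5, models=2)]
        ranks = drug_scores(tiny_db, profiles)
        assert repurposing_candidates(ranks, profiles, tiny_db) == []

    def test_no_animal_studies_excluded(self, tiny_db):
        profiles = [profile("d1", {"GENEA"}, studies=0)]
        ranks = drug_scores(tiny_db, profiles)
        assert repurposing_candidates(ranks, profiles, tiny_db) == []

    def test_no_db_target_excluded(self, tiny_db):
        profiles = [profile("d1", {"XNOTDB"}, studies=3, models=1)]
        ranks = drug_scores(tiny_db, profiles)
        assert repurposing_candidates(ranks, profiles, tiny_db) == []

    def test_sorted_by_score_descending(self, tiny_db):
        profiles = [profile("low", {"GENEB"}, studies=1, models=1),
                    profile("high", {"GENEA"}, studies=1, models=1)]
        ranks = drug_scores(tiny_db, profiles)
        out = repurposing_candidates(ranks, profiles, tiny_db)
        assert [c.drug_name for c in out] == ["high", "low"]


def test_profile_invariant_enforced():
    with pytest.raises(ValueError, match="used_in_humans"):
        DrugProfile("d", frozenset(), used_in_humans=False, antiseizure_approved=True)


def test_drug_tsv_round_trip(tmp_path):
    profiles = [
        profile("d1", {"A", "B"}, studies=3, models=2, indications=("pain", "migraine")),
        profile("d2", set(), asd=True, indications=()),
    ]
    tpath, mpath = tmp_path / "targets.tsv", tmp_path / "meta.tsv"
    write_drug_profiles(profiles, tpath, mpath)
    again = load_drug_profiles(tpath, mpath)
    assert again == profiles


def test_reference_repurposing_table_shape():
    table = load_repurposing_reference()
    assert len(table) == 16
    top = table.iloc[0]
    assert (top.drug_name, top.citations, top.studies, top.models) == ("Riluzole", 482, 4, 4)
    assert (table.studies >= 1).all()  # every row has animal efficacy evidence
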