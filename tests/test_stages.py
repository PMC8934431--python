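import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from meadowsucc.community import community_summary
from meadowsucc.io import SurveyTable
from meadowsucc.stages import (
    WardStageClusterer,
    assign_stages,
    feature_matrix,
    order_stages,
    ward_cluster,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# brute-force Ward oracle: greedy minimum increase in within-cluster variance,
# evaluated directly from the raw points (Lance-Williams-free)

def brute_force_ward(X):
    """Return the merge sequence [(members_a, members_b, height), ...]."""
    X = np.asarray(X, dtype=float)
    clusters = [[i] for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = X[clusters[a]], X[clusters[b]]
                na, nb = len(ca), len(cb)
                delta = (na * nb / (na + nb)) * np.sum(
                    (ca.mean(axis=0) - cb.mean(axis=0)) ** 2)
                if best is None or delta < best[0]:
                    best = (delta, a, b)
        delta, a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]),
                       np.sqrt(2.0 * delta)))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [
            clusters[a] + clusters[b]]
    return merges


def _linkage_merges(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (i, j, h, _) in enumerate(Z):
        a, b = members[int(i)], members[int(j)]
        out.append((a, b, h))
        members[n + k] = a | b
    return out


def test_ward_matches_brute_force_oracle(rng):
    """Merge sets and heights agree with direct variance-increase greedy."""
    for trial in range(100):
        n = int(rng.integers(3, 9))
        d = int(rng.integers(1, 4))
        X = rng.normal(size=(n, d))
        model = WardStageClusterer(n_clusters=1).fit(X)
        got = _linkage_merges(model.linkage_, n)
        expected = brute_force_ward(X)
        for (ga, gb, gh), (ea, eb, eh) in zip(got, expected):
            assert {ga, gb} == {ea, eb}
            assert gh == pytest.approx(eh, rel=1e-9)


def test_merge_heights_non_decreasing(rng):
    X = rng.normal(size=(40, 4))
    model = WardStageClusterer(n_clusters=4).fit(X)
    heights = model.linkage_[:, 2]
    assert (np.diff(heights) >= -1e-12).all()


def test_two_separated_clouds_recovered(rng):
    X = np.vstack([rng.normal(0, 0.1, size=(20, 2)),
                   rng.normal(10, 0.1, size=(20, 2))])
    truth = [0] * 20 + [1] * 20
    labels = WardStageClusterer(n_clusters=2).fit_predict(X)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_degenerate_cut_each_point_own_cluster(rng):
    X = rng.normal(size=(6, 3))
    labels, _ = ward_cluster(X, 6)
    assert len(set(labels.tolist())) == 6


def test_k_bounds_validated(rng):
    X = rng.normal(size=(5, 2))
    with pytest.raises(ValueError):
        WardStageClusterer(n_clusters=6).fit(X)
    with pytest.raises(ValueError):
        WardStageClusterer(n_clusters=0).fit(X)


def test_clustering_invariant_to_row_order(survey, fgmap):
    a1 = assign_stages(survey, fgmap)
    reordered = SurveyTable(list(reversed(survey.records)),
                            species_universe=survey.species_universe)
    a2 = assign_stages(reordered, fgmap)
    s1 = dict(zip(a1.quadrat_ids, a1.stages))
    s2 = dict(zip(a2.quadrat_ids, a2.stages))
    assert s1 == s2


def test_feature_matrix_hand_case(tiny_fgmap):
    recs = [make_record("Q1", {"A": 2.0}), make_record("Q2", {"B": 3.0}, sbd=1.1)]
    feats = feature_matrix(SurveyTable(recs), tiny_fgmap)
    # pure-sedge vs pure-grass: share columns are opposite-signed z-scores
    assert feats.loc["Q1", "share_sedge"] > 0 > feats.loc["Q2", "share_sedge"]
    assert feats.loc["Q2", "share_grass"] > 0 > feats.loc["Q1", "share_grass"]
    # constant columns (toxic/shrub shares, sr) are dropped
    assert "share_toxic_forb" not in feats.columns
    np.testing.assert_allclose(feats.mean(), 0, atol=1e-12)
    np.testing.assert_allclose(feats.std(ddof=0), 1, atol=1e-12)


def test_identical_quadrats_identical_rows(tiny_fgmap):
    recs = [make_record("Q1", {"A": 2.0, "B": 1.0}),
            make_record("Q2", {"A": 2.0, "B": 1.0}),
            make_record("Q3", {"B": 4.0})]
    feats = feature_matrix(SurveyTable(recs), tiny_fgmap)
    np.testing.assert_allclose(feats.loc["Q1"], feats.loc["Q2"])


def test_generated_survey_separates_at_k4(survey, fgmap):
    feats = feature_matrix(survey, fgmap)
    labels, _ = ward_cluster(feats.to_numpy(), 4)
    assert silhouette_score(feats.to_numpy(), labels) > 0


def test_order_stages_by_sedge_then_toxic():
    labels = np.repeat([0, 1, 2, 3], 5)
    sedge = np.repeat([0.05, 0.46, 0.23, 0.24], 5)
    toxic = np.repeat([0.44, 0.08, 0.29, 0.10], 5)
    stage_of = order_stages(labels, sedge, toxic)
    # descending sedge share: cluster 1 (0.46) -> stage 1, ... cluster 0 -> 4
    assert stage_of == {1: 1, 3: 2, 2: 3, 0: 4}


def test_order_stages_tie_broken_by_toxic_then_label():
    labels = np.repeat([0, 1], 3)
    sedge = np.repeat([0.3, 0.3], 3)
    toxic = np.repeat([0.5, 0.1], 3)
    assert order_stages(labels, sedge, toxic) == {1: 1, 0: 2}
    stage_of = order_stages(labels, sedge, np.repeat([0.2, 0.2], 3))
    assert stage_of == {0: 1, 1: 2}


def test_single_cluster_is_stage_one():
    labels = np.zeros(4, dtype=int)
    assert order_stages(labels, np.ones(4) * 0.3, np.ones(4) * 0.1) == {0: 1}


def test_stage_recovery_on_default_survey(survey, fgmap):
    truth = [r.stage for r in survey.records]
    assignment = assign_stages(survey, fgmap)
    assert adjusted_rand_score(truth, assignment.stages) >= 0.75
    # ordered stages point the right way: stage 1 sedge-rich, stage 4 toxic-rich
    summ = community_summary(survey, fgmap)
    by_stage = summ.groupby(assignment.stages)[["share_sedge", "share_toxic_forb"]].mean()
    assert by_stage.loc[1, "share_sedge"] == by_stage["share_sedge"].max()
    assert by_stage.loc[4, "share_toxic_forb"] == by_stage["share_toxic_forb"].max()
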