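import math

import numpy as np
import pytest
import scipy.stats

from kinsnp import (
    MISSING,
    ConditionalTable,
    DegreeRanges,
    GammaParams,
    IbdSegment,
    UNRELATED_ORDINAL,
    build_reference_model,
    classify_conditional,
    classify_gamma,
    classify_mean_length,
    embed_pairs,
    fit_gamma,
    gamma_distance,
    gamma_profile,
    ibd0_classify,
    king_classify,
    king_phi,
    pair_sharing_matrix,
    simulate_founders,
    total_shared_length,
)
from kinsnp.kinship_methods import ReferenceModel

from conftest import uniform_manifest


def seg(length_mbp, chrom=1):
    return IbdSegment(chrom, 0, 1, 1, int(length_mbp * 1e6) + 1, 2)


class TestDegreeRanges:
    def test_expected_ibd0_values(self):
        r = DegreeRanges()
        assert r.expected_ibd0(1) == 0.0  # parent-child row
        assert [e for _, d, e, _, _ in r.ibd0 if d == 1] == [0.0, 0.25]
        assert r.expected_ibd0(4) == pytest.approx(0.875)
        assert r.expected_ibd0(5) == pytest.approx(0.9375)
        assert r.expected_ibd0(2) == pytest.approx(0.5)

    def test_expected_values_classify_into_own_degree(self):
        r = DegreeRanges()
        for label, d, expected, lo, hi in r.ibd0:
            if label == "parent-child":
                continue  # expected 0 sits at the open lower end of its row
            assert r.lookup_ibd0(expected)[1] == d
        assert r.lookup_ibd0(0.0)[0] == "parent-child"
        for label, d, expected, lo, hi in r.king:
            if label == "unrelated":
                continue
            assert r.lookup_king(expected)[1] == d

    def test_intervals_tile_without_overlap(self):
        r = DegreeRanges()
        for grid, lookup in [
            (np.linspace(1e-6, 1.0, 4001), r.lookup_ibd0),
            (np.linspace(1e-6, 2 ** (-3 / 2), 4001), r.lookup_king),
        ]:
            for x in grid:
                lookup(float(x))  # exactly one interval matches, else raises

    def test_king_boundaries(self):
        r = DegreeRanges()
        assert r.lookup_king(0.25) == ("degree-1", 1)
        assert r.lookup_king(2 ** (-11 / 2)) == ("degree-5", 5)  # upper-inclusive
        assert r.lookup_king(0.0001) == ("unrelated", UNRELATED_ORDINAL)


class TestGamma:
    def test_ml_fit_recovers_parameters(self):
        rng = np.random.default_rng(1)
        draws = scipy.stats.gamma.rvs(a=2.0, scale=15.0, size=5000, random_state=rng)
        params = fit_gamma(draws)
        assert params.k == pytest.approx(2.0, abs=0.1)
        assert params.k * params.theta == pytest.approx(draws.mean(), rel=1e-9)

    def test_exponential_data_shape_one(self):
        rng = np.random.default_rng(2)
        draws = rng.exponential(20.0, size=5000)
        params = fit_gamma(draws)
        assert params.k == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("lengths", [[], [12.0], [7.0, 7.0, 7.0]])
    def test_degenerate_data_abstains(self, lengths):
        assert fit_gamma(lengths) is None

    def test_profile_closed_forms(self):
        # k=1 is the exponential density: P(20) = e^-1 / 20
        p = gamma_profile(GammaParams(1.0, 20.0))
        assert p[19] == pytest.approx(math.exp(-1) / 20)
        # k=2, theta=10: P(10) = 10 e^-1 / 100
        p = gamma_profile(GammaParams(2.0, 10.0))
        assert p[9] == pytest.approx(10 * math.exp(-1) / 100)
        assert (p >= 0).all()

    def test_profile_mass_captured_when_mean_small(self):
        p = gamma_profile(GammaParams(2.0, 10.0))
        assert p.sum() == pytest.approx(1.0, abs=0.02)

    def test_distance_properties(self):
        a = gamma_profile(GammaParams(2.0, 10.0))
        b = gamma_profile(GammaParams(1.5, 20.0))
        assert gamma_distance(a, a) == 0.0
        assert gamma_distance(a, b) == gamma_distance(b, a)
        x = np.zeros(150)
        y = np.zeros(150)
        y[10], y[20] = 0.1, 0.1
        assert gamma_distance(x, y) == pytest.approx(0.2 / 150)
        with pytest.raises(ValueError):
            gamma_distance(np.zeros(150), np.zeros(100))


def toy_model(ms, detector="A1", degrees=None, gammas=None):
    degrees = degrees or {"deg3": 3, "deg4": 4, "deg5": 5, "unrelated": 10}
    table = ConditionalTable.from_totals(
        [(r, m) for r, m in ms.items()], relationships=sorted(ms)
    )
    return ReferenceModel(
        detector=detector,
        degrees=degrees,
        ms=ms,
        gammas=gammas or {r: None for r in ms},
        conditional=table,
        genome_length_mbp=2900.0,
    )


class TestMeanLengthClassifier:
    def test_nearest_mean(self):
        model = toy_model({"deg3": 170.0, "deg4": 90.0, "deg5": 45.0})
        assert classify_mean_length(100.0, model).relationship == "deg4"

    def test_tie_resolves_to_higher_degree(self):
        model = toy_model({"deg3": 170.0, "deg4": 90.0, "deg5": 45.0})
        # 130 is equidistant from deg3 and deg4
        assert classify_mean_length(130.0, model).degree == 4

    def test_zero_total_matches_unrelated(self):
        model = toy_model(
            {"deg3": 170.0, "unrelated": 1.0},
            degrees={"deg3": 3, "unrelated": UNRELATED_ORDINAL},
        )
        assert classify_mean_length(0.0, model).relationship == "unrelated"


class TestConditionalClassifier:
    def test_probabilities_from_counts(self):
        table = ConditionalTable.from_totals(
            [("R1", 120.0)] * 3 + [("R2", 130.0)], relationships=["R1", "R2"]
        )
        probs = table.probabilities(110.0)
        assert probs["R1"] == pytest.approx(0.75)
        assert probs.sum() == pytest.approx(1.0)

    def test_populated_bins_normalised(self):
        rng = np.random.default_rng(0)
        totals = [("A", float(t)) for t in rng.uniform(0, 500, 200)]
        totals += [("B", float(t)) for t in rng.uniform(100, 900, 200)]
        table = ConditionalTable.from_totals(totals)
        sums = table.counts.sum(axis=1)
        for b in np.flatnonzero(sums.to_numpy() > 0):
            assert table.counts.loc[b].sum() / sums.iloc[b] == pytest.approx(1.0)

    def test_overflow_clamped_to_last_bin(self):
        table = ConditionalTable.from_totals([("A", 3100.0)])
        assert table.bin_of(3100.0) == 59
        assert table.counts.loc[59, "A"] == 1

    def test_empty_bin_falls_back_to_nearest_populated(self):
        model = toy_model({"deg3": 600.0, "deg5": 100.0})
        res = classify_conditional(320.0, model)  # empty bin between the two
        assert res.relationship == "deg5"  # 100 is nearer than 600

    def test_argmax_tie_resolves_to_higher_degree(self):
        table = ConditionalTable.from_totals(
            [("deg3", 120.0), ("deg4", 130.0)], relationships=["deg3", "deg4"]
        )
        model = toy_model({"deg3": 0.0, "deg4": 0.0})
        model.conditional = table
        assert classify_conditional(110.0, model).degree == 4


class TestGammaClassifier:
    def test_matching_reference_profile_wins(self):
        gammas = {"deg3": GammaParams(2.0, 30.0), "deg5": GammaParams(1.2, 10.0)}
        model = toy_model({"deg3": 0, "deg5": 0}, gammas=gammas)
        rng = np.random.default_rng(3)
        lengths = scipy.stats.gamma.rvs(a=2.0, scale=30.0, size=400, random_state=rng)
        res = classify_gamma([seg(l) for l in lengths], model)
        assert res.relationship == "deg3"

    def test_single_segment_abstains(self):
        model = toy_model({"deg3": 0}, gammas={"deg3": GammaParams(2, 20)})
        res = classify_gamma([seg(30.0)], model)
        assert res.abstained and res.degree is None


class TestIbd0Classifier:
    @pytest.mark.parametrize(
        "proportion,label",
        [(0.05, "parent-child"), (0.80, "degree-3"), (0.999, "unrelated")],
    )
    def test_examples(self, proportion, label):
        res = ibd0_classify((1 - proportion) * 1000.0, 1000.0, DegreeRanges())
        assert res.relationship == label

    def test_total_exceeding_genome_rejected(self):
        with pytest.raises(ValueError):
            ibd0_classify(1200.0, 1000.0, DegreeRanges())


class TestKingPhi:
    def test_self_pair_is_exactly_half(self):
        man = uniform_manifest(2000, spacing_bp=100_000)
        codes = simulate_founders(man, 1, seed=0).codes
        phi, counts = king_phi(np.vstack([codes, codes]))
        assert phi == 0.5
        assert counts.n_opp_hom == 0

    def test_direct_count_arithmetic(self):
        # counts: both-het 30, opposite-hom 5, het_i 40, het_j 30
        cols = []
        cols += [(1, 1)] * 30   # both heterozygous
        cols += [(1, 0)] * 10   # only the first sample heterozygous
        cols += [(0, 2)] * 5    # opposite homozygotes
        cols += [(0, 0)] * 55
        a, b = np.array(cols, dtype=np.int8).T
        phi, counts = king_phi(np.vstack([a, b]), convention="greater")
        assert (counts.n_both_het, counts.n_opp_hom) == (30, 5)
        assert (counts.n_het_i, counts.n_het_j) == (40, 30)
        assert phi == pytest.approx(20 / 80 + 0.5 - 70 / 160)  # 0.3125

    def test_unrelated_pair_near_zero(self):
        man = uniform_manifest(10_000, spacing_bp=250_000, alt_freq=0.4)
        f = simulate_founders(man, 2, seed=4)
        phi, _ = king_phi(f.codes)
        assert phi == pytest.approx(0.0, abs=0.02)

    def test_no_heterozygotes_abstains(self):
        pair = np.zeros((2, 50), dtype=np.int8)
        phi, _ = king_phi(pair)
        assert phi is None
        res = king_classify(phi, DegreeRanges())
        assert res.abstained

    def test_missing_loci_excluded(self):
        a = np.array([1, 1, MISSING, 0], dtype=np.int8)
        b = np.array([1, MISSING, 1, 2], dtype=np.int8)
        _, counts = king_phi(np.vstack([a, b]))
        assert counts.n_both_het == 1
        assert counts.n_opp_hom == 1

    def test_classify_clamps_above_first_degree(self):
        res = king_classify(0.45, DegreeRanges())
        assert res.degree == 1


class TestReferenceModel:
    def test_mean_total_length(self):
        refs = [("cousins", 3, [seg(60), seg(40)]), ("cousins", 3, [seg(200)])]
        model = build_reference_model(refs, genome_length_mbp=2900.0)
        assert model.ms["cousins"] == pytest.approx(150.0)

    def test_zero_segment_relationship_has_no_gamma(self):
        refs = [("unrelated", 10, []), ("unrelated", 10, [])]
        model = build_reference_model(refs, genome_length_mbp=2900.0)
        assert model.ms["unrelated"] == 0.0
        assert model.gammas["unrelated"] is None

    def test_json_roundtrip(self, tmp_path):
        refs = [
            ("sibs", 1, [seg(100), seg(80), seg(55), seg(70)]),
            ("cousins", 3, [seg(60), seg(40)]),
        ]
        model = build_reference_model(refs, genome_length_mbp=2900.0)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ReferenceModel.from_json(path)
        assert back.ms == model.ms
        assert back.degrees == model.degrees
        assert back.gammas["sibs"].k == pytest.approx(model.gammas["sibs"].k)
        assert back.conditional.counts.to_numpy().sum() == 4 + 2 - 4  # per-pair totals


class TestEmbeddings:
    def test_sharing_matrix_codes(self):
        man = uniform_manifest(6)
        same = np.vstack([np.ones(6), np.ones(6)]).astype(np.int8)
        opposite = np.vstack([np.zeros(6), np.full(6, 2)]).astype(np.int8)
        hole = same.copy()
        hole[0, 2] = MISSING
        M = pair_sharing_matrix([same, opposite, hole], man, missing_policy="pca")
        assert (M[0] == 2).all()
        assert (M[1] == 0).all()
        assert M[2, 2] == -1
        M2 = pair_sharing_matrix([hole], man, missing_policy="pcoa")
        assert np.isnan(M2[0, 2])

    def test_duplicated_rows_embed_identically(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, (6, 50)).astype(float)
        X[3] = X[0]
        for method in ("pca", "pcoa"):
            Y = embed_pairs(X, method=method, n_components=2)
            np.testing.assert_allclose(Y[0], Y[3], atol=1e-8)

    def test_component_count_truncated_to_rank(self, caplog):
        X = np.random.default_rng(1).random((3, 20))
        with caplog.at_level("WARNING"):
            Y = embed_pairs(X, method="pca", n_components=10)
        assert Y.shape[1] == 2

    def test_first_degree_separates_from_unrelated(self, small_panel, small_map):
        import kinsnp

        cat = {s.name: s for s in kinsnp.relationship_catalogue()}
        from kinsnp.pedigree_sim import _founder_haplotypes

        rng = np.random.default_rng(5)
        pairs, labels = [], []
        for _ in range(15):
            hap = _founder_haplotypes(small_panel, 2, rng)
            mat, _ = kinsnp.gene_drop_pair(cat["full-siblings"], hap, small_map,
                                           small_panel, rng)
            pairs.append(mat.codes)
            labels.append("sib")
        for _ in range(15):
            f = _founder_haplotypes(small_panel, 2, rng)
            pairs.append(np.vstack([(f[0] + f[1]), (f[2] + f[3])]).astype(np.int8))
            labels.append("unrel")
        M = pair_sharing_matrix(pairs, small_panel)
        Y = embed_pairs(M, method="pca", n_components=2)
        pc1 = Y[:, 0]
        sib = pc1[np.array(labels) == "sib"]
        unrel = pc1[np.array(labels) == "unrel"]
        pooled_sd = np.sqrt((sib.var() + unrel.var()) / 2)
        assert abs(sib.mean() - unrel.mean()) > 4 * pooled_sd


class TestTotals:
    def test_sum_and_empty(self):
        assert total_shared_length([seg(30), seg(20)]) == pytest.approx(50.0)
        assert total_shared_length([]) == 0.0
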