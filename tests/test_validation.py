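"""Sampling, agreement, adjudication and validation-table arithmetic."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from infoveil import (
    CategoryAssignment,
    ValidationTable,
    adjudicate,
    build_validation_table,
    cohens_kappa,
    kappa_by_stratum,
    kappa_range,
    stratified_sample,
)
from infoveil.errors import (
    AllocationError,
    AnnotationMismatchError,
    MissingResolutionError,
    MissingStratumError,
    ValidationError,
)
from infoveil.rounding import percent


def labels_to_maps(a_labels, b_labels):
    ids = [f"p{i}" for i in range(len(a_labels))]
    return dict(zip(ids, a_labels)), dict(zip(ids, b_labels))


FULL = {"m": "motivation", "c": "consequence", "n": "neither"}


def expand(short):
    return [FULL[s] for s in short]


class TestKappa:
    def test_identical_coders_give_exactly_one(self):
        a, b = labels_to_maps(expand("mmcnn"), expand("mmcnn"))
        result = cohens_kappa(a, b)
        assert result.kappa == 1.0
        assert result.observed_agreement == 1.0

    def test_hand_computed_contingency_example(self):
        # 3x3 table: p_o = 8/10, p_e = (3*3 + 2*3 + 5*4)/100 = 0.35
        a, b = labels_to_maps(expand("mmmccnnnnn"), expand("mmcccnnnnm"))
        result = cohens_kappa(a, b)
        assert result.observed_agreement == pytest.approx(0.8, abs=1e-15)
        assert result.expected_agreement == pytest.approx(0.35, abs=1e-15)
        assert result.kappa == pytest.approx(9 / 13, abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(5)
        labels = ["motivation", "consequence", "neither"]
        for _ in range(20):
            n = int(rng.integers(5, 60))
            va = [labels[i] for i in rng.integers(0, 3, n)]
            vb = [labels[i] for i in rng.integers(0, 3, n)]
            if len(set(va)) == 1 and va == vb:
                continue  # sklearn returns nan for a degenerate 1x1 table
            a, b = labels_to_maps(va, vb)
            ours = cohens_kappa(a, b).kappa
            ref = cohen_kappa_score(va, vb)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_symmetric_and_relabel_invariant(self):
        a, b = labels_to_maps(expand("mmcnncmn"), expand("mcnnnmmn"))
        forward = cohens_kappa(a, b).kappa
        assert cohens_kappa(b, a).kappa == pytest.approx(forward, abs=1e-15)
        swap = {"motivation": "neither", "neither": "motivation",
                "consequence": "consequence"}
        a2 = {k: swap[v] for k, v in a.items()}
        b2 = {k: swap[v] for k, v in b.items()}
        assert cohens_kappa(a2, b2).kappa == pytest.approx(forward, abs=1e-15)

    def test_errors(self):
        a, b = labels_to_maps(expand("mn"), expand("mn"))
        with pytest.raises(AnnotationMismatchError):
            cohens_kappa(a, {"q1": "neither", "q2": "neither"})
        with pytest.raises(ValidationError):
            cohens_kappa({"p": "neither"}, {"p": "neither"})

    def test_independent_uniform_coders_center_on_zero(self):
        rng = np.random.default_rng(6)
        labels = ["motivation", "consequence", "neither"]
        kappas = []
        for _ in range(60):
            n = 300
            a, b = labels_to_maps(
                [labels[i] for i in rng.integers(0, 3, n)],
                [labels[i] for i in rng.integers(0, 3, n)],
            )
            kappas.append(cohens_kappa(a, b).kappa)
        sem = np.std(kappas, ddof=1) / np.sqrt(len(kappas))
        # the kappa ratio estimator carries O(1/n) finite-sample bias
        assert abs(np.mean(kappas)) < 3 * sem + 1 / (n - 1)


class TestAdjudicate:
    def test_full_agreement_needs_no_resolutions(self):
        a, b = labels_to_maps(expand("mcn"), expand("mcn"))
        assert adjudicate(a, b) == a

    def test_disagreement_takes_resolution_label(self):
        a, b = labels_to_maps(expand("mc"), expand("mn"))
        final = adjudicate(a, b, {"p1": "neither"})
        assert final == {"p0": "motivation", "p1": "neither"}

    def test_missing_resolution_is_an_error(self):
        a, b = labels_to_maps(expand("mc"), expand("mn"))
        with pytest.raises(MissingResolutionError):
            adjudicate(a, b)

    def test_every_post_gets_exactly_one_label(self):
        rng = np.random.default_rng(7)
        labels = ["motivation", "consequence", "neither"]
        for _ in range(10):
            n = int(rng.integers(2, 50))
            a, b = labels_to_maps(
                [labels[i] for i in rng.integers(0, 3, n)],
                [labels[i] for i in rng.integers(0, 3, n)],
            )
            resolutions = {p: "neither" for p in a if a[p] != b[p]}
            final = adjudicate(a, b, resolutions)
            assert set(final) == set(a)
            assert all(v in labels for v in final.values())


def single_cat(post_id, category):
    return CategoryAssignment(
        post_id=post_id,
        categories=frozenset({category}),
        evidence={category: frozenset({"term"})},
    )


class TestStratifiedSample:
    def test_exhaustive_allocation_returns_whole_stratum(self):
        assignments = [single_cat("p1", "Cancer"), single_cat("p2", "Cancer")]
        frame = stratified_sample(assignments, {"Cancer": 2}, seed=99)
        assert sorted(frame["post_id"]) == ["p1", "p2"]
        assert set(frame["stratum"]) == {"Cancer"}

    def test_deterministic_under_seed(self):
        assignments = [single_cat(f"p{i}", "Pain") for i in range(30)]
        first = stratified_sample(assignments, {"Pain": 10}, seed=5)
        second = stratified_sample(assignments, {"Pain": 10}, seed=5)
        assert first.equals(second)
        third = stratified_sample(assignments, {"Pain": 10}, seed=6)
        assert set(first["post_id"]) != set(third["post_id"])

    def test_multilabel_post_occupies_one_stratum(self):
        multi = CategoryAssignment(
            post_id="p0",
            categories=frozenset({"Pain", "Stress"}),
            evidence={"Pain": frozenset({"achy"}), "Stress": frozenset({"stressed"})},
        )
        seen = set()
        for seed in range(30):
            frame = stratified_sample(
                [multi] + [single_cat(f"q{i}", "Pain") for i in range(3)]
                + [single_cat(f"r{i}", "Stress") for i in range(3)],
                {"Pain": 1, "Stress": 1},
                seed=seed,
            )
            assert list(frame["post_id"]).count("p0") <= 1
            seen |= set(frame.loc[frame["post_id"] == "p0", "stratum"])
        assert seen == {"Pain", "Stress"}  # both strata reachable across seeds

    def test_allocation_errors(self):
        assignments = [single_cat("p1", "Cancer")]
        with pytest.raises(AllocationError):
            stratified_sample(assignments, {"Cancer": 2}, seed=0)
        with pytest.raises(AllocationError):
            stratified_sample(assignments, {"Respiratory": 1}, seed=0)

    def test_inclusion_frequency_is_uniform(self):
        assignments = [single_cat(f"p{i}", "Pain") for i in range(5)]
        hits = {f"p{i}": 0 for i in range(5)}
        n_reps = 400
        for seed in range(n_reps):
            for post_id in stratified_sample(assignments, {"Pain": 2}, seed)["post_id"]:
                hits[post_id] += 1
        p = 2 / 5
        se = np.sqrt(p * (1 - p) / n_reps)
        for post_id, count in hits.items():
            assert abs(count / n_reps - p) < 3.5 * se


class TestValidationTable:
    def test_single_stratum_all_neither(self):
        table = build_validation_table(
            {f"p{i}": "neither" for i in range(7)},
            {f"p{i}": "Weight" for i in range(7)},
        )
        assert table.counts["Weight"] == {"motivation": 0, "consequence": 0, "neither": 7}
        assert table.row_percent("Weight", "neither") == 100.0
        assert table.row_percent("Weight", "motivation") == 0.0
        assert table.health_related_percent == 0.0

    def test_missing_stratum_is_an_error(self):
        with pytest.raises(MissingStratumError):
            build_validation_table({"p0": "neither"}, {})

    def test_row_and_column_conservation_on_random_inputs(self):
        rng = np.random.default_rng(8)
        labels = ["motivation", "consequence", "neither"]
        strata_names = ["Cancer", "Pain", "Stress"]
        for _ in range(10):
            n = int(rng.integers(1, 80))
            adjudicated = {f"p{i}": labels[int(rng.integers(3))] for i in range(n)}
            strata = {f"p{i}": strata_names[int(rng.integers(3))] for i in range(n)}
            table = build_validation_table(adjudicated, strata)
            assert table.n_annotated == n
            for stratum in table.counts:
                assert table.row_total(stratum) == sum(table.counts[stratum].values())
            assert sum(table.column_total(l) for l in labels) == n

    def test_percentages_round_half_up_to_1_decimal(self):
        assert percent(1, 16) == 6.3  # 6.25 ties upward
        assert percent(3, 27) == 11.1
        assert percent(15, 35) == 42.9

    def test_from_counts_round_trip(self):
        table = ValidationTable.from_counts(
            {"Cancer": {"motivation": 15, "consequence": 4, "neither": 16}}
        )
        assert table.row_total("Cancer") == 35
        frame = table.to_frame()
        assert list(frame["stratum"]) == ["Cancer", "Total"]


class TestKappaByStratum:
    def test_range_over_strata(self):
        a, b = labels_to_maps(expand("mmnn" "mcnc"), expand("mmnn" "ccnn"))
        strata = {f"p{i}": ("good" if i < 4 else "bad") for i in range(8)}
        per = kappa_by_stratum(a, b, strata)
        assert per["good"].kappa == 1.0
        assert per["bad"].kappa < 1.0
        lo, hi = kappa_range(per)
        assert (lo, hi) == (per["bad"].kappa, 1.0)

    def test_missing_stratum_is_an_error(self):
        a, b = labels_to_maps(expand("mn"), expand("mn"))
        with pytest.raises(MissingStratumError):
            kappa_by_stratum(a, b, {"p0": "Cancer"})
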