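"""Unit-space construction and scaled Mahalanobis distance scoring."""

import numpy as np
import pytest

from mtshazard import (
    DataError,
    HazardCategory,
    ReferenceSpace,
    ScoreVector,
    SelectionCriteria,
    VARIABLES,
    fit_reference,
    fixture_flutolanil,
    mahalanobis_distance,
    quantify,
    quantify_all,
    score_all,
    select_normal_group,
)

from conftest import make_record

C = HazardCategory


def sv(cas, values):
    """Pad a short value list to a full 10-variable score vector."""
    values = [float(v) for v in values] + [1.0] * (len(VARIABLES) - len(values))
    return ScoreVector(cas, tuple(values), sum(values))


def make_ref(means, sds, corr, variables):
    corr = np.asarray(corr, dtype=float)
    return ReferenceSpace(
        variables=tuple(variables),
        means=dict(zip(variables, means)),
        sds=dict(zip(variables, sds)),
        degenerate=(),
        corr=corr,
        corr_inv=np.linalg.inv(corr),
        n_members=50,
        member_cas=(),
    )


def brute_force_md(x, means, sds, corr):
    """Independent oracle: cofactor-expansion inverse for k <= 3."""
    k = len(x)
    z = [(x[i] - means[i]) / sds[i] for i in range(k)]
    R = [[corr[i][j] for j in range(k)] for i in range(k)]
    if k == 1:
        Rinv = [[1.0 / R[0][0]]]
    elif k == 2:
        det = R[0][0] * R[1][1] - R[0][1] * R[1][0]
        Rinv = [[R[1][1] / det, -R[0][1] / det], [-R[1][0] / det, R[0][0] / det]]
    else:
        det = (
            R[0][0] * (R[1][1] * R[2][2] - R[1][2] * R[2][1])
            - R[0][1] * (R[1][0] * R[2][2] - R[1][2] * R[2][0])
            + R[0][2] * (R[1][0] * R[2][1] - R[1][1] * R[2][0])
        )
        cof = [
            [
                R[1][1] * R[2][2] - R[1][2] * R[2][1],
                -(R[1][0] * R[2][2] - R[1][2] * R[2][0]),
                R[1][0] * R[2][1] - R[1][1] * R[2][0],
            ],
            [
                -(R[0][1] * R[2][2] - R[0][2] * R[2][1]),
                R[0][0] * R[2][2] - R[0][2] * R[2][0],
                -(R[0][0] * R[2][1] - R[0][1] * R[2][0]),
            ],
            [
                R[0][1] * R[1][2] - R[0][2] * R[1][1],
                -(R[0][0] * R[1][2] - R[0][2] * R[1][0]),
                R[0][0] * R[1][1] - R[0][1] * R[1][0],
            ],
        ]
        Rinv = [[cof[j][i] / det for j in range(k)] for i in range(k)]
    quad = sum(z[i] * Rinv[i][j] * z[j] for i in range(k) for j in range(k))
    return quad / k


class TestSelectNormalGroup:
    def _population(self, n=15):
        """Low-hazard filler so the group always clears the size minimum."""
        recs = [make_record(cas=f"{i}-00-0") for i in range(n)]
        return recs

    def test_flutolanil_profile_selected(self):
        recs = self._population() + [fixture_flutolanil()]
        scores = quantify_all(recs)
        members = select_normal_group(scores, recs)
        assert "66332-96-5" in members

    def test_category1_excluded_even_with_low_total(self):
        bad = make_record(
            cas="9-99-9",
            **{**{v: C.NOT_APPLICABLE for v in VARIABLES}, "skin": C.CAT1},
        )
        recs = self._population() + [bad]
        scores = quantify_all(recs)
        assert quantify(bad).total < 280
        assert "9-99-9" not in select_normal_group(scores, recs)

    def test_total_over_limit_excluded(self):
        # ten Classification Not Possible = 300 points, no Category 1/2
        cnp = make_record(
            cas="9-99-9", **{v: C.CLASSIFICATION_NOT_POSSIBLE for v in VARIABLES}
        )
        recs = self._population() + [cnp]
        scores = quantify_all(recs)
        assert "9-99-9" not in select_normal_group(scores, recs)

    def test_threshold_inclusive_by_default(self):
        # nine Classification Not Possible + one NC hits 280 exactly
        rec = make_record(
            cas="8-88-8",
            **{
                **{v: C.CLASSIFICATION_NOT_POSSIBLE for v in VARIABLES},
                "acute_oral": C.NOT_CLASSIFIED,
            },
        )
        assert quantify(rec).total == 280.0
        recs = self._population() + [rec]
        scores = quantify_all(recs)
        assert "8-88-8" in select_normal_group(scores, recs)
        strict = SelectionCriteria(inclusive=False)
        assert "8-88-8" not in select_normal_group(scores, recs, strict)

    def test_too_small_group_fatal(self):
        recs = self._population(n=5)
        scores = quantify_all(recs)
        with pytest.raises(DataError, match="relax"):
            select_normal_group(scores, recs)


class TestFitReference:
    def test_matches_textbook_correlation(self, rng):
        vars2 = ("acute_oral", "acute_dermal")
        X = rng.normal(size=(20, 2)) @ np.array([[1.0, 0.0], [0.6, 0.8]])
        members = [sv(f"{i}-00-0", row) for i, row in enumerate(X)]
        ref = fit_reference(members, variables=vars2)
        x, y = X[:, 0], X[:, 1]
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert ref.corr[0, 1] == pytest.approx(r_hand, abs=1e-12)
        assert ref.means["acute_oral"] == pytest.approx(x.mean(), abs=1e-12)
        assert ref.sds["acute_dermal"] == pytest.approx(y.std(ddof=1), abs=1e-12)

    def test_constant_variable_flagged_degenerate(self, rng):
        vars2 = ("acute_oral", "acute_dermal", "skin")
        members = []
        for i in range(20):
            members.append(sv(f"{i}-00-0", [rng.normal(), rng.normal(), 7.0]))
        ref = fit_reference(members, variables=vars2)
        assert ref.degenerate == ("skin",)
        assert ref.corr.shape == (2, 2)
        assert ref.k == 2

    def test_identity_population_inverse_is_identity(self, rng):
        # independent variables -> correlation and its inverse near identity
        members = [sv(f"{i}-00-0", rng.normal(size=10)) for i in range(5000)]
        ref = fit_reference(members)
        assert np.allclose(ref.corr_inv, np.eye(10), atol=0.15)
        assert np.allclose(ref.corr @ ref.corr_inv @ ref.corr, ref.corr, atol=1e-8)

    def test_too_few_members_fatal(self, rng):
        members = [sv(f"{i}-00-0", rng.normal(size=10)) for i in range(5)]
        with pytest.raises(DataError):
            fit_reference(members)

    def test_all_constant_fatal(self):
        members = [sv(f"{i}-00-0", [3.0, 4.0]) for i in range(30)]
        with pytest.raises(DataError):
            fit_reference(members, variables=("acute_oral", "acute_dermal"))


class TestMahalanobisDistance:
    def test_zero_at_reference_center(self):
        vars2 = ("acute_oral", "acute_dermal")
        ref = make_ref([10.0, 20.0], [2.0, 3.0], np.eye(2), vars2)
        x = sv("c", [10.0, 20.0])
        assert mahalanobis_distance(x, ref) == 0.0

    def test_identity_correlation_closed_form(self):
        # z = (3, 4) -> md = (9 + 16) / 2 = 12.5
        vars2 = ("acute_oral", "acute_dermal")
        ref = make_ref([0.0, 0.0], [1.0, 1.0], np.eye(2), vars2)
        x = sv("c", [3.0, 4.0])
        assert mahalanobis_distance(x, ref) == pytest.approx(12.5, abs=1e-12)

    def test_correlated_closed_form(self):
        # r = 0.5, z = (1, 1) -> md = 2/3
        vars2 = ("acute_oral", "acute_dermal")
        ref = make_ref([0.0, 0.0], [1.0, 1.0], [[1.0, 0.5], [0.5, 1.0]], vars2)
        x = sv("c", [1.0, 1.0])
        assert mahalanobis_distance(x, ref) == pytest.approx(2.0 / 3.0, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_agrees_with_cofactor_oracle(self, k, rng):
        variables = VARIABLES[:k]
        for _ in range(50):
            A = rng.normal(size=(k, k))
            cov = A @ A.T + k * np.eye(k)
            d = np.sqrt(np.diag(cov))
            corr = cov / np.outer(d, d)
            means = rng.normal(size=k) * 10
            sds = rng.uniform(0.5, 3.0, size=k)
            x = rng.normal(size=k) * 5
            ref = make_ref(means, sds, corr, variables)
            got = mahalanobis_distance(sv("c", x), ref)
            want = brute_force_md(x, means, sds, corr)
            assert got == pytest.approx(want, abs=1e-10)

    def test_mean_md_over_members(self, rng):
        """Average scaled MD over the fitting sample is exactly (n-1)/n."""
        n = 80
        members = [
            sv(f"{i}-00-0", rng.normal(size=10) * 3 + 20) for i in range(n)
        ]
        ref = fit_reference(members)
        mds = [mahalanobis_distance(m, ref) for m in members]
        assert np.mean(mds) == pytest.approx((n - 1) / n, abs=1e-8)

    def test_invariant_under_variable_reordering(self, rng):
        members = [sv(f"{i}-00-0", rng.normal(size=10) * 2 + 5) for i in range(60)]
        probe = sv("probe", rng.normal(size=10) * 4)
        ref = fit_reference(members)
        perm = tuple(VARIABLES[i] for i in rng.permutation(10))
        ref_perm = fit_reference(members, variables=perm)
        assert mahalanobis_distance(probe, ref) == pytest.approx(
            mahalanobis_distance(probe, ref_perm), abs=1e-10
        )


class TestScoreAll:
    def test_extreme_record_ranks_first(self):
        """An all-Category-1 record tops a background-only population."""
        from mtshazard import SimulationConfig, generate

        records, _ = generate(
            SimulationConfig(n_chemicals=400, n_planted_hazards=0, seed=77)
        )
        base_scores = quantify_all(records)
        extreme = make_record(cas="7-77-7", **{v: C.CAT1 for v in VARIABLES})
        scores = base_scores + [quantify(extreme)]
        members = select_normal_group(base_scores, records)
        by_cas = {s.cas: s for s in base_scores}
        ref = fit_reference([by_cas[c] for c in members])
        results = score_all(scores, ref)
        best = min(results, key=lambda r: r.rank)
        assert best.cas == "7-77-7" and best.rank == 1

    def test_ties_get_competition_ranks(self, rng):
        members = [sv(f"{i}-00-0", rng.normal(size=10) + 10) for i in range(40)]
        ref = fit_reference(members)
        probe = sv("p1", [20.0] * 10)
        probe2 = ScoreVector("p2", probe.values, probe.total)
        low = sv("low", [ref.means[v] for v in VARIABLES])
        results = {r.cas: r for r in score_all([probe, probe2, low], ref)}
        assert results["p1"].rank == results["p2"].rank == 1
        assert results["low"].rank == 3  # rank 2 skipped after the tie

    def test_input_order_irrelevant(self, rng):
        members = [sv(f"{i}-00-0", rng.normal(size=10) + 10) for i in range(40)]
        ref = fit_reference(members)
        probes = [sv(f"p{i}", rng.normal(size=10) * 3 + 10) for i in range(25)]
        fwd = {r.cas: (r.md, r.rank) for r in score_all(probes, ref)}
        rev = {r.cas: (r.md, r.rank) for r in score_all(probes[::-1], ref)}
        assert fwd == rev
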