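"""Composite repurposing score: Box-Cox normalization, DrSS/DiSS, R-score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugrex import scoring
from drugrex.embedding import EmbeddingModel
from drugrex.scoring import (
    DegenerateTransformWarning,
    ScoringContext,
    boxcox_normalize,
    diss,
    drss,
    normalized_similarity,
    r_score,
    raw_lps,
    score_all,
)


class TestBoxCoxNormalize:
    def test_lambda_one_reduces_to_min_max(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        spec = scoring.TransformSpec(shift=0.0, lmbda=1.0,
                                     min=x.min() - 1.0, max=x.max() - 1.0)
        out, _ = boxcox_normalize(x, spec)
        expected = (x - x.min()) / (x.max() - x.min())
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_sorted_input_stays_sorted(self):
        x = np.sort(np.random.default_rng(0).gamma(2.0, size=50))
        out, _ = boxcox_normalize(x)
        assert np.all(np.diff(out) >= 0)
        assert out[0] == 0.0 and out[-1] == 1.0

    def test_rank_order_preserved_on_random_positives(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(3.0, size=100) + 0.1
        out, _ = boxcox_normalize(x)
        assert np.array_equal(np.argsort(x), np.argsort(out))

    def test_nonpositive_values_are_shifted(self):
        x = np.array([-5.0, -1.0, 0.0, 2.0])
        out, spec = boxcox_normalize(x)
        assert spec.shift == pytest.approx(5.0 + 1e-6)
        assert np.all((out >= 0) & (out <= 1))

    def test_constant_population_normalizes_to_half_with_warning(self):
        with pytest.warns(DegenerateTransformWarning):
            out, spec = boxcox_normalize(np.full(7, 2.5))
        assert np.all(out == 0.5) and spec.degenerate

    def test_refit_spec_reapplies_stored_parameters(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(2.0, size=60)
        out, spec = boxcox_normalize(x)
        again, _ = boxcox_normalize(x, spec)
        np.testing.assert_allclose(out, again, atol=1e-12)
        # new values within the fitted range stay in [0, 1] and keep order
        sub = np.sort(x)[5:-5]
        mapped, _ = boxcox_normalize(sub, spec)
        assert np.all((mapped >= 0) & (mapped <= 1))
        assert np.all(np.diff(mapped) >= 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=-1e3, max_value=1e3,
                              allow_nan=False, allow_infinity=False),
                    min_size=2, max_size=60))
    def test_bounds_hold_on_arbitrary_populations(self, values):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateTransformWarning)
            out, _ = boxcox_normalize(values)
        assert np.all((out >= 0.0) & (out <= 1.0))

    def test_empty_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            boxcox_normalize([])
        with pytest.raises(ValueError):
            boxcox_normalize([1.0, np.nan])


class TestNormalizedSimilarity:
    @pytest.mark.parametrize("c,s", [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5)])
    def test_affine_endpoints_and_midpoint(self, c, s):
        assert normalized_similarity(c) == pytest.approx(s)


def _toy_context(sims: np.ndarray, treats, drugs, diseases):
    """Context over an explicit entity-vector matrix (rows are unit-free)."""
    ids = drugs + diseases
    R = np.ones((2, sims.shape[1]))
    model = EmbeddingModel(sims, R, ids, ["TREATS", "INHIBITS"], "TransE", "l1")
    return ScoringContext(model=model, drugs=drugs, diseases=diseases,
                          known={"TREATS": set(treats)})


class TestDrssDiss:
    def test_drss_is_mean_similarity_to_other_treaters(self):
        # vectors chosen so S(d1,d0)=0.2 and S(d2,d0)=0.6 exactly:
        # cos = 2S-1 -> cos(d1,d0) = -0.6, cos(d2,d0) = 0.2
        def vec(cos):  # unit vectors at a chosen cosine to (1, 0)
            return [cos, np.sqrt(1 - cos**2)]

        E = np.array([[1.0, 0.0], vec(-0.6), vec(0.2), [0.0, 1.0]])
        ctx = _toy_context(E, {("d1", "s0"), ("d2", "s0")},
                           ["d0", "d1", "d2"], ["s0"])
        assert drss(ctx, "d0", "s0") == pytest.approx(0.4, abs=1e-12)

    def test_drss_na_when_theta_is_only_treater(self):
        E = np.eye(3)
        ctx = _toy_context(E, {("d0", "s0")}, ["d0", "d1"], ["s0"])
        assert drss(ctx, "d0", "s0") is None

    def test_diss_is_mean_similarity_to_other_treated_diseases(self):
        def vec(cos):
            return [cos, np.sqrt(1 - cos**2)]

        # diseases s1, s2 at S = 0.3 and 0.5 from s0 (cos -0.4, 0.0)
        E = np.array([[1.0, 0.0], [1.0, 0.0], vec(-0.4), vec(0.0)])
        ctx = _toy_context(E, {("d0", "s1"), ("d0", "s2")},
                           ["d0"], ["s0", "s1", "s2"])
        assert diss(ctx, "d0", "s0") == pytest.approx(0.4, abs=1e-12)

    def test_diss_na_when_theta_treats_nothing_else(self):
        E = np.eye(3)
        ctx = _toy_context(E, {("d0", "s0")}, ["d0"], ["s0", "s1"])
        assert diss(ctx, "d0", "s0") is None

    def test_random_contexts_match_double_loop_oracle(self):
        """DrSS/DiSS equal an independent Eq.-style double loop to 1e-12."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n_d, n_s = rng.integers(2, 7), rng.integers(2, 6)
            drugs = [f"d{i}" for i in range(n_d)]
            diseases = [f"s{j}" for j in range(n_s)]
            E = rng.normal(size=(n_d + n_s, 5))
            treats = {
                (drugs[i], diseases[j])
                for i in range(n_d) for j in range(n_s)
                if rng.random() < 0.4
            }
            ctx = _toy_context(E, treats, drugs, diseases)

            def S(a, b):
                va, vb = ctx.model.vector(a), ctx.model.vector(b)
                c = va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
                return (c + 1) / 2

            theta = drugs[int(rng.integers(n_d))]
            lam = diseases[int(rng.integers(n_s))]
            num = sum(S(i, theta) for i in drugs if i != theta and (i, lam) in treats)
            den = sum(1 for i in drugs if i != theta and (i, lam) in treats)
            expected_drss = num / den if den else None
            got = drss(ctx, theta, lam)
            if expected_drss is None:
                assert got is None
            else:
                assert got == pytest.approx(expected_drss, abs=1e-12)

            num2 = sum(S(lam, j) for j in diseases if j != lam and (theta, j) in treats)
            den2 = sum(1 for j in diseases if j != lam and (theta, j) in treats)
            expected_diss = num2 / den2 if den2 else None
            got2 = diss(ctx, theta, lam)
            if expected_diss is None:
                assert got2 is None
            else:
                assert got2 == pytest.approx(expected_diss, abs=1e-12)


class TestRScore:
    @pytest.mark.parametrize(
        "lps,dr,di,expected",
        [
            (0.6, 0.3, 0.9, 0.6),
            (0.4, None, 0.8, 0.6),
            (0.7, None, None, 0.7),
            (0.5, 0.1, None, 0.3),
        ],
    )
    def test_mean_with_omission_rule(self, lps, dr, di, expected):
        assert r_score(lps, dr, di) == pytest.approx(expected)

    def test_missing_lps_is_an_error(self):
        with pytest.raises(ValueError):
            r_score(None, 0.5, 0.5)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.floats(0, 1),
        st.one_of(st.none(), st.floats(0, 1)),
        st.one_of(st.none(), st.floats(0, 1)),
    )
    def test_bounds(self, lps, dr, di):
        assert 0.0 <= r_score(lps, dr, di) <= 1.0


class TestRawLps:
    def test_equals_embedding_scorer(self, small_context, small_kg):
        kg, _ = small_kg
        ctx = small_context
        rng = np.random.default_rng(4)
        for _ in range(20):
            theta = ctx.drugs[int(rng.integers(len(ctx.drugs)))]
            lam = ctx.diseases[int(rng.integers(len(ctx.diseases)))]
            assert raw_lps(ctx, theta, lam) == ctx.model.score(theta, "TREATS", lam)

    def test_perfect_translation_is_maximal(self):
        E = np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.5]])
        R = np.array([[1.0, 1.0], [0.0, 0.0]])
        m = EmbeddingModel(E, R, ["d0", "s0", "s1"], ["TREATS", "INHIBITS"],
                           "TransE", "l1")
        ctx = ScoringContext(model=m, drugs=["d0"], diseases=["s0", "s1"])
        assert raw_lps(ctx, "d0", "s0") == 0.0
        assert raw_lps(ctx, "d0", "s1") < 0.0

    def test_unsupported_predicate_rejected(self, small_context):
        with pytest.raises(ValueError):
            raw_lps(small_context, small_context.drugs[0],
                    small_context.diseases[0], "CAUSES")


class TestScoreAll:
    def test_shape_and_bounds(self, small_context):
        table = score_all(small_context)
        n = len(small_context.drugs) * len(small_context.diseases)
        assert len(table.frame) == n
        for col in ("lps_prime", "drss_prime", "diss_prime", "r_score"):
            vals = table.frame[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()
        # r_score present iff lps_prime present (always, here)
        assert table.frame["r_score"].notna().all()

    def test_equals_pairwise_recomposition(self, small_context):
        """The vectorized table equals composing the per-pair operations."""
        ctx = small_context
        table = score_all(ctx)
        rng = np.random.default_rng(5)
        # recompute primes by reapplying the fitted transforms to raw values
        for _ in range(25):
            theta = ctx.drugs[int(rng.integers(len(ctx.drugs)))]
            lam = ctx.diseases[int(rng.integers(len(ctx.diseases)))]
            row = table.pair(theta, lam)
            assert row["lps_raw"] == pytest.approx(raw_lps(ctx, theta, lam), abs=1e-9)
            dr = drss(ctx, theta, lam)
            if dr is None:
                assert np.isnan(row["drss_raw"])
            else:
                assert row["drss_raw"] == pytest.approx(dr, abs=1e-9)
            di = diss(ctx, theta, lam)
            if di is None:
                assert np.isnan(row["diss_raw"])
            else:
                assert row["diss_raw"] == pytest.approx(di, abs=1e-9)
            lp, _ = boxcox_normalize([row["lps_raw"]], table.transforms[("lps", "TREATS")])
            assert row["lps_prime"] == pytest.approx(lp[0], abs=1e-9)
            parts = [row["lps_prime"]]
            for key, val in (("drss_prime", dr), ("diss_prime", di)):
                if val is not None:
                    parts.append(row[key])
            assert row["r_score"] == pytest.approx(np.mean(parts), abs=1e-12)

    def test_monotonicity_of_primes_in_raw(self, small_context):
        table = score_all(small_context).frame
        for raw, prime in (("lps_raw", "lps_prime"), ("drss_raw", "drss_prime"),
                           ("diss_raw", "diss_prime")):
            sub = table[[raw, prime]].dropna().sort_values(raw)
            assert np.all(np.diff(sub[prime].to_numpy()) >= -1e-12)

    def test_constant_population_rule(self):
        # two drugs with identical vectors: the LPS population is constant
        m = EmbeddingModel(np.array([[1.0, 0.0], [1.0, 0.0], [0.5, 0.5]]),
                           np.zeros((1, 2)), ["d0", "d1", "s0"], ["TREATS"],
                           "TransE", "l1")
        ctx = ScoringContext(model=m, drugs=["d0", "d1"], diseases=["s0"],
                             known={"TREATS": set()})
        with pytest.warns(DegenerateTransformWarning):
            table = score_all(ctx, [("s0", "TREATS")])
        assert (table.frame["lps_prime"] == 0.5).all()

    def test_protein_targets_form_their_own_population(self, small_kg, small_model):
        kg, _ = small_kg
        ctx = ScoringContext.from_graph(kg, small_model)
        proteins = kg.entities_of_type("Gene/Protein")[:3]
        targets = [(d, "TREATS") for d in ctx.diseases[:3]]
        targets += [(p, "INHIBITS") for p in proteins]
        table = score_all(ctx, targets)
        assert ("lps", "INHIBITS") in table.transforms
        assert ("lps", "TREATS") in table.transforms
        inhibit_rows = table.frame[table.frame.predicate == "INHIBITS"]
        assert len(inhibit_rows) == 3 * len(ctx.drugs)
        assert inhibit_rows["r_score"].notna().all()

    def test_empty_targets_rejected(self, small_context):
        with pytest.raises(ValueError):
            score_all(small_context, [])


def test_score_table_tsv_round_trip(tmp_path, small_context):
    table = score_all(small_context)
    path = tmp_path / "scores.tsv"
    table.to_tsv(path)
    text = path.read_text()
    assert "NA" in text or table.frame["drss_raw"].notna().all()
    back = scoring.ScoreTable.from_tsv(path)
    np.testing.assert_allclose(back.frame["r_score"], table.frame["r_score"], atol=1e-9)
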