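"""Progression operators, reduced-space paths, and axis decompositions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainspaces import (
    apply_k,
    compute_k,
    invert_k,
    pair_contributions,
    reduced_path,
)
from brainspaces.brain_space import Embedding

from .conftest import make_state, random_connectivity


def embedding_of(coords, ids=None):
    coords = np.asarray(coords, dtype=float)
    ids = ids or tuple(f"s{i}" for i in range(coords.shape[0]))
    return Embedding(
        state_ids=tuple(ids),
        coords=coords,
        dims=coords.shape[1],
        stress=0.0,
        method="classical",
    )


@pytest.fixture
def state_pair(rng, labels5):
    src = make_state("base", random_connectivity(rng, labels5), timepoint="baseline")
    tgt = make_state(
        "fu",
        random_connectivity(rng, labels5),
        subject_id="base",
        timepoint="FU1",
    )
    return src, tgt


class TestComputeK:
    def test_identical_states_give_zero_operator(self, state_pair):
        src, _ = state_pair
        k = compute_k(src, src.with_matrix(src.matrix))
        assert not k.values.any()

    def test_applying_k_reproduces_target(self, state_pair):
        src, tgt = state_pair
        k = compute_k(src, tgt)
        assert np.allclose(
            apply_k(k, src.matrix.values), tgt.matrix.values, atol=1e-12, rtol=0.0
        )

    def test_equals_cellwise_subtraction_oracle(self, state_pair):
        src, tgt = state_pair
        k = compute_k(src, tgt)
        n = len(src.matrix.roi_labels)
        for i in range(n):
            for j in range(n):
                assert k.values[i, j] == tgt.matrix.values[i, j] - src.matrix.values[i, j]

    def test_roi_mismatch_rejected(self, rng):
        a = make_state("a", random_connectivity(rng, ("x", "y", "z")))
        b = make_state("b", random_connectivity(rng, ("x", "y", "w")))
        with pytest.raises(ValueError, match="harmonized"):
            compute_k(a, b)

    def test_multiplicative_masks_zero_source_cells(self, rng, labels5):
        src = random_connectivity(rng, labels5)
        v = src.values.copy()
        v[0, 1] = v[1, 0] = 0.0
        src = type(src)(labels5, v)
        tgt = random_connectivity(rng, labels5)
        k = compute_k(make_state("a", src), make_state("b", tgt), mode="multiplicative")
        assert np.isnan(k.values[0, 1])
        assert k.n_undefined == 2


class TestInvertK:
    def test_inverse_of_zero_is_zero(self, state_pair):
        src, _ = state_pair
        k = compute_k(src, src)
        assert not invert_k(k).values.any()

    def test_round_trip_is_identity(self, state_pair):
        src, tgt = state_pair
        k = compute_k(src, tgt)
        restored = apply_k(invert_k(k), apply_k(k, src.matrix.values))
        assert np.allclose(restored, src.matrix.values, atol=1e-12, rtol=0.0)

    def test_double_inversion_is_involution(self, state_pair):
        k = compute_k(*state_pair)
        kk = invert_k(invert_k(k))
        assert np.array_equal(kk.values, k.values)
        assert kk.source_state_id == k.source_state_id

    def test_masked_multiplicative_inversion_rejected(self, rng, labels5):
        src = random_connectivity(rng, labels5)
        v = src.values.copy()
        v[0, 1] = v[1, 0] = 0.0
        src = type(src)(labels5, v)
        k = compute_k(
            make_state("a", src),
            make_state("b", random_connectivity(rng, labels5)),
            mode="multiplicative",
        )
        with pytest.raises(ValueError, match="defined and nonzero"):
            invert_k(k)

    def test_additive_closure_over_chained_pairs(self, rng, labels5):
        a = make_state("a", random_connectivity(rng, labels5))
        b = make_state("b", random_connectivity(rng, labels5))
        c = make_state("c", random_connectivity(rng, labels5))
        assert np.allclose(
            compute_k(a, b).values + compute_k(b, c).values,
            compute_k(a, c).values,
            atol=0.0,
        )


class TestReducedPath:
    def test_longitudinal_worked_example(self):
        """Baseline/follow-up coordinates of a Parkinson's subject yield the
        published per-dimension percentage variations."""
        emb = embedding_of(
            [[-34.25, -15.81, -3.611], [-13.48, -47.21, -69.99]],
            ids=("PD_patB", "PD_patB_FU"),
        )
        rp = reduced_path(emb, "PD_patB", "PD_patB_FU")
        assert np.round(rp.pct_variation, 2).tolist() == [60.64, 198.61, 1838.24]

    def test_no_motion_is_zero_percent(self):
        emb = embedding_of([[1.0, -2.0], [1.0, -2.0]])
        rp = reduced_path(emb, "s0", "s1")
        assert rp.pct_variation.tolist() == [0.0, 0.0]

    def test_hand_computed_two_dimensional_case(self):
        emb = embedding_of([[1.0, 2.0], [2.0, 1.0]])
        rp = reduced_path(emb, "s0", "s1")
        assert rp.pct_variation.tolist() == [100.0, 50.0]

    def test_zero_source_coordinate_reports_absolute_change(self):
        emb = embedding_of([[0.0, 1.0], [3.0, 2.0]])
        rp = reduced_path(emb, "s0", "s1")
        assert np.isnan(rp.pct_variation[0])
        assert rp.abs_change[0] == 3.0
        assert rp.pct_variation[1] == 100.0

    def test_unknown_state_id_rejected(self):
        emb = embedding_of([[0.0], [1.0]])
        with pytest.raises(KeyError, match="nope"):
            reduced_path(emb, "s0", "nope")


class TestPairContributions:
    def _k(self, rng, labels5):
        src = make_state("a", random_connectivity(rng, labels5))
        tgt = make_state("b", random_connectivity(rng, labels5))
        return compute_k(src, tgt)

    def test_contribution_is_change_times_correlation(self, rng, labels5):
        k = self._k(rng, labels5)
        corr = rng.uniform(-1, 1, size=(10, 3))
        df = pair_contributions(k, corr, axis=1)
        assert np.allclose(
            df.estimated_contribution, df.connectivity_change * df.axis_corr
        )
        assert (
            df.estimated_contribution.abs().values
            <= df.connectivity_change.abs().values + 1e-15
        ).all()

    def test_published_row_reproduced(self):
        """change 1.78 at axis correlation -0.865 contributes -1.54."""
        assert round(1.78 * -0.865, 2) == -1.54

    def test_zero_change_or_zero_correlation_contribute_nothing(self, rng, labels5):
        src = make_state("a", random_connectivity(rng, labels5))
        k = compute_k(src, src)
        corr = rng.uniform(-1, 1, size=(10, 2))
        assert not pair_contributions(k, corr, axis=0).estimated_contribution.any()
        k2 = self._k(rng, labels5)
        assert not pair_contributions(
            k2, np.zeros((10, 2)), axis=1
        ).estimated_contribution.any()

    def test_ranked_by_absolute_contribution(self, rng, labels5):
        k = self._k(rng, labels5)
        corr = rng.uniform(-1, 1, size=(10, 3))
        df = pair_contributions(k, corr, axis=2)
        mags = df.estimated_contribution.abs().values
        assert (np.diff(mags) <= 1e-15).all()

    def test_axis_out_of_range_rejected(self, rng, labels5):
        with pytest.raises(ValueError, match="out of range"):
            pair_contributions(self._k(rng, labels5), np.zeros((10, 2)), axis=5)

    @settings(derandomize=True, max_examples=200)
    @given(
        change=st.floats(-2.0, 2.0, allow_nan=False),
        corr=st.floats(-1.0, 1.0, allow_nan=False),
    )
    def test_contribution_never_exceeds_raw_change(self, change, corr):
        contribution = change * corr
        assert abs(contribution) <= abs(change) + 1e-15
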