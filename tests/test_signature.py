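import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mpcin.signature import (
    cpm_normalize,
    load_cin25,
    mann_whitney,
    paired_signature_test,
)
from mpcin.simulate import simulate_expression


@pytest.fixture(scope="module")
def mouse_signature():
    return [g.capitalize() for g in load_cin25()]


def _paired_manifest(n_pairs):
    rows = []
    for i in range(n_pairs):
        rows.append({"sample_id": f"m{i}_t", "subject_id": f"m{i}", "condition": "tumor"})
        rows.append({"sample_id": f"m{i}_a", "subject_id": f"m{i}", "condition": "adjacent"})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# CPM
# ----------------------------------------------------------------------

def test_cpm_contract():
    counts = pd.DataFrame({"s1": [500_000, 500_000], "s2": [10, 30]}, index=["g1", "g2"])
    cpm, logcpm = cpm_normalize(counts)
    assert cpm.loc["g1", "s1"] == 500_000  # total 1e6 -> cpm equals counts
    doubled, _ = cpm_normalize(counts * 2)
    pd.testing.assert_frame_equal(doubled, cpm)  # per-sample scale invariance
    zero = counts.copy()
    zero.loc["g1", "s2"] = 0
    zero.loc["g2", "s2"] = 0
    with pytest.raises(ValueError, match="s2"):
        cpm_normalize(zero)


def test_all_zero_gene_logcpm_zero():
    counts = pd.DataFrame({"s1": [100, 0], "s2": [50, 0]}, index=["g1", "g2"])
    cpm, logcpm = cpm_normalize(counts)
    assert (cpm.loc["g2"] == 0).all()
    assert (logcpm.loc["g2"] == 0).all()


# ----------------------------------------------------------------------
# paired sign-flip test
# ----------------------------------------------------------------------

def test_null_identity_gives_p_one():
    """Tumor identical to adjacent: all log2FC 0, all p-values 1."""
    rng = np.random.default_rng(0)
    base = rng.integers(10, 1000, size=(20, 4))
    counts = pd.DataFrame(
        np.hstack([base, base]),
        index=[f"g{i}" for i in range(20)],
        columns=[f"m{i}_t" for i in range(4)] + [f"m{i}_a" for i in range(4)],
    )
    res = paired_signature_test(counts, _paired_manifest(4), [f"g{i}" for i in range(20)], B=2000, seed=0)
    assert (res.table["log2fc"] == 0).all()
    assert (res.table["p_value"] == 1).all()


def test_foxm1_planted_largest_effect_ranks_first(mouse_signature):
    effects = {g: 1.0 for g in mouse_signature}
    effects["Foxm1"] = 3.0
    sim = simulate_expression(200, 4, mouse_signature, effects, dispersion=0.1, seed=3)
    res = paired_signature_test(sim.counts, sim.manifest, mouse_signature, B=2000, seed=3)
    assert res.rank_of("Foxm1") == 1
    assert res.missing == []


def test_case_insensitive_matching_and_missing_reported(mouse_signature):
    sim = simulate_expression(50, 3, mouse_signature[:5], 1.0, seed=4)
    wanted = [g.upper() for g in mouse_signature[:5]] + ["NOTAGENE"]
    res = paired_signature_test(sim.counts, sim.manifest, wanted, B=2000, seed=4)
    assert res.missing == ["NOTAGENE"]
    assert len(res.table) == 5


def test_unpaired_subject_rejected(mouse_signature):
    sim = simulate_expression(50, 3, mouse_signature[:5], 1.0, seed=5)
    manifest = sim.manifest[sim.manifest["sample_id"] != "mouse2_adjacent"]
    with pytest.raises(ValueError, match="mouse2"):
        paired_signature_test(sim.counts, manifest, mouse_signature[:5])


def test_permutation_p_invariant_to_gene_and_subject_order(mouse_signature):
    sim = simulate_expression(60, 4, mouse_signature[:10], 1.0, seed=6)
    res1 = paired_signature_test(sim.counts, sim.manifest, mouse_signature[:10], B=2000, seed=6)
    shuffled_counts = sim.counts.sample(frac=1.0, random_state=1)
    shuffled_manifest = sim.manifest.sample(frac=1.0, random_state=2)
    res2 = paired_signature_test(shuffled_counts, shuffled_manifest, mouse_signature[:10], B=2000, seed=6)
    left = res1.table.set_index("gene")["p_value"]
    right = res2.table.set_index("gene")["p_value"]
    pd.testing.assert_series_equal(left.sort_index(), right.sort_index())


def test_bh_adjustment_monotone():
    sim = simulate_expression(100, 4, [], {}, dispersion=0.2, seed=7)
    genes = list(sim.counts.index)[:40]
    res = paired_signature_test(sim.counts, sim.manifest, genes, B=2000, seed=7)
    t = res.table
    assert (t["q_value"] >= t["p_value"] - 1e-12).all()
    ordered = t.sort_values("p_value")
    assert (np.diff(ordered["q_value"]) >= -1e-12).all()
    assert sorted(t["rank"]) == list(range(1, len(t) + 1))


# ----------------------------------------------------------------------
# Mann-Whitney
# ----------------------------------------------------------------------

def _enumeration_oracle(x, y):
    """Exact two-sided p by enumerating all assignments of the pooled ranks."""
    pooled = sorted(list(x) + list(y))
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(1 for a in xs for b in ys if a == b)

    observed = u_stat(x, y)
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n) if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


def test_mann_whitney_tiny_example():
    u, p = mann_whitney([1, 2], [3, 4])
    assert u == 0
    assert p == pytest.approx(1 / 3, abs=1e-9)


def test_mann_whitney_identical_samples_p_one():
    _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 3), (2, 5)])
def test_exact_branch_matches_enumeration_oracle(n1, n2, rng):
    for _ in range(5):
        values = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float))
        x, y = values[:n1], values[n1:]
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(_enumeration_oracle(list(x), list(y)), abs=1e-9)


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=10**6), min_size=1, max_size=30),
    st.lists(st.integers(min_value=0, max_value=10**6), min_size=1, max_size=30),
)
def test_mann_whitney_symmetric_in_samples(xs, ys):
    """Swapping the samples mirrors U and leaves the p-value unchanged."""
    u_xy, p_xy = mann_whitney(xs, ys)
    u_yx, p_yx = mann_whitney(ys, xs)
    assert u_xy + u_yx == pytest.approx(len(xs) * len(ys), abs=1e-9)
    assert p_xy == pytest.approx(p_yx, abs=1e-9)
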