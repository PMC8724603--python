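"""Core averaging, matched fold changes, t-tests, grouping, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from glycoims import (
    CoreRecord, IMSDataset, Spectrum, assign_biomarker_group, cluster_masses,
    core_average, matched_log2fc, paired_t, welch_t,
)


def _core(patient, cid, cls, **feats):
    return CoreRecord(patient_id=patient, core_id=cid, tissue_class=cls,
                      features=feats)


# ---------------------------------------------------------------------------
# core_average
# ---------------------------------------------------------------------------

def test_core_average_mean_and_identity():
    pixels = [
        (0, 0, Spectrum([1000.0], [0.2])),
        (1, 0, Spectrum([1000.0], [0.4])),
    ]
    d = IMSDataset(pixels=pixels, grid_shape=(2, 1), mz_range=(900, 1100),
                   normalized=True)
    out = core_average(d, [(0, 0), (1, 0)], {"g": 1000.0})
    assert out["g"] == pytest.approx(0.3)
    single = core_average(d, [(1, 0)], {"g": 1000.0})
    assert single["g"] == pytest.approx(0.4)
    with pytest.raises(ValueError):
        core_average(d, [], {"g": 1000.0})


def test_core_average_matches_bruteforce_on_large_core():
    rng = np.random.default_rng(5)
    n = 171  # representative core pixel count
    pixels = [(i % 20, i // 20, Spectrum([1500.0], [float(v)]))
              for i, v in enumerate(rng.random(n))]
    d = IMSDataset(pixels=pixels, grid_shape=(20, 9), mz_range=(1000, 2000),
                   normalized=True)
    coords = [(x, y) for x, y, _ in pixels]
    out = core_average(d, coords, {"g": 1500.0})
    brute = np.mean([s.intensity[0] for _, _, s in pixels])
    assert out["g"] == pytest.approx(brute, rel=1e-12)


# ---------------------------------------------------------------------------
# matched_log2fc
# ---------------------------------------------------------------------------

def test_matched_log2fc_basics():
    tum = [_core("p1", "t1", "tumor", g=0.4)]
    nor = [_core("p1", "n1", "adjacent_normal", g=0.1)]
    fc = matched_log2fc(tum, nor, epsilon=1e-15)
    assert fc["g"] == pytest.approx(2.0, abs=1e-9)
    fc0 = matched_log2fc(tum, [_core("p1", "n1", "adjacent_normal", g=0.4)],
                         epsilon=1e-15)
    assert fc0["g"] == pytest.approx(0.0, abs=1e-12)


def test_matched_log2fc_antisymmetry():
    rng = np.random.default_rng(0)
    tum = [_core(f"p{i}", f"t{i}", "tumor", a=rng.random() + 0.1,
                 b=rng.random() + 0.1) for i in range(6)]
    nor = [_core(f"p{i}", f"n{i}", "adjacent_normal", a=rng.random() + 0.1,
                 b=rng.random() + 0.1) for i in range(6)]
    fwd = matched_log2fc(tum, nor, epsilon=1e-12)
    rev = matched_log2fc(nor, tum, epsilon=1e-12)
    np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-10)


def test_matched_log2fc_excludes_unpaired_patients():
    tum = [_core("p1", "t1", "tumor", g=0.4), _core("p2", "t2", "tumor", g=8.0)]
    nor = [_core("p1", "n1", "adjacent_normal", g=0.1)]
    fc = matched_log2fc(tum, nor, epsilon=1e-15)
    assert fc["g"] == pytest.approx(2.0, abs=1e-9)  # p2 dropped


def test_matched_log2fc_fuzz_against_direct_formula():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n_pat = rng.integers(2, 6)
        eps = 1e-9
        tum, nor, expect = [], [], []
        for p in range(n_pat):
            tv = rng.random(rng.integers(1, 4)) + 0.01
            nv = rng.random(rng.integers(1, 4)) + 0.01
            tum += [_core(f"p{p}", f"t{p}{i}", "tumor", g=float(v))
                    for i, v in enumerate(tv)]
            nor += [_core(f"p{p}", f"n{p}{i}", "adjacent_normal", g=float(v))
                    for i, v in enumerate(nv)]
            expect.append(np.log2((tv.mean() + eps) / (nv.mean() + eps)))
        fc = matched_log2fc(tum, nor, epsilon=eps)
        assert fc["g"] == pytest.approx(np.mean(expect), abs=1e-10)


# ---------------------------------------------------------------------------
# t-tests against closed-form oracles
# ---------------------------------------------------------------------------

def _welch_oracle(a, b):
    a, b = np.asarray(a), np.asarray(b)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), dof)
    return t, dof, p


def test_welch_identical_groups():
    r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.statistic == pytest.approx(0.0, abs=1e-12)
    assert r.p_value == pytest.approx(1.0, abs=1e-12)


def test_welch_p_monotone_in_shift():
    a = [1.0, 2.0, 3.0]
    ps = [welch_t(a, [x + shift for x in a]).p_value for shift in (0.5, 2.0, 10.0)]
    assert ps[0] > ps[1] > ps[2]


def test_welch_fuzz_against_closed_form():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        a = rng.normal(size=rng.integers(2, 12))
        b = rng.normal(loc=rng.normal(), size=rng.integers(2, 12))
        r = welch_t(a, b)
        t, dof, p = _welch_oracle(a, b)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.dof == pytest.approx(dof, abs=1e-10)
        assert r.p_value == pytest.approx(p, abs=1e-10)


def test_welch_reduces_to_student_under_equal_variance_design():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = a + 0.5
    r = welch_t(a, b)
    t_student = sps.ttest_ind(a, b, equal_var=True)
    assert r.statistic == pytest.approx(t_student.statistic, abs=1e-12)
    assert r.dof == pytest.approx(len(a) + len(b) - 2, abs=1e-12)


def test_paired_t_edge_cases():
    r0 = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (r0.statistic, r0.p_value) == (0.0, 1.0)
    rc = paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])  # constant diff
    assert np.isinf(rc.statistic) and rc.statistic > 0 and rc.p_value == 0.0


def test_paired_t_fuzz_against_closed_form():
    rng = np.random.default_rng(13)
    for _ in range(1000):
        n = rng.integers(2, 12)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        p = 2 * sps.t.sf(abs(t), n - 1)
        r = paired_t(a, b)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.p_value == pytest.approx(p, abs=1e-10)


# ---------------------------------------------------------------------------
# biomarker grouping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ca,st_,expected", [
    (0.0, 0.0, "neither"),
    (50.0, 50.0, "both"),
    (50.0, 0.0, "ca199_only"),
    (0.0, 50.0, "stra_only"),
    (5.0, 5.0, "both"),  # boundary inclusive at default threshold 5%
    (4.999, 5.0, "stra_only"),
])
def test_assign_biomarker_group(ca, st_, expected):
    assert assign_biomarker_group(ca, st_) == expected


@settings(max_examples=200, deadline=None)
@given(ca=st.floats(0, 100), st_=st.floats(0, 100))
def test_group_assignment_total_and_deterministic(ca, st_):
    g1 = assign_biomarker_group(ca, st_)
    assert g1 in ("both", "ca199_only", "stra_only", "neither")
    assert assign_biomarker_group(ca, st_) == g1


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _block_matrix(seed=0):
    rng = np.random.default_rng(seed)
    up = np.r_[np.ones(6) * 4, np.ones(6)]
    down = up[::-1]
    cols = {}
    for i in range(3):
        cols[f"u{i}"] = up * np.exp(rng.normal(0, 0.05, 12))
    for i in range(3):
        cols[f"d{i}"] = down * np.exp(rng.normal(0, 0.05, 12))
    return pd.DataFrame(cols)


def test_cluster_masses_block_recovery():
    m = _block_matrix()
    labels, order = cluster_masses(m, n_clusters=2)
    assert len({labels[f"u{i}"] for i in range(3)}) == 1
    assert len({labels[f"d{i}"] for i in range(3)}) == 1
    assert labels["u0"] != labels["d0"]
    assert sorted(order) == sorted(m.columns)


def test_cluster_masses_identical_columns_cluster_together():
    m = _block_matrix()
    m["u_copy"] = m["u0"]
    labels, _ = cluster_masses(m, n_clusters=2)
    assert labels["u_copy"] == labels["u0"]


def test_cluster_masses_permutation_invariance():
    m = _block_matrix()
    labels_a, _ = cluster_masses(m, 2)
    shuffled = m[list(m.columns[::-1])]
    labels_b, _ = cluster_masses(shuffled, 2)
    # same partition, possibly relabeled
    part_a = {frozenset(k for k, v in labels_a.items() if v == c)
              for c in set(labels_a.values())}
    part_b = {frozenset(k for k, v in labels_b.items() if v == c)
              for c in set(labels_b.values())}
    assert part_a == part_b
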