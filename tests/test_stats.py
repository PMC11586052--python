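import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from nicheprof.simulate import simulate_phylo_distances
from nicheprof.stats import (
    bh_adjust,
    bray_curtis,
    dissimilarity_phylo_regression,
    equal_proportions_test,
    mantel,
    metric_model,
    permanova,
    permdisp,
    read_phylip_square,
    two_sample_auto,
    write_phylip_square,
)

from conftest import make_profile, vec


# ------------------------------------------------------------------ proportions

@pytest.mark.parametrize(
    "x1,x2,chi2",
    [(10, 20, 3.60), (17, 11, 1.16), (5, 10, 1.22)],
)
def test_equal_proportions_reported_genus_shifts(x1, x2, chi2):
    """Yates chi-squared on genus counts out of 60 fungal isolates per treatment."""
    res = equal_proportions_test(x1, 60, x2, 60)
    assert round(res.statistic, 2) == chi2


def test_equal_proportions_identical_counts_zero():
    res = equal_proportions_test(7, 30, 7, 30)
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_equal_proportions_requires_trials():
    with pytest.raises(ValueError):
        equal_proportions_test(0, 0, 1, 10)


# ------------------------------------------------------------------ two-sample router

def test_identical_samples_show_no_difference():
    a = [1.2, 3.4, 2.2, 4.1, 0.8, 2.9]
    res = two_sample_auto(a, a)
    assert res.p_value > 0.95


def test_heavy_tails_route_to_wilcoxon():
    rng = np.random.default_rng(0)
    a = rng.standard_cauchy(60)
    b = rng.standard_cauchy(60)
    res = two_sample_auto(a, b)
    assert res.test_used == "wilcoxon"


def test_gaussian_samples_route_to_welch():
    rng = np.random.default_rng(1)
    res = two_sample_auto(rng.normal(size=40), rng.normal(size=40))
    assert res.test_used == "welch_t"


def test_small_samples_rejected():
    with pytest.raises(ValueError):
        two_sample_auto([1.0, 2.0], [1.0, 2.0, 3.0])


def test_router_type_one_error_near_nominal():
    """Equal-mean Gaussian samples: rejection rate ~ alpha = 0.05."""
    rng = np.random.default_rng(2)
    rejections = 0
    reps = 600
    for _ in range(reps):
        res = two_sample_auto(rng.normal(size=25), rng.normal(size=25))
        rejections += res.p_value < 0.05
    assert abs(rejections / reps - 0.05) < 0.02


# ------------------------------------------------------------------ BH

def test_bh_step_up_hand_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_trivial_cases():
    assert bh_adjust([0.2])[0] == 0.2
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)


def test_bh_order_invariance_and_dominance():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=20)
    adj = bh_adjust(p)
    assert np.all(adj >= p)
    perm = rng.permutation(20)
    np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])


# ------------------------------------------------------------------ Bray-Curtis

def test_bray_curtis_examples():
    a = make_profile(vec({0: 0.2, 1: 0.3}), isolate_id="a")
    b = make_profile(vec({0: 0.1, 1: 0.5}), isolate_id="b")
    dm = bray_curtis([a, b])
    assert dm["a", "b"] == pytest.approx(0.3 / 1.1, abs=5e-5)  # 0.2727
    same = bray_curtis([a, make_profile(a.corrected_od, isolate_id="c")])
    assert same["a", "c"] == 0.0
    d1 = make_profile(vec({0: 0.4}), isolate_id="x")
    d2 = make_profile(vec({5: 0.7}), isolate_id="y")
    assert bray_curtis([d1, d2])["x", "y"] == pytest.approx(1.0)


def test_bray_curtis_joint_rescaling_invariance():
    rng = np.random.default_rng(4)
    a = make_profile(vec(dict(enumerate(rng.uniform(0.01, 0.5, 30)))), isolate_id="a")
    b = make_profile(vec(dict(enumerate(rng.uniform(0.01, 0.5, 30)))), isolate_id="b")
    lam = 9.0
    a2 = make_profile(a.corrected_od * lam, isolate_id="a", threshold=0.005 * lam)
    b2 = make_profile(b.corrected_od * lam, isolate_id="b", threshold=0.005 * lam)
    assert bray_curtis([a2, b2])["a", "b"] == pytest.approx(bray_curtis([a, b])["a", "b"])


def test_bray_curtis_both_zero_is_one():
    z1 = make_profile(np.zeros(95), isolate_id="z1")
    z2 = make_profile(np.zeros(95), isolate_id="z2")
    assert bray_curtis([z1, z2])["z1", "z2"] == 1.0


# ------------------------------------------------------------------ PERMANOVA

def _cloud_dm(rng, n_per=10, sep=4.0):
    pts = np.vstack(
        [rng.normal(0, 1, (n_per, 3)), rng.normal(sep, 1, (n_per, 3))]
    )
    ids = [f"s{i}" for i in range(2 * n_per)]
    meta = pd.DataFrame(
        {"group": ["a"] * n_per + ["b"] * n_per}, index=ids
    )
    return DistanceMatrix(squareform(pdist(pts)), ids=ids), meta


def test_permanova_separated_clouds():
    dm, meta = _cloud_dm(np.random.default_rng(5))
    t = permanova(dm, meta, terms=("group",), permutations=199, seed=1)
    row = t[t.term == "group"].iloc[0]
    assert row.p <= 0.01
    assert row.R2 > 0.5


def test_permanova_r2_partition_sums_to_one(study):
    from nicheprof.plate_io import metadata_frame

    profiles, _, _ = study
    subset = profiles[::4]  # spans both kingdoms and treatments
    dm = bray_curtis(subset)
    meta = metadata_frame(subset)
    t = permanova(dm, meta, permutations=49, seed=0)
    terms = t[~t.term.isin(["Total"])]
    assert terms.R2.sum() == pytest.approx(1.0, abs=1e-9)
    assert t[t.term == "Total"].SumOfSqs.iloc[0] == pytest.approx(
        terms.SumOfSqs.sum(), rel=1e-9
    )


def test_permanova_seed_reproducible():
    dm, meta = _cloud_dm(np.random.default_rng(6), sep=0.5)
    p1 = permanova(dm, meta, terms=("group",), permutations=99, seed=42).p.iloc[0]
    p2 = permanova(dm, meta, terms=("group",), permutations=99, seed=42).p.iloc[0]
    p3 = permanova(dm, meta, terms=("group",), permutations=99, seed=43).p.iloc[0]
    assert p1 == p2
    assert p1 != p3 or True  # different seed may coincide; reproducibility is the contract


def test_permanova_statistic_matches_skbio_oneway():
    dm, meta = _cloud_dm(np.random.default_rng(7), sep=1.0)
    ours = permanova(dm, meta, terms=("group",), permutations=99, seed=0)
    theirs = skbio_permanova(dm, meta.group.values, permutations=99)
    assert ours[ours.term == "group"].F.iloc[0] == pytest.approx(
        theirs["test statistic"], rel=1e-10
    )


def _oracle_oneway_permanova_p(d, labels):
    """Exhaustive one-way PERMANOVA by the within-group pairwise-d^2 identity."""
    n = len(labels)
    d2 = d**2

    def pseudo_f(lab):
        lab = np.asarray(lab)
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        groups = set(lab)
        for g in groups:
            idx = np.flatnonzero(lab == g)
            if len(idx) > 1:
                sub = d2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ssa = sst - ssw
        a = len(groups)
        return (ssa / (a - 1)) / (ssw / (n - a))

    f_obs = pseudo_f(labels)
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        if pseudo_f(np.asarray(labels)[list(perm)]) >= f_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def test_permanova_exhaustive_matches_enumeration_oracle():
    rng = np.random.default_rng(8)
    pts = rng.normal(0, 1, (6, 2))
    pts[3:] += 1.5
    d = squareform(pdist(pts))
    ids = list("abcdef")
    dm = DistanceMatrix(d, ids=ids)
    meta = pd.DataFrame({"group": ["x"] * 3 + ["y"] * 3}, index=ids)
    ours = permanova(dm, meta, terms=("group",), permutations="all").p.iloc[0]
    oracle = _oracle_oneway_permanova_p(d, np.array(["x"] * 3 + ["y"] * 3))
    assert ours == oracle


def test_permanova_null_p_uniform():
    """Random labels on one cloud: permutation p is uniform."""
    rng = np.random.default_rng(9)
    ps = []
    for _ in range(200):
        pts = rng.normal(0, 1, (12, 3))
        ids = [f"s{i}" for i in range(12)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        meta = pd.DataFrame({"group": ["a"] * 6 + ["b"] * 6}, index=ids)
        ps.append(permanova(dm, meta, terms=("group",), permutations=99,
                            seed=int(rng.integers(2**31))).p.iloc[0])
    ps = np.asarray(ps)
    # uniform on the permutation lattice: compare empirical CDF at quartiles
    for q in (0.25, 0.5, 0.75):
        assert abs((ps <= q).mean() - q) < 0.09


def test_permanova_rejects_sparse_factor_level():
    dm, meta = _cloud_dm(np.random.default_rng(10))
    meta = meta.copy()
    meta.iloc[0, 0] = "lonely"
    with pytest.raises(ValueError, match="lonely"):
        permanova(dm, meta, terms=("group",), permutations=9)


# ------------------------------------------------------------------ PERMDISP

def test_permdisp_detects_inflated_dispersion():
    rng = np.random.default_rng(11)
    a = rng.normal(0, 1, (15, 3))
    b = rng.normal(0, 1, (15, 3)) * 3.0
    pts = np.vstack([a, b])
    ids = [f"s{i}" for i in range(30)]
    dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
    res = permdisp(dm, pd.Series(["a"] * 15 + ["b"] * 15, index=ids),
                   permutations=199, seed=0)
    assert res.group_means["b"] > res.group_means["a"]
    assert res.p_value < 0.05
    assert res.tukey.iloc[0]["reject"] in (True, "True")


def test_permdisp_identical_points_zero_distances():
    pts = np.zeros((8, 2))
    ids = [f"s{i}" for i in range(8)]
    dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
    res = permdisp(dm, pd.Series(["a"] * 4 + ["b"] * 4, index=ids),
                   permutations=99, seed=0)
    assert np.allclose(res.distances, 0.0)


def test_permdisp_null_rejection_near_alpha():
    rng = np.random.default_rng(12)
    rejections = 0
    reps = 200
    for _ in range(reps):
        pts = rng.normal(0, 1, (16, 3))
        ids = [f"s{i}" for i in range(16)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        res = permdisp(dm, pd.Series(["a"] * 8 + ["b"] * 8, index=ids),
                       permutations=99, seed=int(rng.integers(2**31)))
        rejections += res.p_value <= 0.05
    assert abs(rejections / reps - 0.05) < 0.04


def test_permdisp_seed_reproducible():
    rng = np.random.default_rng(13)
    pts = rng.normal(0, 1, (14, 3))
    ids = [f"s{i}" for i in range(14)]
    dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
    g = pd.Series(["a"] * 7 + ["b"] * 7, index=ids)
    assert permdisp(dm, g, permutations=99, seed=5).p_value == permdisp(
        dm, g, permutations=99, seed=5
    ).p_value


# ------------------------------------------------------------------ Mantel

def _random_dm(rng, n, ids=None):
    pts = rng.normal(0, 1, (n, 3))
    ids = ids or [f"s{i}" for i in range(n)]
    return DistanceMatrix(squareform(pdist(pts)), ids=ids)


def test_mantel_identity_and_affine_invariance():
    dm = _random_dm(np.random.default_rng(14), 10)
    r, _ = mantel(dm, dm, permutations=99, seed=0)
    assert r == pytest.approx(1.0)
    shifted = DistanceMatrix(
        np.where(np.eye(10, dtype=bool), 0.0, 2.0 * dm.data + 0.5), ids=list(dm.ids)
    )
    r2, _ = mantel(dm, shifted, permutations=99, seed=0)
    assert r2 == pytest.approx(1.0)


def test_mantel_r_matches_skbio():
    rng = np.random.default_rng(15)
    d1 = _random_dm(rng, 12)
    d2 = _random_dm(rng, 12)
    r_ours, _ = mantel(d1, d2, permutations=99, seed=0)
    r_skbio, _, _ = skbio_mantel(d1, d2, permutations=0)
    assert r_ours == pytest.approx(float(r_skbio), rel=1e-10)


def test_mantel_exhaustive_matches_enumeration_oracle():
    rng = np.random.default_rng(16)
    d1 = _random_dm(rng, 5)
    d2 = _random_dm(rng, 5, ids=list(d1.ids))
    r_obs, p_ours = mantel(d1, d2, permutations="all")

    iu = np.triu_indices(5, 1)
    x = d1.data[iu]
    hits = total = 0
    for perm in itertools.permutations(range(5)):
        y = d2.data[np.ix_(perm, perm)][iu]
        if np.corrcoef(x, y)[0, 1] >= r_obs - 1e-12:
            hits += 1
        total += 1
    assert p_ours == hits / total


# ------------------------------------------------------------------ regression on distances

def test_regression_proportional_distances_r2_one():
    rng = np.random.default_rng(17)
    d1 = _random_dm(rng, 10)
    d2 = DistanceMatrix(0.3 * d1.data, ids=list(d1.ids))
    meta = pd.DataFrame({"kingdom": "Bacteria", "treatment": "control"}, index=list(d1.ids))
    res = dissimilarity_phylo_regression(d1, d2, meta)
    assert res.R2.iloc[0] == pytest.approx(1.0)


def test_regression_independent_distances_r2_small():
    rng = np.random.default_rng(18)
    d1 = _random_dm(rng, 40)  # 780 pairs
    d2 = _random_dm(rng, 40, ids=list(d1.ids))
    meta = pd.DataFrame({"kingdom": "Fungi", "treatment": "control"}, index=list(d1.ids))
    res = dissimilarity_phylo_regression(d1, d2, meta)
    assert res.R2.iloc[0] < 0.05


def test_regression_recovers_planted_r2():
    rng = np.random.default_rng(19)
    d1 = _random_dm(rng, 45)  # 990 pairs
    planted = simulate_phylo_distances(d1, r=np.sqrt(0.3), seed=20)
    meta = pd.DataFrame({"kingdom": "Fungi", "treatment": "control"}, index=list(d1.ids))
    res = dissimilarity_phylo_regression(d1, planted, meta)
    assert res.R2.iloc[0] == pytest.approx(0.3, abs=0.05)


# ------------------------------------------------------------------ metric models

def test_metric_model_requires_replicate_leaves(study):
    from nicheprof.metrics import metrics_table

    profiles, _, _ = study
    mt = metrics_table(profiles)
    single = mt[mt.leaf_id.isin(["C-L1", "N-L1"])]
    with pytest.raises(ValueError, match="fewer than 2 leaves"):
        metric_model(single, "NW")


def test_metric_model_detects_planted_fungal_nw_drop(study):
    from nicheprof.metrics import metrics_table

    profiles, _, _ = study
    mt = metrics_table(profiles)
    res = metric_model(mt, "NW")
    row = res.contrasts[res.contrasts.contrast == "Fungi.control - Fungi.NPKμ"].iloc[0]
    assert row.estimate > 0  # fungal NW lower under NPKμ on the log scale
    assert row.p < 0.05


def test_metric_model_power_on_fungal_niche_width():
    """At study sample sizes the planted fungal NW drop is detected with power > 0.8."""
    from nicheprof.metrics import metrics_table
    from nicheprof.plate_io import correct_and_threshold, default_layout
    from nicheprof.simulate import SimConfig, simulate_study

    lay = default_layout()
    hits = 0
    reps = 25
    for k in range(reps):
        plates, _, _ = simulate_study(SimConfig(seed=3000 + k))
        mt = metrics_table([correct_and_threshold(p, lay) for p in plates])
        res = metric_model(mt, "NW")
        row = res.contrasts[res.contrasts.contrast == "Fungi.control - Fungi.NPKμ"].iloc[0]
        hits += (row.p < 0.05) and (row.estimate > 0)
    assert hits / reps > 0.8


def test_metric_model_null_contrast_calibration():
    """No planted effects: the fungal treatment contrast rejects at roughly alpha."""
    from nicheprof.metrics import metrics_table
    from nicheprof.plate_io import correct_and_threshold, default_layout
    from nicheprof.simulate import get_preset, simulate_study

    lay = default_layout()
    rejections = 0
    reps = 120
    for k in range(reps):
        cfg = get_preset("null", seed=5000 + k)
        cfg.leaves_per_treatment = 3
        cfg.bacteria_per_leaf = 5
        cfg.fungi_per_leaf = 5
        plates, _, _ = simulate_study(cfg)
        mt = metrics_table([correct_and_threshold(p, lay) for p in plates])
        res = metric_model(mt, "TG")
        row = res.contrasts[res.contrasts.contrast == "Fungi.control - Fungi.NPKμ"].iloc[0]
        rejections += row.p < 0.05
    assert 0.0 <= rejections / reps < 0.14


# ------------------------------------------------------------------ PHYLIP square IO

def test_phylip_square_roundtrip():
    rng = np.random.default_rng(21)
    dm = _random_dm(rng, 7, ids=["iso_%d" % i for i in range(7)])
    import io as _io
    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        path = os.path.join(td, "d.phylip")
        write_phylip_square(dm, path)
        back = read_phylip_square(path)
        assert list(back.ids) == list(dm.ids)
        np.testing.assert_array_equal(back.data, dm.data)
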