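"""Split-plot F maps, cluster extraction, and the permutation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ticsupp import cluster_stats as cst
from ticsupp.cluster_stats import (
    FStatMap,
    extract_clusters,
    mixed_anova_fmaps,
    wfwer_permutation_test,
)


def _random_stack(rng, n1=4, n2=5, shape=(4, 5)):
    data = rng.normal(size=(n1 + n2, 2) + shape)
    groups = np.array(["a"] * n1 + ["b"] * n2)
    return data, groups


def test_identical_observations_give_zero_f():
    data = np.ones((6, 2, 3, 4))
    groups = np.array(["a"] * 3 + ["b"] * 3)
    fmaps = mixed_anova_fmaps(data, groups)
    for effect in cst.EFFECTS:
        np.testing.assert_array_equal(fmaps[effect].F, 0.0)


def test_pure_suppression_shift_loads_on_main_effect(rng):
    data, groups = _random_stack(rng, 6, 6)
    data[:, 1] += 5.0  # same shift for every IC of both groups
    fmaps = mixed_anova_fmaps(data, groups)
    assert fmaps["Suppression"].F.min() > fmaps["Interaction"].F.max()
    assert np.median(fmaps["Suppression"].p) < 1e-4


def test_group_constant_offset_loads_on_group_effect(rng):
    data, groups = _random_stack(rng, 6, 6)
    data[groups == "b"] += 4.0
    fmaps = mixed_anova_fmaps(data, groups)
    assert np.median(fmaps["Group"].p) < 1e-3


def _pingouin_f(data, groups, fi, ti):
    import pingouin as pg

    n = data.shape[0]
    df = pd.DataFrame(
        {
            "y": np.concatenate([data[:, 0, fi, ti], data[:, 1, fi, ti]]),
            "cond": ["c0"] * n + ["c1"] * n,
            "subj": list(range(n)) * 2,
            "grp": list(groups) * 2,
        }
    )
    aov = pg.mixed_anova(
        data=df, dv="y", within="cond", subject="subj", between="grp"
    ).set_index("Source")
    return {
        "Group": aov.loc["grp", "F"],
        "Suppression": aov.loc["cond", "F"],
        "Interaction": aov.loc["Interaction", "F"],
    }


def test_f_maps_match_mixed_anova_oracle():
    """Closed-form F maps agree with an independent mixed-ANOVA implementation."""
    pytest.importorskip("pingouin")
    rng = np.random.default_rng(0)
    for _ in range(5):
        n1, n2 = rng.integers(3, 6, size=2)
        data = rng.normal(size=(n1 + n2, 2, 2, 3))
        groups = np.array(["a"] * n1 + ["b"] * n2)
        fmaps = mixed_anova_fmaps(data, groups)
        for fi in range(2):
            for ti in range(3):
                oracle = _pingouin_f(data, groups, fi, ti)
                for effect in cst.EFFECTS:
                    assert fmaps[effect].F[fi, ti] == pytest.approx(
                        oracle[effect], abs=1e-8, rel=1e-8
                    )


def test_input_validation(rng):
    data, groups = _random_stack(rng)
    with pytest.raises(ValueError, match="2 group levels"):
        mixed_anova_fmaps(data, np.array(["a"] * len(groups)))
    with pytest.raises(ValueError, match="at least 2 ICs"):
        mixed_anova_fmaps(data, np.array(["a"] + ["b"] * (len(groups) - 1)))
    with pytest.raises(ValueError, match="shape"):
        mixed_anova_fmaps(data[:, :1], groups)


# --------------------------------------------------------------------------
# cluster extraction


def _fmap_from_p(p, f=None):
    p = np.asarray(p, dtype=float)
    f = 1.0 / p if f is None else np.asarray(f, dtype=float)
    return FStatMap(effect="Suppression", F=f, p=p, df=(1, 10))


def test_singleton_cluster_mass():
    p = np.ones((3, 3))
    f = np.zeros((3, 3))
    p[1, 1] = 0.01
    f[1, 1] = 7.3
    clusters = extract_clusters(_fmap_from_p(p, f))
    assert len(clusters) == 1
    assert clusters[0].mass == pytest.approx(7.3)
    assert clusters[0].size == 1


def test_diagonal_pixels_split_under_4_connectivity():
    p = np.ones((4, 4))
    p[1, 1] = p[2, 2] = 0.01
    fmap = _fmap_from_p(p)
    assert len(extract_clusters(fmap, connectivity=4)) == 2
    assert len(extract_clusters(fmap, connectivity=8)) == 1


def _floodfill_oracle(supra, absf):
    """Exhaustive 4-neighbour flood fill, independent of scipy labelling."""
    visited = np.zeros_like(supra, dtype=bool)
    comps = []
    nf, nt = supra.shape
    for i in range(nf):
        for j in range(nt):
            if supra[i, j] and not visited[i, j]:
                stack, members = [(i, j)], []
                visited[i, j] = True
                while stack:
                    a, b = stack.pop()
                    members.append((a, b))
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        x, y = a + da, b + db
                        if 0 <= x < nf and 0 <= y < nt and supra[x, y] and not visited[x, y]:
                            visited[x, y] = True
                            stack.append((x, y))
                comps.append(
                    (frozenset(members), sum(absf[a, b] for a, b in members))
                )
    return comps


def test_cluster_partition_matches_floodfill_oracle():
    rng = np.random.default_rng(1)
    for _ in range(100):
        p = rng.uniform(size=(8, 10))
        f = rng.chisquare(1, size=(8, 10))
        clusters = extract_clusters(_fmap_from_p(p, f))
        got = {
            (frozenset(zip(*[idx.tolist() for idx in c.pixels])), c.mass)
            for c in clusters
        }
        oracle = _floodfill_oracle(p < 0.05, np.abs(f))
        assert {m for m, _ in got} == {m for m, _ in oracle}
        masses_got = dict((m, mass) for m, mass in got)
        for members, mass in oracle:
            assert masses_got[members] == pytest.approx(mass, rel=1e-12)


def test_empty_extraction():
    assert extract_clusters(_fmap_from_p(np.ones((5, 5)))) == []


# --------------------------------------------------------------------------
# permutation test


def _stack_with_subjects(rng, n_subj_per_group=6, ics_per_subject=2, shape=(6, 8), delta=0.0):
    n = 2 * n_subj_per_group * ics_per_subject
    data = rng.normal(size=(n, 2) + shape)
    data[:, 1] += delta
    groups, subjects = [], []
    for g in ("a", "b"):
        for s in range(n_subj_per_group):
            for _ in range(ics_per_subject):
                groups.append(g)
                subjects.append(f"{g}{s}")
    return data, np.array(groups), np.array(subjects)


def test_identity_shuffle_reproduces_true_f(rng):
    data, groups, subjects = _stack_with_subjects(rng)
    M, D, g, shape = cst._prepare(data, groups)
    true = mixed_anova_fmaps(data, groups)
    identity_signs = np.ones((1, data.shape[0]))
    f_supp = cst._suppression_f_from_signs(D, g, identity_signs)[0].reshape(shape)
    np.testing.assert_allclose(f_supp, true["Suppression"].F, rtol=1e-10)
    indicator = g[None, :]
    f_grp = cst._between_f_from_indicator(M, indicator, "Group")[0].reshape(shape)
    np.testing.assert_allclose(f_grp, true["Group"].F, rtol=1e-10)
    f_int = cst._between_f_from_indicator(D, indicator, "Interaction")[0].reshape(shape)
    np.testing.assert_allclose(f_int, true["Interaction"].F, rtol=1e-10)


def test_permutation_test_is_deterministic(rng):
    data, groups, subjects = _stack_with_subjects(rng)
    a = wfwer_permutation_test(data, groups, subjects, "Suppression", n_perm=120, seed=9)
    b = wfwer_permutation_test(data, groups, subjects, "Suppression", n_perm=120, seed=9)
    np.testing.assert_array_equal(a[0].max_masses, b[0].max_masses)
    np.testing.assert_array_equal(a[1].mask, b[1].mask)


def test_mask_subset_of_suprathreshold(rng):
    data, groups, subjects = _stack_with_subjects(rng, delta=1.0)
    fmaps = mixed_anova_fmaps(data, groups)
    _, mask = wfwer_permutation_test(
        data, groups, subjects, "Suppression", n_perm=150, seed=0
    )
    assert mask.mask.sum() > 0  # the shift is large enough to detect
    assert np.all(fmaps["Suppression"].p[mask.mask] < 0.05)
    assert mask.direction > 0


def test_threshold_is_95th_percentile(rng):
    data, groups, subjects = _stack_with_subjects(rng)
    null, mask = wfwer_permutation_test(
        data, groups, subjects, "Interaction", n_perm=200, seed=3
    )
    assert null.threshold == pytest.approx(np.percentile(null.max_masses, 95))
    assert null.threshold >= np.median(null.max_masses)


def test_null_distribution_sign_flip_invariance(rng):
    """Flipping the sign of the data leaves the null distribution unchanged in law."""
    data, groups, subjects = _stack_with_subjects(rng)
    null_a, _ = wfwer_permutation_test(
        data, groups, subjects, "Suppression", n_perm=300, seed=21
    )
    null_b, _ = wfwer_permutation_test(
        -data, groups, subjects, "Suppression", n_perm=300, seed=22
    )
    _, p = stats.ks_2samp(null_a.max_masses, null_b.max_masses)
    assert p > 0.01


def test_refuses_too_few_units(rng):
    data, groups, subjects = _stack_with_subjects(rng, n_subj_per_group=2, ics_per_subject=1)
    with pytest.raises(ValueError, match="subjects"):
        wfwer_permutation_test(data, groups, subjects, "Interaction", n_perm=100, seed=0)
    small = data[:4]
    with pytest.raises(ValueError, match="ICs"):
        wfwer_permutation_test(
            small, groups[:4], subjects[:4], "Suppression", n_perm=100, seed=0
        )


def test_permutation_parameter_validation(rng):
    data, groups, subjects = _stack_with_subjects(rng)
    with pytest.raises(ValueError, match="100 permutations"):
        wfwer_permutation_test(data, groups, subjects, "Suppression", n_perm=50)
    with pytest.raises(ValueError, match="effect"):
        wfwer_permutation_test(data, groups, subjects, "Condition", n_perm=100)
    bad_subjects = subjects.copy()
    bad_subjects[0] = subjects[-1]  # subject now spans both groups
    with pytest.raises(ValueError, match="varies"):
        wfwer_permutation_test(data, groups, bad_subjects, "Group", n_perm=100)
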