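import numpy as np
import pytest

import ringmodes as rm
from ringmodes.enm import SpringNetwork, gnm_cross_correlation, gnm_decompose, gnm_msf
from ringmodes.modes import (
    build_ring_parameterization,
    classify_motion_type,
    compare_rings,
    detect_hinges,
    fold_by_symmetry,
    group_degenerate_modes,
    map_similarity,
    match_gnm_anm,
)


# ------------------------------------------------------------ mode grouping

@pytest.mark.parametrize(
    "eigs, expected",
    [
        ((1.0, 1.0, 2.0, 3.0, 3.0), [[1, 2], [3], [4, 5]]),
        ((1.0, 1.5, 2.0), [[1], [2], [3]]),
        ((1.0, 1.001, 1.02, 2.0), [[1, 2], [3], [4]]),  # run of 3 split at larger gap
        ((1.0, 1.005, 1.02), [[1, 2], [3]]),
    ],
)
def test_group_degenerate_modes(eigs, expected):
    assert group_degenerate_modes(eigs, n_consider=len(eigs), rel_tol=0.02 if len(eigs) > 3 else 0.01) == expected


def test_grouping_rejects_bad_arguments():
    with pytest.raises(ValueError):
        group_degenerate_modes([1.0, 2.0], 0, 0.01)
    with pytest.raises(ValueError):
        group_degenerate_modes([1.0, 2.0], 2, -1.0)
    with pytest.raises(ValueError):
        group_degenerate_modes([0.0, 1.0], 2, 0.01)


def test_c14_groups_as_pair_singleton_pair(c14_analysis):
    groups, _, _, _ = c14_analysis
    assert [g.gnm_modes for g in groups] == [(1, 2), (3,), (4, 5)]


# ------------------------------------------------------------------ folding

def test_fold_constant_profile(c14_structure):
    out = fold_by_symmetry(np.ones(len(c14_structure)), c14_structure)
    np.testing.assert_allclose(out, 1.0)


def test_fold_perfect_ring_reproduces_each_monomer(c14_structure, c14_gnm):
    msf = gnm_msf(c14_gnm, [1, 2])
    folded = fold_by_symmetry(msf, c14_structure)
    per_monomer = msf.reshape(14, -1)
    assert np.abs(per_monomer - folded).max() < 1e-9


def test_fold_reduces_estimator_variance_for_noisy_rings():
    """Monomer-averaged MSF profiles vary far less across noise realizations
    than single-monomer profiles (the point of symmetry folding)."""
    spec = dict(n_monomers=8, tm1_length=12, tm2_length=10, loop_length=3, noise_sd=0.3)
    folded_profiles, single_profiles = [], []
    for seed in range(6):
        s, _ = rm.build_synthetic_ring(rm.RingSpec(seed=seed, **spec))
        gnm = gnm_decompose(SpringNetwork(s, 10.0))
        msf = gnm_msf(gnm, [1, 2, 3, 4, 5])
        folded_profiles.append(fold_by_symmetry(msf, s))
        single_profiles.append(msf.reshape(8, -1)[0])
    var_folded = np.var(np.array(folded_profiles), axis=0).mean()
    var_single = np.var(np.array(single_profiles), axis=0).mean()
    assert var_folded < var_single / 3


def test_fold_requires_equal_monomers():
    from ringmodes.structure_io import CoarseStructure, ResidueRecord

    recs = (
        ResidueRecord("A", 1, "", "ALA", (0.0, 0.0, 0.0)),
        ResidueRecord("A", 2, "", "ALA", (4.0, 0.0, 0.0)),
        ResidueRecord("B", 1, "", "ALA", (8.0, 0.0, 0.0)),
    )
    uneven = CoarseStructure(recs)
    with pytest.raises(ValueError):
        fold_by_symmetry(np.ones(3), uneven)


# ------------------------------------------------------------------- hinges

def test_hinge_detection_on_constructed_profiles():
    v = np.concatenate([np.linspace(5, 1.5, 9), np.ones(5), np.linspace(1.5, 5, 9)])
    assert detect_hinges(v, quantile=0.2, min_run=3) == [(10, 14)]
    assert detect_hinges(np.ones(20)) == []
    # single-position gaps inside a low run are bridged
    v2 = np.full(20, 5.0)
    v2[[5, 6, 8, 9]] = 1.0  # 1-based positions 6, 7, 9, 10
    assert detect_hinges(v2, quantile=0.2, min_run=3) == [(6, 10)]


def test_short_runs_are_dropped():
    v = np.full(20, 5.0)
    v[[3, 10, 11, 12, 13]] = 1.0  # 1-based: lone 4, run 11-14
    assert detect_hinges(v, quantile=0.2, min_run=3) == [(11, 14)]


def test_hinges_of_bending_groups_contain_generator_kinks(c14_analysis, c14_truth):
    groups, _, _, _ = c14_analysis
    by_type = {g.motion_type: g for g in groups}
    for motion in ("II", "III"):
        hinges = by_type[motion].hinge_ranges
        for helix in ("TM1", "TM2"):
            kink = c14_truth.kink_positions[helix]
            assert any(a <= kink <= b for a, b in hinges), (motion, helix, hinges)


# ------------------------------------------------------- degenerate-pair gauge

@pytest.mark.parametrize("seed", range(5))
def test_pair_averages_invariant_under_eigenvector_remixing(c14_gnm, seed):
    """For an exactly degenerate pair any orthogonal remix of the two
    eigenvectors is an equally valid gauge; averaged MSF and correlation
    maps must not depend on it."""
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    angle = rng.uniform(0, 2 * np.pi)
    rot = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )
    if rng.random() < 0.5:
        rot[:, 1] *= -1.0  # include reflections: any orthogonal gauge
    vecs = c14_gnm.eigenvectors.copy()
    cols = [c14_gnm.n_zero_modes, c14_gnm.n_zero_modes + 1]  # modes 1, 2
    vecs[:, cols] = vecs[:, cols] @ rot
    remixed = replace(c14_gnm, eigenvectors=vecs)

    np.testing.assert_allclose(
        gnm_msf(remixed, [1, 2]), gnm_msf(c14_gnm, [1, 2]), atol=1e-8
    )
    np.testing.assert_allclose(
        gnm_cross_correlation(remixed, [1, 2]),
        gnm_cross_correlation(c14_gnm, [1, 2]),
        atol=1e-8,
    )


def test_pair_averaged_profiles_are_cn_symmetric(c14_structure, c14_analysis):
    """Individual degenerate eigenvectors break Cn symmetry; subspace
    averages restore it exactly."""
    groups, _, gnm, _ = c14_analysis
    for g in groups:
        if len(g.gnm_modes) != 2:
            continue
        msf = g.averaged_msf.reshape(14, -1)
        assert np.abs(msf - msf.mean(axis=0)).max() < 1e-8
        single = gnm_msf(gnm, [g.gnm_modes[0]]).reshape(14, -1)
        assert np.abs(single - single.mean(axis=0)).max() > 1e-4


# -------------------------------------------------------------- map matching

def test_map_similarity_endpoints(c14_analysis):
    groups, _, _, _ = c14_analysis
    m = groups[0].averaged_crosscorr
    assert map_similarity(m, m) == pytest.approx(1.0)
    assert map_similarity(m, -m) == pytest.approx(-1.0)


def test_type_one_group_matches_a_degenerate_anm_pair(c14_analysis):
    groups, _, _, anm = c14_analysis
    type_one = next(g for g in groups if g.motion_type == "I")
    matched, sims = match_gnm_anm(type_one.averaged_crosscorr, anm, range(1, 10))
    assert len(matched) == 2
    k1, k2 = matched
    assert anm.mode_eigenvalue(k2) == pytest.approx(anm.mode_eigenvalue(k1), rel=1e-9)
    worst_matched = min(sims[k] for k in matched)
    best_other = max(sims[k] for k in sims if k not in matched)
    assert worst_matched - best_other >= 0.05


def test_match_rejects_empty_candidates(c14_analysis):
    groups, _, _, anm = c14_analysis
    with pytest.raises(ValueError):
        match_gnm_anm(groups[0].averaged_crosscorr, anm, [])


# ------------------------------------------------------------ classification

def test_c14_three_slowest_groups_are_types_i_ii_iii(c14_analysis):
    groups, _, _, _ = c14_analysis
    assert [g.motion_type for g in groups] == ["I", "II", "III"]
    for g in groups:
        assert max(g.template_scores.values()) >= 0.6


def test_parameterization_labels_everything(c14_structure, c14_analysis, c14_truth):
    _, param, _, _ = c14_analysis
    assert param.theta.shape == (len(c14_structure),)
    assert np.all((param.theta >= 0) & (param.theta < 2 * np.pi))
    assert param.stromal.dtype == bool
    # hinge plane sits near the generator's waist (TM1 kink level)
    m = c14_structure.residues_per_monomer
    kink_z = param.z.reshape(14, m)[:, c14_truth.kink_positions["TM1"] - 1].mean()
    assert abs(param.hinge_plane_z - kink_z) < 5.0


def test_random_patterns_classify_as_other(c14_structure, c14_analysis):
    """Template correlation of random per-residue patterns is far below the
    0.6 acceptance threshold: essentially no false positives."""
    from dataclasses import replace

    groups, param, gnm, _ = c14_analysis
    rng = np.random.default_rng(2024)
    n = gnm.n_nodes
    labels = []
    for trial in range(100):
        vecs = gnm.eigenvectors.copy()
        pair = trial % 2 == 0
        cols = [gnm.n_zero_modes, gnm.n_zero_modes + 1]
        rand = rng.standard_normal((n, 2))
        rand /= np.linalg.norm(rand, axis=0)
        vecs[:, cols] = rand
        fake = replace(gnm, eigenvectors=vecs)
        modes = (1, 2) if pair else (1,)
        label, scores = classify_motion_type(modes, param, fake)
        labels.append(label)
        assert max(scores.values()) < 0.6, scores
    assert labels.count("other") == 100


def test_classification_respects_group_size(c14_analysis):
    """A degenerate pair can never be type II, a singleton never I/III."""
    groups, param, gnm, _ = c14_analysis
    label_pair, _ = classify_motion_type((1, 2), param, gnm)
    assert label_pair != "II"
    label_single, _ = classify_motion_type((3,), param, gnm)
    assert label_single != "I" and label_single != "III"


# -------------------------------------------------------------- ring batches

def test_compare_rings_smallest_and_largest():
    structures = []
    for n in (15, 8):
        s, _ = rm.build_synthetic_ring(rm.RingSpec(n_monomers=n))
        structures.append(s)
    table = compare_rings(structures, match_anm=False)
    assert list(table["n_monomers"]) == [8, 15]
    for types in table["motion_types"]:
        assert set(types) == {"I", "II", "III"}


def test_compare_rings_single_input(c14_structure):
    table = compare_rings([c14_structure], match_anm=False)
    assert len(table) == 1


def test_compare_rings_contains_per_ring_errors(c14_structure, small_structure):
    table = compare_rings(
        [small_structure, c14_structure], match_anm=False, gnm_cutoff=3.0
    )
    # a 3 Å cutoff disconnects the network: errors are contained per row
    assert (table["error"] != "").all()
    table2 = compare_rings([small_structure], match_anm=False)
    assert (table2["error"] == "").all()
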