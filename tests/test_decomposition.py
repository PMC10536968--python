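"""Energy-term catalogue, splitting conservation, region validation."""
import numpy as np
import pytest

from selgamd.region_decomposition import (
    AccelerationRegionSpec,
    DecompositionError,
    DecomposedSystem,
    GroupDefinition,
    build_catalogue,
    groups_from_system,
    split_energy,
    split_forces,
    validate_regions,
)
from selgamd.terms import TermIndex
from selgamd.toy_systems import BeadSystem, make_random_system, make_solute_solvent


@pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
def test_catalogue_size(n):
    groups = [
        GroupDefinition(str(g), frozenset({2 * g, 2 * g + 1})) for g in range(n)
    ]
    cat = build_catalogue(groups)
    assert len(cat) == 2 * n + n * (n - 1) // 2
    kinds = [t.kind for t in cat]
    assert kinds.count("bonded") == n
    assert kinds.count("self") == n
    assert kinds.count("pair") == n * (n - 1) // 2
    dual = build_catalogue(groups, dual_boost=True)
    assert len(dual) == len(cat) + n


def test_catalogue_small_cases():
    g0 = GroupDefinition("0", frozenset({0, 1}))
    cat1 = build_catalogue([g0])
    assert cat1 == [TermIndex("bonded", 0), TermIndex("self", 0)]
    g1 = GroupDefinition("1", frozenset({2, 3}))
    cat2 = build_catalogue([g0, g1])
    assert set(t.label for t in cat2) == {"b0", "b1", "0-0", "1-1", "0-1"}


def test_catalogue_rejects_bad_partitions():
    with pytest.raises(DecompositionError):
        build_catalogue(
            [GroupDefinition("a", {0, 1}), GroupDefinition("b", {1, 2})]
        )
    with pytest.raises(DecompositionError):
        build_catalogue([GroupDefinition("a", {0, 1})], n_beads=4)


def _brute_force_split(sys_, catalogue):
    """Independent per-term tally: explicit loops with group tagging."""
    import math

    from selgamd.toy_systems import dihedral_angle

    x = sys_.positions
    lab = sys_.group_label
    out = {t: 0.0 for t in catalogue}
    dual = any(t.kind == "dihedral" for t in catalogue)
    for (i, j, r0, kb) in sys_.bonds:
        r = float(np.linalg.norm(sys_.displacement(x[i], x[j])))
        out[TermIndex("bonded", int(lab[i]))] += 0.5 * kb * (r - r0) ** 2
    for (i, j, k, l, kt, m, ph) in sys_.torsions:
        phi = dihedral_angle(x[i], x[j], x[k], x[l], sys_.box)
        kind = "dihedral" if dual else "bonded"
        out[TermIndex(kind, int(lab[i]))] += kt * (
            1 + math.cos(math.radians(m * phi - ph))
        )
    excl = sys_.excluded_pairs
    for i in range(sys_.n_beads):
        for j in range(i + 1, sys_.n_beads):
            if (i, j) in excl:
                continue
            r = float(np.linalg.norm(sys_.displacement(x[i], x[j])))
            gi, gj = int(lab[i]), int(lab[j])
            t = (
                TermIndex("self", gi)
                if gi == gj
                else TermIndex("pair", min(gi, gj), max(gi, gj))
            )
            out[t] += sys_.pair_energy(r)
    return out


@pytest.mark.parametrize("dual", [False, True])
def test_split_energy_matches_brute_force(dual):
    sys_ = make_random_system(14, 3, seed=17)
    cat = build_catalogue(groups_from_system(sys_), dual_boost=dual)
    got = split_energy(sys_, sys_.positions, cat)
    want = _brute_force_split(sys_, cat)
    for t in cat:
        assert got[t] == pytest.approx(want[t], rel=1e-10, abs=1e-12), t.label


def test_split_energy_two_beads_one_group():
    sys_ = make_solute_solvent(2, 0)
    cat = build_catalogue(groups_from_system(sys_))
    split = split_energy(sys_, sys_.positions, cat)
    assert set(split) == {TermIndex("bonded", 0), TermIndex("self", 0)}
    # the only bead pair is bonded, hence excluded from the nonbonded term
    assert split[TermIndex("self", 0)] == 0.0


@pytest.mark.parametrize("seed", range(4))
def test_conservation_energy_and_forces(seed):
    sys_ = make_random_system(15, 3, seed=seed)
    cat = build_catalogue(groups_from_system(sys_))
    rng = np.random.default_rng(seed)
    x = sys_.positions + rng.normal(scale=0.02, size=sys_.positions.shape)
    energies = split_energy(sys_, x, cat)
    total = sum(energies.values())
    assert total == pytest.approx(sys_.potential_energy(x), rel=1e-9)
    forces = split_forces(sys_, x, cat)
    f_sum = sum(forces.values())
    # undecomposed total: the trivial one-group catalogue
    mono = BeadSystem(
        positions=sys_.positions, masses=sys_.masses,
        group_label=np.zeros(sys_.n_beads, dtype=int),
        bonds=sys_.bonds, torsions=sys_.torsions,
        nonbonded=sys_.nonbonded, box=sys_.box,
    )
    mono_cat = build_catalogue(groups_from_system(mono))
    f_mono = sum(split_forces(mono, x, mono_cat).values())
    scale = np.abs(f_mono).max()
    assert np.allclose(f_sum, f_mono, atol=1e-9 * max(1.0, scale))


def test_per_term_force_is_minus_gradient_of_term_energy():
    sys_ = make_random_system(12, 3, seed=23)
    cat = build_catalogue(groups_from_system(sys_), dual_boost=True)
    x0 = sys_.positions
    forces = split_forces(sys_, x0, cat)
    h = 1e-6
    rng = np.random.default_rng(0)
    for t in cat:
        for _ in range(3):
            i = int(rng.integers(sys_.n_beads))
            d = int(rng.integers(3))
            xp, xm = x0.copy(), x0.copy()
            xp[i, d] += h
            xm[i, d] -= h
            fd = -(
                split_energy(sys_, xp, cat)[t] - split_energy(sys_, xm, cat)[t]
            ) / (2 * h)
            assert forces[t][i, d] == pytest.approx(fd, rel=1e-5, abs=1e-6)


def test_refinement_consistency():
    """Merging two groups yields term sums equal to the finer-term sums."""
    sys_ = make_random_system(15, 3, seed=31)
    fine_cat = build_catalogue(groups_from_system(sys_))
    fine = split_energy(sys_, sys_.positions, fine_cat)

    merged = BeadSystem(
        positions=sys_.positions, masses=sys_.masses,
        group_label=np.minimum(sys_.group_label, 1),  # merge groups 1 and 2
        bonds=sys_.bonds, torsions=sys_.torsions,
        nonbonded=sys_.nonbonded, box=sys_.box,
    )
    coarse_cat = build_catalogue(groups_from_system(merged))
    coarse = split_energy(merged, sys_.positions, coarse_cat)

    b = TermIndex("bonded", 1)
    assert coarse[b] == pytest.approx(
        fine[TermIndex("bonded", 1)] + fine[TermIndex("bonded", 2)], rel=1e-12
    )
    assert coarse[TermIndex("self", 1)] == pytest.approx(
        fine[TermIndex("self", 1)]
        + fine[TermIndex("self", 2)]
        + fine[TermIndex("pair", 1, 2)],
        rel=1e-12,
    )
    assert coarse[TermIndex("pair", 0, 1)] == pytest.approx(
        fine[TermIndex("pair", 0, 1)] + fine[TermIndex("pair", 0, 2)], rel=1e-12
    )


def test_bond_spanning_groups_is_an_error():
    sys_ = make_solute_solvent(4, 4, seed=1)
    bad = BeadSystem(
        positions=sys_.positions, masses=sys_.masses,
        group_label=sys_.group_label,
        bonds=sys_.bonds + [(0, 5, 0.4, 100.0)],  # solute-solvent bond
        torsions=sys_.torsions, box=sys_.box,
    )
    cat = build_catalogue(groups_from_system(bad))
    with pytest.raises(DecompositionError, match="spans groups"):
        split_energy(bad, bad.positions, cat)


def test_validate_regions_solute_solvent_split(small_mixture_model):
    cat = list(small_mixture_model.catalogue)
    specs = [
        AccelerationRegionSpec("solute", frozenset({"b0", "0-0", "0-1"})),
        AccelerationRegionSpec("solvent", frozenset({"b1", "1-1"})),
    ]
    rs = validate_regions(specs, cat)
    assert [r.name for r in rs.regions] == ["solute", "solvent"]
    assert not rs.unassigned_slots
    claimed = {s for r in rs.regions for s in r.all_slots}
    assert claimed == set(range(len(cat)))


def test_validate_regions_errors(small_mixture_model):
    cat = list(small_mixture_model.catalogue)
    with pytest.raises(DecompositionError, match="claimed by both"):
        validate_regions(
            [
                AccelerationRegionSpec("a", frozenset({"0-1"})),
                AccelerationRegionSpec("b", frozenset({"0-1", "b1"})),
            ],
            cat,
        )
    with pytest.raises(DecompositionError, match="no member terms"):
        validate_regions([AccelerationRegionSpec("a", frozenset())], cat)
    with pytest.raises(DecompositionError, match="unknown term"):
        validate_regions([AccelerationRegionSpec("a", frozenset({"0-7"}))], cat)


def test_unassigned_terms_recorded(small_mixture_model):
    cat = list(small_mixture_model.catalogue)
    rs = validate_regions(
        [AccelerationRegionSpec("solute", frozenset({"b0", "0-0"}))], cat
    )
    labels = {cat[s].label for s in rs.unassigned_slots}
    assert labels == {"b1", "1-1", "0-1"}


def test_dihedral_terms_carved_out_of_bonded(small_mixture):
    model = DecomposedSystem(small_mixture, dual_boost=True)
    plain = DecomposedSystem(small_mixture, dual_boost=False)
    e_dual, _ = model.term_energies_forces(small_mixture.positions)
    e_plain, _ = plain.term_energies_forces(small_mixture.positions)
    lab_d = [t.label for t in model.catalogue]
    lab_p = [t.label for t in plain.catalogue]
    # refined bonded + dihedral = unrefined bonded, totals conserved
    assert e_dual[lab_d.index("b0")] + e_dual[lab_d.index("d0")] == pytest.approx(
        e_plain[lab_p.index("b0")], rel=1e-12
    )
    assert e_dual.sum() == pytest.approx(e_plain.sum(), rel=1e-12)
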