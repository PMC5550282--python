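import numpy as np
import pytest

from utrisim import EnergyParams, Lattice, hexgrid, metropolis_accept
from utrisim._kernels import proposal_delta, seed_rng
from utrisim.synth import gen_initial_tissue

from conftest import make_speckle_lattice


def reference_energy(lat: Lattice) -> dict:
    """Independent pure-Python energy decomposition via hexgrid.neighbors."""
    p = lat.params
    c = p.boundary_pair_factor
    S = 0
    cc = 0
    vols = {}
    surfs = {}
    for r in range(lat.height):
        for col in range(lat.width):
            a = int(lat.owner[r, col])
            if a != 0:
                vols[a] = vols.get(a, 0) + 1
            for nb in lat.neighbors((r, col)):
                b = int(lat.owner[nb])
                if b == a:
                    continue
                if a != 0:
                    surfs[a] = surfs.get(a, 0) + 1
                    if b == 0:
                        S += 1  # counted once, from the cell side
                    elif a < b:
                        cc += 1
    H_vol = sum(p.lambda_vol * (v - p.VT) ** 2 for v in vols.values())
    H_surf = sum(
        p.lambda_surf * (surfs.get(k, 0) - p.ST) ** 2 for k in vols
    )
    return {
        "contact": c * p.JC * cc,
        "volume": float(H_vol),
        "surface": float(H_surf),
        "boundary": c * p.E * S**2,
        "S": S,
        "vols": vols,
        "surfs": surfs,
    }


def lattice_with_pixels(pixels, cid=1, shape=(12, 12), params=None):
    owner = np.zeros(shape, dtype=np.int64)
    for r, c in pixels:
        owner[r, c] = cid
    return Lattice(owner, params or EnergyParams())


# ---------------------------------------------------------------------------
# perimeter and energy terms
# ---------------------------------------------------------------------------


def test_perimeter_empty_lattice_is_zero():
    assert Lattice.empty(10, 10).perimeter() == 0


def test_perimeter_single_pixel_cell_is_six():
    assert lattice_with_pixels([(5, 5)]).perimeter() == 6


def test_perimeter_two_adjacent_pixels_is_ten():
    lat = lattice_with_pixels([(5, 5), (5, 6)])
    assert lat.perimeter() == 10  # 12 single-pixel links minus the 2 shared


def test_volume_and_surface_penalties_direct_evaluation():
    # deviation of 2 pixels below VT=40 at lambda_vol=9 costs 36
    p = EnergyParams()
    lat = make_speckle_lattice(params=p)
    ref = reference_energy(lat)
    terms = lat.energy_terms()
    for key in ("contact", "volume", "surface", "boundary"):
        assert terms[key] == pytest.approx(ref[key])
    assert terms["total"] == pytest.approx(
        terms["contact"] + terms["volume"] + terms["surface"] + terms["boundary"]
    )
    # spot check the quadratic forms
    some_v = next(iter(ref["vols"].values()))
    assert p.lambda_vol * (38 - p.VT) ** 2 == 36
    assert p.lambda_surf * (27 - p.ST) ** 2 == 6
    del some_v


def test_boundary_term_single_pixel_cell_matches_hand_count():
    # S = 6, H_boundary = c*E*S^2 = 2*0.069*36 = 4.968
    lat = lattice_with_pixels([(5, 5)])
    assert lat.energy_terms()["boundary"] == pytest.approx(4.968)


def test_zero_volume_deviation_costs_nothing():
    p = EnergyParams(VT=7, ST=18)
    flower = [(5, 5)] + hexgrid.neighbors((5, 5), 12, 12)
    lat = lattice_with_pixels(flower, params=p)
    terms = lat.energy_terms()
    assert terms["volume"] == 0.0
    assert terms["surface"] == 0.0  # flower surface is 18 external links


def test_hex_flower_bookkeeping():
    flower = [(5, 5)] + hexgrid.neighbors((5, 5), 12, 12)
    lat = lattice_with_pixels(flower)
    assert lat.volumes[1] == 7
    assert lat.surfaces[1] == 18
    assert lat.perimeter() == 18


# ---------------------------------------------------------------------------
# delta_H against brute-force recomputation
# ---------------------------------------------------------------------------


def _oracle_delta(lat: Lattice, target, B) -> float:
    after = lat.owner.copy()
    after[target] = B
    return (
        Lattice(after, lat.params).energy_terms()["total"]
        - lat.energy_terms()["total"]
    )


def test_delta_h_same_owner_pair_is_zero(speckle):
    lat = speckle
    for r in range(lat.height - 1):
        c = 0
        if lat.owner[r, c] == lat.owner[r + 1, c]:
            assert lat.delta_H((r, c), (r + 1, c)) == 0.0
            break


def test_delta_h_matches_full_recompute_on_random_proposals():
    lat = make_speckle_lattice(seed=3)
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 10_000:
        r = int(rng.integers(lat.height))
        c = int(rng.integers(lat.width))
        nbrs = lat.neighbors((r, c))
        src = nbrs[int(rng.integers(len(nbrs)))]
        B = int(lat.owner[src])
        if B == lat.owner[r, c]:
            continue
        inc = lat.delta_H(src, (r, c))
        full = _oracle_delta(lat, (r, c), B)
        assert inc == pytest.approx(full, rel=1e-9, abs=1e-9)
        checked += 1
        # occasionally commit the move so the state keeps changing
        if rng.random() < 0.3:
            lat.owner[r, c] = B
            lat._rebuild()


def test_delta_h_removes_penalties_of_annihilated_single_pixel_cell():
    owner = np.zeros((10, 10), dtype=np.int64)
    owner[4, 4] = 1
    owner[4, 5] = 2
    owner[5, 4] = 3  # the 1-pixel victim, adjacent to both
    lat = Lattice(owner, EnergyParams())
    target = (5, 4)
    src = (4, 4)
    assert target in lat.neighbors(src)
    inc = lat.delta_H(src, target)
    assert inc == pytest.approx(_oracle_delta(lat, target, 1), rel=1e-12)


def test_non_neighbor_delta_rejected(speckle):
    with pytest.raises(ValueError):
        speckle.delta_H((0, 0), (5, 5))


# ---------------------------------------------------------------------------
# Metropolis acceptance
# ---------------------------------------------------------------------------


def test_nonpositive_delta_always_accepted():
    rng = np.random.default_rng(0)
    assert all(metropolis_accept(-1.0, 5.0, rng) for _ in range(1000))
    assert all(metropolis_accept(0.0, 5.0, rng) for _ in range(1000))


def test_invalid_temperature_rejected():
    with pytest.raises(ValueError):
        metropolis_accept(1.0, 0.0, np.random.default_rng(0))
    with pytest.raises(ValueError):
        EnergyParams(Tm=-1)


@pytest.mark.parametrize("mult", [1.0, 2.0])
def test_boltzmann_acceptance_frequency(mult):
    Tm = 5.0
    dH = mult * Tm
    rng = np.random.default_rng(123)
    n = 100_000
    acc = sum(metropolis_accept(dH, Tm, rng) for _ in range(n))
    p = np.exp(-mult)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(acc / n - p) < 3 * se


def test_acceptance_invariant_under_joint_energy_rescaling():
    # dH is linear in the energy parameters, so scaling them with Tm leaves
    # exp(-dH/Tm) unchanged
    base = EnergyParams()
    k = 3.7
    scaled = EnergyParams(
        Tm=base.Tm * k,
        VT=base.VT,
        lambda_vol=base.lambda_vol * k,
        ST=base.ST,
        lambda_surf=base.lambda_surf * k,
        JC=base.JC * k,
        E=base.E * k,
    )
    lat1 = make_speckle_lattice(seed=9, params=base)
    lat2 = Lattice(lat1.owner.copy(), scaled)
    rng = np.random.default_rng(11)
    checked = 0
    while checked < 200:
        r = int(rng.integers(lat1.height))
        c = int(rng.integers(lat1.width))
        nbrs = lat1.neighbors((r, c))
        src = nbrs[int(rng.integers(len(nbrs)))]
        if lat1.owner[src] == lat1.owner[r, c]:
            continue
        d1 = lat1.delta_H(src, (r, c))
        d2 = lat2.delta_H(src, (r, c))
        assert d2 == pytest.approx(k * d1, rel=1e-12)
        checked += 1


# ---------------------------------------------------------------------------
# Monte Carlo steps
# ---------------------------------------------------------------------------


def test_mcs_bookkeeping_matches_brute_force_recount():
    owner = gen_initial_tissue(8, 50, 50, seed=2)
    lat = Lattice(owner, EnergyParams(E=0.3))
    seed_rng(99)
    for _ in range(100):
        lat.monte_carlo_step()
    lat.audit()  # volumes, surfaces, CM sums, S all equal brute force
    assert lat.mcs == 100


def test_volume_conservation_under_dynamics():
    owner = gen_initial_tissue(8, 50, 50, seed=2)
    lat = Lattice(owner, EnergyParams(E=0.3))
    n_sites = lat.height * lat.width
    seed_rng(7)
    for _ in range(50):
        lat.monte_carlo_step()
        n = lat._max_id + 1
        eb_sites = int((lat.owner == 0).sum())
        assert int(lat.volumes[1:n].sum()) + eb_sites == n_sites


def test_kernel_and_python_delta_agree(speckle):
    lat = make_speckle_lattice(seed=21)
    p = lat.params
    rng = np.random.default_rng(5)
    for _ in range(500):
        r = int(rng.integers(lat.height))
        c = int(rng.integers(lat.width))
        nbrs = lat.neighbors((r, c))
        src = nbrs[int(rng.integers(len(nbrs)))]
        B = int(lat.owner[src])
        dH, dS, dsA, dsB = proposal_delta(
            lat.owner, lat.volumes, lat.surfaces, int(lat._S[0]), r, c, B,
            p.VT, p.lambda_vol, p.ST, p.lambda_surf, p.JC, p.E,
            p.boundary_pair_factor,
        )
        if B == lat.owner[r, c]:
            assert dH == 0.0
        else:
            assert dH == pytest.approx(_oracle_delta(lat, (r, c), B), rel=1e-9, abs=1e-9)


def test_text_round_trip(speckle, tmp_path):
    path = tmp_path / "labels.txt"
    speckle.save_text(path)
    again = Lattice.load_text(path, speckle.params)
    np.testing.assert_array_equal(again.owner, speckle.owner)
    assert again.perimeter() == speckle.perimeter()
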