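import itertools

import numpy as np
import pytest

import meadowdiv as md
from meadowdiv.zeta import terminal_ratio, zeta_ratios

from conftest import random_incidence


def brute_force_zeta(presence, order):
    """Mean shared-species count over every combination of `order` units."""
    n = presence.shape[0]
    vals = [
        presence[list(c)].all(axis=0).sum()
        for c in itertools.combinations(range(n), order)
    ]
    return float(np.mean(vals))


def make_inc(rows):
    pres = np.array(rows)
    return md.IncidenceMatrix(
        [f"u{i}" for i in range(pres.shape[0])],
        [f"s{j}" for j in range(pres.shape[1])],
        pres,
    )


def test_three_unit_worked_example():
    # occupancies A:3, B:2, C:1 -> shared pairs 2,1,1
    inc = make_inc([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
    assert md.zeta_exact(inc, 1) == pytest.approx(2.0)
    assert md.zeta_exact(inc, 2) == pytest.approx(4 / 3)
    assert md.zeta_exact(inc, 3) == pytest.approx(1.0)
    dec = md.zeta_decline(inc, max_order=3)
    assert zeta_ratios(dec) == pytest.approx([2 / 3, 3 / 4])


def test_saturated_matrix_flat_curve():
    inc = make_inc(np.ones((5, 7), dtype=int))
    dec = md.zeta_decline(inc, max_order=5)
    assert np.allclose(dec.zeta, 7)
    assert np.allclose(zeta_ratios(dec), 1)


def test_disjoint_units_share_nothing():
    inc = make_inc([[1, 1, 0, 0], [0, 0, 1, 1]])
    assert md.zeta_exact(inc, 2) == 0


def test_closed_form_equals_enumeration_on_random_matrices():
    rng = np.random.default_rng(42)
    for _ in range(100):
        inc = random_incidence(rng)
        for order in range(1, inc.n_units + 1):
            assert md.zeta_exact(inc, order) == pytest.approx(
                brute_force_zeta(inc.presence, order), abs=1e-12
            )


def test_boundary_identities_and_monotonicity():
    rng = np.random.default_rng(9)
    for _ in range(50):
        inc = random_incidence(rng)
        dec = md.zeta_decline(inc, max_order=inc.n_units, sd=False)
        assert dec.zeta[0] == pytest.approx(inc.presence.sum(axis=1).mean())
        assert dec.zeta[-1] == pytest.approx((inc.occupancy == inc.n_units).sum())
        assert np.all(np.diff(dec.zeta) <= 1e-12)  # nonincreasing


def test_ubiquitous_species_adds_one_to_every_order():
    rng = np.random.default_rng(5)
    inc = random_incidence(rng, n_units=6, n_species=10)
    plus = md.IncidenceMatrix(
        inc.unit_ids, inc.species_ids + ["ubiq"],
        np.hstack([inc.presence, np.ones((6, 1), dtype=int)]),
    )
    for order in range(1, 7):
        assert md.zeta_exact(plus, order) == pytest.approx(md.zeta_exact(inc, order) + 1)


def test_monte_carlo_agrees_with_exact():
    rng = np.random.default_rng(12)
    inc = random_incidence(rng, n_units=8, n_species=15)
    mc = md.zeta_decline(inc, max_order=5, mode="monte_carlo", n_samples=10_000, seed=1)
    ex = md.zeta_decline(inc, max_order=5, sd=False)
    se = mc.sd / np.sqrt(mc.n_samples)
    assert np.all(np.abs(mc.zeta - ex.zeta) <= 3 * np.maximum(se, 1e-9))


def test_ratio_semantics_at_zero():
    # disjoint units: zeta hits 0 at order 2, so ratio[0] = 0, ratio[1] missing
    inc = make_inc([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
    dec = md.zeta_decline(inc, max_order=3)
    r = zeta_ratios(dec)
    assert r[0] == 0.0 and np.isnan(r[1])
    assert terminal_ratio(dec) == 0.0


def test_decline_reaches_zero_on_rare_dominated_communities():
    d = md.SyntheticDesign(
        n_treatments=1, occupancy_profile={"T1": "rare_dominated"},
        dark_withhold_rate=0.0, seed=4,
    )
    cm, _, _ = md.simulate_community(d)
    dec = md.zeta_decline(md.to_incidence(cm), max_order=12, sd=False)
    assert np.all(np.diff(dec.zeta) <= 1e-12)
    assert dec.zeta[-1] == pytest.approx(0.0)


def test_mode_and_order_validation():
    inc = make_inc([[1, 0], [0, 1]])
    with pytest.raises(ValueError):
        md.zeta_exact(inc, 3)
    with pytest.raises(ValueError):
        md.zeta_decline(inc, max_order=2, mode="monte_carlo", n_samples=0, seed=1)
    with pytest.raises(ValueError):
        md.zeta_decline(inc, max_order=2, mode="bogus")


def test_permutation_test_null_on_identical_strata():
    rng = np.random.default_rng(2)
    inc = random_incidence(rng, n_units=6, n_species=12)
    res = md.zeta_permutation_test(inc, inc, max_order=4, n_perm=199, seed=0)
    assert res["p_global"] > 0.5
    assert np.all(res["p_per_order"] > 0.5)
    with pytest.raises(ValueError):
        md.zeta_permutation_test(inc, inc, n_perm=0)


def test_permutation_test_detects_preset_contrast():
    hits = 0
    for s in range(8):
        strata = {}
        for prof in ("widespread_dominated", "rare_dominated"):
            d = md.SyntheticDesign(
                n_treatments=1, occupancy_profile={"T1": prof},
                dark_withhold_rate=0.0, n_species=40, seed=100 + s,
            )
            cm, _, _ = md.simulate_community(d)
            strata[prof] = md.to_incidence(cm)
        res = md.zeta_permutation_test(
            strata["widespread_dominated"], strata["rare_dominated"],
            max_order=5, n_perm=199, seed=s,
        )
        hits += res["p_global"] < 0.05
    assert hits >= 6
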