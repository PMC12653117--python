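import numpy as np
import pandas as pd
import pytest

import meadowdiv as md
from meadowdiv.community import ConsistencyError
from meadowdiv.dark import beals_matrix, cci, dark_sets, pdd, species_thresholds

from conftest import random_incidence


def brute_force_beals(inc_presence, ref_presence):
    """O(units x species^2) double-loop reference for Beals smoothing."""
    n_units, n_sp = inc_presence.shape
    M = ref_presence.T @ ref_presence
    n = ref_presence.sum(axis=0)
    P = np.zeros((n_units, n_sp))
    for k in range(n_units):
        for j in range(n_sp):
            total, s_prime = 0.0, 0
            for i in range(n_sp):
                if i == j or inc_presence[k, i] == 0:
                    continue
                s_prime += 1
                if n[i] > 0:
                    total += M[i, j] / n[i]
            P[k, j] = total / s_prime if s_prime else 0.0
    return P


def make_inc(rows, species=None):
    pres = np.array(rows)
    return md.IncidenceMatrix(
        [f"u{i}" for i in range(pres.shape[0])],
        species or [f"s{j}" for j in range(pres.shape[1])],
        pres,
    )


def test_hand_worked_beals_probability():
    # units: s1={A,B}, s2={A,B}, s3={B}; P(A at s3) = M_AB / n_B = 2/3
    inc = make_inc([[1, 1], [1, 1], [0, 1]], species=["A", "B"])
    bm = beals_matrix(inc)
    assert bm.to_frame().loc["u2", "A"] == pytest.approx(2 / 3)


def test_always_cooccurring_pair_gives_probability_one():
    inc = make_inc([[1, 1, 0], [1, 1, 0], [1, 1, 1]])
    bm = beals_matrix(inc)
    # s0 and s1 always co-occur: any unit containing s1 predicts s0 with 1
    assert bm.to_frame().loc["u0", "s0"] == pytest.approx(1.0)


def test_vectorized_beals_equals_double_loop_oracle():
    rng = np.random.default_rng(17)
    for _ in range(50):
        inc = random_incidence(rng, n_units=6, n_species=10)
        bm = beals_matrix(inc)
        assert np.allclose(bm.p, brute_force_beals(inc.presence, inc.presence), atol=1e-12)
        assert bm.p.min() >= 0 and bm.p.max() <= 1


def test_self_exclusion():
    """Flipping a species' own presence at a unit leaves its probability there
    unchanged when the reference pool is held fixed."""
    rng = np.random.default_rng(23)
    inc = random_incidence(rng, n_units=6, n_species=10)
    ref = random_incidence(rng, n_units=8, n_species=10)
    bm = beals_matrix(inc, ref)
    flipped = inc.presence.copy()
    flipped[2, 4] = 1 - flipped[2, 4]
    inc2 = md.IncidenceMatrix(inc.unit_ids, inc.species_ids, flipped)
    bm2 = beals_matrix(inc2, ref)
    assert bm2.p[2, 4] == pytest.approx(bm.p[2, 4], abs=1e-12)


def test_reference_species_mismatch_rejected():
    inc = make_inc([[1, 0], [0, 1]])
    ref = make_inc([[1, 0, 1], [0, 1, 1]])
    with pytest.raises(ConsistencyError):
        beals_matrix(inc, ref)


def test_thresholds_minimum_and_quantile():
    inc = make_inc([[1, 1], [1, 1], [0, 1], [1, 1]], species=["A", "B"])
    bm = beals_matrix(inc)
    thr0, _ = species_thresholds(bm, inc, q=0.0)
    vals = bm.p[inc.presence[:, 0] == 1, 0]
    assert thr0["A"] == pytest.approx(vals.min())
    thr_q, _ = species_thresholds(bm, inc, q=0.25)
    assert thr_q["A"] == pytest.approx(np.quantile(vals, 0.25))
    with pytest.raises(ValueError):
        species_thresholds(bm, inc, q=1.5)


def test_threshold_singleton_presence():
    inc = make_inc([[1, 1], [0, 1], [0, 1]], species=["A", "B"])
    bm = beals_matrix(inc)
    only = bm.p[0, 0]
    for q in (0.0, 0.01, 0.5, 1.0):
        thr, _ = species_thresholds(bm, inc, q=q)
        assert thr["A"] == pytest.approx(only)


def test_full_occupancy_species_skipped_and_never_dark():
    inc = make_inc([[1, 1], [1, 0], [1, 1]], species=["ubiq", "B"])
    bm = beals_matrix(inc)
    thr, skipped = species_thresholds(bm, inc, q=0.0)
    assert "ubiq" in skipped and np.isnan(thr["ubiq"])
    dk = dark_sets(bm, inc, thr)
    assert not dk["ubiq"].any()


def test_dark_sets_strict_inequality_and_monotonicity():
    rng = np.random.default_rng(31)
    inc = random_incidence(rng, n_units=8, n_species=12)
    bm = beals_matrix(inc)
    sizes = []
    prev_thr = None
    for q in (0.0, 0.1, 0.3, 0.6):
        thr, _ = species_thresholds(bm, inc, q=q)
        if prev_thr is not None:
            assert np.all(thr.fillna(0) >= prev_thr.fillna(0) - 1e-12)
        prev_thr = thr
        dk = dark_sets(bm, inc, thr)
        assert not (dk.to_numpy() & (inc.presence == 1)).any()  # only absences
        sizes.append(dk.to_numpy().sum())
    assert np.all(np.diff(sizes) <= 0)  # dark sets shrink as thresholds rise
    # unreachable threshold: never dark
    high = prev_thr.copy()
    high[:] = 1.1
    assert dark_sets(bm, inc, high).to_numpy().sum() == 0


def test_pdd_ratios():
    inc = make_inc([[1, 0], [0, 0], [0, 0], [0, 0]], species=["A", "B"])
    dark = pd.DataFrame(
        [[False, False], [True, False], [True, False], [True, False]],
        index=inc.unit_ids, columns=inc.species_ids,
    )
    tab = pdd(dark, inc).set_index("species")
    assert tab.loc["A", "ND"] == 3 and tab.loc["A", "NP"] == 4
    assert tab.loc["A", "PDD"] == pytest.approx(0.75)
    assert np.isnan(tab.loc["B", "PDD"])  # NP = 0 -> not applicable


def test_cci_values_and_monotonicity():
    assert cci(9, 1) == pytest.approx(0.9)
    assert cci(5, 0) == 1.0
    assert cci(3, 3) == pytest.approx(0.5)
    vals = [cci(4, pr) for pr in range(6)]
    assert np.all(np.diff(vals) < 0)  # strictly decreasing in PR
    assert np.isnan(cci(0, 0))
    with pytest.raises(ValueError):
        cci(-1, 2)


def test_dark_diversity_recovers_withheld_occurrences(default_bundle):
    cm, gt, truth = default_bundle
    res = md.dark_diversity(cm, level="transect", q=0.01)
    metrics = md.evaluate_dark_recovery(truth, res)
    assert metrics["n_withheld"] > 0
    assert 0 <= metrics["sensitivity"] <= 1
    assert metrics["sensitivity"] > metrics["flag_rate_ineligible_absences"]


def test_dark_diversity_plot_level_default(default_bundle):
    cm, gt, _ = default_bundle
    res = md.dark_diversity(cm, gt, guild="Ph", level="plot", q=0.01)
    assert len(res.cci) == 12  # plots
    assert ((res.cci.CCI > 0) & (res.cci.CCI <= 1)).all()
    for u, s in res.dark_sets.items():
        assert s <= set(res.beals.species_ids)
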