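import math

import numpy as np
import pytest

from hexbind.constants import rt
from hexbind.io import read_structure, write_pdb
from hexbind.synthetic import (
    FixtureSpec,
    LigandPlacement,
    PMFSpec,
    make_hexamer_fixture,
    make_insser_t3r3_spec,
    make_ti_series,
    make_titration,
    sample_bound_positions,
    sample_umbrella_windows,
)


# ---------------------------------------------------------------------------
# determinism contracts


def test_fixture_bit_reproducible_and_jitter_bounded():
    spec_a = FixtureSpec(monomer_states=("T",) * 6, seed=5)
    spec_b = FixtureSpec(monomer_states=("T",) * 6, seed=5)
    a = make_hexamer_fixture(spec_a)
    b = make_hexamer_fixture(spec_b)
    assert np.array_equal(a.positions(), b.positions())
    c = make_hexamer_fixture(FixtureSpec(monomer_states=("T",) * 6, seed=6))
    assert len(c.atoms) == len(a.atoms)
    diff = np.abs(a.positions() - c.positions()).max()
    assert 0.0 < diff <= 0.05


def test_generators_bit_reproducible():
    s1, _ = make_ti_series(a=1.0, c=0.5, noise_sem=0.1, seed=9)
    s2, _ = make_ti_series(a=1.0, c=0.5, noise_sem=0.1, seed=9)
    assert np.array_equal(s1.dudl_mean, s2.dudl_mean)

    t1 = make_titration(1.0, 0.2, 2.0, np.geomspace(0.1, 10, 8), 0.01, 3, seed=4)
    t2 = make_titration(1.0, 0.2, 2.0, np.geomspace(0.1, 10, 8), 0.01, 3, seed=4)
    for a, b in zip(t1, t2):
        assert np.array_equal(a.delta_a, b.delta_a)

    spec = PMFSpec(form="harmonic", curvature=1.0)
    u1 = sample_umbrella_windows(spec, [0.0], 5.0, 100, seed=2)
    u2 = sample_umbrella_windows(spec, [0.0], 5.0, 100, seed=2)
    assert np.array_equal(u1.windows[0].samples, u2.windows[0].samples)

    p1, _ = sample_bound_positions(np.eye(3), 50, seed=3)
    p2, _ = sample_bound_positions(np.eye(3), 50, seed=3)
    assert np.array_equal(p1, p2)


def test_replicate_subseeds_are_stable_under_extension():
    three = make_titration(1.0, 0.2, 2.0, np.geomspace(0.1, 10, 8), 0.01, 3, seed=7)
    five = make_titration(1.0, 0.2, 2.0, np.geomspace(0.1, 10, 8), 0.01, 5, seed=7)
    for a, b in zip(three, five):
        assert np.array_equal(a.delta_a, b.delta_a)


# ---------------------------------------------------------------------------
# hexamer fixture content


def test_insser_fixture_composition(insser_hexamer):
    resnames = {}
    for a in insser_hexamer.atoms:
        resnames.setdefault(a.residue_name, set()).add(
            (a.chain_id, a.residue_number)
        )
    assert len(resnames["SRO"]) == 6  # six serotonins
    assert len(resnames["ZN"]) == 2
    assert len(resnames["CL"]) == 2


def test_fixture_round_trip_preserves_coordinates(tmp_path, bare_hexamers):
    path = tmp_path / "t6.pdb"
    write_pdb(bare_hexamers["T6"], path)
    reread = read_structure(path)
    assert np.abs(reread.positions() - bare_hexamers["T6"].positions()).max() <= 1e-3


def test_fixture_spec_validation():
    with pytest.raises(ValueError):
        FixtureSpec(monomer_states=("T",) * 5)
    with pytest.raises(ValueError):
        FixtureSpec(monomer_states=("T",) * 5 + ("X",))
    with pytest.raises(ValueError):
        LigandPlacement("serotonin", "I", 0, anchors={"oh": 5.0})
    with pytest.raises(ValueError):
        LigandPlacement("serotonin", "II", 0)


# ---------------------------------------------------------------------------
# umbrella sampling emulation


def test_flat_pmf_window_is_gaussian_with_rt_over_k_sigma():
    spec = PMFSpec(form="table", table=(np.array([-50.0, 50.0]), np.zeros(2)))
    k = 8.0
    ws = sample_umbrella_windows(spec, [0.0], spring_k=k, n_per_window=100_000, seed=1)
    s = ws.windows[0].samples
    expected = math.sqrt(rt(spec.temperature) / k)
    assert s.std() == pytest.approx(expected, rel=0.02)
    assert s.mean() == pytest.approx(0.0, abs=3 * expected / math.sqrt(s.size))


def test_harmonic_pmf_plus_spring_combines_variances():
    a, k = 3.0, 7.0
    spec = PMFSpec(form="harmonic", curvature=a, center=0.0)
    ws = sample_umbrella_windows(spec, [0.0], spring_k=k, n_per_window=100_000, seed=2)
    expected = math.sqrt(rt(spec.temperature) / (a + k))
    assert ws.windows[0].samples.std() == pytest.approx(expected, rel=0.02)


def test_umbrella_argument_validation():
    spec = PMFSpec(form="harmonic", curvature=1.0)
    with pytest.raises(ValueError):
        sample_umbrella_windows(spec, [0.0], spring_k=5.0, n_per_window=0)
    flat = PMFSpec(form="table", table=(np.array([-50.0, 50.0]), np.zeros(2)))
    with pytest.raises(ValueError, match="confine"):
        sample_umbrella_windows(flat, [0.0], spring_k=1e-6, n_per_window=10)


# ---------------------------------------------------------------------------
# TI series and bound clouds


@pytest.mark.parametrize(
    "a,b,c,expected",
    [
        (-4.49, 0.0, 0.0, -4.49),
        (0.0, 2.0, 0.0, 1.0),
        (0.0, 0.0, 1.0, 2.0 / math.pi),
    ],
)
def test_ti_series_analytic_integral(a, b, c, expected):
    series, analytic = make_ti_series(a=a, b=b, c=c, n_lambda=21)
    assert analytic == pytest.approx(expected, abs=1e-12)
    assert series.lambdas[0] == 0.0 and series.lambdas[-1] == 1.0


def test_noise_free_titration_lies_on_model():
    from hexbind.titration import hill_model

    conc = np.geomspace(0.05, 10, 12)
    series = make_titration(0.86, 0.17, 2.22, conc, noise_sd=0.0)[0]
    assert np.allclose(series.delta_a, hill_model(conc, 0.86, 0.17, 2.22))


def test_bound_positions_validation():
    with pytest.raises(ValueError):
        sample_bound_positions(np.zeros((3, 3)), 100)
    with pytest.raises(ValueError):
        sample_bound_positions(np.eye(2), 100)
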