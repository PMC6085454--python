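"""Electron/element balance composition and CO partitioning."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carboxyfe.redox_balance import (BalanceError, BruttoEquation,
                                     NoDistinctPhasesError, PhaseSummary,
                                     breakpoint_from_eh, check_balance,
                                     co_partition, compose_brutto,
                                     detect_breakpoint, h2_from_ledger,
                                     partition_from_timeseries)
from carboxyfe.timeseries import CultureTimeseries


@pytest.mark.parametrize(
    "L,F,H,expected",
    [
        # iron-reducing phase: 1 lactate, 30 Fe(III), 17 H2 -> 30 CO
        (1, 30, 17, dict(CO=30, H2O=31, CO2=31, Fe2=30, Hplus=30, H2=17)),
        # hydrogenogenic phase: 1 lactate, 10 Fe(III), 267 H2 -> 270 CO
        (1, 10, 267, dict(CO=270, H2O=271, CO2=271, Fe2=10, Hplus=10, H2=267)),
        # pure hydrogenogenic carboxydotrophy: CO + H2O -> CO2 + H2
        (0, 0, 1, dict(CO=1, H2O=1, CO2=1, Fe2=0, Hplus=0, H2=1)),
    ],
)
def test_compose_brutto_canonical_phases(L, F, H, expected):
    b = compose_brutto(PhaseSummary(L, F, H))
    for species, coefficient in expected.items():
        assert b.coefficient(species) == coefficient
    assert all(r == 0 for r in check_balance(b).values())


@pytest.mark.parametrize(
    "L,F,H,co_fe,co_h2,fraction",
    [
        (1, 30, 17, 13, 17, 13 / 30),    # "13:17, about 43%"
        (1, 10, 267, 3, 267, 3 / 270),   # 3 moles of 270, about 1%
        (0, 0, 5, 0, 5, 0.0),            # no iron at all
    ],
)
def test_co_partition(L, F, H, co_fe, co_h2, fraction):
    part = co_partition(compose_brutto(PhaseSummary(L, F, H)))
    assert part.co_to_fe == co_fe
    assert part.co_to_h2 == co_h2
    assert part.fraction_fe == pytest.approx(fraction)


def test_partition_undefined_without_co():
    # lactate electrons fully absorbed by iron, no CO consumed at all
    b = compose_brutto(PhaseSummary(1, 4, 0))
    assert b.CO == 0
    part = co_partition(b)
    assert part.empty and part.fraction_fe is None


def test_check_balance_flags_deliberate_imbalance():
    b = compose_brutto(PhaseSummary(1, 30, 17))
    # hand element count for the balanced case, e.g. H: 5 + 62 = 3 + 30 + 34
    assert all(r == 0 for r in check_balance(b).values())
    from dataclasses import replace
    broken = replace(b, H2=Fraction(18))
    residuals = check_balance(broken)
    assert residuals["H"] == 2 and residuals["C"] == 0
    assert residuals["charge"] == 0  # H2 is neutral: only H goes off


@pytest.mark.parametrize("L,CO,F,expected", [(1, 30, 30, 17), (1, 270, 10, 267)])
def test_h2_from_electron_ledger(L, CO, F, expected):
    assert h2_from_ledger(L, CO, F) == expected


def test_validation_errors():
    with pytest.raises(BalanceError, match="donor electron excess"):
        compose_brutto(PhaseSummary(2, 4, 1))
    with pytest.raises(BalanceError):
        PhaseSummary(-1, 0, 1)
    with pytest.raises(BalanceError):
        PhaseSummary(0, 0, 0)


@given(
    L=st.integers(0, 50),
    extra_fe=st.integers(0, 500),
    H=st.integers(0, 500),
)
@settings(max_examples=200, deadline=None)
def test_composition_conserves_elements_and_electrons(L, extra_fe, H):
    """Any feasible phase yields a fully balanced equation satisfying the
    electron ledger 4L + 2CO = F + 2H2."""
    F = 4 * L + extra_fe
    if L == F == H == 0:
        return
    b = compose_brutto(PhaseSummary(L, F, H))
    assert all(r == 0 for r in check_balance(b).values())
    assert 4 * b.lactate + 2 * b.CO == b.Fe3 + 2 * b.H2
    part = co_partition(b)
    if not part.empty:
        assert 0.0 <= part.fraction_fe <= 1.0


def test_fraction_fe_strictly_decreases_with_h2():
    fractions = [co_partition(compose_brutto(PhaseSummary(1, 30, h))).fraction_fe
                 for h in (5, 10, 20, 40)]
    assert all(a > b for a, b in zip(fractions, fractions[1:]))


# --- time-series interface -------------------------------------------------


def test_ferrihydrite_partition_recovery(ferrihydrite_ts):
    """The analyzer recovers the simulator's configured phase partitions
    from the trajectory alone (noise-free, phase split at the Eh switch)."""
    bp = breakpoint_from_eh(ferrihydrite_ts, -320.0)
    parts = partition_from_timeseries(ferrihydrite_ts, [bp])
    assert len(parts) == 2
    truth1 = ferrihydrite_ts.meta["phase1_partition"]
    truth2 = ferrihydrite_ts.meta["phase2_partition"]
    assert parts[0].fraction_fe == pytest.approx(truth1, rel=0.05)
    assert parts[1].fraction_fe == pytest.approx(truth2, rel=0.05)


def test_glauconite_all_phases_lactate_free(glauconite_ts):
    """Without acetate production L = 0 in every phase: co_to_fe is exactly
    half the Fe(II) increment (all non-H2 CO electrons assigned to iron)."""
    t = glauconite_ts.time
    mid = float(t[len(t) // 2])
    fe2 = glauconite_ts.column("Fe2_mM")
    edges = [float(t[0]), mid, float(t[-1])]
    parts = partition_from_timeseries(glauconite_ts, [mid])
    assert len(parts) == 2
    for part, (t0, t1) in zip(parts, zip(edges[:-1], edges[1:])):
        d_fe = (glauconite_ts.value_at("Fe2_mM", t1)
                - glauconite_ts.value_at("Fe2_mM", t0))
        assert float(part.co_to_fe) == pytest.approx(d_fe / 2, rel=1e-6)


def test_single_phase_without_breakpoints(ferrihydrite_ts):
    parts = partition_from_timeseries(ferrihydrite_ts, [])
    assert len(parts) == 1
    assert 0.0 < parts[0].fraction_fe < 1.0


def test_inactive_phase_skipped_with_warning():
    df = pd.DataFrame({
        "time_h": [0.0, 1, 2, 3, 4, 5],
        "acetate_mM": [0.0, 1, 2, 2, 2, 2],
        "Fe2_mM": [0.0, 5, 10, 10, 10, 10],
        "H2_mmol": [0.0, 1, 2, 2, 2, 2],
    })
    ts = CultureTimeseries(df)
    with pytest.warns(UserWarning, match="no metabolic activity"):
        parts = partition_from_timeseries(ts, [2.0])
    assert len(parts) == 1


# --- breakpoint detection --------------------------------------------------


def _two_slope(t, knee, s1, s2, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.where(t <= knee, s1 * t, s1 * knee + s2 * (t - knee))
    return CultureTimeseries(pd.DataFrame({
        "time_h": t, "Fe2_mM": y + noise * rng.standard_normal(len(t))}))


def test_detect_breakpoint_matches_exhaustive_oracle():
    t = np.arange(0.0, 49.0, 2.0)
    ts = _two_slope(t, knee=24.0, s1=1.0, s2=0.1)
    found = detect_breakpoint(ts)
    # independent oracle: brute-force hinge regression over every interior knot
    y = ts.column("Fe2_mM")
    best = min(
        (float(np.sum((y - np.column_stack(
            [np.ones_like(t), t, np.maximum(t - t[k], 0)]) @ np.linalg.lstsq(
            np.column_stack([np.ones_like(t), t, np.maximum(t - t[k], 0)]),
            y, rcond=None)[0]) ** 2)), float(t[k]))
        for k in range(2, len(t) - 2))
    assert found == best[1]
    assert abs(found - 24.0) <= 2.0  # within one sampling interval


def test_detect_breakpoint_linear_curve_has_no_phases():
    t = np.arange(0.0, 30.0, 2.0)
    ts = _two_slope(t, knee=15.0, s1=1.0, s2=1.0)  # same slope: a line
    with pytest.raises(NoDistinctPhasesError):
        detect_breakpoint(ts)


def test_detect_breakpoint_stable_under_noise():
    t = np.arange(0.0, 49.0, 2.0)
    found = [detect_breakpoint(_two_slope(t, 24.0, 1.0, 0.1,
                                          noise=0.5, seed=s))
             for s in (1, 2, 3)]
    assert all(abs(f - 24.0) <= 4.0 for f in found)  # within two intervals


def test_detect_breakpoint_needs_six_points():
    t = np.arange(0.0, 10.0, 2.0)
    with pytest.raises(ValueError, match="6 time points"):
        detect_breakpoint(_two_slope(t, 4.0, 1.0, 0.1))
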