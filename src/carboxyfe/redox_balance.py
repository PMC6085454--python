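"""Electron-balance composition of growth-phase brutto-equations.

A culture oxidizing lactate and CO while reducing Fe(III) runs three
catabolic half-processes in parallel:

* lactate -> acetate, donating 4 electrons per mole,
* CO + H2O -> CO2, donating 2 electrons per mole, and
* either Fe3+ -> Fe2+ (1 electron per Fe) or 2 H+ -> H2 (2 electrons per H2)
  on the accepting side.

Given a growth phase's net metabolite changes — lactate catabolized ``L``
(measured as acetate formed, since assimilated lactate carries no catabolic
electrons), Fe(III) reduced ``F`` and H2 produced ``H`` — the electron ledger

    4 L + 2 CO = F + 2 H

fixes the CO consumption ``CO = (F - 4 L) / 2 + H`` and hence the whole
balanced overall equation

    L C3H5O3- + CO CO + (CO + L) H2O + F Fe3+
        -> L C2H3O2- + (CO + L) CO2 + F Fe2+ + F H+ + H H2

from which the partition of consumed CO between iron reduction and
hydrogenogenesis follows directly.  All coefficients are kept as exact
rationals; the canonical examples (a 30:1 CO:lactate iron-reducing phase and
a 270:1 hydrogenogenic phase) are integer-exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .timeseries import CultureTimeseries

Rational = Union[int, Fraction]


class BalanceError(ValueError):
    """Raised when a phase summary cannot be balanced."""


class NoDistinctPhasesError(ValueError):
    """Raised when a trajectory shows no two-slope structure."""


# --- species composition: element counts and charge -----------------------

_SPECIES = {
    # name: (C, H, O, Fe, charge)
    "lactate": (3, 5, 3, 0, -1),
    "CO": (1, 0, 1, 0, 0),
    "H2O": (0, 2, 1, 0, 0),
    "Fe3": (0, 0, 0, 1, +3),
    "acetate": (2, 3, 2, 0, -1),
    "CO2": (1, 0, 2, 0, 0),
    "Fe2": (0, 0, 0, 1, +2),
    "Hplus": (0, 1, 0, 0, +1),
    "H2": (0, 2, 0, 0, 0),
}
_REACTANTS = ("lactate", "CO", "H2O", "Fe3")
_PRODUCTS = ("acetate", "CO2", "Fe2", "Hplus", "H2")
_ELEMENTS = ("C", "H", "O", "Fe", "charge")


@dataclass(frozen=True)
class HalfReaction:
    """A catabolic half-reaction and the electrons it moves per mole."""

    id: str
    electrons_per_mole: int
    role: str  # "donor" | "acceptor"
    description: str = ""

    def __post_init__(self) -> None:
        if self.electrons_per_mole <= 0:
            raise ValueError("electrons_per_mole must be positive")
        if self.role not in ("donor", "acceptor"):
            raise ValueError("role must be 'donor' or 'acceptor'")


#: The registry of half-reactions the balance rests on.
HALF_REACTIONS = {
    r.id: r
    for r in (
        HalfReaction("lactate_to_acetate", 4, "donor",
                     "C3H5O3- + H2O -> C2H3O2- + CO2 + 4e- + 4H+"),
        HalfReaction("co_oxidation", 2, "donor", "CO + H2O -> CO2 + 2e- + 2H+"),
        HalfReaction("fe3_reduction", 1, "acceptor", "Fe3+ + e- -> Fe2+"),
        HalfReaction("hydrogenogenesis", 2, "acceptor", "2H+ + 2e- -> H2"),
    )
}


@dataclass(frozen=True)
class PhaseSummary:
    """Net metabolite changes of one growth phase, in moles (or mmol).

    ``lactate_catabolized`` is taken equal to acetate formed: the organism
    assimilates roughly half of the consumed lactate as carbon source, and
    only the acetate-forming half donates catabolic electrons.
    """

    lactate_catabolized: Rational
    fe_reduced: Rational
    h2_produced: Rational
    phase_label: str = ""

    def __post_init__(self) -> None:
        L, F, H = (Fraction(self.lactate_catabolized),
                   Fraction(self.fe_reduced), Fraction(self.h2_produced))
        if min(L, F, H) < 0:
            raise BalanceError("phase summary quantities must be non-negative")
        if L == F == H == 0:
            raise BalanceError("phase summary is all zero")
        object.__setattr__(self, "lactate_catabolized", L)
        object.__setattr__(self, "fe_reduced", F)
        object.__setattr__(self, "h2_produced", H)


@dataclass(frozen=True)
class BruttoEquation:
    """Exact-rational coefficients of the composed overall reaction."""

    lactate: Fraction
    CO: Fraction
    H2O: Fraction
    Fe3: Fraction
    acetate: Fraction
    CO2: Fraction
    Fe2: Fraction
    Hplus: Fraction
    H2: Fraction

    def coefficient(self, species: str) -> Fraction:
        return getattr(self, species)

    def as_dict(self) -> dict:
        return {s: self.coefficient(s) for s in _REACTANTS + _PRODUCTS}

    def __str__(self) -> str:
        pretty = {"lactate": "C3H5O3-", "Fe3": "Fe3+", "acetate": "C2H3O2-",
                  "Fe2": "Fe2+", "Hplus": "H+"}

        def side(names: Sequence[str]) -> str:
            terms = []
            for n in names:
                c = self.coefficient(n)
                if c == 0:
                    continue
                if c == 1:
                    coef = ""
                elif c.denominator == 1:
                    coef = f"{c} "
                else:  # exact internally, rounded for display only
                    coef = f"{float(c):.4g} "
                terms.append(f"{coef}{pretty.get(n, n)}")
            return " + ".join(terms) or "0"

        return f"{side(_REACTANTS)} -> {side(_PRODUCTS)}"


@dataclass(frozen=True)
class PartitionResult:
    """How the consumed CO splits between Fe(III) reduction and H2 production."""

    co_to_fe: Fraction
    co_to_h2: Fraction
    phase_label: str = ""
    empty: bool = False  # True when no CO was consumed (fraction undefined)

    @property
    def fraction_fe(self) -> Optional[float]:
        if self.empty:
            return None
        total = self.co_to_fe + self.co_to_h2
        return float(self.co_to_fe / total)


def compose_brutto(phase: PhaseSummary) -> BruttoEquation:
    """Compose the balanced overall equation for one growth phase.

    Raises :class:`BalanceError` if the lactate electrons alone exceed what
    the reduced iron can absorb (``F < 4 L`` with ``L > 0``): the ledger
    would then demand negative CO consumption.
    """
    L, F, H = phase.lactate_catabolized, phase.fe_reduced, phase.h2_produced
    if L > 0 and F < 4 * L:
        raise BalanceError(
            f"donor electron excess: 4*L = {4 * L} electrons from lactate but "
            f"only {F} Fe(III) to absorb them")
    co = (F - 4 * L) / 2 + H
    return BruttoEquation(
        lactate=L, CO=co, H2O=co + L, Fe3=F,
        acetate=L, CO2=co + L, Fe2=F, Hplus=F, H2=H,
    )


def co_partition(b: BruttoEquation) -> PartitionResult:
    """Split the CO coefficient into its Fe(III)-reducing and H2-producing parts."""
    co_to_fe = (b.Fe3 - 4 * b.lactate) / 2
    co_to_h2 = b.H2
    if b.CO == 0:
        return PartitionResult(Fraction(0), Fraction(0), empty=True)
    return PartitionResult(co_to_fe, co_to_h2)


def check_balance(b: BruttoEquation) -> dict:
    """Per-element and charge residuals (products minus reactants).

    All residuals are exactly zero for any :func:`compose_brutto` output;
    nonzero entries locate a deliberate or accidental imbalance.
    """
    residuals = {}
    for i, element in enumerate(_ELEMENTS):
        total = Fraction(0)
        for name in _PRODUCTS:
            total += b.coefficient(name) * _SPECIES[name][i]
        for name in _REACTANTS:
            total -= b.coefficient(name) * _SPECIES[name][i]
        residuals[element] = total
    return residuals


def h2_from_ledger(lactate: Rational, co: Rational, fe: Rational) -> Fraction:
    """Solve the electron ledger 4 L + 2 CO = F + 2 H2 for the H2 coefficient."""
    L, CO, F = Fraction(lactate), Fraction(co), Fraction(fe)
    h2 = (4 * L + 2 * CO - F) / 2
    if h2 < 0:
        raise BalanceError("electron ledger gives negative H2")
    return h2


# --- time-series interface -------------------------------------------------


def _phase_delta(ts: CultureTimeseries, column: str, t0: float, t1: float) -> Fraction:
    if not ts.has(column):
        return Fraction(0)
    d = ts.value_at(column, t1) - ts.value_at(column, t0)
    return Fraction(d).limit_denominator(10**9)


def partition_from_timeseries(
    ts: CultureTimeseries,
    breakpoints: Iterable[float] = (),
) -> list[PartitionResult]:
    """Per-phase CO partitions from a culture trajectory.

    Phases are the intervals between consecutive breakpoints (hours), padded
    with the trajectory's first and last time.  Per phase, lactate
    catabolized is read as acetate produced (zero when the acetate column is
    absent or flat, the glauconite case: all non-H2 CO electrons then go to
    iron), Fe(III) reduced as the Fe2+ increment and H2 produced as the H2
    increment.  A phase with no activity is skipped with a warning.
    """
    t = ts.time
    edges = [float(t[0])] + sorted(float(b) for b in breakpoints) + [float(t[-1])]
    for b in edges[1:-1]:
        if not (t[0] <= b <= t[-1]):
            raise ValueError(f"breakpoint {b} outside time range")
    results: list[PartitionResult] = []
    for i, (t0, t1) in enumerate(zip(edges[:-1], edges[1:]), start=1):
        label = f"phase-{i} [{t0:g}h, {t1:g}h]"
        L = max(_phase_delta(ts, "acetate_mM", t0, t1), Fraction(0))
        F = max(_phase_delta(ts, "Fe2_mM", t0, t1), Fraction(0))
        H = max(_phase_delta(ts, "H2_mmol", t0, t1), Fraction(0))
        if L == F == H == 0:
            warnings.warn(f"{label}: no metabolic activity, skipped")
            continue
        try:
            b = compose_brutto(PhaseSummary(L, F, H, phase_label=label))
        except BalanceError as err:
            warnings.warn(f"{label}: {err}; treating lactate as assimilated only")
            b = compose_brutto(PhaseSummary(0, F, H, phase_label=label))
        part = co_partition(b)
        results.append(PartitionResult(part.co_to_fe, part.co_to_h2,
                                       phase_label=label, empty=part.empty))
    return results


def detect_breakpoint(ts: CultureTimeseries, column: str = "Fe2_mM",
                      min_improvement: float = 0.05) -> float:
    """Knee of a two-segment piecewise-linear fit to the Fe(II) curve.

    Exhaustively tries every interior sample time as the knot of a continuous
    hinge fit and returns the time minimizing total squared error.  If the
    best hinge improves on a single straight line by less than
    ``min_improvement`` (relative SSE), the curve has no distinct phases and
    :class:`NoDistinctPhasesError` is raised.
    """
    if len(ts) < 6:
        raise ValueError("breakpoint detection needs at least 6 time points")
    if not ts.has(column):
        raise ValueError(f"no {column!r} column")
    t, y = ts.time, ts.column(column)

    def sse(design: np.ndarray) -> float:
        beta, res, *_ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ beta
        return float(np.sum((y - fitted) ** 2))

    base = sse(np.column_stack([np.ones_like(t), t]))
    best_sse, best_t = np.inf, None
    for k in range(2, len(t) - 2):
        hinge = np.maximum(t - t[k], 0.0)
        s = sse(np.column_stack([np.ones_like(t), t, hinge]))
        if s < best_sse:
            best_sse, best_t = s, float(t[k])
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if base <= 1e-10 * max(ss_total, 1e-30):  # already a perfect line
        raise NoDistinctPhasesError(
            "no distinct phases: Fe(II) curve is a single straight line")
    if (base - best_sse) / base < min_improvement:
        raise NoDistinctPhasesError(
            "no distinct phases: two-segment fit does not improve on a line")
    return best_t


def breakpoint_from_eh(ts: CultureTimeseries, threshold_mV: float) -> float:
    """First time the medium redox potential crosses below a threshold.

    The physiological phase switch (Fe(III) reduction giving way to
    hydrogenogenesis) is gated by redox potential, so when an Eh trace is
    available its threshold crossing is the natural phase boundary.
    Linearly interpolated between samples; raises if Eh never crosses.
    """
    if not ts.has("Eh_mV"):
        raise ValueError("no Eh_mV column")
    t, eh = ts.time, ts.column("Eh_mV")
    below = np.nonzero(eh < threshold_mV)[0]
    if len(below) == 0 or below[0] == 0:
        raise NoDistinctPhasesError(
            f"Eh never crosses {threshold_mV} mV (or starts below it)")
    i = below[0]
    frac = (threshold_mV - eh[i - 1]) / (eh[i] - eh[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def balance_report(ts: CultureTimeseries,
                   breakpoints: Iterable[float] = ()) -> dict:
    """JSON-ready report: per-phase brutto coefficients, partitions, residuals."""
    t = ts.time
    edges = [float(t[0])] + sorted(float(b) for b in breakpoints) + [float(t[-1])]
    phases = []
    for part, (t0, t1) in zip(partition_from_timeseries(ts, breakpoints),
                              zip(edges[:-1], edges[1:])):
        L = max(_phase_delta(ts, "acetate_mM", t0, t1), Fraction(0))
        F = max(_phase_delta(ts, "Fe2_mM", t0, t1), Fraction(0))
        H = max(_phase_delta(ts, "H2_mmol", t0, t1), Fraction(0))
        if L > 0 and F < 4 * L:
            L = Fraction(0)
        b = compose_brutto(PhaseSummary(L, F, H))
        phases.append({
            "phase": part.phase_label,
            "coefficients": {k: float(v) for k, v in b.as_dict().items()},
            "equation": str(b),
            "residuals": {k: float(v) for k, v in check_balance(b).items()},
            "co_to_fe": float(part.co_to_fe),
            "co_to_h2": float(part.co_to_h2),
            "fraction_fe": part.fraction_fe,
        })
    return {"label": ts.label, "phases": phases}
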