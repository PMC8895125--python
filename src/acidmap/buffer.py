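"""Buffer-capacity chemistry for droplet-based tissue pH transfer.

Buffer capacity beta is the strong-base (or acid) increment, in
milliequivalents per litre, needed to move one litre of solution by one pH
unit. The closed form is the Van Slyke expression

    beta = 2.303 * ([H+] + [OH-] + sum_i C_i * Ka_i * [H+] / (Ka_i + [H+])^2)

with one term per ionization step (steps treated independently, valid for
well-separated pKa values) and the water autoprotolysis terms. An
independent titration oracle recovers beta by adding a small strong-base
increment and root-finding the new pH from the full charge balance.

The droplet-equilibration model captures the observable behavior of
water-droplet tissue sampling: a pure-water droplet (pH 7 once CO2-free)
pulled toward the tissue pH with a strength growing in the tissue's buffer
capacity. It is a one-parameter saturating mix, not a transport simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .exceptions import NumericError

LN10 = np.log(10.0)


@dataclass(frozen=True)
class BufferSpecies:
    """One weak acid: total concentration (mol/L) and its Ka values."""

    name: str
    conc: float
    kas: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError("concentration must be nonnegative")
        if any(k <= 0 for k in self.kas) or list(self.kas) != sorted(self.kas, reverse=True):
            raise ValueError("Ka values must be positive and strictly decreasing")


@dataclass(frozen=True)
class BufferSystem:
    """A set of weak-acid species in water (ion product ``kw``, 25 C default)."""

    species: tuple[BufferSpecies, ...] = ()
    kw: float = 1e-14

    def scaled(self, factor: float) -> "BufferSystem":
        """The system diluted ``factor``-fold (water unchanged)."""
        return BufferSystem(
            tuple(
                BufferSpecies(s.name, s.conc / factor, s.kas) for s in self.species
            ),
            kw=self.kw,
        )


#: dissolved CO2 in water exposed to the normal atmosphere (~0.012 mM)
CARBONIC = BufferSpecies("carbonic", 1.2e-5, (4.45e-7, 4.69e-11))
PHOSPHORIC = BufferSpecies("phosphoric", 0.0, (7.11e-3, 6.32e-8, 4.49e-13))
CITRIC = BufferSpecies("citric", 0.0, (7.45e-4, 1.73e-5, 4.02e-7))

SPECIES_TABLE = {
    "carbonic": CARBONIC,
    "phosphoric": PHOSPHORIC,
    "citric": CITRIC,
}


def species_beta_term(species: BufferSpecies, ph: float) -> float:
    """Van Slyke contribution of one species at ``ph`` (mEq/L/pH)."""
    h = 10.0 ** (-ph)
    term = sum(species.conc * ka * h / (ka + h) ** 2 for ka in species.kas)
    return LN10 * term * 1000.0


def beta_closed_form(
    system: BufferSystem, ph: float, include_water: bool = True
) -> float:
    """Closed-form buffer capacity at ``ph`` in mEq/L/pH.

    ``include_water=False`` returns only the weak-acid species contribution
    (the quantity relevant when judging whether a dilute buffer interferes
    with a measurement, since the water terms are common to every sample).
    """
    h = 10.0 ** (-ph)
    beta = sum(species_beta_term(s, ph) for s in system.species)
    if include_water:
        beta += LN10 * (h + system.kw / h) * 1000.0
    return beta


def _mean_deprotonation(species: BufferSpecies, h: float) -> float:
    """Average number of protons released per molecule at [H+] = h."""
    weights = [1.0]
    for ka in species.kas:
        weights.append(weights[-1] * ka / h)
    weights = np.array(weights)
    return float(np.sum(np.arange(len(weights)) * weights) / np.sum(weights))


def _base_for_ph(system: BufferSystem, ph: float) -> float:
    """Strong-base concentration (mol/L) fixing the system at ``ph``.

    From the charge balance Cb + [H+] = [OH-] + sum C * nbar, where nbar is
    the mean deprotonation of each species. Negative values mean strong
    acid is required.
    """
    h = 10.0 ** (-ph)
    return system.kw / h - h + sum(
        s.conc * _mean_deprotonation(s, h) for s in system.species
    )


def _ph_for_base(system: BufferSystem, cb: float) -> float:
    """Invert the titration function (monotone in pH) by root-finding."""
    f = lambda ph: _base_for_ph(system, ph) - cb
    try:
        return brentq(f, 0.0, 14.0, xtol=1e-12, rtol=8.9e-16)
    except ValueError as exc:
        raise NumericError(f"titration root-finding failed: {exc}") from exc


def beta_numeric(system: BufferSystem, ph: float, dc: float = 1e-9) -> float:
    """Finite-difference titration oracle for the buffer capacity (mEq/L/pH).

    Adds/removes a strong-base increment ``dc`` (mol/L) and measures the pH
    response through the full charge balance; central difference.
    """
    cb0 = _base_for_ph(system, ph)
    ph_up = _ph_for_base(system, cb0 + dc)
    ph_dn = _ph_for_base(system, cb0 - dc)
    if ph_up <= ph_dn:
        raise NumericError("titration response not monotone")
    return 2.0 * dc / (ph_up - ph_dn) * 1000.0


def dilution_series(
    system: BufferSystem,
    factors: tuple[float, ...] = (2.0, 3.0, 10.0, 20.0),
    ph: float = 7.4,
    include_water: bool = True,
) -> list[float]:
    """Buffer capacity of the system after each dilution factor, at ``ph``.

    Species terms scale ~1/factor; the water terms do not, so strong
    dilutions fall above the linear-scaling prediction.
    """
    if any(f < 1 for f in factors):
        raise ValueError("dilution factors must be >= 1")
    return [
        beta_closed_form(system.scaled(f), ph, include_water=include_water)
        for f in factors
    ]


#: droplet mixing strength calibrated so that a tissue of buffer capacity
#: 2.8 mEq/L/pH read at pH 6.0 stays within 0.22 pH units of truth
DROPLET_K = 0.78
WATER_PH = 7.0  # newly boiled (CO2-free) ultrapure water


def droplet_equilibration(
    tissue_ph: float | np.ndarray,
    beta_t: float | np.ndarray,
    k: float = DROPLET_K,
    ph_water: float = WATER_PH,
):
    """pH of the sampling droplet after contact with tissue.

    Saturating mix: droplet = tissue + (water - tissue) * k / (k + beta_t).
    Unbuffered tissue (beta_t = 0) returns the water pH; infinitely buffered
    tissue returns its own pH exactly; the error decreases monotonically in
    beta_t.
    """
    beta_t = np.asarray(beta_t, dtype=float)
    if np.any(beta_t < 0):
        raise ValueError("beta_t must be nonnegative")
    tissue_ph = np.asarray(tissue_ph, dtype=float)
    out = tissue_ph + (ph_water - tissue_ph) * k / (k + beta_t)
    return float(out) if out.ndim == 0 else out
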