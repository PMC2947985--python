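"""Two-state (telegraph) gene model: rate constants, burst coordinates, regimes.

The gene switches between a repressed state and an active state that
transcribes at rate ``kappa_t_plus``.  Transcripts are translated into protein
and both species decay first-order.  All rates are expressed in units of the
transcript degradation rate ``kappa_t_minus`` (identically 1), because
steady-state distribution shapes depend only on rate ratios; conversion from
absolute units (per hour) happens only at I/O.

Coordinates
-----------
The fit-relevant parameterisation is the *burst coordinates*:

* burst size      ``b   = kappa_t_plus / kappa_r``  (transcripts per activation)
* burst frequency ``kappa_a``                       (activations per transcript lifetime)
* active duration ``tau = 1 / kappa_r``             (active-state lifetime, transcript lifetimes)

and the *active fraction* ``f = kappa_a * tau / (1 + kappa_a * tau)``, the
steady-state probability of finding the promoter in the active state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "RateConstants",
    "BurstCoordinates",
    "CalibrationConstants",
    "RegimeThresholds",
    "to_burst_coordinates",
    "from_burst_coordinates",
    "active_fraction",
    "classify_regime",
    "rates_to_config",
    "rates_from_config",
    "save_rates",
    "load_rates",
]

#: Default transcript degradation rate in absolute units, used only when
#: converting configs given in per-hour rates.  (~0.2 h^-1 for this system.)
DEFAULT_KAPPA_T_MINUS_PER_HOUR = 0.2


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class RateConstants:
    """Kinetic rates of the two-state model, normalized to kappa_t_minus = 1.

    Parameters
    ----------
    kappa_a : float
        Gene activation rate (repressed -> active).
    kappa_r : float
        Gene inactivation rate (active -> repressed).
    kappa_t_plus : float
        Transcription rate in the active state.
    kappa_p_plus : float
        Translation rate per transcript.
    kappa_p_minus : float
        Effective protein degradation/dilution rate; must be < 1 because
        protein decays slower than transcript in this system.
    """

    kappa_a: float
    kappa_r: float
    kappa_t_plus: float
    kappa_p_plus: float = 10.0
    kappa_p_minus: float = 0.25

    #: normalizing unit, identically one
    kappa_t_minus: float = field(default=1.0, init=False, repr=False)

    def __post_init__(self) -> None:
        _require_positive(
            kappa_a=self.kappa_a,
            kappa_r=self.kappa_r,
            kappa_t_plus=self.kappa_t_plus,
            kappa_p_plus=self.kappa_p_plus,
            kappa_p_minus=self.kappa_p_minus,
        )
        if self.kappa_p_minus >= 1.0:
            raise ValueError(
                "kappa_p_minus must be < 1 (protein decays slower than transcript); "
                f"got {self.kappa_p_minus}"
            )

    @property
    def active_fraction(self) -> float:
        """Steady-state probability of the active gene state."""
        return self.kappa_a / (self.kappa_a + self.kappa_r)

    def as_dict(self) -> dict[str, float]:
        return {
            "kappa_a": self.kappa_a,
            "kappa_r": self.kappa_r,
            "kappa_t_plus": self.kappa_t_plus,
            "kappa_p_plus": self.kappa_p_plus,
            "kappa_p_minus": self.kappa_p_minus,
        }

    def replace(self, **changes: float) -> "RateConstants":
        return replace(self, **changes)


@dataclass(frozen=True)
class BurstCoordinates:
    """Burst-coordinate parameterisation (b, kappa_a, tau)."""

    b: float
    kappa_a: float
    tau: float

    def __post_init__(self) -> None:
        _require_positive(b=self.b, kappa_a=self.kappa_a, tau=self.tau)

    @property
    def kappa_r(self) -> float:
        return 1.0 / self.tau

    @property
    def kappa_t_plus(self) -> float:
        return self.b / self.tau

    @property
    def active_fraction(self) -> float:
        return active_fraction(self.kappa_a, self.tau)


@dataclass(frozen=True)
class CalibrationConstants:
    """Non-fit constants shared by all clones.

    ``gamma`` is the calibrated fluorescence yield per *mean transcript*
    (RFU/transcript, measured as a ratio of means).  ``kappa_p_minus`` is the
    protein dilution rate set by cell division (0.05 h^-1 / 0.2 h^-1 = 0.25 in
    transcript-degradation units).  ``kappa_p_plus`` only needs to be large
    enough that protein shot noise is negligible; the derived per-protein
    fluorescence ``nu = gamma * kappa_p_minus / kappa_p_plus`` co-varies with
    it so that predicted RFU histograms are invariant to its choice (up to
    protein-copy-number shot noise).
    """

    gamma: float = 2.5
    kappa_p_minus: float = 0.25
    kappa_p_plus: float = 10.0

    def __post_init__(self) -> None:
        _require_positive(
            gamma=self.gamma,
            kappa_p_minus=self.kappa_p_minus,
            kappa_p_plus=self.kappa_p_plus,
        )

    @property
    def nu(self) -> float:
        """RFU per protein molecule (derived)."""
        return self.gamma * self.kappa_p_minus / self.kappa_p_plus

    def with_kappa_p_plus(self, kappa_p_plus: float) -> "CalibrationConstants":
        """Rescale the translation rate; ``nu`` co-updates automatically."""
        return replace(self, kappa_p_plus=kappa_p_plus)

    def rates(self, coords: BurstCoordinates) -> RateConstants:
        """Full rate set for burst coordinates under this calibration."""
        return from_burst_coordinates(coords, self.kappa_p_plus, self.kappa_p_minus)


def to_burst_coordinates(rates: RateConstants) -> BurstCoordinates:
    """Map kinetic rates to burst coordinates (b, kappa_a, tau)."""
    return BurstCoordinates(
        b=rates.kappa_t_plus / rates.kappa_r,
        kappa_a=rates.kappa_a,
        tau=1.0 / rates.kappa_r,
    )


def from_burst_coordinates(
    coords: BurstCoordinates,
    kappa_p_plus: float = 10.0,
    kappa_p_minus: float = 0.25,
) -> RateConstants:
    """Inverse of :func:`to_burst_coordinates` given the fixed protein rates."""
    return RateConstants(
        kappa_a=coords.kappa_a,
        kappa_r=coords.kappa_r,
        kappa_t_plus=coords.kappa_t_plus,
        kappa_p_plus=kappa_p_plus,
        kappa_p_minus=kappa_p_minus,
    )


def active_fraction(kappa_a, tau):
    """Steady-state active-gene-state probability f = kappa_a*tau/(1+kappa_a*tau).

    Accepts scalars or arrays; ``tau`` may be zero (f = 0).  Monotone
    increasing in both arguments; always in [0, 1).
    """
    kappa_a = np.asarray(kappa_a, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(kappa_a <= 0) or np.any(tau < 0):
        raise ValueError("require kappa_a > 0 and tau >= 0")
    x = kappa_a * tau
    out = x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RegimeThresholds:
    """Order-of-magnitude thresholds separating qualitative model regimes."""

    fast: float = 10.0       # "much greater than 1" for gene-state rates
    slow: float = 0.1        # "much less than 1"
    bursting_kappa_r: float = 10.0
    bursting_b: float = 2.0  # burst size not small


def classify_regime(rates: RateConstants, thresholds: RegimeThresholds | None = None) -> str:
    """Classify parameters into 'Bursting', 'Fast', 'Slow' or 'Intermediate'.

    Bursting: fast inactivation (kappa_r >> 1) with a non-small burst size.
    Fast: both gene-state rates fast.  Slow: both slow (pulsatile/bimodal
    limit).  Everything else is Intermediate.
    """
    t = thresholds or RegimeThresholds()
    b = rates.kappa_t_plus / rates.kappa_r
    if rates.kappa_r >= t.bursting_kappa_r and b >= t.bursting_b:
        return "Bursting"
    if min(rates.kappa_a, rates.kappa_r) >= t.fast:
        return "Fast"
    if max(rates.kappa_a, rates.kappa_r) <= t.slow:
        return "Slow"
    return "Intermediate"


# ---------------------------------------------------------------------------
# Flat-config serialization

def rates_to_config(rates: RateConstants, calib: CalibrationConstants | None = None) -> dict:
    cfg = rates.as_dict()
    if calib is not None:
        cfg["gamma"] = calib.gamma
    return cfg


def rates_from_config(cfg: dict) -> tuple[RateConstants, CalibrationConstants]:
    """Parse a flat key-value config.

    Rates may be given either already normalized to kappa_t_minus = 1, or in
    absolute per-hour units together with ``kappa_t_minus_per_hour`` (default
    0.2), in which case every rate is divided by that normalizer.
    """
    cfg = dict(cfg)
    scale = 1.0
    if any(key.endswith("_per_hour") for key in cfg):
        norm = float(cfg.pop("kappa_t_minus_per_hour", DEFAULT_KAPPA_T_MINUS_PER_HOUR))
        scale = 1.0 / norm
        cfg = {key.removesuffix("_per_hour"): value for key, value in cfg.items()}
    gamma = float(cfg.pop("gamma", 2.5))
    rates = RateConstants(
        kappa_a=float(cfg["kappa_a"]) * scale,
        kappa_r=float(cfg["kappa_r"]) * scale,
        kappa_t_plus=float(cfg["kappa_t_plus"]) * scale,
        kappa_p_plus=float(cfg.get("kappa_p_plus", 10.0)) * scale,
        kappa_p_minus=float(cfg.get("kappa_p_minus", 0.25)) * scale,
    )
    calib = CalibrationConstants(
        gamma=gamma,
        kappa_p_minus=rates.kappa_p_minus,
        kappa_p_plus=rates.kappa_p_plus,
    )
    return rates, calib


def save_rates(path: str | Path, rates: RateConstants, calib: CalibrationConstants | None = None) -> None:
    path = Path(path)
    cfg = rates_to_config(rates, calib)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg))
    else:
        path.write_text(json.dumps(cfg, indent=2))


def load_rates(path: str | Path) -> tuple[RateConstants, CalibrationConstants]:
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return rates_from_config(cfg)
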