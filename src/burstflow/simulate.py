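"""Synthetic clonal cytometry data with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: ~31 clonal
populations of ~10^4 cells each, GFP fluorescence on a 4-decade log scale,
forward/side scatter on a linear 1-1024 channel, lognormal autofluorescence
background, a latent cell-size factor coupling GFP to FSC, and clone means
spanning roughly an order of magnitude.

Protein copy numbers are drawn either from the exact steady-state protein
marginal of the chemical master equation (inverse-CDF sampling of the
interpolated fine-grained PMF; default) or by exact stochastic simulation
(Gillespie), and the two paths are statistically indistinguishable.

Scenarios mirror the qualitative burst-modulation regimes: varying only the
burst frequency kappa_a (Poisson-like variance-mean scaling, slope 1),
varying only the burst size b (distribution scaling, slope 2), or the
combined modulation b = c * kappa_a^2 (slope 5/3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cme
from .moments import analytic_moments
from .params import BurstCoordinates, CalibrationConstants, RateConstants

__all__ = [
    "ScenarioSpec",
    "SyntheticClone",
    "SIM_SOLVER_OPTIONS",
    "scenario_coordinates",
    "simulate_clone",
    "simulate_clone_ssa",
    "generate_autofluorescence",
    "generate_ensemble",
    "ensemble_moments",
    "write_ensemble",
]

#: solver settings for fixture generation: accurate enough that sampling
#: noise at 10^4 events dominates any discretisation error
SIM_SOLVER_OPTIONS = cme.SolverOptions(
    method="adi", growth=1.06, fine_cap=384, boundary_tol=1e-6, n_sd=8.0,
    residual_tol=1e-8,
)

#: translation rate used inside the solver when generating events; the
#: per-protein fluorescence nu co-updates so RFU output is invariant to this
#: choice up to protein shot noise, while keeping the state space desk-scale
SOLVER_KAPPA_P_PLUS = 2.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Generation scenario for a clonal ensemble.

    ``scenario`` is one of 'frequency_only', 'size_only', 'combined'.
    Ranges follow the observed spread of fitted parameters: burst sizes from
    a few to tens of transcripts, burst frequencies scattered around one
    burst per several transcript lifetimes, short active durations.
    """

    scenario: str = "combined"
    n_clones: int = 31
    kappa_a_range: tuple = (0.1, 3.0)
    b_range: tuple = (2.0, 50.0)
    b_fixed: float = 15.0
    kappa_a_fixed: float = 0.3
    tau: float = 0.02
    calib: CalibrationConstants = field(default_factory=CalibrationConstants)
    n_events: int = 10_000
    autofluor_mean: float = 5.0
    autofluor_cv: float = 0.5
    size_coupling: float = 0.5   # eta: GFP ~ nu * protein * s^eta
    size_cv: float = 0.25        # lognormal sigma of the latent size factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("frequency_only", "size_only", "combined"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("kappa_a_range", "b_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must be an increasing positive pair")


@dataclass(frozen=True)
class SyntheticClone:
    """Event table plus the ground truth that generated it."""

    events: pd.DataFrame
    rates: RateConstants
    coords: BurstCoordinates
    calib: CalibrationConstants
    scenario: str
    seed: int
    clone_id: str = ""

    @property
    def ground_truth(self) -> dict:
        return {
            "clone_id": self.clone_id,
            "b": self.coords.b,
            "kappa_a": self.coords.kappa_a,
            "tau": self.coords.tau,
            "scenario": self.scenario,
            "seed": self.seed,
            **{f"rate_{k}": v for k, v in self.rates.as_dict().items()},
        }


def scenario_coordinates(spec: ScenarioSpec, rng: np.random.Generator) -> list[BurstCoordinates]:
    """Draw per-clone burst coordinates for a scenario.

    combined: b = c * kappa_a^2 with the kappa_a range derived from the
    b range (ratio sqrt(b_max/b_min) below the configured upper end) so the
    burst sizes span exactly ``b_range``.
    """
    n = spec.n_clones
    if spec.scenario == "frequency_only":
        ka = np.exp(rng.uniform(*np.log(spec.kappa_a_range), size=n))
        b = np.full(n, spec.b_fixed)
    elif spec.scenario == "size_only":
        b = np.exp(rng.uniform(*np.log(spec.b_range), size=n))
        ka = np.full(n, spec.kappa_a_fixed)
    else:  # combined
        b_lo, b_hi = spec.b_range
        ka_hi = spec.kappa_a_range[1]
        ka_lo = ka_hi * np.sqrt(b_lo / b_hi)
        c = b_hi / ka_hi**2
        ka = np.exp(rng.uniform(np.log(ka_lo), np.log(ka_hi), size=n))
        b = c * ka**2
    return [BurstCoordinates(b=bi, kappa_a=ki, tau=spec.tau) for bi, ki in zip(b, ka)]


def _solver_calib(calib: CalibrationConstants) -> CalibrationConstants:
    return calib.with_kappa_p_plus(SOLVER_KAPPA_P_PLUS)


def _sample_sizes(rng: np.random.Generator, n: int, size_cv: float):
    sigma = np.sqrt(np.log1p(size_cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def _scatter_channels(rng: np.random.Generator, s: np.ndarray):
    fsc = np.clip(512.0 * s * (1.0 + 0.05 * rng.standard_normal(s.size)), 1.0, 1024.0)
    ssc = np.clip(512.0 * s * (1.0 + 0.10 * rng.standard_normal(s.size)), 1.0, 1024.0)
    return fsc, ssc


def _autofluor_draws(rng, n, mean, cv):
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=np.log(mean) - 0.5 * sigma**2, sigma=sigma, size=n)


def simulate_clone(
    coords: BurstCoordinates,
    calib: CalibrationConstants | None = None,
    n_events: int = 10_000,
    autofluor_mean: float = 5.0,
    autofluor_cv: float = 0.5,
    size_coupling: float = 0.5,
    size_cv: float = 0.25,
    seed: int = 0,
    method: str = "cme",
    clone_id: str = "",
    scenario: str = "manual",
    solver_options: cme.SolverOptions | None = None,
    protein_pmf: np.ndarray | None = None,
) -> SyntheticClone:
    """Simulate one clonal cytometry acquisition.

    Per cell: protein count n from the exact steady state (CME marginal or
    SSA; a precomputed ``protein_pmf`` skips the solve when many replicate
    acquisitions of the same clone are drawn), latent size factor
    s ~ lognormal, GFP = nu*n*s^eta + autofluorescence,
    FSC/SSC = 512*s*(1+noise) clipped to the 1-1024 channel, GFP clipped to
    the 4-decade range.  Fully seeded and reproducible.
    """
    if n_events < 1000:
        raise ValueError("need n_events >= 1000")
    calib = calib or CalibrationConstants()
    rng = np.random.default_rng(seed)
    sim_calib = _solver_calib(calib)
    rates = sim_calib.rates(coords)

    if method == "cme":
        if protein_pmf is None:
            sol = cme.steady_state(rates, options=solver_options or SIM_SOLVER_OPTIONS)
            protein_pmf = cme.fine_pmf(sol.marginal("protein"))
        cdf = np.cumsum(protein_pmf)
        cdf /= cdf[-1]
        protein = np.searchsorted(cdf, rng.uniform(size=n_events), side="left")
    elif method == "ssa":
        protein = simulate_clone_ssa(
            rates, n_cells=n_events, seed=int(rng.integers(2**31))
        )["protein"]
    else:
        raise ValueError(f"unknown method {method!r}")

    s = _sample_sizes(rng, n_events, size_cv)
    signal = sim_calib.nu * protein * s**size_coupling
    gfp = np.clip(signal + _autofluor_draws(rng, n_events, autofluor_mean, autofluor_cv),
                  0.1, 1000.0)
    fsc, ssc = _scatter_channels(rng, s)
    events = pd.DataFrame({"gfp": gfp, "fsc": fsc, "ssc": ssc})
    events.attrs["clone"] = clone_id
    return SyntheticClone(
        events=events,
        rates=rates,
        coords=coords,
        calib=calib,
        scenario=scenario,
        seed=seed,
        clone_id=clone_id,
    )


def simulate_clone_ssa(
    rates: RateConstants,
    duration: float | None = None,
    n_cells: int = 10_000,
    seed: int = 0,
) -> dict:
    """Exact stochastic simulation (Gillespie) of the two-state scheme.

    Each cell is an independent trajectory started at (repressed, 0, 0) and
    sampled at ``duration`` (default 12 protein lifetimes, comfortably past
    stationarity).  Returns transcript and protein samples.
    """
    from ._kernels import ssa_endpoint  # deferred: numba compilation on first use

    if duration is None:
        duration = 12.0 / rates.kappa_p_minus
    if duration < 10.0 / rates.kappa_p_minus:
        raise ValueError("duration must cover >= 10 protein lifetimes for stationarity")
    m, n = ssa_endpoint(
        rates.kappa_a,
        rates.kappa_r,
        rates.kappa_t_plus,
        rates.kappa_p_plus,
        rates.kappa_p_minus,
        float(duration),
        int(n_cells),
        int(seed),
    )
    return {"transcript": m, "protein": n}


def generate_autofluorescence(
    n_events: int = 10_000,
    mean: float = 5.0,
    cv: float = 0.5,
    size_cv: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Uninfected-cell event table: lognormal background, no signal."""
    rng = np.random.default_rng(seed)
    gfp = np.clip(_autofluor_draws(rng, n_events, mean, cv), 0.1, 1000.0)
    s = _sample_sizes(rng, n_events, size_cv)
    fsc, ssc = _scatter_channels(rng, s)
    events = pd.DataFrame({"gfp": gfp, "fsc": fsc, "ssc": ssc})
    events.attrs["clone"] = "autofluorescence"
    return events


def generate_ensemble(spec: ScenarioSpec, method: str = "cme") -> list[SyntheticClone]:
    """Simulate all clones of a scenario; pure function of (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    coords = scenario_coordinates(spec, rng)
    clones = []
    for i, c in enumerate(coords):
        clones.append(
            simulate_clone(
                c,
                calib=spec.calib,
                n_events=spec.n_events,
                autofluor_mean=spec.autofluor_mean,
                autofluor_cv=spec.autofluor_cv,
                size_coupling=spec.size_coupling,
                size_cv=spec.size_cv,
                seed=int(rng.integers(2**31)),
                method=method,
                clone_id=f"clone{i:02d}",
                scenario=spec.scenario,
            )
        )
    return clones


def ensemble_moments(spec: ScenarioSpec) -> pd.DataFrame:
    """Exact steady-state protein moments for each clone of a scenario.

    No event sampling: uses the closed-form moments at the full calibration
    (kappa_p_plus from ``spec.calib``).  One row per clone with ground-truth
    coordinates, protein mean/variance (counts) and RFU mean/variance.
    """
    rng = np.random.default_rng(spec.seed)
    coords = scenario_coordinates(spec, rng)
    rows = []
    for i, c in enumerate(coords):
        mom = analytic_moments(spec.calib.rates(c))
        nu = spec.calib.nu
        rows.append(
            {
                "clone_id": f"clone{i:02d}",
                "b": c.b,
                "kappa_a": c.kappa_a,
                "tau": c.tau,
                "protein_mean": mom.protein_mean,
                "protein_variance": mom.protein_variance,
                "rfu_mean": nu * mom.protein_mean,
                "rfu_variance": nu**2 * mom.protein_variance,
            }
        )
    return pd.DataFrame(rows)


def write_ensemble(clones: list[SyntheticClone], out_dir: str | Path) -> None:
    """Write per-clone event CSVs and a ground-truth JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for clone in clones:
        path = out / f"{clone.clone_id or 'clone'}.csv"
        clone.events.to_csv(path, index=False)
        manifest.append({**clone.ground_truth, "events": path.name})
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
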