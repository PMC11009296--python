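"""Closed-loop 0D four-chamber heart and circulation simulator.

A time-varying-elastance model of the four cardiac chambers coupled to
systemic and pulmonary windkessel compartments.  Each chamber generates
pressure ``p = E(t) (V - V_rest)`` where the elastance rises periodically
from ``E_min`` to ``E_max`` during activation; valves are pressure-gated
conductances with a smooth sigmoidal opening so the right-hand side stays
continuously differentiable for the adaptive solver.  The 8 ODE states are
the four chamber volumes and the four vascular compartment pressures, so
total blood volume (chamber volumes plus compliance-weighted vascular
pressures) is conserved exactly by construction.

The simulator is the package's data source: :func:`generate_dataset` draws
Latin-hypercube parameter samples, runs several beats to wash out the
initial transient, and stores the last cardiac cycle of each run.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .parameters import ParameterSpace, ParameterVector
from .traces import BeatSeries, PVTrace, SimulationDataset, last_beat

__all__ = [
    "IntegrationError",
    "default_space",
    "reduced_space",
    "chamber_elastance",
    "simulate",
    "total_blood_volume",
    "generate_dataset",
]

logger = logging.getLogger(__name__)


class IntegrationError(RuntimeError):
    """Raised when the circulation ODE produces a non-finite state."""


# ---------------------------------------------------------------------------
# fixed circulation constants (mmHg, mL, s)
# ---------------------------------------------------------------------------
CONSTANTS = {
    "E_min_LV": 0.08,        # mmHg/mL, ventricular passive elastance
    "E_min_RV": 0.05,
    "V_rest_LA": 5.0,        # mL, zero-pressure chamber volumes
    "V_rest_LV": 10.0,
    "V_rest_RA": 5.0,
    "V_rest_RV": 10.0,
    "R_mv": 0.006,           # mmHg s/mL, valve resistances
    "R_av": 0.004,
    "R_tv": 0.006,
    "R_pv": 0.004,
    "R_sys_base": 0.80,      # systemic arterial -> venous resistance
    "R_ven_sys": 0.08,       # venous return into RA
    "R_pulm_base": 0.12,
    "R_ven_pul": 0.045,
    "C_art_sys_base": 1.5,   # mL/mmHg, windkessel compliances
    "C_ven_sys": 12.0,
    "C_art_pul": 4.0,
    "C_ven_pul": 7.0,
    "valve_width": 0.5,      # mmHg, sigmoid smoothing of valve opening
    "atrial_act_fraction": 0.25,   # activation duration as fraction of T_HB
    "vent_act_fraction": 0.45,
}

# near-limit-cycle initial state at the reference parameters
_INITIAL_STATE = np.array([65.0, 125.0, 65.0, 130.0, 75.0, 9.0, 16.0, 9.0])

_PARAM_DEFS = [
    # name, lower, upper, unit, reference
    ("E_max_LA", 0.40, 0.90, "mmHg/mL", 0.60),
    ("E_max_LV", 1.20, 3.50, "mmHg/mL", 2.00),
    ("E_max_RA", 0.30, 0.70, "mmHg/mL", 0.45),
    ("E_max_RV", 0.35, 1.00, "mmHg/mL", 0.55),
    ("E_min_atria", 0.08, 0.28, "mmHg/mL", 0.18),
    ("act_dur_scale", 0.85, 1.20, "-", 1.00),
    ("act_steepness", 1.00, 3.00, "-", 1.50),
    ("AV_delay", 0.08, 0.24, "s", 0.16),
    ("T_HB", 0.65, 1.00, "s", 0.80),
    ("R_sys_scale", 0.60, 1.60, "-", 1.00),
    ("R_pulm_scale", 0.60, 1.60, "-", 1.00),
    ("C_art_scale", 0.70, 1.40, "-", 1.00),
]

#: the 8 analogs varied in the scaled-down training studies
REDUCED_NAMES = (
    "E_max_LA", "E_max_LV", "E_max_RV", "E_min_atria",
    "act_dur_scale", "AV_delay", "R_sys_scale", "R_pulm_scale",
)


def default_space() -> ParameterSpace:
    """The full 12-parameter analog space exposed by the simulator."""
    names, lo, hi, units, ref = zip(*_PARAM_DEFS)
    return ParameterSpace(names, lo, hi, units, ref)


def reduced_space(names: Sequence[str] = REDUCED_NAMES) -> ParameterSpace:
    """A subspace of :func:`default_space` (others pinned at reference)."""
    return default_space().subspace(names)


def _theta_full(theta: ParameterVector) -> dict[str, float]:
    """Physical parameter dict with unexposed analogs at reference."""
    full = {name: ref for name, _, _, _, ref in _PARAM_DEFS}
    full.update(theta.as_dict())
    return full


def _activation(tau: np.ndarray, duration: float, steepness: float) -> np.ndarray:
    """Smooth activation in [0, 1]: a raised-cosine bump to a power.

    ``tau`` is time since activation onset (already wrapped to one period).
    The bump reaches exactly 1 at ``tau = duration / 2`` and is identically
    0 outside ``[0, duration]``; it is C^1 in time for steepness >= 1.
    """
    tau = np.asarray(tau, float)
    inside = (tau >= 0) & (tau < duration)
    bump = np.where(inside, 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / duration)), 0.0)
    return bump ** steepness


_CHAMBERS = ("LA", "LV", "RA", "RV")


def _elastance_params(p: dict[str, float], chamber: str):
    T_HB = p["T_HB"]
    if chamber in ("LA", "RA"):
        e_min = p["E_min_atria"]
        e_max = p["E_max_LA"] if chamber == "LA" else p["E_max_RA"]
        onset, duration = 0.0, CONSTANTS["atrial_act_fraction"] * T_HB
    elif chamber in ("LV", "RV"):
        e_min = CONSTANTS["E_min_LV"] if chamber == "LV" else CONSTANTS["E_min_RV"]
        e_max = p["E_max_LV"] if chamber == "LV" else p["E_max_RV"]
        onset = p["AV_delay"]
        duration = p["act_dur_scale"] * CONSTANTS["vent_act_fraction"] * T_HB
    else:
        raise KeyError(f"unknown chamber {chamber!r}; expected one of {_CHAMBERS}")
    return e_min, e_max, onset, duration


def chamber_elastance(t, chamber: str, theta: ParameterVector) -> np.ndarray | float:
    """Time-varying elastance E(t) of one chamber, mmHg/mL, T_HB-periodic.

    Atrial activation begins at cycle onset; ventricular activation begins
    ``AV_delay`` later.
    """
    p = _theta_full(theta)
    e_min, e_max, onset, duration = _elastance_params(p, chamber)
    tau = np.mod(np.asarray(t, float) - onset, p["T_HB"])
    a = _activation(tau, duration, p["act_steepness"])
    out = e_min + (e_max - e_min) * a
    return float(out) if np.isscalar(t) else out


def _valve_flow(dp: np.ndarray, resistance: float) -> np.ndarray:
    """Smoothed diode: conductance gated by a logistic in the pressure drop."""
    w = CONSTANTS["valve_width"]
    return expit(dp / w) * dp / resistance


def _rhs(t, y, p):
    c = CONSTANTS
    V_LA, V_LV, V_RA, V_RV, p_as, p_vs, p_ap, p_vp = y
    E = {ch: chamber_elastance_scalar(t, ch, p) for ch in _CHAMBERS}
    p_LA = E["LA"] * (V_LA - c["V_rest_LA"])
    p_LV = E["LV"] * (V_LV - c["V_rest_LV"])
    p_RA = E["RA"] * (V_RA - c["V_rest_RA"])
    p_RV = E["RV"] * (V_RV - c["V_rest_RV"])

    q_mv = _valve_flow(p_LA - p_LV, c["R_mv"])
    q_av = _valve_flow(p_LV - p_as, c["R_av"])
    q_tv = _valve_flow(p_RA - p_RV, c["R_tv"])
    q_pv = _valve_flow(p_RV - p_ap, c["R_pv"])
    q_sys = (p_as - p_vs) / (c["R_sys_base"] * p["R_sys_scale"])
    q_ra_in = (p_vs - p_RA) / c["R_ven_sys"]
    q_pul = (p_ap - p_vp) / (c["R_pulm_base"] * p["R_pulm_scale"])
    q_la_in = (p_vp - p_LA) / c["R_ven_pul"]

    C_as = c["C_art_sys_base"] * p["C_art_scale"]
    return [
        q_la_in - q_mv,
        q_mv - q_av,
        q_ra_in - q_tv,
        q_tv - q_pv,
        (q_av - q_sys) / C_as,
        (q_sys - q_ra_in) / c["C_ven_sys"],
        (q_pv - q_pul) / c["C_art_pul"],
        (q_pul - q_la_in) / c["C_ven_pul"],
    ]


def chamber_elastance_scalar(t: float, chamber: str, p: dict[str, float]) -> float:
    """Scalar fast path of :func:`chamber_elastance` on a resolved dict."""
    e_min, e_max, onset, duration = _elastance_params(p, chamber)
    tau = (t - onset) % p["T_HB"]
    if 0.0 <= tau < duration:
        a = (0.5 * (1.0 - math.cos(2.0 * math.pi * tau / duration))) ** p["act_steepness"]
        return e_min + (e_max - e_min) * a
    return e_min


def _pressures(values_V: np.ndarray, t: np.ndarray, p: dict[str, float]) -> np.ndarray:
    c = CONSTANTS
    rest = [c["V_rest_LA"], c["V_rest_LV"], c["V_rest_RA"], c["V_rest_RV"]]
    cols = []
    for j, ch in enumerate(_CHAMBERS):
        e_min, e_max, onset, duration = _elastance_params(p, ch)
        tau = np.mod(t - onset, p["T_HB"])
        a = _activation(tau, duration, p["act_steepness"])
        cols.append((e_min + (e_max - e_min) * a) * (values_V[:, j] - rest[j]))
    return np.column_stack(cols)


INTERNAL_NAMES = ("p_art_sys", "p_ven_sys", "p_art_pul", "p_ven_pul")


def simulate(
    theta: ParameterVector,
    n_beats: int = 5,
    dt_out: float | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    y0: np.ndarray | None = None,
) -> BeatSeries:
    """Integrate the closed loop for ``n_beats`` heartbeats.

    Output is resampled from the solver's dense output onto a uniform grid
    of spacing ``dt_out`` (default ``T_HB / 200``), half-open at the final
    time.  Deterministic given ``theta`` and the solver configuration.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    p = _theta_full(theta)
    T_HB = p["T_HB"]
    if dt_out is None:
        dt_out = T_HB / 200.0
    if dt_out <= 0:
        raise ValueError("dt_out must be positive")
    t_end = n_beats * T_HB
    y0 = _INITIAL_STATE.copy() if y0 is None else np.asarray(y0, float)

    sol = solve_ivp(
        _rhs, (0.0, t_end), y0, args=(p,), method="RK45",
        rtol=rtol, atol=atol, dense_output=True, max_step=T_HB / 20.0,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(
            f"circulation solve failed near t = {t_fail:.4f} s: {sol.message}"
        )
    n_out = int(round(t_end / dt_out))
    t = np.arange(n_out) * dt_out
    y = sol.sol(t).T
    if not np.all(np.isfinite(y)):
        bad = t[~np.all(np.isfinite(y), axis=1)][0]
        raise IntegrationError(f"non-finite state at t = {bad:.4f} s")
    pressures = _pressures(y[:, :4], t, p)
    values = np.column_stack([pressures, y[:, :4]])
    return BeatSeries(
        t=t, values=values, T_HB=T_HB, AV_delay=p["AV_delay"],
        internal=y[:, 4:], internal_names=INTERNAL_NAMES,
    )


def total_blood_volume(beats: BeatSeries, theta: ParameterVector) -> np.ndarray:
    """Chamber volumes plus compliance-weighted vascular volumes, per sample.

    Constant along exact trajectories of the closed loop; its relative
    drift measures integrator conservation error.
    """
    c = CONSTANTS
    p = _theta_full(theta)
    compliances = np.array(
        [c["C_art_sys_base"] * p["C_art_scale"], c["C_ven_sys"], c["C_art_pul"], c["C_ven_pul"]]
    )
    return beats.values[:, 4:].sum(axis=1) + beats.internal @ compliances


def generate_dataset(
    space: ParameterSpace | None = None,
    n: int = 405,
    n_beats: int = 5,
    seed: int = 0,
    samples_per_beat: int = 200,
    max_retries: int = 5,
) -> SimulationDataset:
    """Latin-hypercube sample ``n`` parameter points and simulate each.

    The first ``n_beats - 1`` beats wash out the initial transient; the last
    cardiac cycle of each run is stored.  Failed simulations are skipped and
    replaced by a fresh uniform draw (bounded retries); the count is recorded
    in the dataset provenance.  The default ``n = 405`` mirrors a 400-train /
    5-test database convention (see :meth:`SimulationDataset.split`).
    """
    if space is None:
        space = default_space()
    if n < 1:
        raise ValueError("n must be >= 1")
    thetas = space.sample_lhs(n, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0D]))
    records, n_failed = [], 0
    for i in range(n):
        vals = thetas[i]
        for attempt in range(max_retries + 1):
            try:
                theta = ParameterVector(space, vals)
                T_HB = _theta_full(theta)["T_HB"]
                beats = simulate(theta, n_beats=n_beats, dt_out=T_HB / samples_per_beat)
                records.append((theta, last_beat(beats)))
                break
            except IntegrationError:
                n_failed += 1
                logger.warning("simulation failed for theta=%s; resampling", vals)
                vals = rng.uniform(space.lower, space.upper)
        else:
            raise IntegrationError(
                f"simulation for record {i} failed after {max_retries} retries"
            )
    provenance = {
        "generator": "cardio0d.generate_dataset",
        "seed": int(seed),
        "n_requested": int(n),
        "n_beats": int(n_beats),
        "samples_per_beat": int(samples_per_beat),
        "n_failed_and_resampled": int(n_failed),
    }
    return SimulationDataset(space, records, provenance)
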