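"""Digital twin of a 3 L oxystat batch fermentation of *M. gryphiswaldense*.

The plant is a seven-state ODE: biomass (OD565), lactate (mM), nitrate (mM),
dissolved oxygen (percent air saturation), cellular iron (mg per g dry
weight) and the running magnetosome size distribution (mean, sd in nm).

Growth follows Monod kinetics on lactate multiplied by an electron-acceptor
availability term that switches between O2 respiration and denitrification
(nitrate respiration is repressed by oxygen through an Fnr-type term) and a
linear oxidative-stress attenuation.  The defaults are calibrated in closed
form so that the specific growth rate hits 0.07 / 0.15 / 0.13 1/h at
95 / 1 / 0 % dO2 (the anoxic anchor at 10 mM nitrate), lactate consumption is
growth-coupled through a single yield (0.15 / 4.63 OD per mM), and nitrate
consumption reproduces 0.71 / 1.09 / 6.13 mM/h/OD across the three regimes.

Oxygen obeys dC/dt = kLa * (C_eq - C) - OUR with a two-term transfer
correlation (sparged + surface aeration) and a Monod-type uptake term, which
is what the PI cascade in :mod:`magnetoferm.controller` actuates against.
Iron content and magnetosome size relax first-order toward dO2-dependent
asymptotes; the magnetic response C_mag is a monotone piecewise-linear map of
cellular iron.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .controller import (
    ControllerConfig,
    ControlTrace,
    SensorModel,
    cascade_map,
    closed_loop,
)

__all__ = [
    "KineticParams",
    "ReactorConfig",
    "FermentationState",
    "FermentationRecord",
    "FixedActuation",
    "Preset",
    "kla",
    "growth_rate",
    "derivatives",
    "simulate_batch",
    "observe",
    "sample_particles",
    "pO2_from_dO2",
    "dO2_from_pO2",
    "cmag_from_iron",
    "preset",
    "run_preset",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "time_h",
    "od565",
    "dO2_pct",
    "lactate_mM",
    "nitrate_mM",
    "cmag",
    "fe_mg_per_gdw",
    "rpm",
    "airflow_slpm",
]

# iron -> C_mag transfer anchors (mg/g_dw, dimensionless response)
_CMAG_IRON = np.array([0.0, 3.3, 14.4, 25.3])
_CMAG_VALUE = np.array([0.0, 0.10, 0.74, 0.99])


@dataclass(frozen=True)
class KineticParams:
    """Per-condition growth / consumption / biomineralization parameters.

    The three ``mu_max_*`` fields are the calibration anchors (1/h at
    saturating substrate); the mechanistic constants that realize them are
    derived properties so recalibration is automatic when an anchor moves.
    """

    mu_max_ox: float = 0.07      # 1/h at 95% dO2
    mu_max_micro: float = 0.15   # 1/h at 1% dO2
    mu_max_anox: float = 0.13    # 1/h at 0% dO2, 10 mM nitrate
    K_lac: float = 0.1           # mM
    K_O2: float = 0.05           # % air saturation
    K_fnr: float = 0.08          # % dO2 at half-repression of denitrification
    K_no3: float = 0.1           # mM
    q_lac: float = 4.63          # mM/h per OD, microoxic anchor
    q_no3_assim: float = 0.71    # mM/h per OD, assimilatory
    q_no3_resp: float = 5.482    # mM/h per OD, respiratory (fully derepressed)
    q_o2: float = 600.0          # %-air-sat/h per OD oxygen uptake capacity
    tau_fnr: float = 0.5         # h, response time of the Fnr-type O2 switch
    lag: float = 8.0             # h
    inoculum_od: float = 0.077
    iron_init: float = 5.0       # mg/g_dw carried over from the seed-train
    k_iron: float = 0.12         # 1/h relaxation toward the dO2 target
    k_size: float = 0.15         # 1/h size-distribution relaxation
    # (dO2 %, iron target mg/g_dw); extra 5% anchor encodes the sharp
    # inhibition of biomineralization above ~5% dO2
    iron_targets: tuple = ((0.0, 25.3), (1.0, 14.4), (5.0, 4.0), (95.0, 3.3))
    # (dO2 %, asymptotic mean nm, asymptotic sd nm)
    size_asymptote: tuple = ((0.0, 33.8, 9.4), (1.0, 29.3, 7.9), (95.0, 26.0, 8.5))
    seed_size: tuple[float, float] = (26.0, 9.0)

    def __post_init__(self) -> None:
        for name in ("mu_max_ox", "mu_max_micro", "mu_max_anox", "q_lac",
                     "q_no3_assim", "q_no3_resp", "q_o2", "k_iron", "k_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("K_lac", "K_O2", "K_fnr", "K_no3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        targets = [w for _, w in self.iron_targets]
        if any(b > a for a, b in zip(targets, targets[1:])) is False and targets != sorted(targets, reverse=True):
            raise ValueError("iron_targets must be monotone decreasing in dO2")

    # ---- derived mechanistic constants -------------------------------

    @property
    def stress_slope(self) -> float:
        """Linear oxidative-stress attenuation per % dO2."""
        r = self.mu_max_ox / self.mu_max_micro
        return (1.0 - r) / (95.0 - r)

    @property
    def mu_max(self) -> float:
        """Intrinsic maximum specific growth rate (1/h)."""
        return self.mu_max_micro / (1.0 - self.stress_slope)

    @property
    def denit_eff(self) -> float:
        """Relative growth efficiency of denitrification vs O2 respiration."""
        monod10 = 10.0 / (self.K_no3 + 10.0)
        return self.mu_max_anox / (self.mu_max * monod10)

    @property
    def y_lac_od(self) -> float:
        """Biomass yield on lactate, OD565 per mM."""
        return self.mu_max_micro / self.q_lac

    def iron_target(self, dO2: float) -> float:
        xs = np.array([c for c, _ in self.iron_targets])
        ys = np.array([w for _, w in self.iron_targets])
        return float(np.interp(dO2, xs, ys))

    def size_target(self, dO2: float) -> tuple[float, float]:
        xs = np.array([c for c, _, _ in self.size_asymptote])
        ms = np.array([m for _, m, _ in self.size_asymptote])
        ss = np.array([s for _, _, s in self.size_asymptote])
        return float(np.interp(dO2, xs, ms)), float(np.interp(dO2, xs, ss))


@dataclass(frozen=True)
class ReactorConfig:
    """Vessel, gassing and conversion constants for the 3 L stirred tank."""

    volume: float = 2.8                  # L working volume
    gas_o2_fraction: float = 0.21        # 0.21 = compressed air, 0 = N2
    n2_sparge: float = 0.2               # SLPM during anoxic operation
    # kLa(N, Q) = a*(N/100)^alpha * Q^beta + k_surface*(N/100), in 1/h
    kla_coeffs: tuple[float, float, float, float] = (0.4, 2.0, 1.5, 0.25)
    c_star: float = 100.0                # % air saturation under air
    od_to_dw: float = 0.286              # g dry weight per L per OD565
    pO2_per_pct: float = 2.12            # mbar per % air saturation
    o2_sat_mg_per_l: float = 8.0         # mg O2/L at air saturation, 28 degC
    lactate_mM: float = 15.0             # medium lactate
    nitrate_mM: float = 4.0              # medium nitrate (10 for anoxic runs)

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if not (0.0 <= self.gas_o2_fraction <= 0.21):
            raise ValueError("gas_o2_fraction must lie in [0, 0.21]")
        a, alpha, beta, k_s = self.kla_coeffs
        if a < 0 or k_s <= 0:
            raise ValueError("kLa coefficients must give a strictly positive kLa")


@dataclass
class FermentationState:
    """One instant of the plant state (units as in the record schema)."""

    time: float
    od: float
    lactate: float
    nitrate: float
    dO2: float
    iron: float
    size_mean: float
    size_sd: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.od, self.lactate, self.nitrate, self.dO2,
                         self.iron, self.size_mean, self.size_sd])


@dataclass
class FermentationRecord:
    """Time-indexed trajectory of state + actuators for one batch."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"record is missing columns: {missing}")
        t = self.frame["time_h"].to_numpy()
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("time column must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class FixedActuation:
    """Open-loop actuation (anoxic runs: 100 rpm, 0.2 SLPM N2)."""

    rpm: float = 100.0
    airflow: float = 0.2


def kla(config: ReactorConfig, rpm: float, airflow: float) -> float:
    """Volumetric O2 transfer coefficient (1/h) of the sparged, stirred tank.

    Two contributions: a sparged term ``a*(N/100)^alpha * Q^beta`` and a
    surface-aeration floor ``k_surface*(N/100)`` that keeps kLa strictly
    positive at zero airflow.
    """
    if rpm < 100.0:
        raise ValueError(f"rpm below stirrer minimum (100), got {rpm}")
    if airflow < 0.0:
        raise ValueError("airflow must be non-negative")
    a, alpha, beta, k_s = config.kla_coeffs
    return a * (rpm / 100.0) ** alpha * airflow**beta + k_s * (rpm / 100.0)


def growth_rate(
    params: KineticParams,
    dO2: float,
    lactate: float,
    nitrate: float,
    dO2_reg: float | None = None,
) -> float:
    """Specific growth rate mu (1/h) at the given dO2 and substrate levels.

    ``dO2_reg`` is the (slow, transcriptional) oxygen signal seen by the
    Fnr-type denitrification switch; it defaults to the instantaneous dO2.
    """
    if dO2 < 0 or lactate < 0 or nitrate < 0:
        raise ValueError("concentrations must be non-negative")
    if dO2_reg is None:
        dO2_reg = dO2
    monod_lac = lactate / (params.K_lac + lactate) if lactate > 0 else 0.0
    f_ox = dO2 / (params.K_O2 + dO2)
    fnr = params.K_fnr / (params.K_fnr + dO2_reg)
    f_denit = params.denit_eff * fnr * (nitrate / (params.K_no3 + nitrate) if nitrate > 0 else 0.0)
    acceptor = min(f_ox + f_denit, 1.0)
    stress = max(1.0 - params.stress_slope * dO2, 0.0)
    return params.mu_max * monod_lac * acceptor * stress


def derivatives(
    t: float,
    y: np.ndarray,
    params: KineticParams,
    config: ReactorConfig,
    rpm: float,
    airflow: float,
) -> np.ndarray:
    """Right-hand side of the plant ODE at absolute process time ``t`` (h).

    State order: [OD, lactate mM, nitrate mM, dO2 %, iron mg/g, size mean nm,
    size sd nm, dO2_reg %].  The last component is the low-pass-filtered
    oxygen signal driving the Fnr-type denitrification switch (transcriptional
    regulation does not follow second-scale dO2 dips).  Growth and substrate
    consumption are gated off before the lag time; oxygen uptake is not
    (resting cells still respire, which is the load the controller works
    against from t = 0).
    """
    if np.any(~np.isfinite(y)):
        names = np.array(["od", "lactate", "nitrate", "dO2", "iron",
                          "size_mean", "size_sd", "dO2_reg"])
        bad = names[~np.isfinite(y)]
        raise FloatingPointError(f"non-finite state component(s): {', '.join(bad)} at t={t:.3f} h")
    X = max(y[0], 0.0)
    s_lac = max(y[1], 0.0)
    s_no3 = max(y[2], 0.0)
    C = min(max(y[3], 0.0), 100.0)
    fe = y[4]
    size_m, size_s = y[5], y[6]
    c_reg = min(max(y[7], 0.0), 100.0)

    growing = t >= params.lag
    mu = growth_rate(params, C, s_lac, s_no3, dO2_reg=c_reg) if growing else 0.0

    dX = mu * X
    dS_lac = -(mu / params.y_lac_od) * X
    fnr = params.K_fnr / (params.K_fnr + c_reg)
    monod_no3 = s_no3 / (params.K_no3 + s_no3) if s_no3 > 0 else 0.0
    q_no3 = (params.q_no3_assim + params.q_no3_resp * fnr) * monod_no3
    dS_no3 = -q_no3 * X if growing else 0.0

    transfer = kla(config, rpm, airflow)
    c_eq = config.c_star * config.gas_o2_fraction / 0.21
    our = params.q_o2 * X * C / (params.K_O2 + C)
    dC = transfer * (c_eq - C) - our
    # non-negativity / ceiling projection for the dO2 state
    if C <= 0.0 and dC < 0.0:
        dC = 0.0
    if C >= 100.0 and dC > 0.0:
        dC = 0.0

    d_fe = params.k_iron * (params.iron_target(C) - fe)
    tgt_m, tgt_s = params.size_target(C)
    d_sm = params.k_size * (tgt_m - size_m)
    d_ss = params.k_size * (tgt_s - size_s)
    d_reg = (C - c_reg) / params.tau_fnr
    return np.array([dX, dS_lac, dS_no3, dC, d_fe, d_sm, d_ss, d_reg])


def cmag_from_iron(iron: float | np.ndarray) -> float | np.ndarray:
    """Magnetic response C_mag from cellular iron (monotone, saturating)."""
    return np.interp(iron, _CMAG_IRON, _CMAG_VALUE)


def pO2_from_dO2(config: ReactorConfig, dO2: float) -> float:
    """Oxygen partial pressure (mbar) equivalent to a dO2 in % air sat."""
    if dO2 < 0:
        raise ValueError("dO2 must be non-negative")
    return config.pO2_per_pct * dO2


def dO2_from_pO2(config: ReactorConfig, pO2: float) -> float:
    if pO2 < 0:
        raise ValueError("pO2 must be non-negative")
    return pO2 / config.pO2_per_pct


def _initial_vector(params: KineticParams, config: ReactorConfig, c0: float) -> np.ndarray:
    m0, s0 = params.seed_size
    return np.array([
        params.inoculum_od,
        config.lactate_mM,
        config.nitrate_mM,
        c0,
        params.iron_init,
        m0,
        s0,
        c0,  # regulatory O2 signal starts equilibrated
    ])


def _integrate(params, config, rpm, airflow, t0, t1, y0, t_eval=None, rtol=1e-9):
    """Advance the plant from t0 to t1 under fixed actuation."""
    if t1 <= t0:
        return np.array([t0]), y0[:, None]
    sol = solve_ivp(
        derivatives,
        (t0, t1),
        y0,
        t_eval=t_eval,
        args=(params, config, rpm, airflow),
        method="LSODA",
        rtol=rtol,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failed at t = {sol.t[-1]:.3f} h: {sol.message}")
    return sol.t, np.clip(sol.y, [[0.0]] * 8, None)


def simulate_batch(
    params: KineticParams,
    config: ReactorConfig,
    control: ControllerConfig | FixedActuation,
    horizon: float = 35.0,
    seed: int = 0,
    sensor: SensorModel | None = None,
    c0: float | None = None,
    record_interval: float = 1.0 / 60.0,
    label: str = "custom",
    rtol: float = 1e-9,
) -> FermentationRecord:
    """Integrate a full batch and return the sampled trajectory.

    ``control`` is either a PI :class:`ControllerConfig` (closed loop with the
    split-range cascade, actuators updated every ``sample_interval`` with a
    zero-order hold) or a :class:`FixedActuation` (open loop, e.g. the anoxic
    N2-sparged regime).  Identical seeds give bit-identical records.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if c0 is None:
        c0 = control.set_point if isinstance(control, ControllerConfig) else 0.0
    y0 = _initial_vector(params, config, c0)

    if isinstance(control, ControllerConfig):
        sensor = sensor or SensorModel()

        def plant_step(state, rpm, airflow, dt):
            t, y = state
            # split at the lag discontinuity if it falls inside the interval
            if t < params.lag < t + dt:
                _, ya = _integrate(params, config, rpm, airflow, t, params.lag, y, rtol=rtol)
                _, yb = _integrate(params, config, rpm, airflow, params.lag, t + dt, ya[:, -1], rtol=rtol)
                return (t + dt, yb[:, -1])
            _, yy = _integrate(params, config, rpm, airflow, t, t + dt, y, rtol=rtol)
            return (t + dt, yy[:, -1])

        trace = closed_loop(
            control,
            sensor,
            plant_step,
            (0.0, y0),
            lambda st: float(st[1][3]),
            horizon,
            seed=seed,
        )
        ys = np.stack([st[1] for st in trace.states], axis=1)
        frame = pd.DataFrame({
            "time_h": trace.time_h,
            "od565": ys[0],
            "dO2_pct": trace.dO2_pct,
            "lactate_mM": ys[1],
            "nitrate_mM": ys[2],
            "cmag": cmag_from_iron(ys[4]),
            "fe_mg_per_gdw": ys[4],
            "rpm": trace.rpm,
            "airflow_slpm": trace.airflow_slpm,
        })
        frame["size_mean_nm"] = ys[5]
        frame["size_sd_nm"] = ys[6]
        frame["output_pct"] = trace.output_pct
        frame["dO2_true_pct"] = trace.dO2_true_pct
        mode = "closed-loop"
    else:
        n = int(round(horizon / record_interval))
        t_grid = np.arange(n + 1) * record_interval
        split = min(max(params.lag, 0.0), horizon)
        pieces_t, pieces_y = [], []
        for (a, b) in ((0.0, split), (split, horizon)):
            if b <= a:
                continue
            t_eval = t_grid[(t_grid >= a - 1e-12) & (t_grid <= b + 1e-12)]
            if len(t_eval) == 0 or t_eval[0] > a:
                t_eval = np.concatenate([[a], t_eval])
            tt, yy = _integrate(params, config, control.rpm, control.airflow,
                                a, b, y0 if a == 0.0 else pieces_y[-1][:, -1],
                                t_eval=t_eval, rtol=rtol)
            pieces_t.append(tt)
            pieces_y.append(yy)
        t_all = np.concatenate(pieces_t)
        y_all = np.concatenate(pieces_y, axis=1)
        keep = np.concatenate([[True], np.diff(t_all) > 1e-12])
        t_all, y_all = t_all[keep], y_all[:, keep]
        frame = pd.DataFrame({
            "time_h": t_all,
            "od565": y_all[0],
            "dO2_pct": y_all[3],
            "lactate_mM": y_all[1],
            "nitrate_mM": y_all[2],
            "cmag": cmag_from_iron(y_all[4]),
            "fe_mg_per_gdw": y_all[4],
            "rpm": np.full(len(t_all), float(control.rpm)),
            "airflow_slpm": np.full(len(t_all), float(control.airflow)),
        })
        frame["size_mean_nm"] = y_all[5]
        frame["size_sd_nm"] = y_all[6]
        mode = "fixed-actuation"

    metadata = {
        "condition": label,
        "mode": mode,
        "seed": int(seed),
        "horizon_h": horizon,
        "params": asdict(params),
        "reactor": asdict(config),
    }
    return FermentationRecord(frame, metadata)


def observe(
    record: FermentationRecord,
    sampling_interval: float,
    noise: float,
    seed: int = 0,
    do2_noise_sd: float | None = None,
) -> FermentationRecord:
    """At-line sampling of a dense record: sparse, noisy, seeded.

    Multiplicative log-normal noise (log-sd = ``noise``, so the CV equals
    ``noise`` to first order and log-linear fits stay unbiased) on OD,
    lactate, nitrate and iron; additive Gaussian noise on dO2 with sd
    ``do2_noise_sd`` (defaults to ``noise`` percentage points), truncated at
    zero.
    """
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    if len(record.frame) == 0:
        raise ValueError("cannot observe an empty record")
    rng = np.random.default_rng(seed)
    t = record.frame["time_h"].to_numpy()
    grid = np.arange(0.0, t[-1] + 1e-9, sampling_interval)
    idx = np.clip(np.searchsorted(t, grid - 1e-9), 0, len(t) - 1)
    sub = record.frame.iloc[idx].reset_index(drop=True).copy()
    sub["time_h"] = t[idx]
    if noise > 0:
        for col in ("od565", "lactate_mM", "nitrate_mM", "fe_mg_per_gdw"):
            sub[col] = sub[col].to_numpy() * np.exp(rng.normal(0.0, noise, len(sub)))
        sd = noise if do2_noise_sd is None else do2_noise_sd
        sub["dO2_pct"] = np.maximum(
            sub["dO2_pct"].to_numpy() + rng.normal(0.0, sd, len(sub)), 0.0
        )
    meta = dict(record.metadata)
    meta.update({"sampling_interval_h": sampling_interval, "observation_noise": noise,
                 "observation_seed": int(seed)})
    return FermentationRecord(sub, meta)


# --------------------------------------------------------------------------
# TEM particle-sampling emulator
# --------------------------------------------------------------------------

# (timepoint h, diameter mean nm, diameter sd nm)
_SIZE_TRAJECTORY = {
    "anoxic": ((0.0, 25.8, 8.9), (15.0, 32.0, 9.5), (20.0, 33.5, 9.1), (34.0, 33.8, 9.4)),
    "microoxic": ((0.0, 26.7, 8.5), (14.0, 26.7, 8.4), (18.0, 29.3, 7.9)),
}
# (timepoint h, length mean um, length sd um, MS/um mean, MS/um per-cell sd)
_CELL_TRAJECTORY = {
    "anoxic": ((0.0, 3.0, 0.7, 8.1), (15.0, 2.9, 0.6, 8.8), (20.0, 3.0, 0.8, 8.4), (34.0, 3.1, 0.7, 8.1)),
    "microoxic": ((0.0, 3.3, 0.8, 8.8), (14.0, 3.1, 0.8, 8.9), (18.0, 3.4, 0.9, 7.7)),
}
_REGIME_ALIASES = {
    "anoxic": "anoxic", "anoxic0": "anoxic", "0%": "anoxic",
    "microoxic": "microoxic", "microoxic1": "microoxic", "1%": "microoxic",
    "seed-train": "microoxic",
}
_MS_PER_UM_SD = 0.8  # per-cell spread of the linear magnetosome density
_MIN_CELL_LENGTH = 1.5  # um, truncation of the cell-length draw


def _interp_trajectory(table, timepoint):
    ts = np.array([row[0] for row in table])
    out = []
    for j in range(1, len(table[0])):
        vals = np.array([row[j] for row in table])
        out.append(float(np.interp(timepoint, ts, vals)))
    return out


def sample_particles(
    regime: str,
    timepoint: float,
    n_per_replicate: int = 1000,
    replicates: int = 3,
    seed: int = 0,
    n_cells_per_replicate: int = 34,
):
    """Emulate TEM particle counting: diameters, cell lengths, counts.

    Diameters are Gaussian draws (non-positive draws rejected) around the
    measured trajectory for the regime, interpolated in time.  Cell records
    follow a density model: magnetosomes per um of cell length is the stable
    quantity, so ``count = round(density * length)``.

    Returns a :class:`magnetoferm.particles.ParticleDataset`.
    """
    from .particles import ParticleDataset  # local import to avoid a cycle

    key = _REGIME_ALIASES.get(regime.lower())
    if key is None:
        raise KeyError(
            f"unknown regime {regime!r}; known: {sorted(set(_REGIME_ALIASES))}"
        )
    if n_per_replicate < 0:
        raise ValueError("n_per_replicate must be non-negative")
    rng = np.random.default_rng(seed)
    mean, sd = _interp_trajectory(_SIZE_TRAJECTORY[key], timepoint)
    l_mean, l_sd, dens_mean = _interp_trajectory(_CELL_TRAJECTORY[key], timepoint)

    part_rows, cell_rows = [], []
    for rep in range(1, replicates + 1):
        d = np.empty(0)
        while len(d) < n_per_replicate:
            draw = rng.normal(mean, sd, n_per_replicate - len(d))
            d = np.concatenate([d, draw[draw > 0]])
        part_rows.append(pd.DataFrame({
            "condition": key,
            "replicate": rep,
            "timepoint_h": timepoint,
            "diameter_nm": d,
        }))
        lengths = np.empty(0)
        while len(lengths) < n_cells_per_replicate:
            draw = rng.normal(l_mean, l_sd, n_cells_per_replicate - len(lengths))
            lengths = np.concatenate([lengths, draw[draw > _MIN_CELL_LENGTH]])
        dens = rng.normal(dens_mean, _MS_PER_UM_SD, n_cells_per_replicate)
        counts = np.maximum(np.round(dens * lengths), 0).astype(int)
        cell_rows.append(pd.DataFrame({
            "condition": key,
            "replicate": rep,
            "timepoint_h": timepoint,
            "cell_id": np.arange(1, n_cells_per_replicate + 1),
            "length_um": lengths,
            "ms_count": counts,
        }))
    particles = (pd.concat(part_rows, ignore_index=True) if part_rows
                 else pd.DataFrame(columns=["condition", "replicate", "timepoint_h", "diameter_nm"]))
    cells = (pd.concat(cell_rows, ignore_index=True) if cell_rows
             else pd.DataFrame(columns=["condition", "replicate", "timepoint_h",
                                        "cell_id", "length_um", "ms_count"]))
    if n_per_replicate == 0:
        particles = particles.iloc[0:0]
    return ParticleDataset(particles, cells)


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Preset:
    name: str
    params: KineticParams
    reactor: ReactorConfig
    control: ControllerConfig | FixedActuation
    sensor: SensorModel
    c0: float
    horizon: float = 35.0


def preset(name: str) -> Preset:
    """Named study conditions: ``oxic95``, ``microoxic1``, ``anoxic0``."""
    if name == "oxic95":
        return Preset(
            name,
            KineticParams(lag=8.0),
            ReactorConfig(),
            ControllerConfig(set_point=95.0),
            SensorModel(noise_sd=0.5),
            c0=95.0,
        )
    if name == "microoxic1":
        return Preset(
            name,
            KineticParams(lag=8.0),
            ReactorConfig(),
            ControllerConfig(set_point=1.0),
            SensorModel(noise_sd=0.2),
            c0=1.0,
        )
    if name == "anoxic0":
        return Preset(
            name,
            KineticParams(lag=13.0),
            ReactorConfig(gas_o2_fraction=0.0, nitrate_mM=10.0),
            FixedActuation(rpm=100.0, airflow=0.2),
            SensorModel(noise_sd=0.2),
            c0=0.0,
        )
    raise KeyError(f"unknown preset {name!r}; known: oxic95, microoxic1, anoxic0")


def run_preset(name: str, seed: int = 0, horizon: float | None = None) -> FermentationRecord:
    """Simulate a named preset end to end."""
    p = preset(name)
    return simulate_batch(
        p.params,
        p.reactor,
        p.control,
        horizon=horizon if horizon is not None else p.horizon,
        seed=seed,
        sensor=p.sensor,
        c0=p.c0,
        label=name,
    )
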