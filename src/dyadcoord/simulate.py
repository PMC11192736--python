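"""Synthetic dyadic-study generator.

Generates complete studies — paired movement traces, gaze AOI series and a
covariate table — with the statistical structure the analysis pipeline
assumes, so every stage can be exercised without any external data.

The movement model is a stochastic Kuramoto-type phase pair: the avatar is
a metronome-paced oscillator (84 bpm -> 1.4 Hz) with a small smooth
frequency jitter; the participant's phase follows

    d(theta_p) = [omega_p + K sin(theta_a - theta_p)] dt + sigma_eta dW

integrated by Euler-Maruyama at the capture rate (50 Hz), with the natural
frequency omega_p detuned per participant and displacement
x = A sin(theta_p) plus measurement noise. The coupling strength K carries
all condition and covariate effects:

    K = K0 + dK_int*[intentional] + dK_direct*[direct]
        + b_lsas_averted*lsas_c*[averted] + b_lsas_direct*lsas_c*[direct]
        + b_aq*aq_c,     floored at 0.

Questionnaire covariates are drawn from truncated normals whose underlying
parameters are solved so the *truncated* mean and SD match the calibration
targets (LSAS M = 55.43, SD = 23.52 on [9, 119]; AQ M = 9.99, SD = 4.83 on
[1, 25]). Gaze is a two-state avatar/room Markov chain whose stationary
avatar-probability is a logistic function of condition and AQ, giving
geometric dwell times.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, IntegrationError
from .gaze import AOISeries
from .phase import instantaneous_phase
from .trace import MovementTrace, TrialPair

__all__ = [
    "SimConfig",
    "TruthRecord",
    "generate_covariates",
    "simulate_avatar",
    "simulate_participant",
    "simulate_dyad_trial",
    "simulate_gaze",
    "generate_study",
]

TRIALS = ("spontaneous", "intentional")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the study conditions.

    Coupling coefficients are in rad/s (per centred covariate point where
    applicable); process noise is in rad/sqrt(s); detuning SD in Hz.
    """

    n_participants: int = 134
    fs: float = 50.0
    trial_s: float = 90.0
    metronome_bpm: float = 84.0
    amplitude: float = 1.0
    process_noise_sd: float = 0.7
    measurement_noise_sd: float = 0.05
    detuning_sd_hz: float = 0.05
    freq_jitter: float = 0.01  # fractional SD of smooth avatar frequency jitter
    # coupling model
    k0: float = 1.0
    dk_intentional: float = 2.0
    dk_direct: float = 0.5
    beta_lsas_averted: float = 0.02
    beta_lsas_direct: float = -0.005
    beta_aq: float = -0.01
    # gaze model (logit scale; dwell in samples)
    gaze_base: float = 0.8
    gaze_shift_direct: float = 0.7
    gaze_shift_intentional: float = 0.5
    gaze_slope_aq: float = -0.06
    gaze_dwell_samples: float = 100.0
    # covariate calibration (printed sample moments)
    lsas_mean: float = 55.43
    lsas_sd: float = 23.52
    lsas_bounds: tuple[float, float] = (9.0, 119.0)
    aq_mean: float = 9.99
    aq_sd: float = 4.83
    aq_bounds: tuple[float, float] = (1.0, 25.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fs, self.trial_s, self.metronome_bpm) <= 0:
            raise ConfigError("fs, trial_s and metronome_bpm must be positive")
        for name in ("process_noise_sd", "measurement_noise_sd",
                     "detuning_sd_hz", "freq_jitter"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("lsas_bounds", "aq_bounds"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ConfigError(f"{name} must be ordered (lo < hi)")

    @property
    def f0(self) -> float:
        """Metronome frequency in Hz (bpm / 60)."""
        return self.metronome_bpm / 60.0

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_s * self.fs))


@dataclass
class TruthRecord:
    """Ground truth stored per simulated trial for recovery testing."""

    participant_id: str
    trial: str
    K: float
    K_raw: float
    floored: bool
    detuning_hz: float
    seed: int


@lru_cache(maxsize=16)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Solve for the underlying (mu, sigma) of a truncated normal whose
    truncated mean/SD equal the targets."""
    if not lo < mean < hi:
        raise ConfigError(f"target mean {mean} outside bounds ({lo}, {hi})")

    def residual(v):
        mu, log_sig = v
        sig = math.exp(log_sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, var = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - mean, math.sqrt(var) - sd]

    sol = optimize.root(residual, x0=[mean, math.log(sd)], tol=1e-12)
    if not sol.success:
        raise ConfigError(
            f"could not calibrate truncated normal to M={mean}, SD={sd} on "
            f"[{lo}, {hi}]: {sol.message}"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _draw_truncnorm(rng, n, mean, sd, bounds):
    mu, sig = _truncnorm_params(mean, sd, bounds[0], bounds[1])
    a, b = (bounds[0] - mu) / sig, (bounds[1] - mu) / sig
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sig, size=n, random_state=rng)


def generate_covariates(n: int, config: SimConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Covariate table: balanced gaze assignment plus LSAS and AQ draws."""
    cfg = config or SimConfig()
    if n < 2:
        raise ConfigError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    lsas = _draw_truncnorm(rng, n, cfg.lsas_mean, cfg.lsas_sd, cfg.lsas_bounds)
    aq = _draw_truncnorm(rng, n, cfg.aq_mean, cfg.aq_sd, cfg.aq_bounds)
    conditions = np.array(
        ["direct"] * ((n + 1) // 2) + ["averted"] * (n // 2), dtype=object
    )
    rng.shuffle(conditions)
    width = max(3, len(str(n)))
    return pd.DataFrame({
        "participant_id": [f"p{i + 1:0{width}d}" for i in range(n)],
        "gaze_condition": conditions,
        "lsas": lsas,
        "aq": aq,
    })


def _smooth_jitter(rng, n: int, fs: float, sd: float, clip: float = 0.02) -> np.ndarray:
    """Slowly varying fractional frequency jitter with the given SD."""
    if sd == 0:
        return np.zeros(n)
    from scipy import signal as _sig

    white = rng.standard_normal(n)
    sos = _sig.butter(2, 0.1, btype="low", fs=fs, output="sos")
    smooth = _sig.sosfiltfilt(sos, white)
    s = smooth.std()
    if s > 0:
        smooth = smooth / s * sd
    return np.clip(smooth, -clip, clip)


def simulate_avatar(
    config: SimConfig | None = None,
    seed: int = 0,
    phase0: float | None = None,
    return_phase: bool = False,
):
    """Metronome-paced avatar oscillator: x = A sin(theta_a(t)).

    With ``freq_jitter = 0`` and a given ``phase0`` the trace is a
    deterministic pure sinusoid at the metronome frequency.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    if phase0 is None:
        phase0 = float(rng.uniform(0, 2 * np.pi))
    jit = _smooth_jitter(rng, n, cfg.fs, cfg.freq_jitter)
    f_inst = cfg.f0 * (1.0 + jit)
    theta = phase0 + 2 * np.pi * (np.cumsum(f_inst) - f_inst[0]) / cfg.fs
    t = np.arange(n) / cfg.fs
    trace = MovementTrace(t=t, x=cfg.amplitude * np.sin(theta),
                          fs=cfg.fs, actor="avatar")
    return (trace, theta) if return_phase else trace


def simulate_participant(
    avatar,
    K: float,
    config: SimConfig | None = None,
    seed: int = 0,
    detuning_hz: float | None = None,
) -> MovementTrace:
    """Participant oscillator phase-coupled to the avatar with strength K.

    ``avatar`` may be the avatar phase array or a MovementTrace (its phase
    is then recovered via the Hilbert transform). ``detuning_hz`` defaults
    to a draw from N(0, detuning_sd_hz).
    """
    cfg = config or SimConfig()
    if K < 0:
        raise ConfigError("coupling K must be >= 0")
    theta_a = (instantaneous_phase(avatar)
               if isinstance(avatar, MovementTrace) else np.asarray(avatar, float))
    n = len(theta_a)
    rng = np.random.default_rng(seed)
    if detuning_hz is None:
        detuning_hz = float(rng.normal(0.0, cfg.detuning_sd_hz))
    omega_p = 2 * np.pi * (cfg.f0 + detuning_hz)
    dt = 1.0 / cfg.fs
    kicks = cfg.process_noise_sd * math.sqrt(dt) * rng.standard_normal(n)
    theta_p = np.empty(n)
    theta_p[0] = rng.uniform(0, 2 * np.pi)
    for i in range(1, n):
        step = (omega_p + K * math.sin(theta_a[i - 1] - theta_p[i - 1])) * dt + kicks[i]
        if abs(step) > math.pi:
            raise IntegrationError(
                f"unstable integration step |dtheta| = {abs(step):.3f} > pi "
                f"at sample {i} (K = {K})"
            )
        theta_p[i] = theta_p[i - 1] + step
    x = cfg.amplitude * np.sin(theta_p)
    if cfg.measurement_noise_sd > 0:
        x = x + cfg.measurement_noise_sd * rng.standard_normal(n)
    t = np.arange(n) / cfg.fs
    return MovementTrace(t=t, x=x, fs=cfg.fs, actor="participant")


def _coupling(row, trial_type: str, cfg: SimConfig) -> tuple[float, float, bool]:
    lsas_c = float(row["lsas"]) - cfg.lsas_mean
    aq_c = float(row["aq"]) - cfg.aq_mean
    direct = 1.0 if row["gaze_condition"] == "direct" else 0.0
    averted = 1.0 - direct
    intentional = 1.0 if trial_type == "intentional" else 0.0
    k_raw = (cfg.k0
             + cfg.dk_intentional * intentional
             + cfg.dk_direct * direct
             + cfg.beta_lsas_averted * lsas_c * averted
             + cfg.beta_lsas_direct * lsas_c * direct
             + cfg.beta_aq * aq_c)
    k = max(0.0, k_raw)
    return k, k_raw, k_raw < 0.0


def simulate_dyad_trial(
    participant_row,
    trial_type: str,
    config: SimConfig | None = None,
    seed: int = 0,
) -> tuple[TrialPair, TruthRecord]:
    """One trial: avatar + coupled participant, with the realised K recorded."""
    cfg = config or SimConfig()
    if trial_type not in TRIALS:
        raise ConfigError(f"trial_type must be one of {TRIALS}")
    k, k_raw, floored = _coupling(participant_row, trial_type, cfg)
    ss = np.random.SeedSequence(seed)
    seed_a, seed_p, seed_d = [int(s.generate_state(1)[0] % (2**31))
                              for s in ss.spawn(3)]
    avatar, theta_a = simulate_avatar(cfg, seed=seed_a, return_phase=True)
    detuning = float(np.random.default_rng(seed_d).normal(0.0, cfg.detuning_sd_hz))
    participant = simulate_participant(theta_a, k, cfg, seed=seed_p,
                                       detuning_hz=detuning)
    pid = str(participant_row.get("participant_id", ""))
    trial_id = f"{pid}_{trial_type}"
    pair = TrialPair(
        participant=participant, avatar=avatar,
        gaze_condition=str(participant_row["gaze_condition"]),
        coordination=trial_type, trial_id=trial_id,
    )
    truth = TruthRecord(participant_id=pid, trial=trial_type, K=k, K_raw=k_raw,
                        floored=floored, detuning_hz=detuning, seed=seed)
    return pair, truth


def simulate_gaze(
    participant_row,
    trial_type: str,
    config: SimConfig | None = None,
    seed: int = 0,
) -> AOISeries:
    """Two-state avatar/room Markov chain with geometric dwell times.

    The stationary avatar-probability is
    logistic(base + shift_direct*[direct] + shift_intentional*[intentional]
    + slope_aq*aq_c).
    """
    cfg = config or SimConfig()
    if trial_type not in TRIALS:
        raise ConfigError(f"trial_type must be one of {TRIALS}")
    aq_c = float(participant_row["aq"]) - cfg.aq_mean
    direct = 1.0 if participant_row["gaze_condition"] == "direct" else 0.0
    intentional = 1.0 if trial_type == "intentional" else 0.0
    logit = (cfg.gaze_base + cfg.gaze_shift_direct * direct
             + cfg.gaze_shift_intentional * intentional
             + cfg.gaze_slope_aq * aq_c)
    p_avatar = 1.0 / (1.0 + math.exp(-logit))
    tau = cfg.gaze_dwell_samples
    leave_avatar = min(1.0, (1.0 - p_avatar) / tau)
    leave_room = min(1.0, p_avatar / tau)

    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    u = rng.random(n)
    state = np.empty(n, dtype=bool)  # True = avatar
    state[0] = u[0] < p_avatar
    for i in range(1, n):
        if state[i - 1]:
            state[i] = u[i] >= leave_avatar
        else:
            state[i] = u[i] < leave_room
    labels = np.where(state, "avatar", "room").astype(object)
    return AOISeries(t=np.arange(n) / cfg.fs, aoi=labels)


def generate_study(config: SimConfig | None = None, out_dir=None):
    """Generate a full synthetic study directory.

    Layout: ``covariates.csv``, ``movement/<pid>_<trial>.csv`` (combined
    ``t,participant,avatar``), ``aoi/<pid>_<trial>.csv``, ``truth.csv`` and
    a flat ``manifest.txt`` with the config and per-trial seeds. Trial
    order is fixed: spontaneous first. Fully reproducible from
    (config, master seed).
    """
    from .io import write_aoi_csv, write_covariates_csv, write_pair_csv

    cfg = config or SimConfig()
    out = Path(out_dir)
    (out / "movement").mkdir(parents=True, exist_ok=True)
    (out / "aoi").mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(cfg.seed)
    cov_seed = int(master.integers(2**31))
    covariates = generate_covariates(cfg.n_participants, cfg, seed=cov_seed)
    write_covariates_csv(covariates, out / "covariates.csv")

    truths = []
    for _, row in covariates.iterrows():
        for trial_type in TRIALS:  # fixed order: spontaneous first
            trial_seed = int(master.integers(2**31))
            gaze_seed = int(master.integers(2**31))
            pair, truth = simulate_dyad_trial(row, trial_type, cfg, seed=trial_seed)
            aoi = simulate_gaze(row, trial_type, cfg, seed=gaze_seed)
            stem = f"{row['participant_id']}_{trial_type}"
            write_pair_csv(pair, out / "movement" / f"{stem}.csv")
            write_aoi_csv(aoi, out / "aoi" / f"{stem}.csv")
            rec = asdict(truth)
            rec["gaze_seed"] = gaze_seed
            truths.append(rec)
    truth_df = pd.DataFrame(truths)
    truth_df.to_csv(out / "truth.csv", index=False)

    with open(out / "manifest.txt", "w") as fh:
        fh.write("format=dyadcoord-study-v1\n")
        for key, val in asdict(cfg).items():
            fh.write(f"config.{key}={val}\n")
        fh.write(f"covariate_seed={cov_seed}\n")
        fh.write(f"n_trials={len(truth_df)}\n")
    return covariates, truth_df
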