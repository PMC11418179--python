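"""Synthetic strike trajectories and bite outcomes with known ground truth.

The generator emulates the statistical structure the analysis assumes —
smooth unimodal gape/protrusion opening profiles with per-species means and
per-individual random intercepts, constant forward (ram) body motion,
isotropic Gaussian landmark noise, and bite dimensions produced by a
configurable (optionally bimodal) performance function of peak gape and
peak protrusion plus residual noise — so every pipeline stage is testable
by parameter and peak recovery without any external data.

Trajectory construction.  Gape opens along a raised cosine
``g(t) = g0 + (G - g0) * (1 - cos(pi t / T)) / 2`` to its peak ``G`` at
frame ``T`` and closes symmetrically; protrusion follows an analogous
profile.  The 20%-of-peak-gape crossing is placed *exactly on an integer
frame* by solving the profile for the baseline gape ``g0`` given the
crossing frame: the discrete extractor (last upward threshold crossing,
linearly interpolated) is then exactly invertible at zero noise, which is
what makes 1e-6-level kinematic recovery a meaningful oracle for a sampled
signal.  The jaw-joint and opercle landmarks are placed so the interior
jaw angle follows a programmed profile reaching its minimum exactly at
peak gape, inside the TTPG window.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_landmarks import (
    CANONICAL_NODES,
    CalibrationRecord,
    LandmarkTrack,
    calibrate,
    write_landmark_file,
)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species strike-level kinematic means and SDs."""

    peak_gape_mm: tuple[float, float]  # (mean, sd)
    peak_protrusion_mm: tuple[float, float]
    min_jaw_angle_deg: tuple[float, float]
    ttpg_ms: tuple[float, float]
    ram_speed_m_s: tuple[float, float]
    n_individuals: int


@dataclass(frozen=True)
class PerformancePeak:
    center_gape: float
    center_protrusion: float
    amplitude: float
    width: float


@dataclass
class SimulationDesign:
    """Everything the synthetic study generator needs.

    Defaults mirror the real study design qualitatively: four groups
    (the scale-eater group with roughly twice the gape and far more
    protrusion than the generalist), 37 individuals, 227 filmed strikes of
    which 130 carry bite dimensions, strikes per individual in [1, 10],
    1100 fps filming, and a bimodal performance function with a
    small-gape/small-protrusion peak and a large-gape/large-protrusion
    peak separated by a valley.  All numbers are explicit, configurable
    defaults of this package, not estimates taken from any dataset.
    """

    species: dict[str, SpeciesParams] = field(default_factory=lambda: {
        "generalist": SpeciesParams((2.5, 0.5), (2.0, 0.5), (120.0, 8.0), (10.0, 2.0), (0.15, 0.05), 8),
        "molluscivore": SpeciesParams((2.2, 0.4), (1.8, 0.4), (115.0, 8.0), (10.0, 2.0), (0.12, 0.04), 8),
        "scale_eater": SpeciesParams((5.0, 1.0), (6.5, 1.5), (100.0, 10.0), (9.0, 2.0), (0.20, 0.06), 9),
        "hybrid": SpeciesParams((3.5, 1.2), (4.0, 1.8), (110.0, 10.0), (9.5, 2.0), (0.17, 0.05), 12),
    })
    individual_intercept_sd: dict[str, float] = field(default_factory=lambda: {
        "peak_gape_mm": 0.3,
        "peak_protrusion_mm": 0.4,
        "min_jaw_angle_deg": 4.0,
        "ttpg_ms": 0.8,
        "ram_speed_m_s": 0.02,
    })
    n_strikes: int = 227
    n_bite_strikes: int = 130
    strikes_per_individual: tuple[int, int] = (1, 10)
    landmark_noise_sd_mm: float = 0.05
    frame_rate_hz: float = 1100.0
    px_per_mm: float = 40.0
    performance_peaks: list[PerformancePeak] = field(default_factory=lambda: [
        PerformancePeak(2.5, 2.0, 4.0, 1.1),
        PerformancePeak(5.0, 6.5, 6.5, 1.5),
    ])
    performance_linear: dict[str, float] = field(default_factory=dict)
    performance_residual_sd: float = 0.8
    performance_individual_sd: float = 0.3
    strike_type_probs: dict[str, float] = field(default_factory=lambda: {
        "edge": 0.45, "corner": 0.25, "scrape": 0.20, "miss": 0.10,
    })
    seed: int = 0

    def __post_init__(self):
        total = sum(self.strike_type_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"strike-type probabilities sum to {total}, not 1")
        if not self.performance_peaks:
            raise SimulationError("need at least one performance peak")
        for sd in self.individual_intercept_sd.values():
            if sd < 0:
                raise SimulationError("negative SD in design")
        if self.landmark_noise_sd_mm < 0 or self.performance_residual_sd < 0:
            raise SimulationError("negative SD in design")

    @property
    def n_individuals(self) -> int:
        return sum(s.n_individuals for s in self.species.values())

    def performance_value(self, gape: np.ndarray, prot: np.ndarray) -> np.ndarray:
        """Noise-free expected bite length at given kinematics."""
        gape = np.asarray(gape, dtype=float)
        prot = np.asarray(prot, dtype=float)
        out = np.zeros(np.broadcast(gape, prot).shape)
        for p in self.performance_peaks:
            out = out + p.amplitude * np.exp(
                -((gape - p.center_gape) ** 2 + (prot - p.center_protrusion) ** 2)
                / (2 * p.width**2)
            )
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["species"] = {
            k: SpeciesParams(**{
                f: tuple(v[f]) if isinstance(v[f], list) else v[f]
                for f in v
            })
            for k, v in raw["species"].items()
        }
        raw["performance_peaks"] = [PerformancePeak(**p) for p in raw["performance_peaks"]]
        if "strikes_per_individual" in raw:
            raw["strikes_per_individual"] = tuple(raw["strikes_per_individual"])
        return cls(**raw)


@dataclass
class StrikeKinParams:
    """True kinematics of one simulated strike."""

    peak_gape_mm: float
    peak_protrusion_mm: float
    min_jaw_angle_deg: float
    ttpg_ms: float
    ram_speed_m_s: float
    open_angle_deg: float = 150.0
    protrusion_baseline_frac: float = 0.4


@dataclass
class GroundTruth:
    strike_id: str
    peak_gape_mm: float
    peak_protrusion_mm: float
    min_jaw_angle_deg: float
    ttpg_ms: float
    ram_speed_m_s: float
    peak_gape_frame: int
    t20_frame: int


# ---------------------------------------------------------------------------
# single-strike trajectory
# ---------------------------------------------------------------------------


def _raised_cosine(t: np.ndarray, lo: float, hi: float, T: float) -> np.ndarray:
    """Open lo -> hi over [0, T], close symmetrically over [T, 2T]."""
    up = lo + (hi - lo) * 0.5 * (1 - np.cos(np.pi * np.minimum(t, T) / T))
    down = lo + (hi - lo) * 0.5 * (1 + np.cos(np.pi * (np.minimum(t, 2 * T) - T) / T))
    return np.where(t <= T, up, np.where(t <= 2 * T, down, lo))


def simulate_strike_track(
    kin: StrikeKinParams,
    noise_sd_mm: float = 0.0,
    frame_rate_hz: float = 1100.0,
    seed: int = 0,
    *,
    px_per_mm: float = 40.0,
    strike_id: str = "sim",
) -> tuple[LandmarkTrack, GroundTruth]:
    """Simulate one strike as a pixel-space landmark track plus ground truth.

    The returned track has ``units='px'`` at scale ``px_per_mm`` (calibrate
    with a matching :class:`CalibrationRecord` before extraction).  The
    ground-truth TTPG is the analytic 20% crossing of the profile, which by
    construction falls on an integer frame.
    """
    rng = np.random.default_rng(seed)
    G = kin.peak_gape_mm
    dt_ms = 1000.0 / frame_rate_hz
    fr_ttpg = int(round(kin.ttpg_ms / dt_ms))
    if fr_ttpg < 3:
        raise SimulationError(
            f"TTPG of {kin.ttpg_ms:.2f} ms spans {fr_ttpg} frames at "
            f"{frame_rate_hz:.0f} fps; need >= 3 for a resolvable 20% crossing"
        )
    if G <= 0 or kin.peak_protrusion_mm <= 0:
        raise SimulationError("peak gape and protrusion must be positive")
    t20 = max(1, round(0.25 * fr_ttpg))
    T = t20 + fr_ttpg  # peak gape frame
    x = t20 / T
    s = 0.5 * (1 - np.cos(np.pi * x))
    if s >= 0.2:
        raise SimulationError("infeasible profile: 20% crossing too close to peak")
    g0 = G * (0.2 - s) / (1 - s)  # baseline gape putting the crossing at t20
    n_frames = 2 * T + 1

    t = np.arange(n_frames, dtype=float)
    gape = _raised_cosine(t, g0, G, T)
    P = kin.peak_protrusion_mm
    p0 = kin.protrusion_baseline_frac * P
    prot = _raised_cosine(t, p0, P, T)

    # constant forward ram motion of the whole head; m/s == mm/ms
    v_mm_frame = kin.ram_speed_m_s * dt_ms
    pupil = np.column_stack([10.0 + v_mm_frame * t, np.full(n_frames, 10.0)])
    upper = pupil + np.column_stack([prot, np.zeros(n_frames)])
    lower = upper + np.column_stack([np.zeros(n_frames), gape])  # ventral = +y
    jaw_joint = pupil + np.array([-1.0, 2.5])

    # jaw angle profile: tied to gape so the minimum lands at peak gape,
    # inside the [t20, peak] window the extractor uses
    th0, thmin = kin.open_angle_deg, kin.min_jaw_angle_deg
    if not 0 < thmin <= th0 <= 180:
        raise SimulationError(
            f"need 0 < min angle <= open angle <= 180, got {thmin}, {th0}"
        )
    theta = np.radians(th0 - (th0 - thmin) * (gape - g0) / (G - g0))
    u = lower - jaw_joint
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rot = np.column_stack([
        cos_t * u[:, 0] - sin_t * u[:, 1],
        sin_t * u[:, 0] + cos_t * u[:, 1],
    ])
    opercle = jaw_joint + 3.0 * rot

    coords_mm = np.stack([upper, lower, pupil, opercle, jaw_joint], axis=1)
    if noise_sd_mm > 0:
        coords_mm = coords_mm + rng.normal(0.0, noise_sd_mm, coords_mm.shape)
    track = LandmarkTrack(
        strike_id=strike_id,
        coords=coords_mm * px_per_mm,
        frame_rate_hz=frame_rate_hz,
        units="px",
        node_names=CANONICAL_NODES,
    )
    truth = GroundTruth(
        strike_id=strike_id,
        peak_gape_mm=G,
        peak_protrusion_mm=P,
        min_jaw_angle_deg=thmin,
        ttpg_ms=fr_ttpg * dt_ms,
        ram_speed_m_s=kin.ram_speed_m_s,
        peak_gape_frame=T,
        t20_frame=t20,
    )
    return track, truth


# ---------------------------------------------------------------------------
# study-level simulation
# ---------------------------------------------------------------------------


def _allocate_strikes(rng, n_individuals: int, n_strikes: int, lo: int, hi: int) -> np.ndarray:
    """Strikes per individual in [lo, hi] summing exactly to n_strikes."""
    if not lo * n_individuals <= n_strikes <= hi * n_individuals:
        raise SimulationError("strike total incompatible with per-individual range")
    counts = rng.integers(lo, hi + 1, size=n_individuals)
    while counts.sum() != n_strikes:
        i = rng.integers(n_individuals)
        if counts.sum() > n_strikes and counts[i] > lo:
            counts[i] -= 1
        elif counts.sum() < n_strikes and counts[i] < hi:
            counts[i] += 1
    return counts


def simulate_kinematic_truth(design: SimulationDesign, seed: int | None = None) -> pd.DataFrame:
    """Per-strike true kinematic values for a whole study design.

    Species mean + individual random intercept + strike-level noise, with
    physical clamps (positive distances, feasible angles and timings).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    kin_vars = [
        "peak_gape_mm", "peak_protrusion_mm", "min_jaw_angle_deg",
        "ttpg_ms", "ram_speed_m_s",
    ]
    ind_counter = 0
    individuals = []
    for sp, params in design.species.items():
        for _ in range(params.n_individuals):
            intercepts = {
                v: rng.normal(0.0, design.individual_intercept_sd[v]) for v in kin_vars
            }
            individuals.append((f"ind{ind_counter:03d}", sp, params, intercepts))
            ind_counter += 1
    lo, hi = design.strikes_per_individual
    counts = _allocate_strikes(rng, len(individuals), design.n_strikes, lo, hi)
    strike_no = 0
    for (ind_id, sp, params, intercepts), k in zip(individuals, counts):
        for _ in range(k):
            means = {
                "peak_gape_mm": params.peak_gape_mm,
                "peak_protrusion_mm": params.peak_protrusion_mm,
                "min_jaw_angle_deg": params.min_jaw_angle_deg,
                "ttpg_ms": params.ttpg_ms,
                "ram_speed_m_s": params.ram_speed_m_s,
            }
            vals = {
                v: means[v][0] + intercepts[v] + rng.normal(0.0, means[v][1])
                for v in kin_vars
            }
            vals["peak_gape_mm"] = max(vals["peak_gape_mm"], 0.8)
            vals["peak_protrusion_mm"] = max(vals["peak_protrusion_mm"], 0.8)
            vals["min_jaw_angle_deg"] = float(np.clip(vals["min_jaw_angle_deg"], 40.0, 145.0))
            vals["ttpg_ms"] = max(vals["ttpg_ms"], 4.0)
            vals["ram_speed_m_s"] = max(vals["ram_speed_m_s"], 0.0)
            rows.append({
                "strike_id": f"strike{strike_no:04d}",
                "individual_id": ind_id,
                "species": sp,
                **vals,
            })
            strike_no += 1
    return pd.DataFrame(rows)


def simulate_performance(
    kin_truth: pd.DataFrame, design: SimulationDesign, seed: int = 0
) -> pd.DataFrame:
    """Bite dimensions for (a subset of) strikes from the performance function.

    Bite length is the Gaussian-peak performance function of true peak gape
    and protrusion, plus optional linear terms, a per-individual intercept
    and Gaussian residual noise, redrawn (not clipped) into [0, 15] mm so
    the cube bound creates no boundary atom.  Width is an individual-level
    constant plus small noise; depth is a fraction of length plus noise;
    misses have all dimensions zero.
    """
    rng = np.random.default_rng(seed)
    n = len(kin_truth)
    n_bite = min(design.n_bite_strikes, n)
    take = np.sort(rng.choice(n, size=n_bite, replace=False))
    sub = kin_truth.iloc[take].reset_index(drop=True)

    ind_ids = sub["individual_id"].unique()
    intercepts = dict(zip(
        ind_ids, rng.normal(0.0, design.performance_individual_sd, len(ind_ids))
    ))
    # bite width tracks the individual's typical gape (a morphology proxy)
    ind_gape = kin_truth.groupby("individual_id")["peak_gape_mm"].mean()
    types = list(design.strike_type_probs)
    probs = np.array([design.strike_type_probs[t] for t in types])

    rows = []
    for _, r in sub.iterrows():
        st = types[rng.choice(len(types), p=probs)]
        base = design.performance_value(r["peak_gape_mm"], r["peak_protrusion_mm"])
        for k, w in design.performance_linear.items():
            base = base + w * r[k]
        base = base + intercepts[r["individual_id"]]
        true_perf = float(base)
        if st == "miss":
            length = width = depth = 0.0
        else:
            for _ in range(1000):
                length = true_perf + rng.normal(0.0, design.performance_residual_sd)
                if 0.0 <= length <= 15.0:
                    break
            else:
                length = float(np.clip(true_perf, 0.0, 15.0))
            width = float(np.clip(
                0.8 * ind_gape[r["individual_id"]] + rng.normal(0.0, 0.15), 0.2, 15.0
            ))
            depth_frac = 0.25 if st != "scrape" else 0.06
            depth = float(np.clip(
                depth_frac * length + rng.normal(0.0, 0.1), 0.0, 15.0
            ))
        rows.append({
            "strike_id": r["strike_id"],
            "individual_id": r["individual_id"],
            "species": r["species"],
            "strike_type": st,
            "length_mm": length,
            "width_mm": width,
            "depth_mm": depth,
            "true_performance": true_perf,
        })
    return pd.DataFrame(rows)


@dataclass
class SyntheticStudy:
    design: SimulationDesign
    tracks: list[LandmarkTrack]  # pixel-space, as exported by a tracker
    calibration: CalibrationRecord
    truth: pd.DataFrame  # per-strike true kinematics (mm)
    bites: pd.DataFrame

    def calibrated_tracks(self) -> list[LandmarkTrack]:
        return [calibrate(t, self.calibration) for t in self.tracks]


def simulate_study(
    design: SimulationDesign | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> SyntheticStudy:
    """Generate a complete synthetic study (tracks + bite table + truth).

    With ``out_dir``, writes one HDF5 per strike under ``tracks/``, plus
    ``calibration.csv``, ``bites.csv`` and ``truth.csv`` — a
    self-describing study a fresh pipeline run can ingest end to end.
    """
    design = design or SimulationDesign()
    base_seed = design.seed if seed is None else seed
    truth_df = simulate_kinematic_truth(design, seed=base_seed)
    rng = np.random.default_rng(base_seed + 1)
    tracks = []
    records = []
    for i, r in truth_df.iterrows():
        kin = StrikeKinParams(
            peak_gape_mm=r["peak_gape_mm"],
            peak_protrusion_mm=r["peak_protrusion_mm"],
            min_jaw_angle_deg=r["min_jaw_angle_deg"],
            ttpg_ms=r["ttpg_ms"],
            ram_speed_m_s=r["ram_speed_m_s"],
        )
        tr, gt = simulate_strike_track(
            kin,
            noise_sd_mm=design.landmark_noise_sd_mm,
            frame_rate_hz=design.frame_rate_hz,
            seed=int(rng.integers(2**31 - 1)),
            px_per_mm=design.px_per_mm,
            strike_id=r["strike_id"],
        )
        tracks.append(tr)
        rec = r.to_dict()
        rec["ttpg_ms"] = gt.ttpg_ms  # snapped to the frame grid
        rec["peak_gape_frame"] = gt.peak_gape_frame
        rec["t20_frame"] = gt.t20_frame
        records.append(rec)
    truth_df = pd.DataFrame(records)
    bites = simulate_performance(truth_df, design, seed=base_seed + 2)
    cal = CalibrationRecord("session0", design.px_per_mm)
    study = SyntheticStudy(design, tracks, cal, truth_df, bites)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "tracks").mkdir(parents=True, exist_ok=True)
        for tr in tracks:
            write_landmark_file(tr, out / "tracks" / f"{tr.strike_id}.h5")
        pd.DataFrame(
            [{"session_id": cal.session_id, "px_per_mm": cal.px_per_mm}]
        ).to_csv(out / "calibration.csv", index=False)
        bites.to_csv(out / "bites.csv", index=False)
        truth_df.to_csv(out / "truth.csv", index=False)
        design.to_yaml(out / "design.yaml")
    return study


def study_checksum(study: SyntheticStudy) -> str:
    """Deterministic digest of all simulated coordinates and tables."""
    h = hashlib.sha256()
    for tr in study.tracks:
        h.update(tr.strike_id.encode())
        h.update(np.ascontiguousarray(tr.coords).tobytes())
    h.update(study.truth.round(12).to_csv(index=False).encode())
    h.update(study.bites.round(12).to_csv(index=False).encode())
    return h.hexdigest()
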