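"""Seeded synthetic data with ground truth for every pipeline stage.

Generators are pure functions of (spec, rng): the same seed reproduces
the same tables bitwise.  Every generated object is returned together
with the ground truth needed to validate the stage that consumes it, so
tests never have to read truth back out of the pipeline under test.

The R-R model is a sinusoid plus white noise at the beat rate,

    RR_k = mean_rr + A * sin(2*pi*f_resp*t_k) + eps_k,

chosen over integral-pulse-frequency modulation because its in-band
variance is available in closed form: A**2/2 from the oscillation, plus
the white noise's share of the band, ``noise_sd**2 * 2 * band_width /
beat_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import ECGRecord, RRSeries
from .interoception import STANDARD_INTERVALS_S
from .rsa import BLOCKS, CONDITIONS

__all__ = [
    "RRSimSpec",
    "CohortSimSpec",
    "synth_rr",
    "synth_ecg",
    "inject_artifacts",
    "synth_counting",
    "synth_cohort",
    "synth_session",
    "synth_proxemics_cells",
]

RESP_BAND = (0.12, 0.40)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class RRSimSpec:
    """Respiratory-modulated R-R series specification.

    Defaults emulate a resting young adult: 75 bpm (800 ms), a 40 ms
    respiratory oscillation at 0.25 Hz (15 breaths/min, mid-band), no
    broadband noise unless requested.
    """

    duration_s: float = 300.0
    mean_rr_ms: float = 800.0
    rsa_amplitude_ms: float = 40.0
    resp_frequency_hz: float = 0.25
    noise_sd_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.resp_frequency_hz < 0.5):
            raise ValueError("invalid spec: resp_frequency must lie in (0, 0.5) Hz")
        if self.mean_rr_ms <= self.rsa_amplitude_ms + 3 * self.noise_sd_ms:
            raise ValueError("invalid spec: intervals could become non-positive")
        if self.duration_s <= 0 or self.rsa_amplitude_ms < 0 or self.noise_sd_ms < 0:
            raise ValueError("invalid spec")


def synth_rr(spec: RRSimSpec, rng=0) -> tuple[RRSeries, dict]:
    """Generate a beat series; truth carries beat times and in-band variance.

    ``truth["inband_variance_ms2"]`` is the analytic respiratory-band
    variance of the underlying continuous modulation (A^2/2 plus the
    noise's in-band share); ``truth["mean_rr_ms"]`` supports predicting
    the linear-interpolation attenuation of the estimator.
    """
    rng = _rng(rng)
    t = 0.0
    times: list[float] = [0.0]
    intervals: list[int] = []
    total_ms = spec.duration_s * 1000.0
    while t < total_ms:
        rr = (
            spec.mean_rr_ms
            + spec.rsa_amplitude_ms
            * np.sin(2 * np.pi * spec.resp_frequency_hz * t / 1000.0)
            + (rng.normal(0.0, spec.noise_sd_ms) if spec.noise_sd_ms > 0 else 0.0)
        )
        rr = max(1.0, rr)
        rr_int = int(round(rr))
        intervals.append(rr_int)
        t += rr_int
        times.append(t)
    onsets = np.asarray(times[:-1])
    series = RRSeries(onsets, np.asarray(intervals))
    beat_rate = 1000.0 / spec.mean_rr_ms
    band_width = RESP_BAND[1] - RESP_BAND[0]
    noise_share = spec.noise_sd_ms**2 * 2 * band_width / beat_rate
    truth = {
        "beat_times_ms": series.beat_times,
        "inband_variance_ms2": spec.rsa_amplitude_ms**2 / 2 + noise_share,
        "mean_rr_ms": spec.mean_rr_ms,
        "resp_frequency_hz": spec.resp_frequency_hz,
    }
    return series, truth


def _qrs_template(sampling_rate: float, width_ms: float = 40.0) -> np.ndarray:
    """Raised-cosine R spike, unit amplitude, centred peak."""
    half = int(round(width_ms / 2 * sampling_rate / 1000.0))
    n = 2 * half + 1
    return 0.5 * (1 + np.cos(np.linspace(-np.pi, np.pi, n)))


def synth_ecg(
    rr: RRSeries,
    sampling_rate: float = 1000.0,
    template: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng=0,
) -> tuple[ECGRecord, np.ndarray]:
    """Plant a QRS-like template at every beat time; return the planted
    R-peak times (ms) for detector validation."""
    rng = _rng(rng)
    if len(rr) < 1:
        raise ValueError("nothing to synthesize: empty RR series")
    template = _qrs_template(sampling_rate) if template is None else np.asarray(template)
    width_ms = 1000.0 * template.size / sampling_rate
    if width_ms >= float(np.min(rr.intervals)):
        raise ValueError("template overlap: template wider than the shortest interval")
    beats = rr.beat_times
    pad_ms = 500.0
    n = int(round((beats[-1] - beats[0] + 2 * pad_ms) * sampling_rate / 1000.0)) + 1
    sig = np.zeros(n)
    half = template.size // 2
    planted = []
    for b in beats:
        centre = int(round((b - beats[0] + pad_ms) * sampling_rate / 1000.0))
        a, z = centre - half, centre - half + template.size
        if a < 0 or z > n:
            continue
        sig[a:z] += template
        planted.append(beats[0] - pad_ms + 1000.0 * centre / sampling_rate)
    if noise_sd > 0:
        sig += rng.normal(0.0, noise_sd, size=n)
    rec = ECGRecord(sig, sampling_rate, start_time=beats[0] - pad_ms)
    return rec, np.asarray(planted)


def inject_artifacts(
    rr: RRSeries,
    kind: str,
    positions: Sequence[int],
    rng=0,
) -> tuple[RRSeries, list[dict]]:
    """Corrupt a beat series with missed or spurious beats.

    ``missed_beat`` merges the interval at each position with its
    successor (the R peak between them went undetected); ``spurious_beat``
    splits the interval at each position at a uniform random point.
    Positions index intervals and must be interior (not first or last).
    Returns the corrupted series and a truth log of each corruption.
    """
    rng = _rng(rng)
    if kind not in {"missed_beat", "spurious_beat"}:
        raise ValueError(f"unknown artifact kind {kind!r}")
    vals = list(rr.intervals.astype(int))
    log: list[dict] = []
    for pos in sorted(positions, reverse=True):
        if pos <= 0 or pos >= len(vals) - 1:
            raise ValueError("cannot corrupt boundary interval")
        if kind == "missed_beat":
            merged = vals[pos] + vals[pos + 1]
            log.append({"kind": kind, "position": pos, "original": (vals[pos], vals[pos + 1])})
            vals[pos : pos + 2] = [merged]
        else:
            u = float(rng.uniform(0.05, 0.95))
            a = max(1, int(round(vals[pos] * u)))
            b = vals[pos] - a
            if b < 1:
                a, b = vals[pos] - 1, 1
            log.append({"kind": kind, "position": pos, "original": vals[pos], "split": (a, b)})
            vals[pos : pos + 1] = [a, b]
    arr = np.asarray(vals, dtype=np.int64)
    onsets = rr.onset_times[0] + np.concatenate(([0], np.cumsum(arr[:-1])))
    return RRSeries(onsets, arr), log


def synth_counting(
    rr: RRSeries,
    accuracy: float,
    rng=0,
    interval_lengths_s: Sequence[float] = STANDARD_INTERVALS_S,
    start_s: float = 0.0,
    gap_s: float = 5.0,
) -> pd.DataFrame:
    """Simulate a heartbeat-counting session over an RR recording.

    Intervals are placed sequentially with ``gap_s`` between them; the
    recorded count is the true number of beats in each half-open window,
    and the simulated perceiver under-reports by a uniform fraction of
    the gap to perfection:  counted = round(recorded * (1 - (1 -
    accuracy) * u)), u ~ U(0, 1), so expected accuracy rises with the
    ``accuracy`` parameter.
    """
    from .interoception import recorded_beats_from_rr

    if not (0 <= accuracy <= 1):
        raise ValueError("accuracy must lie in [0, 1]")
    rng = _rng(rng)
    rows = []
    t = rr.onset_times[0] + start_s * 1000.0
    for length in interval_lengths_s:
        recorded = recorded_beats_from_rr(rr, t, length * 1000.0)
        u = float(rng.uniform())
        counted = int(round(recorded * (1.0 - (1.0 - accuracy) * u)))
        rows.append(
            {
                "interval_s": length,
                "onset_ms": t,
                "recorded_beats": recorded,
                "counted_beats": counted,
            }
        )
        t += (length + gap_s) * 1000.0
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _group_defaults() -> dict:
    # Group-level moments taken from the study population this emulates:
    # 24 restrictive-anorexia patients vs 25 healthy controls, all women.
    return {
        "AN": {
            "n": 24,
            "ia_rsa_correlation": -0.4,
            "distance_rsa_slope_std": 0.0,
            "rsa_mean": 3.7,
            "rsa_sd": 1.4,
            "ia_mean": 0.53,
            "ia_sd": 0.17,
            "age": (23.0, 9.3),
            "bmi": (16.1, 1.5),
            "stai_trait": (61.3, 10.8),
            "stai_state": (49.8, 10.8),
            "bdi": (27.2, 13.2),
        },
        "HC": {
            "n": 25,
            "ia_rsa_correlation": 0.4,
            "distance_rsa_slope_std": -0.47,
            "rsa_mean": 5.3,
            "rsa_sd": 1.4,
            "ia_mean": 0.41,
            "ia_sd": 0.17,
            "age": (22.9, 5.5),
            "bmi": (21.0, 2.9),
            "stai_trait": (40.3, 11.0),
            "stai_state": (35.0, 13.5),
            "bdi": (6.5, 6.5),
        },
    }


@dataclass(frozen=True)
class CohortSimSpec:
    """Two-group cohort with programmable IA-RSA correlation structure.

    ``groups`` maps group label to its parameters (see
    ``CohortSimSpec().groups`` for the full dictionary); the defaults
    plant a +0.4 IA-RSA correlation in HC and -0.4 in AN, and a
    standardized comfort-distance-on-RSA slope of -0.47 in HC only.
    """

    groups: dict = field(default_factory=_group_defaults)
    distance_mean_cm: float = 126.0
    distance_sd_cm: float = 30.0

    def __post_init__(self) -> None:
        for label, g in self.groups.items():
            if abs(g["ia_rsa_correlation"]) >= 1:
                raise ValueError(f"invalid correlation spec for group {label!r}")
            if g["n"] < 4:
                raise ValueError("n_per_group must be >= 4")


def synth_cohort(spec: CohortSimSpec | None = None, rng=0) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table; truth echoes the planted parameters.

    Per group, (IA, resting RSA) are bivariate normal with the planted
    correlation; comfort distance is linear in RSA with the group's
    standardized slope plus independent noise; covariates are independent
    normals.  IA is clipped into [0, 1] (rare at the default moments).
    """
    spec = spec or CohortSimSpec()
    rng = _rng(rng)
    rows = []
    sid = 0
    for label, g in spec.groups.items():
        n = int(g["n"])
        rho = float(g["ia_rsa_correlation"])
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        ia = np.clip(g["ia_mean"] + g["ia_sd"] * z[:, 0], 0.0, 1.0)
        rsa = g["rsa_mean"] + g["rsa_sd"] * z[:, 1]
        b = float(g["distance_rsa_slope_std"])
        z_rsa = (rsa - g["rsa_mean"]) / g["rsa_sd"]
        resid_sd = np.sqrt(max(1e-12, 1.0 - b * b))
        dist = spec.distance_mean_cm + spec.distance_sd_cm * (
            b * z_rsa + resid_sd * rng.normal(size=n)
        )
        dist = np.maximum(dist, 30.0)
        for i in range(n):
            sid += 1
            rows.append(
                {
                    "subject_id": f"S{sid:03d}",
                    "group": label,
                    "age": float(rng.normal(*g["age"])),
                    "bmi": float(rng.normal(*g["bmi"])),
                    "stai_trait": float(rng.normal(*g["stai_trait"])),
                    "stai_state": float(rng.normal(*g["stai_state"])),
                    "bdi": float(rng.normal(*g["bdi"])),
                    "ia": float(ia[i]),
                    "resting_rsa": float(rsa[i]),
                    "comfort_distance": float(dist[i]),
                }
            )
    truth = {
        label: {
            "ia_rsa_correlation": g["ia_rsa_correlation"],
            "distance_rsa_slope_std": g["distance_rsa_slope_std"],
        }
        for label, g in spec.groups.items()
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Full sessions and proxemics cell tables
# ---------------------------------------------------------------------------

def synth_session(
    rng=0,
    baseline_amplitude_ms: float = 60.0,
    condition_amplitudes_ms: dict[str, float] | float = 50.0,
    mean_rr_ms: float = 800.0,
    resp_frequency_hz: float = 0.25,
    noise_sd_ms: float = 0.0,
    lead_s: float = 15.0,
    trial_s: float = 30.0,
    iti_s: float = 15.0,
    rest_s: float = 120.0,
) -> tuple[RRSeries, pd.DataFrame, dict]:
    """One full proxemics session: lead-in, 2-min baseline, two 16-trial
    blocks (thin/fat x 4 conditions x 4 trials), 2-min recovery, lead-out.

    The respiratory-band amplitude switches per segment: baseline/recovery
    use ``baseline_amplitude_ms``; each condition uses its entry in
    ``condition_amplitudes_ms`` (a scalar applies to all).  Returns the
    RR series, the event table (trial epochs plus four 30-s epochs each
    for baseline and recovery), and the truth amplitudes per label.
    """
    rng = _rng(rng)
    if np.isscalar(condition_amplitudes_ms):
        amp_by_cond = {c: float(condition_amplitudes_ms) for c in CONDITIONS}
    else:
        amp_by_cond = {c: float(condition_amplitudes_ms[c]) for c in CONDITIONS}

    # Build the segment schedule: (label, duration_ms, amplitude).
    segments: list[tuple[str, float, float]] = [("lead", lead_s * 1000, 0.0)]
    epoch = trial_s * 1000
    for k in range(int(rest_s * 1000 // epoch)):
        segments.append((f"baseline[{k}]", epoch, baseline_amplitude_ms))
    for block in BLOCKS:
        order = list(np.repeat(CONDITIONS, 4))
        rng.shuffle(order)
        for cond in order:
            segments.append((f"{block}:{cond}", epoch, amp_by_cond[cond]))
            segments.append(("iti", iti_s * 1000, baseline_amplitude_ms))
    for k in range(int(rest_s * 1000 // epoch)):
        segments.append((f"recovery[{k}]", epoch, baseline_amplitude_ms))
    segments.append(("tail", lead_s * 1000, 0.0))

    bounds = np.cumsum([0.0] + [d for _, d, _ in segments])
    amps = [a for _, _, a in segments]

    def amp_at(t: float) -> float:
        idx = int(np.searchsorted(bounds, t, side="right")) - 1
        return amps[min(max(idx, 0), len(amps) - 1)]

    t = 0.0
    times = [0.0]
    intervals = []
    while t < bounds[-1]:
        rr = (
            mean_rr_ms
            + amp_at(t) * np.sin(2 * np.pi * resp_frequency_hz * t / 1000.0)
            + (rng.normal(0.0, noise_sd_ms) if noise_sd_ms > 0 else 0.0)
        )
        rr_int = max(1, int(round(rr)))
        intervals.append(rr_int)
        t += rr_int
        times.append(t)
    series = RRSeries(np.asarray(times[:-1]), np.asarray(intervals))

    ev_rows = []
    truth_amp = {}
    for (label, dur, amp), onset in zip(segments, bounds[:-1]):
        if label in ("lead", "tail", "iti"):
            continue
        ev_rows.append({"label": label, "onset_ms": onset, "duration_ms": dur})
        truth_amp[label] = amp
    events = pd.DataFrame(ev_rows)
    truth = {
        "amplitude_by_label": truth_amp,
        "baseline_amplitude_ms": baseline_amplitude_ms,
        "condition_amplitudes_ms": amp_by_cond,
        "mean_rr_ms": mean_rr_ms,
        "resp_frequency_hz": resp_frequency_hz,
    }
    return series, events, truth


def synth_proxemics_cells(
    rng=0,
    n_per_group: int = 24,
    base_reactivity: float = -0.4,
    modulation: float = 0.4,
    modulated_cell: tuple[str, str, str] = ("thin", "far", "gaze"),
    modulated_group: str = "HC",
    cell_sd: float = 0.15,
) -> tuple[pd.DataFrame, dict]:
    """Per-subject 2x2x2 reactivity cells with a planted 4-way interaction.

    All cells share ``base_reactivity`` except ``modulated_cell`` in
    ``modulated_group``, which is raised by ``modulation`` ln-units —
    a single group modulating a single condition, the signature the
    4-way (BMI x Distance x Gaze x Group) interaction detects.
    """
    rng = _rng(rng)
    rows = []
    sid = 0
    for group in ("HC", "AN"):
        for _ in range(n_per_group):
            sid += 1
            subj_shift = rng.normal(0.0, 0.1)
            for bmi in ("thin", "fat"):
                for dist in ("far", "near"):
                    for gaze in ("gaze", "nogaze"):
                        mu = base_reactivity + subj_shift
                        if group == modulated_group and (bmi, dist, gaze) == modulated_cell:
                            mu += modulation
                        rows.append(
                            {
                                "subject": f"S{sid:03d}",
                                "group": group,
                                "bmi": bmi,
                                "distance": dist,
                                "gaze": gaze,
                                "reactivity": float(rng.normal(mu, cell_sd)),
                            }
                        )
    truth = {
        "modulation": modulation,
        "modulated_cell": modulated_cell,
        "modulated_group": modulated_group,
        "cell_sd": cell_sd,
    }
    return pd.DataFrame(rows), truth
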