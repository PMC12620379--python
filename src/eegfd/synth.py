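"""Synthetic EEG cohorts with known per-channel fractal dimension.

Each channel is a fractal Gaussian signal with a chosen Hurst exponent H:
stationary fractional Gaussian noise (fGn) is drawn by exact circulant
embedding and integrated into the corresponding fractional-Brownian-motion
path, whose graph has the analytically known fractal dimension 2 - H.
That gives every downstream stage (preprocessing, HFD estimation, ranking,
classification, ANOVA) a ground truth to recover.  Group structure is
planted by giving a designated channel subset group-specific H while all
other channels share a common H across groups.  Recordings are contaminated
with the nuisances real EEG carries and preprocessing removes: 50 Hz mains
interference, slow drift, and rare high-amplitude transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeding import substream
from .montage import STANDARD_1020_NAMES
from .recording import Recording, SubjectRecord, write_csv

GROUPS: tuple[str, ...] = ("addict", "first", "second", "normal")

#: Default per-group Hurst exponent on the affected channels.  Active
#: addiction shows reduced complexity (higher H, lower fractal dimension);
#: recovery moves H toward the healthy value in 0.10 steps.
DEFAULT_AFFECTED_HURST: dict[str, float] = {
    "addict": 0.85,
    "first": 0.75,
    "second": 0.65,
    "normal": 0.55,
}
#: Hurst exponent shared by all groups on unaffected channels.
DEFAULT_BASELINE_HURST: float = 0.70


@dataclass
class ArtifactParams:
    """Amplitudes and rates of the injected contamination (microvolts, Hz)."""

    line_amplitude: float = 10.0
    line_freq_hz: float = 50.0
    drift_amplitude: float = 30.0
    drift_freq_hz: float = 0.1
    transient_rate_per_s: float = 0.05
    transient_amplitude: float = 800.0

    def __post_init__(self) -> None:
        for name in ("line_amplitude", "drift_amplitude", "transient_amplitude",
                     "transient_rate_per_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the study conditions: four groups with subject counts
    (19, 24, 23, 20), 19 channels in 10-20 order at 250 Hz, two eyes-closed
    recordings per subject, and a planted complexity effect on channels
    4, 5, 6 and 15 (1-based; F3, Fz, F4, Pz).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"addict": 19, "first": 24, "second": 23, "normal": 20}
    )
    n_channels: int = 19
    rate_hz: float = 250.0
    duration_s: float = 20.0
    recordings_per_subject: int = 2
    affected_channels: tuple[int, ...] = (4, 5, 6, 15)  # 1-based
    group_hurst_profiles: dict[str, np.ndarray] | None = None
    baseline_hurst: float = DEFAULT_BASELINE_HURST
    affected_hurst: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AFFECTED_HURST)
    )
    signal_sd_uv: float = 1.0  # per-sample increment SD, microvolts
    artifact_params: ArtifactParams = field(default_factory=ArtifactParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_per_group) != set(GROUPS):
            raise ValueError(f"n_per_group must have exactly the groups {GROUPS}")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("every group needs at least one subject")
        if not set(self.affected_channels) <= set(range(1, self.n_channels + 1)):
            raise ValueError("affected_channels must be 1-based indices within n_channels")
        for prof in (self.group_hurst_profiles or {}).values():
            if np.any((np.asarray(prof) <= 0) | (np.asarray(prof) >= 1)):
                raise ValueError("Hurst exponents must lie in the open interval (0, 1)")
        if not 0 < self.baseline_hurst < 1:
            raise ValueError("baseline_hurst must lie in (0, 1)")
        for h in self.affected_hurst.values():
            if not 0 < h < 1:
                raise ValueError("affected Hurst values must lie in (0, 1)")
        if self.duration_s * self.rate_hz < 16:
            raise ValueError("recording too short")

    def hurst_profile(self, group: str) -> np.ndarray:
        """Per-channel Hurst exponents for a group."""
        if self.group_hurst_profiles is not None:
            return np.asarray(self.group_hurst_profiles[group], dtype=float)
        prof = np.full(self.n_channels, self.baseline_hurst)
        for ch in self.affected_channels:
            prof[ch - 1] = self.affected_hurst[group]
        return prof


def fgn_autocovariance(n_lags: int, hurst: float) -> np.ndarray:
    """Autocovariance gamma(0..n_lags) of unit-variance fGn with exponent H."""
    k = np.arange(n_lags + 1, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def generate_fgn(
    n_samples: int,
    hurst: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sample fractional Gaussian noise by circulant embedding.

    The covariance of the 2(n-1)-periodic extension of the fGn
    autocovariance is diagonalised by the FFT (Davies-Harte construction),
    so an exact stationary Gaussian sample costs two FFTs.  Unit variance;
    fractal dimension 2 - ``hurst``.

    Parameters
    ----------
    n_samples
        Series length, at least 16.
    hurst
        Hurst exponent in the open interval (0, 1).  H = 0.5 is white noise.
    seed
        Integer seed or an existing Generator.
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must lie in the open interval (0, 1)")
    if n_samples < 16:
        raise ValueError("n_samples must be at least 16")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if hurst == 0.5:
        return rng.standard_normal(n_samples)

    m = 2 * (n_samples - 1)
    gamma = fgn_autocovariance(n_samples - 1, hurst)
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    eigvals = np.fft.rfft(circ).real
    # The embedding is positive semi-definite for fGn; clip tiny negative
    # round-off so the square root is defined.
    eigvals = np.clip(eigvals, 0.0, None)

    z = rng.standard_normal(len(eigvals)) + 1j * rng.standard_normal(len(eigvals))
    z[0] = z[0].real * np.sqrt(2)
    z[-1] = z[-1].real * np.sqrt(2)
    coeffs = z * np.sqrt(eigvals / (2 * m))
    series = np.fft.irfft(coeffs, n=m) * m
    return series[:n_samples]


def generate_fractal_signal(
    n_samples: int,
    hurst: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """A Gaussian series whose graph has fractal dimension exactly 2 - H.

    The cumulative sum of fGn increments — a sampled fractional-Brownian-
    motion path — standardized to zero mean and unit SD.  This is the
    series the Higuchi estimator recovers 2 - H from; the stationary
    increments themselves (:func:`generate_fgn`) have a much shallower
    length-scaling and are not the truth carrier.
    """
    path = np.cumsum(generate_fgn(n_samples, hurst, seed))
    return (path - path.mean()) / path.std()


def inject_artifacts(
    rec: Recording,
    params: ArtifactParams | None = None,
    seed: int | np.random.Generator = 0,
) -> Recording:
    """Add mains sinusoid, slow drift and Poisson-timed transients.

    Returns a new Recording; the input is untouched.  Each contamination
    is scaled by its amplitude parameter, so zero amplitudes make this the
    identity.
    """
    params = params or ArtifactParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(rec.n_samples) / rec.rate_hz
    out = rec.copy_with()

    if params.line_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, rec.n_channels)
        out.data += params.line_amplitude * np.sin(
            2 * np.pi * params.line_freq_hz * t[None, :] + phases[:, None]
        )
    if params.drift_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, rec.n_channels)
        out.data += params.drift_amplitude * np.sin(
            2 * np.pi * params.drift_freq_hz * t[None, :] + phases[:, None]
        )
    if params.transient_rate_per_s > 0:
        n_transients = rng.poisson(params.transient_rate_per_s * rec.duration_s)
        for _ in range(n_transients):
            pos = rng.integers(0, rec.n_samples)
            width = max(int(0.05 * rec.rate_hz), 1)  # ~50 ms spike
            lo, hi = max(0, pos - width), min(rec.n_samples, pos + width)
            shape = np.exp(-0.5 * ((np.arange(lo, hi) - pos) / (width / 3)) ** 2)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            out.data[:, lo:hi] += sign * params.transient_amplitude * shape[None, :]
    return out


def generate_subject(
    subject_id: str,
    group: str,
    cfg: CohortConfig,
    rng: np.random.Generator,
    clean: bool = False,
) -> SubjectRecord:
    """Draw one subject: per-channel fGn at the group's Hurst profile."""
    profile = cfg.hurst_profile(group)
    n_samples = int(round(cfg.duration_s * cfg.rate_hz))
    montage = tuple(STANDARD_1020_NAMES[: cfg.n_channels])
    recordings = []
    for _ in range(cfg.recordings_per_subject):
        data = np.empty((cfg.n_channels, n_samples))
        for ch in range(cfg.n_channels):
            # Equal increment scale across channels (not equal path scale):
            # under common average re-referencing each channel absorbs a
            # 1/n_channels admixture of every other channel, and only equal
            # small-scale increment variance keeps that cross-talk a
            # uniform few-percent perturbation of the curve lengths.
            data[ch] = cfg.signal_sd_uv * np.cumsum(
                generate_fgn(n_samples, profile[ch], rng))
        rec = Recording(data=data, rate_hz=cfg.rate_hz, montage=montage)
        if not clean:
            rec = inject_artifacts(rec, cfg.artifact_params, rng)
        recordings.append(rec)
    return SubjectRecord(subject_id=subject_id, group=group,
                         recordings=recordings, truth=profile)


def generate_cohort(cfg: CohortConfig, clean: bool = False) -> list[SubjectRecord]:
    """Generate the full cohort, deterministic under ``cfg.seed``.

    Each subject draws from its own named substream, so cohorts of
    different sizes share the subjects they have in common.
    With ``clean=True`` no artifacts are injected (useful for calibration).
    """
    subjects: list[SubjectRecord] = []
    for group in GROUPS:
        for i in range(cfg.n_per_group[group]):
            sid = f"{group}-{i + 1:03d}"
            rng = substream(cfg.seed, "subject", sid)
            subjects.append(generate_subject(sid, group, cfg, rng, clean=clean))
    return subjects


def truth_table(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Per-subject ground-truth Hurst exponents as a tidy table."""
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "group": s.group}
        if s.truth is not None:
            row.update({f"hurst_ch{c + 1}": h for c, h in enumerate(s.truth)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(subjects: list[SubjectRecord], out_dir: str | Path) -> Path:
    """Write recordings as matrix CSVs plus a cohort manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        paths = []
        for r_i, rec in enumerate(s.recordings, start=1):
            rel = f"{s.subject_id}_ec{r_i}.csv"
            write_csv(rec, out_dir / rel)
            paths.append(rel)
        row = {"subject_id": s.subject_id, "group": s.group,
               "recordings": ";".join(paths)}
        if s.truth is not None:
            row.update({f"hurst_ch{c + 1}": h for c, h in enumerate(s.truth)})
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path, rate_hz: float = 250.0) -> list[SubjectRecord]:
    """Load a cohort previously written by :func:`write_cohort`."""
    from .recording import read_csv

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    subjects = []
    for _, row in df.iterrows():
        recs = [read_csv(base / p, rate_hz=rate_hz) for p in str(row["recordings"]).split(";")]
        hurst_cols = sorted(
            (c for c in df.columns if c.startswith("hurst_ch")),
            key=lambda c: int(c.removeprefix("hurst_ch")),
        )
        truth = row[hurst_cols].to_numpy(dtype=float) if hurst_cols else None
        subjects.append(SubjectRecord(subject_id=row["subject_id"], group=row["group"],
                                      recordings=recs, truth=truth))
    if not subjects:
        warnings.warn("empty cohort manifest")
    return subjects
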