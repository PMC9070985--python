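"""Plumbing between measured in-vivo data and the model.

Covers the measured side of the pipeline that the model consumes:

* conduction velocity (with confidence interval) from tract length and
  interhemispheric transfer time (IHTT) — 1 mm/ms = 1 m/s, so no numeric
  conversion factor is needed;
* IHTT from per-hemisphere current-density magnitude time courses, as the
  latency difference between the first contralateral and ipsilateral
  activation peaks, with a four-split standard deviation for the CI and a
  signed-rank check of peak amplitudes against baseline;
* voxelwise aggregate g-ratio arithmetic from MT saturation and diffusion
  compartment maps:  MVF = α_cal·MT_sat,
  AVF = (1 − α_cal·MT_sat)(1 − v_iso)·v_ic,  g = 1/sqrt(1 + MVF/AVF);
* the packaged 14-subject cohort table (per-subject mean ± sd of g_MRI,
  tract length, group IHTT 11.72 ± 2.87 ms) and a seeded synthetic cohort
  generator emulating its structure.

The MVF calibration factor is named ``alpha_cal`` throughout to avoid
collision with the power-law exponent α.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .exceptions import InvalidParameterError, PeakDetectionError

__all__ = [
    "SubjectMeasurement",
    "CurrentDensitySeries",
    "IhttResult",
    "velocity_from_tract",
    "estimate_ihtt",
    "split_ihtt_sd",
    "voxel_g_ratio",
    "load_table1",
    "SynthCohortSpec",
    "synth_cohort",
    "read_g_samples",
    "GROUP_IHTT_MS",
    "GROUP_IHTT_SD_MS",
]

GROUP_IHTT_MS = 11.72
GROUP_IHTT_SD_MS = 2.87


def velocity_from_tract(
    tract_length_mm: float, ihtt_ms: float, ihtt_sd_ms: float = 0.0
) -> tuple[float, tuple[float, float]]:
    """Conduction velocity and CI from tract length and transfer time.

    velocity = length / IHTT (mm/ms ≡ m/s); the confidence interval is
    [length/(IHTT+sd), length/(IHTT−sd)].
    """
    if tract_length_mm <= 0:
        raise InvalidParameterError("tract_length_mm must be positive")
    if ihtt_ms <= 0:
        raise InvalidParameterError("ihtt_ms must be positive")
    if ihtt_sd_ms < 0 or ihtt_sd_ms >= ihtt_ms:
        raise InvalidParameterError("ihtt_sd_ms must satisfy 0 <= sd < IHTT")
    v = tract_length_mm / ihtt_ms
    ci = (tract_length_mm / (ihtt_ms + ihtt_sd_ms), tract_length_mm / (ihtt_ms - ihtt_sd_ms))
    return v, ci


@dataclass(frozen=True)
class SubjectMeasurement:
    """One subject's observables for the visual transcallosal tract."""

    subject_id: str
    tract_length_mm: float
    ihtt_ms: float
    ihtt_sd_ms: float = 0.0
    g_mean: float | None = None
    g_sd: float | None = None
    g_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        velocity_from_tract(self.tract_length_mm, self.ihtt_ms, self.ihtt_sd_ms)  # validates
        if self.g_samples is not None:
            g = np.asarray(self.g_samples, dtype=float)
            if g.size == 0 or np.any(g <= 0) or np.any(g >= 1):
                raise InvalidParameterError("g_samples must be non-empty and lie in (0, 1)")
            object.__setattr__(self, "g_samples", g)
            if self.g_mean is None:
                object.__setattr__(self, "g_mean", float(g.mean()))
            if self.g_sd is None:
                object.__setattr__(self, "g_sd", float(g.std(ddof=1)) if g.size > 1 else 0.0)
        if self.g_mean is None:
            raise InvalidParameterError("either g_mean or g_samples is required")
        if not 0.0 < self.g_mean < 1.0:
            raise InvalidParameterError("g_mean must lie in (0, 1)")

    @property
    def velocity_mps(self) -> float:
        return velocity_from_tract(self.tract_length_mm, self.ihtt_ms, self.ihtt_sd_ms)[0]

    @property
    def velocity_ci_mps(self) -> tuple[float, float]:
        return velocity_from_tract(self.tract_length_mm, self.ihtt_ms, self.ihtt_sd_ms)[1]


@dataclass(frozen=True)
class CurrentDensitySeries:
    """ROI-averaged current-density magnitude time course for one hemisphere.

    ``time_ms`` must be uniformly sampled (e.g., 1024 Hz); windows are
    (start, stop) in ms relative to stimulus onset at 0.
    """

    time_ms: np.ndarray
    amplitude: np.ndarray
    baseline_window: tuple[float, float] = (-100.0, 0.0)
    analysis_window: tuple[float, float] = (0.0, 300.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        if t.ndim != 1 or t.size < 3 or a.shape != t.shape:
            raise InvalidParameterError("time_ms and amplitude must be matching 1-D arrays")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            raise InvalidParameterError("time axis must be uniformly increasing")
        if not np.all(np.isfinite(a)):
            raise InvalidParameterError("amplitudes must be finite")
        for name, (lo, hi) in (("baseline", self.baseline_window), ("analysis", self.analysis_window)):
            if not (lo < hi and t[0] <= lo and hi <= t[-1]):
                raise InvalidParameterError(f"{name} window [{lo}, {hi}] outside the time axis")
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "amplitude", a)

    def _window_mask(self, window):
        lo, hi = window
        return (self.time_ms >= lo) & (self.time_ms <= hi)

    def peak_latency_ms(self) -> float:
        """Latency of the maximum amplitude inside the analysis window.

        Ties break to the earliest sample.  A flat window (no sample above
        the window minimum) carries no peak.
        """
        mask = self._window_mask(self.analysis_window)
        amp = self.amplitude[mask]
        if np.ptp(amp) == 0.0:
            raise PeakDetectionError("flat time course: no activation peak in analysis window")
        return float(self.time_ms[mask][int(np.argmax(amp))])

    def baseline_mean(self) -> float:
        return float(self.amplitude[self._window_mask(self.baseline_window)].mean())


@dataclass
class IhttResult:
    ihtt_ms: float
    contra_peak_ms: float
    ipsi_peak_ms: float
    contra_p_value: float | None = None
    ipsi_p_value: float | None = None


def estimate_ihtt(
    contra: CurrentDensitySeries,
    ipsi: CurrentDensitySeries,
    subject_contra: np.ndarray | None = None,
    subject_ipsi: np.ndarray | None = None,
) -> IhttResult:
    """IHTT as the ipsilateral-minus-contralateral peak latency difference.

    Interhemispheric transfer runs from the hemisphere contralateral to
    the stimulated hemifield to the ipsilateral one, so the contralateral
    peak must come first.  When per-subject amplitude matrices (one row
    per subject, aligned to the shared time axis) are supplied, each
    hemisphere's peak amplitudes are compared against the subjects'
    time-averaged baselines with a Wilcoxon signed-rank test.
    """
    if contra.time_ms.shape != ipsi.time_ms.shape or not np.allclose(
        contra.time_ms, ipsi.time_ms
    ):
        raise InvalidParameterError("both series must share the time axis")
    t_contra = contra.peak_latency_ms()
    t_ipsi = ipsi.peak_latency_ms()
    if t_ipsi < t_contra:
        raise PeakDetectionError(
            f"ipsilateral peak ({t_ipsi} ms) precedes contralateral peak ({t_contra} ms); "
            "transfer-direction assumption violated"
        )
    result = IhttResult(ihtt_ms=t_ipsi - t_contra, contra_peak_ms=t_contra, ipsi_peak_ms=t_ipsi)
    for name, series, peak_ms, mat in (
        ("contra", contra, t_contra, subject_contra),
        ("ipsi", ipsi, t_ipsi, subject_ipsi),
    ):
        if mat is None:
            continue
        mat = np.asarray(mat, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != series.time_ms.size:
            raise InvalidParameterError(f"subject_{name} must be (n_subjects, n_times)")
        idx = int(np.argmin(np.abs(series.time_ms - peak_ms)))
        peaks = mat[:, idx]
        baseline = mat[:, series._window_mask(series.baseline_window)].mean(axis=1)
        p = float(wilcoxon(peaks, baseline, alternative="greater").pvalue)
        setattr(result, f"{name}_p_value", p)
    return result


def split_ihtt_sd(trial_splits) -> float:
    """Standard deviation of the IHTT across independent trial splits.

    ``trial_splits`` is a sequence of four (contra, ipsi) series pairs,
    each built from a disjoint subset of trials.  Splits that fail peak
    detection are reported together in a single error.
    """
    splits = list(trial_splits)
    if len(splits) != 4:
        raise InvalidParameterError(f"expected four non-overlapping splits, got {len(splits)}")
    ihtts, failures = [], []
    for i, (contra, ipsi) in enumerate(splits):
        try:
            ihtts.append(estimate_ihtt(contra, ipsi).ihtt_ms)
        except PeakDetectionError as exc:
            failures.append(f"split {i}: {exc}")
    if failures:
        raise PeakDetectionError("; ".join(failures))
    return float(np.std(ihtts, ddof=1))


def voxel_g_ratio(mt_sat, v_iso, v_ic, alpha_cal: float = 0.23) -> np.ma.MaskedArray:
    """Voxelwise aggregate g-ratio from quantitative maps.

    MVF = α_cal·MT_sat;  AVF = (1 − MVF)(1 − v_iso)·v_ic;
    g = 1/sqrt(1 + MVF/AVF).  Voxels with AVF = 0 but MVF > 0 are masked
    (undefined) rather than raising; MVF = AVF = 0 conventionally gives 1
    (no myelin, no axon signal).
    """
    mt_sat = np.asarray(mt_sat, dtype=float)
    v_iso = np.asarray(v_iso, dtype=float)
    v_ic = np.asarray(v_ic, dtype=float)
    if np.any((v_iso < 0) | (v_iso > 1)) or np.any((v_ic < 0) | (v_ic > 1)):
        raise InvalidParameterError("v_iso and v_ic must lie in [0, 1]")
    mvf = alpha_cal * mt_sat
    if np.any((mvf < 0) | (mvf >= 1)):
        raise InvalidParameterError("alpha_cal * mt_sat must lie in [0, 1)")
    avf = (1.0 - mvf) * (1.0 - v_iso) * v_ic
    undefined = (avf == 0) & (mvf > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 1.0 / np.sqrt(1.0 + np.where(undefined, np.nan, mvf) / np.where(avf == 0, 1.0, avf))
    g = np.where((avf == 0) & (mvf == 0), 1.0, g)
    return np.ma.masked_invalid(np.ma.masked_array(g, mask=undefined))


def load_table1() -> list[SubjectMeasurement]:
    """The packaged 14-subject cohort summary table.

    Per-subject mean ± sd of the tract g_MRI samples and tract length;
    all velocities derive from the group transfer time 11.72 ± 2.87 ms.
    """
    with resources.files("axonmorph.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        SubjectMeasurement(
            subject_id=row.subject_id,
            tract_length_mm=row.tract_length_mm,
            ihtt_ms=GROUP_IHTT_MS,
            ihtt_sd_ms=GROUP_IHTT_SD_MS,
            g_mean=row.g_mean,
            g_sd=row.g_sd,
        )
        for row in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class SynthCohortSpec:
    """Generator settings for a synthetic measurement cohort.

    Per-subject mean g and the tract-length/IHTT Gaussians are chosen so
    the implied velocities are ≈ N(10, 0.8) m/s, matching the dispersion
    used in the simulation studies; within-subject g noise has sd 0.03.
    """

    n_subjects: int = 14
    mean_g: float = 0.70
    between_g_sd: float = 0.05
    within_g_sd: float = 0.03
    n_g_samples: int = 700
    tract_length_mean_mm: float = 150.0
    tract_length_sd_mm: float = 8.0
    ihtt_mean_ms: float = 15.0
    ihtt_between_sd_ms: float = 0.85
    ihtt_split_sd_ms: float = 2.87
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        for name in ("between_g_sd", "within_g_sd", "tract_length_sd_mm", "ihtt_between_sd_ms"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")


def synth_cohort(spec: SynthCohortSpec | None = None) -> list[SubjectMeasurement]:
    """Draw a seeded synthetic cohort of subject measurements."""
    spec = spec or SynthCohortSpec()
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for s in range(spec.n_subjects):
        g_mean = float(np.clip(rng.normal(spec.mean_g, spec.between_g_sd), 0.05, 0.95))
        g = rng.normal(g_mean, spec.within_g_sd, spec.n_g_samples)
        g = np.clip(g, 1e-3, 1 - 1e-3)
        length = max(float(rng.normal(spec.tract_length_mean_mm, spec.tract_length_sd_mm)), 1.0)
        ihtt = max(float(rng.normal(spec.ihtt_mean_ms, spec.ihtt_between_sd_ms)), 1.0)
        subjects.append(
            SubjectMeasurement(
                subject_id=f"SYN{s + 1:02d}",
                tract_length_mm=length,
                ihtt_ms=ihtt,
                ihtt_sd_ms=min(spec.ihtt_split_sd_ms, 0.99 * ihtt),
                g_samples=g,
            )
        )
    return subjects


def read_g_samples(path) -> np.ndarray:
    """Read a one-column CSV of g-ratio samples (header optional)."""
    first = pd.read_csv(path, nrows=1, header=None)
    try:
        float(first.iloc[0, 0])
        has_header = False
    except (TypeError, ValueError):
        has_header = True
    df = pd.read_csv(path, header=0 if has_header else None)
    g = df.iloc[:, 0].to_numpy(dtype=float)
    if g.size == 0:
        raise InvalidParameterError(f"no samples found in {path}")
    return g
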