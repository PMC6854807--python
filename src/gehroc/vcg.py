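"""Vectorcardiographic global electrical heterogeneity (GEH) metrics.

Pipeline from a multi-beat 12-lead ECG to the GEH marker set:

1. ``kors_transform`` — project the 8 independent standard leads
   (I, II, V1–V6) onto orthogonal X, Y, Z leads with the Kors
   regression matrix.
2. ``build_median_beat`` — time-coherent median beat over the normal
   sinus beats (PVCs, their neighbours, and noisy beats excluded),
   aligned on vector-magnitude cross-correlation.
3. ``detect_origin`` — locate the heart-vector zero reference in the
   quietest pre-QRS window and subtract it.
4. Metric operations — spatial peak/area QRS and T vectors, QRS-T
   angles, spatial ventricular gradient (SVG) azimuth / elevation /
   magnitude in both peak and area (Wilson) forms, SAI QRST, and the
   traditional heart rate / QRS duration / Bazett-corrected QT.

Axis convention (used consistently by this module and the synthetic
generator): X points right→left, Y superior→inferior (positive down),
Z anterior→posterior (positive back).  Azimuth is the angle of a vector's
transverse-plane projection, ``atan2(z, x)`` in (−180°, 180°], with 0° at
+X and +90° at +Z.  Elevation defaults to the geometric polar angle from
the +Y axis, ``atan2(hypot(x, z), y)`` in [0°, 180°]; a "literal"
``arctan(x / y)`` variant is available for comparability with reports
that use the plain-ratio definition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KORS_MATRIX",
    "KORS_LEADS",
    "LEAD_NAMES_12",
    "Ecg12Record",
    "MedianBeatXyz",
    "SpatialVector",
    "GehMetrics",
    "kors_transform",
    "build_median_beat",
    "detect_origin",
    "vector_magnitude",
    "peak_vectors",
    "area_vectors",
    "spatial_angle",
    "svg_peak",
    "svg_area",
    "azimuth",
    "elevation",
    "magnitude",
    "sai_qrst",
    "qtc_bazett",
    "compute_geh",
]

LEAD_NAMES_12 = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")

#: The 8 independent leads the Kors regression operates on, in matrix order.
KORS_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

# Kors regression coefficients (Kors et al., Eur Heart J 1990, Table: the
# regression-based 12-lead -> Frank XYZ reconstruction).  Rows X, Y, Z;
# columns I, II, V1..V6.
KORS_MATRIX = np.array(
    [
        [0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54],
        [-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13],
        [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31],
    ]
)

#: Beat classes excluded from the median beat.
EXCLUDED_BEAT_LABELS = frozenset({"pvc", "pre_post_pvc", "noisy"})


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class Ecg12Record:
    """A multi-beat 12-lead ECG with beat labels and fiducial points.

    ``signal`` is samples x 12 in μV with columns ordered as
    ``LEAD_NAMES_12``.  ``fiducials`` holds per-record QRS onset, QRS
    offset and T offset as sample offsets relative to each R peak.
    """

    signal: np.ndarray
    fs: float
    lead_names: Sequence[str] = LEAD_NAMES_12
    beat_labels: Sequence[str] = ()
    r_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    fiducials: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if self.signal.ndim != 2 or self.signal.shape[1] != 12:
            raise ValueError("signal must be a samples x 12 matrix")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.beat_labels) != len(self.r_peaks):
            raise ValueError("beat_labels and r_peaks must have equal length")
        if len(self.r_peaks) > 1 and np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")


@dataclass
class MedianBeatXyz:
    """Time-coherent orthogonal median beat with fiducials.

    ``origin`` is the heart-vector zero reference already subtracted from
    the stored samples (zeros until :func:`detect_origin` has run).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float
    qrs_onset: int
    qrs_offset: int
    t_offset: int
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_beats_used: int = 0
    rr_median: float = float("nan")  # ms

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.x)
        if not (0 <= self.qrs_onset < self.qrs_offset < self.t_offset <= n):
            raise ValueError(
                "fiducials must satisfy qrs_onset < qrs_offset < t_offset <= length"
            )

    @property
    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])


@dataclass(frozen=True)
class SpatialVector:
    """A 3-component heart vector (μV for peak vectors, μV·ms for areas)."""

    vx: float
    vy: float
    vz: float
    basis: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.vx, self.vy, self.vz], dtype=float)


@dataclass(frozen=True)
class GehMetrics:
    """The GEH marker set plus traditional ECG metrics for one record."""

    peak_qrst_angle: float  # degrees
    area_qrst_angle: float  # degrees
    peak_svg_azimuth: float  # degrees
    peak_svg_elevation: float  # degrees
    area_svg_azimuth: float  # degrees
    area_svg_elevation: float  # degrees
    peak_svg_magnitude: float  # μV
    area_svg_magnitude: float  # μV·ms
    sai_qrst: float  # mV·ms
    heart_rate: float  # bpm
    qrs_duration: float  # ms
    qtc: float  # ms
    elevation_mode: str = "conventional"


# --------------------------------------------------------------------------
# Transform and median beat
# --------------------------------------------------------------------------

def kors_transform(record: Ecg12Record) -> np.ndarray:
    """Project a 12-lead record onto orthogonal X, Y, Z (samples x 3, μV).

    Only the 8 independent leads (I, II, V1–V6) enter the regression; the
    limb-derived leads III, aVR, aVL, aVF are redundant and ignored.
    """
    name_to_col = {name: i for i, name in enumerate(record.lead_names)}
    cols = []
    for lead in KORS_LEADS:
        if lead not in name_to_col:
            raise ValueError(f"missing lead {lead!r} required by the Kors transform")
        col = record.signal[:, name_to_col[lead]]
        if not np.all(np.isfinite(col)):
            raise ValueError(f"lead {lead!r} contains non-finite samples")
        cols.append(col)
    l8 = np.column_stack(cols)
    return l8 @ KORS_MATRIX.T


def _align_offsets(vm_beats: np.ndarray, template: np.ndarray, max_shift: int) -> np.ndarray:
    """Per-beat integer shifts maximizing cross-correlation with a template."""
    shifts = np.zeros(len(vm_beats), dtype=int)
    for i, vm in enumerate(vm_beats):
        best, best_s = -np.inf, 0
        for s in range(-max_shift, max_shift + 1):
            rolled = np.roll(vm, s)
            # ignore wrapped edges
            if s > 0:
                score = float(rolled[s:] @ template[s:])
            elif s < 0:
                score = float(rolled[:s] @ template[:s])
            else:
                score = float(rolled @ template)
            if score > best:
                best, best_s = score, s
        shifts[i] = best_s
    return shifts


def build_median_beat(
    xyz: np.ndarray,
    beat_labels: Sequence[str],
    r_peaks: np.ndarray,
    fs: float,
    fiducials: dict | None = None,
    max_align_shift_ms: float = 10.0,
) -> MedianBeatXyz:
    """Construct the time-coherent normal-sinus median beat.

    Beats labelled ``pvc``, ``pre_post_pvc`` or ``noisy`` never contribute.
    The remaining beats are windowed around their R peaks on a grid
    spanning the median RR interval, aligned by maximizing the
    cross-correlation of each beat's spatial vector magnitude against the
    running median template (one refinement pass), and reduced by a
    per-sample median.

    ``fiducials`` (qrs_onset/qrs_offset/t_offset, samples relative to the
    R peak) are carried onto the median-beat grid when provided.
    """
    xyz = np.asarray(xyz, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    usable = [
        (r, lab) for r, lab in zip(r_peaks, beat_labels) if lab not in EXCLUDED_BEAT_LABELS
    ]
    if len(usable) < 3:
        raise ValueError(
            f"insufficient beats: {len(usable)} usable normal sinus beats (need >= 3)"
        )
    use_peaks = np.array([r for r, _ in usable], dtype=int)

    rr = np.diff(r_peaks)
    rr_median_samp = int(np.median(rr)) if len(rr) else int(0.8 * fs)
    rr_median_ms = rr_median_samp / fs * 1000.0

    # Window spanning the median RR: 35% before the R peak (covers the
    # pre-QRS origin-search region), 65% after (covers the T wave).
    pre = int(round(0.35 * rr_median_samp))
    post = rr_median_samp - pre
    n_samples = len(xyz)

    segs = []
    for r in use_peaks:
        lo, hi = r - pre, r + post
        if lo < 0 or hi > n_samples:
            continue  # partial beat at a record edge
        segs.append(xyz[lo:hi])
    if len(segs) < 3:
        raise ValueError("insufficient beats: fewer than 3 complete windows in record")
    beats = np.stack(segs)  # (nbeats, window, 3)

    # Alignment on the spatial vector magnitude, refined once against the
    # median template.
    vm = np.sqrt((beats**2).sum(axis=2))
    max_shift = max(1, int(round(max_align_shift_ms / 1000.0 * fs)))
    template = np.median(vm, axis=0)
    shifts = _align_offsets(vm, template, max_shift)
    if np.any(shifts != 0):
        beats = np.stack([np.roll(b, s, axis=0) for b, s in zip(beats, shifts)])

    median = np.median(beats, axis=0)

    fid = fiducials or {}
    qrs_onset = pre + int(fid.get("qrs_onset", -int(0.05 * fs)))
    qrs_offset = pre + int(fid.get("qrs_offset", int(0.05 * fs)))
    t_offset = pre + int(fid.get("t_offset", int(0.4 * fs)))
    t_offset = min(t_offset, len(median))

    return MedianBeatXyz(
        x=median[:, 0],
        y=median[:, 1],
        z=median[:, 2],
        fs=fs,
        qrs_onset=qrs_onset,
        qrs_offset=qrs_offset,
        t_offset=t_offset,
        n_beats_used=len(segs),
        rr_median=rr_median_ms,
    )


def detect_origin(beat: MedianBeatXyz) -> tuple[SpatialVector, MedianBeatXyz]:
    """Locate and subtract the heart-vector origin.

    The origin is the mean XYZ over the flattest 20-ms window — minimum
    mean absolute spatial velocity — inside [qrs_onset − 40 ms, qrs_onset].
    Returns the origin vector and the corrected beat.
    """
    fs = beat.fs
    win = max(1, int(round(0.020 * fs)))
    search = int(round(0.040 * fs))
    lo = beat.qrs_onset - search
    if lo < 0:
        logger.warning("origin search window clipped at beat start")
        lo = 0
    hi = beat.qrs_onset
    if hi - lo < win:
        win = max(1, hi - lo)

    xyz = beat.xyz
    vel = np.abs(np.diff(xyz, axis=0)).sum(axis=1)  # L1 spatial velocity per step

    best_start, best_score = lo, np.inf
    for start in range(lo, hi - win + 1):
        seg = vel[start : start + win - 1]
        score = seg.mean() if len(seg) else 0.0
        if score < best_score:
            best_score, best_start = score, start
    origin = xyz[best_start : best_start + win].mean(axis=0)

    corrected = MedianBeatXyz(
        x=beat.x - origin[0],
        y=beat.y - origin[1],
        z=beat.z - origin[2],
        fs=fs,
        qrs_onset=beat.qrs_onset,
        qrs_offset=beat.qrs_offset,
        t_offset=beat.t_offset,
        origin=beat.origin + origin,
        n_beats_used=beat.n_beats_used,
        rr_median=beat.rr_median,
    )
    return SpatialVector(*origin, basis="origin"), corrected


# --------------------------------------------------------------------------
# Vector measurements
# --------------------------------------------------------------------------

def vector_magnitude(beat: MedianBeatXyz) -> np.ndarray:
    """Per-sample spatial vector magnitude sqrt(x² + y² + z²), μV."""
    return np.sqrt(beat.x**2 + beat.y**2 + beat.z**2)


def peak_vectors(beat: MedianBeatXyz) -> tuple[SpatialVector, SpatialVector]:
    """Spatial peak QRS and T vectors.

    The peak is the sample of maximal vector magnitude inside
    [qrs_onset, qrs_offset] for QRS and (qrs_offset, t_offset] for T;
    ties resolve to the earliest sample.
    """
    vm = vector_magnitude(beat)
    q_lo, q_hi = beat.qrs_onset, beat.qrs_offset
    t_lo, t_hi = beat.qrs_offset + 1, beat.t_offset
    if q_hi < q_lo or t_hi < t_lo:
        raise ValueError("empty QRS or T search window")
    qi = q_lo + int(np.argmax(vm[q_lo : q_hi + 1]))
    ti = t_lo + int(np.argmax(vm[t_lo : t_hi + 1]))
    xyz = beat.xyz
    return (
        SpatialVector(*xyz[qi], basis="QRSpeak"),
        SpatialVector(*xyz[ti], basis="Tpeak"),
    )


def _trapz_window(beat: MedianBeatXyz, lo: int, hi: int) -> np.ndarray:
    """Componentwise trapezoidal integral of XYZ over samples [lo, hi], μV·ms."""
    dt_ms = 1000.0 / beat.fs
    seg = beat.xyz[lo : hi + 1]
    if len(seg) < 2:
        return np.zeros(3)
    return np.trapezoid(seg, dx=dt_ms, axis=0)


def area_vectors(beat: MedianBeatXyz) -> tuple[SpatialVector, SpatialVector]:
    """Spatial area (mean) QRS and T vectors, μV·ms.

    QRS integrates [qrs_onset, qrs_offset]; T integrates
    (qrs_offset, t_offset], half-open at the shared boundary so the
    sample at QRS offset is not double counted.
    """
    if not (beat.qrs_onset < beat.qrs_offset < beat.t_offset):
        raise ValueError("invalid fiducial windows")
    qrs = _trapz_window(beat, beat.qrs_onset, beat.qrs_offset)
    t = _trapz_window(beat, beat.qrs_offset + 1, beat.t_offset)
    return (
        SpatialVector(*qrs, basis="QRSarea"),
        SpatialVector(*t, basis="Tarea"),
    )


def spatial_angle(a: SpatialVector, b: SpatialVector) -> float:
    """3-D angle between two spatial vectors, degrees in [0, 180]."""
    va, vb = a.as_array(), b.as_array()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("undefined angle: zero-magnitude vector")
    c = float(np.clip(va @ vb / (na * nb), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def svg_peak(qrs_peak: SpatialVector, t_peak: SpatialVector) -> SpatialVector:
    """Spatial ventricular gradient, peak form: QRSpeak + Tpeak."""
    return SpatialVector(
        qrs_peak.vx + t_peak.vx,
        qrs_peak.vy + t_peak.vy,
        qrs_peak.vz + t_peak.vz,
        basis="SVGpeak",
    )


def svg_area(beat: MedianBeatXyz) -> SpatialVector:
    """Wilson (area) SVG: componentwise integral over [qrs_onset, t_offset], μV·ms."""
    v = _trapz_window(beat, beat.qrs_onset, beat.t_offset)
    return SpatialVector(*v, basis="SVGarea")


def azimuth(v: SpatialVector) -> float:
    """Transverse-plane direction atan2(z, x), degrees in (−180, 180]."""
    if v.vx == 0 and v.vz == 0:
        raise ValueError("undefined azimuth: zero transverse projection")
    a = float(np.degrees(np.arctan2(v.vz, v.vx)))
    return 180.0 if a == -180.0 else a


def elevation(v: SpatialVector, mode: Literal["conventional", "literal"] = "conventional") -> float:
    """Vector elevation in degrees.

    ``conventional`` (default): polar angle from the +Y (inferior) axis,
    atan2(hypot(x, z), y), in [0, 180].  ``literal``: the plain-ratio
    arctan(x / y) in (−90, 90), matching reports that print the
    two-component form.
    """
    va = v.as_array()
    if np.linalg.norm(va) == 0:
        raise ValueError("undefined elevation: zero vector")
    if mode == "conventional":
        return float(np.degrees(np.arctan2(np.hypot(v.vx, v.vz), v.vy)))
    if mode == "literal":
        if v.vy == 0:
            return 90.0 if v.vx > 0 else (-90.0 if v.vx < 0 else 0.0)
        return float(np.degrees(np.arctan(v.vx / v.vy)))
    raise ValueError(f"unknown elevation mode {mode!r}")


def magnitude(v: SpatialVector) -> float:
    """Euclidean norm of a spatial vector, in that vector's units."""
    return float(np.linalg.norm(v.as_array()))


def sai_qrst(beat: MedianBeatXyz) -> float:
    """Sum absolute QRST integral, mV·ms.

    Sum of the absolute-value areas of X, Y and Z over
    [qrs_onset, t_offset] (trapezoidal), converted from μV·ms to mV·ms.
    """
    dt_ms = 1000.0 / beat.fs
    seg = np.abs(beat.xyz[beat.qrs_onset : beat.t_offset + 1])
    if len(seg) < 2:
        return 0.0
    areas = np.trapezoid(seg, dx=dt_ms, axis=0)
    return float(areas.sum() / 1000.0)


def qtc_bazett(qt_ms: float, rr_ms: float) -> float:
    """Bazett heart-rate-corrected QT: qt / sqrt(rr in seconds), ms."""
    if rr_ms <= 0:
        raise ValueError("rr_ms must be positive")
    return float(qt_ms / np.sqrt(rr_ms / 1000.0))


# --------------------------------------------------------------------------
# Facade
# --------------------------------------------------------------------------

def compute_geh(
    record: Ecg12Record,
    elevation_mode: Literal["conventional", "literal"] = "conventional",
) -> GehMetrics:
    """Run the full chain from a 12-lead record to the GEH metric set."""
    try:
        xyz = kors_transform(record)
    except Exception as exc:
        raise RuntimeError(f"kors_transform failed: {exc}") from exc
    try:
        beat = build_median_beat(
            xyz, record.beat_labels, record.r_peaks, record.fs, record.fiducials
        )
    except Exception as exc:
        raise RuntimeError(f"build_median_beat failed: {exc}") from exc
    try:
        _, beat = detect_origin(beat)
        qrs_p, t_p = peak_vectors(beat)
        qrs_a, t_a = area_vectors(beat)
        svg_p = svg_peak(qrs_p, t_p)
        svg_a = svg_area(beat)

        qrs_ms = (beat.qrs_offset - beat.qrs_onset) / beat.fs * 1000.0
        qt_ms = (beat.t_offset - beat.qrs_onset) / beat.fs * 1000.0
        return GehMetrics(
            peak_qrst_angle=spatial_angle(qrs_p, t_p),
            area_qrst_angle=spatial_angle(qrs_a, t_a),
            peak_svg_azimuth=azimuth(svg_p),
            peak_svg_elevation=elevation(svg_p, elevation_mode),
            area_svg_azimuth=azimuth(svg_a),
            area_svg_elevation=elevation(svg_a, elevation_mode),
            peak_svg_magnitude=magnitude(svg_p),
            area_svg_magnitude=magnitude(svg_a),
            sai_qrst=sai_qrst(beat),
            heart_rate=60000.0 / beat.rr_median,
            qrs_duration=qrs_ms,
            qtc=qtc_bazett(qt_ms, beat.rr_median),
            elevation_mode=elevation_mode,
        )
    except (ValueError, ZeroDivisionError) as exc:
        raise RuntimeError(f"metric computation failed: {exc}") from exc
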