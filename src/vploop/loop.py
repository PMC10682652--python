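"""Velocity-pressure loop construction, landmarks and derived indices.

A VP loop is the parametric curve of LVOT flow velocity (abscissa, cm/s)
against ascending-aorta pressure (ordinate, mmHg) over one averaged cardiac
cycle.  From the loop we extract the landmark points — peak velocity Vmax,
ejection-onset velocity Vo, peak (systolic) pressure Pmax, and the pressures
coincident with Vmax and Vo — and from those the chord angles ALPHA, BETA
and GALA and the stenosis-burden index

    slope_index = [P(Vmax) - P(Vo)] / Vmax        (mmHg per cm/s)

which satisfies tan(ALPHA) = slope_index exactly under the native-unit axis
convention used here (1 cm/s and 1 mmHg are one axis unit each; angles are
measured from the velocity axis).

P(Vo) is the beat's minimum (diastolic) pressure.  A simplified clinical
path estimates P(Vmax) without building the loop, by applying the R-wave to
Doppler-peak delay to the pressure recording
(:func:`pressure_at_vmax_by_rwave`).

The BETA and GALA chord definitions use only the named landmarks:
BETA is the late-systolic chord from (Vmax, P(Vmax)) to (V(Pmax), Pmax),
GALA the global chord from (0, P(Vo)) to (V(Pmax), Pmax).  Both are
provisional conventions (see docs/methods.md) and are isolated in one
function each so they can be swapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import Channel, MeshedBeat, SampledTrace, TraceValidationError

__all__ = [
    "VPLoop",
    "LoopLandmarks",
    "LoopFeatures",
    "DegenerateLoopError",
    "build_loop",
    "extract_landmarks",
    "pressure_at_vmax_by_rwave",
    "compute_features",
    "features_to_dict",
    "beta_angle_deg",
    "gala_angle_deg",
]

#: ejection-onset velocity threshold as a fraction of Vmax
DEFAULT_ONSET_FRACTION = 0.05

#: maximum tolerated relative duration mismatch between the paired beats
MAX_DURATION_MISMATCH = 0.10


class DegenerateLoopError(ValueError):
    """The loop carries no usable velocity information."""


@dataclass(frozen=True)
class VPLoop:
    """An averaged cardiac cycle as paired (velocity, pressure) samples."""

    mesh: np.ndarray      # relative seconds, uniform, shared
    velocity: np.ndarray  # cm/s
    pressure: np.ndarray  # mmHg

    def __post_init__(self):
        object.__setattr__(self, "mesh", np.asarray(self.mesh, dtype=float))
        object.__setattr__(self, "velocity", np.asarray(self.velocity, dtype=float))
        object.__setattr__(self, "pressure", np.asarray(self.pressure, dtype=float))
        if not (self.mesh.size == self.velocity.size == self.pressure.size):
            raise TraceValidationError("mesh, velocity, pressure length mismatch")
        steps = np.diff(self.mesh)
        if not np.all(steps > 0):
            raise TraceValidationError("loop mesh must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
            raise TraceValidationError("loop mesh must be uniform")

    @property
    def duration(self) -> float:
        return float(self.mesh[-1] - self.mesh[0])


@dataclass(frozen=True)
class LoopLandmarks:
    """Landmark points of one VP loop (times relative to the R-peak)."""

    Vmax: float    # peak LVOT velocity, cm/s
    t_Vmax: float  # s
    Vo: float      # velocity at ejection onset, cm/s
    t_Vo: float    # s
    P_Vo: float    # minimum (diastolic) pressure over the beat, mmHg
    P_Vmax: float  # pressure at t_Vmax, mmHg
    Pmax: float    # peak (systolic) pressure, mmHg
    t_Pmax: float  # s
    V_Pmax: float  # velocity at t_Pmax, cm/s

    def __post_init__(self):
        if self.Vo > self.Vmax:
            raise TraceValidationError("Vo cannot exceed Vmax")
        if self.P_Vo > self.Pmax:
            raise TraceValidationError("P_Vo cannot exceed Pmax")


@dataclass(frozen=True)
class LoopFeatures:
    """Chord angles and derived indices of one VP loop."""

    alpha_deg: float    # arctan of slope_index, degrees
    beta_deg: float     # late-systolic chord angle, degrees
    gala_deg: float     # global chord angle, degrees
    dP_ejection: float  # P(Vmax) - P(Vo), mmHg
    slope_index: float  # [P(Vmax) - P(Vo)] / Vmax, mmHg per cm/s
    late_rise: float    # Pmax - P(Vmax), mmHg
    landmarks: LoopLandmarks


def build_loop(pressure_beat: MeshedBeat, velocity_beat: MeshedBeat) -> VPLoop:
    """Pair an averaged pressure beat with an averaged velocity beat.

    Both beats must be on meshes of identical length with durations within
    10% of each other.  Identical meshes are used as-is; slightly different
    durations are reconciled by placing both channels on the uniform mesh of
    the mean duration (no value re-interpolation — uniform meshes of equal
    length map point-for-point).
    """
    if pressure_beat.channel is not Channel.PRESSURE:
        raise ValueError("first argument must be the pressure beat")
    if velocity_beat.channel is not Channel.VELOCITY:
        raise ValueError("second argument must be the velocity beat")
    if pressure_beat.n_points != velocity_beat.n_points:
        raise TraceValidationError(
            f"mesh length mismatch: {pressure_beat.n_points} vs "
            f"{velocity_beat.n_points}"
        )
    dp, dv = pressure_beat.duration, velocity_beat.duration
    if abs(dp - dv) > MAX_DURATION_MISMATCH * max(dp, dv):
        raise TraceValidationError(
            f"beat durations differ by more than 10% ({dp:.3f} s vs {dv:.3f} s); "
            "re-segment the traces on consistent R-peaks"
        )
    if np.array_equal(pressure_beat.mesh, velocity_beat.mesh):
        mesh = pressure_beat.mesh
    else:
        mesh = np.linspace(0.0, 0.5 * (dp + dv), pressure_beat.n_points)
    return VPLoop(mesh, velocity_beat.values, pressure_beat.values)


def extract_landmarks(
    loop: VPLoop, onset_fraction: float = DEFAULT_ONSET_FRACTION
) -> LoopLandmarks:
    """Locate the loop landmarks on the mesh.

    Vmax/Pmax are mesh maxima (first occurrence on ties); P(Vmax) and
    V(Pmax) are read at the corresponding mesh times; Vo is the velocity at
    the first mesh point reaching ``onset_fraction`` of Vmax; P(Vo) is the
    minimum pressure over the beat, i.e. the diastolic pressure.
    """
    v, p, t = loop.velocity, loop.pressure, loop.mesh
    if np.all(v == 0):
        raise DegenerateLoopError("all-zero velocity: degenerate loop")
    i_vmax = int(np.argmax(v))
    i_pmax = int(np.argmax(p))
    vmax = float(v[i_vmax])
    onset_idx = int(np.argmax(v >= onset_fraction * vmax))
    return LoopLandmarks(
        Vmax=vmax,
        t_Vmax=float(t[i_vmax]),
        Vo=float(v[onset_idx]),
        t_Vo=float(t[onset_idx]),
        P_Vo=float(np.min(p)),
        P_Vmax=float(p[i_vmax]),
        Pmax=float(p[i_pmax]),
        t_Pmax=float(t[i_pmax]),
        V_Pmax=float(v[i_pmax]),
    )


def pressure_at_vmax_by_rwave(pressure: SampledTrace, t_r_to_vmax: float) -> float:
    """Estimate P(Vmax) from the R-wave to Doppler-peak delay alone.

    For every complete beat the pressure is linearly interpolated at
    (R-peak + ``t_r_to_vmax``) and the per-beat values are averaged.  This is
    the simplified clinical path: the delay is read off the Doppler tracing
    (both recordings share the ECG lead) and applied to the pressure curve
    without constructing the loop.
    """
    if pressure.channel is not Channel.PRESSURE:
        raise ValueError("expected a pressure trace")
    r = pressure.r_peaks
    if r.size < 1:
        raise TraceValidationError("pressure trace has no R-peak annotations")
    if t_r_to_vmax < 0:
        raise ValueError("t_r_to_vmax must be non-negative")
    if r.size >= 2:
        rr = np.diff(r)
        if np.any(t_r_to_vmax >= rr):
            raise ValueError(
                f"offset {t_r_to_vmax:.3f} s reaches beyond a beat "
                f"(min R-R {rr.min():.3f} s)"
            )
        starts = r[:-1]
    else:
        if r[0] + t_r_to_vmax > pressure.times[-1]:
            raise ValueError("offset reaches beyond the recorded pressure trace")
        starts = r
    samples = np.interp(starts + t_r_to_vmax, pressure.times, pressure.values)
    return float(np.mean(samples))


def beta_angle_deg(landmarks: LoopLandmarks) -> float:
    """Late-systolic chord angle from (Vmax, P(Vmax)) to (V(Pmax), Pmax)."""
    return math.degrees(
        math.atan2(landmarks.Pmax - landmarks.P_Vmax,
                   landmarks.Vmax - landmarks.V_Pmax)
    )


def gala_angle_deg(landmarks: LoopLandmarks) -> float:
    """Global chord angle from (0, P(Vo)) to (V(Pmax), Pmax)."""
    return math.degrees(
        math.atan2(landmarks.Pmax - landmarks.P_Vo, landmarks.V_Pmax)
    )


def compute_features(landmarks: LoopLandmarks) -> LoopFeatures:
    """Derive the chord angles and the slope index from the loop landmarks.

    ``slope_index = (P(Vmax) - P(Vo)) / Vmax`` with Vmax in cm/s, so
    ``tan(alpha_deg) == slope_index`` holds as an exact algebraic identity.
    """
    if landmarks.Vmax <= 0:
        raise DegenerateLoopError("Vmax must be positive to compute features")
    slope = (landmarks.P_Vmax - landmarks.P_Vo) / landmarks.Vmax
    return LoopFeatures(
        alpha_deg=math.degrees(math.atan(slope)),
        beta_deg=beta_angle_deg(landmarks),
        gala_deg=gala_angle_deg(landmarks),
        dP_ejection=landmarks.P_Vmax - landmarks.P_Vo,
        slope_index=slope,
        late_rise=landmarks.Pmax - landmarks.P_Vmax,
        landmarks=landmarks,
    )


def features_to_dict(features: LoopFeatures) -> dict:
    """Flatten features + landmarks to a JSON-ready dict, units in key names."""
    lm = features.landmarks
    return {
        "alpha_deg": features.alpha_deg,
        "beta_deg": features.beta_deg,
        "gala_deg": features.gala_deg,
        "dP_ejection_mmHg": features.dP_ejection,
        "slope_index_mmHg_per_cm_s": features.slope_index,
        "late_rise_mmHg": features.late_rise,
        "landmarks": {
            "Vmax_cm_s": lm.Vmax,
            "t_Vmax_s": lm.t_Vmax,
            "Vo_cm_s": lm.Vo,
            "t_Vo_s": lm.t_Vo,
            "P_Vo_mmHg": lm.P_Vo,
            "P_Vmax_mmHg": lm.P_Vmax,
            "Pmax_mmHg": lm.Pmax,
            "t_Pmax_s": lm.t_Pmax,
            "V_Pmax_cm_s": lm.V_Pmax,
        },
    }
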