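"""Synthetic ground-truth data: procedural torso phantom, breathing traces,
consistent/invertible ground-truth motion, and simulated slice acquisition.

The phantom is a procedural stand-in for an anthropomorphic torso: a body
ellipsoid containing two lungs bounded below by a diaphragm dome, a tumour
inside one lung, intra-lung vessel structures (which provide the intensity
features that drive registration and model fitting), a heart analog between
the lungs and a liver analog below the right diaphragm.

Ground-truth motion comes in two flavours:

* ``svf``  — the displacement for a breathing state (a1, a2) is the
  scaling-and-squaring exponential of the stationary velocity field
  ``a1*v_A + a2*v_B``; forward and backward fields are exponentials of the
  field and its negation and hence mutually inverse by construction.
* ``span`` — the backward displacement is the cubic B-spline field
  ``a1*W_A + a2*W_B`` on a control lattice, i.e. motion that is exactly
  representable by the fitted correspondence model.  This separates model
  discretisation error from fitting error in parameter-recovery studies.

Breathing is driven by two signals: a1 (SI-dominant amplitude, raised-cosine
cycles with per-cycle period and amplitude jitter) and a2 (a scaled temporal
derivative of a1, producing hysteresis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage

from . import interp
from .acquisition import SliceOperator, SliceSchedule
from .ffd import DVF, FFDGrid
from .geometry import ROIMaskSet, VolumeImage

SOFT_TISSUE_INTENSITY = 100.0


class SpecError(ValueError):
    pass


class RangeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------
@dataclass
class PhantomSpec:
    fov_mm: tuple[float, float, float] = (128.0, 128.0, 128.0)
    spacing_mm: float = 2.0
    body_semiaxes: tuple[float, float, float] = (55.0, 45.0, 60.0)
    lung_semiaxes: tuple[float, float, float] = (17.0, 25.0, 29.0)
    lung_offset_lr: float = 22.0
    diaphragm_height: float = 14.0
    tumour_centre: tuple[float, float, float] | None = None  # default: inside right lung
    tumour_radius: float = 8.0
    n_vessels: int = 14
    vessel_radius_range: tuple[float, float] = (1.6, 3.4)
    intensities: dict = field(
        default_factory=lambda: dict(
            air=0.0, body=SOFT_TISSUE_INTENSITY, lung=18.0, vessel=130.0,
            tumour=150.0, heart=115.0, liver=108.0,
        )
    )
    inhomogeneity: float = 0.06
    # soft-tissue texture (fractional sd ~ 2 x amplitude / 100): real T1
    # anatomy carries visible structure everywhere; a near-uniform interior
    # would make interior motion unobservable to image registration
    texture_amplitude: float = 6.0
    seed: int = 0


def _ellipsoid(X, Y, Z, centre, semi):
    return ((X - centre[0]) / semi[0]) ** 2 + ((Y - centre[1]) / semi[1]) ** 2 + (
        (Z - centre[2]) / semi[2]
    ) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, ROIMaskSet]:
    """Render the procedural torso phantom; deterministic given ``spec.seed``."""
    if min(spec.intensities.values()) < 0:
        raise SpecError("intensities must be non-negative")
    rng = np.random.default_rng(spec.seed)
    sp = float(spec.spacing_mm)
    n = tuple(int(round(f / sp)) for f in spec.fov_mm)
    vol = VolumeImage(values=np.zeros(n), spacing=(sp, sp, sp), origin=(0.0, 0.0, 0.0))
    cx, cy, cz = [(m - 1) * sp / 2.0 for m in n]
    ax = [vol.axis_coords(a) for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")

    body = _ellipsoid(X, Y, Z, (cx, cy, cz), spec.body_semiaxes)
    z_base = cz - 8.0
    lung_centre_z = z_base + spec.lung_semiaxes[2] * 0.8
    lungs = np.zeros(n, dtype=bool)
    dome_r2 = ((X - cx) ** 2 / 30.0**2) + ((Y - cy) ** 2 / 28.0**2)
    for side in (-1.0, 1.0):
        lc = (cx + side * spec.lung_offset_lr, cy, lung_centre_z)
        ell = _ellipsoid(X, Y, Z, lc, spec.lung_semiaxes)
        dome = Z > (z_base + spec.diaphragm_height * np.exp(-dome_r2))
        lungs |= ell & dome
    lungs &= body

    heart = _ellipsoid(X, Y, Z, (cx, cy + 8.0, z_base + 22.0), (13.0, 12.0, 18.0)) & body
    heart &= ~lungs
    liver = (
        body
        & (Z <= z_base + spec.diaphragm_height * np.exp(-dome_r2) + 1e-9)
        & (Z >= z_base - 38.0)
        & (X < cx + 2.0)
        & ~heart
    )

    if spec.tumour_centre is None:
        tumour_centre = (cx - spec.lung_offset_lr, cy, lung_centre_z - 4.0)
    else:
        tumour_centre = spec.tumour_centre
    if spec.tumour_radius > 0:
        tumour = _ellipsoid(X, Y, Z, tumour_centre, (spec.tumour_radius,) * 3)
        if not tumour.any() or not np.all(lungs[tumour]):
            raise SpecError("tumour must lie inside a lung")
    else:
        warnings.warn("tumour radius is zero: empty tumour mask")
        tumour = np.zeros(n, dtype=bool)

    vessels = np.zeros(n, dtype=bool)
    lung_idx = np.argwhere(lungs & ~tumour)
    for _ in range(spec.n_vessels):
        for _attempt in range(50):
            c_idx = lung_idx[rng.integers(len(lung_idx))]
            centre = vol.origin + c_idx * vol.spacing
            r = rng.uniform(*spec.vessel_radius_range)
            ball = _ellipsoid(X, Y, Z, centre, (r, r, r))
            if np.all(lungs[ball]) and not np.any(tumour[ball]):
                vessels |= ball
                break

    ints = spec.intensities
    values = np.zeros(n)
    values[body] = ints["body"]
    values[liver] = ints["liver"]
    values[heart] = ints["heart"]
    values[lungs] = ints["lung"]
    values[vessels] = ints["vessel"]
    values[tumour] = ints["tumour"]

    # mild smooth intensity inhomogeneity + texture (soft-tissue structure)
    blob = np.exp(
        -(((X - cx - 20) / 70.0) ** 2 + ((Y - cy + 15) / 80.0) ** 2 + ((Z - cz) / 90.0) ** 2)
    )
    values *= 1.0 + spec.inhomogeneity * (blob - 0.5)
    if spec.texture_amplitude > 0:
        noise = rng.standard_normal(n)
        texture = ndimage.gaussian_filter(noise, sigma=3.0)
        texture /= max(np.abs(texture).max(), 1e-12)
        values[body] += spec.texture_amplitude * texture[body] * 2.0
    values = np.clip(values, 0.0, None)

    vol = vol.copy_with(values)
    masks = ROIMaskSet(
        masks=dict(body=body, lungs=lungs | tumour | vessels, tumour=tumour, liver=liver, heart=heart),
        reference=vol,
    )
    return vol, masks


# ---------------------------------------------------------------------------
# breathing trace
# ---------------------------------------------------------------------------
@dataclass
class TraceConfig:
    mean_period_s: float = 4.0
    period_jitter_s: float = 0.5
    amplitude_jitter: float = 0.15
    a2_scale: float = 0.4  # seconds; a2 = a2_scale * d(a1)/dt
    drift_per_min: float = 0.0
    centre_median: bool = True


@dataclass
class BreathingTrace:
    a1: np.ndarray
    a2: np.ndarray
    t_seconds: np.ndarray
    frame_interval: float
    config: TraceConfig
    seed: int

    def state(self, t_index: int) -> tuple[float, float]:
        return float(self.a1[t_index]), float(self.a2[t_index])

    def __len__(self):
        return self.a1.shape[0]


def generate_trace(
    config: TraceConfig, n_frames: int, frame_interval: float, seed: int
) -> BreathingTrace:
    """Cycle-by-cycle raised-cosine breathing trace with jitter.

    a1 rises from end-exhale (0) to end-inhale (cycle amplitude); a2 is the
    scaled temporal derivative, giving hysteresis.  With ``centre_median``
    the empirical median of a1 is subtracted so the modelled reference
    (median) position sits near zero displacement.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    total = n_frames * frame_interval
    starts, periods, amps = [], [], []
    t0 = 0.0
    while t0 < total:
        for _ in range(100):
            period = rng.normal(config.mean_period_s, config.period_jitter_s)
            if period > 0.5:
                break
        else:
            raise RuntimeError("could not draw a positive cycle period")
        for _ in range(100):
            amp = rng.normal(1.0, config.amplitude_jitter)
            if amp > 0.05:
                break
        else:
            raise RuntimeError("could not draw a positive cycle amplitude")
        starts.append(t0)
        periods.append(period)
        amps.append(amp)
        t0 += period
    starts = np.asarray(starts)
    t = np.arange(n_frames) * frame_interval
    cyc = np.searchsorted(starts, t, side="right") - 1
    tau = t - starts[cyc]
    period = np.asarray(periods)[cyc]
    amp = np.asarray(amps)[cyc]
    phase = 2.0 * np.pi * tau / period
    a1 = amp * 0.5 * (1.0 - np.cos(phase))
    a2 = config.a2_scale * amp * (np.pi / period) * np.sin(phase)
    if config.drift_per_min:
        a1 = a1 + config.drift_per_min * t / 60.0
    if config.centre_median:
        # centre on the *vector median* state: the element of {(a1, a2)}
        # minimising summed distances, i.e. the same convention the
        # modelling pipeline uses for its zero-signal reference state
        from scipy.spatial.distance import cdist

        pts = np.column_stack([a1, a2])
        sub = pts[:: max(1, len(pts) // 400)]  # median of a subsample is ample
        k = int(np.argmin(cdist(sub, sub).sum(axis=1)))
        a1 = a1 - sub[k, 0]
        a2 = a2 - sub[k, 1]
    return BreathingTrace(
        a1=a1, a2=a2, t_seconds=t, frame_interval=frame_interval, config=config, seed=seed
    )


# ---------------------------------------------------------------------------
# ground-truth motion
# ---------------------------------------------------------------------------
def compose_displacement(u_first: np.ndarray, u_then: np.ndarray, spacing) -> np.ndarray:
    """phi = (x + u_then) o (x + u_first):  u(x) = u_first(x) + u_then(x + u_first(x)).

    ``u_then`` is sampled with linear interpolation; where the displaced
    point leaves the lattice the second field contributes zero.
    """
    spacing = np.asarray(spacing, dtype=np.float64)
    shape = u_first.shape[:-1]
    base = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    coords = base + u_first / spacing
    out = u_first.copy()
    for c in range(3):
        vals, _ = interp.gather(u_then[..., c], coords)
        out[..., c] += vals
    return out


def invert_displacement(u: np.ndarray, spacing, n_iter: int = 25) -> np.ndarray:
    """Fixed-point inverse:  u_inv(x) = -u(x + u_inv(x))."""
    spacing = np.asarray(spacing, dtype=np.float64)
    shape = u.shape[:-1]
    base = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    u_inv = -u
    for _ in range(n_iter):
        coords = base + u_inv / spacing
        new = np.empty_like(u_inv)
        for c in range(3):
            vals, _ = interp.gather(u[..., c], coords)
            new[..., c] = -vals
        u_inv = new
    return u_inv


def exp_velocity(v: np.ndarray, spacing) -> np.ndarray:
    """Scaling-and-squaring exponential of a stationary velocity field."""
    spacing = np.asarray(spacing, dtype=np.float64)
    mx = np.max(np.linalg.norm(v, axis=-1))
    if mx == 0:
        return np.zeros_like(v)
    k = max(0, int(np.ceil(np.log2(mx / (0.25 * float(np.min(spacing)))))))
    u = v / (2.0**k)
    for _ in range(k):
        u = compose_displacement(u, u, spacing)
    return u


@dataclass
class GroundTruthMotion:
    """Invertible forward/backward ground-truth DVF generator.

    ``mode='svf'``: v_A/v_B are velocity volumes; the displacement for a
    state is the scaling-and-squaring exponential.
    ``mode='span'``: W_A/W_B are B-spline grids; the *backward* (t->0)
    displacement is exactly their linear combination.

    All field arithmetic (exponentials, compositions, inversions) runs on
    a lattice padded by ``pad`` voxels around the phantom FOV so that
    sample paths leaving the FOV stay supported; public fields are cropped
    back to the phantom lattice.
    """

    mode: str
    spacing: np.ndarray
    origin: np.ndarray
    shape: tuple[int, int, int]
    pad: int = 0
    v_A: np.ndarray | None = None  # on the padded lattice (svf mode)
    v_B: np.ndarray | None = None
    W_A: FFDGrid | None = None
    W_B: FFDGrid | None = None
    max_displacement_mm: float = 40.0

    def _check_range(self, a1: float, a2: float):
        if self.mode == "svf":
            v = a1 * self.v_A + a2 * self.v_B
            mx = np.max(np.linalg.norm(v, axis=-1))
        else:
            mx = np.max(
                np.linalg.norm(
                    a1 * self.W_A.displacements + a2 * self.W_B.displacements, axis=-1
                )
            )
        if mx > self.max_displacement_mm:
            raise RangeError(
                f"displacement {mx:.1f} mm exceeds configured bound "
                f"{self.max_displacement_mm} mm at state ({a1:.2f}, {a2:.2f})"
            )

    def backward_grid(self, a1: float, a2: float) -> FFDGrid:
        """span mode: B-spline grid of u_{t->0}.

        The driving fields W describe the anatomy's displacement d(a); the
        pull-back field that renders frame t from the reference anatomy is
        (to first order) its negation, matching the svf convention
        u_{t->0} = exp(-v(a)).
        """
        if self.mode != "span":
            raise ValueError("backward_grid is only defined for span-mode motion")
        self._check_range(a1, a2)
        return (-a1) * self.W_A + (-a2) * self.W_B

    def _padded_coords(self):
        p = self.pad
        return [
            self.origin[a] + (np.arange(self.shape[a] + 2 * p) - p) * self.spacing[a]
            for a in range(3)
        ]

    def _crop(self, u: np.ndarray) -> np.ndarray:
        p = self.pad
        if p == 0:
            return u
        return np.ascontiguousarray(u[p:-p, p:-p, p:-p])

    def _backward_padded(self, a1: float, a2: float) -> np.ndarray:
        self._check_range(a1, a2)
        if self.mode == "svf":
            return exp_velocity(-(a1 * self.v_A + a2 * self.v_B), self.spacing)
        return self.backward_grid(a1, a2).displacement_on_lattice(self._padded_coords())

    def _forward_padded(self, a1: float, a2: float) -> np.ndarray:
        self._check_range(a1, a2)
        if self.mode == "svf":
            return exp_velocity(a1 * self.v_A + a2 * self.v_B, self.spacing)
        return invert_displacement(self._backward_padded(a1, a2), self.spacing)

    def backward_field(self, a1: float, a2: float) -> np.ndarray:
        """u_{t->0} sampled on the phantom lattice."""
        return self._crop(self._backward_padded(a1, a2))

    def forward_field(self, a1: float, a2: float) -> np.ndarray:
        """u_{0->t} sampled on the phantom lattice."""
        return self._crop(self._forward_padded(a1, a2))

    def dvf(self, a1: float, a2: float, direction: str = "backward") -> DVF:
        f = self.backward_field if direction == "backward" else self.forward_field
        tag = "t->0" if direction == "backward" else "0->t"
        return DVF(values=f(a1, a2), spacing=self.spacing, origin=self.origin, direction=tag)

    def between_field(self, state_a, state_b, forward_b: np.ndarray | None = None) -> np.ndarray:
        """u_{ta->tb} by composition: u_{0->tb}(x + u_{ta->0}(x)) + u_{ta->0}(x).

        ``forward_b`` may carry a precomputed *padded* u_{0->tb} (reused
        across many ta when tb is the fixed reference state; see
        :meth:`forward_padded`).
        """
        u_a0 = self._backward_padded(*state_a)
        u_0b = self._forward_padded(*state_b) if forward_b is None else forward_b
        return self._crop(compose_displacement(u_a0, u_0b, self.spacing))

    def forward_padded(self, a1: float, a2: float) -> np.ndarray:
        """Padded u_{0->t} for reuse in repeated compositions."""
        return self._forward_padded(a1, a2)

    def invertibility_residual(self, a1: float, a2: float) -> np.ndarray:
        """|u_fwd o u_bwd| residual field (mm) on the phantom lattice."""
        fwd = self._forward_padded(a1, a2)
        bwd = self._backward_padded(a1, a2)
        res = compose_displacement(fwd, bwd, self.spacing)
        return np.linalg.norm(self._crop(res), axis=-1)

    def between(self, state_a, state_b, forward_b=None) -> DVF:
        return DVF(
            values=self.between_field(state_a, state_b, forward_b=forward_b),
            spacing=self.spacing,
            origin=self.origin,
            direction="ta->tb",
        )


def _analytic_velocity(points: np.ndarray, vol: VolumeImage, peak_si_mm: float):
    """The two analytic driving fields at world points (..., 3).

    v_A: SI-dominant, largest at/below the diaphragm analog and decaying
    upward, with a smaller chest AP component.  v_B: concentrated around
    the diaphragm with AP/LR weight, linearly independent of v_A, so the
    (a1, a2) pair produces hysteresis loops.
    """
    X, Y, Z = points[..., 0], points[..., 1], points[..., 2]
    cx, cy, cz = [(m - 1) * s / 2.0 for m, s in zip(vol.shape, vol.spacing)]
    z_base = cz - 8.0
    s_z = 1.0 / (1.0 + np.exp((Z - (z_base + 22.0)) / 16.0))
    s_z *= 1.0 / (1.0 + np.exp(((z_base - 40.0) - Z) / 7.0))
    # flat-top laterally with a decisive rolloff toward the chest wall:
    # the interior (diaphragm/abdomen) moves, the body surface barely does
    r_xy = np.exp(-(((X - cx) / 52.0) ** 4 + ((Y - cy) / 48.0) ** 4))
    s_chest = 1.0 / (1.0 + np.exp(-(Z - z_base) / 20.0))
    g_z = np.exp(-(((Z - z_base) / 34.0) ** 2))

    A = float(peak_si_mm)
    vA = np.zeros(points.shape)
    vA[..., 2] = -A * s_z * r_xy
    vA[..., 1] = 0.30 * A * s_chest * r_xy
    vB = np.zeros(points.shape)
    vB[..., 2] = -0.30 * A * g_z * r_xy
    vB[..., 1] = 0.40 * A * g_z * r_xy
    vB[..., 0] = 0.12 * A * g_z * r_xy * (X - cx) / 50.0
    return vA, vB


def build_motion(
    vol: VolumeImage,
    peak_si_mm: float = 10.0,
    mode: str = "svf",
    control_spacing_mm: float = 16.0,
    pad_mm: float = 24.0,
    max_displacement_mm: float = 40.0,
) -> GroundTruthMotion:
    """Construct ground-truth motion for a phantom lattice.

    Peak SI displacement near the diaphragm analog is ``peak_si_mm``
    (realistic range 5-20 mm); AP and LR components are smaller by
    construction.  ``span`` mode samples the same analytic fields at the
    control points of a B-spline lattice covering the (padded) FOV.
    """
    if not 0.0 <= peak_si_mm <= max_displacement_mm:
        raise RangeError("peak_si_mm outside configured displacement bound")
    pad = int(np.ceil(pad_mm / float(np.min(vol.spacing))))
    if mode == "svf":
        coords = [
            vol.origin[a] + (np.arange(vol.shape[a] + 2 * pad) - pad) * vol.spacing[a]
            for a in range(3)
        ]
        pts = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1)
        vA, vB = _analytic_velocity(pts, vol, peak_si_mm)
        return GroundTruthMotion(
            mode="svf", spacing=vol.spacing.copy(), origin=vol.origin.copy(), shape=vol.shape,
            pad=pad, v_A=vA, v_B=vB, max_displacement_mm=max_displacement_mm,
        )
    if mode != "span":
        raise ValueError(f"unknown motion mode {mode!r}")
    lo, hi = vol.fov_bounds()
    grid = FFDGrid.for_fov(lo - pad_mm - 8.0, hi + pad_mm + 8.0, control_spacing_mm)
    pts = np.stack(
        np.meshgrid(
            *[grid.origin[a] + np.arange(grid.n_points[a]) * grid.spacing[a] for a in range(3)],
            indexing="ij",
        ),
        axis=-1,
    )
    vA_cp, vB_cp = _analytic_velocity(pts, vol, peak_si_mm)
    return GroundTruthMotion(
        mode="span", spacing=vol.spacing.copy(), origin=vol.origin.copy(), shape=vol.shape,
        pad=pad, W_A=grid.with_displacements(vA_cp), W_B=grid.with_displacements(vB_cp),
        max_displacement_mm=max_displacement_mm,
    )


# ---------------------------------------------------------------------------
# slice acquisition simulation
# ---------------------------------------------------------------------------
def rician(values: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the complex sum of the signal and two Gaussian channels."""
    if sigma <= 0:
        return values
    n1 = rng.normal(0.0, sigma, size=values.shape)
    n2 = rng.normal(0.0, sigma, size=values.shape)
    return np.sqrt((values + n1) ** 2 + n2**2)


def simulate_acquisition(
    phantom: VolumeImage,
    masks: ROIMaskSet,
    motion: GroundTruthMotion,
    trace: BreathingTrace,
    schedule: SliceSchedule,
    noise_sigma_rel: float = 0.05,
    seed: int = 0,
    building_repetitions: tuple[int, ...] | None = None,
    evaluation_repetitions: tuple[int, ...] | None = None,
):
    """Simulate the interleaved thick-slice acquisition of a moving phantom.

    For each schedule entry the phantom is deformed by the backward
    ground-truth DVF of the trace state at that frame, the Gaussian-profile
    slice is extracted and Rician noise (sd = ``noise_sigma_rel`` x the
    soft-tissue intensity) added.  The driving state is stored per slice.
    """
    from .dataset import SliceDataset

    if len(trace) < len(schedule):
        raise ValueError("trace shorter than schedule")
    rng = np.random.default_rng(seed)
    sigma = noise_sigma_rel * SOFT_TISSUE_INTENSITY
    ops: dict = {}
    slices = []
    for entry in schedule:
        g = entry.geometry
        key = (tuple(g.origin), tuple(g.normal), g.shape, g.thickness)
        if key not in ops:
            ops[key] = SliceOperator(g, phantom)
        op = ops[key]
        a1, a2 = trace.state(entry.t_index)
        if motion is None or (a1 == 0.0 and a2 == 0.0 and motion.mode == "span"):
            disp_quad = None
        elif motion.mode == "span":
            disp_quad = op.displacement_from_grid(motion.backward_grid(a1, a2))
        else:
            u_vol = motion.backward_field(a1, a2)
            coords = op.static_vox_coords()
            disp_quad = np.stack(
                [interp.gather(u_vol[..., c], coords)[0] for c in range(3)], axis=-1
            )
        vals, valid = op.forward_deformed(phantom.values, disp_quad)
        vals = rician(vals, sigma, rng)
        from .geometry import DynamicSlice

        slices.append(
            DynamicSlice(
                geometry=g,
                values=vals,
                t_index=entry.t_index,
                t_seconds=entry.t_seconds,
                role=entry.role,
                valid=valid,
                meta=dict(
                    a1=a1, a2=a2, repetition=entry.repetition, shift_mm=entry.shift_mm,
                    orientation=entry.orientation, station=entry.station,
                ),
            )
        )
    n_rep = schedule.params.get("n_repetitions", 1)
    if building_repetitions is None:
        building_repetitions = tuple(range(1, min(3, n_rep) + 1))
    if evaluation_repetitions is None:
        evaluation_repetitions = tuple(r for r in range(1, n_rep + 1) if r not in building_repetitions)
    return SliceDataset(
        slices=slices,
        schedule=schedule,
        ref_geometry=VolumeImage(
            values=np.zeros(phantom.shape), spacing=phantom.spacing, origin=phantom.origin
        ),
        trace=trace,
        motion=motion,
        phantom=phantom,
        masks=masks,
        building_repetitions=tuple(building_repetitions),
        evaluation_repetitions=tuple(evaluation_repetitions),
        seed=seed,
        noise_sigma_rel=noise_sigma_rel,
    )
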