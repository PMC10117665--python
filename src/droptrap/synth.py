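"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: heading cohorts for
the three mobility classes, tracer/fish image stacks advected by the flow
models, and no-flow random-walk tracks for MSD work.  Defaults mirror the
experimental conditions: a 12 mm droplet, 20 fps fish video, 30 fps tracer
video, 1 um-scale tracer spots, cohorts of five fish per class observed for
5 min (20 min for the recovery class).

Mobility classes
----------------
type_i      untreated, fully mobile; activity ``A = 5 * eps`` (well above the
            critical ``2 * eps``), which with ``Dr = 0.05 rad^2/s`` holds the
            heading in a ~20-degree band around the source axis.
type_ii     anesthetized; ``A = 0`` (pure passive rod).
type_iii    recovering from anesthesia; ``A`` ramps linearly 0 -> 5*eps over
            20 simulated minutes.
lipin1      motor-neuron-deficient; parameterized identically to type_ii
            (no recovery) but kept as a distinct label in reports.

Every generator is a pure function of its spec and seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .flow import FlowField, FlowPattern, velocity_at
from .swimmer import OrientationTrajectory, SimConfig, SwimmerParams, simulate
from .tracking import Detection, FrameStack, TrackedTrajectory

ACTIVITY_FACTOR_DEFAULT = 5.0  # A = factor * eps for a fully mobile fish


@dataclass(frozen=True)
class CohortSpec:
    """Study design for a synthetic cohort of individually housed fish."""

    n_per_class: dict = field(
        default_factory=lambda: {"type_i": 5, "type_ii": 5, "type_iii": 5}
    )
    strain_rate: float = 1.0  # 1/s; free parameter of the droplet flow
    rot_noise_Dr: float = 0.05  # rad^2/s
    dt: float = 0.01  # s integrator step (finer than the 20 fps video rate
    # so the explicit step resolves the fastest drift, eps + A)
    duration_s: float = 300.0  # 5 min observation for steady classes
    ramp_duration_s: float = 1200.0  # 20 min recovery ramp for type_iii
    activity_factor: float = ACTIVITY_FACTOR_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_class.values()):
            raise ValueError("all class counts must be >= 1")


@dataclass
class CohortFish:
    fish_id: str
    class_label: str  # ground truth
    activity_A: float  # ground-truth steady activity (final value for ramps)
    trajectory: OrientationTrajectory


def _fish_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(spec: CohortSpec) -> list[CohortFish]:
    """Simulate every fish of the cohort with its class parameters.

    Initial headings are uniform; per-fish seeds are spawned from the spec
    seed, so the cohort is fully deterministic and fish are independent.
    """
    eps = spec.strain_rate
    a_full = spec.activity_factor * eps
    out: list[CohortFish] = []
    for ci, label in enumerate(sorted(spec.n_per_class)):
        for k in range(spec.n_per_class[label]):
            child = np.random.SeedSequence(spec.seed, spawn_key=(ci, k))
            theta0 = float(np.random.default_rng(_fish_seed(child)).uniform(0, 360))
            sim_seed = _fish_seed(child.spawn(1)[0])
            if label == "type_iii":
                duration = spec.ramp_duration_s
                params = SwimmerParams(activity_A=a_full, rot_noise_Dr=spec.rot_noise_Dr)
                ramp = spec.ramp_duration_s

                def a_of_t(t: float, _full=a_full, _ramp=ramp) -> float:
                    return _full * min(t / _ramp, 1.0)

                traj = simulate(
                    params,
                    SimConfig(spec.dt, duration, theta0, sim_seed),
                    eps,
                    activity_fn=a_of_t,
                )
                a_truth = a_full
            else:
                a_truth = a_full if label == "type_i" else 0.0
                params = SwimmerParams(activity_A=a_truth, rot_noise_Dr=spec.rot_noise_Dr)
                traj = simulate(
                    params, SimConfig(spec.dt, spec.duration_s, theta0, sim_seed), eps
                )
            traj.meta["class_label"] = label
            traj.meta["fish_id"] = f"{label}_{k:02d}"
            out.append(CohortFish(f"{label}_{k:02d}", label, a_truth, traj))
    return out


@dataclass(frozen=True)
class SceneSpec:
    """Rendering recipe for a synthetic tracer/fish video."""

    pattern: FlowPattern = FlowPattern.FOUR_CELL_BOUNDED
    strain_rate: float = 1.0  # 1/s
    droplet_radius: float = 6.0e-3  # m (12 mm droplet)
    n_particles: int = 30
    min_separation_m: float = 0.0  # enforce initial particle spacing (0 = off)
    psf_sigma_px: float = 1.5
    particle_amplitude: float = 1.0
    noise_sigma: float = 0.02  # additive Gaussian intensity noise
    frame_rate: float = 30.0  # fps (tracer video)
    duration_s: float = 2.0
    px_scale: float = 20.0e-6  # m per pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if not self.psf_sigma_px > 0:
            raise ValueError("psf_sigma_px must be > 0")


def _add_gaussian_spot(img: np.ndarray, cx: float, cy: float, sigma: float, amp: float) -> None:
    H, W = img.shape
    r = int(math.ceil(4 * sigma))
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, W)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, H)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma * sigma))
    img[y0:y1, x0:x1] += amp * g


def _add_fish_ellipse(
    img: np.ndarray,
    cx: float,
    cy: float,
    angle_deg: float,
    half_len_px: float,
    half_wid_px: float,
    head_boost: float = 0.6,
) -> None:
    """Draw an oriented ellipse with a brighter head end (head = +axis tip).

    ``angle_deg`` is in the physical convention (counterclockwise, y up);
    image rows run downward, so the y offset is negated.
    """
    H, W = img.shape
    r = int(math.ceil(half_len_px)) + 2
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, W)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, H)
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    X, Y = np.meshgrid(xs, -ys)  # flip to physical y
    th = math.radians(angle_deg)
    xi = X * math.cos(th) + Y * math.sin(th)  # along-body coordinate
    eta = -X * math.sin(th) + Y * math.cos(th)
    inside = (xi / half_len_px) ** 2 + (eta / half_wid_px) ** 2 <= 1.0
    intensity = np.where(inside, 1.0 + head_boost * np.clip(xi / half_len_px, 0, 1), 0.0)
    img[y0:y1, x0:x1] += intensity


def _advect_rk2(flow: FlowField, x: np.ndarray, y: np.ndarray, dt: float):
    u1, v1 = velocity_at(flow, x, y, check_domain=False)
    xm, ym = x + 0.5 * dt * u1, y + 0.5 * dt * v1
    u2, v2 = velocity_at(flow, xm, ym, check_domain=False)
    xn, yn = x + dt * u2, y + dt * v2
    # keep tracers inside the droplet (discretization can push them out)
    r = np.hypot(xn, yn)
    R = flow.droplet_radius
    out = r > 0.995 * R
    if np.any(out):
        scale = 0.995 * R / r[out]
        xn[out] *= scale
        yn[out] *= scale
    return xn, yn


def render_scene(
    spec: SceneSpec,
    fish: OrientationTrajectory | None = None,
    *,
    fish_length_m: float = 4.0e-3,
    fish_width_m: float = 0.5e-3,
) -> tuple[FrameStack, list[list[Detection]]]:
    """Render a droplet scene and return it with per-frame ground truth.

    Tracer particles start uniformly inside the droplet, are advected by the
    flow field with RK2 steps at the frame interval, and are rendered as
    Gaussian spots; an optional fish is rendered at the droplet centre as an
    oriented ellipse with a brighter head, its per-frame angle taken from
    the supplied heading trajectory (nearest sample).  Seeded Gaussian
    noise is added and intensities are clipped at zero.

    The returned ground truth holds one :class:`Detection` per particle per
    frame (pixel coordinates) plus, when a fish is present, a final
    detection per frame with its centroid and orientation.
    """
    rng = np.random.default_rng(spec.seed)
    flow = FlowField(spec.pattern, spec.strain_rate, spec.droplet_radius)
    R = spec.droplet_radius
    n_px = int(math.ceil(2 * R / spec.px_scale)) + 9
    c_px = (n_px - 1) / 2.0
    n_frames = max(int(round(spec.duration_s * spec.frame_rate)), 2)
    dt = 1.0 / spec.frame_rate

    # uniform in the disk, kept away from the rim; optional rejection
    # sampling keeps initial positions at least min_separation_m apart
    xs: list[float] = []
    ys: list[float] = []
    attempts = 0
    max_attempts = 1000 * max(spec.n_particles, 1)
    while len(xs) < spec.n_particles:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("cannot place particles at the requested separation")
        rr = 0.93 * R * math.sqrt(rng.uniform())
        ph = rng.uniform(0, 2 * math.pi)
        cand = (rr * math.cos(ph), rr * math.sin(ph))
        if spec.min_separation_m > 0 and any(
            math.hypot(cand[0] - a, cand[1] - b) < spec.min_separation_m
            for a, b in zip(xs, ys)
        ):
            continue
        xs.append(cand[0])
        ys.append(cand[1])
    px_, py_ = np.array(xs), np.array(ys)

    frames = np.zeros((n_frames, n_px, n_px))
    truth: list[list[Detection]] = []
    half_len = 0.5 * fish_length_m / spec.px_scale
    half_wid = 0.5 * fish_width_m / spec.px_scale
    for k in range(n_frames):
        img = frames[k]
        gt: list[Detection] = []
        xp = px_ / spec.px_scale + c_px
        yp = c_px - py_ / spec.px_scale  # physical y up -> rows down
        for j in range(spec.n_particles):
            _add_gaussian_spot(img, xp[j], yp[j], spec.psf_sigma_px, spec.particle_amplitude)
            gt.append(Detection(k, float(xp[j]), float(yp[j]), 0))
        if fish is not None:
            i = min(int(round(k * dt / fish.dt)), len(fish.angles_deg) - 1)
            ang = float(fish.angles_deg[i])
            _add_fish_ellipse(img, c_px, c_px, ang, half_len, half_wid)
            gt.append(Detection(k, c_px, c_px, 0, ang % 180.0))
        truth.append(gt)
        if spec.noise_sigma > 0:
            img += rng.normal(0.0, spec.noise_sigma, img.shape)
            np.clip(img, 0.0, None, out=img)
        if k < n_frames - 1:
            px_, py_ = _advect_rk2(flow, px_, py_, dt)
    stack = FrameStack(
        frames,
        spec.frame_rate,
        spec.px_scale,
        meta={
            "pattern": spec.pattern.value,
            "strain_rate": spec.strain_rate,
            "droplet_radius": spec.droplet_radius,
            "seed": spec.seed,
        },
    )
    return stack, truth


def generate_pool_walk(
    n_steps: int,
    step_sigma: float,
    seed: int = 0,
    *,
    dt: float = 0.05,
    start: tuple[float, float] = (0.0, 0.0),
    bound_radius: float | None = None,
) -> TrackedTrajectory:
    """Seeded 2-D Gaussian random walk in physical units (no-flow pool).

    ``step_sigma`` is the per-step displacement s.d. per axis (m).  With
    ``bound_radius`` set, steps reflect off a circular wall, which makes the
    MSD saturate at long lags.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sigma, size=(n_steps - 1, 2))
    pos = np.empty((n_steps, 2))
    pos[0] = start
    for k in range(1, n_steps):
        p = pos[k - 1] + steps[k - 1]
        if bound_radius is not None:
            d = math.hypot(*p)
            if d > bound_radius:
                p *= (2 * bound_radius - d) / d  # radial reflection
        pos[k] = p
    times = np.arange(n_steps) * dt
    return TrackedTrajectory(0, np.arange(n_steps), times, pos[:, 0], pos[:, 1])
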