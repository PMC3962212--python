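"""Ground-truthed synthetic time-lapse movies and track sets.

Everything the pipeline assumes about real data is emulated here with known
parameters, so each stage can be verified end to end without external
recordings: cells move as a persistent random walk (discrete
Ornstein-Uhlenbeck velocity process, whose stationary law is exactly the
exponential velocity autocovariance / Fürth MSD the estimators fit),
centroid measurement noise is white Gaussian, and frames are rendered as
sparse bright Gaussian blobs on flat, ramped or grainy speckle backgrounds
(the speckle mimics nanostructured silicon-black substrates).

Default parameters match the reference study conditions: Δt = 2 min,
pixel size 0.977 µm, P = 35 min, φ₀ = 0.18 µm²/min², σ_pos = 1.40 µm,
~12 cells per ~12 h movie, 1024×768 frames, cells 30-50 px across.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import Track

__all__ = [
    "MotilityGroundTruth",
    "SceneParams",
    "glass_scene",
    "silicon_black_scene",
    "simulate_ou_tracks",
    "add_positional_noise",
    "render_frames",
    "make_comparison_fixture",
]

DEFAULT_PIXEL_SIZE = 0.977  # µm per pixel

# flat "glass" scene and grainy nanostructured ("silicon-black"-like) scene;
# the grainy level sits mid-range so the speckle does not clip at 8 bit
def glass_scene(**overrides) -> "SceneParams":
    return SceneParams(**overrides)


def silicon_black_scene(**overrides) -> "SceneParams":
    kwargs = dict(background_mode="grainy", background_level=100.0)
    kwargs.update(overrides)
    return SceneParams(**kwargs)


@dataclass(frozen=True)
class MotilityGroundTruth:
    """True motility parameters of a simulated cell population."""

    P_true: float = 35.0  # minutes
    phi0_true: float = 0.18  # µm²/min²
    sigma_pos_true: float = 0.0  # µm, per coordinate
    dt: float = 2.0  # minutes
    n_cells: int = 12
    n_frames: int = 360
    seed: int = 0

    def __post_init__(self) -> None:
        if self.P_true <= 0 or self.phi0_true <= 0 or self.dt <= 0:
            raise ValueError("P_true, phi0_true and dt must be positive")
        if self.sigma_pos_true < 0:
            raise ValueError("sigma_pos_true must be >= 0")
        if self.n_cells < 1 or self.n_frames < 2:
            raise ValueError("need n_cells >= 1 and n_frames >= 2")


@dataclass(frozen=True)
class SceneParams:
    """Rendering parameters for synthetic frames.

    `cell_radius` is the visible radius in px (cells ~30-50 px across);
    blobs are drawn as Gaussians of σ = cell_radius / 2. Background modes:
    flat (constant + pixel noise), gradient (linear illumination ramp),
    grainy (band-limited speckle of correlation length `grain_scale`,
    silicon-black-like).
    """

    frame_shape: tuple[int, int] = (768, 1024)  # rows, cols
    pixel_size: float = DEFAULT_PIXEL_SIZE
    cell_radius: float = 15.0
    cell_peak: float = 100.0
    background_mode: str = "flat"
    background_level: float = 20.0
    gradient_amplitude: float = 50.0
    grain_scale: float = 1.5
    grain_contrast: float = 20.0
    pixel_noise: float = 2.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.background_mode not in ("flat", "gradient", "grainy"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")
        if self.grain_scale >= self.cell_radius:
            raise ValueError("grain_scale must be smaller than cell_radius")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


def _seed_positions(
    rng: np.random.Generator,
    n_cells: int,
    box: tuple[float, float],
    min_spacing: float,
    margin: float = 0.0,
) -> np.ndarray:
    """Uniform positions with minimum mutual spacing (rejection sampling)."""
    lo = np.array([margin, margin])
    hi = np.array(box) - margin
    if np.any(hi <= lo):
        raise ValueError("margin leaves no room inside the box")
    pts: list[np.ndarray] = []
    for _ in range(200 * n_cells):
        cand = rng.uniform(lo, hi)
        if all(np.hypot(*(cand - p)) >= min_spacing for p in pts):
            pts.append(cand)
            if len(pts) == n_cells:
                return np.asarray(pts)
    raise ValueError(
        f"could not place {n_cells} cells with spacing {min_spacing} in box {box}"
    )


def simulate_ou_tracks(
    gt: MotilityGroundTruth,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    box_um: tuple[float, float] | None = None,
    min_spacing_um: float = 80.0,
    margin_um: float = 0.0,
) -> list[Track]:
    """Exact persistent-random-walk tracks (noise-free positions, px).

    Velocities follow the discrete Ornstein-Uhlenbeck update
    ``v_{n+1} = a v_n + b η_n`` per component, with ``a = exp(-dt/P)`` and
    stationary variance φ₀/2 per component (so E[v·v] = φ₀), i.e.
    ``b = sqrt((φ₀/2)(1 - a²))``; initial velocities are stationary.
    Positions integrate the velocities and are returned in pixels. The true
    velocity autocovariance is exactly ``φ₀ exp(-τ/P)`` and the MSD the
    Fürth curve. Cells start uniformly in `box_um` with minimum mutual
    spacing, inset by `margin_um` from the box edges (keeps rendered cells
    clear of the filter's zeroed border in short movies). Note
    `gt.sigma_pos_true` is NOT applied here; use `add_positional_noise`.
    """
    rng = np.random.default_rng(gt.seed)
    if box_um is None:
        box_um = (1024 * pixel_size, 768 * pixel_size)
    starts = _seed_positions(rng, gt.n_cells, box_um, min_spacing_um, margin_um)

    a = np.exp(-gt.dt / gt.P_true)
    b = np.sqrt((gt.phi0_true / 2.0) * (1.0 - a * a))
    tracks = []
    for cid in range(gt.n_cells):
        v = rng.normal(0.0, np.sqrt(gt.phi0_true / 2.0), size=2)
        pos = np.empty((gt.n_frames, 2))
        pos[0] = starts[cid]
        for n in range(1, gt.n_frames):
            pos[n] = pos[n - 1] + v * gt.dt
            v = a * v + b * rng.normal(size=2)
        tracks.append(
            Track(
                track_id=cid,
                frames=np.arange(gt.n_frames),
                positions=pos / pixel_size,
            )
        )
    return tracks


def add_positional_noise(
    tracks: list[Track],
    sigma_pos: float,
    seed: int,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> list[Track]:
    """Add white centroid measurement noise, std `sigma_pos` µm per coordinate.

    Each position acquires independent Gaussian noise (total variance
    2·σ_pos² per point over both coordinates). σ_pos = 0 returns copies.
    """
    if sigma_pos < 0:
        raise ValueError("sigma_pos must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for tr in tracks:
        noise = rng.normal(0.0, sigma_pos / pixel_size, size=tr.positions.shape)
        if sigma_pos == 0:
            noise = np.zeros_like(tr.positions)
        out.append(
            Track(
                track_id=tr.track_id,
                frames=tr.frames.copy(),
                positions=tr.positions + noise,
                flags=tr.flags.copy(),
            )
        )
    return out


def _speckle(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Band-limited speckle: white noise smoothed at `scale` px, unit std."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=scale, mode="reflect")
    return (field - field.mean()) / field.std()


def render_frames(
    tracks: list[Track],
    scene: SceneParams,
    seed: int,
):
    """Render tracks into an image stack; returns (stack, ground_truth table).

    Each cell is a radially symmetric Gaussian blob (σ = cell_radius/2, peak
    `cell_peak`) at its sub-pixel position. The ground-truth table is a
    pandas DataFrame (frame, cell_id, x_true, y_true, overlapping) where
    `overlapping` flags cells closer than 2·cell_radius to a neighbor in
    that frame. Output is quantized to the scene bit depth.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    h, w = scene.frame_shape
    n_frames = max((int(tr.frames.max()) for tr in tracks), default=-1) + 1
    dtype = np.uint8 if scene.bit_depth == 8 else np.uint16
    maxval = 255 if scene.bit_depth == 8 else 65535
    sigma = scene.cell_radius / 2.0

    # static parts of the background
    yy, xx = np.mgrid[0:h, 0:w]
    if scene.background_mode == "gradient":
        static_bg = scene.background_level + scene.gradient_amplitude * (
            (xx + yy) / (w + h)
        )
    elif scene.background_mode == "grainy":
        static_bg = scene.background_level + scene.grain_contrast * _speckle(
            rng, (h, w), scene.grain_scale
        )
    else:
        static_bg = np.full((h, w), float(scene.background_level))

    stack = np.zeros((n_frames, h, w), dtype=dtype)
    rows = []
    half = int(np.ceil(4 * sigma))
    for fi in range(n_frames):
        frame = static_bg.copy()
        pts = []
        for tr in tracks:
            hit = np.nonzero(tr.frames == fi)[0]
            if len(hit) == 0:
                continue
            x, y = tr.positions[hit[0]]
            pts.append((tr.track_id, x, y))
        for cid, x, y in pts:
            if not (0 <= x < w and 0 <= y < h):
                continue
            xi, yi = int(round(x)), int(round(y))
            x0, x1 = max(xi - half, 0), min(xi + half + 1, w)
            y0, y1 = max(yi - half, 0), min(yi + half + 1, h)
            gy, gx = np.mgrid[y0:y1, x0:x1]
            frame[y0:y1, x0:x1] += scene.cell_peak * np.exp(
                -((gx - x) ** 2 + (gy - y) ** 2) / (2 * sigma**2)
            )
        if scene.pixel_noise > 0:
            frame = frame + rng.normal(0.0, scene.pixel_noise, size=frame.shape)
        stack[fi] = np.clip(np.rint(frame), 0, maxval).astype(dtype)
        for cid, x, y in pts:
            others = [(ox, oy) for oc, ox, oy in pts if oc != cid]
            overlap = any(
                np.hypot(x - ox, y - oy) < 2 * scene.cell_radius for ox, oy in others
            )
            rows.append((fi, cid, x, y, overlap))
    gt = pd.DataFrame(rows, columns=["frame", "cell_id", "x_true", "y_true", "overlapping"])
    return stack, gt


def make_comparison_fixture(
    base_tracks: list[Track],
    sigma_a: float,
    sigma_b: float,
    offset: tuple[float, float],
    seed: int,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> tuple[list[Track], list[Track]]:
    """Two noisy measurements of the same ground truth, for comparison tests.

    Set A gets white noise σ_a, set B gets independent noise σ_b plus a
    constant offset (µm) — the generative model behind pairwise-RMSD
    decomposition: after translational alignment,
    ``E[RMSD²] = 2σ_a² + 2σ_b²``.
    """
    set_a = add_positional_noise(base_tracks, sigma_a, seed, pixel_size)
    set_b = add_positional_noise(base_tracks, sigma_b, seed + 1, pixel_size)
    off_px = np.asarray(offset, dtype=float) / pixel_size
    for tr in set_b:
        tr.positions = tr.positions + off_px
    return set_a, set_b
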