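"""Synthetic data generators.

Four families, all pure functions of (spec, seed):

* classic fractals with analytically known dimension (line, Koch curve,
  quadratic Koch, Sierpinski triangle) for validating the box-counting
  estimator;
* parametric bSSFP-like LV short-axis slices and stacks — bright blood
  pool, darker myocardial annulus, dark trabecular fingers and papillary
  bodies protruding into the pool, base->apex radius taper and a
  mid-ventricular trabeculation-complexity peak — with ground-truth masks;
* cohort tables with a linear age trend, a sex offset and Gaussian
  residuals, for reference-range testing;
* rating matrices (subject effect + rater shift + noise) for ICC testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from skimage.draw import disk, line

from .errors import ValidationError
from .image_io import SliceImage, StackED

FractalKind = Literal["line", "koch", "quadratic-koch", "sierpinski-triangle"]

ANALYTIC_FD = {
    "line": 1.0,
    "koch": np.log(4) / np.log(3),
    "quadratic-koch": 1.5,
    "sierpinski-triangle": np.log(3) / np.log(2),
}

DEFAULT_DEPTH = {"line": 0, "koch": 6, "quadratic-koch": 5,
                 "sierpinski-triangle": 7}


@dataclass
class FractalSpec:
    kind: FractalKind
    depth: int | None = None
    canvas: int = 1024

    def __post_init__(self) -> None:
        if self.kind not in ANALYTIC_FD:
            raise ValidationError(f"unsupported fractal kind {self.kind!r}")
        if self.canvas < 256:
            raise ValidationError("fractal canvas must be >= 256 px")
        if self.depth is None:
            self.depth = DEFAULT_DEPTH[self.kind]

    @property
    def analytic_fd(self) -> float:
        return ANALYTIC_FD[self.kind]


def _draw_polyline(img: np.ndarray, pts: np.ndarray) -> None:
    p = np.rint(pts).astype(int)
    p = np.clip(p, 0, np.array(img.shape)[::-1] - 1)  # pts are (x, y)
    for (x0, y0), (x1, y1) in zip(p[:-1], p[1:]):
        rr, cc = line(y0, x0, y1, x1)
        img[rr, cc] = True


def _koch_refine(pts: np.ndarray) -> np.ndarray:
    """One triadic Koch step: each segment -> 4 segments with a 60-degree bump."""
    out = []
    rot = np.array([[0.5, -np.sqrt(3) / 2], [np.sqrt(3) / 2, 0.5]])
    for p0, p1 in zip(pts[:-1], pts[1:]):
        d = (p1 - p0) / 3.0
        a = p0 + d
        b = p0 + 2 * d
        peak = a + rot @ d
        out.extend([p0, a, peak, b])
    out.append(pts[-1])
    return np.asarray(out)


def _quad_koch_refine(pts: np.ndarray) -> np.ndarray:
    """One quadratic (type 1) Koch step: each segment -> 8 segments of 1/4
    length forming a square bump up then down; similarity dimension
    log 8 / log 4 = 1.5."""
    out = []
    for p0, p1 in zip(pts[:-1], pts[1:]):
        u = (p1 - p0) / 4.0
        v = np.array([-u[1], u[0]])  # left-hand perpendicular
        out.extend([
            p0,
            p0 + u,
            p0 + u + v,
            p0 + 2 * u + v,
            p0 + 2 * u,
            p0 + 2 * u - v,
            p0 + 3 * u - v,
            p0 + 3 * u,
        ])
    out.append(pts[-1])
    return np.asarray(out)


def _sierpinski(img: np.ndarray, p0, p1, p2, depth: int) -> None:
    if depth == 0:
        tri = np.array([p0, p1, p2, p0])
        _draw_polyline(img, tri)
        return
    m01 = (np.asarray(p0) + p1) / 2.0
    m12 = (np.asarray(p1) + p2) / 2.0
    m20 = (np.asarray(p2) + p0) / 2.0
    _sierpinski(img, p0, m01, m20, depth - 1)
    _sierpinski(img, m01, p1, m12, depth - 1)
    _sierpinski(img, m20, m12, p2, depth - 1)


def make_fractal(spec: FractalSpec) -> tuple[np.ndarray, float]:
    """Rasterize a fractal; returns (binary image, analytic dimension)."""
    n = spec.canvas
    img = np.zeros((n, n), dtype=bool)
    if spec.kind == "line":
        img[n // 2, :] = True
    elif spec.kind == "koch":
        pts = np.array([[0.0, 0.62 * n], [n - 1.0, 0.62 * n]])
        for _ in range(spec.depth):
            pts = _koch_refine(pts)
        _draw_polyline(img, pts)
    elif spec.kind == "quadratic-koch":
        pts = np.array([[0.0, 0.5 * n], [n - 1.0, 0.5 * n]])
        for _ in range(spec.depth):
            pts = _quad_koch_refine(pts)
        _draw_polyline(img, pts)
    elif spec.kind == "sierpinski-triangle":
        h = (n - 1) * np.sqrt(3) / 2
        y0 = (n - 1 + h) / 2
        p0 = (0.0, y0)
        p1 = (n - 1.0, y0)
        p2 = ((n - 1) / 2.0, y0 - h)
        _sierpinski(img, p0, p1, p2, spec.depth)
    return img, spec.analytic_fd


def fractal_suite(canvas: int = 1024) -> list[tuple[str, np.ndarray, float]]:
    """The packaged validation suite: (kind, image, analytic FD) triples."""
    out = []
    for kind in ("line", "koch", "quadratic-koch", "sierpinski-triangle"):
        img, fd = make_fractal(FractalSpec(kind=kind, canvas=canvas))
        out.append((kind, img, fd))
    return out


# ---------------------------------------------------------------------------
# LV short-axis phantom


@dataclass
class LvPhantomSpec:
    """Parametric short-axis LV stack.

    complexity c in [0, 1] maps linearly to the number K in [0, 24],
    depth A in [0, 0.35 r] and angular width of dark trabecular fingers
    indenting the endocardial border, plus two papillary bodies.  The
    per-slice complexity follows a raised-cosine axial profile peaking at
    60% of the base->apex axis; endocardial/epicardial radii taper toward
    the apex.  Intensities mimic 3T bSSFP (bright pool 400, myocardium
    120, background 30); optional Gaussian noise and a low-order
    multiplicative bias field.
    """

    canvas: int = 160
    epicardial_radius: float | None = None
    endocardial_radius: float | None = None
    complexity: float = 0.5
    intensity_pool: float = 400.0
    intensity_myocardium: float = 120.0
    intensity_background: float = 30.0
    noise_sd: float = 8.0
    bias_amplitude: float = 0.10
    n_slices: int = 9
    apex_taper: float = 0.55  # apical endocardial radius = (1 - taper) x basal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epicardial_radius is None:
            self.epicardial_radius = 0.42 * self.canvas
        if self.endocardial_radius is None:
            self.endocardial_radius = 0.30 * self.canvas
        if not 0.0 <= self.complexity <= 1.0:
            raise ValidationError("complexity must lie in [0, 1]")
        if self.n_slices < 5:
            raise ValidationError("phantom stacks need >= 5 slices")
        if self.epicardial_radius >= self.canvas / 2:
            raise ValidationError("epicardial radius exceeds the canvas")
        if self.endocardial_radius >= self.epicardial_radius:
            raise ValidationError("endocardial radius must be < epicardial radius")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValidationError("noise and bias amplitudes must be >= 0")


def axial_complexity_profile(n_slices: int) -> np.ndarray:
    """Relative complexity weight per slice: raised cosine peaking at 60%
    of the base->apex axis (the mid-ventricular papillary level)."""
    t = np.linspace(0.0, 1.0, n_slices)
    w = 0.5 * (1.0 + np.cos(np.pi * (t - 0.6) / 0.8))
    return 0.35 + 0.65 * w


def _finger_profile(theta: np.ndarray, centers, widths, depths) -> np.ndarray:
    """Fractional radial indentation of the endocardial border at angle theta."""
    dent = np.zeros_like(theta)
    for c, w, d in zip(centers, widths, depths):
        u = np.angle(np.exp(1j * (theta - c))) / w  # wrapped distance / width
        m = np.abs(u) < 1.0
        dent[m] = np.maximum(dent[m], d * np.cos(np.pi * u[m] / 2.0) ** 2)
    return dent


def make_lv_slice(
    spec: LvPhantomSpec, slice_frac: float, complexity: float,
    rng: np.random.Generator,
) -> tuple[SliceImage, dict]:
    """One slice at fractional position `slice_frac` (0 = base, 1 = apex)."""
    n = spec.canvas
    taper = 1.0 - spec.apex_taper * slice_frac
    r_endo = spec.endocardial_radius * taper
    r_epi = spec.epicardial_radius * (1.0 - 0.45 * spec.apex_taper * slice_frac)

    k_fingers = int(round(24 * complexity))
    depth_max = 0.35 * complexity

    # trabeculae are spread around the circumference: evenly spaced
    # angular slots with jitter rather than fully uniform placement
    if k_fingers:
        slots = np.arange(k_fingers) + rng.uniform(0.0, 0.6, size=k_fingers)
        centers = 2 * np.pi * slots / k_fingers + rng.uniform(0, 2 * np.pi)
    else:
        centers = np.empty(0)
    base_w = 2 * np.pi / max(k_fingers, 8)
    widths = base_w * rng.uniform(0.35, 0.7, size=k_fingers)
    depths = depth_max * rng.uniform(0.6, 1.0, size=k_fingers)

    rr, cc = np.mgrid[0:n, 0:n]
    y = rr - (n - 1) / 2.0
    x = cc - (n - 1) / 2.0
    rho = np.hypot(y, x)
    theta = np.arctan2(y, x)

    border = r_endo * (1.0 - _finger_profile(theta, centers, widths, depths))
    pool = rho < border
    myo = (rho >= border) & (rho < r_epi)

    # papillary bodies: two dark disks in the mid-cavity; kept clear of the
    # deepest trabecular indentations (<= 0.65 r) so recesses between
    # fingers remain contiguous with the cavity
    pap = np.zeros((n, n), dtype=bool)
    if complexity > 0.15:
        pap_r = 0.12 * r_endo
        for ang in rng.uniform(0, 2 * np.pi, size=2):
            pr = 0.45 * r_endo
            c0 = ((n - 1) / 2.0 + pr * np.sin(ang), (n - 1) / 2.0 + pr * np.cos(ang))
            dd, dc = disk(c0, pap_r, shape=(n, n))
            pap[dd, dc] = True
        pap &= pool
    pool_true = pool & ~pap
    myo_true = myo | pap

    img = np.full((n, n), spec.intensity_background)
    img[myo_true] = spec.intensity_myocardium
    img[pool_true] = spec.intensity_pool

    if spec.bias_amplitude > 0:
        gy = y / n
        gx = x / n
        bias = 1.0 + spec.bias_amplitude * (gy + 0.5 * gx - gy * gx)
        img = img * bias
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    truth = {"pool": pool_true, "myocardium": myo_true, "complexity": complexity}
    return SliceImage(img), truth


def make_lv_stack(spec: LvPhantomSpec) -> tuple[StackED, list[dict]]:
    """Seeded, reproducible LV stack with per-slice ground truth."""
    rng = np.random.default_rng(spec.seed)
    profile = axial_complexity_profile(spec.n_slices)
    slices: list[SliceImage] = []
    truths: list[dict] = []
    for i in range(spec.n_slices):
        frac = i / (spec.n_slices - 1)
        c_i = spec.complexity * profile[i]
        s, t = make_lv_slice(spec, frac, c_i, rng)
        s.slice_index = i
        s.slice_location = -10.0 * i  # base at the highest location
        slices.append(s)
        truths.append(t)
    stack = StackED(slices=slices, subject_id=f"phantom-seed{spec.seed}")
    return stack, truths


def make_lv_cine(spec: LvPhantomSpec, n_frames: int = 5):
    """Minimal multi-frame phantom: the pool contracts over the cycle so
    frame 0 (end-diastole) has the largest pool area."""
    from .image_io import CineSlice, CineStack

    base_stack, _ = make_lv_stack(spec)
    cine_slices = []
    for s in base_stack.slices:
        frames = [s.pixels]
        for f in range(1, n_frames):
            shrink = 1.0 - 0.25 * f / (n_frames - 1)
            sub = LvPhantomSpec(
                canvas=spec.canvas,
                endocardial_radius=spec.endocardial_radius * shrink,
                epicardial_radius=spec.epicardial_radius,
                complexity=spec.complexity,
                noise_sd=spec.noise_sd,
                bias_amplitude=spec.bias_amplitude,
                n_slices=spec.n_slices,
                seed=spec.seed,
            )
            rng = np.random.default_rng(spec.seed + 1000 + f)
            frac = s.slice_index / (spec.n_slices - 1)
            img, _ = make_lv_slice(sub, frac, spec.complexity, rng)
            frames.append(img.pixels)
        cine_slices.append(
            CineSlice(np.stack(frames), slice_index=s.slice_index,
                      slice_location=s.slice_location)
        )
    return CineStack(slices=cine_slices, subject_id=base_stack.subject_id)


# ---------------------------------------------------------------------------
# cohort and rater simulators


def simulate_cohort(
    n_per_sex: int = 90,
    age_range: tuple[float, float] = (20.0, 69.0),
    slope: float = 0.0004,
    intercepts: dict[str, float] | None = None,
    residual_sd: float = 0.029,
    seed: int = 0,
    metric: str = "global_fd",
) -> pd.DataFrame:
    """Cohort table: value = intercept_sex + slope*age + N(0, sd).

    Defaults emulate a healthy adult reference cohort: ages uniform over
    20-69, FD rising slowly with age, males offset above females by 0.021.
    """
    if n_per_sex < 10:
        raise ValidationError("need n >= 10 per sex")
    if residual_sd < 0:
        raise ValidationError("residual SD must be >= 0")
    if intercepts is None:
        intercepts = {"male": 1.201, "female": 1.180}
    rng = np.random.default_rng(seed)
    rows = []
    for sex in ("male", "female"):
        ages = rng.uniform(age_range[0], age_range[1], size=n_per_sex)
        noise = (rng.normal(0.0, residual_sd, size=n_per_sex)
                 if residual_sd > 0 else np.zeros(n_per_sex))
        values = intercepts[sex] + slope * ages + noise
        for i, (a, v) in enumerate(zip(ages, values)):
            rows.append(
                {"subject_id": f"{sex[0]}{i:04d}", "age": float(a),
                 "sex": sex, "value": float(v), "metric": metric}
            )
    return pd.DataFrame(rows)


def simulate_raters(
    n: int = 20,
    k: int = 2,
    subject_sd: float = np.sqrt(0.9),
    rater_shifts: tuple[float, ...] | None = None,
    error_sd: float = np.sqrt(0.1),
    seed: int = 0,
    mean: float = 1.2,
):
    """Rating matrix: value = mean + subject effect + rater shift + noise."""
    from .agreement import RatingMatrix

    if n < 5 or k < 2:
        raise ValidationError("need n >= 5 subjects and k >= 2 raters")
    if subject_sd < 0 or error_sd < 0:
        raise ValidationError("SDs must be >= 0")
    if rater_shifts is None:
        rater_shifts = tuple(0.0 for _ in range(k))
    if len(rater_shifts) != k:
        raise ValidationError("rater_shifts length must equal k")
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, subject_sd, size=n) if subject_sd > 0 else np.zeros(n)
    noise = (rng.normal(0.0, error_sd, size=(n, k))
             if error_sd > 0 else np.zeros((n, k)))
    values = mean + subj[:, None] + np.asarray(rater_shifts)[None, :] + noise
    return RatingMatrix(values=values)
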