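"""Synthetic shape populations and simulated crowd-worker tracings.

The original study graded crowd tracings of photographed bovid molars;
the photographs are not redistributable, so this module provides a
fully generative stand-in.  Truth outlines are defined directly in EFA
coefficient space: each class (a synthetic "tribe") has a mean outline
— a superellipse-with-waist caricature of a molar occlusal surface —
and specimens are drawn by perturbing the mean's harmonic amplitudes
with zero-mean noise whose scale decays with harmonic order.  Defining
truth in coefficient space makes class separation and within-class
dispersion directly controllable in the same feature space the
classifier uses.

Worker behaviour is simulated per tracing with three independent
mechanisms, mirroring what crowd workers actually do:

* smooth hand-jitter — Gaussian landmark noise correlated along the
  contour (hand-tracing errors are locally smooth; i.i.d. noise would
  inject unrealistic high-frequency harmonics);
* a signed inward/outward boundary bias (tracing consistently inside
  or outside the true edge);
* occasional gross errors — a "clearly wrong" tracing (e.g. the wrong
  tooth or a wildly distorted outline), constructed to lie beyond the
  0.2 rejection distance so the quality-control stage has real work;
* dropout — a tracing that is simply never returned.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .contours import BinaryMask
from .efa import (EFADecomposition, LandmarkSet, efa_forward, efa_inverse,
                  normalize)
from .shapes import riemann_distance

__all__ = [
    "ShapeClassTemplate",
    "WorkerNoiseModel",
    "SpecimenRecord",
    "SyntheticDataset",
    "tooth_outline",
    "make_template",
    "default_templates",
    "lm2_templates",
    "mini_templates",
    "generate_population",
    "simulate_worker_tracings",
    "rasterize",
    "write_dataset",
]

DEFAULT_K = 150
DEFAULT_H = 10


@dataclass(frozen=True)
class ShapeClassTemplate:
    """Mean shape and dispersion of one synthetic class.

    ``coeff_sd_scale`` is a dimensionless dispersion multiplier: the
    s.d. of the noise added to each coefficient of harmonic ``j`` is
    ``coeff_sd_scale * size / j`` where ``size`` is the mean shape's
    first-harmonic amplitude, so perturbations decay with harmonic
    order.  ``tooth_positions`` optionally assigns tooth-position
    labels (e.g. LM2) to the specimens; counts must sum to
    ``n_specimens``.
    """

    class_label: str
    mean_coeffs: EFADecomposition
    coeff_sd_scale: float
    n_specimens: int
    tooth_positions: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.mean_coeffs.H < 2:
            raise ValueError("template mean needs at least 2 harmonics")
        if self.coeff_sd_scale < 0:
            raise ValueError("coeff_sd_scale must be nonnegative")
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if self.tooth_positions is not None:
            if sum(self.tooth_positions.values()) != self.n_specimens:
                raise ValueError("tooth_positions counts must sum to n_specimens")


@dataclass(frozen=True)
class WorkerNoiseModel:
    """Stochastic model of one crowd worker's tracing of one tooth.

    jitter_sd
        s.d. of landmark jitter, in units of the outline's r.m.s.
        centroid radius.
    jitter_correlation_length
        fraction of the perimeter over which jitter is correlated.
    boundary_bias
        signed normal offset (same units as jitter_sd); positive traces
        outside the true edge.
    p_gross_error, p_missing
        per-tracing probabilities of a "clearly wrong" submission and
        of no submission at all.
    """

    jitter_sd: float = 0.2
    jitter_correlation_length: float = 0.08
    boundary_bias: float = 0.0
    p_gross_error: float = 0.05
    p_missing: float = 0.05
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.p_gross_error <= 1 and 0 <= self.p_missing <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.jitter_sd < 0 or self.jitter_correlation_length <= 0:
            raise ValueError("jitter_sd >= 0 and correlation length > 0 required")
        if self.n_replicates < 0:
            raise ValueError("n_replicates must be >= 0")


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    class_label: str
    tooth_position: str
    landmarks: LandmarkSet
    coeffs: EFADecomposition


@dataclass
class SyntheticDataset:
    """Specimens with ground-truth outlines plus simulated tracings."""

    specimens: list[SpecimenRecord]
    tracings: dict[str, list[LandmarkSet]] = field(default_factory=dict)
    seed: int | None = None

    def specimen(self, specimen_id: str) -> SpecimenRecord:
        for s in self.specimens:
            if s.specimen_id == specimen_id:
                return s
        raise KeyError(specimen_id)

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"specimen_id": s.specimen_id, "class_label": s.class_label,
              "tooth_position": s.tooth_position} for s in self.specimens])


# ---------------------------------------------------------------------------
# template construction

def tooth_outline(aspect: float = 1.6, squareness: float = 2.5,
                  waist: float = 0.12, size: float = 1.0,
                  n_points: int = 256) -> np.ndarray:
    """Parametric molar-like outline: an elongated superellipse with a
    mild mid-length waist (the two-lobed character of a molar's
    occlusal surface).  Returns an (n_points, 2) simple polygon.
    """
    if aspect <= 0 or squareness <= 0 or size <= 0:
        raise ValueError("aspect, squareness and size must be positive")
    if not 0 <= waist < 1:
        raise ValueError("waist must lie in [0, 1)")
    t = 2 * np.pi * np.arange(n_points) / n_points
    e = 2.0 / squareness
    x = aspect * np.sign(np.cos(t)) * np.abs(np.cos(t)) ** e
    y = np.sign(np.sin(t)) * np.abs(np.sin(t)) ** e
    y = y * (1.0 - waist * (1.0 - (x / aspect) ** 2))
    return size * np.column_stack([x, y])


def make_template(class_label: str, aspect: float, squareness: float,
                  waist: float, size: float, coeff_sd_scale: float,
                  n_specimens: int,
                  tooth_positions: dict[str, int] | None = None,
                  H: int = DEFAULT_H) -> ShapeClassTemplate:
    """Build a class template by fitting EFA to the parametric outline."""
    poly = tooth_outline(aspect=aspect, squareness=squareness, waist=waist,
                         size=size)
    mean = normalize(efa_forward(poly, H=H))
    return ShapeClassTemplate(class_label=class_label, mean_coeffs=mean,
                              coeff_sd_scale=coeff_sd_scale,
                              n_specimens=n_specimens,
                              tooth_positions=tooth_positions)


def default_templates(coeff_sd_scale: float = 0.03,
                      H: int = DEFAULT_H) -> list[ShapeClassTemplate]:
    """Four-class population mirroring the study layout: 33 + 10 + 35
    + 18 = 96 specimens, tooth positions distributed as in the original
    sample.  Alcelaphini- and Hippotragini-like classes are given
    deliberately similar outlines (the pair the real data confuses);
    the Bovini-like class is large and square, the Neotragini-like
    class small and round."""
    return [
        make_template("Alcelaphini", aspect=1.75, squareness=2.6, waist=0.18,
                      size=1.00, coeff_sd_scale=coeff_sd_scale, n_specimens=33,
                      tooth_positions={"LM1": 8, "LM2": 15, "LM3": 5, "UM3": 5},
                      H=H),
        make_template("Bovini", aspect=1.50, squareness=3.2, waist=0.08,
                      size=1.55, coeff_sd_scale=coeff_sd_scale, n_specimens=10,
                      tooth_positions={"LM3": 5, "UM3": 5}, H=H),
        make_template("Hippotragini", aspect=1.62, squareness=2.4, waist=0.13,
                      size=1.08, coeff_sd_scale=coeff_sd_scale, n_specimens=35,
                      tooth_positions={"LM1": 5, "LM2": 15, "UM2": 5, "UM3": 10},
                      H=H),
        make_template("Neotragini", aspect=1.30, squareness=2.1, waist=0.04,
                      size=0.68, coeff_sd_scale=coeff_sd_scale, n_specimens=18,
                      tooth_positions={"LM2": 8, "LM3": 10}, H=H),
    ]


def lm2_templates(coeff_sd_scale: float = 0.03,
                  H: int = DEFAULT_H) -> list[ShapeClassTemplate]:
    """Three-class second-lower-molar layout (15/15/8 = 38 specimens),
    the subset used for the classification experiment."""
    return [
        make_template("Alcelaphini", aspect=1.75, squareness=2.6, waist=0.18,
                      size=1.00, coeff_sd_scale=coeff_sd_scale, n_specimens=15,
                      tooth_positions={"LM2": 15}, H=H),
        make_template("Hippotragini", aspect=1.62, squareness=2.4, waist=0.13,
                      size=1.08, coeff_sd_scale=coeff_sd_scale, n_specimens=15,
                      tooth_positions={"LM2": 15}, H=H),
        make_template("Neotragini", aspect=1.30, squareness=2.1, waist=0.04,
                      size=0.68, coeff_sd_scale=coeff_sd_scale, n_specimens=8,
                      tooth_positions={"LM2": 8}, H=H),
    ]


def mini_templates(coeff_sd_scale: float = 0.03, n_specimens: int = 4,
                   H: int = DEFAULT_H) -> list[ShapeClassTemplate]:
    """Tiny three-class layout (n each) for quick runs and examples."""
    return [
        make_template("Alcelaphini", aspect=1.75, squareness=2.6, waist=0.18,
                      size=1.00, coeff_sd_scale=coeff_sd_scale,
                      n_specimens=n_specimens, H=H),
        make_template("Hippotragini", aspect=1.62, squareness=2.4, waist=0.13,
                      size=1.08, coeff_sd_scale=coeff_sd_scale,
                      n_specimens=n_specimens, H=H),
        make_template("Neotragini", aspect=1.30, squareness=2.1, waist=0.04,
                      size=0.68, coeff_sd_scale=coeff_sd_scale,
                      n_specimens=n_specimens, H=H),
    ]


# ---------------------------------------------------------------------------
# population generation

def generate_population(templates: list[ShapeClassTemplate], seed: int,
                        K: int = DEFAULT_K) -> SyntheticDataset:
    """Draw specimens for each template by perturbing the class mean's
    harmonic amplitudes; deterministic given ``seed``."""
    if not templates:
        raise ValueError("template list must be non-empty")
    labels = [t.class_label for t in templates]
    if len(set(labels)) != len(labels):
        raise ValueError("class labels must be distinct")
    specimens: list[SpecimenRecord] = []
    idx = 0
    for t_i, tmpl in enumerate(templates):
        size = float(np.sqrt(np.sum(tmpl.mean_coeffs.coeffs[0] ** 2)))
        sd = tmpl.coeff_sd_scale * size / np.arange(1, tmpl.mean_coeffs.H + 1)
        positions: list[str] = []
        if tmpl.tooth_positions:
            for pos, cnt in tmpl.tooth_positions.items():
                positions += [pos] * cnt
        else:
            positions = ["LM2"] * tmpl.n_specimens
        for k in range(tmpl.n_specimens):
            rng = np.random.default_rng([seed, t_i, k])
            noise = rng.normal(0.0, 1.0, size=(tmpl.mean_coeffs.H, 4)) * sd[:, None]
            coeffs = tmpl.mean_coeffs.coeffs + noise
            decomp = normalize(EFADecomposition(
                A0=tmpl.mean_coeffs.A0, C0=tmpl.mean_coeffs.C0,
                coeffs=coeffs, normalized=False))
            landmarks = efa_inverse(decomp, K=K)
            specimens.append(SpecimenRecord(
                specimen_id=f"S{idx:03d}", class_label=tmpl.class_label,
                tooth_position=positions[k], landmarks=landmarks,
                coeffs=decomp))
            idx += 1
    return SyntheticDataset(specimens=specimens, seed=seed)


# ---------------------------------------------------------------------------
# worker simulation

def _rms_radius(points: np.ndarray) -> float:
    c = points.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((points - c) ** 2, axis=1))))


def _correlated_jitter(rng: np.random.Generator, K: int,
                       correlation_length: float) -> np.ndarray:
    """Unit-variance Gaussian noise per landmark, smoothed circularly
    so neighbouring landmarks move together."""
    e = rng.normal(0.0, 1.0, size=(K, 2))
    sigma = correlation_length * K
    freq = np.fft.fftfreq(K)
    transfer = np.exp(-2.0 * (np.pi * sigma * freq) ** 2)
    smoothed = np.fft.ifft(np.fft.fft(e, axis=0) * transfer[:, None], axis=0).real
    gain = np.sqrt(np.mean(transfer**2))
    return smoothed / gain


def _outward_normals(points: np.ndarray) -> np.ndarray:
    """Unit outward normals of a counter-clockwise closed polyline."""
    tangent = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    return np.column_stack([tangent[:, 1], -tangent[:, 0]])


def _gross_error_shape(rng: np.random.Generator, dataset: SyntheticDataset,
                       spec_index: int, threshold: float = 0.2) -> LandmarkSet:
    """A 'clearly wrong' tracing: another specimen's outline given a
    strong anisotropic stretch plus a low-order radial bump, escalated
    until its distance from the true outline exceeds the rejection
    threshold (so the quality filter provably has work to do)."""
    truth = dataset.specimens[spec_index].landmarks.points
    others = [i for i in range(len(dataset.specimens)) if i != spec_index]
    source = dataset.specimens[rng.choice(others)].landmarks.points \
        if others else truth
    amplitude = 0.35
    for _ in range(20):
        pts = source - source.mean(axis=0)
        angle = rng.uniform(0, 2 * np.pi)
        ca, sa = np.cos(angle), np.sin(angle)
        rot = np.array([[ca, -sa], [sa, ca]])
        stretch = np.diag([rng.uniform(1.6, 2.6), 1.0])
        pts = pts @ rot.T @ stretch @ rot
        K = len(pts)
        t = 2 * np.pi * np.arange(K) / K
        phase = rng.uniform(0, 2 * np.pi)
        radial = 1.0 + amplitude * np.sin(2 * t + phase)
        pts = pts * radial[:, None]
        candidate = LandmarkSet(points=pts + source.mean(axis=0),
                                start_convention="gross-error")
        if riemann_distance(candidate.points, truth) > threshold:
            return candidate
        amplitude *= 1.5
    return candidate  # pragma: no cover - escalation virtually always succeeds


def simulate_worker_tracings(dataset: SyntheticDataset,
                             noise: WorkerNoiseModel,
                             seed: int) -> SyntheticDataset:
    """Fill the dataset's tracings with simulated worker submissions.

    For each specimen, ``n_replicates`` candidate tracings are drawn;
    each is independently missing with ``p_missing``, a gross error
    with ``p_gross_error``, and otherwise the true outline plus
    correlated jitter and the normal-direction bias.
    """
    if not dataset.specimens:
        raise ValueError("dataset has no specimens")
    tracings: dict[str, list[LandmarkSet]] = {}
    for i, spec in enumerate(dataset.specimens):
        subs: list[LandmarkSet] = []
        for r in range(noise.n_replicates):
            rng = np.random.default_rng([seed, i, r])
            u_missing, u_gross = rng.uniform(size=2)
            if u_missing < noise.p_missing:
                continue
            if u_gross < noise.p_gross_error:
                subs.append(_gross_error_shape(rng, dataset, i))
                continue
            pts = spec.landmarks.points
            scale = _rms_radius(pts)
            jitter = _correlated_jitter(rng, len(pts),
                                        noise.jitter_correlation_length)
            offset = noise.jitter_sd * scale * jitter
            if noise.boundary_bias != 0.0:
                offset = offset + noise.boundary_bias * scale * _outward_normals(pts)
            subs.append(LandmarkSet(points=pts + offset,
                                    start_convention=spec.landmarks.start_convention))
        tracings[spec.specimen_id] = subs
    return SyntheticDataset(specimens=dataset.specimens, tracings=tracings,
                            seed=dataset.seed)


# ---------------------------------------------------------------------------
# rasterization

def rasterize(landmarks, image_size: int = 512, margin: float = 0.05) -> BinaryMask:
    """Render a closed outline as a filled binary mask.

    The polygon is scaled and translated to fit the image with the
    stated margin; foreground pixels are those whose centers fall
    inside the polygon.  Self-intersecting outlines are refused so the
    interior is well defined.
    """
    pts = landmarks.points if hasattr(landmarks, "points") else \
        np.asarray(landmarks, dtype=float)
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 points")
    ring = shapely.LinearRing(pts)
    if not ring.is_simple:
        raise ValueError("self-intersecting polygon cannot be rasterized")
    poly = shapely.Polygon(ring)
    minx, miny, maxx, maxy = poly.bounds
    span = max(maxx - minx, maxy - miny)
    if span <= 0:
        raise ValueError("degenerate polygon with zero extent")
    scale = image_size * (1.0 - 2.0 * margin) / span
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    target = (image_size - 1) / 2.0
    fitted = shapely.transform(
        poly, lambda a: (a - [cx, cy]) * scale + [target, target])
    xs, ys = np.meshgrid(np.arange(image_size), np.arange(image_size))
    inside = shapely.contains_xy(fitted, xs.ravel(), ys.ravel())
    grid = inside.reshape(image_size, image_size)
    # Cartesian y-up -> image rows top-down
    return BinaryMask(foreground=grid[::-1])


# ---------------------------------------------------------------------------
# serialization

def write_dataset(dataset: SyntheticDataset, out_dir: str | Path,
                  masks: bool = False, image_size: int = 512) -> dict[str, Path]:
    """Export metadata, true outlines and tracings as CSV (and masks as
    PNG when requested).  Floats are written with shortest round-trip
    precision; read them back with ``float_precision="round_trip"`` to
    reproduce the arrays bit-for-bit."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"metadata": out / "specimens.csv",
             "truth": out / "true_outlines.csv",
             "tracings": out / "tracings.csv"}
    dataset.metadata().to_csv(paths["metadata"], index=False)

    def outline_rows(specimen_id, tracing_id, pts):
        return pd.DataFrame({
            "specimen_id": specimen_id, "tracing_id": tracing_id,
            "point_index": np.arange(len(pts)),
            "x": pts[:, 0], "y": pts[:, 1]})

    truth = pd.concat([outline_rows(s.specimen_id, "truth", s.landmarks.points)
                       for s in dataset.specimens], ignore_index=True)
    truth.to_csv(paths["truth"], index=False, float_format=None)
    rows = [outline_rows(sid, f"{sid}_t{i}", t.points)
            for sid, ts in dataset.tracings.items() for i, t in enumerate(ts)]
    tracing_df = pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame(columns=["specimen_id", "tracing_id", "point_index", "x", "y"])
    tracing_df.to_csv(paths["tracings"], index=False)
    if masks:
        from .contours import mask_to_image
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        for s in dataset.specimens:
            img = mask_to_image(rasterize(s.landmarks, image_size=image_size))
            img.save(mask_dir / f"{s.specimen_id}_truth.png")
        for sid, ts in dataset.tracings.items():
            for i, t in enumerate(ts):
                img = mask_to_image(rasterize(t, image_size=image_size))
                img.save(mask_dir / f"{sid}_t{i}.png")
        paths["masks"] = mask_dir
    return paths
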