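"""Seeded synthetic cSLO fundus images and cohorts with planted ground truth.

The generator emulates the features of blue-autofluorescence fundus frames
that the quantification pipeline has to cope with: a dark noisy background
with a smooth illumination gradient and vignetting, dark vessel-like
streaks, and bright GFP-positive somata rendered as Gaussian blobs
(optionally with thin radiating processes). Every planted cell's position,
pixel mask and peak intensity are recorded, so recovery can be scored
against exact truth.

Truth-mask convention: a soma of nominal radius r is a 2D Gaussian with
sigma = r/2, truncated at 2 sigma (= r); the truth mask is exactly the
pixels inside that disc. A continuous blob has no canonical area, so the
truncation radius *defines* the planted area.

Cohorts follow the longitudinal design of the animal study: three groups
(immunized, sham, naive), two eyes per animal, a fixed week grid, a slow
age-related drift of cell count and size in all groups, and an
activation bump peaking at week 6 applied only to the immunized group.
All randomness flows from one seed through an explicit generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .imgio import Eye, FundusImage, Group, ImageMeta, write_image, write_manifest


class PackingError(RuntimeError):
    """Raised when n_cells cannot be placed at the requested separation."""


@dataclass(frozen=True)
class SynthImageParams:
    """Parameters of one synthetic frame (intensities on the 8-bit scale)."""

    shape_px: tuple[int, int] = (512, 512)
    background_level: float = 12.0
    background_noise_sd: float = 2.0
    vignette_strength: float = 0.3
    illumination_gradient: tuple[float, float] = (0.002, 0.004)  # per px (row, col)
    n_vessels: int = 3
    n_cells: int = 50
    cell_intensity_mean: float = 160.0
    cell_intensity_sd: float = 20.0
    soma_radius_px_range: tuple[float, float] = (2.0, 4.0)
    process_probability: float = 0.3
    min_cell_separation_px: float = 20.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.vignette_strength <= 1:
            raise ValueError("vignette_strength must be in [0, 1]")
        if not 0 <= self.process_probability <= 1:
            raise ValueError("process_probability must be in [0, 1]")
        if self.soma_radius_px_range[0] > self.soma_radius_px_range[1]:
            raise ValueError("soma_radius_px_range must be (lo, hi) with lo <= hi")
        if self.n_cells < 0 or self.n_vessels < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def high_snr(cls, seed: int = 0, n_cells: int = 50,
                 shape_px: tuple[int, int] = (512, 512)) -> "SynthImageParams":
        """The documented high-SNR recovery benchmark setting.

        Bright, well-separated somata without processes: the truth-mask
        convention covers somata only, so the soma-area recovery benchmark
        renders somata only. Peak intensity sits far above the background
        plus 5 noise SDs.
        """
        return cls(seed=seed, n_cells=n_cells, shape_px=shape_px,
                   process_probability=0.0)


@dataclass(frozen=True)
class PlantedCell:
    centroid_rc: tuple[float, float]
    radius_px: float
    peak_intensity: float
    area_px: int


@dataclass
class GroundTruth:
    cells: list[PlantedCell]
    mask: np.ndarray  # union of planted soma masks

    @property
    def count(self) -> int:
        return len(self.cells)

    @property
    def total_area_px(self) -> int:
        return int(self.mask.sum())


def _place_centers(rng: np.random.Generator, shape: tuple[int, int],
                   n: int, margin: float, min_sep: float) -> np.ndarray:
    """Rejection-sample n centers with pairwise separation >= min_sep."""
    h, w = shape
    if h - 2 * margin <= 1 or w - 2 * margin <= 1:
        raise PackingError("margin leaves no interior to place cells in")
    centers: list[tuple[float, float]] = []
    tries = 0
    limit = 400 * max(n, 1)
    while len(centers) < n:
        if tries >= limit:
            raise PackingError(
                f"could not place {n} cells with separation {min_sep} px "
                f"in a {h}x{w} frame after {limit} tries"
            )
        tries += 1
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - cr) ** 2 + (c - cc) ** 2 >= min_sep ** 2
               for cr, cc in centers):
            centers.append((r, c))
    return np.array(centers).reshape(n, 2)


def _paint_vessels(rng: np.random.Generator, shape: tuple[int, int],
                   n_vessels: int) -> np.ndarray:
    """Soft multiplicative darkening field for vessel-like streaks."""
    h, w = shape
    canvas = np.zeros(shape, dtype=bool)
    for _ in range(n_vessels):
        # quadratic Bezier from one border to another through the interior
        edges = rng.permutation(4)[:2]
        pts = []
        for e in edges:
            if e == 0:
                pts.append((0.0, rng.uniform(0, w - 1)))
            elif e == 1:
                pts.append((h - 1.0, rng.uniform(0, w - 1)))
            elif e == 2:
                pts.append((rng.uniform(0, h - 1), 0.0))
            else:
                pts.append((rng.uniform(0, h - 1), w - 1.0))
        p0, p2 = np.array(pts[0]), np.array(pts[1])
        p1 = np.array([rng.uniform(0.2 * h, 0.8 * h), rng.uniform(0.2 * w, 0.8 * w)])
        t = np.linspace(0.0, 1.0, 4 * (h + w))[:, None]
        curve = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
        rr = np.clip(np.rint(curve[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.rint(curve[:, 1]).astype(int), 0, w - 1)
        canvas[rr, cc] = True
    width = 2
    dilated = ndi.binary_dilation(canvas, iterations=width)
    return ndi.gaussian_filter(dilated.astype(np.float64), 1.0)


def generate_image(p: SynthImageParams,
                   meta: ImageMeta | None = None) -> tuple[FundusImage, GroundTruth]:
    """Render one synthetic frame; bit-identical for a fixed seed."""
    rng = np.random.default_rng(p.seed)
    h, w = p.shape_px
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]

    gr, gc = p.illumination_gradient
    base = p.background_level + gr * p.background_level * rows + \
        gc * p.background_level * cols
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    d2 = ((rows - cy) ** 2 + (cols - cx) ** 2) / (cy ** 2 + cx ** 2)
    img = base * (1.0 - p.vignette_strength * d2)

    if p.n_vessels > 0:
        img *= 1.0 - 0.35 * _paint_vessels(rng, p.shape_px, p.n_vessels)

    r_lo, r_hi = p.soma_radius_px_range
    margin = math.ceil(r_hi) + 3
    centers = _place_centers(rng, p.shape_px, p.n_cells, margin,
                             p.min_cell_separation_px)

    truth_mask = np.zeros(p.shape_px, dtype=bool)
    cells: list[PlantedCell] = []
    for ci in range(p.n_cells):
        crow, ccol = centers[ci]
        radius = rng.uniform(r_lo, r_hi)
        sigma = radius / 2.0
        amp = max(10.0, rng.normal(p.cell_intensity_mean, p.cell_intensity_sd))
        rad = math.ceil(radius)
        r0, r1 = int(crow) - rad - 1, int(crow) + rad + 2
        c0, c1 = int(ccol) - rad - 1, int(ccol) + rad + 2
        yy = np.arange(r0, r1, dtype=np.float64)[:, None]
        xx = np.arange(c0, c1, dtype=np.float64)[None, :]
        dd = (yy - crow) ** 2 + (xx - ccol) ** 2
        soma = dd <= radius * radius  # truncation at 2 sigma = nominal radius
        blob = np.where(soma, amp * np.exp(-dd / (2.0 * sigma * sigma)), 0.0)
        img[r0:r1, c0:c1] += blob
        truth_mask[r0:r1, c0:c1] |= soma
        cells.append(PlantedCell(centroid_rc=(float(crow), float(ccol)),
                                 radius_px=float(radius),
                                 peak_intensity=float(amp),
                                 area_px=int(soma.sum())))
        if rng.uniform() < p.process_probability:
            for _ in range(int(rng.integers(2, 6))):
                ang = rng.uniform(0, 2 * math.pi)
                length = rng.uniform(2.0, 4.0) * radius
                ts = np.linspace(0.0, 1.0, int(4 * length))
                pr = np.clip(np.rint(crow + ts * length * math.sin(ang)).astype(int),
                             0, h - 1)
                pc = np.clip(np.rint(ccol + ts * length * math.cos(ang)).astype(int),
                             0, w - 1)
                img[pr, pc] += 0.25 * amp

    img += rng.normal(0.0, p.background_noise_sd, size=p.shape_px)
    maxval = 2 ** p.bit_depth - 1
    dtype = np.uint8 if p.bit_depth == 8 else np.uint16
    quantized = np.clip(np.rint(img), 0, maxval).astype(dtype)
    if meta is None:
        meta = ImageMeta(animal_id=f"synthetic{p.seed}")
    frame = FundusImage(pixels=quantized, bit_depth=p.bit_depth, meta=meta,
                        provenance=({"stage": "synth", "seed": p.seed},))
    return frame, GroundTruth(cells=cells, mask=truth_mask)


def _bump(week: float, peak: float, width: float) -> float:
    return math.exp(-((week - peak) / width) ** 2)


@dataclass(frozen=True)
class SynthCohortParams:
    """Longitudinal cohort design mirrored from the animal study layout.

    Group sizes default to the study's 34 immunized / 21 sham / 20 naive
    animals and the week grid 0,1,2,4,6,8,12; tests and the acceptance
    script run scaled-down cohorts. Cell count and soma size share a slow
    maturation drift in all groups. Each immunized animal carries a random
    disease-severity factor that scales a Gaussian-shaped activation bump
    (peak week 6) on both cell count and soma radius, so count and total
    area share the disease signal while their baseline noise sources stay
    independent: baseline soma size is inversely coupled to baseline
    density (microglial tiling), so animals with more cells have smaller
    ones, and soma size carries its own between-animal variation.
    """

    n_per_group: dict = field(default_factory=lambda: {"EAE": 34, "sham": 21,
                                                       "naive": 20})
    weeks: tuple[int, ...] = (0, 1, 2, 4, 6, 8, 12)
    shape_px: tuple[int, int] = (256, 256)
    base_cell_count: float = 25.0
    maturation_per_week: float = 1.5
    count_bump_frac: float = 0.40
    radius_bump_frac: float = 0.03
    eae_bump_peak_week: float = 6.0
    eae_bump_width_weeks: float = 2.0
    severity_sd: float = 0.35
    base_soma_radius_px: float = 3.4
    density_size_coupling: float = 1.0
    animal_count_sd: float = 0.18
    eye_count_sd: float = 0.08
    animal_radius_sd: float = 0.13
    radius_halfwidth_px: float = 0.5
    min_soma_radius_px: float = 2.6
    min_cell_separation_px: float = 10.0
    image: SynthImageParams = field(default_factory=SynthImageParams)
    seed: int = 0

    def mean_cell_count(self, group: str, week: float, severity: float = 1.0) -> float:
        mu = self.base_cell_count + self.maturation_per_week * week
        if group == "EAE":
            mu *= 1.0 + self.count_bump_frac * severity * _bump(
                week, self.eae_bump_peak_week, self.eae_bump_width_weeks)
        return mu

    def mean_soma_radius(self, group: str, week: float, severity: float = 1.0) -> float:
        mu = self.base_soma_radius_px
        if group == "EAE":
            mu *= 1.0 + self.radius_bump_frac * severity * _bump(
                week, self.eae_bump_peak_week, self.eae_bump_width_weeks)
        return mu


@dataclass
class SynthCohort:
    images: list[tuple[FundusImage, GroundTruth]]
    manifest: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir) -> None:
        """Write TIFF frames, manifest.csv and truth.csv into a directory."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metas = []
        for frame, _ in self.images:
            m = frame.meta
            fname = f"{m.animal_id}_{m.eye.value}_week{m.week}.tif"
            write_image(out / fname, frame)
            metas.append(replace(m, source_path=fname))
        write_manifest(out / "manifest.csv", metas)
        self.truth.to_csv(out / "truth.csv", index=False)


def generate_cohort(p: SynthCohortParams) -> SynthCohort:
    """One frame per animal/eye/week, with per-image planted truth.

    Animal-level random effects (baseline cell density, baseline soma
    size, disease severity for the immunized group) persist across weeks
    and eyes, giving the within-animal correlation a longitudinal design
    implies; eye-level noise is applied on top per frame.
    """
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    gamma = p.density_size_coupling
    images: list[tuple[FundusImage, GroundTruth]] = []
    manifest_rows = []
    truth_rows = []
    for group, n_animals in p.n_per_group.items():
        Group(group)  # validate label
        for a in range(n_animals):
            animal_id = f"{group}{a + 1:02d}"
            severity = max(0.0, rng.normal(1.0, p.severity_sd)) \
                if group == "EAE" else 0.0
            count_effect = max(0.3, rng.normal(1.0, p.animal_count_sd))
            radius_effect = max(0.5, rng.normal(1.0, p.animal_radius_sd))
            for eye in (Eye.LEFT, Eye.RIGHT):
                for week in p.weeks:
                    mu_cc = p.mean_cell_count(group, week, severity) * count_effect
                    n_cells = max(0, int(round(
                        mu_cc * rng.normal(1.0, p.eye_count_sd))))
                    mu_r = max(
                        p.min_soma_radius_px,
                        p.mean_soma_radius(group, week, severity)
                        * radius_effect * count_effect ** (-gamma / 2.0),
                    )
                    meta = ImageMeta(animal_id=animal_id, eye=eye, week=week,
                                     group=Group(group))
                    params = replace(
                        p.image,
                        shape_px=p.shape_px,
                        n_cells=n_cells,
                        soma_radius_px_range=(mu_r - p.radius_halfwidth_px,
                                              mu_r + p.radius_halfwidth_px),
                        min_cell_separation_px=p.min_cell_separation_px,
                        seed=int(rng.integers(0, 2 ** 31)),
                    )
                    frame, truth = generate_image(params, meta=meta)
                    images.append((frame, truth))
                    row = {"animal_id": animal_id, "eye": eye.value,
                           "week": week, "group": group}
                    manifest_rows.append(
                        {**row,
                         "source_path": f"{animal_id}_{eye.value}_week{week}.tif"})
                    truth_rows.append({**row, "true_cc": truth.count,
                                       "true_total_area_px": truth.total_area_px})
    return SynthCohort(images=images,
                       manifest=pd.DataFrame(manifest_rows),
                       truth=pd.DataFrame(truth_rows))
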