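"""Synthetic bright-field micrographs of copepod-like silhouettes.

Real copepod micrographs show one large dark body on a light
background with salt-and-pepper noise from suspended matter and small
distractor particles.  This module renders that situation from
parameterised body-shape models so the whole pipeline can be exercised
and tested on labelled data with known ground truth.

A silhouette is the union of three parts, defined in a body frame with
the anterior (head) end at u = 0:

* prosome: an ellipse spanning the first ``prosome_fraction`` of the
  body length, with half-width ``body_len * body_aspect / 2``;
* urosome: a trapezoid over the remaining length, tapering from
  ``urosome_width_ratio`` of the prosome width down to 80% of that;
* caudal rami: two short rectangular blades at the posterior tip,
  splayed by ``caudal_spread_deg``.

Eight default classes mimic the taxonomy structure of a mangrove
copepod assemblage: two large distinctive species, two within-genus
look-alike pairs, and one cross-genus pair that overlaps in size and is
distinguished mainly by its prosome/urosome proportions (hence by the
lower-ROI feature).  The default canvas is (612, 480), a quarter of the
2448 x 1920 micrograph frame linearly, with the minimum specimen area
scaled by the same factor squared (50000 / 16 ~ 3125 px^2).

Rendering is fully deterministic given a seed; every image comes with
its noise-free ground-truth mask and bookkeeping (silhouette area,
prosome mass fraction) for oracle checks.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import RasterImage, save_image

MeanSd = tuple[float, float]

#: Posterior/anterior width ratio of the urosome trapezoid.
_UROSOME_TAPER = 0.80


@dataclass(frozen=True)
class SpeciesShapeParams:
    """Mean and SD of the shape parameters of one synthetic class."""

    label: str
    body_len: MeanSd            # px
    body_aspect: MeanSd         # width / length
    prosome_fraction: MeanSd    # fraction of body length
    urosome_width_ratio: MeanSd # urosome / prosome width
    caudal_spread_deg: MeanSd   # total splay of the rami pair

    def __post_init__(self) -> None:
        for name in ("body_len", "body_aspect", "prosome_fraction",
                     "urosome_width_ratio", "caudal_spread_deg"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name}: mean must be > 0 and sd >= 0")
        if not 0.3 < self.prosome_fraction[0] < 0.9:
            raise ValueError("prosome_fraction mean must lie in (0.3, 0.9)")


#: Default 8-class assemblage.  As/Bs are large and distinctive; Od/Os
#: and Tb/Tf are within-genus look-alike pairs; Os/Pc overlap in body
#: size and differ mainly in prosome fraction.
DEFAULT_CLASS_PARAMS: dict[str, SpeciesShapeParams] = {
    "As": SpeciesShapeParams("As", (312, 10), (0.42, 0.020), (0.70, 0.02), (0.26, 0.02), (42, 5)),
    "Bs": SpeciesShapeParams("Bs", (185, 8),  (0.55, 0.020), (0.68, 0.02), (0.30, 0.02), (30, 5)),
    "Oa": SpeciesShapeParams("Oa", (245, 9),  (0.29, 0.015), (0.58, 0.02), (0.58, 0.02), (25, 5)),
    "Od": SpeciesShapeParams("Od", (175, 6),  (0.33, 0.015), (0.55, 0.02), (0.62, 0.02), (25, 5)),
    "Os": SpeciesShapeParams("Os", (150, 5),  (0.37, 0.015), (0.55, 0.02), (0.62, 0.02), (25, 5)),
    "Pc": SpeciesShapeParams("Pc", (142, 5),  (0.44, 0.015), (0.70, 0.02), (0.26, 0.02), (30, 5)),
    "Tb": SpeciesShapeParams("Tb", (258, 8),  (0.48, 0.020), (0.66, 0.02), (0.40, 0.02), (45, 5)),
    "Tf": SpeciesShapeParams("Tf", (245, 8),  (0.43, 0.020), (0.62, 0.02), (0.48, 0.02), (45, 5)),
}


@dataclass(frozen=True)
class SceneParams:
    """Canvas, contrast and nuisance-structure settings."""

    canvas: tuple[int, int] = (612, 480)   # (height, width)
    background_level: float = 0.85
    body_level: float = 0.25
    salt_pepper_rate: float = 0.002
    n_distractors: int = 3
    distractor_area_range: tuple[float, float] = (20.0, 400.0)
    min_area_scaled: int = 3125            # 50000 scaled by (1/4)^2
    margin: int = 16                       # keep-off border band, px

    def __post_init__(self) -> None:
        # a distractor dilated by the edge halo must stay below the
        # size cutoff, otherwise the size filter cannot remove it
        if self.distractor_area_range[1] >= self.min_area_scaled:
            raise ValueError("distractor max area must be < min_area_scaled")


@dataclass(frozen=True)
class SpecimenDraw:
    """One sampled parameter set plus analytic area bookkeeping."""

    label: str
    body_len: float
    body_aspect: float
    prosome_fraction: float
    urosome_width_ratio: float
    caudal_spread_deg: float
    analytic_area: float

    @property
    def body_width(self) -> float:
        return self.body_len * self.body_aspect


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n_sigma: float = 3.0) -> float:
    if sd == 0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= n_sigma * sd:
            return x


def _analytic_area(L: float, aspect: float, pf: float, uwr: float) -> float:
    """Closed-form silhouette area (prosome ellipse + urosome trapezoid)."""
    W = L * aspect
    prosome = math.pi * (pf * L / 2.0) * (W / 2.0)
    u_len = (1.0 - pf) * L
    w0 = uwr * W / 2.0
    urosome = u_len * (w0 + _UROSOME_TAPER * w0)  # trapezoid, both sides
    return prosome + urosome


def sample_specimen(params: SpeciesShapeParams,
                    rng: np.random.Generator) -> SpecimenDraw:
    """Draw one specimen's shape parameters (3-sigma truncated normal)."""
    L = _truncated_normal(rng, *params.body_len)
    aspect = _truncated_normal(rng, *params.body_aspect)
    pf = min(max(_truncated_normal(rng, *params.prosome_fraction), 0.31), 0.89)
    uwr = _truncated_normal(rng, *params.urosome_width_ratio)
    spread = _truncated_normal(rng, *params.caudal_spread_deg)
    return SpecimenDraw(
        label=params.label, body_len=L, body_aspect=aspect,
        prosome_fraction=pf, urosome_width_ratio=uwr,
        caudal_spread_deg=spread,
        analytic_area=_analytic_area(L, aspect, pf, uwr),
    )


def _silhouette_membership(draw: SpecimenDraw, u: np.ndarray,
                           v: np.ndarray) -> np.ndarray:
    """Boolean membership of body-frame points (u along axis from head)."""
    L = draw.body_len
    W = draw.body_width
    pf = draw.prosome_fraction
    pro_a = pf * L / 2.0
    pro = ((u - pro_a) / pro_a) ** 2 + (v / (W / 2.0)) ** 2 <= 1.0

    u1 = pf * L
    w0 = draw.urosome_width_ratio * W / 2.0
    w1 = _UROSOME_TAPER * w0
    t = np.clip((u - u1) / max(L - u1, 1e-9), 0.0, 1.0)
    half_w = w0 + (w1 - w0) * t
    uro = (u >= u1) & (u <= L) & (np.abs(v) <= half_w)

    # caudal rami: two splayed blades from just inside the posterior tip
    theta = math.radians(draw.caudal_spread_deg / 2.0)
    lr = 0.10 * L
    wr = 3.0  # half-width, px: wide enough to survive a 10x10 median
    rami = np.zeros_like(pro)
    for s in (-1.0, 1.0):
        bu, bv = L - 2.0, s * w1 * 0.6
        du, dv = math.cos(theta), s * math.sin(theta)
        tu = (u - bu) * du + (v - bv) * dv
        perp = -(u - bu) * dv + (v - bv) * du
        rami |= (tu >= 0) & (tu <= lr) & (np.abs(perp) <= wr)
    return pro | uro | rami


def _max_radius(draw: SpecimenDraw) -> float:
    """Radius of the smallest disc around the body centre that holds it."""
    return draw.body_len * 0.5 + 0.10 * draw.body_len + 4.0


def render_copepod(draw: SpecimenDraw, scene: SceneParams,
                   rng: np.random.Generator):
    """Render one scene: (image, ground-truth mask, ground-truth record).

    The specimen is placed at a uniform random centre and orientation;
    distractor blobs are kept clear of the specimen (and below the size
    cutoff) so the cleaning chain can always remove them.
    """
    H, W = scene.canvas
    R = _max_radius(draw)
    m = scene.margin
    if 2 * (R + m) >= min(H, W):
        raise ValueError("specimen too large for canvas")
    cr = rng.uniform(R + m, H - R - m)
    cc = rng.uniform(R + m, W - R - m)
    phi = rng.uniform(0.0, 2.0 * math.pi)

    rows, cols = np.mgrid[0:H, 0:W]
    # body axis unit vector (anterior -> posterior) at angle phi, y-up
    au, av = math.cos(phi), math.sin(phi)
    # anterior tip sits half a body length "up-axis" from the centre
    tip_x = cc - (draw.body_len / 2.0) * au
    tip_y = -cr - (draw.body_len / 2.0) * av
    x = cols - tip_x
    y = -rows - tip_y
    u = x * au + y * av
    v = -x * av + y * au
    mask = _silhouette_membership(draw, u, v)

    img = np.full((H, W), scene.background_level)
    img[mask] = scene.body_level

    # distractor blobs: small ellipses clear of the specimen
    rmask, cmask = np.nonzero(mask)
    for _ in range(scene.n_distractors):
        area = rng.uniform(*scene.distractor_area_range)
        q = rng.uniform(0.5, 1.0)
        a = math.sqrt(area / (math.pi * q))
        b = q * a
        for _attempt in range(100):
            dr = rng.uniform(b + 1, H - b - 1)
            dc = rng.uniform(a + 1, W - a - 1)
            clearance = a + 26.0  # 2 x edge window + safety
            d2 = (rmask - dr) ** 2 + (cmask - dc) ** 2
            if d2.min() > clearance**2:
                break
        else:
            continue
        ang = rng.uniform(0, math.pi)
        xx = (cols - dc) * math.cos(ang) + (rows - dr) * math.sin(ang)
        yy = -(cols - dc) * math.sin(ang) + (rows - dr) * math.cos(ang)
        img[(xx / a) ** 2 + (yy / b) ** 2 <= 1.0] = scene.body_level

    # salt-and-pepper noise
    n_noise = int(round(scene.salt_pepper_rate * H * W))
    if n_noise:
        rr = rng.integers(0, H, n_noise)
        cc_n = rng.integers(0, W, n_noise)
        val = rng.integers(0, 2, n_noise).astype(float)
        img[rr, cc_n] = val

    area = int(mask.sum())
    u_mask = u[mask]
    prosome_mass = float(
        (u_mask <= draw.prosome_fraction * draw.body_len).mean()
    )
    record = {
        "label": draw.label,
        "true_area": area,
        "analytic_area": draw.analytic_area,
        "prosome_fraction": draw.prosome_fraction,
        "prosome_mass_fraction": prosome_mass,
        "pose_deg": math.degrees(phi),
    }
    return RasterImage(img), mask, record


@dataclass
class SyntheticDataset:
    """In-memory dataset: images, ground-truth masks and records."""

    images: list[RasterImage]
    masks: list[np.ndarray]
    records: pd.DataFrame
    scene: SceneParams

    def subset(self, role: str) -> pd.DataFrame:
        return self.records[self.records["role"] == role]


def _spawn_rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=path))


def generate_arrays(
    class_params: dict[str, SpeciesShapeParams] | None = None,
    n_train: int = 30,
    n_test: int = 20,
    scene: SceneParams = SceneParams(),
    seed: int = 0,
) -> SyntheticDataset:
    """Generate the full labelled dataset in memory, deterministically.

    Every (class, role, index) triple gets its own derived random
    stream, so the same seed always reproduces the same images and the
    draw for one specimen does not depend on how many others were made.
    """
    class_params = class_params or DEFAULT_CLASS_PARAMS
    images, masks, rows = [], [], []
    for ci, (code, params) in enumerate(sorted(class_params.items())):
        for role, count, base in (("train", n_train, 0), ("test", n_test, 1)):
            for i in range(count):
                rng = _spawn_rng(seed, ci, base, i)
                draw = sample_specimen(params, rng)
                img, mask, rec = render_copepod(draw, scene, rng)
                rec.update({"species_code": code, "role": role, "index": i})
                images.append(img)
                masks.append(mask)
                rows.append(rec)
    return SyntheticDataset(images, masks, pd.DataFrame(rows), scene)


def generate_dataset(
    out_dir: str | os.PathLike,
    class_params: dict[str, SpeciesShapeParams] | None = None,
    n_train: int = 30,
    n_test: int = 20,
    scene: SceneParams = SceneParams(),
    seed: int = 0,
) -> SyntheticDataset:
    """Generate and write images + train/test manifests + truth CSV.

    Layout: ``out_dir/images/<code>_<role>_<i>.png`` plus
    ``train.csv``, ``test.csv`` (manifest format) and ``truth.csv``.
    """
    out_dir = os.fspath(out_dir)
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    ds = generate_arrays(class_params, n_train, n_test, scene, seed)
    paths = []
    for img, (_, rec) in zip(ds.images, ds.records.iterrows()):
        name = f"{rec['species_code']}_{rec['role']}_{int(rec['index']):03d}.png"
        save_image(img, os.path.join(img_dir, name))
        paths.append(os.path.join("images", name))
    ds.records = ds.records.assign(image_path=paths)
    for role in ("train", "test"):
        sub = ds.records[ds.records["role"] == role]
        sub[["image_path", "species_code", "role"]].to_csv(
            os.path.join(out_dir, f"{role}.csv"), index=False
        )
    ds.records.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    return ds


def validate_class_separation(
    class_params: dict[str, SpeciesShapeParams] | None = None,
    min_sigma: float = 2.0,
    min_params: int = 2,
) -> pd.DataFrame:
    """Check every class pair differs in >= 2 parameter means by >= 2 SD.

    Returns the pairwise table of per-parameter standardised gaps;
    raises ``ValueError`` if any pair fails the separation rule.
    """
    class_params = class_params or DEFAULT_CLASS_PARAMS
    names = ("body_len", "body_aspect", "prosome_fraction",
             "urosome_width_ratio", "caudal_spread_deg")
    codes = sorted(class_params)
    rows = []
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            gaps = {}
            for nm in names:
                ma, sa = getattr(class_params[a], nm)
                mb, sb = getattr(class_params[b], nm)
                pooled = math.sqrt((sa**2 + sb**2) / 2.0) or 1e-12
                gaps[nm] = abs(ma - mb) / pooled
            n_sep = sum(g >= min_sigma for g in gaps.values())
            rows.append({"pair": f"{a}/{b}", **gaps, "n_separated": n_sep})
            if n_sep < min_params:
                raise ValueError(
                    f"classes {a}/{b} differ in only {n_sep} parameter(s) "
                    f"by >= {min_sigma} pooled SD"
                )
    return pd.DataFrame(rows)
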