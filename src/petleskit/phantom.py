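"""Synthetic whole-body PET/CT phantoms with known lesion truth.

The generator emulates the structure of a somatostatin-receptor PET cohort:
a body with organ compartments whose background uptake mimics the tracer's
physiology (notably a high hepatic background), spherical lesions spanning
small/low-uptake to large/high-uptake, a Gaussian point-spread blur applied
to the emission image only, and heteroscedastic noise. A companion
degradation step turns the ground-truth mask into an imperfect "prediction"
with controlled per-lesion misses, optional 1-voxel boundary morphology and
Poisson-count false-positive blobs, returning exact per-lesion bookkeeping
so every downstream metric has a known expected value.

Organ label codes (fixed contract, consumed by the failure-analysis stage):

====  =============
code  region
====  =============
0     background
1     brain_skull
2     lung
3     mediastinum
4     liver
5     spleen
6     kidney
7     other_abdomen
8     bone
====  =============
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import SpecError
from .grid import VolumeGrid

ORGAN_CODES: dict[str, int] = {
    "background": 0,
    "brain_skull": 1,
    "lung": 2,
    "mediastinum": 3,
    "liver": 4,
    "spleen": 5,
    "kidney": 6,
    "other_abdomen": 7,
    "bone": 8,
}
ORGAN_NAMES: dict[int, str] = {v: k for k, v in ORGAN_CODES.items()}

#: default background SUV per organ compartment (body-weight SUV units)
DEFAULT_ORGAN_SUV: dict[str, float] = {
    "background": 0.0,
    "brain_skull": 0.2,
    "lung": 0.4,
    "mediastinum": 1.2,
    "liver": 6.0,       # high physiologic hepatic background
    "spleen": 18.0,
    "kidney": 10.0,
    "other_abdomen": 1.0,
    "bone": 0.8,
    "bladder": 12.0,    # uptake-only region, labelled other_abdomen
}

DEFAULT_ORGAN_HU: dict[str, float] = {
    "background": -1000.0,
    "brain_skull": 35.0,
    "lung": -700.0,
    "mediastinum": 40.0,
    "liver": 55.0,
    "spleen": 45.0,
    "kidney": 40.0,
    "other_abdomen": 40.0,
    "bone": 700.0,
}


@dataclass
class LesionSpec:
    """One lesion: voxel-index center, radius in mm, nominal peak SUV."""

    center: tuple[int, int, int]
    radius_mm: float
    peak_suv: float


@dataclass
class DegradationRules:
    """How to corrupt a ground-truth mask into a synthetic 'AI prediction'.

    ``miss_prob`` fixes a uniform per-lesion miss probability; when None the
    logistic model ``logit(p_miss) = c0 + c_suv*log(SUVpeak) + c_vol*log(TTV)``
    is used, so small and low-uptake lesions are missed preferentially.
    False-positive blob count per scan is Poisson(``fp_lambda``); blobs are
    placed so they never touch ground-truth lesions. ``morphology`` applies
    at most a 1-voxel erosion/dilation to kept lesions.
    """

    miss_prob: float | None = None
    logistic_c0: float = 2.2
    logistic_c_suv: float = -1.2
    logistic_c_vol: float = -0.8
    fp_lambda: float = 3.0
    fp_radius_mm: tuple[float, float] = (3.0, 10.0)
    fp_suv: tuple[float, float] = (4.0, 15.0)
    fp_region: str | None = None  # organ name; None = anywhere in the body
    morphology: str = "none"  # none | erode | dilate | random
    enabled: bool = True

    def miss_probability(self, peak_suv: float, ttv_cm3: float) -> float:
        if not self.enabled:
            return 0.0
        if self.miss_prob is not None:
            return float(self.miss_prob)
        lp = (
            self.logistic_c0
            + self.logistic_c_suv * np.log(max(peak_suv, 1e-6))
            + self.logistic_c_vol * np.log(max(ttv_cm3, 1e-6))
        )
        return float(1.0 / (1.0 + np.exp(-lp)))


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic scan.

    Lesion count: ``lesions`` (explicit list) wins; else ``n_lesions``; else
    a log-normal count with median ~30 clipped to [3, 280], mirroring a
    heavily metastatic cohort.
    """

    shape: tuple[int, int, int] = (96, 96, 192)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    organ_suv: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ORGAN_SUV))
    lesions: list[LesionSpec] | None = None
    n_lesions: int | None = None
    lesion_count_median: float = 30.0
    lesion_count_sigma: float = 0.9
    lesion_count_range: tuple[int, int] = (3, 280)
    radius_range_mm: tuple[float, float] = (3.0, 25.0)  # log-uniform
    peak_suv_range: tuple[float, float] = (4.0, 40.0)   # uniform
    lesion_region: str | None = None  # restrict placement to one organ
    psf_fwhm_mm: float = 5.0
    noise_coeff: float = 0.15  # sd = coeff * sqrt(intensity)
    bg_texture_cv: float = 0.10  # smooth multiplicative background variation
    min_gap_mm: float | None = None  # default 2*max(spacing)
    max_attempts: int = 1000
    degradation: DegradationRules = field(default_factory=DegradationRules)
    seed: int = 0

    def with_(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)


@dataclass
class PhantomScan:
    """Output bundle of :func:`generate_scan`."""

    pet: VolumeGrid
    ct: VolumeGrid
    gt_mask: VolumeGrid       # binary union of lesion spheres
    lesion_labels: VolumeGrid  # one integer label per truth row
    organ_labels: VolumeGrid
    truth: pd.DataFrame
    spec: PhantomSpec


@dataclass
class DegradedScan:
    """Output bundle of :func:`degrade_mask`."""

    pred_mask: VolumeGrid  # binary
    flags: pd.DataFrame    # lesion_id, kept, miss_prob
    fp_table: pd.DataFrame  # fp_id, center, radius_mm, nominal_suv, region
    n_fp: int


def _ellipsoid(xx, yy, zz, center, semi) -> np.ndarray:
    return (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    ) <= 1.0


def build_anatomy(
    shape: tuple[int, int, int], spacing: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic organ geometry: (organ_labels, bladder_mask).

    The body is a stack of xy-ellipses along z - pelvis, abdomen, thorax,
    neck and head - with ellipsoidal organs placed at fixed relative
    positions. Everything is computed in physical mm so the same anatomy
    (up to voxelization) appears at any grid resolution.
    """
    nx, ny, nz = shape
    sx, sy, sz = spacing
    X, Y, Z = nx * sx, ny * sy, nz * sz
    xx, yy, zz = np.meshgrid(
        (np.arange(nx) + 0.5) * sx,
        (np.arange(ny) + 0.5) * sy,
        (np.arange(nz) + 0.5) * sz,
        indexing="ij",
    )
    cx, cy = X / 2, Y / 2
    zf = zz / Z  # z as a fraction of the scan length

    # torso semi-axes taper toward the feet and the neck
    ax = np.where(zf < 0.82, 0.42 * X * (0.85 + 0.15 * np.clip(zf / 0.3, 0, 1)), 0.20 * X)
    ay = np.where(zf < 0.82, 0.30 * Y * (0.85 + 0.15 * np.clip(zf / 0.3, 0, 1)), 0.22 * Y)
    # head bulge above the neck
    head = zf >= 0.86
    ax = np.where(head, 0.26 * X, ax)
    ay = np.where(head, 0.26 * Y, ay)
    body = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    labels[body & (zf < 0.52)] = ORGAN_CODES["other_abdomen"]
    labels[body & (zf >= 0.52) & (zf < 0.82)] = ORGAN_CODES["mediastinum"]
    labels[body & (zf >= 0.82)] = ORGAN_CODES["brain_skull"]

    # thorax: lungs flank a central mediastinal block; chest wall -> other
    lung_l = _ellipsoid(xx, yy, zz, (0.32 * X, 0.48 * Y, 0.68 * Z), (0.11 * X, 0.16 * Y, 0.12 * Z))
    lung_r = _ellipsoid(xx, yy, zz, (0.68 * X, 0.48 * Y, 0.68 * Z), (0.11 * X, 0.16 * Y, 0.12 * Z))
    medi = _ellipsoid(xx, yy, zz, (0.50 * X, 0.46 * Y, 0.68 * Z), (0.09 * X, 0.13 * Y, 0.13 * Z))
    chest_wall = body & (zf >= 0.52) & (zf < 0.82) & ~(lung_l | lung_r | medi)
    labels[chest_wall] = ORGAN_CODES["other_abdomen"]
    labels[body & (lung_l | lung_r)] = ORGAN_CODES["lung"]
    labels[body & medi] = ORGAN_CODES["mediastinum"]

    liver = _ellipsoid(xx, yy, zz, (0.63 * X, 0.46 * Y, 0.44 * Z), (0.17 * X, 0.19 * Y, 0.09 * Z))
    spleen = _ellipsoid(xx, yy, zz, (0.30 * X, 0.50 * Y, 0.46 * Z), (0.07 * X, 0.09 * Y, 0.045 * Z))
    kid_l = _ellipsoid(xx, yy, zz, (0.37 * X, 0.62 * Y, 0.35 * Z), (0.055 * X, 0.055 * Y, 0.05 * Z))
    kid_r = _ellipsoid(xx, yy, zz, (0.63 * X, 0.62 * Y, 0.35 * Z), (0.055 * X, 0.055 * Y, 0.05 * Z))
    labels[body & liver] = ORGAN_CODES["liver"]
    labels[body & spleen] = ORGAN_CODES["spleen"]
    labels[body & (kid_l | kid_r)] = ORGAN_CODES["kidney"]

    spine = (
        (((xx - 0.5 * X) / (0.045 * X)) ** 2 + ((yy - 0.64 * Y) / (0.045 * Y)) ** 2 <= 1.0)
        & (zf >= 0.12)
        & (zf < 0.80)
        & body
    )
    labels[spine] = ORGAN_CODES["bone"]

    bladder = _ellipsoid(xx, yy, zz, (0.50 * X, 0.45 * Y, 0.08 * Z), (0.06 * X, 0.07 * Y, 0.04 * Z)) & body
    return labels, bladder


def _background_maps(
    labels: np.ndarray, bladder: np.ndarray, organ_suv: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """(SUV background, CT HU) maps from the organ label map."""
    suv = np.zeros(labels.shape, dtype=np.float64)
    hu = np.full(labels.shape, DEFAULT_ORGAN_HU["background"], dtype=np.float64)
    for name, code in ORGAN_CODES.items():
        sel = labels == code
        suv[sel] = organ_suv.get(name, DEFAULT_ORGAN_SUV[name])
        hu[sel] = DEFAULT_ORGAN_HU[name]
    suv[bladder] = organ_suv.get("bladder", DEFAULT_ORGAN_SUV["bladder"])
    return suv, hu


def _sphere_indices(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[int, int, int],
    radius_mm: float,
) -> tuple[np.ndarray, ...]:
    """Voxel indices whose centers fall within radius_mm of the center voxel."""
    half = [int(np.ceil(radius_mm / s)) + 1 for s in spacing]
    lo = [max(0, c - h) for c, h in zip(center, half)]
    hi = [min(n, c + h + 1) for c, h, n in zip(center, half, shape)]
    ix, iy, iz = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    d2 = (
        ((ix - center[0]) * spacing[0]) ** 2
        + ((iy - center[1]) * spacing[1]) ** 2
        + ((iz - center[2]) * spacing[2]) ** 2
    )
    sel = d2 <= radius_mm**2
    return ix[sel], iy[sel], iz[sel]


def _sample_lesions(
    spec: PhantomSpec,
    labels: np.ndarray,
    rng: np.random.Generator,
) -> list[LesionSpec]:
    if spec.lesions is not None:
        return list(spec.lesions)
    if spec.n_lesions is not None:
        n = int(spec.n_lesions)
    else:
        lo, hi = spec.lesion_count_range
        n = int(np.clip(
            round(float(rng.lognormal(np.log(spec.lesion_count_median), spec.lesion_count_sigma))),
            lo, hi,
        ))
    if n == 0:
        return []

    body = labels > 0
    if spec.lesion_region is not None:
        allowed = labels == ORGAN_CODES[spec.lesion_region]
        if not allowed.any():
            raise SpecError(f"no voxels in region {spec.lesion_region!r}")
    else:
        allowed = body
    # distance (mm) from each body voxel to the outside: a lesion of radius r
    # fits entirely inside the body iff edt[center] >= r
    edt = ndimage.distance_transform_edt(body, sampling=spec.spacing)
    cand = np.argwhere(allowed)
    min_gap = spec.min_gap_mm if spec.min_gap_mm is not None else 2.0 * max(spec.spacing)
    spacing = np.asarray(spec.spacing)

    placed: list[LesionSpec] = []
    centers_mm: list[np.ndarray] = []
    radii: list[float] = []
    r_lo, r_hi = spec.radius_range_mm
    attempts = 0
    budget = spec.max_attempts * max(n, 1)
    while len(placed) < n:
        if attempts >= budget:
            raise SpecError(
                f"could not place {n} non-overlapping lesions after {budget} attempts"
            )
        attempts += 1
        c = cand[rng.integers(len(cand))]
        r = float(np.exp(rng.uniform(np.log(r_lo), np.log(r_hi))))
        if edt[tuple(c)] < r:
            continue
        c_mm = (c + 0.5) * spacing
        ok = True
        for o_mm, o_r in zip(centers_mm, radii):
            if np.linalg.norm(c_mm - o_mm) <= r + o_r + min_gap:
                ok = False
                break
        if not ok:
            continue
        suv = float(rng.uniform(*spec.peak_suv_range))
        placed.append(LesionSpec(tuple(int(v) for v in c), r, suv))
        centers_mm.append(c_mm)
        radii.append(r)
    return placed


def generate_scan(spec: PhantomSpec) -> PhantomScan:
    """Generate one synthetic whole-body scan.

    Returns PET (SUV, PSF-blurred + noisy), CT (HU), the crisp binary
    ground-truth mask, a per-lesion labeled mask, the organ label map, and
    a truth table with one row per lesion (center, radius, nominal peak
    SUV, region tag, voxel count, volume). Identical spec + seed gives
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    labels, bladder = build_anatomy(spec.shape, spec.spacing)
    bg_suv, hu = _background_maps(labels, bladder, spec.organ_suv)

    if spec.bg_texture_cv > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=3.0)
        tex /= max(tex.std(), 1e-12)
        bg_suv = bg_suv * np.clip(1.0 + spec.bg_texture_cv * tex, 0.2, None)

    lesions = _sample_lesions(spec, labels, rng)
    lesion_labels = np.zeros(spec.shape, dtype=np.int32)
    pet_clean = bg_suv.copy()
    voxvol_cm3 = float(np.prod(spec.spacing)) * 1e-3
    rows = []
    for i, les in enumerate(lesions, start=1):
        idx = _sphere_indices(spec.shape, spec.spacing, les.center, les.radius_mm)
        if len(idx[0]) == 0:  # radius below half the voxel size: keep the center voxel
            idx = tuple(np.array([c]) for c in les.center)
        lesion_labels[idx] = i
        pet_clean[idx] = np.maximum(pet_clean[idx], les.peak_suv)
        region = ORGAN_NAMES.get(int(labels[les.center]), "background")
        rows.append({
            "lesion_id": i,
            "cx": les.center[0], "cy": les.center[1], "cz": les.center[2],
            "radius_mm": les.radius_mm,
            "peak_suv": les.peak_suv,
            "region": region,
            "n_voxels": int(len(idx[0])),
            "ttv_cm3": float(len(idx[0])) * voxvol_cm3,
        })
    truth = pd.DataFrame(
        rows,
        columns=["lesion_id", "cx", "cy", "cz", "radius_mm", "peak_suv",
                 "region", "n_voxels", "ttv_cm3"],
    )

    sigma_vox = [spec.psf_fwhm_mm / 2.3548200450309493 / s for s in spec.spacing]
    pet = ndimage.gaussian_filter(pet_clean, sigma=sigma_vox)
    if spec.noise_coeff > 0:
        pet = pet + rng.standard_normal(spec.shape) * (spec.noise_coeff * np.sqrt(np.clip(pet, 0, None)))
    pet = np.clip(pet, 0.0, None)

    g = lambda a: VolumeGrid(a, spec.spacing)  # noqa: E731
    return PhantomScan(
        pet=g(pet.astype(np.float32)),
        ct=g(hu.astype(np.float32)),
        gt_mask=g((lesion_labels > 0).astype(np.int32)),
        lesion_labels=g(lesion_labels),
        organ_labels=g(labels),
        truth=truth,
        spec=spec,
    )


def _morph_component(sel: np.ndarray, op: str) -> np.ndarray:
    struct = ndimage.generate_binary_structure(3, 1)
    if op == "dilate":
        return ndimage.binary_dilation(sel, structure=struct)
    out = ndimage.binary_erosion(sel, structure=struct)
    if not out.any():  # never erode a small lesion to nothing
        return sel
    return out


def degrade_mask(
    lesion_labels: VolumeGrid,
    truth: pd.DataFrame,
    rules: DegradationRules,
    seed: int,
    organ_labels: VolumeGrid | None = None,
) -> DegradedScan:
    """Corrupt a labeled ground-truth mask into a synthetic prediction.

    Each lesion is dropped independently with its miss probability; kept
    lesions optionally get a 1-voxel erosion/dilation; false-positive blobs
    (Poisson count) are added where the ground truth is empty, never
    touching a true lesion. The returned flags make expected detection
    metrics exactly computable.
    """
    rng = np.random.default_rng(seed)
    lab = np.asarray(lesion_labels.data)
    shape = lab.shape
    spacing = lesion_labels.spacing

    pred = np.zeros(shape, dtype=bool)
    flags = []
    if rules.morphology == "random":
        ops = rng.choice(["none", "erode", "dilate"], size=max(len(truth), 1))
    for j, row in enumerate(truth.itertuples(index=False)):
        p_miss = rules.miss_probability(row.peak_suv, row.ttv_cm3)
        kept = bool(rng.random() >= p_miss) if rules.enabled else True
        flags.append({"lesion_id": int(row.lesion_id), "kept": kept, "miss_prob": p_miss})
        if not kept:
            continue
        sel = lab == int(row.lesion_id)
        op = rules.morphology if rules.morphology != "random" else str(ops[j])
        if rules.enabled and op in ("erode", "dilate"):
            sel = _morph_component(sel, op)
        pred |= sel
    flags_df = pd.DataFrame(flags, columns=["lesion_id", "kept", "miss_prob"])

    fp_rows = []
    if rules.enabled and rules.fp_lambda > 0:
        n_fp = int(rng.poisson(rules.fp_lambda))
        if n_fp > 0:
            if organ_labels is not None:
                org = np.asarray(organ_labels.data)
                if rules.fp_region is not None:
                    allowed = org == ORGAN_CODES[rules.fp_region]
                else:
                    allowed = org > 0
            else:
                allowed = np.ones(shape, dtype=bool)
            cand = np.argwhere(allowed)
            if len(cand) == 0:
                raise SpecError("no voxels available for false-positive placement")
            # clearance (mm) to the nearest ground-truth voxel
            gt_edt = (
                ndimage.distance_transform_edt(lab == 0, sampling=spacing)
                if (lab > 0).any()
                else np.full(shape, np.inf)
            )
            margin = 2.5 * max(spacing)  # stay clear even after 1-voxel dilation
            placed_mm: list[np.ndarray] = []
            placed_r: list[float] = []
            sp = np.asarray(spacing)
            for k in range(n_fp):
                for _ in range(500):
                    c = cand[rng.integers(len(cand))]
                    r = float(np.exp(rng.uniform(*np.log(rules.fp_radius_mm))))
                    if gt_edt[tuple(c)] <= r + margin:
                        continue
                    c_mm = (c + 0.5) * sp
                    if any(
                        np.linalg.norm(c_mm - o) <= r + orr + margin
                        for o, orr in zip(placed_mm, placed_r)
                    ):
                        continue
                    idx = _sphere_indices(shape, spacing, tuple(int(v) for v in c), r)
                    if len(idx[0]) == 0:
                        idx = tuple(np.array([v]) for v in c)
                    pred[idx] = True
                    region = (
                        ORGAN_NAMES.get(int(np.asarray(organ_labels.data)[tuple(c)]), "background")
                        if organ_labels is not None
                        else "unassigned"
                    )
                    fp_rows.append({
                        "fp_id": k + 1,
                        "cx": int(c[0]), "cy": int(c[1]), "cz": int(c[2]),
                        "radius_mm": r,
                        "nominal_suv": float(rng.uniform(*rules.fp_suv)),
                        "region": region,
                    })
                    placed_mm.append(c_mm)
                    placed_r.append(r)
                    break
    fp_df = pd.DataFrame(
        fp_rows, columns=["fp_id", "cx", "cy", "cz", "radius_mm", "nominal_suv", "region"]
    )
    return DegradedScan(
        pred_mask=lesion_labels.like(pred.astype(np.int32)),
        flags=flags_df,
        fp_table=fp_df,
        n_fp=len(fp_df),
    )


def add_fp_uptake(pet: VolumeGrid, degraded: DegradedScan) -> VolumeGrid:
    """Paint the degraded scan's false-positive blobs into a PET volume.

    Used when a false positive should carry real uptake (e.g. a hot kidney
    FP inflating the predicted SUVmax); returns a new PET grid.
    """
    out = np.asarray(pet.data, dtype=np.float64).copy()
    for row in degraded.fp_table.itertuples(index=False):
        idx = _sphere_indices(pet.shape, pet.spacing, (row.cx, row.cy, row.cz), row.radius_mm)
        if len(idx[0]):
            out[idx] = np.maximum(out[idx], row.nominal_suv)
    return pet.like(out)
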