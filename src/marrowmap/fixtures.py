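"""Seeded synthetic micrograph generator with ground truth.

Emulates the statistical structure of confocal bone-marrow fields: annular
vessel cross-sections with log-normally distributed inner calibers, an
optional perivascular-cell ring, a cytoskeletal channel (NESTIN-like) and a
membrane channel (CD34/CD31-like) whose rings are radially offset so the two
markers co-occur without overlapping pixel-by-pixel, a bone trabecula
entering from one image edge, and immature-hematopoietic-cell (imHC) point
patterns that are either uniform over the marrow or condensed in an
exponential shell around a chosen target.

Everything is deterministic under (config, seed): a single
``numpy.random.SeedSequence`` fans out child generators per image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import TUBULAR_CLASSES, FixtureConfig

CHANNELS = ("nestin", "endothelial", "perivascular", "nuclei")


@dataclass
class MicrographSet:
    """One multi-channel field with its label masks and calibration."""

    name: str
    channels: Dict[str, np.ndarray]
    lumen_labels: np.ndarray
    wall_labels: np.ndarray
    bone_mask: np.ndarray
    um_per_px: float


@dataclass
class GroundTruth:
    """Per-dataset truth tables, recomputable from the rendered masks."""

    vessel_table: pd.DataFrame
    bone_mask: np.ndarray
    imhc_points: pd.DataFrame
    distance_table: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# single-vessel rendering


def render_vessel(
    vessel_class: str,
    ic_um: float,
    has_pericytes: bool,
    marker_offset_px: int,
    um_per_px: float,
    *,
    wall_um: float = 2.0,
    membrane_um: float = 1.0,
    pericyte_um: float = 1.5,
    compression: float = 1.0,
    angle_rad: float = 0.0,
    patch_px: Optional[int] = None,
) -> dict:
    """Render one vessel cross-section patch.

    The endothelial wall is an annulus positive in the cytoskeletal channel
    (the cytoskeletal marker fills the cell body); the membrane channel is a
    thinner ring centered mid-wall and displaced radially outward by
    ``marker_offset_px`` (sub-cellular offset between a cytoskeletal and a
    surface marker: the two signals co-occur on the same cells without
    coinciding pixel-by-pixel once the offset exceeds the ring thickness).
    ``compression`` < 1 renders an elliptical lumen whose minor axis equals
    ``ic_um`` (compressed-lumen arterioles); ``ic_um`` = 0 renders a filled
    cell body with an empty lumen mask.

    Returns a dict with ``channels`` (per-channel float arrays), ``lumen``
    and ``wall`` boolean masks, and ``radius_px`` (outer extent).
    """
    if ic_um < 0:
        raise ValueError("ic_um must be >= 0")
    if not 0 < compression <= 1:
        raise ValueError("compression must be in (0, 1]")

    wall_px = max(wall_um / um_per_px, 1.0)
    mem_px = max(membrane_um / um_per_px, 1.0)
    peri_px = pericyte_um / um_per_px
    b_in = 0.5 * ic_um / um_per_px  # semi-minor of the lumen, px
    a_in = b_in / compression  # semi-major, px
    body_px = 2.5 / um_per_px  # cell-body radius for lumenless structures

    outer = a_in + wall_px + (peri_px if has_pericytes else 0.0) + marker_offset_px
    outer = max(outer, body_px) + 2.0
    if patch_px is None:
        patch_px = 2 * int(math.ceil(outer)) + 1
    if 2 * a_in + 2 >= patch_px:
        raise ValueError("ic_um exceeds patch size")

    c = patch_px // 2
    yy, xx = np.mgrid[0:patch_px, 0:patch_px].astype(float)
    yy -= c
    xx -= c
    ca, sa = math.cos(angle_rad), math.sin(angle_rad)
    u = ca * xx + sa * yy  # along the major axis
    v = -sa * xx + ca * yy

    def ellipse(a: float, b: float) -> np.ndarray:
        if a <= 0 or b <= 0:
            return np.zeros((patch_px, patch_px), dtype=bool)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    channels = {ch: np.zeros((patch_px, patch_px), dtype=float) for ch in CHANNELS}

    if ic_um == 0:
        lumen = np.zeros((patch_px, patch_px), dtype=bool)
        wall = ellipse(body_px, body_px)
    else:
        lumen = ellipse(a_in, b_in)
        wall = ellipse(a_in + wall_px, b_in + wall_px) & ~lumen

    channels["nestin"][wall] = 1.0
    if ic_um > 0:
        mid = wall_px / 2.0 + marker_offset_px
        membrane = ellipse(a_in + mid + mem_px / 2, b_in + mid + mem_px / 2) & ~ellipse(
            a_in + mid - mem_px / 2, b_in + mid - mem_px / 2
        )
    else:
        # membrane ring on the cell edge, displaced by the marker offset but
        # referenced to the outer half of the cell body
        mid = body_px - wall_px / 2.0 + marker_offset_px
        membrane = ellipse(mid + mem_px / 2, mid + mem_px / 2) & ~ellipse(
            max(mid - mem_px / 2, 0.5), max(mid - mem_px / 2, 0.5)
        )
    channels["endothelial"][membrane] = 1.0

    if has_pericytes:
        peri = ellipse(a_in + wall_px + peri_px, b_in + wall_px + peri_px) & ~ellipse(
            a_in + wall_px, b_in + wall_px
        )
        channels["perivascular"][peri] = 1.0

    # a ring of endothelial nuclei, rendered as small blobs on the wall
    n_nuclei = max(2, int(round((a_in + b_in) * math.pi / 8)) or 2)
    r_nuc = 0.5 * (a_in + b_in) + 0.5 * wall_px if ic_um > 0 else 0.0
    for k in range(n_nuclei):
        th = 2 * math.pi * k / n_nuclei
        ny, nx = r_nuc * math.sin(th), r_nuc * math.cos(th)
        channels["nuclei"][((u - nx) ** 2 + (v - ny) ** 2) <= (1.0 / um_per_px) ** 2] = 1.0

    return {
        "channels": channels,
        "lumen": lumen,
        "wall": wall | membrane,
        "radius_px": outer,
        "patch_px": patch_px,
    }


# ---------------------------------------------------------------------------
# inner-caliber sampling


def sample_ic(cls: str, cfg: FixtureConfig, rng: np.random.Generator) -> float:
    """Draw one inner caliber (um) for a class, honouring truncation and the
    zero-lumen fraction."""
    p = cfg.ic_lognormal_params[cls]
    if p.zero_lumen_fraction and rng.random() < p.zero_lumen_fraction:
        return 0.0
    while True:
        x = rng.lognormal(p.mu, p.sigma)
        if p.truncate_um is None or x < p.truncate_um:
            return float(x)


# ---------------------------------------------------------------------------
# bone trabecula


def make_bone_mask(
    shape: Tuple[int, int], bone_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Smoothed random region entering from the top edge, covering
    approximately ``bone_fraction`` of the field."""
    h, w = shape
    if bone_fraction <= 0:
        return np.zeros(shape, dtype=bool)
    profile = rng.normal(size=w)
    profile = ndimage.gaussian_filter1d(profile, sigma=w / 8, mode="wrap")
    profile -= profile.mean()
    if profile.std() > 0:
        profile /= profile.std()
    base = bone_fraction * h
    depth = np.clip(base + 0.25 * base * profile, 1, h - 1)
    rows = np.arange(h)[:, None]
    return rows < depth[None, :]


# ---------------------------------------------------------------------------
# imHC placement


def place_imhcs(
    cfg: FixtureConfig,
    vessel_table: pd.DataFrame,
    bone_mask: np.ndarray,
    rng: np.random.Generator,
    lumen_labels: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Place imHC centroids either uniformly over the marrow or condensed in
    an exponential shell around the configured target.

    Returns a table (row, col, clustered flag, nearest-target distance um).
    Points never fall inside the bone mask or a vessel lumen.
    """
    pl = cfg.imhc_placement
    h, w = bone_mask.shape
    umpp = cfg.um_per_px
    n = pl.n_points

    forbidden = bone_mask.copy()
    if lumen_labels is not None:
        forbidden |= lumen_labels > 0

    if pl.shell_center == "bone":
        targets = None
        if pl.mode == "shell" and pl.clustered_fraction > 0 and not bone_mask.any():
            raise ValueError("shell placement around bone requires a bone mask")
    else:
        sel = vessel_table[vessel_table["class"] == pl.shell_center]
        targets = sel[["row", "col"]].to_numpy(dtype=float)
        if (
            pl.mode == "shell"
            and pl.clustered_fraction > 0
            and len(targets) == 0
        ):
            raise ValueError(
                f"shell placement requires at least one {pl.shell_center} vessel"
            )

    if bone_mask.any():
        bone_edt = ndimage.distance_transform_edt(~bone_mask)
    else:
        bone_edt = None

    n_clustered = int(round(pl.clustered_fraction * n)) if pl.mode == "shell" else 0
    pts: List[Tuple[float, float, bool]] = []

    def ok(r: float, c: float) -> bool:
        ri, ci = int(round(r)), int(round(c))
        return 0 <= ri < h and 0 <= ci < w and not forbidden[ri, ci]

    while len(pts) < n_clustered:
        d_um = rng.exponential(pl.shell_decay_um)
        th = rng.uniform(0, 2 * math.pi)
        if pl.shell_center == "bone":
            # pick a marrow pixel at that distance from the bone surface
            band = np.abs(bone_edt * umpp - d_um) < max(umpp, 0.5)
            band &= ~forbidden
            idx = np.flatnonzero(band)
            if idx.size == 0:
                continue
            k = idx[rng.integers(idx.size)]
            r, c = divmod(k, w)
        else:
            tr, tc = targets[rng.integers(len(targets))]
            r = tr + (d_um / umpp) * math.sin(th)
            c = tc + (d_um / umpp) * math.cos(th)
        if ok(r, c):
            pts.append((float(r), float(c), True))

    while len(pts) < n:
        r = rng.uniform(0, h - 1)
        c = rng.uniform(0, w - 1)
        if ok(r, c):
            pts.append((r, c, False))

    df = pd.DataFrame(pts, columns=["row", "col", "clustered"])
    if targets is not None and len(targets):
        diff = df[["row", "col"]].to_numpy()[:, None, :] - targets[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2)).min(axis=1) * umpp
        df["nearest_target_um"] = d
    elif bone_edt is not None:
        rr = df["row"].round().astype(int).clip(0, h - 1)
        cc = df["col"].round().astype(int).clip(0, w - 1)
        df["nearest_target_um"] = bone_edt[rr, cc] * umpp
    else:
        df["nearest_target_um"] = np.nan
    return df


# ---------------------------------------------------------------------------
# dataset assembly


def _noise(img: np.ndarray, cfg: FixtureConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.noise
    lam = np.clip(img + n.background_level, 0, None) * n.poisson_scale
    out = rng.poisson(lam).astype(float) / n.poisson_scale
    if n.gaussian_sd > 0:
        out = out + rng.normal(0.0, n.gaussian_sd, img.shape)
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


def generate_dataset(
    cfg: FixtureConfig, n_images: Optional[int] = None
) -> Tuple[List[MicrographSet], GroundTruth]:
    """Generate a full synthetic dataset.

    Vessels are apportioned over class-homogeneous fields
    (``cfg.vessels_per_image`` per field, mirroring micrographs centered on
    one structure type); each field includes a bone trabecula with the
    class-specific probability in ``cfg.bone_presence`` and gets its own
    imHC pattern.  Ground truth records every vessel's class, caliber,
    flags, centroid, its normalized distance to bone, and every imHC point
    with its nearest-vessel distance.
    """
    counts = {c: int(n) for c, n in cfg.n_vessels_per_class.items()}
    per_img = cfg.vessels_per_image
    batches: List[List[str]] = []
    for c, n in counts.items():
        for start in range(0, n, per_img):
            batches.append([c] * min(per_img, n - start))
    if n_images is not None:
        batches = batches[:n_images]
    n_images = len(batches)

    root = np.random.SeedSequence(cfg.seed)
    img_seeds = root.spawn(max(n_images, 1))

    h, w = cfg.image_size_px
    umpp = cfg.um_per_px
    sets: List[MicrographSet] = []
    vessel_rows = []
    imhc_frames = []
    dist_rows = []
    vid = 0

    for i in range(n_images):
        rng = np.random.default_rng(img_seeds[i])
        chans = {ch: np.zeros((h, w), dtype=float) for ch in CHANNELS}
        lumen_labels = np.zeros((h, w), dtype=np.uint16)
        wall_labels = np.zeros((h, w), dtype=np.uint16)
        batch = batches[i]
        bone_prob = cfg.bone_presence.get(batch[0], 1.0)
        has_bone = rng.random() < bone_prob and cfg.bone_fraction > 0
        bone = (
            make_bone_mask((h, w), cfg.bone_fraction, rng)
            if has_bone
            else np.zeros((h, w), dtype=bool)
        )
        bone_edt = (
            ndimage.distance_transform_edt(~bone) if bone.any() else None
        )
        # random non-overlapping placement below the bone region
        top = int(bone.sum(axis=1).astype(bool).sum() * 1.1) + 8
        placed_boxes: List[Tuple[int, int, int]] = []
        img_vessels = []
        for j, cls in enumerate(batch):
            ic = sample_ic(cls, cfg, rng)
            p = cfg.ic_lognormal_params[cls]
            compression = p.compression if p.compression else 1.0
            has_peri = bool(cfg.has_pericytes.get(cls, False))
            tubular = cls in TUBULAR_CLASSES
            angle = rng.uniform(0, math.pi) if compression < 1 else 0.0
            patch = render_vessel(
                cls,
                ic,
                has_peri,
                cfg.marker_offset_px,
                umpp,
                wall_um=cfg.wall_thickness_um,
                membrane_um=cfg.membrane_um,
                pericyte_um=cfg.pericyte_ring_um,
                compression=compression,
                angle_rad=angle,
            )
            pp = patch["patch_px"]
            r_lo, r_hi = min(top, h - pp), h - pp
            # keep structures clear of each other and of each other's
            # translation-lattice images, so a translated negative control
            # lands on empty marrow (the sparse-field regime the control
            # analysis presumes)
            shifts = ((0, 0), cfg.control_offset_px, tuple(-o for o in cfg.control_offset_px))
            for _try in range(300):
                r0 = int(rng.integers(r_lo, r_hi + 1))
                c0 = int(rng.integers(0, w - pp + 1))
                ok_pos = True
                for pr, pc, ps in placed_boxes:
                    lim = (pp + ps) // 2 + 4
                    for dr, dc in shifts:
                        if abs(r0 - (pr + dr)) < lim and abs(c0 - (pc + dc)) < lim:
                            ok_pos = False
                            break
                    if not ok_pos:
                        break
                if ok_pos:
                    break
            placed_boxes.append((r0, c0, pp))
            sl = (slice(r0, r0 + pp), slice(c0, c0 + pp))
            vid += 1
            for ch in CHANNELS:
                np.maximum(chans[ch][sl], patch["channels"][ch], out=chans[ch][sl])
            lumen_labels[sl][patch["lumen"]] = vid
            wall_labels[sl][patch["wall"]] = vid
            cr, cc = r0 + pp // 2, c0 + pp // 2
            row = {
                "id": vid,
                "image": i,
                "class": cls,
                "true_ic_um": ic,
                "has_pericytes": has_peri,
                "tubular": tubular,
                "compressed": compression < 1,
                "row": cr,
                "col": cc,
                "bone_in_fov": bool(bone.any()),
            }
            vessel_rows.append(row)
            img_vessels.append(row)
            if bone_edt is not None:
                d_raw = float(bone_edt[cr, cc]) * umpp
                dist_rows.append(
                    {
                        "structure_id": vid,
                        "class": cls,
                        "target_kind": "bone",
                        "d_raw_um": d_raw,
                        "ic_um": ic,
                        "d_norm_um": max(0.0, d_raw - ic / 2),
                    }
                )
            else:
                dist_rows.append(
                    {
                        "structure_id": vid,
                        "class": cls,
                        "target_kind": "bone",
                        "d_raw_um": np.nan,
                        "ic_um": ic,
                        "d_norm_um": np.nan,
                    }
                )

        vt_img = pd.DataFrame(img_vessels)
        img_cfg = cfg
        pl = cfg.imhc_placement
        if (
            pl.mode == "shell"
            and pl.shell_center != "bone"
            and not (vt_img["class"] == pl.shell_center).any()
        ):
            # no eligible target in this field: points fall back to uniform
            img_cfg = cfg.model_copy(
                update={
                    "imhc_placement": pl.model_copy(
                        update={"mode": "uniform", "clustered_fraction": 0.0}
                    )
                }
            )
        imhc = place_imhcs(img_cfg, vt_img, bone, rng, lumen_labels)
        imhc["image"] = i
        # nuclei channel also carries the imHC nuclei
        for r, c in imhc[["row", "col"]].to_numpy():
            ri, ci = int(round(r)), int(round(c))
            rad = int(round(2.0 / umpp))
            r1, r2 = max(ri - rad, 0), min(ri + rad + 1, h)
            c1, c2 = max(ci - rad, 0), min(ci + rad + 1, w)
            win_r, win_c = np.ogrid[r1:r2, c1:c2]
            disk = (win_r - r) ** 2 + (win_c - c) ** 2 <= (1.5 / umpp) ** 2
            chans["nuclei"][r1:r2, c1:c2][disk] = 1.0
            ring = ((win_r - r) ** 2 + (win_c - c) ** 2 <= (2.0 / umpp) ** 2) & ~disk
            chans["endothelial"][r1:r2, c1:c2][ring] = np.maximum(
                chans["endothelial"][r1:r2, c1:c2][ring], 0.8
            )
        imhc_frames.append(imhc)

        # dim single-channel cell populations: NESTIN-dim stromal cells in
        # the cytoskeletal channel, weakly CD34/CD31-positive cells in the
        # membrane channel.  They are independent between channels, so the
        # population below the vessel-signal intensity is anti-correlated -
        # the feature the threshold search keys on in real marrow fields.
        # The NESTIN-dim population is denser: stromal NESTIN is widespread,
        # which is also what keeps the converse Manders coefficient low.
        if cfg.autofluorescence_level > 0:
            for ch, density, level in (
                ("nestin", 0.004, 2.5 * cfg.autofluorescence_level),
                ("endothelial", 0.0015, 0.15 * cfg.autofluorescence_level),
            ):
                impulses = (rng.random((h, w)) < density).astype(float)
                f = ndimage.gaussian_filter(impulses, sigma=1.5 / umpp)
                if f.max() > 0:
                    f = f / f.max()
                chans[ch] = np.maximum(chans[ch], level * f)

        # optical point-spread blur: renders the sharp geometric rings as
        # smooth confocal intensity profiles
        if cfg.psf_sigma_um > 0:
            for ch in CHANNELS:
                chans[ch] = ndimage.gaussian_filter(
                    chans[ch], sigma=cfg.psf_sigma_um / umpp
                )

        # bone autofluorescence: faint in every channel
        for ch in CHANNELS:
            chans[ch][bone] = np.maximum(chans[ch][bone], 0.08)

        mixed = {}
        k = cfg.crosstalk
        sig = cfg.signal_level
        mixed["nestin"] = (1 - k) * chans["nestin"] + k * chans["endothelial"]
        mixed["endothelial"] = (1 - k) * chans["endothelial"] + k * chans["nestin"]
        mixed["perivascular"] = chans["perivascular"]
        mixed["nuclei"] = chans["nuclei"]
        noisy = {ch: _noise(sig * mixed[ch], cfg, rng) for ch in CHANNELS}

        sets.append(
            MicrographSet(
                name=f"set{i:03d}",
                channels=noisy,
                lumen_labels=lumen_labels,
                wall_labels=wall_labels,
                bone_mask=bone,
                um_per_px=umpp,
            )
        )

    vessel_table = pd.DataFrame(vessel_rows)
    imhc_points = (
        pd.concat(imhc_frames, ignore_index=True) if imhc_frames else pd.DataFrame()
    )
    truth = GroundTruth(
        vessel_table=vessel_table,
        bone_mask=sets[0].bone_mask if sets else np.zeros((0, 0), bool),
        imhc_points=imhc_points,
        distance_table=pd.DataFrame(dist_rows),
    )
    return sets, truth


# ---------------------------------------------------------------------------
# distance-series simulation (table-level study conditions)


def simulate_distance_series(
    mode: str,
    n: int,
    rng: np.random.Generator,
    *,
    shell_decay_um: float = 8.0,
    clustered_fraction: float = 0.6,
    uniform_max_um: float = 125.0,
    normal_mean_um: float = 60.0,
    normal_sd_um: float = 20.0,
) -> np.ndarray:
    """Draw a raw distance series (um) under a named placement law.

    ``clustered``: mixture of Exponential(shell_decay_um) with weight
    ``clustered_fraction`` and Uniform(0, uniform_max_um); ``uniform``:
    Uniform(0, uniform_max_um); ``normal``: Normal truncated at 0.
    ``uniform_max_um`` defaults to the radius of a 1,000x field (125 um).
    """
    if mode == "clustered":
        k = rng.random(n) < clustered_fraction
        out = np.where(
            k,
            rng.exponential(shell_decay_um, n),
            rng.uniform(0, uniform_max_um, n),
        )
    elif mode == "uniform":
        out = rng.uniform(0, uniform_max_um, n)
    elif mode == "normal":
        out = np.abs(rng.normal(normal_mean_um, normal_sd_um, n))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out

def nclt_coloc_config(seed: int, n_vessels: int = 16) -> FixtureConfig:
    """Study condition for the capillary co-occurrence analysis: a field of
    NCLT-like offset-ring vessels only (no bone, no imHC points), the regime
    in which the cytoskeletal/membrane co-occurrence signature is measured."""
    return FixtureConfig(
        seed=seed,
        n_vessels_per_class={"NCLT": n_vessels},
        vessels_per_image=n_vessels,
        image_size_px=(512, 512),
        bone_fraction=0.0,
        imhc_placement={"mode": "uniform", "n_points": 0},
    )
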