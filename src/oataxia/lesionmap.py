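"""Voxelwise lesion cartography on a shared reference grid.

All volumes (binary lesion masks and the integer-labelled nucleus
atlas) are assumed to be pre-registered to a common grid; registration
itself is out of scope.  The first voxel axis is taken to run
left-to-right (RAS-like orientation), so hemisphere operations --
mirroring a lesion across the midsagittal plane, splitting left/right
volumes -- act on axis 0.  Mirroring reverses the axis about the grid
centre: an odd-sized axis reflects about its centre slice, an even one
about the inter-voxel midplane.

Group-level products are the classical descriptive lesion maps: the
voxelwise overlap (how many / what percentage of patients carry a
lesion in a voxel) and the percentage subtraction map between two
patient groups, in which positive values mark voxels lesioned more
often in the first group.  For display the subtraction map is usually
thresholded (differences of 20 percentage points or less hidden); the
unthresholded map is always retained.
"""
from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

TERRITORY_ORDER = ("medial", "lateral", "posterior")
DEFAULT_REFERENCE = "right"
DEFAULT_DISPLAY_THRESHOLD = 20.0
DEFAULT_BILATERAL_MIN_VOXELS = 10
DEFAULT_AFFECTED_MIN_VOXELS = 1

#: voxel axis running left -> right
LR_AXIS = 0


class GridMismatchError(ValueError):
    """Volumes entering a joint operation do not share a grid."""


@dataclass
class VolumeGrid:
    """A 3D voxel array with its grid metadata.

    ``voxels`` holds either a binary mask (values {0, 1}) or integer
    atlas labels.  ``voxel_size`` is the edge length per axis in mm.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.voxels), (0, 1)).all())

    def like(self, voxels: np.ndarray) -> "VolumeGrid":
        """A new grid with the same metadata and different voxel data."""
        return VolumeGrid(voxels, self.voxel_size, self.orientation, self.affine)


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI volume into a :class:`VolumeGrid`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if np.allclose(data, np.round(data)):
        data = np.round(data).astype(np.int32)
    return VolumeGrid(
        voxels=data,
        voxel_size=tuple(float(z) for z in img.header.get_zooms()[:3]),
        affine=np.asarray(img.affine),
    )


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` as NIfTI."""
    affine = grid.affine
    if affine is None:
        affine = np.diag(list(grid.voxel_size) + [1.0])
    data = grid.voxels
    dtype = np.int16 if np.issubdtype(data.dtype, np.integer) else np.float32
    img = nib.Nifti1Image(data.astype(dtype), affine)
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))


def check_same_grid(grids: Sequence[VolumeGrid]) -> None:
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if g.shape != ref.shape or not np.allclose(g.voxel_size, ref.voxel_size):
            raise GridMismatchError(
                f"volume {i} (shape {g.shape}, voxel {g.voxel_size}) does not "
                f"match the reference grid (shape {ref.shape}, voxel {ref.voxel_size})"
            )
        if g.orientation != ref.orientation:
            raise GridMismatchError("volumes differ in axis orientation")


def _require_binary(grid: VolumeGrid, what: str = "mask") -> None:
    if not grid.is_binary:
        raise ValueError(f"{what} must be binary (values 0/1); found other values")


def mirror(grid: VolumeGrid, axis: int = LR_AXIS) -> VolumeGrid:
    """Reflect a volume across the midplane of the given axis."""
    return grid.like(np.flip(grid.voxels, axis=axis).copy())


def flip_to_reference_hemisphere(
    mask: VolumeGrid, lesion_side: str, reference: str = DEFAULT_REFERENCE
) -> VolumeGrid:
    """Mirror a lesion onto the reference hemisphere if needed.

    Lesions whose predominant side already equals ``reference`` are
    returned unchanged (as a copy); the others are reflected across the
    midsagittal plane.  Voxel counts are preserved exactly.
    """
    for name, v in (("lesion_side", lesion_side), ("reference", reference)):
        if v not in ("left", "right"):
            raise ValueError(f"{name} must be 'left' or 'right', got {v!r}")
    if lesion_side == reference:
        return mask.like(mask.voxels.copy())
    return mirror(mask)


def lesion_volume(mask: VolumeGrid) -> float:
    """Total lesion volume in mm^3 (voxel count x voxel volume)."""
    _require_binary(mask)
    return float(mask.voxels.sum()) * mask.voxel_volume_mm3


def hemisphere_voxel_counts(mask: VolumeGrid, axis: int = LR_AXIS) -> tuple[int, int]:
    """Lesion voxels in the (left, right) hemisphere.

    The grid is split at the axis midpoint; for an odd-sized axis the
    centre slice belongs to neither hemisphere.
    """
    _require_binary(mask)
    n = mask.shape[axis]
    left = np.take(mask.voxels, range(0, n // 2), axis=axis)
    right = np.take(mask.voxels, range((n + 1) // 2, n), axis=axis)
    return int(left.sum()), int(right.sum())


def laterality(
    mask: VolumeGrid, bilateral_min_voxels: int = DEFAULT_BILATERAL_MIN_VOXELS
) -> tuple[str, bool]:
    """Predominant lesion side and bilaterality flag.

    The predominant side carries the larger lesion volume; the lesion
    counts as bilateral when both hemispheres hold at least
    ``bilateral_min_voxels`` lesioned voxels.  An exact 50/50 split has
    no defined predominant side and raises.
    """
    nl, nr = hemisphere_voxel_counts(mask)
    if nl + nr == 0:
        raise ValueError("empty lesion mask: no predominant side")
    if nl == nr:
        raise ValueError(
            "lesion volume split exactly 50/50 between hemispheres; "
            "assign the predominant side manually"
        )
    side = "left" if nl > nr else "right"
    bilateral = min(nl, nr) >= bilateral_min_voxels
    return side, bilateral


@dataclass
class AtlasDefinition:
    """A labelled nucleus atlas with a nucleus -> territory lookup."""

    volume: VolumeGrid
    labels: dict[int, str]  # label value -> nucleus name; 0 = background
    territories: dict[str, str]  # nucleus name -> territory

    def __post_init__(self) -> None:
        if 0 in self.labels:
            raise ValueError("label 0 is reserved for background")
        unknown = set(self.territories) - set(self.labels.values())
        if unknown:
            raise ValueError(f"territory table names unknown nuclei: {sorted(unknown)}")

    def label_inventory(self) -> pd.Series:
        """Voxel count per label present in the atlas volume."""
        values, counts = np.unique(self.volume.voxels, return_counts=True)
        return pd.Series(counts, index=values, name="n_voxels").drop(0, errors="ignore")


def load_territories(path=None) -> dict[str, str]:
    """Nucleus -> territory map from a YAML territory table.

    Without a path the table shipped with the package is used.  The
    YAML maps each territory to the list of its member nuclei.
    """
    if path is None:
        text = (
            importlib.resources.files("oataxia").joinpath("data/territories.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    table = yaml.safe_load(text)
    out: dict[str, str] = {}
    for territory, nuclei in table.items():
        for nucleus in nuclei:
            if nucleus in out:
                raise ValueError(f"nucleus {nucleus!r} listed in more than one territory")
            out[nucleus] = territory
    return out


def load_atlas(volume_path, labels_path) -> AtlasDefinition:
    """Load an atlas from a NIfTI label volume plus a YAML sidecar.

    The sidecar holds ``labels`` (int -> nucleus name) and optionally
    ``territories`` (territory -> [nuclei]); territories default to the
    packaged table.
    """
    meta = yaml.safe_load(Path(labels_path).read_text())
    labels = {int(k): str(v) for k, v in meta["labels"].items()}
    if "territories" in meta:
        territories: dict[str, str] = {}
        for terr, nuclei in meta["territories"].items():
            for nucleus in nuclei:
                territories[nucleus] = terr
    else:
        territories = load_territories()
    territories = {n: t for n, t in territories.items() if n in labels.values()}
    return AtlasDefinition(read_volume(volume_path), labels, territories)


def save_atlas(atlas: AtlasDefinition, volume_path, labels_path) -> None:
    write_volume(atlas.volume, volume_path)
    by_territory: dict[str, list[str]] = {}
    for nucleus, terr in atlas.territories.items():
        by_territory.setdefault(terr, []).append(nucleus)
    Path(labels_path).write_text(
        yaml.safe_dump(
            {"labels": {int(k): v for k, v in atlas.labels.items()},
             "territories": by_territory},
            sort_keys=False,
        )
    )


def nucleus_damage_profile(
    mask: VolumeGrid,
    atlas: AtlasDefinition,
    affected_min_voxels: int = DEFAULT_AFFECTED_MIN_VOXELS,
) -> pd.DataFrame:
    """Per-nucleus lesion overlap, percentage damage and affected flag.

    The atlas labels both hemispheres with the same nucleus label, so
    the profile is frame-independent.  A nucleus counts as affected when
    the lesion overlaps it by at least ``affected_min_voxels`` voxels
    (default 1: any involvement).  Empty atlas nuclei yield NaN
    percentages and a warning.
    """
    _require_binary(mask)
    check_same_grid([mask, atlas.volume])
    labels = atlas.volume.voxels.astype(np.int64)
    n_labels = int(labels.max()) + 1
    totals = np.bincount(labels.ravel(), minlength=n_labels)
    damaged = np.bincount(
        labels.ravel(), weights=mask.voxels.ravel().astype(float), minlength=n_labels
    ).astype(np.int64)
    rows = []
    for value, name in sorted(atlas.labels.items()):
        tot = int(totals[value]) if value < n_labels else 0
        dam = int(damaged[value]) if value < n_labels else 0
        if tot == 0:
            log.warning("atlas nucleus %s (label %d) is empty; percentage undefined", name, value)
            pct = np.nan
        else:
            pct = 100.0 * dam / tot
        rows.append(
            {
                "nucleus": name,
                "label": value,
                "territory": atlas.territories.get(name, "other"),
                "nucleus_voxels": tot,
                "damaged_voxels": dam,
                "pct_nucleus_damaged": pct,
                "affected": dam >= affected_min_voxels,
            }
        )
    return pd.DataFrame(rows).set_index("nucleus")


def territory_classification(profile: pd.DataFrame) -> str:
    """Territory holding the largest share of the lesioned atlas voxels.

    Only the canonical territories (medial, lateral, posterior) compete;
    a lesion with no nucleus overlap is classified "other".  Ties are
    resolved deterministically in the order medial < lateral < posterior
    with a logged warning.
    """
    damage = {
        t: int(profile.loc[profile["territory"] == t, "damaged_voxels"].sum())
        for t in TERRITORY_ORDER
    }
    if sum(damage.values()) == 0:
        log.warning("lesion overlaps no atlas nucleus; territory 'other'")
        return "other"
    best = max(damage.values())
    winners = [t for t in TERRITORY_ORDER if damage[t] == best]
    if len(winners) > 1:
        log.warning("territory tie %s; resolved to %r by fixed order", winners, winners[0])
    return winners[0]


@dataclass
class LesionStats:
    """Per-patient lesion summary."""

    subject_id: str
    volume_mm3: float
    predominant_side: str
    bilateral: bool
    territory: str
    profile: pd.DataFrame = field(repr=False)


def lesion_stats(
    subject_id: str,
    mask: VolumeGrid,
    atlas: AtlasDefinition,
    affected_min_voxels: int = DEFAULT_AFFECTED_MIN_VOXELS,
    bilateral_min_voxels: int = DEFAULT_BILATERAL_MIN_VOXELS,
) -> LesionStats:
    """Volume, laterality, nucleus profile and territory of one lesion."""
    profile = nucleus_damage_profile(mask, atlas, affected_min_voxels)
    side, bilateral = laterality(mask, bilateral_min_voxels)
    return LesionStats(
        subject_id=subject_id,
        volume_mm3=lesion_volume(mask),
        predominant_side=side,
        bilateral=bilateral,
        territory=territory_classification(profile),
        profile=profile,
    )


def overlap_map(masks: Sequence[VolumeGrid]) -> tuple[VolumeGrid, VolumeGrid]:
    """Voxelwise lesion count and percentage maps over a patient group."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    check_same_grid(list(masks))
    for m in masks:
        _require_binary(m)
    count = np.zeros(masks[0].shape, dtype=np.int16)
    for m in masks:
        count += m.voxels.astype(np.int16)
    pct = 100.0 * count.astype(np.float64) / len(masks)
    return masks[0].like(count), masks[0].like(pct)


@dataclass
class GroupMaps:
    """Overlap maps of two groups and their percentage subtraction map."""

    count_a: VolumeGrid
    pct_a: VolumeGrid
    count_b: VolumeGrid
    pct_b: VolumeGrid
    diff: VolumeGrid  # pct_a - pct_b, range [-100, 100]
    diff_display: VolumeGrid  # |diff| <= threshold zeroed, for display
    display_threshold: float
    n_a: int
    n_b: int


def subtraction_map(
    masks_a: Sequence[VolumeGrid],
    masks_b: Sequence[VolumeGrid],
    display_threshold: float = DEFAULT_DISPLAY_THRESHOLD,
) -> GroupMaps:
    """Percentage lesion-subtraction map between two patient groups.

    ``diff = pct(A) - pct(B)`` per voxel; positive values mark voxels
    lesioned more frequently in group A.  The display copy zeroes
    differences not exceeding the threshold (strictly; exactly 20%
    stays hidden at the default); the raw map is retained.
    """
    if len(masks_a) == 0 or len(masks_b) == 0:
        raise ValueError("both groups must be nonempty")
    check_same_grid(list(masks_a) + list(masks_b))
    count_a, pct_a = overlap_map(masks_a)
    count_b, pct_b = overlap_map(masks_b)
    diff = pct_a.voxels - pct_b.voxels
    display = np.where(np.abs(diff) > display_threshold, diff, 0.0)
    ref = masks_a[0]
    return GroupMaps(
        count_a=count_a,
        pct_a=pct_a,
        count_b=count_b,
        pct_b=pct_b,
        diff=ref.like(diff),
        diff_display=ref.like(display),
        display_threshold=float(display_threshold),
        n_a=len(masks_a),
        n_b=len(masks_b),
    )


def cohort_nucleus_frequency(
    profiles: Iterable[pd.DataFrame],
) -> pd.DataFrame:
    """Per-nucleus affected counts and cohort percentages.

    ``profiles`` are per-patient outputs of
    :func:`nucleus_damage_profile` computed against a common atlas.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one damage profile")
    index = profiles[0].index
    n = len(profiles)
    affected = sum(p["affected"].reindex(index).astype(int) for p in profiles)
    return pd.DataFrame(
        {
            "n_affected": affected.astype(int),
            "n_cohort": n,
            "pct_affected": 100.0 * affected / n,
        },
        index=index,
    )
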