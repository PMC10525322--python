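"""Tumor-occurrence statistics over a brain parcellation.

Given binary tumor label volumes co-registered to a common space and a
parcellation atlas, this module accumulates per-voxel occurrence counts,
computes the parcellation-averaged sampling probability

    P_Ri = sum_j f_ij / (V_Ri * sum_i sum_j f_ij)

(where f_ij is the occurrence count of voxel j in region i and V_Ri the
region volume), and broadcasts P_Ri over each region to form the voxelwise
sampling weight map used by the prior-informed masking strategy.

With voxel_volume = 1 the probabilities satisfy the conservation law
sum_i P_Ri * V_Ri = 1.  Background voxels (atlas label 0) are excluded from
both the numerator and the grand total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParcellationAtlas",
    "OccurrenceCounts",
    "RegionProbabilityTable",
    "SamplingWeightMap",
    "accumulate_occurrence",
    "region_probability",
    "build_weight_map",
    "read_table",
    "write_table",
    "load_reference_table",
    "TUMOR_CLASSES",
]

TUMOR_CLASSES = ("et", "tc", "wt")


@dataclass(frozen=True)
class ParcellationAtlas:
    """Integer 3D label volume defining parcellation regions (0 = background)."""

    labels: np.ndarray
    voxel_volume: float = 1.0
    region_ids: tuple[int, ...] = field(init=False)
    voxel_counts: dict[int, int] = field(init=False)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"atlas must be 3D, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "region_ids", tuple(int(i) for i in ids))
        object.__setattr__(
            self, "voxel_counts", {int(i): int(c) for i, c in zip(ids, counts)}
        )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def region_volume(self, region_id: int) -> float:
        return self.voxel_counts[region_id] * self.voxel_volume


@dataclass(frozen=True)
class OccurrenceCounts:
    """Voxelwise occurrence counts f_ij accumulated over n_cases label maps."""

    counts: np.ndarray
    n_cases: int

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if counts.min() < 0 or counts.max() > self.n_cases:
            raise ValueError("counts must lie in [0, n_cases]")
        object.__setattr__(self, "counts", counts)


@dataclass
class RegionProbabilityTable:
    """Per-region, per-class occurrence probabilities (Table-style container).

    ``frame`` is indexed by region_id with one column per tumor class
    ("et", "tc", "wt" — any subset).  ``units`` records the scale the values
    are written in ("fraction" or "permille"); downstream weighted sampling
    re-normalizes, so the scale never changes masking results.
    """

    frame: pd.DataFrame
    units: str = "fraction"

    def __post_init__(self):
        if self.frame.empty:
            raise ValueError("region probability table is empty")
        if self.frame.index.has_duplicates:
            dups = sorted(self.frame.index[self.frame.index.duplicated()])
            raise ValueError(f"duplicate region ids: {dups}")
        if (self.frame.values < 0).any():
            raise ValueError("probabilities must be nonnegative")
        self.frame = self.frame.sort_index()

    @property
    def region_ids(self) -> tuple[int, ...]:
        return tuple(int(i) for i in self.frame.index)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def probability(self, region_id: int, tumor_class: str = "et") -> float:
        return float(self.frame.loc[region_id, tumor_class])


@dataclass(frozen=True)
class SamplingWeightMap:
    """Voxelwise sampling weights: P_Ri broadcast over region voxels, 0 outside."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 3:
            raise ValueError("weight map must be 3D")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "weights", w)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.weights.shape


def accumulate_occurrence(label_volumes: Sequence[np.ndarray]) -> OccurrenceCounts:
    """Sum binary tumor label maps voxelwise into occurrence counts."""
    volumes = list(label_volumes)
    if not volumes:
        raise ValueError("no label volumes given")
    shape = np.asarray(volumes[0]).shape
    counts = np.zeros(shape, dtype=np.int64)
    for i, vol in enumerate(volumes):
        arr = np.asarray(vol)
        if arr.shape != shape:
            raise ValueError(
                f"label volume {i} has shape {arr.shape}, expected {shape}"
            )
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"label volume {i} is not binary (values {uniq})")
        counts += arr.astype(np.int64)
    return OccurrenceCounts(counts=counts, n_cases=len(volumes))


def region_probability(
    counts: OccurrenceCounts,
    atlas: ParcellationAtlas,
    tumor_class: str = "et",
) -> RegionProbabilityTable:
    """Parcellation-averaged sampling probability per region.

    P_Ri = (region-summed counts) / (V_Ri * grand total over all regions),
    with background voxels excluded from the grand total.  With unit voxel
    volume this conserves sum_i P_Ri * V_Ri = 1.
    """
    if counts.counts.shape != atlas.shape:
        raise ValueError(
            f"counts shape {counts.counts.shape} != atlas shape {atlas.shape}"
        )
    labels = atlas.labels
    fg = labels > 0
    grand_total = float(counts.counts[fg].sum())
    if grand_total == 0:
        raise ValueError("no tumor occurrence observed in any parcellation region")
    max_label = int(labels.max())
    sums = np.bincount(
        labels[fg].ravel(), weights=counts.counts[fg].ravel(), minlength=max_label + 1
    )
    probs = {
        rid: sums[rid] / (atlas.region_volume(rid) * grand_total)
        for rid in atlas.region_ids
    }
    frame = pd.DataFrame({tumor_class: pd.Series(probs)})
    frame.index.name = "region_id"
    return RegionProbabilityTable(frame=frame, units="fraction")


def build_weight_map(
    table: RegionProbabilityTable,
    atlas: ParcellationAtlas,
    tumor_class: str = "et",
) -> SamplingWeightMap:
    """Broadcast each region's probability over its voxels; background gets 0."""
    if tumor_class not in table.classes:
        raise KeyError(
            f"class {tumor_class!r} not in table (has {list(table.classes)})"
        )
    missing = sorted(set(atlas.region_ids) - set(table.region_ids))
    if missing:
        raise KeyError(f"regions missing from table: {missing}")
    max_label = int(atlas.labels.max())
    lut = np.zeros(max_label + 1, dtype=np.float64)
    for rid in atlas.region_ids:
        lut[rid] = table.probability(rid, tumor_class)
    return SamplingWeightMap(weights=lut[atlas.labels])


# ---------------------------------------------------------------------------
# TSV dialect: optional "# units: <fraction|permille>" comment, then a header
# line "region_id<TAB>et<TAB>tc<TAB>wt" (class columns may be a subset).
# ---------------------------------------------------------------------------

def write_table(table: RegionProbabilityTable, path) -> None:
    path = Path(path)
    with path.open("w") as f:
        f.write(f"# units: {table.units}\n")
        f.write("region_id\t" + "\t".join(table.classes) + "\n")
        for rid in table.region_ids:
            vals = "\t".join(repr(float(table.frame.loc[rid, c]))
                             for c in table.classes)
            f.write(f"{rid}\t{vals}\n")


def _parse_table_lines(lines, source: str) -> RegionProbabilityTable:
    units = "fraction"
    header = None
    rows: dict[int, list[float]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("units:"):
                units = body.split(":", 1)[1].strip()
            continue
        cells = line.split("\t")
        if header is None:
            if cells[0] != "region_id":
                raise ValueError(
                    f"{source}:{lineno}: expected header starting with 'region_id'"
                )
            header = cells[1:]
            if not header:
                raise ValueError(f"{source}:{lineno}: no class columns in header")
            continue
        if len(cells) != len(header) + 1:
            raise ValueError(
                f"{source}:{lineno}: expected {len(header) + 1} columns, "
                f"got {len(cells)}"
            )
        try:
            rid = int(cells[0])
            vals = [float(c) for c in cells[1:]]
        except ValueError as exc:
            raise ValueError(f"{source}:{lineno}: non-numeric cell ({exc})") from None
        if rid in rows:
            raise ValueError(f"{source}:{lineno}: duplicate region id {rid}")
        rows[rid] = vals
    if header is None or not rows:
        raise ValueError(f"{source}: table has no data rows")
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=header)
    frame.index.name = "region_id"
    return RegionProbabilityTable(frame=frame, units=units)


def read_table(path) -> RegionProbabilityTable:
    path = Path(path)
    with path.open() as f:
        return _parse_table_lines(f, str(path))


def load_reference_table() -> RegionProbabilityTable:
    """Bundled 128-region ET/TC/WT occurrence table (SRI-24 space, in permille)."""
    ref = resources.files("priormae.data") / "occurrence_table_sri24_128.tsv"
    return _parse_table_lines(ref.read_text().splitlines(), str(ref))
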