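"""Cohort I/O: regional voxel samples, phenotype tables, network lookups.

The pipeline starts from modulated grey-matter-volume (GMV) maps plus an
integer-labelled parcellation in the same voxel grid, or from a
pre-extracted archive of per-region voxel samples.  All tabular formats
are plain TSV/CSV; images are NIfTI-1 read through nibabel.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from contextlib import contextmanager
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("iscn")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[iscn %(asctime)s] %(message)s", "%H:%M:%S"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@contextmanager
def stage_timer(name: str):
    """Log wall time of a pipeline stage to stderr."""
    t0 = time.perf_counter()
    logger.info("%s ...", name)
    yield
    logger.info("%s done in %.1fs", name, time.perf_counter() - t0)


GROUPS = ("patient", "control")
GENDERS = ("male", "female")
EPISODES = ("first_episode_drug_naive", "recurrent", "other", "control")
YEO_LABELS = ("DMN", "VAN", "VN", "DAN", "SMN", "FPN", "LN", "subcortical")


@dataclasses.dataclass
class RegionalVoxelSamples:
    """Per-subject voxel GMV values grouped by parcellation region.

    ``samples[k]`` holds the voxel values of the region with label
    ``region_ids[k]``; region ordering must be identical across all
    subjects of a cohort.
    """

    subject_id: str
    region_ids: list[int]
    samples: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.region_ids) != len(self.samples):
            raise ValueError("region_ids and samples length mismatch")
        self.samples = [np.asarray(s, dtype=float) for s in self.samples]
        for rid, s in zip(self.region_ids, self.samples):
            if s.size < 2:
                raise ValueError(f"region {rid} has {s.size} voxels; >= 2 required")
            if np.isnan(s).any():
                raise ValueError(f"region {rid} contains NaN voxel values")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclasses.dataclass
class Phenotype:
    """Subject-level clinical and demographic record."""

    subject_id: str
    group: str
    site: str
    age: float
    gender: str
    hamd17: float | None = None
    episode: str = "other"
    extra: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.episode not in EPISODES:
            raise ValueError(f"episode must be one of {EPISODES}, got {self.episode!r}")
        if self.hamd17 is not None and not np.isnan(self.hamd17):
            if not (0 <= self.hamd17 <= 52):
                raise ValueError(f"hamd17 out of range [0,52]: {self.hamd17}")


class NetworkAssignment:
    """Region -> canonical functional network lookup (Yeo 7 + subcortical)."""

    def __init__(self, mapping: Mapping[int, str]):
        for rid, lab in mapping.items():
            if lab not in YEO_LABELS:
                raise ValueError(f"region {rid}: unknown network label {lab!r}")
        self.mapping = dict(mapping)

    def __getitem__(self, region_id: int) -> str:
        if region_id not in self.mapping:
            raise KeyError(f"region {region_id} has no network assignment")
        return self.mapping[region_id]

    def __contains__(self, region_id: int) -> bool:
        return region_id in self.mapping

    @classmethod
    def read_tsv(cls, path: str | Path) -> "NetworkAssignment":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["region_id"].astype(int), df["network"])))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"region_id": list(self.mapping), "network": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)


def _as_array(img) -> np.ndarray:
    """Accept a numpy array, a nibabel image, or a path to a NIfTI file."""
    if isinstance(img, np.ndarray):
        return img
    if isinstance(img, (str, Path)):
        import nibabel as nib

        img = nib.load(str(img))
    if hasattr(img, "get_fdata"):
        return np.asanyarray(img.get_fdata())
    raise TypeError(f"cannot interpret {type(img)} as a 3D image")


def extract_regional_samples(
    gmv_image,
    atlas_image,
    subject_id: str = "subject",
    drop_zeros: bool = False,
) -> RegionalVoxelSamples:
    """Collect the voxel GMV values inside each atlas parcel.

    Parameters
    ----------
    gmv_image, atlas_image
        3D arrays, nibabel images, or NIfTI paths on the same voxel grid.
        Atlas labels are positive integers; 0 is background.
    drop_zeros
        Drop voxels whose GMV is exactly 0 (by default all in-parcel
        voxels are kept).

    Returns one voxel-value vector per nonzero atlas label, labels in
    ascending order.
    """
    gmv = np.asarray(_as_array(gmv_image), dtype=float)
    atlas = _as_array(atlas_image)
    if gmv.shape != atlas.shape:
        raise ValueError(
            f"image/atlas shape mismatch: GMV {gmv.shape} vs atlas {atlas.shape}"
        )
    atlas_int = np.rint(atlas).astype(int)
    if (atlas_int < 0).any():
        raise ValueError("atlas contains negative labels")
    labels = sorted(int(v) for v in np.unique(atlas_int) if v != 0)
    if not labels:
        raise ValueError("atlas contains no nonzero labels")
    samples = []
    for lab in labels:
        vals = gmv[atlas_int == lab]
        if drop_zeros:
            vals = vals[vals != 0]
        if vals.size < 2:
            raise ValueError(
                f"atlas label {lab} covers {vals.size} usable voxels; >= 2 required"
            )
        samples.append(vals)
    return RegionalVoxelSamples(subject_id, labels, samples)


REQUIRED_PHENOTYPE_COLUMNS = ("subject_id", "group", "site", "age", "gender")


def read_phenotype(path: str | Path) -> list[Phenotype]:
    """Read and validate a phenotype TSV/CSV.

    Requires subject_id, group, site, age, gender; optional hamd17 and
    episode columns are typed, and any further column (e.g. TIV) is kept
    in ``extra`` so it can be selected as an additional covariate.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing required columns: {missing}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dups}")
    known = set(REQUIRED_PHENOTYPE_COLUMNS) | {"hamd17", "episode"}
    records = []
    for _, row in df.iterrows():
        hamd = row.get("hamd17")
        hamd = None if hamd is None or (isinstance(hamd, float) and np.isnan(hamd)) else float(hamd)
        records.append(
            Phenotype(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                site=str(row["site"]),
                age=float(row["age"]),
                gender=str(row["gender"]),
                hamd17=hamd,
                episode=str(row.get("episode", "other")) if "episode" in df.columns else "other",
                extra={c: row[c] for c in df.columns if c not in known},
            )
        )
    return records


def phenotype_frame(records: Sequence[Phenotype]) -> pd.DataFrame:
    """Tabular view of phenotype records, extras expanded to columns."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d.update(d.pop("extra"))
        rows.append(d)
    return pd.DataFrame(rows)


def write_phenotype(records: Sequence[Phenotype], path: str | Path) -> None:
    phenotype_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Regional-sample archive: one (subject, region, voxel_value) TSV per cohort
# plus a JSON sidecar freezing the shared region ordering.
# ---------------------------------------------------------------------------

def write_samples_archive(
    cohort: Sequence[RegionalVoxelSamples], path: str | Path
) -> None:
    """Write a cohort of regional voxel samples as long-format TSV + sidecar.

    Values are written with ``repr`` precision so a read round-trips
    bit-exactly.
    """
    path = Path(path)
    order = cohort[0].region_ids
    for subj in cohort:
        if subj.region_ids != order:
            raise ValueError(
                f"subject {subj.subject_id} region ordering differs from cohort"
            )
    with open(path, "w") as fh:
        fh.write("subject_id\tregion_id\tvoxel_value\n")
        for subj in cohort:
            for rid, vals in zip(subj.region_ids, subj.samples):
                for v in vals:
                    fh.write(f"{subj.subject_id}\t{rid}\t{float(v)!r}\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"region_ids": order, "subjects": [s.subject_id for s in cohort]},
            indent=1,
        )
    )


def read_samples_archive(path: str | Path) -> list[RegionalVoxelSamples]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    order = [int(r) for r in meta["region_ids"]]
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"subject_id": str, "region_id": int},
        float_precision="round_trip",
    )
    out = []
    grouped = df.groupby("subject_id", sort=False)
    for sid in meta["subjects"]:
        sub = grouped.get_group(sid)
        by_region = {rid: g["voxel_value"].to_numpy() for rid, g in sub.groupby("region_id", sort=False)}
        out.append(RegionalVoxelSamples(sid, order, [by_region[r] for r in order]))
    return out
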