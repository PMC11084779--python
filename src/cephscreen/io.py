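"""File I/O: masks (NIfTI / NRRD), landmark JSON, cohort CSV."""

from __future__ import annotations

import gzip
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .morphometry import AirwayMask


def save_mask_nifti(mask: AirwayMask, path: str | Path) -> None:
    affine = np.diag([*mask.spacing, 1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def load_mask_nifti(path: str | Path) -> AirwayMask:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: NIfTI header carries no positive voxel spacing")
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    data = np.asarray(img.dataobj) > 0
    return AirwayMask(data, tuple(float(z) for z in zooms), origin)


# minimal NRRD support (raw / gzip encodings, 3D, as written by save_mask_nrrd)

def save_mask_nrrd(mask: AirwayMask, path: str | Path) -> None:
    sx, sy, sz = mask.spacing
    header = (
        "NRRD0004\n"
        "type: uint8\n"
        "dimension: 3\n"
        f"sizes: {mask.shape[0]} {mask.shape[1]} {mask.shape[2]}\n"
        "encoding: gzip\n"
        "space: left-posterior-superior\n"
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})\n"
        f"space origin: ({mask.origin[0]},{mask.origin[1]},{mask.origin[2]})\n"
        "\n"
    )
    payload = gzip.compress(mask.data.astype(np.uint8).tobytes(order="F"))
    with open(path, "wb") as fh:
        fh.write(header.encode())
        fh.write(payload)


def load_mask_nrrd(path: str | Path) -> AirwayMask:
    with open(path, "rb") as fh:
        blob = fh.read()
    head, _, payload = blob.partition(b"\n\n")
    fields: dict[str, str] = {}
    for line in head.decode().splitlines()[1:]:
        if ":" in line:
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
    sizes = tuple(int(v) for v in fields["sizes"].split())
    vecs = re.findall(r"\(([^)]*)\)", fields.get("space directions", ""))
    if len(vecs) != 3:
        raise ValueError(f"{path}: NRRD header lacks voxel spacing (space directions)")
    spacing = tuple(float(np.linalg.norm([float(c) for c in v.split(",")]))
                    for v in vecs)
    origin = (0.0, 0.0, 0.0)
    if "space origin" in fields:
        origin = tuple(float(c) for c in
                       re.findall(r"\(([^)]*)\)", fields["space origin"])[0].split(","))
    if fields.get("encoding") == "gzip":
        payload = gzip.decompress(payload)
    elif fields.get("encoding") != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {fields.get('encoding')!r}")
    data = np.frombuffer(payload, dtype=np.uint8)[: int(np.prod(sizes))]
    data = data.reshape(sizes, order="F") > 0
    return AirwayMask(data, spacing, origin)


def load_mask(path: str | Path) -> AirwayMask:
    p = Path(path)
    if p.suffix == ".nrrd":
        return load_mask_nrrd(p)
    return load_mask_nifti(p)


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
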