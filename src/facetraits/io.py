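"""Dataset readers/writers and cross-file validation.

On-disk dataset layout (also what the synthetic generator writes, and what
an externally obtained rated-face database should be adapted to):

    <dir>/images/<id>.png    8-bit grayscale face images
    <dir>/landmarks.csv      id,x1,y1,...,x21,y21 (pixels, origin top-left)
    <dir>/scores.csv         id,<trait>,...       (continuous 1–9 ratings)
    <dir>/manifest.yaml      optional provenance record
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_faces import TRAITS, FaceSample
from .template import N_POINTS

__all__ = ["read_dataset", "DatasetError"]


class DatasetError(ValueError):
    """Dataset files are inconsistent or malformed."""


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:  # surfaced with pandas' line info
        raise DatasetError(f"malformed CSV {path}: {exc}") from exc


def read_dataset(path, traits=TRAITS, require_images: bool = True) -> list[FaceSample]:
    """Load a dataset directory into FaceSample objects, validating ids.

    Every id must appear in the landmark file, the score file and (unless
    ``require_images`` is off) the image directory; any mismatch raises a
    DatasetError listing the offending ids.
    """
    from PIL import Image

    root = Path(path)
    landmarks = _read_csv(root / "landmarks.csv")
    scores = _read_csv(root / "scores.csv")
    for df, name in ((landmarks, "landmarks.csv"), (scores, "scores.csv")):
        if "id" not in df.columns:
            raise DatasetError(f"{name}: missing 'id' column")
    missing_traits = [t for t in traits if t not in scores.columns]
    if missing_traits:
        raise DatasetError(f"scores.csv: missing trait column(s) {missing_traits}")

    coord_cols = [c for c in landmarks.columns if c != "id"]
    if len(coord_cols) != 2 * N_POINTS:
        raise DatasetError(
            f"landmarks.csv: expected {2 * N_POINTS} coordinate columns "
            f"({N_POINTS} points), found {len(coord_cols)}"
        )

    lm_ids = list(landmarks["id"].astype(str))
    sc_ids = set(scores["id"].astype(str))
    only_lm = sorted(set(lm_ids) - sc_ids)
    only_sc = sorted(sc_ids - set(lm_ids))
    if only_lm or only_sc:
        raise DatasetError(
            f"id mismatch between files; only in landmarks.csv: {only_lm[:5]}, "
            f"only in scores.csv: {only_sc[:5]}"
        )

    scores = scores.set_index(scores["id"].astype(str))
    samples = []
    for _, row in landmarks.iterrows():
        sid = str(row["id"])
        pts = row[coord_cols].to_numpy(float).reshape(N_POINTS, 2)
        if not np.all(np.isfinite(pts)):
            raise DatasetError(f"non-finite landmark coordinates for id {sid!r}")
        img_path = root / "images" / f"{sid}.png"
        if img_path.exists():
            img = np.asarray(Image.open(img_path).convert("L"), float) / 255.0
        elif require_images:
            raise DatasetError(f"missing image for id {sid!r}: {img_path}")
        else:
            img = np.zeros((1, 1))
        trait_scores = {t: float(scores.loc[sid, t]) for t in traits}
        samples.append(FaceSample(id=sid, image=img, landmarks=pts, scores=trait_scores))
    return samples
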