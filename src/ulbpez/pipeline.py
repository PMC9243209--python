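"""End-to-end convenience: fundus images -> padded ULBPEZ vectors + feature images."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import LBPConfig, build_uniform_mapping, extract
from .preprocessing import FundusImage, PreprocessConfig, preprocess

__all__ = ["extract_dataset", "features_to_frame"]


def extract_dataset(
    images: Sequence[FundusImage],
    lbp_cfg: Optional[LBPConfig] = None,
    pre_cfg: Optional[PreprocessConfig] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Preprocess and extract every image.

    Returns (padded vectors (N, capacity), feature images (N, side, side),
    grades (N,)); grades are -1 where unlabelled.
    """
    lbp_cfg = lbp_cfg or LBPConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    mapping = build_uniform_mapping(lbp_cfg.P)
    vectors, fimgs, labels = [], [], []
    for img in images:
        img = getattr(img, "image", img)  # unwrap SynthImage
        enhanced, mask = preprocess(img, pre_cfg)
        vec, fimg = extract(enhanced, mask, lbp_cfg, mapping)
        vectors.append(vec)
        fimgs.append(fimg)
        labels.append(img.label if img.label is not None else -1)
    return np.stack(vectors), np.stack(fimgs), np.asarray(labels)


def features_to_frame(
    vectors: np.ndarray,
    grades: np.ndarray,
    lbp_cfg: LBPConfig,
    image_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One row per image: id, grade, (P, R), capacity, then the padded vector."""
    n, cap = vectors.shape
    ids = list(image_ids) if image_ids is not None else [f"img_{i:04d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "image_id": ids,
            "grade": grades,
            "P": lbp_cfg.P,
            "R": lbp_cfg.R,
            "capacity": cap,
        }
    )
    vals = pd.DataFrame(vectors, columns=[f"v{i}" for i in range(cap)])
    return pd.concat([meta, vals], axis=1)
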