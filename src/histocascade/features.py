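"""Per-ROI feature assembly and the tabular feature schema.

One tile yields 588 features: 48 nuclear-architecture features computed on
the detected centroids, followed by 540 texture features computed on the
raw RGB pixels.  The tabular schema prepends ``path``, ``label`` and
``seed`` metadata columns, giving the stable 591-column CSV layout used
by the experiment and ranking stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import ARCHITECTURE_FEATURE_NAMES, architecture_vector
from .errors import SchemaError
from .nuclei import DEFAULT_MIN_AREA, DEFAULT_MIN_DISTANCE, detect
from .stain import StainMatrix, default_he_matrix
from .texture import DEFAULT_OFFSETS, TEXTURE_FEATURE_NAMES, texture_vector

__all__ = [
    "FEATURE_NAMES",
    "METADATA_COLUMNS",
    "TABLE_COLUMNS",
    "extract_features",
    "extract_dataset",
    "write_feature_csv",
    "read_feature_csv",
]

FEATURE_NAMES: tuple[str, ...] = ARCHITECTURE_FEATURE_NAMES + TEXTURE_FEATURE_NAMES
METADATA_COLUMNS = ("path", "label", "seed")
TABLE_COLUMNS: tuple[str, ...] = METADATA_COLUMNS + FEATURE_NAMES
assert len(TABLE_COLUMNS) == 591


def extract_features(
    image: np.ndarray,
    stains: StainMatrix | None = None,
    centroids: np.ndarray | None = None,
    min_distance: float = DEFAULT_MIN_DISTANCE,
    min_area: int = DEFAULT_MIN_AREA,
    fo_window: int = 3,
    cooc_window: int = 9,
    offsets=DEFAULT_OFFSETS,
    bank=None,
) -> np.ndarray:
    """The full 588-feature vector for one RGB tile.

    When ``centroids`` is given (e.g. ground-truth or manual annotations)
    the detection stage is skipped and architecture features are computed
    on the supplied points.
    """
    stains = stains if stains is not None else default_he_matrix()
    if centroids is None:
        centroids = detect(
            image, stains, min_distance=min_distance, min_area=min_area
        ).coords
    arch = architecture_vector(centroids, image.shape[:2])
    tex = texture_vector(
        image, fo_window=fo_window, cooc_window=cooc_window, offsets=offsets, bank=bank
    )
    return np.concatenate([arch, tex])


def extract_dataset(items, stains: StainMatrix | None = None, **kwargs) -> pd.DataFrame:
    """Feature table for a list of ``(image, GroundTruth)`` items."""
    rows = []
    for image, truth in items:
        vec = extract_features(image, stains=stains, **kwargs)
        rows.append([("", truth.label, truth.seed) + tuple(vec)][0])
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def write_feature_csv(df: pd.DataFrame, path) -> None:
    _check_schema(df)
    df.to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df)
    return df


def _check_schema(df: pd.DataFrame) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"feature table is missing {len(missing)} columns "
            f"(first few: {missing[:5]})"
        )
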