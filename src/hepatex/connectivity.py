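"""Horizontal run-connectivity counts on complemented binary images.

A "k-connected black object" is a maximal horizontal run of black pixels
(bit 0) of length at least ``k``; runs are bounded by white pixels or the
row edges and each maximal run is counted once per ``k`` it reaches, so
``count(k+1) <= count(k)`` always.  The feature vector of a template is
the 9 counts for radii 1-3 and k = 3, 4, 5 of the pipeline

    template -> LBP/DLBP code image -> 8-bit rescale -> Otsu binarize
             -> complement -> per-row run counting.

A uniform code image (no Otsu split) contributes zero counts for that
radius: a flat transform means no salient texture at that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hepatex.dlbp import dlbp_image
from hepatex.image_io import validate_template
from hepatex.lbp import lbp_image
from hepatex.otsu import (
    DegenerateHistogramError,
    binarize,
    complement,
    histogram,
    otsu_threshold,
    rescale_codes,
)

RADII = (1, 2, 3)
RUN_LENGTHS = (3, 4, 5)
OPERATORS = ("lbp", "dlbp")

#: Feature CSV column for transform radius R and run length k.
COLUMN_TEMPLATE = "lbp_r{radius}_k{run_length}"

FEATURE_COLUMNS = tuple(
    COLUMN_TEMPLATE.format(radius=r, run_length=k) for r in RADII for k in RUN_LENGTHS
)


def count_runs(image: np.ndarray, k: int, *, black: int = 0) -> int:
    """Number of maximal horizontal runs of ``black`` pixels of length >= k.

    Rows are scanned independently; vertical adjacency never joins runs.
    """
    if k < 1:
        raise ValueError(f"run length k must be >= 1, got {k}")
    arr = np.asarray(image)
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D binary image, got shape {arr.shape}")
    if arr.size == 0:
        return 0
    mask = (arr == black).astype(np.int8)
    # Pad each row with white so run boundaries become +1/-1 transitions.
    padded = np.zeros((mask.shape[0], mask.shape[1] + 2), dtype=np.int8)
    padded[:, 1:-1] = mask
    diff = np.diff(padded, axis=1)
    starts = np.argwhere(diff == 1)
    ends = np.argwhere(diff == -1)
    # Per row, starts and ends alternate and pair up in order.
    lengths = ends[:, 1] - starts[:, 1]
    return int((lengths >= k).sum())


@dataclass
class ConnectivityFeatures:
    """The per-template run-connectivity counts.

    ``counts`` maps ``(radius, run_length)`` to a nonnegative integer.
    """

    counts: dict[tuple[int, int], int]
    operator: str
    template_id: str | None = None
    radii: tuple[int, ...] = RADII
    run_lengths: tuple[int, ...] = RUN_LENGTHS

    def __post_init__(self) -> None:
        for (r, k), v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative count {v} at radius {r}, k={k}")
        for r in self.radii:
            ks = sorted(k for (rr, k) in self.counts if rr == r)
            vals = [self.counts[(r, k)] for k in ks]
            if any(a < b for a, b in zip(vals, vals[1:])):
                raise ValueError(f"counts not monotone in k at radius {r}: {vals}")

    def __getitem__(self, key: tuple[int, int]) -> int:
        return self.counts[key]

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "template_id": self.template_id,
            "operator": self.operator,
        }
        for (r, k), v in sorted(self.counts.items()):
            row[COLUMN_TEMPLATE.format(radius=r, run_length=k)] = v
        return row


def _code_image(template: np.ndarray, operator: str, radius: int) -> np.ndarray:
    if operator == "lbp":
        return lbp_image(template, radius)
    if operator == "dlbp":
        return dlbp_image(template, radius)
    raise ValueError(f"unknown operator {operator!r}; expected one of {OPERATORS}")


def extract_features(
    template: np.ndarray,
    operator: str = "dlbp",
    *,
    radii: tuple[int, ...] = RADII,
    run_lengths: tuple[int, ...] = RUN_LENGTHS,
    template_id: str | None = None,
) -> ConnectivityFeatures:
    """Run the full pipeline on one template and collect the counts.

    For each radius: code image -> 8-bit rescale -> Otsu binarize ->
    complement -> count black runs for each requested k.  A degenerate
    (uniform) code image yields zero counts for that radius.
    """
    arr = validate_template(template)
    max_r = max(radii)
    if min(arr.shape) < 2 * max_r + 1:
        raise ValueError(
            f"template {arr.shape} too small for radius {max_r}"
        )
    counts: dict[tuple[int, int], int] = {}
    for r in radii:
        codes = _code_image(arr, operator, r)
        try:
            scaled = rescale_codes(codes)
            result = otsu_threshold(histogram(scaled))
        except DegenerateHistogramError:
            for k in run_lengths:
                counts[(r, k)] = 0
            continue
        black_objects = complement(binarize(scaled, result))
        for k in run_lengths:
            counts[(r, k)] = count_runs(black_objects, k)
    return ConnectivityFeatures(
        counts=counts,
        operator=operator,
        template_id=template_id,
        radii=tuple(radii),
        run_lengths=tuple(run_lengths),
    )


def features_frame(features: list[ConnectivityFeatures]) -> pd.DataFrame:
    """Stack feature vectors into the interchange CSV schema."""
    return pd.DataFrame([f.as_row() for f in features])
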