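"""Packaged reference feature tables from the 50-template clinical study.

Three count tables (one template per row, 44 cirrhotic + 6 normal) are
shipped as CSV, transcribed from the study report:

* ``otsu``  — Otsu applied directly to the raw templates (k = 3, 4, 5);
* ``lbp``   — standard LBP then Otsu, radii 1-3 x k in {3, 4, 5};
* ``dlbp``  — differential LBP then Otsu, same layout.

The original ultrasound frames are not deposited, so these printed counts
are the only recoverable inputs of the study's classification step; they
feed the margin/neighbor classifiers and the interval-rule derivation.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from hepatex.connectivity import COLUMN_TEMPLATE

_FILES = {
    "otsu": "otsu_counts.csv",
    "lbp": "lbp_otsu_counts.csv",
    "dlbp": "dlbp_otsu_counts.csv",
}


def load_reference_counts(method: str) -> pd.DataFrame:
    """Load one packaged count table as a DataFrame.

    Parameters
    ----------
    method
        ``"otsu"``, ``"lbp"`` or ``"dlbp"``.
    """
    try:
        fname = _FILES[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; expected one of {sorted(_FILES)}"
        ) from None
    ref = resources.files("hepatex.data").joinpath(fname)
    with ref.open() as fh:
        return pd.read_csv(fh)


def feature_pair(
    df: pd.DataFrame, radius: int = 3, run_lengths: tuple[int, int] = (4, 5)
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the 2-D feature points and labels used by the classifiers.

    Default projection: radius-3 counts for k = 4 (x) and k = 5 (y).
    """
    cols = [
        COLUMN_TEMPLATE.format(radius=radius, run_length=k) for k in run_lengths
    ]
    x = df[cols].to_numpy(dtype=np.float64)
    y = df["label"].to_numpy()
    return x, y
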