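"""Reading and writing the standard on-disk formats.

Images travel as single- or multi-page TIFF (8/16-bit unsigned or 32-bit
float; channels are pages, order taken from the caller's channel list) and
are promoted to float on load.  Label maps are written as 16-bit TIFF.
Tables are CSV/TSV with a header row; result CSVs carry a ``#`` comment
header recording tool version, parameters and seed so every output is
self-describing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .imaging import MultiChannelImage


def read_image(
    path, channel_names: Sequence[str], pixel_size_um: float
) -> MultiChannelImage:
    """Read a multi-page TIFF; page k becomes channel ``channel_names[k]``."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(channel_names):
        raise ValueError(
            f"{path}: {arr.shape[0]} pages but {len(channel_names)} channel names"
        )
    data = {name: arr[i].astype(float) for i, name in enumerate(channel_names)}
    return MultiChannelImage(data=data, pixel_size_um=pixel_size_um)


def write_image(path, img: MultiChannelImage) -> None:
    stack = np.stack([img.data[ch] for ch in img.channel_names]).astype(np.float32)
    tifffile.imwrite(path, stack)


def write_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit label image")
    tifffile.imwrite(path, labels.astype(np.uint16))


def write_table(path, table: pd.DataFrame, params: Optional[dict] = None) -> None:
    """Write a CSV with a commented provenance header."""
    path = Path(path)
    with path.open("w") as fh:
        from . import __version__

        fh.write(f"# rdnalinks {__version__}\n")
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        table.to_csv(fh, index=False)


def read_table(path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")
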