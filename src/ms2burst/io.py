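"""Reading and writing pipeline artifacts.

Movies and label masks travel as multi-page TIFF (dimension order
T,Z,C,Y,X for movies, T,Y,X for masks, 16-bit); tables as CSV with a
header comment carrying the config hash.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["write_movie", "read_movie", "write_masks", "read_masks",
           "write_csv", "read_csv"]


def write_movie(path: str | Path, movie: np.ndarray) -> None:
    """Write a (T, Z, C, Y, X) uint16 movie as multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(movie, dtype=np.uint16),
                     metadata={"axes": "TZCYX"})


def read_movie(path: str | Path) -> np.ndarray:
    a = tifffile.imread(str(path))
    if a.ndim != 5:
        raise ValueError(f"expected a T,Z,C,Y,X movie, got shape {a.shape}")
    return a


def write_masks(path: str | Path, masks: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(masks, dtype=np.uint16),
                     metadata={"axes": "TYX"})


def read_masks(path: str | Path) -> np.ndarray:
    a = tifffile.imread(str(path))
    if a.ndim == 2:
        a = a[None]
    return a.astype(np.uint16)


def write_csv(path: str | Path, df: pd.DataFrame,
              config_hash: str | None = None) -> None:
    """CSV with an optional '# config=<hash>' header comment."""
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
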