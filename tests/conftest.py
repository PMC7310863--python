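"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nanofoci.nanoseg import Nanofocus, RoiRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_nanofocus(
    channel: str,
    com,
    area_px: int = 60,
    mask: np.ndarray | None = None,
    origin=(0.0, 0.0),
    pixel: float = 5.0,
    n_locs: int = 600,
) -> Nanofocus:
    """Build a nanofocus with a square mask blob centred on ``com``."""
    com = np.asarray(com, dtype=float)
    if mask is None:
        side = max(1, int(round(np.sqrt(area_px))))
        shape = (120, 120)
        mask = np.zeros(shape, dtype=bool)
        cx = int((com[0] - origin[0]) / pixel)
        cy = int((com[1] - origin[1]) / pixel)
        half = side // 2
        mask[max(0, cy - half):cy - half + side,
             max(0, cx - half):cx - half + side] = True
    return Nanofocus(channel=channel, mask=mask, pixel_size=pixel,
                     origin=np.asarray(origin, dtype=float),
                     area_px=int(mask.sum()), com_nm=com, n_locs=n_locs)


def make_roi(roi_id: str, events: pd.DataFrame, centre=(0.0, 0.0),
             **kwargs) -> RoiRecord:
    return RoiRecord(id=roi_id, centre=np.asarray(centre, dtype=float),
                     events=events, **kwargs)


def gaussian_cluster(rng, centre, sigma, n, channel) -> pd.DataFrame:
    xy = np.asarray(centre, dtype=float) + rng.normal(scale=sigma, size=(n, 2))
    return pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1],
                         "channel": channel})


@pytest.fixture
def bar_mask():
    """Axis-like binary mask: three horizontal bars in a 120x120 field."""
    mask = np.zeros((120, 120), dtype=bool)
    for row in (25, 60, 95):
        mask[row:row + 4, 10:110] = True
    return mask
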