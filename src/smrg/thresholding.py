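"""Per-crop choice between the mixture model and Otsu thresholding.

Crops whose intensity histogram is multimodal (several labelled structures,
or structure plus background shoulder) violate the single-signal-class
assumption of the local mixture model.  Hartigan's dip test decides: if
unimodality is rejected at p < 0.01 the crop is thresholded with Otsu's
method, otherwise the EM-fitted mixture posterior is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from ._dip import dip_statistic, dip_pvalue

__all__ = ["CropDecision", "dip_test", "otsu_threshold"]

#: significance level of the unimodality test
DIP_ALPHA = 0.01


@dataclass(frozen=True)
class CropDecision:
    multimodal: bool
    dip_stat: float
    p_value: float
    method: str  # "mixture" or "otsu"


def dip_test(pixels, alpha: float = DIP_ALPHA, n_boot: int = 2000) -> CropDecision:
    """Test a crop's intensity distribution for unimodality.

    The p-value is bootstrapped against the uniform null (B = 2000, seeded),
    cached per sample size.  Integer (tied) samples are dithered with a
    seeded uniform box of one level spacing first: the dip statistic of
    heavily tied data is inflated relative to the continuous null, which
    would spuriously reject unimodality on every quantised crop, while
    dithering preserves (uni)modality of the underlying histogram.  Samples
    with fewer than 8 points are called unimodal by convention.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("dip test on an empty crop")
    ux = np.unique(x)
    if x.size < 8 or ux.size == 1:
        return CropDecision(False, 0.0, 1.0, "mixture")
    if ux.size < x.size:
        if np.allclose(x, np.round(x)):
            spacing = 1.0  # integer-quantised intensities
        else:
            spacing = float(np.min(np.diff(ux)))
        rng = np.random.default_rng(19850101)
        x = x + rng.uniform(-0.5, 0.5, x.size) * spacing
    dip = dip_statistic(x)
    p = dip_pvalue(dip, x.size, n_boot=n_boot)
    multimodal = p < alpha
    return CropDecision(multimodal, dip, p, "otsu" if multimodal else "mixture")


def otsu_threshold(pixels) -> int:
    """Otsu threshold on the exact integer-level histogram.

    Foreground is the set of pixels *strictly above* the returned level, a
    conservative rule that keeps the boundary level in the background.
    """
    x = np.asarray(pixels).ravel()
    if x.size == 0:
        raise ValueError("Otsu threshold of an empty crop")
    xi = np.asarray(np.round(x), dtype=np.int64)
    lo, hi = int(xi.min()), int(xi.max())
    if lo == hi:
        raise ValueError("Otsu threshold of a constant crop")
    counts = np.bincount(xi - lo, minlength=hi - lo + 1)
    centers = np.arange(lo, hi + 1)
    return int(threshold_otsu(hist=(counts, centers)))
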