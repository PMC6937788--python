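"""Cavity volumes, global LV function, and infarct size scoring.

Volumes use voxel counting on the time-resolved cavity mask (Simpson-style
slice summation); end diastole/systole are the frames of maximum/minimum
cavity volume, with the earliest frame winning ties.  Infarct size follows
the 17-segment transmurality scoring convention: each AHA segment is scored
0-4 (0 = none, 4 = >75% transmural), the scores are averaged, and the result
divided by four gives the infarcted fraction of the myocardium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import SegmentationCine

__all__ = [
    "VentricularFunction",
    "InfarctScore",
    "cavity_volumes",
    "cardiac_output",
    "infarct_fraction",
]


@dataclass
class VentricularFunction:
    volume_curve_ml: np.ndarray
    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    ed_frame: int
    es_frame: int
    co_l_min: Optional[float] = None  # filled when heart rate is known

    def as_dict(self) -> dict:
        d = {
            "edv_ml": self.edv_ml,
            "esv_ml": self.esv_ml,
            "sv_ml": self.sv_ml,
            "ef_pct": self.ef_pct,
            "ed_frame": self.ed_frame,
            "es_frame": self.es_frame,
        }
        if self.co_l_min is not None:
            d["co_l_min"] = self.co_l_min
        return d


def cavity_volumes(seg: SegmentationCine, heart_rate: Optional[float] = None) -> VentricularFunction:
    """Voxel-counting volume curve and global function (EDV/ESV/SV/EF, CO if HR given)."""
    curve = seg.volume_curve_ml()
    ed = int(np.argmax(curve))
    es = int(np.argmin(curve))
    edv = float(curve[ed])
    esv = float(curve[es])
    sv = edv - esv
    fn = VentricularFunction(
        volume_curve_ml=curve,
        edv_ml=edv,
        esv_ml=esv,
        sv_ml=sv,
        ef_pct=100.0 * sv / edv,
        ed_frame=ed,
        es_frame=es,
    )
    if heart_rate is not None:
        fn.co_l_min = cardiac_output(sv, heart_rate)
    return fn


def cardiac_output(sv_ml: float, heart_rate_bpm: float) -> float:
    """Cardiac output in L/min from stroke volume (mL) and heart rate (bpm)."""
    if sv_ml < 0:
        raise ValueError("stroke volume must be non-negative")
    if heart_rate_bpm <= 0:
        raise ValueError("heart rate must be positive")
    return sv_ml * heart_rate_bpm / 1000.0


@dataclass
class InfarctScore:
    scores: np.ndarray  # 17 segment scores in {0..4}
    fraction_pct: float


def infarct_fraction(scores) -> InfarctScore:
    """Mean 17-segment transmurality score divided by 4, as a percentage."""
    scores = np.asarray(scores)
    if scores.shape != (17,):
        raise ValueError(f"expected 17 segment scores, got shape {scores.shape}")
    if not np.all(np.isin(scores, (0, 1, 2, 3, 4))):
        raise ValueError("segment scores must be integers in {0..4}")
    fraction = float(scores.mean() / 4.0 * 100.0)
    return InfarctScore(scores=scores.astype(int), fraction_pct=fraction)
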