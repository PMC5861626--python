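"""Small factories shared across test modules."""

from bridgeflow import MinWSS, StableValue, WallLabel
from bridgeflow.sweep import ModelResult


def make_result(rid, group, d, a, ssd_min, bvu_min, ssd_pos=5.0, bvu_pos=1.0):
    minima = {
        "SSD": MinWSS(WallLabel.SSD, ssd_min, ssd_pos),
        "BVU": MinWSS(WallLabel.BVU, bvu_min, bvu_pos),
    }
    stable = {
        "SSD": StableValue(WallLabel.SSD, 0.563, (10.0, 20.0)),
        "BVU": StableValue(WallLabel.BVU, 0.619, (8.0, 14.0)),
    }
    return ModelResult(rid, group, d, a, True, stable, minima)
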