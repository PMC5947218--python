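"""Packaged tissue parameter presets.

Literature two-pool parameter sets commonly used for brain quantitative
MRI: a myelin-water exchange model (Bloch-McConnell, visible short-T2
water pool) and white-matter / caudate-nucleus magnetization-transfer
models (semisolid bound pool, 1.5 T estimates). ``single_wm`` is the
single-compartment comparison tissue whose T1 equals the apparent
(inversion-recovery) T1 of the white-matter MT model.
"""

from __future__ import annotations

from .models import SinglePoolModel, TwoPoolBMModel, TwoPoolMTModel

__all__ = ["PRESETS", "get_preset", "preset_names"]


def _build():
    return {
        "myelin_bm": TwoPoolBMModel(
            t1a=1000.0, t1b=500.0, t2a=100.0, t2b=20.0, ka=2.0, f=0.2
        ),
        "wm_mt": TwoPoolMTModel(
            t1a=779.0, t1b=779.0, t2a=45.0, t2b_us=12.0, ka=4.3, f=0.117
        ),
        "cn_mt": TwoPoolMTModel(
            t1a=1087.0, t1b=1087.0, t2a=59.0, t2b_us=12.0, ka=2.3, f=0.061
        ),
        "single_wm": SinglePoolModel(t1=779.0, t2=45.0),
        "csf": SinglePoolModel(t1=4000.0, t2=2000.0),
    }


PRESETS = _build()


def preset_names():
    return sorted(PRESETS)


def get_preset(name: str):
    """Return a fresh copy of a named preset model."""
    try:
        template = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}") from None
    from dataclasses import replace

    return replace(template)
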