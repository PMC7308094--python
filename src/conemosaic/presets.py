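"""Strain presets for opsin-expression gradients along the dorso-ventral axis.

The mouse retina expresses S- and M-opsin in opposing gradients along the
dorso-ventral axis.  Most cones co-express both opsins ("mixed", M+S+); a
minority express only one ("true S", S+M-; or M-only, M+S-).  The presets
here encode, for the two commonly studied strains (pigmented C57BL/6-like
and albino CD1-like), the probability that a cone at dorso-ventral position
y belongs to each class, as logistic functions of y.

Calibration: the dorsal asymptote of the true-S fraction is 1% in both
strains; the ventral asymptote is 33% (pigmented) or 29% (albino).  The
M-only fraction at the dorsal pole is 97% (pigmented) versus 7% (albino,
where S-opsin expression extends dorsally so nearly all dorsal cones are
mixed).  Midpoints/slopes were chosen so that the whole-retina true-S
fraction works out to roughly 10%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class Logistic:
    """Logistic profile along y (μm): value_ventral + (value_dorsal - value_ventral) * expit((y - midpoint)/slope).

    ``slope`` > 0 gives a profile rising toward dorsal (+y) when
    value_dorsal > value_ventral.
    """

    value_dorsal: float
    value_ventral: float
    midpoint_um: float
    slope_um: float

    def __call__(self, y):
        t = expit((np.asarray(y, dtype=float) - self.midpoint_um) / self.slope_um)
        return self.value_ventral + (self.value_dorsal - self.value_ventral) * t


@dataclass(frozen=True)
class StrainPreset:
    """Per-strain class-probability and expression-level gradients."""

    name: str
    trueS_fraction: Logistic
    m_only_fraction: Logistic
    # relative expression level of each opsin where it is expressed, in (0, 1]
    s_level: Logistic
    m_level: Logistic

    def __post_init__(self):
        for g in (self.trueS_fraction, self.m_only_fraction):
            for v in (g.value_dorsal, g.value_ventral):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"class fraction outside [0, 1]: {v}")

    @property
    def trueS_fraction_dorsal(self) -> float:
        return self.trueS_fraction.value_dorsal

    @property
    def trueS_fraction_ventral(self) -> float:
        return self.trueS_fraction.value_ventral

    @property
    def m_only_fraction_dorsal(self) -> float:
        return self.m_only_fraction.value_dorsal

    def class_probabilities(self, y):
        """Return (p_trueS, p_m_only, p_mixed) arrays at dorso-ventral position y (μm)."""
        p_s = np.asarray(self.trueS_fraction(y), dtype=float)
        p_m = np.asarray(self.m_only_fraction(y), dtype=float)
        total = p_s + p_m
        # logistic families may momentarily sum past 1 mid-gradient; renormalize
        over = total > 1.0
        if np.any(over):
            p_s = np.where(over, p_s / total, p_s)
            p_m = np.where(over, p_m / total, p_m)
        return p_s, p_m, 1.0 - p_s - p_m


def pigmented() -> StrainPreset:
    return StrainPreset(
        name="pigmented",
        trueS_fraction=Logistic(0.01, 0.33, midpoint_um=-600.0, slope_um=250.0),
        m_only_fraction=Logistic(0.97, 0.0, midpoint_um=0.0, slope_um=150.0),
        s_level=Logistic(0.35, 1.0, midpoint_um=-300.0, slope_um=400.0),
        m_level=Logistic(1.0, 0.55, midpoint_um=300.0, slope_um=400.0),
    )


def albino() -> StrainPreset:
    return StrainPreset(
        name="albino",
        trueS_fraction=Logistic(0.01, 0.29, midpoint_um=-600.0, slope_um=250.0),
        m_only_fraction=Logistic(0.07, 0.0, midpoint_um=0.0, slope_um=150.0),
        s_level=Logistic(0.55, 1.0, midpoint_um=-300.0, slope_um=400.0),
        m_level=Logistic(1.0, 0.55, midpoint_um=300.0, slope_um=400.0),
    )


_PRESETS = {"pigmented": pigmented, "albino": albino}


def get_preset(name: str) -> StrainPreset:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown strain preset {name!r}; choose from {sorted(_PRESETS)}") from None
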