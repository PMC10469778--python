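"""Canonical sensorimotor frequency bands.

Six logarithmically scaled sub-bands cover beta (12-35 Hz), gamma
(35-70 Hz), and high gamma (70-140 Hz). Low/high sub-band pairs are
merged by power averaging into the three named parent bands.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SubBand:
    """A half-open frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: f_lo must be < f_hi")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


#: The six analysis sub-bands, in canonical (ascending) order.
SUB_BANDS: dict[str, SubBand] = {
    "beta_l": SubBand("beta_l", 12.0, 21.0),
    "beta_h": SubBand("beta_h", 21.0, 35.0),
    "gamma_l": SubBand("gamma_l", 35.0, 50.0),
    "gamma_h": SubBand("gamma_h", 50.0, 70.0),
    "hgamma_l": SubBand("hgamma_l", 70.0, 99.0),
    "hgamma_h": SubBand("hgamma_h", 99.0, 140.0),
}

SUB_BAND_NAMES: tuple[str, ...] = tuple(SUB_BANDS)

#: Merged parent bands: elementwise power average of the low/high pair.
MERGED_PAIRS: dict[str, tuple[str, str]] = {
    "beta": ("beta_l", "beta_h"),
    "gamma": ("gamma_l", "gamma_h"),
    "hgamma": ("hgamma_l", "hgamma_h"),
}

MERGED_BANDS: dict[str, SubBand] = {
    "beta": SubBand("beta", 12.0, 35.0),
    "gamma": SubBand("gamma", 35.0, 70.0),
    "hgamma": SubBand("hgamma", 70.0, 140.0),
}

#: Frequencies (Hz) notched out as mains interference.
LINE_NOISE_HZ: tuple[float, ...] = (60.0, 120.0, 180.0)

#: Pretty labels used in reports.
BAND_LABELS: dict[str, str] = {
    "beta_l": "β_l (12–21 Hz)",
    "beta_h": "β_h (21–35 Hz)",
    "gamma_l": "γ_l (35–50 Hz)",
    "gamma_h": "γ_h (50–70 Hz)",
    "hgamma_l": "Γ_l (70–99 Hz)",
    "hgamma_h": "Γ_h (99–140 Hz)",
    "beta": "β (12–35 Hz)",
    "gamma": "γ (35–70 Hz)",
    "hgamma": "Γ (70–140 Hz)",
}
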