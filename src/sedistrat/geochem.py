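"""Companion geochemical and biomass metrics.

Covers the bulk-sediment quantities that accompany the community profiles:
stable-isotope delta notation (per mil vs VPDB for carbon, vs atmospheric
N2 for nitrogen), elemental C:N and nucleic-acid DNA:RNA ratios with
explicit below-detection handling, and the branched fatty acid (BrFA) sum
used as a living-bacterial-biomass biomarker in phospholipid fatty acid
(PLFA) profiles.

Below-detection values are a dedicated missing state: they propagate as
NaN through every ratio, never as zero or infinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: the seven iso/anteiso branched fatty acids summed as bacterial biomass proxy
BRFA_NAMES = ("i14:0", "i15:0", "a15:0", "i16:0", "i17:0", "a17:0", "i18:0")

_PROFILE_COLUMNS = ("layer_top_cm", "layer_bottom_cm", "analyte", "value", "below_detection")


def delta_notation(r_sample, r_standard) -> float | np.ndarray:
    """Isotope delta value in per mil: ``[(R_sample/R_standard) - 1] * 10^3``.

    ``r_standard`` must be positive (e.g. the VPDB 13C/12C ratio);
    ``r_sample`` must be non-negative. Accepts scalars or arrays.
    """
    r_sample = np.asarray(r_sample, dtype=float)
    r_standard = np.asarray(r_standard, dtype=float)
    if np.any(r_standard <= 0):
        raise ValueError("r_standard must be positive")
    if np.any(r_sample < 0):
        raise ValueError("r_sample must be non-negative")
    out = (r_sample / r_standard - 1.0) * 1e3
    return float(out) if out.ndim == 0 else out


def ratio_metric(
    numerator: float,
    denominator: float,
    *,
    numerator_below_detection: bool = False,
    denominator_below_detection: bool = False,
) -> float:
    """A ratio such as C:N or DNA:RNA with detection-limit semantics.

    Returns NaN (missing) when either input is below its detection limit
    or the denominator is zero/missing — never 0 and never infinity.
    """
    if numerator_below_detection or denominator_below_detection:
        return float("nan")
    if denominator is None or not np.isfinite(denominator) or denominator == 0:
        return float("nan")
    if numerator is None or not np.isfinite(numerator):
        return float("nan")
    return float(numerator) / float(denominator)


def brfa_sum(plfa) -> float:
    """Sum the seven branched fatty acids (µg/g dw) from a named PLFA profile.

    ``plfa`` maps fatty-acid names in the iX:Y / aX:Y nomenclature to
    abundances. Non-BrFA keys are ignored; BrFA names absent from the
    profile contribute zero with a warning. Negative abundances are errors.
    """
    items = dict(plfa)
    for name, value in items.items():
        if value < 0:
            raise ValueError(f"negative abundance for {name!r}: {value}")
    missing = [name for name in BRFA_NAMES if name not in items]
    if missing:
        warnings.warn(f"BrFA components absent from profile: {missing}", stacklevel=2)
    return float(sum(items.get(name, 0.0) for name in BRFA_NAMES))


@dataclass
class GeochemProfile:
    """Tidy per-layer analyte table with below-detection flags.

    Rows: layer_top_cm, layer_bottom_cm, analyte, value, below_detection.
    Below-detection rows carry ``value`` NaN and the flag True.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PROFILE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"geochem profile missing columns: {missing}")
        flagged = self.data["below_detection"].astype(bool)
        if self.data.loc[flagged, "value"].notna().any():
            raise ValueError("below-detection rows must not carry a numeric value")

    @classmethod
    def from_tsv(cls, path) -> "GeochemProfile":
        df = pd.read_csv(path, sep="\t")
        df["below_detection"] = df["below_detection"].astype(bool)
        df.loc[df["below_detection"], "value"] = np.nan
        return cls(df)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def analyte(self, name: str) -> pd.DataFrame:
        """One analyte's per-layer values (NaN where below detection)."""
        sub = self.data[self.data["analyte"] == name]
        out = sub[["layer_top_cm", "layer_bottom_cm", "value", "below_detection"]].copy()
        out["layer_mid_cm"] = 0.5 * (out["layer_top_cm"] + out["layer_bottom_cm"])
        return out.set_index(["layer_top_cm", "layer_bottom_cm"]).sort_index()

    def ratio_profile(self, numerator: str, denominator: str) -> pd.DataFrame:
        """Per-layer ratio of two analytes with detection-limit propagation."""
        num = self.analyte(numerator)
        den = self.analyte(denominator)
        idx = num.index.intersection(den.index)
        rows = []
        for key in idx:
            n, d = num.loc[key], den.loc[key]
            rows.append(
                {
                    "layer_top_cm": key[0],
                    "layer_bottom_cm": key[1],
                    "layer_mid_cm": 0.5 * (key[0] + key[1]),
                    "value": ratio_metric(
                        n["value"],
                        d["value"],
                        numerator_below_detection=bool(n["below_detection"]),
                        denominator_below_detection=bool(d["below_detection"]),
                    ),
                }
            )
        return pd.DataFrame(rows).sort_values("layer_top_cm").reset_index(drop=True)
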