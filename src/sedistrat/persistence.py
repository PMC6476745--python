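"""Surface-OTU survival curves and persisting-OTU statistics.

If deep sediment communities assemble by selective survival, the OTUs
observed at depth should be a nested subset of the surface community: few
OTUs remain continuously present from the surface down ("persisting"
OTUs), yet those few carry a large share of the reads at every depth.

The survival curve counts, at each layer, the surface OTUs present at
every layer from the surface down to that layer (a cumulative
intersection, so the value at the deepest layer equals the size of the
persisting set). :func:`persistence_fractions` reports the persisting
set's share of each layer's richness and of each layer's summed relative
abundance, plus min--max ranges across layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layers import LayerSeries


def _as_frame(series) -> pd.DataFrame:
    return series.values if isinstance(series, LayerSeries) else series


def presence(series, threshold: float = 0.0) -> pd.DataFrame:
    """OTU x layer boolean presence matrix.

    An OTU is present in a layer when its core-averaged relative abundance
    exceeds ``threshold`` (default 0: one read in one replicate core
    suffices). Missing layers (NaN) count as absent.
    """
    frame = _as_frame(series)
    return frame.gt(threshold).fillna(False).astype(bool)


def survival_curve(pm: pd.DataFrame) -> pd.Series:
    """Count of surface OTUs continuously present from the surface to each layer.

    Layers must be ordered shallow to deep. The first value is the surface
    richness; the last equals the number of persisting OTUs.
    """
    if pm.shape[1] == 0:
        raise ValueError("presence matrix needs at least one layer")
    cumulative = np.cumprod(pm.to_numpy(dtype=bool), axis=1)
    curve = pd.Series(cumulative.sum(axis=0), index=pm.columns, name="n_surviving")
    assert (np.diff(curve.to_numpy()) <= 0).all(), "survival curve must be non-increasing"
    assert curve.iloc[-1] == int(cumulative[:, -1].sum())
    return curve


def persisting_otus(pm: pd.DataFrame) -> pd.Index:
    """OTUs present in every layer from top to bottom."""
    return pm.index[pm.all(axis=1)]


@dataclass
class PersistenceResult:
    """Survival curve, persisting set and per-layer persisting fractions."""

    survival_curve: pd.Series
    persisting_ids: tuple
    richness_fraction: pd.Series
    abundance_fraction: pd.Series
    richness_range: tuple[float, float]
    abundance_range: tuple[float, float]

    def summary_frame(self, layer_mid_cm=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "n_surviving": self.survival_curve,
                "richness_fraction": self.richness_fraction,
                "abundance_fraction": self.abundance_fraction,
            }
        )
        if layer_mid_cm is not None:
            df.insert(0, "layer_mid_cm", np.asarray(layer_mid_cm))
        df.index.name = "layer"
        return df


def persistence_fractions(pm: pd.DataFrame, series) -> PersistenceResult:
    """Persisting-OTU share of each layer's richness and read abundance.

    ``richness_fraction`` is |persisting ∩ present(layer)| / |present(layer)|
    and ``abundance_fraction`` the persisting OTUs' share of the layer's
    summed relative abundance. Layers with no present OTU yield NaN. The
    reported ranges are min--max across layers.
    """
    frame = _as_frame(series)
    if not pm.index.equals(frame.index) or not pm.columns.equals(frame.columns):
        raise ValueError("presence matrix and series must share OTU and layer axes")
    curve = survival_curve(pm)
    persisting = persisting_otus(pm)
    assert curve.iloc[-1] == len(persisting)

    present_counts = pm.sum(axis=0).astype(float)
    n_persist = float(len(persisting))
    with np.errstate(invalid="ignore", divide="ignore"):
        richness = (n_persist / present_counts).where(present_counts > 0, np.nan)

    values = frame.fillna(0.0).clip(lower=0.0)
    totals = values.sum(axis=0)
    persist_sum = values.loc[persisting].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        abundance = (persist_sum / totals).where(totals > 0, np.nan)

    def _range(s: pd.Series) -> tuple[float, float]:
        vals = s.dropna()
        if vals.empty:
            return (float("nan"), float("nan"))
        return (float(vals.min()), float(vals.max()))

    return PersistenceResult(
        survival_curve=curve,
        persisting_ids=tuple(persisting),
        richness_fraction=richness.rename("richness_fraction"),
        abundance_fraction=abundance.rename("abundance_fraction"),
        richness_range=_range(richness),
        abundance_range=_range(abundance),
    )
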