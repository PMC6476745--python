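"""Depth-layer schemes, replicate-core averaging and rebinning.

A :class:`LayerScheme` is an ordered list of non-overlapping
``[top_cm, bottom_cm)`` depth bins (gaps are allowed: the study design this
package targets skips the 15--16 cm layer). A :class:`LayerSeries` holds
per-layer, core-averaged values for a set of features (typically OTU
relative abundances), together with the average deviation across replicate
cores and the number of cores contributing per layer.

Averaging operates on relative abundances rather than raw counts, because
replicate cores are rarefied independently; this makes replicate averaging
and rebinning commute with normalisation.

:func:`rebin` maps one layering scheme onto another by thickness-weighted
averaging of the overlapping source bins. When the source bins covering a
target bin are equally thick this reduces to a plain mean — e.g. a fine
0--1 / 1--2 cm pair averaged onto a coarse 0--2 cm bin — which is how an
archaeal fine layering is re-expressed on a coarser bacterial layering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RelAbundTable


def _bin_label(top: float, bottom: float) -> str:
    def fmt(x: float) -> str:
        return f"{x:g}"

    return f"{fmt(top)}-{fmt(bottom)}"


@dataclass(frozen=True)
class LayerScheme:
    """Ordered, non-overlapping depth bins in cm below the interface."""

    bins: tuple[tuple[float, float], ...]

    def __init__(self, bins: Sequence[Sequence[float]]):
        norm = tuple((float(t), float(b)) for t, b in bins)
        for top, bottom in norm:
            if not top < bottom:
                raise ValueError(f"bin [{top}, {bottom}): top must be < bottom")
        for (t0, b0), (t1, _) in zip(norm, norm[1:]):
            if t1 < b0:
                raise ValueError(
                    f"bins [{t0}, {b0}) and starting at {t1} overlap or are unsorted"
                )
        object.__setattr__(self, "bins", norm)

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    @property
    def labels(self) -> list[str]:
        return [_bin_label(t, b) for t, b in self.bins]

    @property
    def midpoints(self) -> np.ndarray:
        """Representative depth of each bin: the interval midpoint."""
        return np.array([0.5 * (t + b) for t, b in self.bins])

    def locate(self, midpoint_cm: float) -> int:
        """Index of the bin whose ``[top, bottom)`` interval contains a depth."""
        for i, (top, bottom) in enumerate(self.bins):
            if top <= midpoint_cm < bottom:
                return i
        raise KeyError(f"depth {midpoint_cm} cm falls in no bin of the scheme")


#: the coarse pooled layering of the target study design
BACTERIAL_LAYERS = LayerScheme(
    [(0, 2), (2, 4), (4, 6), (6, 8), (8, 10), (10, 12), (12, 15), (16, 18), (18, 20), (20, 26)]
)

#: the fine 1-cm layering (15--16 cm unsampled) plus 2-cm bins below 20 cm
ARCHAEAL_LAYERS = LayerScheme(
    [(i, i + 1) for i in range(20) if i != 15] + [(20, 22), (22, 24), (24, 26)]
)

SCHEME_PRESETS: dict[str, LayerScheme] = {
    "bacterial": BACTERIAL_LAYERS,
    "archaeal": ARCHAEAL_LAYERS,
}


@dataclass
class LayerSeries:
    """Feature x layer matrix of core-averaged values on a named scheme.

    ``dispersion`` is the average deviation (mean absolute deviation from
    the mean) across replicate cores, elementwise; it is zero wherever a
    single core contributed. Layers covered by no core hold NaN and
    ``n_cores`` 0 — missing data propagate as missing, never as zero.
    """

    scheme: LayerScheme
    values: pd.DataFrame
    dispersion: pd.DataFrame
    n_cores: pd.Series

    def __post_init__(self) -> None:
        expected = self.scheme.labels
        if list(self.values.columns) != expected:
            raise ValueError("values columns must equal the scheme labels")
        if list(self.dispersion.columns) != expected:
            raise ValueError("dispersion columns must equal the scheme labels")
        disp = self.dispersion.to_numpy()
        if np.any(disp[np.isfinite(disp)] < 0):
            raise ValueError("dispersion must be non-negative")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    def layer_midpoints(self) -> np.ndarray:
        return self.scheme.midpoints


def average_replicates(
    core_values: Mapping[str, pd.DataFrame], scheme: LayerScheme
) -> LayerSeries:
    """Average per-core feature x layer matrices into one :class:`LayerSeries`.

    Each value of ``core_values`` maps a core id to a DataFrame whose
    columns are (a subset of) the scheme's bin labels. Layers missing from
    a core are averaged over the cores that do provide them; layers covered
    by no core are flagged missing (NaN), not zero.
    """
    if not core_values:
        raise ValueError("no cores supplied")
    labels = scheme.labels
    features = pd.Index([])
    for df in core_values.values():
        unknown = [c for c in df.columns if c not in labels]
        if unknown:
            raise ValueError(f"core provides layers outside the scheme: {unknown}")
        features = features.union(df.index, sort=False)

    mean = pd.DataFrame(np.nan, index=features, columns=labels)
    disp = pd.DataFrame(np.nan, index=features, columns=labels)
    n_cores = pd.Series(0, index=labels, dtype=int)
    for label in labels:
        cols = [
            df[label].reindex(features)
            for df in core_values.values()
            if label in df.columns
        ]
        if not cols:
            continue
        stack = pd.concat(cols, axis=1).to_numpy(dtype=float)
        m = stack.mean(axis=1)
        mean[label] = m
        disp[label] = np.abs(stack - m[:, None]).mean(axis=1)
        n_cores[label] = stack.shape[1]
    return LayerSeries(scheme=scheme, values=mean, dispersion=disp, n_cores=n_cores)


def series_from_relabund(
    rel: RelAbundTable, scheme: LayerScheme, domain_tag: str | None = None
) -> LayerSeries:
    """Build a core-averaged :class:`LayerSeries` from per-sample abundances.

    Each sample is assigned to the scheme bin containing its depth-interval
    midpoint; a core may supply at most one sample per bin.
    """
    samples = rel.samples
    if domain_tag is not None:
        samples = [s for s in samples if s.domain_tag == domain_tag]
    if not samples:
        raise ValueError("no samples to average (check domain_tag)")
    per_core: dict[str, dict[str, str]] = {}
    labels = scheme.labels
    for s in samples:
        label = labels[scheme.locate(s.midpoint_cm)]
        bins = per_core.setdefault(s.core_id, {})
        if label in bins:
            raise ValueError(
                f"core {s.core_id!r} supplies two samples for layer {label}: "
                f"{bins[label]!r} and {s.sample_id!r}"
            )
        bins[label] = s.sample_id
    core_frames = {
        core: rel.values[[sid for sid in mapping.values()]].set_axis(
            list(mapping.keys()), axis=1
        )
        for core, mapping in per_core.items()
    }
    return average_replicates(core_frames, scheme)


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Length of the intersection of two ``[top, bottom)`` intervals."""
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def rebin(series: LayerSeries, target: LayerScheme) -> LayerSeries:
    """Re-express a layer series on another scheme.

    Every target bin receives the thickness-weighted mean of the source
    bins overlapping it (weights are overlap lengths on ``[top, bottom)``
    intervals). Equal-thickness source bins fully inside a target bin
    therefore contribute a plain average. Target bins with no overlapping
    source data are flagged missing.
    """
    src_bins = series.scheme.bins
    values = series.values.to_numpy(dtype=float)
    disp = series.dispersion.to_numpy(dtype=float)
    out_v = pd.DataFrame(np.nan, index=series.features, columns=target.labels)
    out_d = pd.DataFrame(np.nan, index=series.features, columns=target.labels)
    out_n = pd.Series(0, index=target.labels, dtype=int)
    for j, tbin in enumerate(target.bins):
        w = np.array([_overlap(sbin, tbin) for sbin in src_bins])
        if not (w > 0).any():
            continue
        label = target.labels[j]
        # per-feature weighted mean over sources with data (NaN-aware)
        vmask = np.isfinite(values) & (w[None, :] > 0)
        weights = np.where(vmask, w[None, :], 0.0)
        denom = weights.sum(axis=1)
        num = (np.where(vmask, np.nan_to_num(values), 0.0) * weights).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out_v[label] = np.where(denom > 0, num / np.where(denom > 0, denom, 1), np.nan)
        dmask = np.isfinite(disp) & (w[None, :] > 0)
        dweights = np.where(dmask, w[None, :], 0.0)
        ddenom = dweights.sum(axis=1)
        dnum = (np.where(dmask, np.nan_to_num(disp), 0.0) * dweights).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out_d[label] = np.where(ddenom > 0, dnum / np.where(ddenom > 0, ddenom, 1), np.nan)
        contributing = series.n_cores.to_numpy()[w > 0]
        out_n[label] = int(contributing.min()) if len(contributing) else 0
    return LayerSeries(scheme=target, values=out_v, dispersion=out_d, n_cores=out_n)
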