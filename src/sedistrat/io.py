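"""OTU-table data model and I/O for depth-stratified amplicon surveys.

The central container is :class:`OtuTable`: an integer count matrix
(OTU x sample) carrying one taxonomic lineage per OTU and one
:class:`SampleMeta` record per sample (core identity plus the depth
interval, in cm below the water--sediment interface, that the sample
represents).

Supported on-disk dialects:

* generic TSV (OTUs as rows, samples as columns, optional trailing
  ``lineage`` column) plus a sample-metadata TSV;
* mothur ``.shared`` + ``.cons.taxonomy`` pairs, plus the metadata TSV;
* BIOM 1.0 JSON (dense or sparse), plus the metadata TSV.

Library-size normalisation follows common amplicon practice: OTUs whose
total count across the whole table is one are dropped
(:func:`remove_singletons`), then every sample is subsampled without
replacement to a common depth (:func:`rarefy`).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DOMAIN_TAGS = ("archaea", "bacteria")

UNCLASSIFIED = "unclassified"


class TableParseError(ValueError):
    """Raised when an input file violates the declared dialect."""


@dataclass(frozen=True)
class SampleMeta:
    """Provenance of one sequencing library.

    Depths are in cm below the water--sediment interface (0 cm at the
    interface); ``layer_top_cm < layer_bottom_cm`` is enforced.
    """

    sample_id: str
    core_id: str
    layer_top_cm: float
    layer_bottom_cm: float
    domain_tag: str = "bacteria"

    def __post_init__(self) -> None:
        if not (0.0 <= self.layer_top_cm < self.layer_bottom_cm):
            raise ValueError(
                f"sample {self.sample_id!r}: need 0 <= top < bottom, got "
                f"[{self.layer_top_cm}, {self.layer_bottom_cm}]"
            )
        if self.domain_tag not in DOMAIN_TAGS:
            raise ValueError(
                f"sample {self.sample_id!r}: domain_tag must be one of "
                f"{DOMAIN_TAGS}, got {self.domain_tag!r}"
            )

    @property
    def midpoint_cm(self) -> float:
        return 0.5 * (self.layer_top_cm + self.layer_bottom_cm)


def _check_axis_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise TableParseError(f"duplicate {what}: {dupes}")


@dataclass
class OtuTable:
    """Integer OTU x sample count matrix with lineages and sample metadata."""

    counts: pd.DataFrame
    lineages: pd.Series
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        _check_axis_unique(self.counts.index, "OTU ids")
        _check_axis_unique(self.counts.columns, "sample ids")
        self.counts.index.name = None
        self.counts.columns.name = None
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise TableParseError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if values.size and self.counts.to_numpy().min() < 0:
            raise TableParseError("counts must be non-negative")
        # every OTU carries a lineage; absent entries degrade to "unclassified"
        self.lineages = (
            pd.Series(self.lineages, dtype=object)
            .reindex(self.counts.index)
            .fillna(UNCLASSIFIED)
            .rename(None)
        )
        self.lineages.index.name = None
        by_id = {s.sample_id: s for s in self.samples}
        if len(by_id) != len(self.samples):
            raise TableParseError("duplicate sample metadata records")
        missing = [c for c in self.counts.columns if c not in by_id]
        if missing:
            raise TableParseError(f"samples without metadata: {missing}")
        self.samples = [by_id[c] for c in self.counts.columns]

    # -- convenience accessors -------------------------------------------
    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def sample(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def totals(self) -> pd.Series:
        """Library size per sample."""
        return self.counts.sum(axis=0)

    def select_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        idx = pd.Index(otu_ids)
        return OtuTable(
            counts=self.counts.loc[idx].copy(),
            lineages=self.lineages.loc[idx].copy(),
            samples=list(self.samples),
        )

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "core_id": [s.core_id for s in self.samples],
                "top_cm": [s.layer_top_cm for s in self.samples],
                "bottom_cm": [s.layer_bottom_cm for s in self.samples],
                "domain_tag": [s.domain_tag for s in self.samples],
            }
        )


@dataclass
class RelAbundTable:
    """Column-normalised companion of :class:`OtuTable`.

    Each sample column sums to 1 unless the sample had zero reads, in
    which case the column is all-zero and listed in ``empty_samples``.
    """

    values: pd.DataFrame
    lineages: pd.Series
    samples: list[SampleMeta]
    empty_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=0)
        for sid, total in sums.items():
            if sid in self.empty_samples:
                continue
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"sample {sid!r} does not sum to 1: {total}")


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs whose total count across all samples equals one.

    This is the dataset-wide singleton definition used by mothur's
    pipeline; it is applied before rarefaction by default.
    """
    keep = table.counts.sum(axis=1) != 1
    if not keep.any():
        warnings.warn("all OTUs were singletons; result is empty", stacklevel=2)
    return OtuTable(
        counts=table.counts.loc[keep].copy(),
        lineages=table.lineages.loc[keep].copy(),
        samples=list(table.samples),
    )


def subsample_counts(
    counts: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Subsample one count vector without replacement to ``depth`` reads.

    Draws from the multivariate hypergeometric distribution, i.e. each of
    the ``depth`` retained reads is taken from the original pool without
    replacement, so per-OTU results never exceed the input counts.
    """
    counts = np.asarray(counts)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"requested depth {depth} exceeds sample total {total}")
    if depth == total:
        return counts.astype(np.int64, copy=True)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def rarefy(table: OtuTable, depth: int | None = None, seed=None) -> OtuTable:
    """Subsample every sample to a common depth, without replacement.

    ``depth`` defaults to the smallest library size in the table. A single
    draw is made per sample (no averaging over repeated draws); the draw is
    reproducible for a fixed ``seed``.
    """
    totals = table.totals()
    if depth is None:
        depth = int(totals.min())
    undersized = totals[totals < depth]
    if len(undersized):
        raise ValueError(
            "samples smaller than requested depth "
            f"{depth}: {dict(undersized)}"
        )
    rng = np.random.default_rng(seed)
    out = {
        sid: subsample_counts(table.counts[sid].to_numpy(), depth, rng)
        for sid in table.sample_ids
    }
    counts = pd.DataFrame(out, index=table.otu_ids, columns=table.sample_ids)
    return OtuTable(counts=counts, lineages=table.lineages.copy(), samples=list(table.samples))


def goods_coverage(sample_counts) -> float:
    """Good's coverage ``1 - F1/N`` of one sample.

    ``F1`` is the number of OTUs observed exactly once and ``N`` the total
    read count. An all-zero sample has no defined coverage and yields NaN.
    """
    counts = np.asarray(sample_counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    if n == 0:
        return float("nan")
    f1 = int((counts == 1).sum())
    return 1.0 - f1 / n


def to_relative(table: OtuTable) -> RelAbundTable:
    """Convert counts to per-sample relative abundances.

    All-zero samples are kept as all-zero columns and flagged in
    ``empty_samples`` rather than producing NaN.
    """
    totals = table.totals()
    empty = tuple(totals.index[totals == 0])
    safe = totals.replace(0, 1)
    values = table.counts.astype(float).div(safe, axis=1)
    return RelAbundTable(
        values=values,
        lineages=table.lineages.copy(),
        samples=list(table.samples),
        empty_samples=empty,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = ("sample_id", "core_id", "top_cm", "bottom_cm", "domain_tag")


def read_metadata(path) -> dict[str, SampleMeta]:
    """Read the sample-metadata TSV (sample_id, core_id, top_cm, bottom_cm, domain_tag)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "core_id": str})
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(f"metadata file {path}: missing columns {missing}")
    metas: dict[str, SampleMeta] = {}
    for rec in df.itertuples(index=False):
        if rec.sample_id in metas:
            raise TableParseError(f"metadata file {path}: duplicate sample {rec.sample_id!r}")
        metas[rec.sample_id] = SampleMeta(
            sample_id=rec.sample_id,
            core_id=rec.core_id,
            layer_top_cm=float(rec.top_cm),
            layer_bottom_cm=float(rec.bottom_cm),
            domain_tag=rec.domain_tag,
        )
    return metas


def _attach_metadata(
    counts: pd.DataFrame, lineages: pd.Series, metadata: Mapping[str, SampleMeta]
) -> OtuTable:
    missing = [c for c in counts.columns if c not in metadata]
    if missing:
        raise TableParseError(f"samples absent from metadata: {missing}")
    samples = [metadata[c] for c in counts.columns]
    return OtuTable(counts=counts, lineages=lineages, samples=samples)


_BOOTSTRAP = re.compile(r"\(\d+(\.\d+)?\)")


def parse_lineage_string(raw: str) -> str:
    """Normalise a taxonomy string: strip bootstrap values and empty tail ranks."""
    cleaned = _BOOTSTRAP.sub("", str(raw)).strip().strip(";")
    tokens = [t.strip().strip('"') for t in cleaned.split(";")]
    tokens = [t for t in tokens if t]
    return ";".join(tokens) if tokens else UNCLASSIFIED


def _read_generic_tsv(path, metadata: Mapping[str, SampleMeta]) -> OtuTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise TableParseError(f"{path}: duplicate OTU ids {dupes}")
    if "lineage" in df.columns:
        lineages = df.pop("lineage").map(parse_lineage_string)
    else:
        lineages = pd.Series(UNCLASSIFIED, index=df.index, dtype=object)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise TableParseError(f"{path}: non-numeric counts in sample {col!r}") from exc
    arr = df.to_numpy()
    if np.any(arr != np.floor(arr)) or np.any(arr < 0):
        bad = df.columns[np.where((arr != np.floor(arr)) | (arr < 0))[1][0]]
        raise TableParseError(f"{path}: negative or non-integer counts in sample {bad!r}")
    return _attach_metadata(df.astype(np.int64), lineages, metadata)


def _read_mothur_shared(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"label", "Group", "numOtus"}
    if not required.issubset(df.columns):
        raise TableParseError(
            f"{path}: not a mothur shared file (need columns {sorted(required)})"
        )
    if df["Group"].duplicated().any():
        dupes = df.loc[df["Group"].duplicated(), "Group"].tolist()
        raise TableParseError(f"{path}: duplicate Group records {dupes}")
    otu_cols = [c for c in df.columns if c not in required]
    counts = df.set_index("Group")[otu_cols].T  # -> OTU x sample
    counts.index.name = "otu_id"
    arr = counts.to_numpy()
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise TableParseError(f"{path}: negative or non-integer counts")
    return counts.astype(np.int64)


def _read_mothur_taxonomy(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if "OTU" not in df.columns or "Taxonomy" not in df.columns:
        raise TableParseError(f"{path}: not a cons.taxonomy file (need OTU and Taxonomy)")
    if df["OTU"].duplicated().any():
        raise TableParseError(f"{path}: duplicate OTU records")
    return pd.Series(
        df["Taxonomy"].map(parse_lineage_string).to_numpy(),
        index=df["OTU"].to_numpy(),
        dtype=object,
    )


def _read_biom_json(path, metadata: Mapping[str, SampleMeta]) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        shape = doc["shape"]
        matrix_type = doc["matrix_type"]
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise TableParseError(f"{path}: not a BIOM 1.0 JSON table ({exc})") from exc
    if shape != [len(rows), len(cols)]:
        raise TableParseError(f"{path}: shape {shape} disagrees with axes")
    mat = np.zeros((len(rows), len(cols)))
    if matrix_type == "dense":
        mat[:] = np.asarray(data)
    elif matrix_type == "sparse":
        for r, c, v in data:
            mat[int(r), int(c)] = v
    else:
        raise TableParseError(f"{path}: unknown matrix_type {matrix_type!r}")
    if np.any(mat < 0) or np.any(mat != np.floor(mat)):
        raise TableParseError(f"{path}: negative or non-integer counts")
    lineages = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy")
        lineages[r["id"]] = (
            parse_lineage_string(";".join(tax)) if tax else UNCLASSIFIED
        )
    counts = pd.DataFrame(mat.astype(np.int64), index=rows, columns=cols)
    return _attach_metadata(counts, pd.Series(lineages), metadata)


def read_table(
    path,
    fmt: str = "tsv",
    *,
    taxonomy=None,
    metadata=None,
) -> OtuTable:
    """Read an OTU table in one of the supported dialects.

    Parameters
    ----------
    path :
        Count-table file (TSV, mothur ``.shared``, or BIOM 1.0 JSON).
    fmt :
        ``"tsv"``, ``"mothur"`` or ``"biom"``.
    taxonomy :
        mothur ``.cons.taxonomy`` path (required for ``fmt="mothur"``).
    metadata :
        Sample-metadata TSV path or a pre-parsed ``{sample_id: SampleMeta}``
        mapping; required for every dialect because none of them encodes
        core identity or depth intervals.
    """
    if metadata is None:
        raise TableParseError("a sample-metadata TSV (or mapping) is required")
    metas = metadata if isinstance(metadata, Mapping) else read_metadata(metadata)
    if fmt == "tsv":
        return _read_generic_tsv(path, metas)
    if fmt == "mothur":
        if taxonomy is None:
            raise TableParseError("mothur format needs a cons.taxonomy file")
        counts = _read_mothur_shared(path)
        lineages = _read_mothur_taxonomy(taxonomy).reindex(counts.index)
        return _attach_metadata(counts, lineages, metas)
    if fmt == "biom":
        return _read_biom_json(path, metas)
    raise TableParseError(f"unknown format {fmt!r}")


def write_metadata(samples: Sequence[SampleMeta], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "core_id": [s.core_id for s in samples],
            "top_cm": [s.layer_top_cm for s in samples],
            "bottom_cm": [s.layer_bottom_cm for s in samples],
            "domain_tag": [s.domain_tag for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_tsv(table: OtuTable, path, metadata_path=None) -> None:
    """Write the generic TSV dialect (and optionally the metadata TSV)."""
    df = table.counts.copy()
    df["lineage"] = table.lineages
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")
    if metadata_path is not None:
        write_metadata(table.samples, metadata_path)


def write_mothur(table: OtuTable, shared_path, taxonomy_path, label: str = "0.03") -> None:
    """Write mothur ``.shared`` + ``.cons.taxonomy`` files."""
    wide = table.counts.T  # sample x OTU
    out = pd.DataFrame(
        {"label": label, "Group": wide.index, "numOtus": wide.shape[1]}
    )
    out = pd.concat([out.reset_index(drop=True), wide.reset_index(drop=True)], axis=1)
    out.to_csv(shared_path, sep="\t", index=False)
    tax = pd.DataFrame(
        {
            "OTU": table.otu_ids,
            "Size": table.counts.sum(axis=1).to_numpy(),
            "Taxonomy": [f"{lin};" for lin in table.lineages],
        }
    )
    tax.to_csv(taxonomy_path, sep="\t", index=False)
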