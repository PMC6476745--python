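"""Synthetic depth-stratified sediment communities with known ground truth.

The generator emulates a two-core, two-domain (archaea/bacteria) 16S survey
of a sediment core: a lognormal surface rank-abundance distribution, a
small persistent cohort that decays slowly with depth while the transient
majority decays fast (``selective_survival``), or an alternative neutral
model in which identities are randomly replaced layer by layer
(``neutral_turnover``). Replicate cores are perturbed with a
Dirichlet-style overdispersion of the true composition before multinomial
read sampling at fixed library sizes, and the archaeal and bacterial
tables are emitted on different layering schemes (fine 1-cm archaeal bins
vs coarse pooled bacterial bins) so that rebinning is exercised end to end.

Ground truth (per-OTU persistence class, decay rate, lineage and surface
abundance) is retained in :class:`SyntheticTruth` so that recovery of the
persistent cohort by the analysis pipeline can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .geochem import GeochemProfile
from .io import OtuTable, SampleMeta, write_metadata, write_mothur, write_tsv
from .layers import ARCHAEAL_LAYERS, BACTERIAL_LAYERS, LayerScheme

AssemblyModel = Literal["selective_survival", "neutral_turnover"]

# Lineage vocabularies. Persistent OTUs are preferentially assigned
# deep-sediment taxa (poorly-known candidate phyla plus the acetoclastic
# methanogens that persist at depth); transients are enriched in
# surface-water-derived groups.
ARCHAEAL_DEEP_LINEAGES = (
    "Archaea;Bathyarchaeota;unclassified;unclassified;unclassified;unclassified",
    "Archaea;Woesearchaeota;unclassified;unclassified;unclassified;unclassified",
    "Archaea;Aenigmarchaeota;unclassified;unclassified;unclassified;unclassified",
    "Archaea;Hadesarchaea;unclassified;unclassified;unclassified;unclassified",
    "Archaea;Euryarchaeota;Thermoplasmata;unclassified;unclassified;unclassified",
    "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosaetaceae;Methanosaeta",
    "Archaea;unclassified;unclassified;unclassified;unclassified;unclassified",
)
ARCHAEAL_SURFACE_LINEAGES = (
    "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosaetaceae;Methanosaeta",
    "Archaea;Euryarchaeota;Methanomicrobia;Methanomicrobiales;Methanoregulaceae;Methanoregula",
    "Archaea;Euryarchaeota;Methanobacteria;Methanobacteriales;Methanobacteriaceae;Methanobacterium",
    "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosarcinaceae;Methanosarcina",
    "Archaea;Thaumarchaeota;unclassified;unclassified;unclassified;unclassified",
    "Archaea;Woesearchaeota;unclassified;unclassified;unclassified;unclassified",
)
BACTERIAL_DEEP_LINEAGES = (
    "Bacteria;Caldiserica;Caldisericia;Caldisericales;Caldisericaceae;unclassified",
    "Bacteria;Aminicenantes;unclassified;unclassified;unclassified;unclassified",
    "Bacteria;Atribacteria;unclassified;unclassified;unclassified;unclassified",
    "Bacteria;Chloroflexi;Dehalococcoidia;unclassified;unclassified;unclassified",
    "Bacteria;Parcubacteria;unclassified;unclassified;unclassified;unclassified",
    "Bacteria;Omnitrophica;unclassified;unclassified;unclassified;unclassified",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Peptostreptococcaceae;unclassified",
    "Bacteria;unclassified;unclassified;unclassified;unclassified;unclassified",
)
BACTERIAL_SURFACE_LINEAGES = (
    "Bacteria;Proteobacteria;Deltaproteobacteria;Syntrophobacterales;Syntrophaceae;Syntrophus",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Methylococcales;Methylococcaceae;Methylobacter",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Methylocystaceae;Methylocystis",
    "Bacteria;Cyanobacteria;Cyanobacteria;SubsectionI;FamilyI;unclassified",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;unclassified;unclassified",
    "Bacteria;Actinobacteria;Actinobacteria;Frankiales;Sporichthyaceae;unclassified",
    "Bacteria;Verrucomicrobia;Verrucomicrobiae;Verrucomicrobiales;Verrucomicrobiaceae;unclassified",
    "Bacteria;Ignavibacteriae;Ignavibacteria;Ignavibacteriales;Ignavibacteriaceae;unclassified",
)

#: probability that a persistent (resp. transient) OTU draws a deep-taxon lineage
DEEP_LINEAGE_PROB = {"persistent": 0.8, "transient": 0.2}


@dataclass(frozen=True)
class DomainParams:
    """Per-domain community and sequencing parameters."""

    n_otus: int
    lognormal_mu: float
    lognormal_sigma: float
    library_size: int
    scheme: LayerScheme

    def __post_init__(self) -> None:
        if self.n_otus < 1 or self.library_size < 1:
            raise ValueError("n_otus and library_size must be >= 1")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")


@dataclass(frozen=True)
class SimParams:
    """Defaults emulate the target study design: two replicate cores, a
    26-cm core with fine archaeal and coarse bacterial layering, library
    sizes of 1239 (archaea) and 11 837 (bacteria) reads per sample, a 10%
    persistent cohort with per-cm decay ~ U(0, 0.05) against transient
    decay ~ U(0.3, 1.0), and a neutral alternative replacing 30% of
    identities per layer transition."""

    archaea: DomainParams = field(
        default_factory=lambda: DomainParams(1200, 0.0, 2.5, 1239, ARCHAEAL_LAYERS)
    )
    bacteria: DomainParams = field(
        default_factory=lambda: DomainParams(15000, 0.0, 2.5, 11837, BACTERIAL_LAYERS)
    )
    assembly_model: AssemblyModel = "selective_survival"
    persistent_fraction: float = 0.10
    persistent_decay_max: float = 0.05  # per cm
    transient_decay_min: float = 0.3  # per cm
    transient_decay_max: float = 1.0  # per cm
    turnover_rate: float = 0.3  # per layer transition
    n_cores: int = 2
    dirichlet_concentration: float = 10000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistent_fraction <= 1.0:
            raise ValueError("persistent_fraction must lie in [0, 1]")
        for rate in (
            self.persistent_decay_max,
            self.transient_decay_min,
            self.transient_decay_max,
            self.turnover_rate,
        ):
            if rate < 0:
                raise ValueError("rates must be non-negative")
        if self.transient_decay_max < self.transient_decay_min:
            raise ValueError("transient decay range inverted")
        if self.n_cores < 1:
            raise ValueError("n_cores must be >= 1")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.assembly_model not in ("selective_survival", "neutral_turnover"):
            raise ValueError(f"unknown assembly model {self.assembly_model!r}")

    def domain(self, name: str) -> DomainParams:
        if name not in ("archaea", "bacteria"):
            raise KeyError(name)
        return getattr(self, name)

    def echo(self) -> dict:
        def dom(d: DomainParams) -> dict:
            return {
                "n_otus": d.n_otus,
                "lognormal_mu": d.lognormal_mu,
                "lognormal_sigma": d.lognormal_sigma,
                "library_size": d.library_size,
                "scheme": [list(b) for b in d.scheme.bins],
            }

        return {
            "archaea": dom(self.archaea),
            "bacteria": dom(self.bacteria),
            "assembly_model": self.assembly_model,
            "persistent_fraction": self.persistent_fraction,
            "persistent_decay_max": self.persistent_decay_max,
            "transient_decay_min": self.transient_decay_min,
            "transient_decay_max": self.transient_decay_max,
            "turnover_rate": self.turnover_rate,
            "n_cores": self.n_cores,
            "dirichlet_concentration": self.dirichlet_concentration,
        }


@dataclass
class SyntheticTruth:
    """Ground truth for one domain: per-OTU class, decay and surface share."""

    domain: str
    otu_ids: list[str]
    lineages: pd.Series
    persistent: pd.Series  # bool
    decay: pd.Series  # per-cm decay rate; NaN for neutral replacements
    raw_weights: pd.Series  # unnormalised lognormal weights
    surface: pd.Series  # surface composition, sums to 1

    def __post_init__(self) -> None:
        total = float(self.surface.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"surface composition sums to {total}, not 1")


def _draw_lineages(rng: np.random.Generator, persistent: np.ndarray, domain: str) -> list[str]:
    deep, surf = (
        (ARCHAEAL_DEEP_LINEAGES, ARCHAEAL_SURFACE_LINEAGES)
        if domain == "archaea"
        else (BACTERIAL_DEEP_LINEAGES, BACTERIAL_SURFACE_LINEAGES)
    )
    out = []
    for is_persistent in persistent:
        p_deep = DEEP_LINEAGE_PROB["persistent" if is_persistent else "transient"]
        pool = deep if rng.random() < p_deep else surf
        out.append(pool[rng.integers(len(pool))])
    return out


def generate_surface(params: SimParams, domain: str, rng: np.random.Generator) -> SyntheticTruth:
    """Draw the true surface community for one domain.

    Abundances come from the stated lognormal rank-abundance distribution
    (normalised); each OTU is persistent with ``persistent_fraction``
    probability; per-cm decay rates are uniform on [0, persistent_decay_max]
    for persistent OTUs and [transient_decay_min, transient_decay_max] for
    transients; lineages are drawn from the domain vocabulary with
    persistent OTUs enriched in deep-sediment taxa.
    """
    dp = params.domain(domain)
    prefix = "A" if domain == "archaea" else "B"
    otu_ids = [f"{prefix}_Otu{i + 1:05d}" for i in range(dp.n_otus)]
    weights = rng.lognormal(dp.lognormal_mu, dp.lognormal_sigma, size=dp.n_otus)
    persistent = rng.random(dp.n_otus) < params.persistent_fraction
    decay = np.where(
        persistent,
        rng.uniform(0.0, params.persistent_decay_max, size=dp.n_otus),
        rng.uniform(params.transient_decay_min, params.transient_decay_max, size=dp.n_otus),
    )
    lineages = _draw_lineages(rng, persistent, domain)
    idx = pd.Index(otu_ids)
    return SyntheticTruth(
        domain=domain,
        otu_ids=otu_ids,
        lineages=pd.Series(lineages, index=idx, dtype=object),
        persistent=pd.Series(persistent, index=idx),
        decay=pd.Series(decay, index=idx),
        raw_weights=pd.Series(weights, index=idx),
        surface=pd.Series(weights / weights.sum(), index=idx),
    )


def propagate_depth(
    truth: SyntheticTruth,
    params: SimParams,
    rng: np.random.Generator | None = None,
    scheme: LayerScheme | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """True per-layer compositions under the chosen assembly model.

    ``selective_survival``: x_i(d) ∝ x_i(0) · exp(-k_i d) at each layer
    midpoint d, renormalised per layer. ``neutral_turnover``: at each layer
    transition every currently present OTU is independently replaced, with
    probability ``turnover_rate``, by a fresh identity whose weight is a
    new draw from the surface lognormal; columns are renormalised. For the
    neutral model the returned truth is extended with the replacement OTUs
    (persistent False, decay NaN, surface share 0).
    """
    dp = params.domain(truth.domain)
    scheme = scheme or dp.scheme
    mids = scheme.midpoints
    if params.assembly_model == "selective_survival":
        surface = truth.surface.to_numpy()
        decay = truth.decay.to_numpy()
        mat = surface[:, None] * np.exp(-decay[:, None] * mids[None, :])
        mat = mat / mat.sum(axis=0, keepdims=True)
        comps = pd.DataFrame(mat, index=truth.surface.index, columns=scheme.labels)
        return comps, truth

    if rng is None:
        raise ValueError("neutral_turnover requires an rng")
    prefix = truth.otu_ids[0].split("_")[0]
    weights = list(truth.raw_weights.to_numpy(dtype=float))
    ids = list(truth.otu_ids)
    lineage_list = list(truth.lineages.to_numpy())
    persistent_list = list(truth.persistent.to_numpy())
    columns: list[np.ndarray] = []
    current = np.array(weights)
    n_novel = 0

    def _normalised(vec: np.ndarray, size: int) -> np.ndarray:
        out = np.zeros(size)
        out[: len(vec)] = vec
        return out

    columns.append(current.copy())
    for _ in range(len(scheme) - 1):
        alive = np.flatnonzero(current > 0)
        replaced = alive[rng.random(len(alive)) < params.turnover_rate]
        current[replaced] = 0.0
        k = len(replaced)
        if k:
            new_flags = np.zeros(k, dtype=bool)
            new_ids = [f"{prefix}_Novel{n_novel + j + 1:05d}" for j in range(k)]
            n_novel += k
            ids.extend(new_ids)
            lineage_list.extend(_draw_lineages(rng, new_flags, truth.domain))
            persistent_list.extend([False] * k)
            current = np.concatenate(
                [current, rng.lognormal(dp.lognormal_mu, dp.lognormal_sigma, size=k)]
            )
        columns.append(current.copy())

    size = len(ids)
    mat = np.column_stack([_normalised(c / c.sum(), size) for c in columns])
    idx = pd.Index(ids)
    comps = pd.DataFrame(mat, index=idx, columns=scheme.labels)
    surface = np.zeros(size)
    surface[: len(truth.otu_ids)] = truth.surface.to_numpy()
    decay = np.full(size, np.nan)
    decay[: len(truth.otu_ids)] = truth.decay.to_numpy()
    raw = np.zeros(size)
    raw[: len(truth.otu_ids)] = truth.raw_weights.to_numpy()
    extended = SyntheticTruth(
        domain=truth.domain,
        otu_ids=ids,
        lineages=pd.Series(lineage_list, index=idx, dtype=object),
        persistent=pd.Series(persistent_list, index=idx),
        decay=pd.Series(decay, index=idx),
        raw_weights=pd.Series(raw, index=idx),
        surface=pd.Series(surface, index=idx),
    )
    return comps, extended


def sample_reads(
    comps: pd.DataFrame,
    truth: SyntheticTruth,
    params: SimParams,
    rng: np.random.Generator,
    scheme: LayerScheme | None = None,
) -> OtuTable:
    """Sequence the true compositions: per core and layer, perturb the
    composition with a Dirichlet overdispersion of concentration
    ``dirichlet_concentration`` and draw ``library_size`` reads
    multinomially. OTUs with zero true abundance in a layer are never
    sampled there."""
    dp = params.domain(truth.domain)
    scheme = scheme or dp.scheme
    prefix = "A" if truth.domain == "archaea" else "B"
    counts = {}
    samples = []
    for core in range(1, params.n_cores + 1):
        core_id = f"core{core}"
        for (top, bottom), label in zip(scheme.bins, scheme.labels):
            p = comps[label].to_numpy(dtype=float)
            support = np.flatnonzero(p > 0)
            alpha = params.dirichlet_concentration * p[support]
            p_core = rng.dirichlet(alpha)
            draw = rng.multinomial(dp.library_size, p_core / p_core.sum())
            col = np.zeros(len(p), dtype=np.int64)
            col[support] = draw
            sample_id = f"{prefix}_{core_id}_{label}"
            counts[sample_id] = col
            samples.append(
                SampleMeta(
                    sample_id=sample_id,
                    core_id=core_id,
                    layer_top_cm=top,
                    layer_bottom_cm=bottom,
                    domain_tag=truth.domain,
                )
            )
    frame = pd.DataFrame(counts, index=comps.index)
    return OtuTable(counts=frame, lineages=truth.lineages.copy(), samples=samples)


# defaults for the biomass/geochemistry emulation: concentrations decay
# exponentially with depth, RNA fastest and BrFA slowest, and RNA crosses
# its detection limit in the deepest layer so DNA:RNA goes missing there.
BIOMASS_DEFAULTS = {
    "dna_surface_ng_g": 50000.0,
    "rna_surface_ng_g": 20000.0,
    "brfa_surface_ug_g": 30.0,
    "dna_decay_per_cm": 0.15,
    "rna_decay_per_cm": 0.35,
    "brfa_decay_per_cm": 0.05,
    "rna_detection_limit_ng_g": 10.0,
    "c_surface_percent": 25.0,
    "n_surface_percent": 1.8,
    "c_decay_per_cm": 0.005,
    "n_decay_per_cm": 0.02,
    "d13c_surface": -28.0,
    "d13c_slope_per_cm": -0.10,
    "d15n_surface": 2.0,
    "d15n_slope_per_cm": 0.08,
}


def generate_biomass(
    params: SimParams,
    rng: np.random.Generator,
    scheme: LayerScheme | None = None,
    noise_sigma: float = 0.15,
    defaults: dict | None = None,
) -> GeochemProfile:
    """Emulated bulk geochemistry on the coarse layering.

    DNA, RNA and BrFA decay exponentially with layer-midpoint depth with
    rate(RNA) > rate(DNA) > rate(BrFA) and multiplicative lognormal noise;
    RNA is truncated at a detection limit so the DNA:RNA ratio goes missing
    at depth. C%, N% decay slowly (C:N rises downcore) and the isotope
    deltas drift linearly (d13C down, d15N up).
    """
    cfg = {**BIOMASS_DEFAULTS, **(defaults or {})}
    scheme = scheme or params.bacteria.scheme
    mids = scheme.midpoints
    noise = lambda n: rng.lognormal(0.0, noise_sigma, size=n) if noise_sigma > 0 else 1.0

    rows = []

    def add(analyte: str, values: np.ndarray, limit: float | None = None) -> None:
        for (top, bottom), v in zip(scheme.bins, values):
            below = limit is not None and v < limit
            rows.append(
                {
                    "layer_top_cm": top,
                    "layer_bottom_cm": bottom,
                    "analyte": analyte,
                    "value": np.nan if below else float(v),
                    "below_detection": below,
                }
            )

    n = len(mids)
    add("DNA", cfg["dna_surface_ng_g"] * np.exp(-cfg["dna_decay_per_cm"] * mids) * noise(n))
    add(
        "RNA",
        cfg["rna_surface_ng_g"] * np.exp(-cfg["rna_decay_per_cm"] * mids) * noise(n),
        limit=cfg["rna_detection_limit_ng_g"],
    )
    add("BrFA", cfg["brfa_surface_ug_g"] * np.exp(-cfg["brfa_decay_per_cm"] * mids) * noise(n))
    add("C_percent", cfg["c_surface_percent"] * np.exp(-cfg["c_decay_per_cm"] * mids) * noise(n))
    add("N_percent", cfg["n_surface_percent"] * np.exp(-cfg["n_decay_per_cm"] * mids) * noise(n))
    delta_noise = (
        rng.normal(0.0, 0.2, size=n) if noise_sigma > 0 else np.zeros(n)
    )
    add("d13C", cfg["d13c_surface"] + cfg["d13c_slope_per_cm"] * mids + delta_noise)
    delta_noise = (
        rng.normal(0.0, 0.2, size=n) if noise_sigma > 0 else np.zeros(n)
    )
    add("d15N", cfg["d15n_surface"] + cfg["d15n_slope_per_cm"] * mids + delta_noise)
    return GeochemProfile(pd.DataFrame(rows))


@dataclass
class SimulationResult:
    """Everything one simulation produced, plus the parameters used."""

    params: SimParams
    seed: int
    truths: dict[str, SyntheticTruth]
    compositions: dict[str, pd.DataFrame]
    tables: dict[str, OtuTable]
    geochem: GeochemProfile


def simulate(
    params: SimParams | None = None,
    seed: int = 0,
    outdir=None,
    fmt: str = "tsv",
) -> SimulationResult:
    """Run the full generator for both domains under one seed.

    With ``outdir`` the result is written out as shared+taxonomy (or TSV)
    files per domain, the sample-metadata TSV, the truth tables, the
    geochemistry TSV and a YAML echo of the parameters.
    """
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    truths: dict[str, SyntheticTruth] = {}
    comps: dict[str, pd.DataFrame] = {}
    tables: dict[str, OtuTable] = {}
    for domain in ("archaea", "bacteria"):
        truth = generate_surface(params, domain, rng)
        comp, truth = propagate_depth(truth, params, rng=rng)
        truths[domain] = truth
        comps[domain] = comp
        tables[domain] = sample_reads(comp, truth, params, rng)
    geochem = generate_biomass(params, rng)
    result = SimulationResult(
        params=params, seed=seed, truths=truths, compositions=comps,
        tables=tables, geochem=geochem,
    )
    if outdir is not None:
        _write_simulation(result, Path(outdir), fmt)
    return result


def _write_simulation(result: SimulationResult, outdir: Path, fmt: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    all_samples = []
    for domain, table in result.tables.items():
        if fmt == "mothur":
            write_mothur(
                table,
                outdir / f"{domain}.shared",
                outdir / f"{domain}.cons.taxonomy",
            )
        else:
            write_tsv(table, outdir / f"{domain}_counts.tsv")
        all_samples.extend(table.samples)
        truth = result.truths[domain]
        pd.DataFrame(
            {
                "otu_id": truth.otu_ids,
                "lineage": truth.lineages.to_numpy(),
                "persistent": truth.persistent.to_numpy(),
                "decay_per_cm": truth.decay.to_numpy(),
                "surface_abundance": truth.surface.to_numpy(),
            }
        ).to_csv(outdir / f"{domain}_truth.tsv", sep="\t", index=False)
    write_metadata(all_samples, outdir / "samples.tsv")
    result.geochem.to_tsv(outdir / "geochem.tsv")
    with open(outdir / "sim_params.yaml", "w") as fh:
        yaml.safe_dump({"seed": result.seed, **result.params.echo()}, fh, sort_keys=True)


def score_recovery(
    predicted_persisting,
    truth: SyntheticTruth,
    library_size: int,
    min_expected_count: float = 10.0,
) -> dict:
    """Score recovery of the true persistent cohort.

    Only OTUs whose expected surface read count is at least
    ``min_expected_count`` (surface relative abundance >=
    ``min_expected_count / library_size``) are eligible — rarer OTUs are
    not resolvable at the survey's sequencing depth. Returns true/false
    positive and false negative counts among eligible OTUs.
    """
    threshold = min_expected_count / library_size
    eligible = truth.surface[truth.surface >= threshold].index
    predicted = pd.Index(predicted_persisting).intersection(eligible)
    true_set = truth.persistent.loc[eligible]
    true_ids = set(true_set.index[true_set])
    pred_ids = set(predicted)
    tp = len(true_ids & pred_ids)
    fp = len(pred_ids - true_ids)
    fn = len(true_ids - pred_ids)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
    }
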