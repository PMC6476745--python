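"""End-to-end workflow: read or simulate tables, normalise, average layers,
classify, and compute persistence and geochemistry summaries.

The stage order mirrors standard amplicon practice for depth profiles:
singleton removal -> rarefaction to the smallest library -> relative
abundances -> replicate-core averaging on the domain's own layering ->
rebinning of the fine archaeal layering onto the coarse bacterial one ->
group/guild summaries and the methanogen pathway ratio -> presence,
survival curve and persisting-OTU fractions -> geochemical ratios. Every
output TSV is hashed into a manifest so a rerun with the same config and
seed can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geochem import GeochemProfile
from .io import (
    OtuTable,
    goods_coverage,
    rarefy,
    read_metadata,
    read_table,
    remove_singletons,
    to_relative,
)
from .layers import (
    LayerScheme,
    LayerSeries,
    SCHEME_PRESETS,
    rebin,
    series_from_relabund,
)
from .persistence import PersistenceResult, persistence_fractions, presence
from .synthetic import SimParams, SimulationResult, simulate
from .taxa import (
    GroupProfile,
    GuildSummary,
    TaxonDictionary,
    classify,
    group_abundance,
    guild_summary,
    pathway_ratio,
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending record."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``inputs`` (paths to on-disk tables) or ``simulate``
    (generator parameters) must be set. ``schemes`` names the layering used
    per domain; ``target_scheme`` is the common layering persistence is
    computed on (the fine archaeal series is rebinned onto it).
    """

    seed: int = 0
    outdir: str | None = None
    inputs: dict | None = None
    simulate: SimParams | None = None
    dictionary: str | None = None
    presence_threshold: float = 0.0
    rarefy_depth: int | None = None
    singleton_removal: str = "before"  # before | after | off
    schemes: dict = field(
        default_factory=lambda: {"archaea": "archaeal", "bacteria": "bacterial"}
    )
    target_scheme: str = "bacterial"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of 'inputs' and 'simulate' must be given")
        if self.singleton_removal not in ("before", "after", "off"):
            raise ValueError("singleton_removal must be before, after or off")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_mapping(doc)

    @classmethod
    def from_mapping(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        sim = doc.pop("simulate", None)
        params = _simparams_from_mapping(sim) if sim is not None else None
        known = {f.name for f in dataclasses.fields(cls)} - {"simulate"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulate=params, **doc)

    def scheme_for(self, domain: str) -> LayerScheme:
        name = self.schemes.get(domain, domain)
        return SCHEME_PRESETS[name] if isinstance(name, str) else LayerScheme(name)

    def canonical(self) -> dict:
        doc = {
            "seed": self.seed,
            "presence_threshold": self.presence_threshold,
            "rarefy_depth": self.rarefy_depth,
            "singleton_removal": self.singleton_removal,
            "schemes": {k: v if isinstance(v, str) else [list(b) for b in v] for k, v in self.schemes.items()},
            "target_scheme": self.target_scheme,
            "dictionary": self.dictionary,
            "inputs": self.inputs,
            "simulate": self.simulate.echo() if self.simulate else None,
        }
        return doc


def _simparams_from_mapping(doc) -> SimParams:
    if doc is None or doc is True or doc == {}:
        return SimParams()
    if isinstance(doc, SimParams):
        return doc
    from .synthetic import DomainParams

    doc = dict(doc)
    kwargs = {}
    for domain in ("archaea", "bacteria"):
        sub = doc.pop(domain, None)
        if sub:
            base = getattr(SimParams(), domain)
            scheme = sub.pop("scheme", None)
            if scheme is not None:
                sub["scheme"] = LayerScheme(scheme)
            kwargs[domain] = dataclasses.replace(base, **sub)
    return SimParams(**kwargs, **doc)


@dataclass
class DomainResult:
    """All per-domain analysis products."""

    table: OtuTable
    coverage: pd.Series
    series: LayerSeries
    analysis_series: LayerSeries
    labels: pd.Series
    group_profile: GroupProfile
    guilds: GuildSummary
    pathway: pd.Series
    presence: pd.DataFrame
    persistence: PersistenceResult


@dataclass
class PipelineResult:
    config: RunConfig
    domains: dict[str, DomainResult]
    geochem: GeochemProfile | None
    geochem_metrics: pd.DataFrame | None
    manifest: dict
    simulation: SimulationResult | None = None


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("acquire")
def _acquire(config: RunConfig) -> tuple[dict[str, OtuTable], GeochemProfile | None, SimulationResult | None]:
    if config.simulate is not None:
        sim = simulate(config.simulate, seed=config.seed)
        return dict(sim.tables), sim.geochem, sim
    inputs = config.inputs or {}
    metadata = read_metadata(inputs["metadata"])
    tables = {}
    for domain in ("archaea", "bacteria"):
        spec = inputs.get(domain)
        if spec is None:
            continue
        tables[domain] = read_table(
            spec["path"],
            fmt=spec.get("format", "tsv"),
            taxonomy=spec.get("taxonomy"),
            metadata=metadata,
        )
    if not tables:
        raise ValueError("inputs provide no archaea or bacteria table")
    geochem = (
        GeochemProfile.from_tsv(inputs["geochem"]) if inputs.get("geochem") else None
    )
    return tables, geochem, None


def _analyze_domain(
    domain: str,
    table: OtuTable,
    config: RunConfig,
    dictionary: TaxonDictionary,
    rarefy_seed,
) -> DomainResult:
    work = table
    if config.singleton_removal == "before":
        work = _stage("remove_singletons")(remove_singletons)(work)
    work = _stage("rarefy")(rarefy)(work, depth=config.rarefy_depth, seed=rarefy_seed)
    if config.singleton_removal == "after":
        work = _stage("remove_singletons")(remove_singletons)(work)
    coverage = pd.Series(
        {sid: goods_coverage(work.counts[sid].to_numpy()) for sid in work.sample_ids},
        name="goods_coverage",
    )
    rel = _stage("to_relative")(to_relative)(work)
    scheme = config.scheme_for(domain)
    series = _stage("average_replicates")(series_from_relabund)(rel, scheme)
    target = (
        SCHEME_PRESETS[config.target_scheme]
        if isinstance(config.target_scheme, str)
        else LayerScheme(config.target_scheme)
    )
    analysis = (
        _stage("rebin")(rebin)(series, target) if scheme != target else series
    )
    labels = _stage("classify")(classify)(work, dictionary)
    groups = _stage("group_abundance")(group_abundance)(
        analysis, labels, fold_unclassified=True,
        provenance={"dictionary_version": dictionary.version},
    )
    guilds = _stage("guild_summary")(guild_summary)(analysis, labels)
    pathway = _stage("pathway_ratio")(pathway_ratio)(analysis, labels)
    pm = _stage("presence")(presence)(analysis, threshold=config.presence_threshold)
    persist = _stage("persistence_fractions")(persistence_fractions)(pm, analysis)
    return DomainResult(
        table=work,
        coverage=coverage,
        series=series,
        analysis_series=analysis,
        labels=labels,
        group_profile=groups,
        guilds=guilds,
        pathway=pathway,
        presence=pm,
        persistence=persist,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow and (optionally) write the output bundle."""
    tables, geochem, sim = _acquire(config)
    dictionary = (
        TaxonDictionary.from_yaml(config.dictionary)
        if config.dictionary
        else TaxonDictionary.default()
    )
    domains = {}
    for i, (domain, table) in enumerate(sorted(tables.items())):
        domains[domain] = _analyze_domain(
            domain, table, config, dictionary, rarefy_seed=[config.seed, i]
        )
    metrics = _geochem_metrics(geochem) if geochem is not None else None
    result = PipelineResult(
        config=config,
        domains=domains,
        geochem=geochem,
        geochem_metrics=metrics,
        manifest={},
        simulation=sim,
    )
    if config.outdir is not None:
        result.manifest = _write_outputs(result, Path(config.outdir))
    return result


def assembly_comparison(seed: int, params: SimParams | None = None) -> dict:
    """Run matched selective-survival and neutral-turnover simulations under
    one seed, analyse both, and summarise the persistence signature.

    Returns, per assembly model, the per-domain maximum across layers of the
    persisting richness fraction, the deepest-layer persisting abundance
    fraction and the Good's coverage range, plus (for the selective run) the
    recovery of the true persistent cohort pooled over both domains among
    OTUs whose expected surface count is at least 10 reads.
    """
    import dataclasses

    from .synthetic import score_recovery

    base = params or SimParams()
    out: dict = {"seed": seed}
    for model in ("selective_survival", "neutral_turnover"):
        sim_params = dataclasses.replace(base, assembly_model=model)
        result = run_pipeline(RunConfig(seed=seed, simulate=sim_params))
        tp = fp = fn = 0
        domains = {}
        for domain, res in result.domains.items():
            persist = res.persistence
            truth = result.simulation.truths[domain]
            lib = sim_params.domain(domain).library_size
            score = score_recovery(persist.persisting_ids, truth, lib)
            tp, fp, fn = tp + score["tp"], fp + score["fp"], fn + score["fn"]
            domains[domain] = {
                "richness_fraction_max": float(persist.richness_fraction.max()),
                "deepest_abundance_fraction": float(persist.abundance_fraction.iloc[-1]),
                "coverage_min": float(res.coverage.min()),
                "coverage_max": float(res.coverage.max()),
                "n_persisting": len(persist.persisting_ids),
            }
        out[model] = {
            "domains": domains,
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
        }
    return out


@_stage("geochem_metrics")
def _geochem_metrics(profile: GeochemProfile) -> pd.DataFrame:
    dna_rna = profile.ratio_profile("DNA", "RNA").rename(columns={"value": "dna_rna"})
    cn = profile.ratio_profile("C_percent", "N_percent").rename(columns={"value": "c_n"})
    merged = dna_rna.merge(cn, on=["layer_top_cm", "layer_bottom_cm", "layer_mid_cm"], how="outer")
    brfa = profile.analyte("BrFA").reset_index()
    merged = merged.merge(
        brfa[["layer_top_cm", "layer_bottom_cm", "value"]].rename(columns={"value": "brfa_ug_g"}),
        on=["layer_top_cm", "layer_bottom_cm"],
        how="outer",
    )
    return merged.sort_values("layer_top_cm").reset_index(drop=True)


def _tsv_bytes(df: pd.DataFrame, index: bool = True) -> bytes:
    return df.to_csv(sep="\t", index=index, float_format="%.10g").encode()


def _write_outputs(result: PipelineResult, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, bytes] = {}
    for domain, res in result.domains.items():
        mids = res.analysis_series.scheme.midpoints
        summary = res.persistence.summary_frame(layer_mid_cm=mids)
        files[f"{domain}_persistence.tsv"] = _tsv_bytes(summary)
        curve = pd.DataFrame(
            {"layer_mid_cm": mids, "n_surviving": res.persistence.survival_curve}
        )
        files[f"{domain}_survival_curve.tsv"] = _tsv_bytes(curve)
        persisting = pd.DataFrame(
            {
                "otu_id": list(res.persistence.persisting_ids),
                "lineage": [
                    res.table.lineages.get(o, "") for o in res.persistence.persisting_ids
                ],
            }
        )
        files[f"{domain}_persisting_otus.tsv"] = _tsv_bytes(persisting, index=False)
        files[f"{domain}_coverage.tsv"] = _tsv_bytes(res.coverage.to_frame())
        gp = res.group_profile.values.copy()
        gp.index.name = "group"
        files[f"{domain}_group_profile.tsv"] = _tsv_bytes(gp)
        gl = res.guilds.per_layer.copy()
        gl.index.name = "guild"
        files[f"{domain}_guild_profile.tsv"] = _tsv_bytes(gl)
        files[f"{domain}_guild_maxima.tsv"] = _tsv_bytes(
            res.guilds.max_across_layers.rename("max_relative_abundance").to_frame()
        )
        files[f"{domain}_pathway_ratio.tsv"] = _tsv_bytes(
            pd.DataFrame(
                {"layer_mid_cm": mids, "acetoclastic_to_hydrogenotrophic": res.pathway}
            )
        )
    if result.geochem_metrics is not None:
        files["geochem_metrics.tsv"] = _tsv_bytes(result.geochem_metrics, index=False)
    hashes = {}
    for name, payload in sorted(files.items()):
        (outdir / name).write_bytes(payload)
        hashes[name] = hashlib.sha256(payload).hexdigest()
    config_doc = json.dumps(result.config.canonical(), sort_keys=True, default=str)
    manifest = {
        "package": "sedistrat",
        "version": __version__,
        "seed": result.config.seed,
        "config_sha256": hashlib.sha256(config_doc.encode()).hexdigest(),
        "config": json.loads(config_doc),
        "files": hashes,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
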