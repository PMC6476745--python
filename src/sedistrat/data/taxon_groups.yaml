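# Knowledge-group and guild dictionary for boreal lake sediment 16S surveys.
#
# Knowledge groups split taxa into "well_characterized" (functional data and
# cultivated representatives exist) and "poorly_known" (negligible functional
# data, no or few cultured representatives). Guild labels mark methanogen
# pathways, methanotrophs and putative protein degraders. Patterns are
# rank-scoped lineage-token prefixes; the deepest matching knowledge rule
# wins, guild labels accumulate from every matching rule.
version: "1.0"
rules:
  # --- archaea: knowledge groups --------------------------------------
  - {pattern: Methanobacteria, rank: class, labels: [well_characterized]}
  - {pattern: Methanomicrobia, rank: class, labels: [well_characterized]}
  - {pattern: Thermoplasmata, rank: class, labels: [poorly_known]}
  - {pattern: Aenigmarchaeota, rank: phylum, labels: [poorly_known]}
  - {pattern: Altiarchae, rank: phylum, labels: [poorly_known]}
  - {pattern: Bathyarchaeota, rank: phylum, labels: [poorly_known]}
  - {pattern: Diapherotrites, rank: phylum, labels: [poorly_known]}
  - {pattern: Hadesarchaea, rank: phylum, labels: [poorly_known]}
  - {pattern: Lokiarchaeota, rank: phylum, labels: [poorly_known]}
  - {pattern: Miscellaneous Euryarchaeotic Group, rank: phylum, labels: [poorly_known]}
  - {pattern: Parvarchaeota, rank: phylum, labels: [poorly_known]}
  - {pattern: Thaumarchaeota, rank: phylum, labels: [poorly_known]}
  - {pattern: Woesearchaeota, rank: phylum, labels: [poorly_known]}
  - {pattern: YNPFFA, rank: phylum, labels: [poorly_known]}
  # --- bacteria: well-characterized phyla -----------------------------
  - {pattern: Acidobacteria, rank: phylum, labels: [well_characterized]}
  - {pattern: Actinobacteria, rank: phylum, labels: [well_characterized]}
  - {pattern: Armatimonadetes, rank: phylum, labels: [well_characterized]}
  - {pattern: Bacteroidetes, rank: phylum, labels: [well_characterized]}
  - {pattern: Chlamydiae, rank: phylum, labels: [well_characterized]}
  - {pattern: Cyanobacteria, rank: phylum, labels: [well_characterized]}
  - {pattern: Deinococcus-Thermus, rank: phylum, labels: [well_characterized]}
  - {pattern: Fibrobacteres, rank: phylum, labels: [well_characterized]}
  - {pattern: Firmicutes, rank: phylum, labels: [well_characterized]}
  - {pattern: Fusobacteria, rank: phylum, labels: [well_characterized]}
  - {pattern: Gemmatimonadetes, rank: phylum, labels: [well_characterized]}
  - {pattern: Lentisphaerae, rank: phylum, labels: [well_characterized]}
  - {pattern: Nitrospirae, rank: phylum, labels: [well_characterized]}
  - {pattern: Planctomycetes, rank: phylum, labels: [well_characterized]}
  - {pattern: Proteobacteria, rank: phylum, labels: [well_characterized]}
  - {pattern: Spirochaetae, rank: phylum, labels: [well_characterized]}
  - {pattern: Verrucomicrobia, rank: phylum, labels: [well_characterized]}
  # --- bacteria: poorly-known phyla -----------------------------------
  - {pattern: AC1, rank: phylum, labels: [poorly_known]}
  - {pattern: Acetothermia, rank: phylum, labels: [poorly_known]}
  - {pattern: Aminicenantes, rank: phylum, labels: [poorly_known]}
  - {pattern: Atribacteria, rank: phylum, labels: [poorly_known]}
  - {pattern: Berkelbacteria, rank: phylum, labels: [poorly_known]}
  - {pattern: BRC1, rank: phylum, labels: [poorly_known]}
  - {pattern: Caldiserica, rank: phylum, labels: [poorly_known]}
  - {pattern: Chlorobi, rank: phylum, labels: [poorly_known]}
  - {pattern: Chloroflexi, rank: phylum, labels: [poorly_known]}
  - {pattern: Cloacimonetes, rank: phylum, labels: [poorly_known]}
  - {pattern: Elusimicrobia, rank: phylum, labels: [poorly_known]}
  - {pattern: FCPU426, rank: phylum, labels: [poorly_known]}
  - {pattern: Gracilibacteria, rank: phylum, labels: [poorly_known]}
  - {pattern: Hydrogenedentes, rank: phylum, labels: [poorly_known]}
  - {pattern: Ignavibacteriae, rank: phylum, labels: [poorly_known]}
  - {pattern: Latescibacteria, rank: phylum, labels: [poorly_known]}
  - {pattern: LCP-89, rank: phylum, labels: [poorly_known]}
  - {pattern: Microgenomates, rank: phylum, labels: [poorly_known]}
  - {pattern: Omnitrophica, rank: phylum, labels: [poorly_known]}
  - {pattern: Parcubacteria, rank: phylum, labels: [poorly_known]}
  - {pattern: Peregrinibacteria, rank: phylum, labels: [poorly_known]}
  - {pattern: RBG-1, rank: phylum, labels: [poorly_known]}
  - {pattern: Saccharibacteria, rank: phylum, labels: [poorly_known]}
  - {pattern: SR1, rank: phylum, labels: [poorly_known]}
  - {pattern: TA06, rank: phylum, labels: [poorly_known]}
  - {pattern: TM6, rank: phylum, labels: [poorly_known]}
  - {pattern: WS1, rank: phylum, labels: [poorly_known]}
  - {pattern: WS2, rank: phylum, labels: [poorly_known]}
  - {pattern: WS6, rank: phylum, labels: [poorly_known]}
  # --- guilds ----------------------------------------------------------
  # acetoclastic methanogenesis operationalised as genus Methanosaeta,
  # hydrogenotrophic as order Methanomicrobiales; Methanosarcina is kept
  # out of both pathway guilds and reported on its own.
  - {pattern: Methanosaeta, rank: genus, labels: [methanogen_acetoclastic]}
  - {pattern: Methanomicrobiales, rank: order, labels: [methanogen_hydrogenotrophic]}
  - {pattern: Methanosarcina, rank: genus, labels: [methanogen_other]}
  - {pattern: Methylococcales, rank: order, labels: [methanotroph_aerobic]}
  - {pattern: Methylocystaceae, rank: family, labels: [methanotroph_aerobic]}
  - {pattern: NC10, rank: phylum, labels: [methanotroph_anaerobic]}
  - {pattern: ANME, rank: genus, labels: [methanotroph_anaerobic]}
  - {pattern: Peptostreptococcaceae, rank: family, labels: [protein_degrader]}
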