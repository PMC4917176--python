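{
  "weights": {
    "1": 2.0,
    "2": 1.0,
    "3": 0.8,
    "4": 0.4,
    "5": 1.0,
    "6": -1.5,
    "7": 1.5,
    "8": 1.2,
    "9": 1.5,
    "10": 0.8,
    "11": 1.0,
    "12": 0.5,
    "13": -2.0,
    "14": 0.0,
    "15": 0.0,
    "16": 1.0,
    "17": 0.5
  },
  "tau": 2.0,
  "positive_keywords": [
    "database", "databases", "software", "tool", "tools", "package",
    "packages", "server", "webserver", "suite", "pipeline", "pipelines",
    "platform", "ontology", "ontologies", "repository", "repositories",
    "resource", "resources", "toolkit", "browser", "application",
    "implementation", "framework", "workbench", "environment"
  ],
  "negative_keywords": [
    "algorithm", "algorithms", "method", "methods", "approach", "approaches",
    "technique", "techniques", "procedure", "procedures", "protocol",
    "protocols", "model", "models", "assay", "assays", "gene", "genes",
    "protein", "proteins", "pathway", "pathways", "strategy", "strategies"
  ],
  "restricted_heads": ["program", "programs", "system", "systems", "project",
                        "projects", "service", "services"],
  "usage_verbs": [
    "used", "using", "use", "ran", "run", "performed", "aligned", "analysed",
    "analyzed", "computed", "implemented", "applied", "generated",
    "visualised", "visualized", "calculated", "downloaded", "queried",
    "searched", "annotated", "processed", "clustered", "assembled", "mapped"
  ],
  "common_words": [
    "analysis", "cluster", "image", "match", "smart", "cell", "genomes",
    "effective", "spring", "focus", "healthcare", "model", "express",
    "prism", "base", "scan", "trace", "pilot", "mosaic", "compass",
    "beacon", "anchor", "bridge", "canvas", "cascade", "catalyst", "circuit",
    "fusion", "gateway", "harbor", "horizon", "lattice", "medley", "nexus",
    "oracle", "prime", "pulse", "quartz", "relay", "sentinel", "spectrum",
    "summit", "tangent", "vertex", "vortex", "zenith", "profile", "network"
  ],
  "acronym_tolerance": 0.2,
  "cohort_rate": 0.35,
  "cohort_cap": 2.0,
  "keyword_window": 3,
  "mixed_bonus": 0.3
}
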