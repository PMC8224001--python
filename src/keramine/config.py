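"""Run configuration: every tunable parameter of the pipeline in one place.

A single ``random_seed`` drives every stochastic component (t-SNE
initialization, Louvain node ordering, fixture generation) so that a full run
is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Annotation keywords that flag a coding sequence as a putative protease.
DEFAULT_MINING_KEYWORDS = (
    "peptidase",
    "protease",
    "proteinase",
    "sortase",
    "caspase",
    "penicillin-binding protein",
    "insulinase",
    "snapalysin",
    "mycosin",
)

#: E-value cutoffs commonly explored for similarity-network construction.
NETWORK_EVALUE_CHOICES = (1e-5, 1e-20, 1e-40, 1e-80)


@dataclass
class PipelineConfig:
    """Parameters for every pipeline stage.

    Defaults follow the study design this package implements: reciprocal
    best-hit family assignment at E <= 1e-20, orthogrouping and network edges
    at E <= 1e-40, weighted Louvain at resolution 1, t-SNE with perplexity 30
    and 1000 iterations at a fixed seed, DBSCAN on the min-max-normalized
    t-SNE plane, a 70% alignment-column occupancy filter, and a strict >50%
    ancestral-probability clade filter.
    """

    mining_keywords: tuple[str, ...] = DEFAULT_MINING_KEYWORDS
    family_evalue: float = 1e-20
    orthogroup_evalue: float = 1e-40
    network_evalue: float = 1e-40
    louvain_resolution: float = 1.0
    tsne_perplexity: float = 30.0
    tsne_iterations: int = 1000
    random_seed: int = 0
    dbscan_eps: float = 0.05
    dbscan_min_samples: int = 4
    occupancy_threshold: float = 0.70
    clade_probability_threshold: float = 0.5
    #: "sum": P(keratinase) + P(keratinase-linked) must exceed the threshold;
    #: "either": one of the two categories alone must exceed it.
    clade_probability_mode: str = "sum"
    #: "community": keratinase-linked means sharing a Louvain community with a
    #: functional keratinase; "direct-edge": a direct network edge is required.
    linkage_mode: str = "community"
    focal_strain: str = "G11C"
    strains: tuple[str, ...] = ("G11C", "CHD11", "Vc74B-19")

    def __post_init__(self) -> None:
        self.mining_keywords = tuple(self.mining_keywords)
        self.strains = tuple(self.strains)
        self.validate()

    def validate(self) -> None:
        for name in ("family_evalue", "orthogroup_evalue", "network_evalue"):
            val = getattr(self, name)
            if not (0.0 < val <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {val}")
        if not (0.0 < self.occupancy_threshold <= 1.0):
            raise ValueError("occupancy_threshold must be in (0, 1]")
        if not (0.0 < self.clade_probability_threshold < 1.0):
            raise ValueError("clade_probability_threshold must be in (0, 1)")
        if self.tsne_perplexity <= 0:
            raise ValueError("tsne_perplexity must be positive")
        if self.tsne_iterations < 250:
            raise ValueError("tsne_iterations must be >= 250")
        if self.dbscan_eps <= 0:
            raise ValueError("dbscan_eps must be positive")
        if self.dbscan_min_samples < 1:
            raise ValueError("dbscan_min_samples must be >= 1")
        if self.clade_probability_mode not in ("sum", "either"):
            raise ValueError("clade_probability_mode must be 'sum' or 'either'")
        if self.linkage_mode not in ("community", "direct-edge"):
            raise ValueError("linkage_mode must be 'community' or 'direct-edge'")
        if not self.mining_keywords:
            raise ValueError("mining_keywords must be non-empty")
        if self.focal_strain not in self.strains:
            raise ValueError(
                f"focal_strain {self.focal_strain!r} not among strains {self.strains}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["mining_keywords"] = list(self.mining_keywords)
        data["strains"] = list(self.strains)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
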