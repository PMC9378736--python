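"""Typed, validated screen configuration.

Configurations are YAML mappings; unknown keys are rejected with the full
key path, values are range-checked, and every omitted key takes its
documented default, so an empty file is a valid (demo) configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml

from .errors import ConfigError


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class SimulateConfig:
    """Synthetic dataset parameters (the demo screen's study conditions)."""

    n_chrom: int = 3
    chrom_length: int = 120_000
    gc: float = 0.45
    n_genes: int = 210
    n_decoys: int = 200
    n_long_orf_upregulated: int = 2
    n_pairs: int = 6
    read_len: int = 150
    depth: int = 28_000
    err: float = 0.002
    positive_lfc: float = 2.0
    nk_set_size: int = 27
    target_r: float = -0.6
    corr_noise_sd: float = 0.3
    n_expr_genes: int = 1000

    def validate(self, path: str) -> None:
        _check(self.n_chrom >= 1, f"{path}.n_chrom: must be >= 1")
        _check(self.chrom_length >= 10_000, f"{path}.chrom_length: must be >= 10000")
        _check(0 < self.gc < 1, f"{path}.gc: must be in (0, 1)")
        _check(self.n_pairs >= 2, f"{path}.n_pairs: must be >= 2")
        _check(self.read_len >= 40, f"{path}.read_len: must be >= 40")
        _check(self.depth >= 0, f"{path}.depth: must be >= 0")
        _check(0 <= self.err < 0.5, f"{path}.err: must be in [0, 0.5)")
        _check(abs(self.target_r) <= 1, f"{path}.target_r: |r| must be <= 1")
        _check(self.nk_set_size >= 2, f"{path}.nk_set_size: must be >= 2")


@dataclass
class PathsConfig:
    """External inputs; all optional when the simulate stage runs."""

    genome_fasta: str | None = None
    annotation_gff: str | None = None
    reads: dict = field(default_factory=dict)       # sample -> FASTQ path
    gene_matrix: str | None = None                  # counts TSV
    gene_lengths: str | None = None                 # TSV feature\tlength
    gene_sets_gmt: str | None = None
    junction_catalogue_bed: str | None = None

    def validate(self, path: str) -> None:
        _check(isinstance(self.reads, dict), f"{path}.reads: must map sample -> FASTQ path")


@dataclass
class DetectConfig:
    anchor_k: int = 20
    mismatches: int = 2
    span_cap: int = 100_000
    min_unique: int = 2

    def validate(self, path: str) -> None:
        _check(self.anchor_k >= 10, f"{path}.anchor_k: below minimum 10")
        _check(self.mismatches >= 0, f"{path}.mismatches: must be >= 0")
        _check(self.span_cap > 0, f"{path}.span_cap: must be positive")
        _check(self.min_unique >= 1, f"{path}.min_unique: must be >= 1")


@dataclass
class DeConfig:
    pseudocount: float = 0.5
    lfc_cut: float = 1.0
    p_cut: float = 0.05
    adjust: bool = False   # circRNA rule: raw P < 0.05 (genes would use FDR)
    paired: bool = True

    def validate(self, path: str) -> None:
        _check(self.pseudocount > 0, f"{path}.pseudocount: must be positive")
        _check(self.lfc_cut >= 0, f"{path}.lfc_cut: must be >= 0")
        _check(0 < self.p_cut < 1, f"{path}.p_cut: must be in (0, 1)")


@dataclass
class OrfConfig:
    max_aa: int = 100
    require_junction: bool = True
    max_passes: int = 3

    def validate(self, path: str) -> None:
        _check(self.max_aa > 0, f"{path}.max_aa: must be positive")
        _check(self.max_passes >= 1, f"{path}.max_passes: must be >= 1")


@dataclass
class GseaConfig:
    weight: float = 1.0
    n_perm: int = 1000
    p_cut: float = 0.05
    pathway: str | None = None    # defaults to the first set in the GMT

    def validate(self, path: str) -> None:
        _check(self.weight in (0.0, 1.0) or self.weight > 0,
               f"{path}.weight: must be a nonnegative exponent")
        _check(self.weight >= 0, f"{path}.weight: must be >= 0")
        _check(self.n_perm >= 100, f"{path}.n_perm: must be >= 100")
        _check(0 < self.p_cut < 1, f"{path}.p_cut: must be in (0, 1)")


@dataclass
class ScreenConfig:
    seed: int = 0
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    de: DeConfig = field(default_factory=DeConfig)
    orfs: OrfConfig = field(default_factory=OrfConfig)
    gsea: GseaConfig = field(default_factory=GseaConfig)

    def validate(self) -> None:
        _check(isinstance(self.seed, int) and 0 <= self.seed < 2**31,
               "seed: must be an integer in [0, 2^31)")
        if self.simulate is not None:
            self.simulate.validate("simulate")
        self.paths.validate("paths")
        self.detect.validate("detect")
        self.de.validate("de")
        self.orfs.validate("orfs")
        self.gsea.validate("gsea")
        if self.simulate is None:
            _check(self.paths.genome_fasta is not None,
                   "paths.genome_fasta: required when no simulate block is given")
            _check(bool(self.paths.reads), "paths.reads: required when no simulate block is given")

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "simulate": SimulateConfig,
    "paths": PathsConfig,
    "detect": DetectConfig,
    "de": DeConfig,
    "orfs": OrfConfig,
    "gsea": GseaConfig,
}


def _build_section(cls, raw: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    for key in raw:
        _check(key in allowed, f"unknown key {path}.{key}")
    try:
        return cls(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def validate_config(raw: str | dict | None) -> ScreenConfig:
    """Parse and validate a YAML (or dict) configuration.

    An empty document yields the all-defaults demo configuration.  A
    ``simulate: null`` entry disables simulation and requires input paths.
    """
    if isinstance(raw, str):
        try:
            raw = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    cfg = ScreenConfig()
    for key, value in raw.items():
        if key == "seed":
            _check(isinstance(value, int), "seed: must be an integer")
            cfg.seed = value
        elif key in _SECTIONS:
            if key == "simulate" and value is None:
                cfg.simulate = None
                continue
            _check(isinstance(value, dict) or value is None,
                   f"{key}: must be a mapping")
            setattr(cfg, key, _build_section(_SECTIONS[key], value or {}, key))
        else:
            raise ConfigError(f"unknown key {key}")
    cfg.validate()
    return cfg
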