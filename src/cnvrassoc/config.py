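"""Schema-validated pipeline configuration (YAML-backed, unknown keys
rejected).  Defaults are the stringent thresholds of the analysis: five
probes and 5 kb minimum per call, confidence 10 (HMM), >10 (Bayes factor)
and 35 (Gaussian), 50% exclusion-region overlap, 50% reciprocal overlap
for consensus, 1% cohort frequency, 10,000 permutations."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LocusConfig(_Model):
    chrom: int
    start: int
    end: int
    copy_number: Literal[0, 1, 3, 4]
    case_frequency: float = Field(ge=0, le=1)
    control_frequency: float = Field(ge=0, le=1)


class SimulateConfig(_Model):
    n_chromosomes: int = 1
    markers_per_chromosome: int = 1200
    mean_spacing: float = 3000.0
    gc_wavelength: float = 1.0e6
    n_cases: int = 300
    n_controls: int = 300
    sd_lrr: float = 0.2
    baf_noise: float = 0.03
    gc_wave_amplitude: float = 0.0
    loci: list[LocusConfig] = Field(default_factory=list)


class CohortConfig(_Model):
    name: str
    simulate: Optional[SimulateConfig] = None
    signal_tsv: Optional[str] = None
    phenotypes_tsv: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self) -> "CohortConfig":
        if (self.simulate is None) == (self.signal_tsv is None):
            raise ValueError("cohort needs exactly one of 'simulate' or 'signal_tsv'")
        return self


class CallerConfig(_Model):
    lrr_sd: Optional[float] = None
    min_lrr_sd: float = 0.02
    baf_sd: float = 0.05
    p_stay: float = 0.999
    d_scale: float = 100_000.0
    gaussian_confidence: float = 35.0


class QcConfig(_Model):
    min_probes: int = 5
    min_length_bp: int = 5000
    exclusion_overlap_fraction: float = 0.5
    hmm_max_sd_lrr: float = 0.35
    hmm_max_baf_drift: float = 0.01
    hmm_max_gcwf: float = 0.05
    bayes_max_sd_lrr: float = 0.25
    bayes_max_sd_baf: float = 0.3
    bayes_max_outlier_rate: float = 0.01
    max_calls: int = 50
    hmm_min_confidence: float = 10.0
    bayes_min_confidence: float = 10.0
    gaussian_min_confidence: float = 35.0


class ConsensusConfig(_Model):
    reciprocal_overlap: float = 0.5
    min_freq: float = 0.01


class AssociationConfig(_Model):
    n_perm: int = 10_000
    alpha: float = 0.05


class PathsConfig(_Model):
    glist: Optional[str] = None
    exclusion_bed: Optional[str] = None
    gmt: Optional[str] = None


class PipelineConfig(_Model):
    seed: int = 0
    out_dir: Optional[str] = None
    cohorts: list[CohortConfig]
    callers: CallerConfig = Field(default_factory=CallerConfig)
    qc: QcConfig = Field(default_factory=QcConfig)
    consensus: ConsensusConfig = Field(default_factory=ConsensusConfig)
    association: AssociationConfig = Field(default_factory=AssociationConfig)
    paths: PathsConfig = Field(default_factory=PathsConfig)

    @model_validator(mode="after")
    def _cohort_count(self) -> "PipelineConfig":
        if not 1 <= len(self.cohorts) <= 2:
            raise ValueError("the pipeline runs one or two cohorts")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)
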