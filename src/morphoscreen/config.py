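"""Pipeline configuration: every stage parameter in one serializable
object.  Unknown keys are rejected so a config typo cannot silently
fall back to a default."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignConfig(_Strict):
    n_subclones: int = 3
    concentrations: tuple[float, ...] = (100.0, 300.0, 1000.0)
    n_compounds: int = 330
    wt_vehicle_wells_per_plate: int = 24
    ko_vehicle_wells_per_plate: int = 16
    ko_untreated_wells_per_plate: int = 6
    fields_per_well: int = 4


class SimulationConfig(_Strict):
    n_features: int = 1100
    affected_fraction: float = 0.2
    delta: float = 1.0
    n_reverters: int = 10
    reverter_rho_min: float = 0.8
    nonreverter_rho_max: float = 0.2
    rho_star: float = 0.8
    offtarget_sd: float = 0.25
    n_latent: int = 20
    block_loading: float = 0.6
    sigma_plate: float = 0.3
    sigma_well: float = 0.3
    sigma_field: float | None = None
    dose_scaling: bool = True
    toxic_well_rate: float = 0.0


class QCConfig(_Strict):
    anchor: str = "ko_vehicle"
    aggregation: str = "median"
    rank_tol: float = 1e-8
    r_threshold: float = 0.95
    alpha: float = 0.05


class ReductionConfig(_Strict):
    rule: str = "fixed"
    k0: int = 50
    rotate: bool = True
    gamma: float = 0.0
    controls_only_fit: bool = False


class SeparationConfig(_Strict):
    metric: str = "bray_curtis"
    n_perm: int = 999


class ClassifierConfig(_Strict):
    algorithm: str = "nn"
    sizes: tuple[int, ...] = (3, 5, 10)
    decays: tuple[float, ...] = (1e-4, 1e-2, 1.0)
    cv_folds: int = 2
    test_fraction: float = 0.2
    focus_class: str = "WT"


class HitConfig(_Strict):
    tau: float = 0.505
    mode: str = "any_conc"


class EnrichmentConfig(_Strict):
    gmt_path: str | None = None            # None -> packaged fixture collection
    expressed_path: str | None = None      # None -> packaged expressed list
    alpha: float = 0.05


class PipelineConfig(_Strict):
    """Root configuration; ``seed`` drives every stochastic stage."""

    seed: int = 1
    version: str = __version__
    design: DesignConfig = DesignConfig()
    simulation: SimulationConfig = SimulationConfig()
    qc: QCConfig = QCConfig()
    reduction: ReductionConfig = ReductionConfig()
    separation: SeparationConfig = SeparationConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    hits: HitConfig = HitConfig()
    enrichment: EnrichmentConfig = EnrichmentConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
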