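"""Parametric generative model of a morphological-profiling screen.

The generator emits image-field-level feature tables with the screen's
plate layout and a known ground truth, so that every downstream stage
(QC, reduction, separation, classification, hit calling) can be verified
against planted effects.

Generative model, per feature f and image record r::

    x[r, f] = mu_f + s_f * ( shift(group, f)
                             + plate[p(r), f] + well[w(r), f]
                             + (L u_r)_f + sigma_field * eps[r, f] )

where shift is 0 for wild-type wells, ``delta * g_f`` for knock-out
vehicle/untreated wells (g = affected-feature mask) and
``(1 - rho_eff) * delta * g_f + eta_c * d_c[f]`` for a knock-out well
treated with compound c.  rho_eff is the compound's reversion strength,
by default scaled by dose/1000 (monotone dose response).  L is a
block-structured latent-factor loading matrix inducing correlated
features; plate/well components are Gaussian random effects.  mu_f and
s_f are arbitrary per-feature baselines and scales, removed by the
robust per-plate normalization downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import METADATA_COLUMNS, ScreenDesign, screen_layout
from .manifest import SALT_PAIR_COMPOUNDS

COMPARTMENTS = [
    "Nuc", "Cyto", "Mito", "ER", "Golgi", "Actin", "Membrane", "Nucleoli", "Cell",
]
FEATURE_CLASSES = [
    "Colocalization", "Adjacency", "Size", "Shape", "Area",
    "Texture", "RadialDistribution", "Granularity", "Intensity",
]


def feature_names(n_features: int) -> list[str]:
    """Compartment_Class_Index names cycling over the nine feature classes."""
    names = []
    for i in range(n_features):
        comp = COMPARTMENTS[i % len(COMPARTMENTS)]
        cls = FEATURE_CLASSES[(i // len(COMPARTMENTS)) % len(FEATURE_CLASSES)]
        names.append(f"{comp}_{cls}_{i + 1:04d}")
    return names


@dataclass
class SimulationParams:
    """Knobs of the generative model.

    delta is the standardized per-feature genotype shift (units of the
    image-level within-group SD, which the noise components sum to 1 by
    default).  Ten compounds are planted as true reverters with reversion
    rho >= 0.8; the two salt-form pairs are always among them so that
    salt-form collapse is exercised end to end.
    """

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
    sigma_field: float | None = None  # None -> total image-level SD == 1
    dose_scaling: bool = True
    toxic_well_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("affected_fraction", "toxic_well_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("delta", "offtarget_sd", "sigma_plate", "sigma_well",
                     "block_loading", "reverter_rho_min", "nonreverter_rho_max"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.sigma_field is not None and (
            not math.isfinite(self.sigma_field) or self.sigma_field < 0
        ):
            raise ValueError("sigma_field must be finite and >= 0")
        if not 0 <= self.reverter_rho_min <= 1:
            raise ValueError("reverter_rho_min must be in [0,1]")

    def resolved_sigma_field(self) -> float:
        if self.sigma_field is not None:
            return self.sigma_field
        rest = self.block_loading**2 + self.sigma_plate**2 + self.sigma_well**2
        return math.sqrt(max(1.0 - rest, 0.05))


@dataclass
class GroundTruth:
    """Planted effects of a simulated screen."""

    rho: dict[str, float]
    eta: dict[str, float]
    true_hit: dict[str, bool]
    rho_star: float
    affected_features: list[str]
    seed: int

    def __post_init__(self) -> None:
        for cid, r in self.rho.items():
            if not 0 <= r <= 1:
                raise ValueError(f"rho[{cid}]={r} outside [0,1]")
            if self.true_hit[cid] != (r >= self.rho_star):
                raise ValueError(f"true_hit[{cid}] inconsistent with rho and rho_star")

    @property
    def true_hits(self) -> list[str]:
        return sorted(c for c, h in self.true_hit.items() if h)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _assign_reversion(
    compound_ids: list[str], params: SimulationParams, rng: np.random.Generator
) -> tuple[dict[str, float], dict[str, float]]:
    """Choose per-compound reversion rho and off-target magnitude eta."""
    planted = [c for c in SALT_PAIR_COMPOUNDS if c in compound_ids]
    remaining = [c for c in compound_ids if c not in planted]
    n_extra = max(params.n_reverters - len(planted), 0)
    extra = list(rng.choice(remaining, size=n_extra, replace=False)) if n_extra else []
    reverters = set(planted) | set(extra)

    rho, eta = {}, {}
    for cid in compound_ids:
        if cid in reverters:
            rho[cid] = float(rng.uniform(params.reverter_rho_min, 1.0))
        else:
            rho[cid] = float(rng.uniform(0.0, params.nonreverter_rho_max))
        eta[cid] = float(abs(rng.normal(0.0, params.offtarget_sd)))
    return rho, eta


def simulate_screen(
    design: ScreenDesign, params: SimulationParams
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an image-field-level feature table plus its ground truth.

    Deterministic given ``params.seed``: the same seed yields a
    bit-identical table.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    nf = params.n_features
    names = feature_names(nf)

    wells = screen_layout(design)
    n_wells = len(wells)

    # planted structure
    n_affected = round(params.affected_fraction * nf)
    affected_idx = rng.choice(nf, size=n_affected, replace=False)
    g = np.zeros(nf)
    g[affected_idx] = 1.0
    rho, eta = _assign_reversion(design.compound_ids, params, rng)
    truth = GroundTruth(
        rho=rho,
        eta=eta,
        true_hit={c: rho[c] >= params.rho_star for c in design.compound_ids},
        rho_star=params.rho_star,
        affected_features=[names[i] for i in sorted(affected_idx)],
        seed=params.seed,
    )

    # per-compound fixed off-target directions (unit vectors)
    directions = {}
    for cid in design.compound_ids:
        d = rng.standard_normal(nf)
        directions[cid] = d / np.linalg.norm(d)

    mu = rng.normal(0.0, 2.0, nf)
    scale = rng.uniform(0.5, 2.0, nf)

    # latent-factor loadings: contiguous feature blocks, one factor each
    L = np.zeros((nf, params.n_latent))
    block = int(np.ceil(nf / params.n_latent))
    for j in range(params.n_latent):
        L[j * block : (j + 1) * block, j] = params.block_loading

    plate_ids = wells["plate_id"].unique()
    plate_eff = {p: params.sigma_plate * rng.standard_normal(nf) for p in plate_ids}
    well_eff = params.sigma_well * rng.standard_normal((n_wells, nf))

    # expected well mean (before plate/well noise), per well
    shift = np.zeros((n_wells, nf))
    is_ko = wells["genotype"].to_numpy() == "KO"
    treatment = wells["treatment"].to_numpy()
    conc = wells["concentration_nM"].to_numpy()
    top_dose = max(design.concentrations)
    base_ko = params.delta * g
    for i in range(n_wells):
        if not is_ko[i]:
            continue
        t = treatment[i]
        if t in ("VEHICLE", "UNTREATED"):
            shift[i] = base_ko
        else:
            r_eff = rho[t] * (conc[i] / top_dose if params.dose_scaling else 1.0)
            shift[i] = (1.0 - r_eff) * base_ko + eta[t] * directions[t]

    # optional simulated toxicity: whole wells lost
    keep_well = np.ones(n_wells, dtype=bool)
    if params.toxic_well_rate > 0:
        is_compound_well = ~np.isin(treatment, ("VEHICLE", "UNTREATED"))
        toxic = rng.random(n_wells) < params.toxic_well_rate
        keep_well = ~(toxic & is_compound_well)

    sigma_field = params.resolved_sigma_field()
    nfields = design.fields_per_well
    n_records = n_wells * nfields

    u = rng.standard_normal((n_records, params.n_latent))
    eps = rng.standard_normal((n_records, nf))
    noise = u @ L.T
    noise += sigma_field * eps
    del u, eps

    rec_well = np.repeat(np.arange(n_wells), nfields)
    plate_arr = np.stack([plate_eff[p] for p in plate_ids])
    plate_index = pd.Categorical(wells["plate_id"], categories=plate_ids).codes
    values = (
        shift[rec_well]
        + plate_arr[plate_index[rec_well]]
        + well_eff[rec_well]
        + noise
    )
    values *= scale
    values += mu

    meta = wells.iloc[rec_well].reset_index(drop=True)
    meta["field"] = np.tile(np.arange(1, nfields + 1), n_wells)
    table = pd.concat(
        [meta[METADATA_COLUMNS], pd.DataFrame(values, columns=names)], axis=1
    )
    table = table[np.repeat(keep_well, nfields)].reset_index(drop=True)
    return table, truth


def expected_well_means(
    design: ScreenDesign, params: SimulationParams, truth: GroundTruth
) -> pd.DataFrame:
    """Raw-scale expected value per (well, feature), for verification.

    Only the deterministic part (mu + scale * shift); random effects have
    mean zero.  Requires the same seed as the simulation so that the
    per-feature baselines, scales, the affected mask and the off-target
    directions are reproduced.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    nf = params.n_features
    names = feature_names(nf)
    wells = screen_layout(design)

    n_affected = round(params.affected_fraction * nf)
    affected_idx = rng.choice(nf, size=n_affected, replace=False)
    g = np.zeros(nf)
    g[affected_idx] = 1.0
    _assign_reversion(design.compound_ids, params, rng)
    directions = {}
    for cid in design.compound_ids:
        d = rng.standard_normal(nf)
        directions[cid] = d / np.linalg.norm(d)
    mu = rng.normal(0.0, 2.0, nf)
    scale = rng.uniform(0.5, 2.0, nf)

    top_dose = max(design.concentrations)
    out = np.zeros((len(wells), nf))
    for i, row in wells.iterrows():
        shift = np.zeros(nf)
        if row["genotype"] == "KO":
            t = row["treatment"]
            if t in ("VEHICLE", "UNTREATED"):
                shift = params.delta * g
            else:
                r_eff = truth.rho[t] * (
                    row["concentration_nM"] / top_dose if params.dose_scaling else 1.0
                )
                shift = (1.0 - r_eff) * params.delta * g + truth.eta[t] * directions[t]
        out[i] = mu + scale * shift
    return pd.concat(
        [wells.reset_index(drop=True), pd.DataFrame(out, columns=names)], axis=1
    )
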