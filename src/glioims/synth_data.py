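"""Synthetic study-condition generators.

Two generators stand in for the data the analysis needs:

* :func:`simulate_section` produces an imaging-MS section (pixel grid of
  centroided spectra) with a planted proliferative region, a white-matter-like
  parenchyma region and matrix-only background pixels. Compositions are taken
  from the packaged study profiles, which encode the published class fold
  changes between study arms (healthy/GBM x vehicle/TMZ) and the within-class
  species mole percentages of the proliferative cluster.
* :func:`simulate_expression_study` produces a genes x samples expression
  matrix with planted co-expression modules aligned to transcriptomic
  subtypes, methylation betas anticorrelated with expression for selected
  genes, and survival times whose hazard depends on selected gene expression.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; equal seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .constants import SCAN_RANGE
from .ims_proc import IMSDataset
from .lipid_chem import (
    LipidClass,
    LipidSpecies,
    Panel,
    parse_shorthand,
)

__all__ = [
    "CompositionProfile",
    "NoiseModel",
    "Region",
    "SectionSpec",
    "PlantedModule",
    "ExpressionStudySpec",
    "ExpressionStudy",
    "SUBTYPES",
    "load_composition_config",
    "make_study_config",
    "default_section_spec",
    "simulate_section",
    "default_study_spec",
    "simulate_expression_study",
]

SUBTYPES = ("Classical", "Mesenchymal", "Proneural", "Neural", "Normal")

ARM_NAMES = ("healthy_vehicle", "gbm_vehicle", "healthy_tmz", "gbm_tmz")


# --------------------------------------------------------------------------
# lipid composition profiles
# --------------------------------------------------------------------------

@dataclass
class CompositionProfile:
    """Expected composition of one tissue population.

    ``class_shares`` maps polarity -> {class: share of TIC} (sums to 1 per
    polarity); ``species_fractions`` maps class -> {species: mole fraction}
    (sums to 1 per class).
    """

    name: str
    class_shares: dict[str, dict[LipidClass, float]]
    species_fractions: dict[LipidClass, dict[LipidSpecies, float]]

    def __post_init__(self) -> None:
        for pol, shares in self.class_shares.items():
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}: {pol} class shares sum to {total}, not 1"
                )
            if any(w <= 0 for w in shares.values()):
                raise ValueError(f"{self.name}: class shares must be positive")
        for cls, fractions in self.species_fractions.items():
            total = sum(fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}/{cls.value}: species fractions sum to {total}"
                )

    def expected_intensity(self, panel: Panel, polarity: str) -> np.ndarray:
        """Noise-free intensity of each panel entry of the given polarity,
        aligned to ``panel.subset(polarity).entries`` order."""
        shares = self.class_shares[polarity]
        sub = panel.subset(polarity)
        out = np.zeros(len(sub))
        for i, entry in enumerate(sub.entries):
            cls = entry.species.lipid_class
            if cls not in shares:
                continue
            frac = self.species_fractions.get(cls, {}).get(entry.species, 0.0)
            out[i] = shares[cls] * frac
        return out

    def class_share(self, lipid_class: LipidClass) -> float:
        for shares in self.class_shares.values():
            if lipid_class in shares:
                return shares[lipid_class]
        raise KeyError(lipid_class.value)

    def species_molpct(self, species: LipidSpecies) -> float:
        return 100.0 * self.species_fractions[species.lipid_class][species]


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic acquisition model for simulated sections."""

    sigma: float = 0.3                 # log-normal log-sd of peak intensity
    mz_jitter_ppm: float = 3.0         # uniform half-width of mass error
    background_tic_fraction: float = 0.01
    background_peaks: tuple[int, int] = (5, 20)


def _class_species(panel: Panel, lipid_class: LipidClass) -> list[LipidSpecies]:
    return sorted(
        {e.species for e in panel.by_class(lipid_class)},
        key=lambda s: (s.total_carbons, s.double_bonds, s.hydroxylation.value),
    )


def _expand_species_pct(
    named_pct: Mapping[str, float],
    lipid_class: LipidClass,
    panel: Panel,
) -> dict[LipidSpecies, float]:
    """Turn named mole-% values into full per-species fractions: species of
    the class not named share the remaining percentage uniformly."""
    species = _class_species(panel, lipid_class)
    prefix = "" if lipid_class is LipidClass.PE_P else " "
    named = {
        parse_shorthand(f"{lipid_class.value}{prefix}{chain}"): pct
        for chain, pct in named_pct.items()
    }
    unknown = set(named) - set(species)
    if unknown:
        raise ValueError(
            f"{lipid_class.value}: species not in panel: "
            f"{[s.shorthand for s in unknown]}"
        )
    remainder = 100.0 - sum(named.values())
    others = [s for s in species if s not in named]
    if remainder < -1e-9:
        raise ValueError(f"{lipid_class.value}: named percentages exceed 100")
    if others:
        per_other = remainder / len(others)
    elif abs(remainder) > 1e-6:
        raise ValueError(f"{lipid_class.value}: percentages must sum to 100")
    fractions = {}
    for s in species:
        pct = named.get(s, per_other if others else 0.0)
        fractions[s] = pct / 100.0
    return fractions


def _arm_class_shares(
    baseline: dict[str, dict[LipidClass, float]],
    increase: Mapping[str, float],
    decrease: Mapping[str, float],
    held: Sequence[str],
) -> dict[str, dict[LipidClass, float]]:
    """Apply fold changes to the baseline shares per polarity.

    Changed classes are scaled by their fold factor, held classes keep their
    baseline share, and the remaining classes absorb the residual pro rata so
    each polarity still sums to 1 (so configured folds are exact share
    ratios).
    """
    folds = {LipidClass(k): v for k, v in increase.items()}
    folds.update({LipidClass(k): 1.0 / v for k, v in decrease.items()})
    held_cls = {LipidClass(k) for k in held}
    out: dict[str, dict[LipidClass, float]] = {}
    for pol, shares in baseline.items():
        new = {}
        fixed_total = 0.0
        absorbers = []
        for cls, share in shares.items():
            if cls in folds:
                new[cls] = share * folds[cls]
                fixed_total += new[cls]
            elif cls in held_cls:
                new[cls] = share
                fixed_total += share
            else:
                absorbers.append(cls)
        residual = 1.0 - fixed_total
        absorber_total = sum(shares[c] for c in absorbers)
        if residual <= 0 or (absorbers and absorber_total <= 0):
            raise ValueError(
                f"fold changes leave no room for unchanged classes in {pol}"
            )
        for cls in absorbers:
            new[cls] = shares[cls] * residual / absorber_total
        out[pol] = new
    return out


def load_composition_config(
    path: str | Path | None = None, panel: Panel | None = None
) -> tuple[dict[str, CompositionProfile], NoiseModel]:
    """Load composition profiles (study arms + bulk parenchyma) and the noise
    defaults from YAML; with no path, use the packaged study configuration."""
    from .lipid_chem import default_panel

    if path is None:
        text = (resources.files("glioims.data") / "composition_study.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    panel = panel or default_panel()

    base_shares = {
        name: {
            pol: {LipidClass(k): float(v) for k, v in shares.items()}
            for pol, shares in block.items()
        }
        for name, block in cfg["class_shares"].items()
    }
    all_shares: dict[str, dict[str, dict[LipidClass, float]]] = dict(base_shares)
    for arm, spec in (cfg.get("class_fold_changes") or {}).items():
        base = all_shares[spec.get("base", "healthy_vehicle")]
        all_shares[arm] = _arm_class_shares(
            base, spec.get("increase") or {}, spec.get("decrease") or {},
            spec.get("held") or [],
        )

    pct_cfg = cfg["species_pct"]
    common = pct_cfg.get("common", {})

    def arm_species_pct(name: str) -> dict[str, dict[str, float]]:
        block = pct_cfg.get(name, {})
        if "base" in block:
            merged = {k: dict(v) for k, v in arm_species_pct(block["base"]).items()}
            for cls_name, overrides in (block.get("overrides") or {}).items():
                merged.setdefault(cls_name, {}).update(overrides)
            return merged
        out = {k: dict(v) for k, v in common.items()}
        out.update({k: dict(v) for k, v in block.items() if k != "base"})
        return out

    profiles = {}
    for name, shares in all_shares.items():
        pct = arm_species_pct(name)
        fractions = {}
        for pol_shares in shares.values():
            for cls in pol_shares:
                fractions[cls] = _expand_species_pct(pct.get(cls.value, {}), cls, panel)
        profiles[name] = CompositionProfile(
            name=name, class_shares=shares, species_fractions=fractions
        )

    noise_cfg = cfg.get("noise") or {}
    noise = NoiseModel(
        sigma=float(noise_cfg.get("sigma", 0.3)),
        mz_jitter_ppm=float(noise_cfg.get("mz_jitter_ppm", 3.0)),
        background_tic_fraction=float(noise_cfg.get("background_tic_fraction", 0.01)),
        background_peaks=tuple(noise_cfg.get("background_peaks", (5, 20))),
    )
    return profiles, noise


def make_study_config(
    panel: Panel | None = None,
) -> tuple[dict[str, CompositionProfile], NoiseModel, "ExpressionStudySpec"]:
    """The packaged study configuration: composition profiles for the four
    study arms plus bulk parenchyma, acquisition noise defaults, and the
    expression/methylation/survival study specification."""
    profiles, noise = load_composition_config(panel=panel)
    return profiles, noise, default_study_spec()


# --------------------------------------------------------------------------
# IMS section simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    region_id: str
    mask: np.ndarray          # 2-D bool, grid shaped
    composition_id: str


@dataclass
class SectionSpec:
    """Layout and provenance of one simulated section."""

    condition: str            # healthy | gbm
    treatment: str            # vehicle | tmz
    polarity: str             # negative | positive
    grid: tuple[int, int]
    regions: list[Region]
    seed: int
    section_id: str = ""

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if rows < 20 or cols < 20:
            raise ValueError("grid must be at least 20x20")
        covered = np.zeros(self.grid, dtype=int)
        for region in self.regions:
            if region.mask.shape != self.grid:
                raise ValueError(
                    f"region {region.region_id}: mask shape {region.mask.shape} "
                    f"does not match grid {self.grid}"
                )
            covered += region.mask.astype(int)
        if covered.max() > 1:
            raise ValueError("region masks must be disjoint")
        if not self.section_id:
            self.section_id = f"{self.condition}_{self.treatment}_{self.seed}"

    @property
    def background_mask(self) -> np.ndarray:
        covered = np.zeros(self.grid, dtype=bool)
        for region in self.regions:
            covered |= region.mask
        return ~covered

    @property
    def background_fraction(self) -> float:
        return float(self.background_mask.mean())


def default_section_spec(
    condition: str,
    treatment: str,
    polarity: str = "negative",
    grid: tuple[int, int] = (60, 60),
    seed: int = 0,
    roi_fraction: float = 0.2,
) -> SectionSpec:
    """Standard section layout: an elliptical tissue area on a matrix-only
    background (about 20% of pixels), containing one compact proliferative
    blob (the MKI67+ proxy, ``roi_fraction`` of tissue pixels) surrounded by
    bulk parenchyma."""
    rows, cols = grid
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    tissue = (((rr - cy) / (rows / 2)) ** 2
              + ((cc - cx) / (cols / 2)) ** 2) <= 1.0

    # compact blob: disc centred at a jittered interior point, radius chosen
    # to cover roughly roi_fraction of the tissue pixels
    n_target = roi_fraction * tissue.sum()
    radius = np.sqrt(n_target / np.pi)
    by = cy + rng.uniform(-0.15, 0.15) * rows
    bx = cx + rng.uniform(-0.15, 0.15) * cols
    blob = (((rr - by) ** 2 + (cc - bx) ** 2) <= radius**2) & tissue

    condition = condition.lower()
    treatment = treatment.lower()
    arm = f"{condition if condition != 'gbm' else 'gbm'}_{treatment}"
    regions = [
        Region("proliferative", blob, arm),
        Region("parenchyma", tissue & ~blob, "bulk_tissue"),
    ]
    return SectionSpec(
        condition=condition,
        treatment=treatment,
        polarity=polarity,
        grid=grid,
        regions=regions,
        seed=seed,
    )


def roi_mask_of(spec: SectionSpec, region_id: str | None = None) -> np.ndarray:
    """ROI mask of the named region (default: the proliferative region if
    present, else the first region)."""
    if region_id is None:
        ids = [r.region_id for r in spec.regions]
        region_id = "proliferative" if "proliferative" in ids else ids[0]
    for region in spec.regions:
        if region.region_id == region_id:
            return region.mask.copy()
    raise KeyError(region_id)


def simulate_section(
    spec: SectionSpec,
    profiles: Mapping[str, CompositionProfile],
    panel: Panel,
    noise: NoiseModel = NoiseModel(),
) -> tuple[IMSDataset, np.ndarray]:
    """Simulate one section and return it with its ROI mask.

    Each tissue pixel carries one centroided peak per panel species of the
    section's polarity: m/z is the theoretical value with uniform ppm jitter,
    intensity is ``class_share x species_fraction x LogNormal(0, sigma)``.
    Background pixels carry a few low-intensity chemical-noise peaks at
    uniform random m/z. Fully reproducible from ``spec.seed``.
    """
    for region in spec.regions:
        if region.composition_id not in profiles:
            raise ValueError(
                f"region {region.region_id}: unknown composition "
                f"{region.composition_id!r}"
            )
    rng = np.random.default_rng(spec.seed)
    sub = panel.subset(spec.polarity)
    if len(sub) == 0:
        raise ValueError(f"panel has no {spec.polarity}-mode entries")
    panel_mz = sub.mzs

    rows, cols = spec.grid
    region_grid = np.full(spec.grid, "", dtype=object)
    for region in spec.regions:
        region_grid[region.mask] = region.composition_id

    base_by_comp = {
        comp_id: profiles[comp_id].expected_intensity(panel, spec.polarity)
        for comp_id in {r.composition_id for r in spec.regions}
    }

    lo, hi = SCAN_RANGE[spec.polarity]
    coords, mzs, intensities = [], [], []
    for y in range(rows):
        for x in range(cols):
            comp_id = region_grid[y, x]
            if comp_id:
                base = base_by_comp[comp_id]
                if noise.sigma > 0:
                    inten = base * np.exp(noise.sigma * rng.standard_normal(base.size))
                else:
                    inten = base.copy()
                if noise.mz_jitter_ppm > 0:
                    jitter = rng.uniform(-noise.mz_jitter_ppm,
                                         noise.mz_jitter_ppm, panel_mz.size)
                    mz = panel_mz * (1.0 + jitter * 1e-6)
                else:
                    mz = panel_mz.copy()
                present = inten > 0
                mz, inten = mz[present], inten[present]
            else:
                n_peaks = rng.integers(noise.background_peaks[0],
                                       noise.background_peaks[1] + 1)
                mz = rng.uniform(lo, hi, n_peaks)
                inten = rng.uniform(0.0, 2.0 * noise.background_tic_fraction / n_peaks,
                                    n_peaks)
            order = np.argsort(mz)
            coords.append((x, y))
            mzs.append(mz[order])
            intensities.append(inten[order])

    dataset = IMSDataset(
        coords=np.array(coords),
        mzs=mzs,
        intensities=intensities,
        metadata={
            "condition": spec.condition,
            "treatment": spec.treatment,
            "section_id": spec.section_id,
            "polarity": spec.polarity,
            "lateral_resolution_um": 50.0,
            "seed": spec.seed,
        },
    )
    return dataset, roi_mask_of(spec)


# --------------------------------------------------------------------------
# expression / methylation / survival study
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedModule:
    name: str
    genes: tuple[str, ...]
    subtype: str
    effect: float             # z-units: subtype shift of the module activity


@dataclass
class ExpressionStudySpec:
    """Specification of the synthetic transcriptome/methylation/survival study."""

    n_genes: int
    samples_per_subtype: dict[str, int]
    modules: list[PlantedModule]
    survival_coefs: dict[str, float]        # gene -> log-hazard per z-unit
    methylation_genes: tuple[str, ...]      # genes with beta ~ -expression
    methylation_slope: float = 2.0
    gene_noise_sd: float = 0.5
    baseline_median_days: float = 600.0
    censor_horizon_days: float = 1825.0
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.modules:
            if seen & set(m.genes):
                raise ValueError("planted module gene sets must be disjoint")
            seen |= set(m.genes)
            if m.subtype not in self.samples_per_subtype:
                raise ValueError(f"module {m.name}: unknown subtype {m.subtype}")
        if any(n < 3 for n in self.samples_per_subtype.values()):
            raise ValueError("at least 3 samples per subtype required")
        if not all(np.isfinite(list(self.survival_coefs.values()) or [0.0])):
            raise ValueError("survival coefficients must be finite")


@dataclass
class ExpressionStudy:
    """Genes x samples expression with subtype labels, methylation betas and
    survival records (overall and disease-specific event columns)."""

    expr: pd.DataFrame            # genes x samples
    subtypes: pd.Series           # per sample
    methylation: pd.DataFrame     # genes x samples, beta in [0, 1]
    survival: pd.DataFrame        # sample, time, event, dss_event, subtype
    planted_modules: dict[str, str] = field(default_factory=dict)  # gene -> module


# module gene anchors named after the lipid-enzyme signature of each subtype
_MODULE_ANCHORS = {
    "M1": ("Classical", ("PLA2G5", "FABP7", "ELOVL2")),
    "M2": ("Mesenchymal", ("PLA2G2A", "FABP5", "PTGS2", "ALOX15B", "ALOX5AP")),
    "M3": ("Neural", ("INPP5F", "DGKB")),
    "M4": ("Proneural", ("UGT8",)),
}


def default_study_spec(
    effect: float = 1.5,
    n_per_subtype: int = 20,
    n_genes: int = 300,
    module_size: int = 25,
    seed: int = 0,
) -> ExpressionStudySpec:
    """Paper-flavoured study: four planted modules anchored by the lipid-enzyme
    genes of each molecular subtype, hazard driven by the five genes reported
    as adverse for overall survival, and methylation coupled to expression for
    the three genes with subtype-dependent methylation."""
    modules = []
    counter = 0
    for name, (subtype, anchors) in _MODULE_ANCHORS.items():
        fillers = tuple(
            f"{name}G{counter + i:03d}" for i in range(module_size - len(anchors))
        )
        counter += module_size
        modules.append(PlantedModule(name, anchors + fillers, subtype, effect))
    return ExpressionStudySpec(
        n_genes=n_genes,
        samples_per_subtype={s: n_per_subtype for s in SUBTYPES},
        modules=modules,
        survival_coefs={g: np.log(2.0) for g in
                        ("PLA2G5", "FABP7", "ELOVL2", "PLA2G2A", "ALOX5AP")},
        methylation_genes=("PLA2G5", "FABP7", "ALOX5AP"),
        seed=seed,
    )


def simulate_expression_study(spec: ExpressionStudySpec) -> ExpressionStudy:
    """Draw one study realisation from the specification.

    Expression of a module gene is ``effect x (subtype indicator + module
    activity) + N(0, gene_noise_sd)``, where the module activity is a shared
    per-sample standard-normal factor; non-module genes are N(0, 1).
    Methylation betas for coupled genes are ``expit(-slope x z + noise)`` of
    the gene's expression z-score; survival is exponential with log-hazard
    ``sum(coef x z)`` and administrative censoring at the horizon.
    """
    rng = np.random.default_rng(spec.seed)

    samples, subtypes = [], []
    for subtype, n in spec.samples_per_subtype.items():
        for i in range(n):
            samples.append(f"{subtype[:4].upper()}_{i:03d}")
            subtypes.append(subtype)
    subtypes = pd.Series(subtypes, index=samples, name="subtype")
    n_samples = len(samples)

    module_genes = [g for m in spec.modules for g in m.genes]
    n_fill = spec.n_genes - len(module_genes)
    if n_fill < 0:
        raise ValueError("n_genes smaller than the planted module genes")
    genes = module_genes + [f"G{i:04d}" for i in range(n_fill)]

    expr = rng.standard_normal((spec.n_genes, n_samples))
    planted: dict[str, str] = {}
    for m in spec.modules:
        indicator = (subtypes.values == m.subtype).astype(float)
        activity = indicator + rng.standard_normal(n_samples)
        rows = [genes.index(g) for g in m.genes]
        noise = rng.standard_normal((len(rows), n_samples)) * spec.gene_noise_sd
        expr[rows, :] = m.effect * activity[None, :] + noise
        planted.update({g: m.name for g in m.genes})
    expr = pd.DataFrame(expr, index=genes, columns=samples)

    z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1) + 1e-12, axis=0)

    meth = expit(rng.normal(-1.0, 1.0, spec.n_genes)[:, None]
                 + rng.normal(0.0, 0.5, (spec.n_genes, n_samples)))
    meth = pd.DataFrame(meth, index=genes, columns=samples)
    for g in spec.methylation_genes:
        meth.loc[g] = expit(
            -spec.methylation_slope * z.loc[g].values
            + rng.normal(0.0, 0.5, n_samples)
        )

    log_hazard = np.zeros(n_samples)
    for g, coef in spec.survival_coefs.items():
        log_hazard += coef * z.loc[g].values
    h0 = np.log(2.0) / spec.baseline_median_days
    latent_time = rng.exponential(1.0 / h0, n_samples) * np.exp(-log_hazard)
    censor_time = rng.exponential(2.0 * spec.censor_horizon_days, n_samples)
    censor_time = np.minimum(censor_time, spec.censor_horizon_days)
    time = np.minimum(latent_time, censor_time)
    event = latent_time <= censor_time
    dss_event = event & (rng.random(n_samples) < 0.9)
    time = np.maximum(time, 1.0)

    survival = pd.DataFrame(
        {
            "sample": samples,
            "time": time,
            "event": event,
            "dss_event": dss_event,
            "subtype": subtypes.values,
        }
    ).set_index("sample")

    return ExpressionStudy(
        expr=expr,
        subtypes=subtypes,
        methylation=meth,
        survival=survival,
        planted_modules=planted,
    )
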