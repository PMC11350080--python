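"""Synthetic FTIR data with exported ground truth.

Generates the three kinds of input the analysis consumes, with the
statistical structure the pipeline assumes:

* a component library of Gaussian-band reference spectra over the
  fingerprint region (stand-ins for holocellulose monomer signatures,
  lignin variants, pectin, proteins);
* a bulk ATR genotype panel (5 easy- / 10 difficult-to-root genotypes,
  several replicate spectra each) with a planted group difference in one
  compound and rooting-percentage traits generated from that compound's
  weight, so screening ground truth is well defined;
* hyperspectral stem cross-section cubes: concentric rings (pith +
  vascular ring, shoot cortex, epidermis) plus dome-shaped root
  primordia subdivided into meristematic tip, root cap shell, root
  cortex and root vasculature — seven labelled regions, each with its
  own component mixing profile.

Every spectrum follows the EMSC forward model,
``s = a * (sum_j w_j K_j) + polynomial baseline + additive noise`` with
lognormal multiplicative scatter ``a``, so EMSC decomposition of
noiseless output recovers the truth to numerical precision. A fixed
seed determines every artifact byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .emsc import ComponentLibrary, EMSCModel, _legendre_terms
from .io_spectra import (
    TRAIT_NAMES,
    HyperCube,
    SampleMeta,
    SpectrumTable,
    WavenumberAxis,
)

__all__ = [
    "SynthConfig",
    "SyntheticTruth",
    "REGION_NAMES",
    "DEFAULT_REGION_PROFILES",
    "make_library",
    "make_panel",
    "make_cube",
    "make_cube_pair",
    "make_emsc_mixtures",
    "majority_region_map",
]

# Stream ids keep the named random substreams of one seed independent.
_STREAM_LIBRARY = 11
_STREAM_PANEL = 21
_STREAM_CUBE_A = 31
_STREAM_CUBE_B = 32
_STREAM_MIXTURES = 41

DEFAULT_COMPONENTS: tuple[tuple[str, str], ...] = (
    ("arabinose_hemicellulose", "hemicellulose_monomer"),
    ("galactose_hemicellulose", "hemicellulose_monomer"),
    ("mannose_hemicellulose", "hemicellulose_monomer"),
    ("xylose_hemicellulose", "hemicellulose_monomer"),
    ("cellulose", "cellulose"),
    ("lignin_g_rich", "lignin"),
    ("lignin_ohg_rich", "lignin"),
    ("pectin_galarha", "pectin"),
    ("protein_type_1", "protein"),
    ("protein_type_2", "protein"),
)

#: Functional tissue regions of a stem cross-section forming adventitious
#: roots; ids match the study's cluster numbering.
REGION_NAMES = {
    1: "epidermis",
    2: "cortex_shoot",
    3: "root_cap",
    4: "meristematic_tip",
    5: "vasculature_root",
    6: "cortex_root",
    7: "pith_vascular_ring",
}

# Mixing weights over the 10 default components, one profile per region.
# Deliberately contrastive (synthetic): hemicellulose monomer signatures
# elevated in root cap/meristem, lignin in vasculature and pith.
DEFAULT_REGION_PROFILES: dict[int, tuple[float, ...]] = {
    1: (0.30, 0.04, 0.04, 0.04, 0.24, 0.04, 0.02, 0.14, 0.10, 0.04),
    2: (0.05, 0.18, 0.16, 0.18, 0.16, 0.05, 0.03, 0.09, 0.05, 0.05),
    3: (0.07, 0.07, 0.18, 0.18, 0.12, 0.04, 0.02, 0.18, 0.07, 0.07),
    4: (0.14, 0.06, 0.10, 0.10, 0.08, 0.02, 0.02, 0.10, 0.22, 0.16),
    5: (0.04, 0.05, 0.07, 0.09, 0.28, 0.22, 0.10, 0.05, 0.05, 0.05),
    6: (0.11, 0.11, 0.08, 0.08, 0.22, 0.07, 0.03, 0.16, 0.07, 0.07),
    7: (0.04, 0.04, 0.07, 0.11, 0.27, 0.13, 0.14, 0.06, 0.06, 0.08),
}


@dataclass
class SynthConfig:
    """All knobs of the generator; the seed fully determines the output."""

    seed: int = 0
    # axis (cm^-1); 6 cm^-1 matches the imaging spectral resolution
    lo: float = 800.0
    hi: float = 1800.0
    step: float = 6.0
    # library
    n_components: int = 10
    bands_per_component: tuple[int, int] = (3, 8)
    min_cosine_distance: float = 0.05  # pairwise cosine similarity < 0.95
    # distortions (EMSC forward model)
    noise_sd: float = 0.001
    scatter_sd: float = 0.15  # lognormal sigma of the multiplicative scale
    # residual baseline after instrument-level correction: offset / tilt /
    # curvature coefficients (absorbance units on the Legendre basis)
    baseline_coeff_sd: tuple[float, ...] = (0.002, 0.001, 0.001)
    # imaging
    layout: str = "rings_with_primordia"  # | blocks | uniform
    image_size: tuple[int, int] = (96, 96)
    n_primordia: int = 2
    n_blocks: int = 2
    pixel_size_um: float = 11.0
    region_profiles: dict[int, tuple[float, ...]] | None = None
    planted_effects: tuple[tuple[int, str, float], ...] = ()
    # bulk genotype panel
    n_easy: int = 5
    n_difficult: int = 10
    replicates: int = 6
    genotype_sd: float = 0.15  # lognormal sigma of per-genotype weights
    planted_base_share: float = 0.05
    panel_planted: tuple[tuple[str, float], ...] = (
        ("mannose_hemicellulose", 1.4),
    )
    trait_link_compound: str = "mannose_hemicellulose"
    trait_link_r: float = 0.8
    trait_sigmoid_gain: float = 0.8

    def axis(self) -> WavenumberAxis:
        n = int(np.floor((self.hi - self.lo) / self.step)) + 1
        values = self.lo + self.step * np.arange(n)
        return WavenumberAxis(values[::-1])


@dataclass
class SyntheticTruth:
    """Ground truth accompanying every generated artifact."""

    region_labels: np.ndarray | None = None  # rows x cols ids, 0 = background
    region_profiles: dict[int, np.ndarray] | None = None
    true_coefficients: np.ndarray | None = None  # per pixel/sample weights
    true_scales: np.ndarray | None = None  # multiplicative a
    true_baselines: np.ndarray | None = None  # baseline coefficients
    genotype_weights: pd.DataFrame | None = None  # genotype x compound
    true_traits: pd.DataFrame | None = None  # genotype x trait
    planted_effects: list = field(default_factory=list)

    def save(self, directory: str | Path, stem: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if self.region_labels is not None:
            np.savetxt(
                directory / f"{stem}_region_labels.csv",
                self.region_labels,
                fmt="%d",
                delimiter=",",
            )
        if self.genotype_weights is not None:
            self.genotype_weights.to_csv(directory / f"{stem}_genotype_weights.csv")
        if self.true_traits is not None:
            self.true_traits.to_csv(directory / f"{stem}_traits.csv")
        summary = {
            "planted_effects": [list(e) for e in self.planted_effects],
            "region_profiles": {
                str(k): list(map(float, v)) for k, v in (self.region_profiles or {}).items()
            },
        }
        (directory / f"{stem}_truth.json").write_text(json.dumps(summary, indent=2))


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _component_names(config: SynthConfig) -> list[tuple[str, str]]:
    if config.n_components <= len(DEFAULT_COMPONENTS):
        return list(DEFAULT_COMPONENTS[: config.n_components])
    extra = [
        (f"component_{i:02d}", "other")
        for i in range(len(DEFAULT_COMPONENTS), config.n_components)
    ]
    return list(DEFAULT_COMPONENTS) + extra


def _gaussian_component(
    rng: np.random.Generator, axis: np.ndarray, n_bands: tuple[int, int]
) -> np.ndarray:
    k = int(rng.integers(n_bands[0], n_bands[1] + 1))
    centers = rng.uniform(axis.min() + 20.0, axis.max() - 20.0, size=k)
    widths = rng.uniform(8.0, 40.0, size=k)
    heights = rng.uniform(0.2, 1.0, size=k)
    spectrum = np.zeros_like(axis)
    for c, w, h in zip(centers, widths, heights):
        spectrum += h * np.exp(-0.5 * ((axis - c) / w) ** 2)
    return spectrum / np.linalg.norm(spectrum)


def make_library(config: SynthConfig) -> ComponentLibrary:
    """Seeded Gaussian-band component spectra, pairwise cosine < 0.95."""
    rng = _rng(config, _STREAM_LIBRARY)
    axis = config.axis()
    v = axis.values
    names_cats = _component_names(config)
    max_cos = 1.0 - config.min_cosine_distance
    spectra: list[np.ndarray] = []
    for _ in names_cats:
        for attempt in range(100):
            cand = _gaussian_component(rng, v, config.bands_per_component)
            if all(float(cand @ s) < max_cos for s in spectra):
                spectra.append(cand)
                break
        else:
            raise RuntimeError(
                "could not generate a sufficiently distinct component in 100 attempts"
            )
    return ComponentLibrary(
        axis,
        [n for n, _ in names_cats],
        [c for _, c in names_cats],
        np.vstack(spectra),
    )


def _distort(
    rng: np.random.Generator,
    chem: np.ndarray,
    axis: WavenumberAxis,
    config: SynthConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply scatter/baseline/noise; returns (spectra, a, baseline coeffs)."""
    n = chem.shape[0]
    a = rng.lognormal(mean=0.0, sigma=config.scatter_sd, size=n)
    sds = np.asarray(config.baseline_coeff_sd, dtype=float)
    P = _legendre_terms(axis, len(sds) - 1)
    b = rng.normal(0.0, 1.0, size=(n, sds.size)) * sds
    noise = rng.normal(0.0, config.noise_sd, size=chem.shape)
    spectra = a[:, None] * chem + b @ P.T + noise
    return spectra, a, b


def make_panel(
    config: SynthConfig, library: ComponentLibrary | None = None
) -> tuple[SpectrumTable, SyntheticTruth]:
    """Bulk ATR genotype panel with planted group effects and linked traits.

    Per genotype, compound weights are a fixed base profile perturbed by
    lognormal genotype-to-genotype variation; easy-to-root genotypes get
    the planted multipliers. The three rooting percentages are
    logistic-squashed linear functions of the designated compound's
    (standardized) weight plus noise, targeting a correlation of
    ``trait_link_r``.
    """
    if library is None:
        library = make_library(config)
    rng = _rng(config, _STREAM_PANEL)
    J = library.n_components
    names = library.names

    base = rng.uniform(0.8, 1.2, size=J)
    base /= base.sum()
    planted_names = [n for n, _ in config.panel_planted]
    if config.trait_link_compound in names:
        j_link = names.index(config.trait_link_compound)
        others = base.sum() - base[j_link]
        base[j_link] = config.planted_base_share
        scale = (1.0 - config.planted_base_share) / others
        for j in range(J):
            if j != j_link:
                base[j] *= scale

    genotypes = [f"G{i + 1:02d}" for i in range(config.n_easy + config.n_difficult)]
    group_of = {
        g: ("easy" if i < config.n_easy else "difficult")
        for i, g in enumerate(genotypes)
    }
    weights = {}
    for g in genotypes:
        w = base * np.exp(rng.normal(0.0, config.genotype_sd, size=J))
        if group_of[g] == "easy":
            for name, mult in config.panel_planted:
                if name in names:
                    w[names.index(name)] *= mult
        weights[g] = w
    wdf = pd.DataFrame(weights, index=names).T

    # Traits: logistic-squashed linear function of the link compound weight.
    link = wdf[config.trait_link_compound].to_numpy()
    z = (link - link.mean()) / link.std(ddof=0)
    r = config.trait_link_r
    traits = {}
    for trait in TRAIT_NAMES:
        eps = rng.normal(0.0, 1.0, size=len(genotypes))
        latent = r * z + np.sqrt(1.0 - r * r) * eps
        traits[trait] = np.clip(
            100.0 / (1.0 + np.exp(-config.trait_sigmoid_gain * latent)), 0.0, 100.0
        )
    tdf = pd.DataFrame(traits, index=genotypes)

    chem_rows = []
    meta = []
    coeff_rows = []
    for g in genotypes:
        for rep in range(config.replicates):
            chem_rows.append(wdf.loc[g].to_numpy() @ library.spectra)
            coeff_rows.append(wdf.loc[g].to_numpy())
            meta.append(
                SampleMeta(
                    sample_id=f"{g}_r{rep + 1}",
                    genotype=g,
                    group=group_of[g],
                    traits={t: float(tdf.loc[g, t]) for t in TRAIT_NAMES},
                )
            )
    chem = np.vstack(chem_rows)
    spectra, a, b = _distort(rng, chem, library.axis, config)
    table = SpectrumTable(library.axis, spectra, meta)
    truth = SyntheticTruth(
        true_coefficients=np.vstack(coeff_rows),
        true_scales=a,
        true_baselines=b,
        genotype_weights=wdf,
        true_traits=tdf,
        planted_effects=[
            ("easy", name, mult) for name, mult in config.panel_planted
        ],
    )
    return table, truth


# ---------------------------------------------------------------------------
# Spatial layouts
# ---------------------------------------------------------------------------


def _paint_rings_with_primordia(config: SynthConfig) -> np.ndarray:
    """Region-id image: concentric stem rings + primordium domes."""
    rows, cols = config.image_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    radius = min(rows, cols) / 2.0
    dist = np.hypot(rr - cy, cc - cx)

    stem_r = 0.92 * radius
    epi_r = 0.79 * radius
    pith_r = 0.375 * radius

    labels = np.zeros((rows, cols), dtype=int)
    labels[dist <= stem_r] = 2  # shoot cortex fills the stem...
    labels[dist <= pith_r] = 7  # ...pith + vascular ring core
    labels[(dist > epi_r) & (dist <= stem_r)] = 1  # epidermis rim

    rng = _rng(config, 51)  # dome placement stream
    base_angle = rng.uniform(0.0, 2.0 * np.pi)
    dome_r = 0.27 * radius
    dome_c = 0.58 * radius
    if dome_c + dome_r > stem_r + 2 or dome_r < 4:
        raise ValueError("image too small for primordium dome placement")
    for i in range(config.n_primordia):
        angle = base_angle + 2.0 * np.pi * i / config.n_primordia
        dy, dx = np.sin(angle), np.cos(angle)
        oy, ox = cy + dome_c * dy, cx + dome_c * dx
        d = np.hypot(rr - oy, cc - ox)
        u = (rr - oy) * dy + (cc - ox) * dx  # outward coordinate
        dome = d <= dome_r
        labels[dome] = 6  # root cortex (default inside dome)
        labels[dome & (d <= 0.31 * dome_r)] = 5  # root vasculature core
        outer = dome & (u > 0)
        labels[outer & (d > 0.46 * dome_r) & (d <= 0.77 * dome_r)] = 4  # meristem
        labels[outer & (d > 0.77 * dome_r)] = 3  # root cap shell
    return labels


def _paint_blocks(config: SynthConfig) -> np.ndarray:
    rows, cols = config.image_size
    labels = np.zeros((rows, cols), dtype=int)
    edges = np.linspace(0, cols, config.n_blocks + 1).astype(int)
    for i in range(config.n_blocks):
        labels[:, edges[i] : edges[i + 1]] = i + 1
    return labels


def _resolve_profiles(
    config: SynthConfig, library: ComponentLibrary, region_ids: list[int]
) -> dict[int, np.ndarray]:
    if config.region_profiles is not None:
        profiles = {k: np.asarray(v, float) for k, v in config.region_profiles.items()}
    elif library.n_components == len(DEFAULT_COMPONENTS):
        profiles = {k: np.array(v) for k, v in DEFAULT_REGION_PROFILES.items()}
    else:
        raise ValueError(
            "region_profiles must be supplied when the library is not the default"
        )
    for rid in region_ids:
        if rid not in profiles:
            # blocks/uniform layouts reuse the ring profiles cyclically
            profiles[rid] = np.array(
                list(DEFAULT_REGION_PROFILES.values())[
                    (rid - 1) % len(DEFAULT_REGION_PROFILES)
                ]
            )
        if np.any(profiles[rid] < 0):
            raise ValueError(f"negative mixing weight in region {rid}")
        if profiles[rid].size != library.n_components:
            raise ValueError(f"profile for region {rid} has wrong length")
    return profiles


def make_cube(
    config: SynthConfig,
    library: ComponentLibrary | None = None,
    stream: int = _STREAM_CUBE_A,
) -> tuple[HyperCube, SyntheticTruth]:
    """Hyperspectral tissue-section cube plus ground-truth labels.

    ``planted_effects`` entries (region, component, multiplier) scale a
    component's mixing weight within a region; background pixels
    (label 0) are masked.
    """
    if library is None:
        library = make_library(config)
    if config.layout == "rings_with_primordia":
        labels = _paint_rings_with_primordia(config)
    elif config.layout == "blocks":
        labels = _paint_blocks(config)
    elif config.layout == "uniform":
        labels = np.ones(config.image_size, dtype=int)
    else:
        raise ValueError(f"unknown layout {config.layout!r}")

    region_ids = sorted(int(r) for r in np.unique(labels) if r > 0)
    profiles = _resolve_profiles(config, library, region_ids)
    for region, component, mult in config.planted_effects:
        if component not in library.names:
            raise ValueError(f"unknown planted component {component!r}")
        if region in profiles:
            profiles[region] = profiles[region].copy()
            profiles[region][library.names.index(component)] *= mult

    rows, cols = labels.shape
    J = library.n_components
    coeffs = np.zeros((rows, cols, J))
    for rid in region_ids:
        coeffs[labels == rid] = profiles[rid]
    mask = labels > 0

    rng = _rng(config, stream)
    chem_flat = coeffs.reshape(-1, J) @ library.spectra
    spectra, a, b = _distort(rng, chem_flat, library.axis, config)
    data = spectra.reshape(rows, cols, -1)

    cube = HyperCube(library.axis, data, mask, config.pixel_size_um)
    truth = SyntheticTruth(
        region_labels=labels,
        region_profiles=profiles,
        true_coefficients=coeffs,
        true_scales=a.reshape(rows, cols),
        true_baselines=b.reshape(rows, cols, -1),
        planted_effects=list(config.planted_effects),
    )
    return cube, truth


def make_cube_pair(
    config: SynthConfig,
    planted_effects: tuple[tuple[int, str, float], ...] = ((3, "mannose_hemicellulose", 1.5),),
    library: ComponentLibrary | None = None,
) -> tuple[
    tuple[HyperCube, SyntheticTruth], tuple[HyperCube, SyntheticTruth]
]:
    """Two genotype cubes sharing geometry: a reference and an effect cube.

    The first cube has no planted effects (the reference genotype); the
    second applies ``planted_effects``. Noise streams are independent.
    """
    if library is None:
        library = make_library(config)
    cfg_a = replace(config, planted_effects=())
    cfg_b = replace(config, planted_effects=tuple(planted_effects))
    pair_a = make_cube(cfg_a, library, stream=_STREAM_CUBE_A)
    pair_b = make_cube(cfg_b, library, stream=_STREAM_CUBE_B)
    return pair_a, pair_b


def make_emsc_mixtures(
    model: EMSCModel,
    n: int,
    seed: int,
    snr_db: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spectra drawn exactly from an EMSC design: s = design @ theta (+ noise).

    theta rows are (a, d_0..d_p, c_1..c_J) with a ~ U(0.8, 1.3),
    d ~ N(0, 0.02) and c ~ U(0, 1). With ``snr_db`` set, i.i.d. Gaussian
    noise is added at that per-spectrum signal-to-noise ratio (power).
    Returns (spectra, theta).
    """
    rng = np.random.default_rng([int(seed), _STREAM_MIXTURES])
    p = model.poly_order
    J = model.n_components
    a = rng.uniform(0.8, 1.3, size=(n, 1))
    d = rng.normal(0.0, 0.02, size=(n, p + 1))
    c = rng.uniform(0.0, 1.0, size=(n, J))
    theta = np.hstack([a, d, c])
    spectra = theta @ model.design.T
    if snr_db is not None:
        rms = np.sqrt(np.mean(spectra**2, axis=1, keepdims=True))
        noise_sd = rms * 10.0 ** (-snr_db / 20.0)
        spectra = spectra + rng.normal(0.0, 1.0, size=spectra.shape) * noise_sd
    return spectra, theta


def majority_region_map(
    cluster_labels: np.ndarray, region_labels: np.ndarray
) -> dict[int, int]:
    """Map each cluster id to the ground-truth region it mostly overlaps."""
    mapping = {}
    for c in np.unique(cluster_labels):
        if c == 0:
            continue
        regions = region_labels[(cluster_labels == c) & (region_labels > 0)]
        if regions.size:
            mapping[int(c)] = int(np.bincount(regions).argmax())
    return mapping
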