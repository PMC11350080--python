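"""End-to-end orchestration of the bulk and imaging analyses.

Two entry points mirror the two acquisition modes:

* :func:`run_bulk` — bulk ATR panel: read -> truncate to the fingerprint
  region -> vector normalize -> EMSC fit -> per-genotype relative
  absorbances -> compound screening table.
* :func:`run_imaging` — genotype pair of tissue-section cubes: shared
  preprocessing, joint hierarchical clustering (concatenated unmasked
  pixels, so cluster ids are comparable), per-cube EMSC component maps,
  and the per-(cluster, component) comparison table with significance
  verdicts.

Every output directory receives the resolved configuration (YAML) and a
machine-readable run manifest (input hashes, versions, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_cube
from .emsc import ComponentLibrary, build_model, fit_cube, fit_table
from .group_stats import compare_clusters, comparisons_to_frame
from .io_spectra import (
    HyperCube,
    SpectrumTable,
    background_mask,
    truncate_range,
    vector_normalize,
    write_envi,
)
from .screening import (
    genotype_groups_and_traits,
    genotype_mean_relative_absorbance,
    correlation_matrix,
    records_to_frame,
    screen_compounds,
)

__all__ = ["PipelineConfig", "run_bulk", "run_imaging"]

log = logging.getLogger("stemftir")


@dataclass
class PreprocessConfig:
    lo: float = 800.0
    hi: float = 1800.0
    normalize: bool = True
    # quantile of total fingerprint absorbance below which imaging pixels
    # are treated as background (ENVI files carry no tissue mask); None
    # keeps the cube's own mask
    background_quantile: float | None = None


@dataclass
class EMSCConfig:
    poly_order: int = 2
    solver: str = "ols"


@dataclass
class ClusterConfig:
    k: int = 7
    linkage: str = "ward"
    max_pixels: int = 20000
    tissue_names: dict = field(default_factory=dict)  # cluster id -> name


@dataclass
class StatsConfig:
    p_thresh: float = 0.001
    d_thresh: float = 0.8
    r2_thresh: float = 0.5


@dataclass
class ScreeningConfig:
    rpd_thresh: float = 3.0
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    emsc: EMSCConfig = field(default_factory=EMSCConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sections = {
            "preprocess": PreprocessConfig,
            "emsc": EMSCConfig,
            "clustering": ClusterConfig,
            "stats": StatsConfig,
            "screening": ScreeningConfig,
        }
        kwargs = {"seed": int(raw.get("seed", 0))}
        for name, klass in sections.items():
            kwargs[name] = klass(**(raw.get(name) or {}))
        return cls(**kwargs)


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _write_manifest(out_dir: Path, config: PipelineConfig, inputs: dict) -> None:
    manifest = {
        "stemftir_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "inputs": inputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    config.to_yaml(out_dir / "config.yaml")


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-24s %.2f s", name, t1 - t0)
    return t1


def run_bulk(
    table: SpectrumTable,
    library: ComponentLibrary,
    config: PipelineConfig,
    out_dir: str | Path,
):
    """Bulk ATR screening; returns the list of ScreeningRecord."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pp = config.preprocess
    t = time.perf_counter()
    table_t = truncate_range(table, pp.lo, pp.hi)
    lib_t = library.truncate(pp.lo, pp.hi)
    if pp.normalize:
        table_t = vector_normalize(table_t)
    t = _stage("preprocess", t)

    model = build_model(table_t, lib_t, poly_order=config.emsc.poly_order)
    fits = fit_table(model, table_t, solver=config.emsc.solver)
    t = _stage("emsc_fit", t)

    means = genotype_mean_relative_absorbance(table_t, fits)
    groups, traits = genotype_groups_and_traits(table_t)
    records = screen_compounds(
        means,
        groups,
        traits,
        rpd_thresh=config.screening.rpd_thresh,
        alpha=config.screening.alpha,
    )
    t = _stage("screening", t)

    records_to_frame(records).to_csv(out_dir / "screening.csv", index=False)
    means.to_csv(out_dir / "genotype_relative_absorbance.csv")
    corr = correlation_matrix(means, traits)
    corr.map(lambda rp: rp[0]).to_csv(out_dir / "correlations_r.csv")
    corr.map(lambda rp: rp[1]).to_csv(out_dir / "correlations_p.csv")
    _write_manifest(
        out_dir,
        config,
        {
            "n_samples": table.n_samples,
            "n_channels": len(table.axis),
            "absorbance_sha256": _sha(table.absorbance),
        },
    )
    log.info("screening records: %d (%d eligible)", len(records), sum(r.eligible for r in records))
    return records


def run_imaging(
    cube_a: HyperCube,
    cube_b: HyperCube,
    library: ComponentLibrary,
    config: PipelineConfig,
    out_dir: str | Path,
    write_maps: bool = False,
):
    """Imaging comparison of genotype pair (A vs reference B).

    Returns ((clusters_a, clusters_b), comparison records).
    """
    if cube_a.axis != cube_b.axis:
        raise ValueError("cube axes differ between genotypes")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pp = config.preprocess
    t = time.perf_counter()
    if pp.background_quantile is not None:
        masked = []
        for c in (cube_a, cube_b):
            mask = background_mask(c, pp.background_quantile, pp.lo, pp.hi)
            masked.append(HyperCube(c.axis, c.data, mask, c.pixel_size_um))
        cube_a, cube_b = masked
    cubes = [truncate_range(c, pp.lo, pp.hi) for c in (cube_a, cube_b)]
    if pp.normalize:
        cubes = [vector_normalize(c) for c in cubes]
    lib_t = library.truncate(pp.lo, pp.hi)
    t = _stage("preprocess", t)

    cc = config.clustering
    clusters_a, clusters_b = cluster_cube(
        cubes,
        k=cc.k,
        linkage=cc.linkage,
        max_pixels=cc.max_pixels,
        seed=config.seed,
        lo=pp.lo,
        hi=pp.hi,
    )
    t = _stage("joint_clustering", t)

    reference = np.vstack([c.masked_spectra() for c in cubes])
    model = build_model(reference, lib_t, poly_order=config.emsc.poly_order)
    fit_a = fit_cube(model, cubes[0], solver=config.emsc.solver)
    fit_b = fit_cube(model, cubes[1], solver=config.emsc.solver)
    t = _stage("emsc_maps", t)

    st = config.stats
    records = compare_clusters(
        fit_a,
        fit_b,
        clusters_a,
        clusters_b,
        thresholds=(st.p_thresh, st.d_thresh, st.r2_thresh),
    )
    t = _stage("cluster_comparison", t)

    frame = comparisons_to_frame(records)
    frame["tissue_name"] = frame["cluster"].map(
        lambda c: cc.tissue_names.get(c, cc.tissue_names.get(str(c), ""))
    )
    frame.to_csv(out_dir / "cluster_comparison.csv", index=False)

    summary_rows = []
    for name, res in (("a", clusters_a), ("b", clusters_b)):
        for c in range(1, res.k + 1):
            summary_rows.append(
                {
                    "cube": name,
                    "cluster": c,
                    "tissue_name": cc.tissue_names.get(c, cc.tissue_names.get(str(c), "")),
                    "area_px": int(res.cluster_areas[c - 1]),
                    "area_um2": res.area_um2(c),
                }
            )
    pd.DataFrame(summary_rows).to_csv(out_dir / "cluster_summary.csv", index=False)

    verdicts = {
        f"cluster{r.cluster}:{r.component}": r.verdict
        for r in records
    }
    (out_dir / "verdicts.json").write_text(json.dumps(verdicts, indent=2))

    for name, res in (("a", clusters_a), ("b", clusters_b)):
        np.savetxt(out_dir / f"labels_{name}.csv", res.labels, fmt="%d", delimiter=",")
        _save_label_png(res.labels, out_dir / f"labels_{name}.png")
    if write_maps:
        for name, (cube, fit) in (("a", (cubes[0], fit_a)), ("b", (cubes[1], fit_b))):
            maps = HyperCube(
                _component_axis_placeholder(len(fit.names)),
                fit.relative_absorbance,
                cube.mask,
                cube.pixel_size_um,
            )
            write_envi(maps, out_dir / f"component_maps_{name}.hdr")
    _write_manifest(
        out_dir,
        config,
        {
            "cube_a_sha256": _sha(cube_a.data),
            "cube_b_sha256": _sha(cube_b.data),
            "shape_a": list(cube_a.shape),
            "shape_b": list(cube_b.shape),
        },
    )
    n_sig = sum(r.verdict == "significant" for r in records)
    log.info("comparison records: %d (%d significant)", len(records), n_sig)
    return (clusters_a, clusters_b), records


def _component_axis_placeholder(n: int):
    # Component maps are not on a wavenumber axis; store descending band
    # indices as pseudo-wavenumbers inside the valid range so band j of
    # the written cube stays component j.
    from .io_spectra import WavenumberAxis

    return WavenumberAxis(800.0 + np.arange(n, dtype=float)[::-1])


def _save_label_png(labels: np.ndarray, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4), dpi=120)
    ax.imshow(labels, cmap="tab10", interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
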